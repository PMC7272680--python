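"""Group-wise interregional correlation matrices and their binarization.

Regional activity tables hold one row per subject with metadata columns
(``subject_id``, ``treatment``, ``age``, ``sex``) followed by one density
column (cells/mm^2) per brain region.  Within each group of subjects,
every unordered pair of regions is correlated across subjects (Pearson),
two-tailed p-values are obtained from the exact t transform, and the
(r, p) matrices are binarized with a dual threshold: an edge requires
both statistical significance at ``alpha_level`` and a correlation of at
least ``r_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import GroupTooSmallError, SchemaError

log = logging.getLogger(__name__)

#: Columns of a regional activity table that are not region densities.
METADATA_COLUMNS = ("subject_id", "treatment", "age", "sex")

_SIGN_MODES = ("positive_only", "absolute")


def region_columns(table: pd.DataFrame) -> list[str]:
    """Region density columns of a regional activity table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def correlation_pvalue(r, n):
    """Two-tailed p-value of a Pearson correlation.

    Uses the exact transform ``t = r * sqrt((n - 2) / (1 - r^2))``
    referred to the t distribution with ``n - 2`` degrees of freedom.
    ``|r| = 1`` maps to ``p = 0``.  Accepts scalars or arrays.

    Parameters
    ----------
    r : float or array-like
        Correlation coefficient(s), ``|r| <= 1``.
    n : int or array-like
        Number of paired observations, ``n >= 3``.
    """
    r_arr = np.asarray(r, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 3):
        raise ValueError("correlation p-value requires n >= 3")
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| must not exceed 1")
    r_clip = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_clip * np.sqrt((n_arr - 2) / (1.0 - r_clip**2))
        p = 2.0 * stats.t.sf(np.abs(t), n_arr - 2)
    p = np.where(np.isclose(np.abs(r_clip), 1.0), 0.0, p)
    if np.isscalar(r) and np.isscalar(n):
        return float(p)
    return p


@dataclass(frozen=True)
class ThresholdPolicy:
    """Dual-threshold filter turning correlations into edges.

    Defaults reproduce the conventional filter: two-tailed significance
    at the 95% confidence level combined with ``r >= 0.8``.

    Attributes
    ----------
    alpha_level : float
        Two-tailed significance level; an edge requires ``p < alpha_level``.
    r_min : float
        Minimum correlation magnitude; comparison is ``>=`` ("at least").
    sign_mode : str
        ``"positive_only"`` applies ``r >= r_min``; ``"absolute"`` applies
        ``|r| >= r_min``.
    fdr : bool
        If True, Benjamini-Hochberg adjust p-values across the defined
        region pairs before applying ``alpha_level``.  Off by default.
    """

    alpha_level: float = 0.05
    r_min: float = 0.8
    sign_mode: str = "positive_only"
    fdr: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError(f"alpha_level must be in (0, 1), got {self.alpha_level}")
        if not 0.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min must be in [0, 1], got {self.r_min}")
        if self.sign_mode not in _SIGN_MODES:
            raise ValueError(f"sign_mode must be one of {_SIGN_MODES}, got {self.sign_mode!r}")


@dataclass
class GroupCorrelationResult:
    """Pairwise Pearson correlations for one group of subjects.

    ``r``, ``p`` and ``n`` are square region-by-region DataFrames.
    Undefined pairs (zero variance, or fewer than ``min_n`` complete
    observations) carry NaN in ``r`` and ``p`` — never 0.  The diagonal
    of ``r`` is exactly 1; the diagonal of ``p`` is NaN (undefined).
    """

    group: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def regions(self) -> list[str]:
        return list(self.r.index)


@dataclass
class BinaryAdjacency:
    """Symmetric 0/1 region graph with zero diagonal."""

    regions: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.regions = tuple(self.regions)
        a = np.asarray(self.matrix)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != len(self.regions):
            raise ValueError("adjacency must be square and match the region labels")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.matrix = a.astype(np.int8)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.matrix, k=1).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.regions), columns=list(self.regions))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BinaryAdjacency":
        if list(frame.index) != list(frame.columns):
            raise ValueError("adjacency frame must have identical row and column labels")
        return cls(tuple(frame.index), frame.to_numpy())


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Plain Pearson r; NaN when either variance is zero."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return np.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _select_group(table: pd.DataFrame, group: Mapping[str, object] | None) -> tuple[pd.DataFrame, str]:
    if group is None:
        return table, "all"
    mask = pd.Series(True, index=table.index)
    for key, value in group.items():
        if key not in table.columns:
            raise SchemaError(f"group key {key!r} is not a column of the table")
        mask &= table[key] == value
    label = "_".join(str(v) for v in group.values())
    return table.loc[mask], label


def pairwise_correlations(
    table: pd.DataFrame,
    group: Mapping[str, object] | None = None,
    *,
    min_n: int = 3,
) -> GroupCorrelationResult:
    """Pearson r/p/n matrices over all region pairs within one group.

    Missing values are handled pairwise-complete; a pair falling below
    ``min_n`` complete observations, or involving a zero-variance region,
    is marked undefined (NaN) with a logged warning.

    Raises
    ------
    GroupTooSmallError
        If the selected group has fewer than ``min_n`` subjects.
    """
    sub, label = _select_group(table, group)
    regions = region_columns(sub)
    if len(regions) < 2:
        raise SchemaError("activity table needs at least two region columns")
    if len(sub) < min_n:
        raise GroupTooSmallError(
            f"group {label!r} has n = {len(sub)} subjects; at least {min_n} required"
        )
    X = sub[regions].to_numpy(dtype=float)
    m = len(regions)
    r = np.eye(m)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    notes: list[str] = []
    finite = np.isfinite(X)
    np.fill_diagonal(n, finite.sum(axis=0))
    for i in range(m):
        for j in range(i + 1, m):
            ok = finite[:, i] & finite[:, j]
            nij = int(ok.sum())
            n[i, j] = n[j, i] = nij
            if nij < min_n:
                notes.append(
                    f"pair ({regions[i]}, {regions[j]}): only {nij} complete subjects; undefined"
                )
                r[i, j] = r[j, i] = np.nan
                continue
            rij = _pearson(X[ok, i], X[ok, j])
            if np.isnan(rij):
                notes.append(
                    f"pair ({regions[i]}, {regions[j]}): zero variance; correlation undefined"
                )
                r[i, j] = r[j, i] = np.nan
                continue
            r[i, j] = r[j, i] = rij
            pij = correlation_pvalue(rij, nij)
            p[i, j] = p[j, i] = pij
    for note in notes:
        log.warning("group %s: %s", label, note)
    idx = list(regions)
    return GroupCorrelationResult(
        group=label,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        warnings=notes,
    )


def group_correlations(
    table: pd.DataFrame,
    by: Iterable[str] = ("treatment", "age"),
    *,
    sex: str | None = None,
    min_n: int = 3,
) -> dict[tuple, GroupCorrelationResult]:
    """Correlation results for every group defined by the ``by`` columns."""
    sub = table if sex is None else table.loc[table["sex"] == sex]
    by = list(by)
    out: dict[tuple, GroupCorrelationResult] = {}
    for key, _ in sub.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out[key] = pairwise_correlations(sub, dict(zip(by, key)), min_n=min_n)
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a flat vector."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def threshold_adjacency(
    result: GroupCorrelationResult,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> BinaryAdjacency:
    """Binarize a correlation result with the dual threshold.

    ``a_ij = 1`` iff ``p_ij < alpha_level`` and the correlation passes
    ``r_min`` under ``sign_mode``.  Undefined pairs become 0 (logged).
    """
    r = result.r.to_numpy()
    p = result.p.to_numpy().copy()
    m = r.shape[0]
    iu = np.triu_indices(m, k=1)
    defined = np.isfinite(r[iu]) & np.isfinite(p[iu])
    n_undefined = int((~defined).sum())
    if n_undefined:
        log.info("group %s: %d undefined pairs set to 0 in adjacency", result.group, n_undefined)
    pvals = p[iu]
    if policy.fdr and defined.any():
        adj = pvals.copy()
        adj[defined] = _bh_adjust(pvals[defined])
        pvals = adj
    if policy.sign_mode == "positive_only":
        pass_r = r[iu] >= policy.r_min
    else:
        pass_r = np.abs(r[iu]) >= policy.r_min
    with np.errstate(invalid="ignore"):
        edge = defined & (pvals < policy.alpha_level) & pass_r
    a = np.zeros((m, m), dtype=np.int8)
    a[iu] = edge.astype(np.int8)
    a = a + a.T
    return BinaryAdjacency(tuple(result.regions), a)
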