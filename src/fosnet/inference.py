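"""Group-level statistics: factorial ANOVA, SNK post hoc, and the
group-level correlation between focal-region degree and neurogenesis.

The ANOVA is a two-way factorial with Type-III sums of squares under
sum-to-zero contrasts, so unbalanced cells are handled the way the
mainstream commercial packages do by default.  The post hoc procedure is
the Student-Newman-Keuls stepwise range test on cell means, with the
harmonic mean of the pair's group sizes standing in for a common n when
the design is unbalanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .connectivity import correlation_pvalue
from .errors import SchemaError

_EFFECT_ORDER = ("factor_a", "factor_b", "interaction", "residual")


@dataclass
class AnovaResult:
    """Factorial-effects table: SS, df, F and p per effect plus residual.

    ``effects`` is indexed by the caller-supplied factor names, then
    ``"<a>:<b>"`` for the interaction and ``"residual"``.
    """

    effects: pd.DataFrame
    factor_names: tuple[str, str]

    @property
    def interaction_name(self) -> str:
        return f"{self.factor_names[0]}:{self.factor_names[1]}"

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])

    def f(self, effect: str) -> float:
        return float(self.effects.loc[effect, "F"])

    @property
    def ms_error(self) -> float:
        row = self.effects.loc["residual"]
        return float(row["ss"] / row["df"])

    @property
    def df_error(self) -> int:
        return int(self.effects.loc["residual", "df"])

    def format_effect(self, effect: str) -> str:
        """Human-readable ``F(df1, df2) = x.xx, p = ...`` line."""
        row = self.effects.loc[effect]
        return (
            f"{effect}: F({int(row['df'])},{self.df_error}) = "
            f"{row['F']:.2f}, p = {row['p']:.4g}"
        )


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    factor_names: tuple[str, str] = ("factor_a", "factor_b"),
) -> AnovaResult:
    """Two-way factorial ANOVA with Type-III SS and sum-to-zero contrasts.

    Parameters
    ----------
    values : sequence of float
        The response (densities or percent-change values).
    factor_a, factor_b : sequences of labels
        Factor level per observation, aligned with ``values``.
    factor_names : pair of str
        Names used for the effect rows of the result.

    Raises
    ------
    SchemaError
        If a factor has fewer than 2 levels, any factor-level cell is
        empty (missing cells are listed), or the residual df is < 1.
    """
    y = np.asarray(values, dtype=float)
    a = pd.Series(factor_a).astype(str)
    b = pd.Series(factor_b).astype(str)
    if not (len(y) == len(a) == len(b)):
        raise SchemaError("values and factor labels must have equal length")
    if a.nunique() < 2 or b.nunique() < 2:
        raise SchemaError("each factor needs at least 2 levels")
    cells = pd.crosstab(a, b)
    empty = [(ai, bi) for ai in cells.index for bi in cells.columns if cells.loc[ai, bi] == 0]
    if empty:
        raise SchemaError(f"empty factor cells {empty}; every cell needs n >= 1")
    df_resid = len(y) - a.nunique() * b.nunique()
    if df_resid < 1:
        raise SchemaError(f"residual df = {df_resid}; need at least 1")

    data = pd.DataFrame({"y": y, "a": a.to_numpy(), "b": b.to_numpy()})
    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=3)

    name_a, name_b = factor_names
    rename = {
        "C(a, Sum)": name_a,
        "C(b, Sum)": name_b,
        "C(a, Sum):C(b, Sum)": f"{name_a}:{name_b}",
        "Residual": "residual",
    }
    table = table.drop(index="Intercept").rename(index=rename)
    effects = pd.DataFrame(
        {
            "ss": table["sum_sq"],
            "df": table["df"].astype(int),
            "F": table["F"],
            "p": table["PR(>F)"],
        }
    )
    return AnovaResult(effects=effects, factor_names=(name_a, name_b))


@dataclass
class PosthocResult:
    """Ordered SNK pairwise comparisons.

    ``comparisons`` has one row per unordered pair with columns
    ``group_i, group_j, diff, k, q, p, significant``; ``k`` is the
    stretch (number of ordered means spanned, endpoints included).
    A non-significant span seals every comparison nested inside it.
    """

    comparisons: pd.DataFrame
    alpha: float
    ms_error: float
    df_error: int

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.comparisons.loc[self.comparisons["significant"]]
        return [tuple(x) for x in sig[["group_i", "group_j"]].itertuples(index=False)]


def snk_critical_value(alpha: float, k: int, df: int) -> float:
    """Critical studentized-range value ``q(alpha; k, df)``."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def snk_posthoc(
    cell_means: Mapping[str, float] | pd.Series,
    cell_ns: Mapping[str, int] | pd.Series,
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> PosthocResult:
    """Student-Newman-Keuls stepwise range test on cell means.

    Means are sorted ascending (ties keep their original order); each
    pair is tested as the range over its stretch k with
    ``q = diff / sqrt(ms_error / n_h)`` where ``n_h`` is the harmonic
    mean of the two group sizes.  Spans are processed widest-first; a
    non-significant span seals all nested comparisons as non-significant
    regardless of their own q.
    """
    if ms_error <= 0:
        raise ValueError(f"ms_error must be positive, got {ms_error}")
    if df_error < 1:
        raise ValueError(f"df_error must be >= 1, got {df_error}")
    means = pd.Series(cell_means, dtype=float)
    ns = pd.Series(cell_ns, dtype=float)
    if set(means.index) != set(ns.index):
        raise ValueError("cell_means and cell_ns must cover the same groups")
    if len(means) < 2:
        raise ValueError("post hoc requires at least 2 groups")
    ns = ns.reindex(means.index)

    # stable ascending sort: mergesort preserves original order among ties
    order = np.argsort(means.to_numpy(), kind="mergesort")
    labels = means.index.to_numpy()[order]
    sorted_means = means.to_numpy()[order]
    sorted_ns = ns.to_numpy()[order]
    m = len(labels)

    sealed: set[tuple[int, int]] = set()
    rows = []
    for k in range(m, 1, -1):
        for lo in range(0, m - k + 1):
            hi = lo + k - 1
            diff = sorted_means[hi] - sorted_means[lo]
            n_h = 2.0 / (1.0 / sorted_ns[lo] + 1.0 / sorted_ns[hi])
            q = diff / np.sqrt(ms_error / n_h)
            p = float(stats.studentized_range.sf(q, k, df_error))
            significant = (p < alpha) and ((lo, hi) not in sealed)
            if not significant:
                for a_ in range(lo, hi + 1):
                    for b_ in range(a_ + 1, hi + 1):
                        sealed.add((a_, b_))
            rows.append(
                {
                    "group_i": labels[lo],
                    "group_j": labels[hi],
                    "diff": diff,
                    "k": k,
                    "q": q,
                    "p": p,
                    "significant": significant,
                }
            )
    comparisons = pd.DataFrame(rows)
    return PosthocResult(comparisons=comparisons, alpha=alpha, ms_error=ms_error, df_error=df_error)


def snk_from_anova(
    values: Sequence[float],
    groups: Sequence,
    anova: AnovaResult,
    alpha: float = 0.05,
) -> PosthocResult:
    """Convenience: SNK over observed group means using the ANOVA residual MS."""
    frame = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": [str(g) for g in groups]})
    means = frame.groupby("g", sort=True)["y"].mean()
    ns = frame.groupby("g", sort=True)["y"].size()
    return snk_posthoc(means, ns, anova.ms_error, anova.df_error, alpha=alpha)


@dataclass
class DegreeNeurogenesisCorrelation:
    """Group-level Pearson correlation of focal degree vs marker density."""

    groups: tuple
    degrees: tuple
    densities: tuple
    r: float
    df: int
    p: float
    r_squared: float = field(init=False)

    def __post_init__(self):
        self.r_squared = self.r**2

    def format(self) -> str:
        return f"r({self.df}) = {self.r:.2f}, p = {self.p:.3g}, r^2 = {self.r_squared:.2f}"


def degree_neurogenesis_correlation(
    degrees: Mapping[object, int],
    densities: Mapping[object, float],
) -> DegreeNeurogenesisCorrelation:
    """Correlate per-group focal node degree with group mean marker density.

    Groups are matched by key; a mismatch between the two inputs is an
    error.  The p-value uses the exact t transform with ``df = points - 2``.
    """
    keys_d = set(degrees)
    keys_x = set(densities)
    if keys_d != keys_x:
        raise ValueError(
            f"group sets differ: only-degrees={sorted(map(str, keys_d - keys_x))}, "
            f"only-densities={sorted(map(str, keys_x - keys_d))}"
        )
    keys = sorted(degrees, key=str)
    if len(keys) < 3:
        raise ValueError(f"need at least 3 group points, got {len(keys)}")
    x = np.array([degrees[k] for k in keys], dtype=float)
    y = np.array([densities[k] for k in keys], dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in degrees or densities; correlation undefined")
    r = float(np.clip((xc @ yc) / denom, -1.0, 1.0))
    df = len(keys) - 2
    p = correlation_pvalue(r, len(keys))
    return DegreeNeurogenesisCorrelation(
        groups=tuple(keys), degrees=tuple(x), densities=tuple(y), r=r, df=df, p=p
    )
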