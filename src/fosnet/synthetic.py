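"""Synthetic cohorts with planted correlation structure and marker trends.

Two generators cover the pipeline's inputs:

* ``sample_region_densities`` draws per-subject regional density vectors
  from a multivariate normal whose correlation matrix is built from a
  per-group block assignment (within-block vs between-block r), truncated
  at zero (truncations are logged because they perturb the planted
  correlations).
* ``sample_marker_counts`` draws per-section marker counts whose implied
  densities follow a baseline level scaled by an age factor and a
  (treatment, age, sex) offset; counts are negative-binomial around
  area x target density, so they are overdispersed non-negative integers.

Randomness comes from one cohort seed, split deterministically per group
by hashing the group labels — adding a group never reshuffles the others.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GroupKey = tuple  # (treatment, age_weeks, sex)

DEFAULT_REGIONS = (
    "DG", "CA1", "CA3", "SUB", "EC", "PER", "RSC", "ACC", "PL", "IL", "BLA", "RE",
)

#: Multiplicative (treatment, age, sex) deviations from the control age
#: trajectory: a deficit in 4-week germ-free males, an elevation in
#: 8-week germ-free females, and a delayed 4->8 week decline in both sexes.
DEFAULT_TREATMENT_OFFSETS: dict[GroupKey, float] = {
    ("germ_free", 4, "male"): 0.55,
    ("germ_free", 8, "male"): 1.30,
    ("germ_free", 12, "male"): 1.00,
    ("germ_free", 4, "female"): 1.00,
    ("germ_free", 8, "female"): 2.30,
    ("germ_free", 12, "female"): 1.00,
}


def _child_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic per-group generator derived by hashing the labels."""
    key = "|".join(str(t) for t in (seed, *tokens))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def group_label(group: GroupKey) -> str:
    treatment, age, sex = group
    return f"{treatment}_{age}w_{sex}"


@dataclass(frozen=True)
class CohortDesign:
    """Factorial layout of a simulated cohort.

    ``n_per_group`` is either one integer for all cells or a mapping
    from (treatment, age, sex) to the cell size.  Every cell must have
    n >= 3 (pairwise correlation needs three points); n < 5 warns.
    """

    treatments: tuple[str, ...] = ("control", "germ_free")
    ages: tuple[int, ...] = (4, 8, 12)
    sexes: tuple[str, ...] = ("male", "female")
    n_per_group: int | Mapping[GroupKey, int] = 8
    region_labels: tuple[str, ...] = DEFAULT_REGIONS
    focal_region: str = "DG"
    seed: int = 0

    def __post_init__(self):
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if len(self.region_labels) < 3:
            raise ValueError("need at least 3 regions")
        if self.focal_region not in self.region_labels:
            raise ValueError(f"focal region {self.focal_region!r} not in region labels")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for g in self.groups():
            n = self.group_n(g)
            if n < 3:
                raise ValueError(f"group {g} has n = {n}; at least 3 required")
            if n < 5:
                warnings.warn(f"group {g} has n = {n} < 5; correlations will be fragile")

    def groups(self) -> list[GroupKey]:
        return [
            (t, a, s)
            for t, a, s in itertools.product(self.treatments, self.ages, self.sexes)
        ]

    def group_n(self, group: GroupKey) -> int:
        if isinstance(self.n_per_group, int):
            return self.n_per_group
        return int(self.n_per_group[group])


@dataclass(frozen=True)
class PlantedStructure:
    """Block-correlation target for regional densities.

    ``blocks`` maps each group to a region -> block-id assignment (or is
    a single region -> block mapping applied to every group).  The
    implied correlation matrix has ``within_block_r`` inside a block and
    ``between_block_r`` elsewhere.
    """

    blocks: Mapping
    within_block_r: float
    between_block_r: float = 0.0
    region_means: Mapping[str, float] = field(default_factory=dict)
    density_noise_sd: float = 25.0

    def __post_init__(self):
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")
        if not 0.0 <= self.between_block_r < 1.0:
            raise ValueError("between_block_r must be in [0, 1)")
        if self.between_block_r > self.within_block_r:
            raise ValueError("between_block_r must not exceed within_block_r")
        if self.density_noise_sd < 0:
            raise ValueError("density_noise_sd must be non-negative")

    def blocks_for(self, group: GroupKey) -> dict[str, int]:
        first = next(iter(self.blocks.values()))
        if isinstance(first, Mapping):  # per-group nesting
            if group not in self.blocks:
                raise KeyError(f"no block assignment for group {group}")
            return dict(self.blocks[group])
        return dict(self.blocks)

    def mean_for(self, region: str) -> float:
        if region not in self.region_means:
            raise KeyError(f"no mean density for region {region!r}")
        return float(self.region_means[region])


def build_group_correlation(structure: PlantedStructure, group: GroupKey) -> pd.DataFrame:
    """The planted correlation matrix for one group.

    Unit diagonal; entry = within_block_r for same-block pairs, else
    between_block_r.  Positive semi-definiteness is verified (smallest
    eigenvalue >= -1e-9) before the matrix is returned.
    """
    blocks = structure.blocks_for(group)
    regions = list(blocks)
    ids = np.array([blocks[r] for r in regions])
    same = ids[:, None] == ids[None, :]
    r = np.where(same, structure.within_block_r, structure.between_block_r)
    np.fill_diagonal(r, 1.0)
    eigmin = float(np.linalg.eigvalsh(r).min())
    if eigmin < -1e-9:
        raise ValueError(
            f"implied correlation matrix for group {group} is not PSD "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    return pd.DataFrame(r, index=regions, columns=regions)


def planted_adjacency(structure: PlantedStructure, group: GroupKey) -> pd.DataFrame:
    """Ground-truth edge indicator (same-block pairs) for recovery tests."""
    blocks = structure.blocks_for(group)
    regions = list(blocks)
    ids = np.array([blocks[r] for r in regions])
    a = (ids[:, None] == ids[None, :]).astype(np.int8)
    np.fill_diagonal(a, 0)
    return pd.DataFrame(a, index=regions, columns=regions)


def sample_region_densities(design: CohortDesign, structure: PlantedStructure) -> pd.DataFrame:
    """Per-subject regional density vectors with the planted correlation.

    Returns a regional activity table: metadata columns followed by one
    density column per region.  Negative draws are clipped to zero and
    the clip count is logged.
    """
    rows = []
    clip_total = 0
    for group in design.groups():
        corr = build_group_correlation(structure, group)
        regions = list(corr.index)
        if set(regions) != set(design.region_labels):
            raise ValueError(
                f"structure regions {sorted(regions)} do not match design regions "
                f"{sorted(design.region_labels)}"
            )
        corr = corr.loc[list(design.region_labels), list(design.region_labels)]
        mu = np.array([structure.mean_for(r) for r in design.region_labels])
        sd = structure.density_noise_sd
        cov = (sd**2) * corr.to_numpy()
        rng = _child_rng(design.seed, "densities", *group)
        n = design.group_n(group)
        x = rng.multivariate_normal(mu, cov, size=n, method="svd")
        clipped = int((x < 0).sum())
        if clipped:
            clip_total += clipped
            x = np.clip(x, 0.0, None)
        label = group_label(group)
        for i in range(n):
            row = {
                "subject_id": f"{label}_s{i + 1:02d}",
                "treatment": group[0],
                "age": group[1],
                "sex": group[2],
            }
            row.update(dict(zip(design.region_labels, x[i])))
            rows.append(row)
    if clip_total:
        log.warning("clipped %d negative density draws to 0", clip_total)
    cols = ["subject_id", "treatment", "age", "sex", *design.region_labels]
    return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class NeurogenesisEffectProfile:
    """Expected marker-density trajectory across age, treatment and sex.

    The target density for a subject is
    ``baseline_density[marker] * age_decline_fraction[age] *
    treatment_offsets.get((treatment, age, sex), 1.0)``.
    Control age factors must be strictly decreasing with age.
    ``dispersion`` scales both the between-subject lognormal effect and
    the negative-binomial overdispersion of section counts; 0 makes the
    generator deterministic apart from section layout.
    """

    baseline_density: Mapping[str, float] = field(
        default_factory=lambda: {"DCX": 1200.0, "BrdU": 160.0, "pyknotic": 40.0}
    )
    age_decline_fraction: Mapping[int, float] = field(
        default_factory=lambda: {4: 1.0, 8: 0.45, 12: 0.25}
    )
    treatment_offsets: Mapping[GroupKey, float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_OFFSETS)
    )
    dispersion: float = 0.2
    mean_section_area: float = 0.22  # mm^2

    def __post_init__(self):
        for marker, dens in self.baseline_density.items():
            if dens <= 0:
                raise ValueError(f"baseline density for {marker} must be positive")
        ages = sorted(self.age_decline_fraction)
        fracs = [self.age_decline_fraction[a] for a in ages]
        if any(f2 >= f1 for f1, f2 in zip(fracs, fracs[1:])):
            raise ValueError("control age factors must be strictly decreasing with age")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.mean_section_area <= 0:
            raise ValueError("mean_section_area must be positive")

    def target_density(self, marker: str, group: GroupKey) -> float:
        treatment, age, sex = group
        return (
            float(self.baseline_density[marker])
            * float(self.age_decline_fraction[age])
            * float(self.treatment_offsets.get((treatment, age, sex), 1.0))
        )


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    if dispersion == 0.0:
        return np.rint(mu).astype(int)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def sample_marker_counts(
    design: CohortDesign, profile: NeurogenesisEffectProfile
) -> pd.DataFrame:
    """Per-section marker counts whose densities follow the planted trend.

    Each subject gets 7-10 sections per marker with lognormal areas; the
    expected implied density is ``profile.target_density(marker, group)``.
    Returns a long section table (see :mod:`fosnet.quantify`).
    """
    rows = []
    markers = list(profile.baseline_density)
    s = profile.dispersion
    for group in design.groups():
        rng = _child_rng(design.seed, "markers", *group)
        label = group_label(group)
        n = design.group_n(group)
        for i in range(n):
            subject = f"{label}_s{i + 1:02d}"
            for marker in markers:
                target = profile.target_density(marker, group)
                n_sections = int(rng.integers(7, 11))
                areas = rng.lognormal(
                    mean=np.log(profile.mean_section_area) - 0.5 * 0.25**2,
                    sigma=0.25,
                    size=n_sections,
                )
                subj_mult = rng.lognormal(mean=-0.5 * s**2, sigma=s) if s > 0 else 1.0
                mu = areas * target * subj_mult
                counts = _nb_counts(rng, mu, s)
                for area, count in zip(areas, counts):
                    rows.append(
                        {
                            "subject_id": subject,
                            "treatment": group[0],
                            "age": group[1],
                            "sex": group[2],
                            "marker": marker,
                            "count": int(count),
                            "area": float(area),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["subject_id", "treatment", "age", "sex", "marker", "count", "area"]
    )


def default_structure(
    design: CohortDesign,
    profile: NeurogenesisEffectProfile | None = None,
    *,
    within_block_r: float = 0.9,
    between_block_r: float = 0.1,
    density_noise_sd: float = 25.0,
) -> PlantedStructure:
    """Per-group block structure coupling focal connectivity to neurogenesis.

    The focal region shares its block with a number of companion regions
    proportional to the group's expected neurogenesis level, so groups
    with higher planted DCX have a better-connected focal region; the
    remaining regions form a second block.
    """
    profile = profile or NeurogenesisEffectProfile()
    focal = design.focal_region
    others = [r for r in design.region_labels if r != focal]
    marker = next(iter(profile.baseline_density))
    blocks: dict[GroupKey, dict[str, int]] = {}
    for group in design.groups():
        rel = profile.target_density(marker, group) / profile.baseline_density[marker]
        companions = int(round(rel * (len(others) - 2)))
        companions = min(max(companions, 1), len(others) - 1)
        assignment = {focal: 0}
        for idx, region in enumerate(others):
            assignment[region] = 0 if idx < companions else 1
        blocks[group] = assignment
    means = {r: 120.0 + 18.0 * i for i, r in enumerate(design.region_labels)}
    return PlantedStructure(
        blocks=blocks,
        within_block_r=within_block_r,
        between_block_r=between_block_r,
        region_means=means,
        density_noise_sd=density_noise_sd,
    )


def default_cohort(
    seed: int = 0, n_per_group: int | Mapping[GroupKey, int] = 8
) -> tuple[CohortDesign, PlantedStructure, NeurogenesisEffectProfile]:
    """Design, structure and effect profile with qualitative defaults."""
    design = CohortDesign(seed=seed, n_per_group=n_per_group)
    profile = NeurogenesisEffectProfile()
    structure = default_structure(design, profile)
    return design, structure, profile


def structure_metadata(
    design: CohortDesign,
    structure: PlantedStructure,
    profile: NeurogenesisEffectProfile | None = None,
) -> dict:
    """YAML-safe record of design, structure and seed for exact replay."""
    meta = {
        "seed": design.seed,
        "treatments": list(design.treatments),
        "ages": list(design.ages),
        "sexes": list(design.sexes),
        "region_labels": list(design.region_labels),
        "focal_region": design.focal_region,
        "n_per_group": (
            design.n_per_group
            if isinstance(design.n_per_group, int)
            else {group_label(k): v for k, v in design.n_per_group.items()}
        ),
        "within_block_r": structure.within_block_r,
        "between_block_r": structure.between_block_r,
        "density_noise_sd": structure.density_noise_sd,
        "region_means": {k: float(v) for k, v in structure.region_means.items()},
        "blocks": {
            group_label(g): dict(structure.blocks_for(g)) for g in design.groups()
        },
    }
    if profile is not None:
        meta["profile"] = {
            "baseline_density": {k: float(v) for k, v in profile.baseline_density.items()},
            "age_decline_fraction": {int(k): float(v) for k, v in profile.age_decline_fraction.items()},
            "treatment_offsets": {group_label(k): float(v) for k, v in profile.treatment_offsets.items()},
            "dispersion": profile.dispersion,
            "mean_section_area": profile.mean_section_area,
        }
    return meta
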