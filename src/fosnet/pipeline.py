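"""End-to-end orchestration: simulate/ingest -> quantify -> connect ->
measure -> infer, with deterministic seeding and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, connectivity, inference, io, metrics, quantify, synthetic
from .connectivity import ThresholdPolicy
from .errors import PipelineStageError, SchemaError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single configuration object for a full pipeline run."""

    mode: str = "synthetic"  # "synthetic" | "tables"
    seed: int = 0
    out_dir: str = "fosnet_run"
    regions_table: str | None = None
    sections_table: str | None = None
    alpha_level: float = 0.05
    r_min: float = 0.8
    sign_mode: str = "positive_only"
    baseline_age: int = 4
    focal_region: str = "DG"
    connectivity_sexes: tuple[str, ...] = ("male",)
    n_per_group: int = 8

    def __post_init__(self):
        if self.mode not in ("synthetic", "tables"):
            raise ValueError(f"mode must be 'synthetic' or 'tables', got {self.mode!r}")
        self.connectivity_sexes = tuple(self.connectivity_sexes)
        self.policy()  # validates threshold fields
        if self.mode == "tables":
            for name, p in (("regions_table", self.regions_table), ("sections_table", self.sections_table)):
                if p is None:
                    raise ValueError(f"tables mode requires {name}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} path does not exist: {p}")

    def policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            alpha_level=self.alpha_level, r_min=self.r_min, sign_mode=self.sign_mode
        )

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connectivity_sexes"] = list(self.connectivity_sexes)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures


def validate_inputs(regions_path=None, sections_path=None) -> ValidationReport:
    """Schema, unit and group-size checks; never mutates the inputs."""
    report = ValidationReport()
    if regions_path is not None:
        try:
            table = io.read_region_table(regions_path)
        except Exception as exc:  # report, do not raise
            report.failures.append(f"regions table: {exc}")
        else:
            regions = connectivity.region_columns(table)
            for col in regions:
                vals = pd.to_numeric(table[col], errors="coerce")
                if vals.isna().all():
                    report.failures.append(f"region column {col!r} is entirely non-numeric")
                elif (vals.dropna() < 0).any():
                    report.failures.append(f"region column {col!r} has negative densities")
            sizes = table.groupby(["treatment", "age", "sex"]).size()
            for key, n in sizes.items():
                if n < 3:
                    report.failures.append(
                        f"group {key} has n = {n}; below the n >= 3 correlation floor"
                    )
                elif n < 5:
                    report.warnings.append(f"group {key} has n = {n} < 5; correlations fragile")
    if sections_path is not None:
        try:
            sections = io.read_section_table(sections_path)
            quantify.validate_sections(sections)
        except Exception as exc:
            report.failures.append(f"sections table: {exc}")
    return report


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __init__(self, stage_name):
            self.stage_name = stage_name

        def __enter__(self):
            log.info("stage %s: start", self.stage_name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(self.stage_name, str(exc)) from exc
            log.info("stage %s: done", self.stage_name)
            return False

    return _Ctx(name)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns a dict with the in-memory stage results and artifact paths.
    Identical config + seed produces byte-identical output files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_warnings: list[str] = []
    artifacts: list[str] = []

    def _write(frame, rel):
        path = io.write_table(frame, out / rel)
        artifacts.append(str(rel))
        return path

    with _stage("inputs"):
        if config.mode == "synthetic":
            design, structure, profile = synthetic.default_cohort(
                seed=config.seed, n_per_group=config.n_per_group
            )
            region_df = synthetic.sample_region_densities(design, structure)
            section_df = synthetic.sample_marker_counts(design, profile)
            _write(region_df, "region_densities.csv")
            _write(section_df, "marker_sections.csv")
            meta = synthetic.structure_metadata(design, structure, profile)
            with open(out / "cohort_meta.yaml", "w") as fh:
                yaml.safe_dump(meta, fh, sort_keys=True)
            artifacts.append("cohort_meta.yaml")
        else:
            region_df = io.read_region_table(config.regions_table)
            section_df = io.read_section_table(config.sections_table)

    with _stage("quantify"):
        density_df = quantify.compute_density(section_df)
        pct_df = quantify.percent_change_from_baseline(density_df, config.baseline_age)
        _write(density_df, "densities.csv")
        _write(pct_df, "percent_change.csv")

    with _stage("connect"):
        results = {}
        adjacencies = {}
        policy = config.policy()
        for sex in config.connectivity_sexes:
            by_group = connectivity.group_correlations(region_df, ("treatment", "age"), sex=sex)
            for (treatment, age), result in by_group.items():
                key = (treatment, int(age), sex)
                run_warnings.extend(f"{result.group}: {w}" for w in result.warnings)
                adj = connectivity.threshold_adjacency(result, policy)
                results[key] = result
                adjacencies[key] = adj
                gdir = Path("connectivity") / synthetic.group_label(key)
                io.write_matrix(result.r, out / gdir / "r.csv")
                io.write_matrix(result.p, out / gdir / "p.csv")
                io.write_matrix(result.n, out / gdir / "n.csv")
                io.write_adjacency(adj, out / gdir / "adjacency.csv")
                artifacts.extend(str(gdir / f) for f in ("r.csv", "p.csv", "n.csv", "adjacency.csv"))

    with _stage("metrics"):
        summaries = {}
        records = []
        for key, adj in adjacencies.items():
            summary = metrics.summarize(adj, synthetic.group_label(key), config.focal_region)
            summaries[key] = summary
            records.append(summary.to_record())
            edges = metrics.export_graph(adj, config.focal_region)
            io.write_table(edges, out / "connectivity" / synthetic.group_label(key) / "edges.csv")
            artifacts.append(str(Path("connectivity") / synthetic.group_label(key) / "edges.csv"))
        summary_df = pd.DataFrame(records).sort_values("group").reset_index(drop=True)
        _write(summary_df, "network_summary.csv")

    with _stage("stats"):
        report_lines = [f"fosnet {__version__} run report", ""]
        anova_rows = []
        posthoc_frames = []
        for marker in sorted(density_df["marker"].unique()):
            for sex in sorted(density_df["sex"].unique()):
                sub = density_df[(density_df["marker"] == marker) & (density_df["sex"] == sex)]
                if sub["treatment"].nunique() < 2 or sub["age"].nunique() < 2:
                    continue
                anova = inference.two_way_anova(
                    sub["density"], sub["treatment"], sub["age"], ("treatment", "age")
                )
                for effect in anova.effects.index:
                    row = anova.effects.loc[effect]
                    anova_rows.append(
                        {
                            "marker": marker,
                            "sex": sex,
                            "effect": effect,
                            "ss": row["ss"],
                            "df": row["df"],
                            "F": row["F"],
                            "p": row["p"],
                        }
                    )
                report_lines.append(f"[{marker} / {sex}] two-way ANOVA (treatment x age)")
                for effect in ("treatment", "age", "treatment:age"):
                    report_lines.append("  " + anova.format_effect(effect))
                cells = sub["treatment"].astype(str) + "@" + sub["age"].astype(str) + "w"
                posthoc = inference.snk_from_anova(sub["density"], cells, anova)
                ph = posthoc.comparisons.copy()
                ph.insert(0, "sex", sex)
                ph.insert(0, "marker", marker)
                posthoc_frames.append(ph)
        if anova_rows:
            _write(pd.DataFrame(anova_rows), "stats/anova.csv")
        if posthoc_frames:
            _write(pd.concat(posthoc_frames, ignore_index=True), "stats/snk_posthoc.csv")

        corr_record = None
        male_groups = [k for k in summaries if k[2] == "male"]
        dcx_male = density_df[(density_df["marker"] == "DCX") & (density_df["sex"] == "male")]
        if len(male_groups) >= 3 and len(dcx_male):
            degrees = {k: summaries[k].focal_degree for k in male_groups}
            means = dcx_male.groupby(["treatment", "age"])["density"].mean()
            densities = {}
            for treatment, age, sex in male_groups:
                if (treatment, age) in means.index:
                    densities[(treatment, age, sex)] = float(means[(treatment, age)])
            if set(densities) == set(degrees):
                corr = inference.degree_neurogenesis_correlation(degrees, densities)
                corr_record = {
                    "n_groups": len(corr.groups),
                    "r": corr.r,
                    "df": corr.df,
                    "p": corr.p,
                    "r_squared": corr.r_squared,
                }
                _write(pd.DataFrame([corr_record]), "stats/degree_dcx_correlation.csv")
                report_lines.append("")
                report_lines.append(
                    f"focal degree vs mean DCX across male groups: {corr.format()}"
                )
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        artifacts.append("report.txt")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "warnings": run_warnings,
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "region_table": region_df,
        "section_table": section_df,
        "densities": density_df,
        "percent_change": pct_df,
        "correlations": results,
        "adjacencies": adjacencies,
        "summaries": summaries,
        "degree_dcx_correlation": corr_record,
        "manifest": manifest,
        "out_dir": str(out),
    }
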