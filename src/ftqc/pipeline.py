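"""End-to-end orchestration: synthesize -> filter -> noise -> subset DE ->
similarity / discordance -> coverage bias, with delimited-text outputs and a
run report.

One master seed fans out to independent per-stage child seeds, so a stage
can be re-run on its own yet the full pipeline is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import CoverageBiasModel
from .de import SubsetReproducibilityModel
from .errors import FtqcError
from .io import read_counts, read_metadata, write_counts, write_metadata, write_truth
from .noise import ReplicateNoiseModel
from .synthetic import SyntheticConfig, generate_cohort, generate_coverage_profiles

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_STAGE_SEED = {"synthetic": 0, "noise": 1, "de": 2, "coverage": 3}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Stage parameters default to the framework's standard values: genes kept
    above an average count of 20, bottom-10th-percentile gene exclusions,
    subset sizes 4-14, 2000 subsets per size, and the |z| >= 1.645
    concentration outlier filter inside the noise regressions.
    """

    output_dir: str = "ftqc_run"
    seed: int = 0
    # inputs; None + synthesize=True generates them
    counts_path: str | None = None
    metadata_path: str | None = None
    coverage_path: str | None = None
    # stage toggles
    synthesize: bool = True
    run_noise: bool = True
    run_de: bool = True
    run_coverage: bool = True
    # synthetic generator parameters (used when synthesize=True)
    synthetic: dict = field(default_factory=dict)
    # stage parameters
    noise_metrics: str = "all"
    min_avg_count: float = 20.0
    subset_sizes: tuple = (4, 6, 8, 10, 12, 14)
    n_subsets: int = 2000
    exclusion_percentile: float = 10.0
    max_pairs: int = 10_000
    pair_mode: str = "sampled"
    quality_metrics: tuple = ("freeze_thaw", "rin")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise FtqcError(f"unknown config keys: {sorted(unknown)}")
        for key in ("subset_sizes", "quality_metrics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    """Summary of one pipeline run: per-stage tables, provenance, warnings."""

    seed: int
    version: str
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"ftqc {self.version} run report",
            f"master seed: {self.seed}",
            "",
        ]
        for stage, summary in self.stages.items():
            lines.append(f"== {stage} ==")
            if isinstance(summary, pd.DataFrame):
                lines.append(summary.to_string(index=False))
            else:
                lines.append(str(summary))
            if stage in self.outputs:
                lines.append(f"outputs: {', '.join(self.outputs[stage])}")
            lines.append("")
        if self.warnings:
            lines.append("== warnings ==")
            lines.extend(str(w) for w in self.warnings)
        return "\n".join(lines)


def _child_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([master, _STAGE_SEED[stage]]).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in order, writing one delimited output per
    stage plus a plain-text run report. A fixed master seed yields
    bit-identical outputs; any stage failure aborts with the stage name
    while retaining partial outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed, version=__version__)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            counts, metadata, profiles = _stage_inputs(config, out, report)
            if config.run_noise:
                _stage_noise(config, counts, metadata, out, report)
            if config.run_de:
                _stage_de(config, counts, metadata, out, report)
            if config.run_coverage and profiles is not None:
                _stage_coverage(config, profiles, metadata, out, report)
        except Exception as exc:
            report.warnings.extend(str(w.message) for w in caught)
            (out / "run_report.txt").write_text(report.to_text())
            raise FtqcError(f"pipeline stage failed: {exc}") from exc
        report.warnings.extend(str(w.message) for w in caught)
    (out / "run_report.txt").write_text(report.to_text())
    return report


def _stage_inputs(config, out, report):
    profiles = None
    if config.synthesize:
        params = dict(config.synthetic)
        params.setdefault("seed", _child_seed(config.seed, "synthetic"))
        cfg = SyntheticConfig(**params)
        counts, metadata, truth = generate_cohort(cfg)
        profiles = generate_coverage_profiles(metadata, cfg)
        write_counts(counts, out / "counts.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_truth(truth, out / "truth.json")
        profiles.to_csv(out / "coverage_profiles.tsv", sep="\t")
        report.stages["synthetic"] = pd.DataFrame(
            {
                "n_genes": [counts.shape[0]],
                "n_samples": [counts.shape[1]],
                "n_individuals": [metadata["individual_id"].nunique()],
            }
        )
        report.outputs["synthetic"] = [
            "counts.tsv", "metadata.tsv", "truth.json", "coverage_profiles.tsv"
        ]
    else:
        counts = read_counts(config.counts_path)
        metadata = read_metadata(config.metadata_path)
        if config.coverage_path:
            profiles = pd.read_csv(config.coverage_path, sep="\t", index_col=0)
    return counts, metadata, profiles


def _stage_noise(config, counts, metadata, out, report):
    model = ReplicateNoiseModel(counts, metadata, metrics=config.noise_metrics)
    res = model.fit(seed=_child_seed(config.seed, "noise"))
    res.noise_table.to_csv(out / "noise.tsv", sep="\t", index=False)
    fits = res.regress("freeze_thaw")
    if not isinstance(fits, dict):
        fits = {res.noise_table["metric"].iloc[0]: fits}
    fit_rows = [
        {
            "metric": m,
            "n0_percent": f.intercept,
            "delta_n_pp_per_cycle": f.slope,
            "p_slope": f.p_slope,
            "n_pairs": f.n_samples_used,
        }
        for m, f in fits.items()
    ]
    fit_df = pd.DataFrame(fit_rows)
    fit_df.to_csv(out / "noise_fits.tsv", sep="\t", index=False)
    report.stages["noise"] = fit_df
    report.outputs["noise"] = ["noise.tsv", "noise_fits.tsv"]


def _stage_de(config, counts, metadata, out, report):
    model = SubsetReproducibilityModel(
        counts,
        metadata,
        sizes=config.subset_sizes,
        n_subsets=config.n_subsets,
        min_avg_count=config.min_avg_count,
        exclusion_percentile=config.exclusion_percentile,
        pair_mode=config.pair_mode,
        max_pairs=config.max_pairs,
    )
    res = model.fit(seed=_child_seed(config.seed, "de"))
    res.similarity_records().to_csv(out / "similarity.tsv", sep="\t", index=False)
    pieces = [res.summary()]
    for quality in config.quality_metrics:
        res.quality_bin_tests(quality).to_csv(
            out / f"similarity_bins_{quality}.tsv", sep="\t", index=False
        )
        disc = pd.DataFrame(
            [
                {k: v for k, v in asdict(f).items() if k != "fit"}
                for f in res.discordance_fits(quality)
            ]
        )
        disc.to_csv(out / f"discordance_{quality}.tsv", sep="\t", index=False)
    formula = "combined" if len(config.subset_sizes) > 1 else "freeze_thaw_only"
    sim_fit = res.similarity_fit(formula)
    sim_fit.summary().to_csv(out / "similarity_fit.tsv", sep="\t")
    report.stages["de"] = pieces[0]
    report.outputs["de"] = ["similarity.tsv", "similarity_fit.tsv"] + [
        f"similarity_bins_{q}.tsv" for q in config.quality_metrics
    ] + [f"discordance_{q}.tsv" for q in config.quality_metrics]


def _stage_coverage(config, profiles, metadata, out, report):
    model = CoverageBiasModel(profiles, metadata)
    res = model.fit()
    res.table.to_csv(out / "mcp.tsv", sep="\t")
    rows = []
    for stratum in res.table["library_prep"].unique():
        sub = res.table[res.table["library_prep"] == stratum]
        if sub["freeze_thaw"].nunique() < 2 or len(sub) < 3:
            continue
        fit = res.bias_fit(stratum)
        rows.append(
            {
                "stratum": stratum,
                "slope_pp_per_log_cycle": fit.params["log_freeze_thaw"],
                "p_slope": fit.pvalues["log_freeze_thaw"],
                "n_samples": fit.nobs,
            }
        )
    fit_df = pd.DataFrame(rows)
    fit_df.to_csv(out / "mcp_fits.tsv", sep="\t", index=False)
    report.stages["coverage"] = fit_df
    report.outputs["coverage"] = ["mcp.tsv", "mcp_fits.tsv"]
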