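"""Synthetic cohorts with freeze-thaw-dependent degradation.

Generates gene x sample count matrices, sample metadata, and gene-body
coverage profiles with the statistical structure the downstream analyses
assume: technical replicates of each individual, negative-binomial counts
around log-normal gene means, per-cycle read randomization, RIN that decays
weakly and noisily with freeze-thaw, and a 3' coverage shift that grows with
the log of the cycle count in poly(A)-enriched samples only.

Degradation is modelled as the same random read loss/gain operator the noise
estimator inverts, applied once per freeze-thaw cycle to each replicate's
independent random stream: a replicate pair at *c* cycles therefore embodies
*c* cycles' worth of mutual randomness. This is a self-consistent generative
choice matching the noise definition, not a claim about degradation
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .noise import perturb

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "apply_freeze_thaw_degradation",
    "generate_coverage_profiles",
    "simulate_noise_table",
]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the emulated study design: 16 individuals with technical
    replicates (48 poly(A) samples, close to the study's 47), a 50/50 case /
    control split, 1-5 freeze-thaw cycles, about 4% of reads randomized per
    cycle, and a 1.12 percentage-point 3' coverage shift per natural-log
    cycle. Depth defaults to 25,000 reads per sample - the study's 25M
    scaled down by 1000x for desk-scale work; scale it back up via config.
    """

    n_individuals: int = 16
    replicates_per_individual: int = 3
    n_genes: int = 5000
    depth: int = 25_000
    group_fraction: float = 0.5
    de_fraction: float = 0.1
    de_lfc_sd: float = 0.5
    dispersion: float | np.ndarray = 0.005
    noise_per_cycle: float = 0.04
    bias_per_log_cycle: float = 1.12
    rin_baseline: float = 8.5
    rin_decay: float = 0.3
    rin_noise_sd: float = 0.4
    freeze_thaw_range: tuple[int, int] = (1, 5)
    library_prep: str = "polyA"
    #: SD of multiplicative log-noise applied per coverage bin.
    coverage_noise_sd: float = 0.05
    #: log-normal gene-mean distribution (natural-log mean / sd).
    log_mean_expression: float = 1.0
    log_sd_expression: float = 1.5
    #: per-gene, per-individual biological log2 jitter around the base means;
    #: deliberately modest so technical degradation, not inter-individual
    #: variability, dominates replicate comparisons.
    biological_lfc_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for name in ("n_individuals", "replicates_per_individual", "n_genes", "depth"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("group_fraction", "de_fraction", "noise_per_cycle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.freeze_thaw_range
        if lo < 0 or hi < lo:
            raise ConfigurationError(
                f"freeze_thaw_range must be a non-decreasing pair of "
                f"non-negative integers, got {self.freeze_thaw_range}"
            )
        if self.library_prep not in ("polyA", "ribo"):
            raise ConfigurationError(
                f"library_prep must be 'polyA' or 'ribo', got {self.library_prep!r}"
            )


def apply_freeze_thaw_degradation(
    counts, cycles: int, noise_per_cycle: float, rng: np.random.Generator
) -> np.ndarray:
    """Degrade a count vector by ``cycles`` rounds of read randomization.

    Each cycle removes and uniformly re-adds ``noise_per_cycle`` of the
    total reads (the perturbation operator of :mod:`ftqc.noise`); the total
    read count is preserved exactly. ``cycles=0`` returns the input
    unchanged.
    """
    if cycles < 0:
        raise DataError(f"cycles must be >= 0, got {cycles}")
    if not 0.0 <= noise_per_cycle <= 1.0:
        raise DataError("noise_per_cycle must lie in [0, 1]")
    out = np.asarray(counts, dtype=np.int64).copy()
    for _ in range(int(cycles)):
        out = perturb(out, noise_per_cycle, rng)
    return out


def _nb_draw(mean: np.ndarray, dispersion, rng) -> np.ndarray:
    """Negative-binomial counts via the gamma-Poisson mixture.

    ``dispersion`` is the NB alpha (Var = mu + alpha * mu^2); alpha -> 0
    falls back to Poisson.
    """
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), mean.shape)
    lam = np.where(
        alpha > 0,
        rng.gamma(np.where(alpha > 0, 1.0 / np.maximum(alpha, 1e-12), 1.0)) *
        np.maximum(alpha, 1e-12) * mean,
        mean,
    )
    return rng.poisson(lam)


def generate_cohort(config: SyntheticConfig):
    """Generate counts, metadata, and the generating-truth record.

    Each individual gets one base expression vector (log-normal gene means,
    a group log2 fold change on the flagged DE genes, and per-individual
    biological jitter); each of its technical replicates draws counts
    negative-binomially around those means at the configured depth, shares
    the individual's freeze-thaw cycle count, and is then degraded by
    :func:`apply_freeze_thaw_degradation` on its own random stream.

    Returns ``(counts, metadata, truth)`` where ``truth`` records the
    generating per-gene LFCs, the DE gene flags, per-sample degradation
    fractions, and baseline gene means.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    base = rng.lognormal(cfg.log_mean_expression, cfg.log_sd_expression, cfg.n_genes)
    p = base / base.sum()

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    lfc = np.zeros(cfg.n_genes)
    lfc[de_idx] = rng.normal(0.0, cfg.de_lfc_sd, n_de)

    n_asd = int(round(cfg.group_fraction * cfg.n_individuals))
    order = rng.permutation(cfg.n_individuals)
    groups = np.array(["TD"] * cfg.n_individuals, dtype=object)
    groups[order[:n_asd]] = "ASD"

    # Freeze-thaw exposure is an assigned experimental condition: spread the
    # cycle counts evenly over the configured range within each group (in a
    # random order) so that neither group nor any expression pattern is
    # confounded with freeze-thaw by an unlucky draw.
    lo, hi = cfg.freeze_thaw_range
    levels = np.arange(lo, hi + 1)
    ind_cycles = np.empty(cfg.n_individuals, dtype=int)
    for label in ("ASD", "TD"):
        idx = np.flatnonzero(groups == label)
        assigned = np.resize(levels, idx.size)
        ind_cycles[idx] = rng.permutation(assigned)

    counts = {}
    meta_rows = []
    degr = {}
    for i in range(cfg.n_individuals):
        ind_id = f"I{i:02d}"
        shift = lfc if groups[i] == "ASD" else 0.0
        jitter = (
            rng.normal(0.0, cfg.biological_lfc_sd, cfg.n_genes)
            if cfg.biological_lfc_sd > 0
            else 0.0
        )
        mean_i = cfg.depth * p * np.exp2(shift + jitter)
        cycles = int(ind_cycles[i])
        for r in range(cfg.replicates_per_individual):
            sid = f"S{i:02d}R{r}"
            raw = _nb_draw(mean_i, cfg.dispersion, rng)
            degraded = apply_freeze_thaw_degradation(
                raw, cycles, cfg.noise_per_cycle, rng
            )
            counts[sid] = degraded
            rin = float(
                np.clip(
                    cfg.rin_baseline
                    - cfg.rin_decay * (cycles - 1)
                    + rng.normal(0.0, cfg.rin_noise_sd),
                    1.0,
                    10.0,
                )
            )
            meta_rows.append(
                {
                    "sample_id": sid,
                    "individual_id": ind_id,
                    "group": groups[i],
                    "freeze_thaw": cycles,
                    "rin": round(rin, 2),
                    "library_prep": cfg.library_prep,
                    "concentration": round(float(rng.lognormal(np.log(50.0), 0.4)), 2),
                }
            )
            degr[sid] = cycles * cfg.noise_per_cycle

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))
    metadata = pd.DataFrame(meta_rows)
    truth = {
        "lfc": lfc,
        "de_genes": [genes[i] for i in sorted(de_idx)],
        "degradation_fraction": degr,
        "gene_means": cfg.depth * p,
        "groups": {f"I{i:02d}": groups[i] for i in range(cfg.n_individuals)},
    }
    return counts_df, metadata, truth


# ---------------------------------------------------------------------------
# coverage profiles

_N_BINS = 101


def _polya_baseline() -> np.ndarray:
    """Smooth unimodal coverage shape leaning slightly 3' of center.

    The shape's tails vanish well inside the [0, 100] percentile window so
    that a small translation moves the median coverage percentile by the
    same amount without edge truncation.
    """
    x = np.arange(_N_BINS, dtype=float)
    return np.exp(-0.5 * ((x - 55.0) / 12.0) ** 2)


def _ribo_baseline() -> np.ndarray:
    """Near-uniform shape with a mild read drop-off at the transcript ends."""
    x = np.arange(_N_BINS, dtype=float)
    return 1.0 - 0.3 * np.exp(-x / 3.0) - 0.3 * np.exp(-(100.0 - x) / 3.0)


def _shifted_polya(delta: float) -> np.ndarray:
    x = np.arange(_N_BINS, dtype=float)
    return np.exp(-0.5 * ((x - delta - 55.0) / 12.0) ** 2)


def generate_coverage_profiles(
    metadata: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-sample 101-bin gene-body coverage profiles.

    Ribosomal-depletion samples draw from a near-uniform baseline
    independent of freeze-thaw. Poly(A) samples draw from a unimodal
    baseline translated toward the 3' end by
    ``bias_per_log_cycle * ln(cycles)`` percentage points, so one freeze-thaw
    (ln 1 = 0) reproduces the baseline. Multiplicative log-normal bin noise
    with SD ``coverage_noise_sd`` is applied when non-zero. Profiles are
    non-negative and scaled to a maximum of 1 within each sample.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    profiles = {}
    for row in metadata.itertuples(index=False):
        prep = row.library_prep
        if prep == "ribo":
            shape = _ribo_baseline()
        elif prep == "polyA":
            cycles = max(int(row.freeze_thaw), 1)
            shape = _shifted_polya(config.bias_per_log_cycle * np.log(cycles))
        else:
            raise DataError(f"unknown library prep label {prep!r}")
        if config.coverage_noise_sd > 0:
            shape = shape * np.exp(
                rng.normal(0.0, config.coverage_noise_sd, _N_BINS)
            )
        profiles[row.sample_id] = shape / shape.max()
    out = pd.DataFrame(profiles).T
    out.columns = [f"p{i}" for i in range(_N_BINS)]
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# direct noise-table synthesis (for regression recovery studies)


def simulate_noise_table(
    n0: float,
    delta_n: float,
    cycles,
    resid_sd: float,
    rng: np.random.Generator | None = None,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Noise observations drawn from a known linear freeze-thaw model.

    ``noise_percent = n0 + delta_n * cycles + Normal(0, resid_sd)``, clipped
    to [0, 100]. Used to study the noise regression's estimator and
    confidence-interval behaviour with a known generating truth; RIN and
    concentration covariates are filled in with neutral values so the table
    passes through :func:`ftqc.noise.fit_noise_model` unchanged.
    """
    if rng is None:
        rng = np.random.default_rng()
    cycles = np.asarray(cycles, dtype=float)
    noise = np.clip(
        n0 + delta_n * cycles + rng.normal(0.0, resid_sd, cycles.size), 0.0, 100.0
    )
    return pd.DataFrame(
        {
            "reference_id": [f"P{i}a" for i in range(cycles.size)],
            "target_id": [f"P{i}b" for i in range(cycles.size)],
            "metric": metric,
            "noise_percent": noise,
            "freeze_thaw": cycles.astype(int),
            "rin": 8.0,
            "concentration": 50.0,
        }
    )
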