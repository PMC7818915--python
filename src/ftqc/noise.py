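"""Technical-replicate noise estimation by read-randomization matching.

"Noise" between two technical replicates is defined as the fraction of reads
in the reference replicate that behave as randomly counted rather than
mapping to a sample-specific gene. It is estimated by simulation: reads are
randomly removed from and re-added to the reference replicate at a trial
fraction *f*, and *f* is adjusted until the dissimilarity between the
simulated replicate and the reference matches the observed dissimilarity
between target and reference. Because the expected dissimilarity is monotone
in *f*, the match is found by bisection on [0, 1].

Four dissimilarity metrics are supported: Euclidean distance, RMSE, and
Pearson / Spearman correlation (correlations are reported as ``1 - r`` so
all four increase with dissimilarity). Counts are log2(x+1)-transformed
before the Euclidean, RMSE and Pearson metrics (raw Euclidean distance is
dominated by a handful of high expressors); Spearman operates on ranks and
needs no transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._linfit import LinearFit, fit_linear
from .errors import DataError, InsufficientDataError

__all__ = [
    "METRICS",
    "NoiseOptions",
    "NoiseEstimate",
    "NoiseRegressionFit",
    "dissimilarity",
    "perturb",
    "estimate_noise",
    "pair_noise_table",
    "replicate_pairs",
    "fit_noise_model",
    "ReplicateNoiseModel",
    "ReplicateNoiseResults",
]

METRICS = ("euclidean", "rmse", "pearson", "spearman")


# ---------------------------------------------------------------------------
# dissimilarity metrics


def _apply_transform(x: np.ndarray, transform) -> np.ndarray:
    if transform is None:
        return np.asarray(x, dtype=float)
    if transform == "log2p1":
        return np.log2(np.asarray(x, dtype=float) + 1.0)
    if callable(transform):
        return np.asarray(transform(x), dtype=float)
    raise DataError(f"unknown transform {transform!r}")


def dissimilarity(x, y, metric: str, transform=None) -> float:
    """Dissimilarity between two equal-length numeric vectors.

    ``euclidean`` is the L2 distance, ``rmse`` is L2 / sqrt(n), and the
    correlation metrics are returned as ``1 - r`` so that every metric is
    non-negative and increases as the vectors diverge. ``transform`` (e.g.
    ``"log2p1"``) is applied to both vectors before the non-rank metrics;
    Spearman always uses ranks of the raw values.

    A constant vector under a correlation metric yields NaN with a warning
    (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise DataError("vectors must have length >= 2")
    if metric not in METRICS:
        raise DataError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if metric == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("constant vector: Spearman dissimilarity undefined")
            return float("nan")
        return 1.0 - float(stats.spearmanr(x, y).statistic)
    tx, ty = _apply_transform(x, transform), _apply_transform(y, transform)
    if metric == "euclidean":
        return float(np.linalg.norm(tx - ty))
    if metric == "rmse":
        return float(np.linalg.norm(tx - ty) / np.sqrt(tx.size))
    # pearson
    if np.ptp(tx) == 0 or np.ptp(ty) == 0:
        warnings.warn("constant vector: Pearson dissimilarity undefined")
        return float("nan")
    return 1.0 - float(stats.pearsonr(tx, ty).statistic)


def _batch_dissimilarity(
    ref: np.ndarray, mat: np.ndarray, metric: str, transform
) -> np.ndarray:
    """Dissimilarity of each row of ``mat`` against ``ref`` (vectorized)."""
    if metric == "spearman":
        r_ref = stats.rankdata(ref)
        r_mat = stats.rankdata(mat, axis=1)
        a = r_ref - r_ref.mean()
        b = r_mat - r_mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((a * a).sum()) * np.sqrt((b * b).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (b @ a) / denom
        return 1.0 - r
    t_ref = _apply_transform(ref, transform)
    t_mat = _apply_transform(mat, transform)
    if metric == "euclidean":
        return np.linalg.norm(t_mat - t_ref, axis=1)
    if metric == "rmse":
        return np.linalg.norm(t_mat - t_ref, axis=1) / np.sqrt(t_ref.size)
    a = t_ref - t_ref.mean()
    b = t_mat - t_mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum()) * np.sqrt((b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (b @ a) / denom
    return 1.0 - r


# ---------------------------------------------------------------------------
# perturbation kernel


def perturb(
    reference,
    f: float,
    rng: np.random.Generator,
    removal: str = "proportional",
    addition: str = "uniform",
):
    """Randomly remove and re-add a fraction ``f`` of the reference's reads.

    ``round(f * T)`` reads (T = total reads) are removed without replacement
    with probability proportional to current counts (``removal="uniform"``
    removes uniformly over genes instead, capped at each gene's count), then
    the same number of reads is added uniformly at random over genes
    (``addition="proportional"`` adds proportionally to the original counts).
    The total read count is preserved exactly and counts stay non-negative.
    """
    ref = np.asarray(reference)
    if np.any(ref < 0):
        raise DataError("reference counts must be non-negative")
    if not 0.0 <= f <= 1.0:
        raise DataError(f"perturbation fraction must be in [0, 1], got {f}")
    return _perturb_batch(ref.astype(np.int64), f, rng, 1, removal, addition)[0]


def _perturb_batch(
    ref: np.ndarray,
    f: float,
    rng: np.random.Generator,
    size: int,
    removal: str = "proportional",
    addition: str = "uniform",
) -> np.ndarray:
    """``size`` independent perturbations of ``ref`` as a (size, G) matrix."""
    total = int(ref.sum())
    if total <= 0:
        raise DataError("reference must have a positive total read count")
    k = int(round(f * total))
    if k == 0:
        return np.tile(ref, (size, 1))
    if removal == "proportional":
        removed = rng.multivariate_hypergeometric(ref, k, size=size)
    elif removal == "uniform":
        removed = np.minimum(
            rng.multinomial(k, np.full(ref.size, 1.0 / ref.size), size=size), ref
        )
    else:
        raise DataError(f"unknown removal kernel {removal!r}")
    if addition == "uniform":
        p_add = np.full(ref.size, 1.0 / ref.size)
    elif addition == "proportional":
        p_add = ref / total
    else:
        raise DataError(f"unknown addition kernel {addition!r}")
    added = rng.multinomial(k, p_add, size=size)
    return ref - removed + added


# ---------------------------------------------------------------------------
# noise estimation


@dataclass
class NoiseOptions:
    """Tuning parameters for :func:`estimate_noise`.

    ``tolerance`` is the relative mismatch between simulated and observed
    dissimilarity below which the estimate is flagged converged; ``f_tol``
    is the bisection interval width at which iteration stops; ``n_repeats``
    perturbations are averaged per dissimilarity evaluation to tame
    Monte-Carlo jitter.
    """

    tolerance: float = 0.1
    f_tol: float = 1e-3
    max_iterations: int = 40
    n_repeats: int = 25
    transform: str | None = "log2p1"
    removal: str = "proportional"
    addition: str = "uniform"


@dataclass
class NoiseEstimate:
    """Estimated percent randomness between one replicate pair, one metric."""

    reference_id: str
    target_id: str
    metric: str
    noise_percent: float
    target_dissimilarity: float
    converged: bool
    n_iterations: int


def estimate_noise(
    reference,
    target,
    metric: str,
    rng=None,
    options: NoiseOptions | None = None,
    reference_id: str = "reference",
    target_id: str = "target",
) -> NoiseEstimate:
    """Estimate percent noise between a reference and a target replicate.

    Solves ``E[D(f)] = D*`` for the perturbation fraction ``f`` by bisection,
    where ``D*`` is the observed reference-target dissimilarity and ``D(f)``
    averages the dissimilarity of ``n_repeats`` perturbed copies of the
    reference. Returns ``noise_percent = 100 * f_hat``. If the replicates
    are more dissimilar than pure randomness (``D* > D(1)``) the estimate is
    pinned at 100% with ``converged=False``.
    """
    opts = options or NoiseOptions()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    ref = np.asarray(reference, dtype=np.int64)
    tgt = np.asarray(target, dtype=np.int64)
    if ref.shape != tgt.shape:
        raise DataError("reference and target must have equal length")
    if ref.sum() <= 0 or tgt.sum() <= 0:
        raise DataError("replicates must have positive total counts")

    transform = opts.transform if metric != "spearman" else None
    d_star = dissimilarity(ref, tgt, metric, transform=transform)
    if not np.isfinite(d_star):
        raise DataError(f"observed dissimilarity undefined under {metric!r}")

    def d_of(f: float) -> float:
        mat = _perturb_batch(ref, f, rng, opts.n_repeats, opts.removal, opts.addition)
        return float(
            np.nanmean(_batch_dissimilarity(ref, mat, metric, opts.transform))
        )

    if d_star <= 0:
        return NoiseEstimate(reference_id, target_id, metric, 0.0, d_star, True, 0)
    if d_star > d_of(1.0):
        return NoiseEstimate(
            reference_id, target_id, metric, 100.0, d_star, False, 0
        )

    lo, hi = 0.0, 1.0
    d_mid = np.inf
    n_iter = 0
    for n_iter in range(1, opts.max_iterations + 1):
        mid = 0.5 * (lo + hi)
        d_mid = d_of(mid)
        if d_mid < d_star:
            lo = mid
        else:
            hi = mid
        if hi - lo < opts.f_tol:
            break
    f_hat = 0.5 * (lo + hi)
    converged = abs(d_mid - d_star) <= opts.tolerance * d_star
    return NoiseEstimate(
        reference_id, target_id, metric, 100.0 * f_hat, d_star, converged, n_iter
    )


# ---------------------------------------------------------------------------
# replicate pairing and the noise table


def replicate_pairs(metadata: pd.DataFrame) -> list[tuple[str, str]]:
    """Unordered technical-replicate pairs eligible for noise estimation.

    Replicates belong to the same individual and are only compared when they
    underwent the same number of freeze-thaw cycles; the reference is the
    replicate appearing first in metadata order.
    """
    pairs = []
    for (_ind, _ft), grp in metadata.groupby(
        ["individual_id", "freeze_thaw"], sort=False
    ):
        ids = grp["sample_id"].tolist()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
    return pairs


def pair_noise_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    metrics="all",
    seed: int = 0,
    options: NoiseOptions | None = None,
    orientation: str = "first",
) -> pd.DataFrame:
    """Estimate noise for every replicate pair under every requested metric.

    Returns one row per pair x metric with the pair's quality covariates
    (freeze-thaw cycles, mean RIN, mean input concentration) joined in, ready
    for :func:`fit_noise_model`. ``orientation="both"`` averages the estimate
    over both reference/target assignments.
    """
    if metrics == "all":
        metrics = METRICS
    elif isinstance(metrics, str):
        metrics = (metrics,)
    opts = options or NoiseOptions()
    meta = metadata.set_index("sample_id")
    pairs = replicate_pairs(metadata)
    if not pairs:
        raise InsufficientDataError("no same-cycle technical replicate pairs found")
    seeds = np.random.SeedSequence(seed).spawn(len(pairs) * len(metrics))
    rows = []
    si = 0
    for ref_id, tgt_id in pairs:
        ref = counts[ref_id].to_numpy()
        tgt = counts[tgt_id].to_numpy()
        for metric in metrics:
            rng = np.random.default_rng(seeds[si])
            si += 1
            est = estimate_noise(
                ref, tgt, metric, rng, opts, reference_id=ref_id, target_id=tgt_id
            )
            noise = est.noise_percent
            if orientation == "both":
                back = estimate_noise(
                    tgt, ref, metric, rng, opts, reference_id=tgt_id, target_id=ref_id
                )
                noise = 0.5 * (noise + back.noise_percent)
            rows.append(
                {
                    "reference_id": ref_id,
                    "target_id": tgt_id,
                    "individual_id": meta.loc[ref_id, "individual_id"],
                    "metric": metric,
                    "noise_percent": noise,
                    "target_dissimilarity": est.target_dissimilarity,
                    "converged": est.converged,
                    "n_iterations": est.n_iterations,
                    "freeze_thaw": int(meta.loc[ref_id, "freeze_thaw"]),
                    "rin": float(
                        np.mean([meta.loc[ref_id, "rin"], meta.loc[tgt_id, "rin"]])
                    ),
                    "concentration": float(
                        np.mean(
                            [
                                meta.loc[ref_id, "concentration"],
                                meta.loc[tgt_id, "concentration"],
                            ]
                        )
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quality regressions


@dataclass
class NoiseRegressionFit:
    """Linear fit of percent noise on a quality predictor.

    ``intercept`` is N0, the expected noise at zero of the predictor (e.g.
    without freeze-thaw); ``slope`` is the expected percentage-point change
    in noise per unit predictor (one freeze-thaw cycle, one RIN point, ...).
    """

    predictor: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_intercept: float
    p_slope: float
    conf_int: pd.DataFrame
    n_samples_used: int
    stratum: int | None = None
    fit: LinearFit = field(repr=False, default=None)


def _single_fit(table, predictor, stratum=None) -> NoiseRegressionFit:
    lf = fit_linear(table["noise_percent"], table[[predictor]])
    return NoiseRegressionFit(
        predictor=predictor,
        intercept=float(lf.params["Intercept"]),
        slope=float(lf.params[predictor]),
        se_intercept=float(lf.bse["Intercept"]),
        se_slope=float(lf.bse[predictor]),
        p_intercept=float(lf.pvalues["Intercept"]),
        p_slope=float(lf.pvalues[predictor]),
        conf_int=lf.conf_int,
        n_samples_used=lf.nobs,
        stratum=stratum,
        fit=lf,
    )


def fit_noise_model(
    noise_table: pd.DataFrame,
    predictor: str = "freeze_thaw",
    metric: str | None = None,
    concentration_z_threshold: float = 1.645,
):
    """Regress percent noise on a sample-quality predictor.

    Before fitting, rows whose input RNA concentration lies in the top or
    bottom 5% (|z| >= 1.645) are removed to mitigate confounding. When
    ``predictor="concentration"``, rows with more than one freeze-thaw cycle
    are additionally excluded. When ``predictor="rin"``, separate fits are
    returned for each freeze-thaw stratum with enough rows (the association
    between RIN and noise differs by freeze-thaw count), as a dict keyed by
    cycle count.

    If the table holds several metrics and ``metric`` is None, a dict keyed
    by metric is returned.
    """
    if predictor not in ("freeze_thaw", "rin", "concentration"):
        raise DataError(f"unknown predictor {predictor!r}")
    table = noise_table
    if "metric" in table.columns:
        present = table["metric"].unique()
        if metric is None and len(present) > 1:
            return {
                m: fit_noise_model(
                    table[table["metric"] == m],
                    predictor,
                    metric=m,
                    concentration_z_threshold=concentration_z_threshold,
                )
                for m in present
            }
        if metric is not None:
            table = table[table["metric"] == metric]
    table = table.dropna(subset=["noise_percent", predictor]).copy()

    conc = table["concentration"]
    if conc.notna().any() and conc.std(ddof=1) > 0:
        z = (conc - conc.mean()) / conc.std(ddof=1)
        table = table[z.abs() < concentration_z_threshold]
    if predictor == "concentration":
        table = table[table["freeze_thaw"] <= 1]
    if predictor == "rin":
        fits = {}
        for cycle, grp in table.groupby("freeze_thaw"):
            if len(grp) >= 3 and grp["rin"].var() > 0:
                fits[int(cycle)] = _single_fit(grp, "rin", stratum=int(cycle))
        if not fits:
            raise InsufficientDataError(
                "no freeze-thaw stratum with >= 3 rows and RIN variance"
            )
        return fits
    return _single_fit(table, predictor)


# ---------------------------------------------------------------------------
# model / results interface


class ReplicateNoiseModel:
    """Noise analysis over all technical-replicate pairs of a cohort.

    Parameters
    ----------
    counts : pd.DataFrame
        Gene x sample count matrix.
    metadata : pd.DataFrame
        Sample metadata (see :mod:`ftqc.io`).
    metrics : "all" or sequence of metric names
    options : NoiseOptions
    """

    def __init__(self, counts, metadata, metrics="all", options=None,
                 orientation: str = "first"):
        from .io import align_counts_metadata

        self.counts, self.metadata = align_counts_metadata(counts, metadata)
        self.metrics = metrics
        self.options = options or NoiseOptions()
        self.orientation = orientation

    def fit(self, seed: int = 0) -> "ReplicateNoiseResults":
        table = pair_noise_table(
            self.counts,
            self.metadata,
            metrics=self.metrics,
            seed=seed,
            options=self.options,
            orientation=self.orientation,
        )
        return ReplicateNoiseResults(self, table)


class ReplicateNoiseResults:
    """Per-pair noise estimates plus quality regressions."""

    def __init__(self, model: ReplicateNoiseModel, noise_table: pd.DataFrame):
        self.model = model
        self.noise_table = noise_table

    def regress(self, predictor: str = "freeze_thaw", metric: str | None = None):
        return fit_noise_model(self.noise_table, predictor, metric=metric)

    def summary(self) -> pd.DataFrame:
        """Median noise per metric and freeze-thaw count."""
        return (
            self.noise_table.groupby(["metric", "freeze_thaw"])["noise_percent"]
            .agg(["count", "median", "mean", "std"])
            .reset_index()
        )
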