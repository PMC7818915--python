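"""Differential-expression reproducibility under subset resampling.

Reproducibility of an ASD-vs-TD differential expression analysis is probed
by drawing many balanced subsets of the cohort (equal ASD and TD counts, at
most one technical replicate per individual), running DE within each
subset, and comparing results across subsets:

* **similarity** - the Spearman correlation of log2-fold-change vectors
  between two subsets of the same size; higher is more reproducible.
* **discordance** - the per-gene standard deviation of LFC across subsets;
  lower is more reproducible, and its slope against effect size (dD)
  contrasts high- vs low-quality subsets.

The default DE engine is an internal median-of-ratios + negative-binomial
delta-method Wald estimator; any callable honouring the same per-gene output
contract (e.g. a DESeq2 bridge) can be plugged in.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._linfit import LinearFit, fit_linear
from .errors import DataError, InsufficientDataError

__all__ = [
    "SubsetSpec",
    "SubsetDEResult",
    "DiscordanceFit",
    "filter_genes",
    "eligible_samples",
    "max_balanced_subsets",
    "enumerate_subsets",
    "run_de",
    "default_de_engine",
    "compute_similarity_table",
    "compare_quality_bins",
    "fit_similarity_model",
    "bin_subsets_by_quality",
    "compute_discordance",
    "fit_discordance_model",
    "adjust_discordance_fits",
    "SubsetReproducibilityModel",
    "ReproducibilityResults",
]

log = logging.getLogger(__name__)

EFFECT_METRICS = ("mvse", "cohens_d", "abs_median_lfc")


# ---------------------------------------------------------------------------
# gene filtering


def filter_genes(counts: pd.DataFrame, min_avg_count: float = 20.0) -> pd.DataFrame:
    """Drop genes whose average count across all samples is <= the threshold.

    Only genes with a strictly greater average are retained. Emits a warning
    (not an error) if nothing survives.
    """
    if counts.empty:
        raise DataError("empty count matrix")
    keep = counts.mean(axis=1) > min_avg_count
    out = counts.loc[keep]
    log.info("gene filter (> %g avg count): %d -> %d genes",
             min_avg_count, counts.shape[0], out.shape[0])
    if out.empty:
        warnings.warn(
            f"no genes exceed an average count of {min_avg_count}; "
            "downstream analyses will be empty"
        )
    return out


# ---------------------------------------------------------------------------
# balanced subset enumeration


@dataclass(frozen=True)
class SubsetSpec:
    """One balanced subset: equal ASD/TD membership, one replicate per
    individual."""

    subset_id: int
    size: int
    sample_ids: tuple[str, ...]
    avg_freeze_thaw: float
    avg_rin: float


def eligible_samples(metadata: pd.DataFrame) -> pd.DataFrame:
    """Samples usable for subset DE: ASD or TD, with recorded quality."""
    ok = (
        metadata["group"].isin(["ASD", "TD"])
        & metadata["rin"].notna()
        & metadata["freeze_thaw"].notna()
    )
    return metadata[ok].reset_index(drop=True)


def _symmetric_combo_count(replicate_counts: list[int], k: int) -> int:
    """Number of ways to pick k individuals and one replicate from each:
    the k-th elementary symmetric polynomial of the replicate counts."""
    e = [0] * (k + 1)
    e[0] = 1
    for r in replicate_counts:
        for j in range(min(k, len(e) - 1), 0, -1):
            e[j] += r * e[j - 1]
    return e[k]


def max_balanced_subsets(metadata: pd.DataFrame, size: int) -> int:
    """Combinatorial maximum of distinct balanced subsets of ``size``."""
    elig = eligible_samples(metadata)
    k = size // 2
    total = 1
    for grp in ("ASD", "TD"):
        reps = elig[elig["group"] == grp].groupby("individual_id").size().tolist()
        total *= _symmetric_combo_count(reps, k)
    return total


def enumerate_subsets(
    metadata: pd.DataFrame,
    size: int,
    n_subsets: int,
    rng: np.random.Generator | None = None,
    max_attempts_per_subset: int = 200,
) -> list[SubsetSpec]:
    """Draw distinct balanced subsets uniformly at random.

    Each subset has ``size/2`` ASD and ``size/2`` TD samples with at most
    one replicate per individual. Samples lacking a group assignment
    (industry standards, unassigned) or a recorded quality value are
    excluded up front. Sampling is rejection-based: a uniform draw of
    ``size/2`` samples from each group is kept only if no two share an
    individual, which makes accepted subsets uniform over the valid set.
    If ``n_subsets`` exceeds the combinatorial maximum, the full set size is
    capped with a warning.
    """
    if size % 2 != 0 or size < 2:
        raise DataError(f"subset size must be a positive even integer, got {size}")
    if rng is None:
        rng = np.random.default_rng()
    elig = eligible_samples(metadata)
    k = size // 2
    by_group = {}
    for grp in ("ASD", "TD"):
        sub = elig[elig["group"] == grp]
        if sub["individual_id"].nunique() < k:
            raise InsufficientDataError(
                f"group {grp} has {sub['individual_id'].nunique()} eligible "
                f"individuals; {k} needed for size {size}"
            )
        by_group[grp] = (
            sub["sample_id"].to_numpy(),
            sub["individual_id"].to_numpy(),
        )
    cap = max_balanced_subsets(metadata, size)
    if n_subsets > cap:
        warnings.warn(
            f"requested {n_subsets} subsets of size {size} but only {cap} "
            "distinct balanced subsets exist; capping"
        )
        n_subsets = cap

    meta = elig.set_index("sample_id")
    seen: set[frozenset] = set()
    specs: list[SubsetSpec] = []
    attempts_left = max_attempts_per_subset * n_subsets + 1000
    while len(specs) < n_subsets and attempts_left > 0:
        attempts_left -= 1
        members: list[str] = []
        ok = True
        for grp in ("ASD", "TD"):
            ids, inds = by_group[grp]
            pick = rng.choice(ids.size, size=k, replace=False)
            if len(set(inds[pick])) < k:  # replicate collision -> reject
                ok = False
                break
            members.extend(ids[pick])
        if not ok:
            continue
        key = frozenset(members)
        if key in seen:
            continue
        seen.add(key)
        rows = meta.loc[members]
        specs.append(
            SubsetSpec(
                subset_id=len(specs),
                size=size,
                sample_ids=tuple(members),
                avg_freeze_thaw=float(rows["freeze_thaw"].mean()),
                avg_rin=float(rows["rin"].mean()),
            )
        )
    if len(specs) < n_subsets:
        warnings.warn(
            f"drew only {len(specs)}/{n_subsets} distinct subsets of size "
            f"{size} within the attempt budget"
        )
    return specs


# ---------------------------------------------------------------------------
# per-subset differential expression


@dataclass
class SubsetDEResult:
    """Per-gene DE results for one subset.

    ``table`` columns: lfc (log2 fold change ASD vs TD), se, base_mean
    (mean depth-normalized count over the subset), wald_stat (lfc/se), and
    cohens_d (|group mean difference| of log2 normalized counts over pooled
    SD).
    """

    subset_id: int
    size: int
    table: pd.DataFrame = field(repr=False)


def _median_of_ratios_size_factors(mat: np.ndarray) -> np.ndarray:
    """DESeq-style size factors over the subset's samples."""
    positive = np.all(mat > 0, axis=1)
    if positive.sum() >= 10:
        log_geo = np.mean(np.log(mat[positive]), axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(mat[positive]) - log_geo, axis=0))
    else:  # too few all-positive genes: fall back to library-size factors
        totals = mat.sum(axis=0).astype(float)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def default_de_engine(
    submatrix: pd.DataFrame,
    is_asd: np.ndarray,
    pseudocount: float = 0.5,
    se_floor: float = 1e-6,
) -> pd.DataFrame:
    """Internal DE engine: median-of-ratios normalization + NB delta-method
    Wald statistics.

    LFC is ``log2((mu_ASD + eps) / (mu_TD + eps))`` on normalized group
    means. The LFC standard error comes from the delta method under an NB
    variance ``mu + alpha mu^2`` with a pooled method-of-moments dispersion
    estimate, floored at a small positive constant.
    """
    mat = submatrix.to_numpy(dtype=float)
    n_asd, n_td = int(is_asd.sum()), int((~is_asd).sum())
    if n_asd == 0 or n_td == 0:
        raise DataError("subset must contain both ASD and TD samples")
    sf = _median_of_ratios_size_factors(mat)
    norm = mat / sf
    a, t = norm[:, is_asd], norm[:, ~is_asd]
    mu_a, mu_t = a.mean(axis=1), t.mean(axis=1)
    lfc = np.log2((mu_a + pseudocount) / (mu_t + pseudocount))
    base_mean = norm.mean(axis=1)

    # pooled within-group method-of-moments NB dispersion
    var_w = 0.5 * (a.var(axis=1, ddof=1) + t.var(axis=1, ddof=1)) \
        if min(n_asd, n_td) > 1 else np.zeros_like(mu_a)
    mu_w = 0.5 * (mu_a + mu_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.clip((var_w - mu_w) / np.where(mu_w > 0, mu_w**2, 1.0), 0.0, None)
    var_mean_a = (mu_a + alpha * mu_a**2) / n_asd
    var_mean_t = (mu_t + alpha * mu_t**2) / n_td
    se = np.sqrt(
        var_mean_a / (mu_a + pseudocount) ** 2
        + var_mean_t / (mu_t + pseudocount) ** 2
    ) / np.log(2.0)
    se = np.maximum(se, se_floor)
    with np.errstate(invalid="ignore"):
        wald = np.where(se > 0, lfc / se, 0.0)

    # Cohen's d on log2 normalized counts
    la, lt = np.log2(a + 1.0), np.log2(t + 1.0)
    sa = la.var(axis=1, ddof=1) if n_asd > 1 else np.zeros_like(mu_a)
    st = lt.var(axis=1, ddof=1) if n_td > 1 else np.zeros_like(mu_t)
    dof = max(n_asd + n_td - 2, 1)
    pooled = np.sqrt(((n_asd - 1) * sa + (n_td - 1) * st) / dof)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            pooled > 0, np.abs(la.mean(axis=1) - lt.mean(axis=1)) / pooled, 0.0
        )
    return pd.DataFrame(
        {
            "lfc": lfc,
            "se": se,
            "base_mean": base_mean,
            "wald_stat": wald,
            "cohens_d": d,
        },
        index=submatrix.index,
    )


def run_de(
    counts: pd.DataFrame, subset: SubsetSpec, metadata: pd.DataFrame, engine=None
) -> SubsetDEResult:
    """Run differential expression within one subset.

    ``engine`` is any callable ``(submatrix, is_asd) -> per-gene DataFrame``
    with columns lfc / se / base_mean / wald_stat (cohens_d optional); the
    default is :func:`default_de_engine`.
    """
    missing = [s for s in subset.sample_ids if s not in counts.columns]
    if missing:
        raise DataError(f"subset members absent from counts: {missing}")
    engine = engine or default_de_engine
    sub = counts.loc[:, list(subset.sample_ids)]
    groups = metadata.set_index("sample_id").loc[list(subset.sample_ids), "group"]
    is_asd = (groups == "ASD").to_numpy()
    if is_asd.all() or not is_asd.any():
        raise DataError("subset contains a single group")
    table = engine(sub, is_asd)
    return SubsetDEResult(subset_id=subset.subset_id, size=subset.size, table=table)


# ---------------------------------------------------------------------------
# similarity


def _lfc_matrix(results: list[SubsetDEResult]) -> pd.DataFrame:
    mats = {r.subset_id: r.table["lfc"] for r in results}
    return pd.DataFrame(mats)


def _gene_retention_mask(
    results: list[SubsetDEResult],
    exclusion_percentile: float,
    use_lfc: bool = True,
    signed_median_lfc: bool = False,
) -> pd.Series:
    """Exclude genes in the bottom percentile of median base mean (and,
    optionally, of median |LFC|) across subsets."""
    def _above_bottom(values: pd.Series) -> pd.Series:
        if exclusion_percentile <= 0:
            return pd.Series(True, index=values.index)
        thr = np.percentile(values, exclusion_percentile)
        keep = values > thr
        # degenerate (tied) distributions: a strict cut would drop everything
        return keep if keep.any() else values >= thr

    bm = pd.DataFrame({r.subset_id: r.table["base_mean"] for r in results}).median(
        axis=1
    )
    keep = _above_bottom(bm)
    if use_lfc:
        lfc_med = _lfc_matrix(results).median(axis=1)
        mag = lfc_med if signed_median_lfc else lfc_med.abs()
        keep &= _above_bottom(mag)
    return keep


def _pair_indices(n: int, mode: str, max_pairs: int, rng) -> np.ndarray:
    all_pairs = n * (n - 1) // 2
    if mode == "disjoint":
        perm = rng.permutation(n)
        m = n // 2
        return np.column_stack([perm[:m], perm[m : 2 * m]])
    if mode != "sampled":
        raise DataError(f"unknown pair mode {mode!r}")
    if all_pairs <= max_pairs:
        iu = np.triu_indices(n, k=1)
        return np.column_stack(iu)
    # sample distinct unordered pairs by linear index
    flat = rng.choice(all_pairs, size=max_pairs, replace=False)
    # invert the triangular linear index
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(
        int
    )
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    return np.column_stack([i, j])


def compute_similarity_table(
    results: list[SubsetDEResult],
    subsets: list[SubsetSpec],
    exclusion_percentile: float = 10.0,
    pair_mode: str = "sampled",
    max_pairs: int = 10_000,
    rng: np.random.Generator | None = None,
    signed_median_lfc: bool = False,
) -> pd.DataFrame:
    """Pairwise Spearman similarity of LFC vectors between same-size subsets.

    Genes whose median base mean or median |LFC| across subsets falls in the
    bottom ``exclusion_percentile`` are removed before correlating. Pairs
    are all unordered pairs when few, otherwise a seeded random sample of
    ``max_pairs`` (``pair_mode="disjoint"`` instead draws a random perfect
    matching so that no subset appears in two pairs - pairs are then
    mutually independent, which rank-based tests on the pair list assume).

    Returns one row per pair with the similarity and pair-averaged quality
    covariates.
    """
    if len(results) < 2:
        raise InsufficientDataError("need at least 2 subsets for similarity")
    if rng is None:
        rng = np.random.default_rng()
    sizes = {r.size for r in results}
    if len(sizes) != 1:
        raise DataError("similarity compares subsets of a single size")
    size = sizes.pop()
    keep = _gene_retention_mask(
        results, exclusion_percentile, use_lfc=True,
        signed_median_lfc=signed_median_lfc,
    )
    if keep.sum() < 2:
        raise InsufficientDataError("fewer than 2 genes retained after exclusions")
    lfc = _lfc_matrix(results).loc[keep]
    ranks = lfc.rank(axis=0).to_numpy()
    z = ranks - ranks.mean(axis=0, keepdims=True)
    z /= np.sqrt((z * z).sum(axis=0, keepdims=True))
    spec_by_id = {s.subset_id: s for s in subsets}
    ids = list(lfc.columns)
    pairs = _pair_indices(len(ids), pair_mode, max_pairs, rng)
    sims = (z[:, pairs[:, 0]] * z[:, pairs[:, 1]]).sum(axis=0)
    rows = []
    for (ia, ib), s in zip(pairs, sims):
        sa, sb = spec_by_id[ids[ia]], spec_by_id[ids[ib]]
        rows.append(
            {
                "subset_a": ids[ia],
                "subset_b": ids[ib],
                "size": size,
                "similarity": float(s),
                "avg_freeze_thaw": 0.5 * (sa.avg_freeze_thaw + sb.avg_freeze_thaw),
                "avg_rin": 0.5 * (sa.avg_rin + sb.avg_rin),
            }
        )
    return pd.DataFrame(rows)


def _quality_high_mask(values: pd.Series, quality: str) -> pd.Series:
    """High-quality indicator with ties at the median sent to low quality."""
    med = values.median()
    if quality == "freeze_thaw":
        return values < med  # fewer cycles = higher quality
    if quality == "rin":
        return values > med
    raise DataError(f"unknown quality metric {quality!r}")


def compare_quality_bins(
    records: pd.DataFrame, quality: str = "freeze_thaw"
) -> pd.DataFrame:
    """Per-size one-sided Mann-Whitney U test: high-quality similarity
    exceeds low-quality.

    Pairs are median-split on the pair-averaged quality covariate (high
    quality = fewer freeze-thaw cycles or higher RIN; ties go to the
    low-quality bin). Also reports the high/low fold change of the median
    similarity. Sizes with an empty bin are skipped with a warning.
    """
    col = "avg_" + quality
    out = []
    for size, grp in records.groupby("size"):
        high = _quality_high_mask(grp[col], quality)
        s_hi, s_lo = grp.loc[high, "similarity"], grp.loc[~high, "similarity"]
        if len(s_hi) < 2 or len(s_lo) < 2:
            warnings.warn(f"size {size}: a quality bin is empty or degenerate; skipped")
            continue
        u, p = stats.mannwhitneyu(s_hi, s_lo, alternative="greater")
        med_lo = s_lo.median()
        out.append(
            {
                "size": size,
                "quality": quality,
                "n_high": len(s_hi),
                "n_low": len(s_lo),
                "median_high": s_hi.median(),
                "median_low": med_lo,
                "fold_change": s_hi.median() / med_lo if med_lo != 0 else np.inf,
                "u_stat": float(u),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(out)


_SIMILARITY_FORMULAS = {
    "combined": ["avg_freeze_thaw", "avg_rin", "size"],
    "freeze_thaw_only": ["avg_freeze_thaw"],
    "rin_only": ["avg_rin"],
}


def fit_similarity_model(
    records: pd.DataFrame, formula: str = "combined"
) -> LinearFit:
    """Linear (identity-link) fit of similarity on quality covariates.

    ``combined`` fits Similarity ~ Freeze-Thaw + RIN + Subset Size; the
    ``*_only`` variants fit a single quality covariate. The intercept is
    S0, the expected similarity at zero of the predictors.
    """
    if formula not in _SIMILARITY_FORMULAS:
        raise DataError(
            f"unknown formula {formula!r}; expected {sorted(_SIMILARITY_FORMULAS)}"
        )
    cols = _SIMILARITY_FORMULAS[formula]
    return fit_linear(records["similarity"], records[cols])


# ---------------------------------------------------------------------------
# discordance


def bin_subsets_by_quality(
    subsets: list[SubsetSpec], quality: str = "freeze_thaw"
) -> tuple[list[int], list[int]]:
    """Median-split subset ids into (low-quality, high-quality) bins."""
    vals = pd.Series(
        {s.subset_id: getattr(s, "avg_" + quality) for s in subsets}
    )
    high = _quality_high_mask(vals, quality)
    return list(vals.index[~high]), list(vals.index[high])


def compute_discordance(
    results: list[SubsetDEResult],
    effect_metric: str = "mvse",
    exclusion_percentile: float = 10.0,
) -> pd.DataFrame:
    """Per-gene (discordance, effect size) over a set of same-size subsets.

    Discordance is the sample SD (n-1 denominator) of each gene's LFC
    across subsets. Effect size is one of:

    * ``mvse`` - median across subsets of the Wald-standardized LFC |lfc/se|
      (the mean-variance standardized effect);
    * ``cohens_d`` - median across subsets of per-subset Cohen's d on log2
      normalized counts;
    * ``abs_median_lfc`` - |median LFC| across subsets.

    Genes with a median base mean in the bottom percentile across subsets
    are excluded.
    """
    if len(results) < 2:
        raise InsufficientDataError("discordance needs >= 2 subsets")
    if effect_metric not in EFFECT_METRICS:
        raise DataError(
            f"unknown effect metric {effect_metric!r}; expected {EFFECT_METRICS}"
        )
    keep = _gene_retention_mask(results, exclusion_percentile, use_lfc=False)
    lfc = _lfc_matrix(results).loc[keep]
    disc = lfc.std(axis=1, ddof=1)
    if effect_metric == "mvse":
        eff = pd.DataFrame(
            {r.subset_id: r.table["wald_stat"].abs() for r in results}
        ).loc[keep].median(axis=1)
    elif effect_metric == "cohens_d":
        eff = pd.DataFrame(
            {r.subset_id: r.table["cohens_d"] for r in results}
        ).loc[keep].median(axis=1)
    else:
        eff = lfc.median(axis=1).abs()
    return pd.DataFrame({"discordance": disc, "effect_size": eff})


@dataclass
class DiscordanceFit:
    """Discordance ~ Effect Size x Quality fit for one subset size.

    ``dd_low`` / ``dd_high`` are the change in discordance per unit effect
    size within the low- and high-quality bins (high = low + interaction);
    ``delta_m = dd_low / dd_high`` is the disparity ratio. ``q_*`` fields
    are filled by :func:`adjust_discordance_fits` (BH across sizes).
    """

    size: int
    quality: str
    effect_metric: str
    dd_low: float
    dd_high: float
    se_low: float
    se_high: float
    p_low: float
    p_high: float
    p_interaction: float
    intercept_low: float
    intercept_high: float
    delta_m: float
    n_genes: int
    q_low: float = math.nan
    q_high: float = math.nan
    q_interaction: float = math.nan
    fit: LinearFit = field(repr=False, default=None)


def fit_discordance_model(
    low_table: pd.DataFrame,
    high_table: pd.DataFrame,
    size: int,
    quality: str = "freeze_thaw",
    effect_metric: str = "mvse",
) -> DiscordanceFit:
    """Fit Discordance ~ Effect Size x Quality for one subset size.

    Quality is a dummy (0 = low-quality bin, 1 = high-quality bin); the
    regression pools the two bins' per-gene tables, so the low-bin slope is
    the effect-size coefficient and the high-bin slope adds the interaction.
    The high-bin slope's Wald test uses the linear-contrast SE.
    """
    frames = []
    for q, tab in ((0, low_table), (1, high_table)):
        f = tab[["discordance", "effect_size"]].copy()
        f["quality"] = q
        frames.append(f)
    data = pd.concat(frames, ignore_index=True)
    data["interaction"] = data["effect_size"] * data["quality"]
    lf = fit_linear(
        data["discordance"], data[["effect_size", "quality", "interaction"]]
    )
    res = lf.sm_results
    contrast = res.t_test("effect_size + interaction = 0")
    dd_low = float(lf.params["effect_size"])
    dd_high = dd_low + float(lf.params["interaction"])
    return DiscordanceFit(
        size=size,
        quality=quality,
        effect_metric=effect_metric,
        dd_low=dd_low,
        dd_high=dd_high,
        se_low=float(lf.bse["effect_size"]),
        se_high=float(np.squeeze(contrast.sd)),
        p_low=float(lf.pvalues["effect_size"]),
        p_high=float(np.squeeze(contrast.pvalue)),
        p_interaction=float(lf.pvalues["interaction"]),
        intercept_low=float(lf.params["Intercept"]),
        intercept_high=float(lf.params["Intercept"] + lf.params["quality"]),
        delta_m=dd_low / dd_high if dd_high != 0 else math.nan,
        n_genes=len(low_table),
        fit=lf,
    )


def adjust_discordance_fits(fits: list[DiscordanceFit]) -> list[DiscordanceFit]:
    """Benjamini-Hochberg adjust the Wald p-values across subset sizes."""
    for attr in ("low", "high", "interaction"):
        p = [getattr(f, "p_" + attr) for f in fits]
        q = multipletests(p, method="fdr_bh")[1]
        for f, qv in zip(fits, q):
            setattr(f, "q_" + attr, float(qv))
    return fits


# ---------------------------------------------------------------------------
# model / results interface


class SubsetReproducibilityModel:
    """Subset-resampling DE reproducibility analysis of one cohort.

    Filters low-count genes, draws balanced subsets at each requested size,
    runs DE per subset, and exposes similarity and discordance analyses on
    the results.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        sizes=tuple(range(4, 15, 2)),
        n_subsets: int = 2000,
        min_avg_count: float = 20.0,
        engine=None,
        exclusion_percentile: float = 10.0,
        pair_mode: str = "sampled",
        max_pairs: int = 10_000,
    ):
        from .io import align_counts_metadata

        counts, metadata = align_counts_metadata(counts, metadata)
        self.counts = filter_genes(counts, min_avg_count)
        self.metadata = metadata
        self.sizes = tuple(int(s) for s in sizes)
        self.n_subsets = n_subsets
        self.engine = engine
        self.exclusion_percentile = exclusion_percentile
        self.pair_mode = pair_mode
        self.max_pairs = max_pairs

    def fit(self, seed: int = 0) -> "ReproducibilityResults":
        ss = np.random.SeedSequence(seed)
        subset_seeds = ss.spawn(len(self.sizes))
        subsets: dict[int, list[SubsetSpec]] = {}
        results: dict[int, list[SubsetDEResult]] = {}
        for size, child in zip(self.sizes, subset_seeds):
            rng = np.random.default_rng(child)
            specs = enumerate_subsets(self.metadata, size, self.n_subsets, rng)
            subsets[size] = specs
            results[size] = [
                run_de(self.counts, spec, self.metadata, self.engine)
                for spec in specs
            ]
        return ReproducibilityResults(self, subsets, results, seed)


class ReproducibilityResults:
    """Subset DE results with similarity / discordance views."""

    def __init__(self, model, subsets, results, seed):
        self.model = model
        self.subsets = subsets
        self.results = results
        self.seed = seed
        self._similarity_cache: dict[int, pd.DataFrame] = {}

    def similarity(self, size: int) -> pd.DataFrame:
        if size not in self._similarity_cache:
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, size, 7]).generate_state(1)
            )
            self._similarity_cache[size] = compute_similarity_table(
                self.results[size],
                self.subsets[size],
                exclusion_percentile=self.model.exclusion_percentile,
                pair_mode=self.model.pair_mode,
                max_pairs=self.model.max_pairs,
                rng=rng,
            )
        return self._similarity_cache[size]

    def similarity_records(self) -> pd.DataFrame:
        return pd.concat(
            [self.similarity(s) for s in self.model.sizes], ignore_index=True
        )

    def quality_bin_tests(self, quality: str = "freeze_thaw") -> pd.DataFrame:
        return compare_quality_bins(self.similarity_records(), quality)

    def similarity_fit(self, formula: str = "combined") -> LinearFit:
        return fit_similarity_model(self.similarity_records(), formula)

    def discordance_fits(
        self, quality: str = "freeze_thaw", effect_metric: str = "mvse"
    ) -> list[DiscordanceFit]:
        fits = []
        for size in self.model.sizes:
            low_ids, high_ids = bin_subsets_by_quality(self.subsets[size], quality)
            by_id = {r.subset_id: r for r in self.results[size]}
            low = compute_discordance(
                [by_id[i] for i in low_ids], effect_metric,
                self.model.exclusion_percentile,
            )
            high = compute_discordance(
                [by_id[i] for i in high_ids], effect_metric,
                self.model.exclusion_percentile,
            )
            fits.append(
                fit_discordance_model(low, high, size, quality, effect_metric)
            )
        return adjust_discordance_fits(fits)

    def summary(self) -> pd.DataFrame:
        recs = self.similarity_records()
        return (
            recs.groupby("size")["similarity"]
            .agg(["count", "median", "mean", "std"])
            .reset_index()
        )
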