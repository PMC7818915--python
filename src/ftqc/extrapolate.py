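"""Back-of-the-envelope projections from the fitted quality coefficients.

These helpers translate the noise and similarity regression estimates into
experiment-scale consequences: how many reads behave randomly at full
sequencing depth, what that means per gene, how much reproducibility a
larger cohort buys, and after how many freeze-thaw cycles the expected
similarity of repeated differential-expression experiments reaches zero.
"""

from __future__ import annotations

from .errors import DataError

__all__ = [
    "expected_random_reads",
    "random_counts_per_gene",
    "similarity_gain",
    "cycles_to_zero_similarity",
]


def expected_random_reads(noise_increase_pp: float, depth: float) -> float:
    """Reads expected to behave randomly given a noise increase.

    E.g. a 4 percentage-point per-cycle noise increase at a depth of 25
    million reads implies 1 million random reads per sample per cycle.
    """
    if depth <= 0:
        raise DataError("depth must be positive")
    return noise_increase_pp / 100.0 * depth


def random_counts_per_gene(n_random_reads: float, n_genes: float) -> float:
    """Random reads spread evenly over genes (e.g. 1M over 20-25k
    protein-coding genes gives ~40-50 counts per gene)."""
    if n_genes <= 0:
        raise DataError("n_genes must be positive")
    return n_random_reads / n_genes


def similarity_gain(per_sample_slope: float, size_from: int, size_to: int) -> float:
    """Expected similarity change when growing a subset from ``size_from``
    to ``size_to`` samples at the fitted per-sample slope."""
    return per_sample_slope * (size_to - size_from)


def cycles_to_zero_similarity(s0: float, per_cycle_decrease: float) -> float:
    """Freeze-thaw cycles at which expected similarity extrapolates to zero.

    With an intercept similarity ``s0`` and a per-cycle decrease of
    ``per_cycle_decrease``, reproducibility extinguishes after
    ``s0 / per_cycle_decrease`` cycles.
    """
    if per_cycle_decrease <= 0:
        raise DataError("per_cycle_decrease must be positive")
    return s0 / per_cycle_decrease
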