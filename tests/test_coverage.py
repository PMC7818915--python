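import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftqc.coverage import (
    CoverageBiasModel,
    compare_bias_groups,
    fit_bias_model,
    gene_body_profile,
    median_coverage_percentile,
    normalize_mcp,
    profile_table,
    read_bed12,
)
from ftqc.errors import DataError, InsufficientDataError


class TestGeneBodyProfile:
    def test_uniform_gene_gives_flat_profile(self):
        bins = gene_body_profile([np.ones(200)])
        assert np.allclose(bins, 1.0)

    def test_three_prime_half_support(self):
        depth = np.zeros(300)
        depth[150:] = 1.0
        bins = gene_body_profile([depth])
        assert np.allclose(bins[:50], 0.0)
        assert bins[60] > 0

    def test_matches_brute_force_for_two_genes(self):
        g1 = np.full(150, 1.0)
        g2 = np.full(300, 2.0)
        bins = gene_body_profile([g1, g2])
        expected = np.zeros(101)
        for depth in (g1, g2):
            idx = np.rint(np.arange(101) * (depth.size - 1) / 100).astype(int)
            expected += depth[idx]
        assert np.allclose(bins, expected / expected.max())

    def test_minus_strand_reversed(self):
        depth = np.zeros(201)
        depth[:100] = 1.0  # genomic left half
        fwd = gene_body_profile([depth], strands=["+"])
        rev = gene_body_profile([depth], strands=["-"])
        assert np.allclose(fwd, rev[::-1])

    def test_short_genes_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            bins = gene_body_profile([np.ones(50), np.ones(150)])
        assert np.allclose(bins, 1.0)

    def test_no_usable_genes_rejected(self):
        with pytest.raises(DataError):
            gene_body_profile([np.ones(10)])


class TestMedianCoveragePercentile:
    def test_uniform_bins(self):
        assert median_coverage_percentile(np.ones(101)) == 50.0

    def test_point_mass_at_three_prime_end(self):
        bins = np.zeros(101)
        bins[100] = 7.0
        assert median_coverage_percentile(bins) == 100.0

    def test_linear_ramp_oracle(self):
        """Brute-force: smallest p with sum(0..p) >= half of sum(0..100)."""
        bins = np.arange(101.0)
        total = bins.sum()
        expected = next(
            p for p in range(101) if bins[: p + 1].sum() >= total / 2
        )
        assert expected == 71
        assert median_coverage_percentile(bins) == 71.0

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            median_coverage_percentile(np.zeros(101))

    @given(st.integers(0, 10_000), st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, seed, scale):
        bins = np.random.default_rng(seed).random(101) + 1e-6
        for interp in (False, True):
            assert median_coverage_percentile(
                bins, interpolate=interp
            ) == pytest.approx(
                median_coverage_percentile(bins * scale, interpolate=interp)
            )

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_shifting_mass_downstream_never_decreases_mcp(self, seed):
        rng = np.random.default_rng(seed)
        bins = rng.random(101) + 0.01
        src = rng.integers(0, 100)
        dst = rng.integers(src + 1, 101)
        moved = bins.copy()
        amount = 0.5 * moved[src]
        moved[src] -= amount
        moved[dst] += amount
        assert median_coverage_percentile(moved) >= median_coverage_percentile(bins)


def _meta(preps, cycles):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(preps))],
            "library_prep": preps,
            "freeze_thaw": cycles,
        }
    )


class TestNormalizeAndFit:
    def _profiles(self, mcps):
        """Synthetic single-spike profiles with the requested (integer) mcp."""
        rows = {}
        for i, m in enumerate(mcps):
            bins = np.zeros(101)
            bins[int(m)] = 1.0
            rows[f"s{i}"] = bins
        return pd.DataFrame(rows).T

    def test_normalization_subtracts_one_cycle_baseline(self):
        prof = self._profiles([50, 50, 55])
        meta = _meta(["polyA"] * 3, [1, 1, 3])
        out = normalize_mcp(profile_table(prof), meta, column="mcp")
        assert out["normalized_mcp"].iloc[0] == 0.0
        assert out["normalized_mcp"].iloc[2] == 5.0

    def test_all_one_cycle_centres_to_zero(self):
        prof = self._profiles([48, 52, 50])
        meta = _meta(["polyA"] * 3, [1, 1, 1])
        out = normalize_mcp(profile_table(prof), meta, column="mcp")
        assert out["normalized_mcp"].mean() == pytest.approx(0.0)

    def test_missing_baseline_stratum_named(self):
        prof = self._profiles([50, 51])
        meta = _meta(["ribo", "ribo"], [2, 3])
        with pytest.raises(DataError, match="ribo"):
            normalize_mcp(profile_table(prof), meta, column="mcp")

    def test_noiseless_slope_recovered_exactly(self):
        cycles = np.array([1, 2, 3, 4, 5] * 3)
        table = pd.DataFrame(
            {
                "normalized_mcp": 1.12 * np.log(cycles),
                "library_prep": "polyA",
                "freeze_thaw": cycles,
            },
            index=[f"s{i}" for i in range(len(cycles))],
        )
        fit = fit_bias_model(table, "polyA")
        assert fit.params["log_freeze_thaw"] == pytest.approx(1.12, abs=1e-12)

    def test_single_cycle_level_rejected(self):
        table = pd.DataFrame(
            {"normalized_mcp": [0.0] * 4, "library_prep": "polyA",
             "freeze_thaw": [2] * 4},
            index=list("abcd"),
        )
        with pytest.raises(DataError):
            fit_bias_model(table, "polyA")


class TestGroupComparisons:
    def _table(self, a, b):
        vals = np.concatenate([a, b])
        return pd.DataFrame(
            {
                "mcp_fine": vals,
                "library_prep": ["polyA"] * len(a) + ["ribo"] * len(b),
                "freeze_thaw": [1] * len(a) + [1] * len(b),
            },
            index=[f"s{i}" for i in range(len(vals))],
        )

    def test_shifted_groups_strongly_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(50, 2, 20)
        b = rng.normal(60, 2, 20)
        out = compare_bias_groups(self._table(a, b), tests=("t",))
        assert (out["qvalue"] < 1e-6).all()

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(200):
            a, b = rng.normal(50, 2, 10), rng.normal(50, 2, 10)
            out = compare_bias_groups(self._table(a, b), tests=("t",))
            hits += (out["pvalue"] < 0.05).any()
        assert hits <= 0.1 * 200  # ~5% nominal

    def test_bh_step_up_hand_example(self):
        """p = {.01,.02,.03,.04} over 4 pairwise tests -> all q = 0.04."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)

    def test_anova_and_kruskal_emitted(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {
                "mcp_fine": rng.normal(50, 2, 24),
                "library_prep": ["polyA", "ribo"] * 12,
                "freeze_thaw": [1, 1, 2, 2] * 6,
            },
            index=[f"s{i}" for i in range(24)],
        )
        out = compare_bias_groups(table, tests=("t", "anova", "kruskal"))
        assert {"t", "anova", "kruskal"} <= set(out["test"].unique())


class TestBed12AndBam:
    SAM = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        "r2\t0\tchr1\t301\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        "r3\t256\tchr1\t301\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"  # secondary
    )
    BED = (
        "chr1\t100\t400\ttx1\t0\t+\t100\t400\t0\t2\t100,100\t0,200\n"
    )

    def test_spliced_depth_skips_secondary(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        sam = tmp_path / "a.sam"
        sam.write_text(self.SAM)
        bam = tmp_path / "a.bam"
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        bed = tmp_path / "m.bed"
        bed.write_text(self.BED)
        from ftqc.coverage import bam_gene_depths

        (name, depth), = list(bam_gene_depths(bam, bed))
        assert name == "tx1"
        assert depth.size == 200  # two 100-base exons, spliced
        assert depth[:50].sum() == 50  # r1 covers first 50 bases of exon 1
        assert depth[100:150].sum() == 50  # r2 covers first 50 of exon 2 only
        assert depth.sum() == 100  # secondary alignment ignored

    def test_bed12_parsing(self, tmp_path):
        bed = tmp_path / "m.bed"
        bed.write_text(self.BED)
        (model,) = read_bed12(bed)
        assert model["exons"] == [(100, 200), (300, 400)]


class TestModelInterface:
    def test_end_to_end_summary(self):
        import ftqc

        cfg = ftqc.SyntheticConfig(coverage_noise_sd=0.02, seed=5)
        meta = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "library_prep": ["polyA"] * 5 + ["ribo"] * 5,
                "freeze_thaw": [1, 2, 3, 4, 5] * 2,
            }
        )
        prof = ftqc.generate_coverage_profiles(meta, cfg)
        res = CoverageBiasModel(prof, meta).fit()
        assert res.table["mcp"].between(0, 100).all()
        assert not res.summary().empty
        fit = res.bias_fit("polyA")
        assert fit.nobs == 5
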