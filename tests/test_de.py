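import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftqc.de import (
    SubsetDEResult,
    SubsetSpec,
    bin_subsets_by_quality,
    compare_quality_bins,
    compute_discordance,
    compute_similarity_table,
    default_de_engine,
    enumerate_subsets,
    filter_genes,
    fit_discordance_model,
    fit_similarity_model,
    max_balanced_subsets,
    run_de,
)
from ftqc.errors import DataError, InsufficientDataError


def _metadata(n_asd, n_td, replicates=1):
    rows = []
    i = 0
    for grp, n in (("ASD", n_asd), ("TD", n_td)):
        for _ in range(n):
            for r in range(replicates):
                rows.append(
                    {
                        "sample_id": f"s{i}r{r}",
                        "individual_id": f"i{i}",
                        "group": grp,
                        "freeze_thaw": 1 + (i % 5),
                        "rin": 6.0 + (i % 4),
                        "library_prep": "polyA",
                        "concentration": 50.0,
                    }
                )
            i += 1
    return pd.DataFrame(rows)


class TestFilterGenes:
    def test_threshold_is_strict(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 21], "s2": [10, 20, 21]},
            index=["low", "boundary", "kept"],
        )
        out = filter_genes(counts)
        assert list(out.index) == ["kept"]

    def test_all_zero_matrix_warns(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [0, 0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="no genes"):
            out = filter_genes(counts)
        assert out.empty


class TestEnumerateSubsets:
    def test_balance_and_distinctness(self):
        meta = _metadata(8, 8)
        rng = np.random.default_rng(0)
        specs = enumerate_subsets(meta, 4, 10, rng)
        assert len(specs) == 10
        groups = meta.set_index("sample_id")["group"]
        seen = set()
        for s in specs:
            labels = groups.loc[list(s.sample_ids)]
            assert (labels == "ASD").sum() == 2 and (labels == "TD").sum() == 2
            key = frozenset(s.sample_ids)
            assert key not in seen
            seen.add(key)

    def test_cap_at_combinatorial_maximum(self):
        meta = _metadata(2, 2)
        assert max_balanced_subsets(meta, 4) == 1
        with pytest.warns(UserWarning, match="capping"):
            specs = enumerate_subsets(meta, 4, 5, np.random.default_rng(1))
        assert len(specs) == 1

    def test_one_replicate_per_individual(self):
        meta = _metadata(4, 4, replicates=2)
        inds = meta.set_index("sample_id")["individual_id"]
        specs = enumerate_subsets(meta, 6, 50, np.random.default_rng(2))
        for s in specs:
            members = inds.loc[list(s.sample_ids)]
            assert members.nunique() == len(members)

    def test_odd_size_rejected(self):
        with pytest.raises(DataError):
            enumerate_subsets(_metadata(4, 4), 5, 3, np.random.default_rng(0))

    def test_standards_and_unassigned_excluded(self):
        meta = _metadata(3, 3)
        meta.loc[0, "group"] = "standard"
        with pytest.raises(InsufficientDataError):
            enumerate_subsets(meta, 6, 3, np.random.default_rng(0))


class TestRunDE:
    def _spec(self, ids, size):
        return SubsetSpec(0, size, tuple(ids), 1.0, 8.0)

    def test_identical_groups_give_zero_lfc(self):
        meta = _metadata(2, 2)
        base = np.array([[30, 40, 100, 7]] * 4).T
        counts = pd.DataFrame(
            base, columns=meta["sample_id"], index=[f"g{i}" for i in range(4)]
        )
        res = run_de(counts, self._spec(meta["sample_id"], 4), meta)
        assert np.allclose(res.table["lfc"], 0.0)

    def test_lfc_formula_on_known_means(self):
        """Normalized group means 100 vs 25 with eps=0.5 give
        log2(100.5/25.5) = 1.9787."""
        is_asd = np.array([True, True, False, False])
        sub = pd.DataFrame(
            {
                "a1": [100, 50, 60], "a2": [100, 50, 60],
                "t1": [25, 50, 135], "t2": [25, 50, 135],
            },
            index=["target", "flat1", "flat2"],
        )
        # columns all sum to 210 -> size factors 1
        table = default_de_engine(sub, is_asd)
        assert table.loc["target", "lfc"] == pytest.approx(
            np.log2(100.5 / 25.5), abs=1e-6
        )

    def test_size_factor_normalization_invariance(self):
        meta = _metadata(2, 2)
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(10, 200, (50, 4)),
            columns=meta["sample_id"],
            index=[f"g{i}" for i in range(50)],
        )
        spec = self._spec(meta["sample_id"], 4)
        base = run_de(counts, spec, meta).table["lfc"]
        scaled = counts.copy()
        scaled.iloc[:, 0] *= 2
        doubled = run_de(scaled, spec, meta).table["lfc"]
        # exact up to the 0.5 pseudocount's interaction with the rescaled
        # normalized means
        assert np.allclose(base, doubled, atol=0.01)

    def test_single_group_rejected(self):
        meta = _metadata(2, 2)
        counts = pd.DataFrame(
            np.ones((3, 4), int), columns=meta["sample_id"], index=list("abc")
        )
        asd_only = meta.loc[meta["group"] == "ASD", "sample_id"]
        with pytest.raises(DataError, match="single group"):
            run_de(counts, self._spec(asd_only, 2), meta)


def _fake_results(lfc_matrix, base_mean=None, wald=None):
    """Wrap an (genes x subsets) LFC array as SubsetDEResults."""
    genes = [f"g{i}" for i in range(lfc_matrix.shape[0])]
    out = []
    for j in range(lfc_matrix.shape[1]):
        table = pd.DataFrame(
            {
                "lfc": lfc_matrix[:, j],
                "se": 1.0,
                "base_mean": 100.0 if base_mean is None else base_mean[:, j],
                "wald_stat": lfc_matrix[:, j] if wald is None else wald[:, j],
                "cohens_d": np.abs(lfc_matrix[:, j]),
            },
            index=genes,
        )
        out.append(SubsetDEResult(subset_id=j, size=4, table=table))
    return out


def _specs(n, size=4, ft=None, rin=None):
    return [
        SubsetSpec(
            j, size, (f"m{j}a", f"m{j}b", f"m{j}c", f"m{j}d"),
            2.0 if ft is None else ft[j], 8.0 if rin is None else rin[j],
        )
        for j in range(n)
    ]


class TestSimilarity:
    def test_identical_and_reversed_lfc_vectors(self, rng):
        lfc = rng.normal(size=(60, 2))
        lfc[:, 1] = lfc[:, 0]
        recs = compute_similarity_table(
            _fake_results(lfc), _specs(2), rng=rng, exclusion_percentile=0
        )
        assert recs["similarity"].iloc[0] == pytest.approx(1.0)
        lfc[:, 1] = -lfc[:, 0]
        recs = compute_similarity_table(
            _fake_results(lfc), _specs(2), rng=rng, exclusion_percentile=0
        )
        assert recs["similarity"].iloc[0] == pytest.approx(-1.0)

    def test_null_similarity_centred_on_zero(self, rng):
        lfc = rng.normal(size=(1000, 30))
        recs = compute_similarity_table(
            _fake_results(lfc), _specs(30), rng=rng, max_pairs=100
        )
        assert recs["similarity"].mean() == pytest.approx(0.0, abs=0.01)

    def test_monotone_transform_invariance(self, rng):
        lfc = rng.normal(size=(80, 4))
        base = compute_similarity_table(
            _fake_results(lfc), _specs(4), rng=np.random.default_rng(0),
            exclusion_percentile=0,
        )
        warped = compute_similarity_table(
            _fake_results(np.sinh(lfc)), _specs(4), rng=np.random.default_rng(0),
            exclusion_percentile=0,
        )
        assert np.allclose(
            base["similarity"].to_numpy(), warped["similarity"].to_numpy()
        )

    def test_low_signal_genes_excluded(self, rng):
        lfc = rng.normal(size=(100, 3)) + 5  # keep |median lfc| off zero
        bm = np.full((100, 3), 100.0)
        bm[:10] = 0.1  # bottom decile by base mean
        recs = compute_similarity_table(
            _fake_results(lfc, base_mean=bm), _specs(3), rng=rng
        )
        assert not recs.empty  # exclusion ran without error


class TestQualityBins:
    def test_separated_bins_detected(self):
        recs = pd.DataFrame(
            {
                "size": 4,
                "similarity": [0.5] * 20 + [0.3] * 20,
                "avg_freeze_thaw": [1.0] * 20 + [4.0] * 20,
                "avg_rin": 8.0,
            }
        )
        out = compare_quality_bins(recs, "freeze_thaw")
        assert out["fold_change"].iloc[0] == pytest.approx(5 / 3, abs=1e-3)
        assert out["pvalue"].iloc[0] < 1e-6

    def test_null_pvalues_approximately_uniform(self):
        """With both bins drawn from one distribution the one-sided MWU
        p-value is approximately uniform."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(200):
            recs = pd.DataFrame(
                {
                    "size": 4,
                    "similarity": rng.normal(0.3, 0.1, 40),
                    "avg_freeze_thaw": rng.uniform(1, 5, 40),
                    "avg_rin": 8.0,
                }
            )
            pvals.append(compare_quality_bins(recs, "freeze_thaw")["pvalue"].iloc[0])
        pvals = np.array(pvals)
        assert abs((pvals < 0.5).mean() - 0.5) < 0.1
        assert abs(pvals.mean() - 0.5) < 0.05


class TestSimilarityModel:
    def test_noiseless_coefficients_recovered(self, rng):
        ft = rng.uniform(1, 5, 200)
        rin_vals = rng.uniform(5, 9, 200)
        size = rng.choice([4, 6, 8, 10], 200)
        recs = pd.DataFrame(
            {
                "similarity": 0.23 - 0.077 * ft + 0.0 * rin_vals + 0.02 * size,
                "avg_freeze_thaw": ft,
                "avg_rin": rin_vals,
                "size": size,
            }
        )
        fit = fit_similarity_model(recs, "combined")
        assert fit.params["Intercept"] == pytest.approx(0.23, abs=1e-9)
        assert fit.params["avg_freeze_thaw"] == pytest.approx(-0.077, abs=1e-9)
        assert fit.params["size"] == pytest.approx(0.02, abs=1e-9)
        solo = fit_similarity_model(recs, "freeze_thaw_only")
        assert "avg_rin" not in solo.params


class TestDiscordance:
    def test_zero_and_two_point_sd(self):
        lfc = np.column_stack([np.array([1.0, 1.0]), np.array([1.0, 2.0])])
        tab = compute_discordance(
            _fake_results(lfc), exclusion_percentile=0
        )
        assert tab["discordance"].iloc[0] == pytest.approx(0.0)
        assert tab["discordance"].iloc[1] == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_sd_estimator_consistency(self, rng):
        """Per-gene LFC drawn Normal(mu_g, sigma_g) over 100 subsets: the
        discordance estimate tracks sigma_g."""
        sigma = rng.uniform(0.2, 2.0, 300)
        lfc = rng.normal(0, 1, (300, 100)) * sigma[:, None]
        tab = compute_discordance(_fake_results(lfc), exclusion_percentile=0)
        rel_err = np.abs(tab["discordance"].to_numpy() - sigma) / sigma
        assert rel_err.mean() < 0.1

    def test_single_subset_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            compute_discordance(_fake_results(rng.normal(size=(10, 1))))

    def test_generating_slope_ratio_recovered_exactly(self):
        effect = np.linspace(0.1, 3.0, 80)
        low = pd.DataFrame({"effect_size": effect, "discordance": 0.1 + 2.0 * effect})
        high = pd.DataFrame({"effect_size": effect, "discordance": 0.1 + 1.0 * effect})
        fit = fit_discordance_model(low, high, size=6)
        assert fit.dd_low == pytest.approx(2.0, abs=1e-9)
        assert fit.dd_high == pytest.approx(1.0, abs=1e-9)
        assert fit.delta_m == pytest.approx(2.0, abs=1e-9)

    def test_quality_binning_ties_to_low_quality(self):
        specs = _specs(4, ft=[1.0, 2.0, 2.0, 3.0])
        low, high = bin_subsets_by_quality(specs, "freeze_thaw")
        assert set(high) == {0}  # only strictly-below-median is high quality
        assert set(low) == {1, 2, 3}


class TestSubsetPropertyInvariants:
    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_every_subset_satisfies_constraints(self, seed):
        meta = _metadata(5, 5, replicates=2)
        rng = np.random.default_rng(seed)
        specs = enumerate_subsets(meta, 6, 12, rng)
        inds = meta.set_index("sample_id")["individual_id"]
        groups = meta.set_index("sample_id")["group"]
        for s in specs:
            ids = list(s.sample_ids)
            assert len(set(ids)) == s.size
            assert inds.loc[ids].nunique() == s.size
            assert (groups.loc[ids] == "ASD").sum() == s.size // 2
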