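import numpy as np
import pandas as pd
import pytest

from conflux.datatypes import AnalysisConfig, CountMatrix, SampleMeta, ValidationError
from conflux.expression import (
    compute_dei,
    cpm_normalize,
    dei_combine,
    difference_de,
    filter_min_cpm,
    median_of_ratios_size_factors,
    pool_lineage_counts,
    ratio_de,
    relative_expression,
)


def cpm_oracle(counts: pd.DataFrame) -> pd.DataFrame:
    """Brute-force per-cell CPM."""
    out = counts.astype(float).copy()
    for s in counts.columns:
        total = counts[s].sum()
        for g in counts.index:
            out.loc[g, s] = counts.loc[g, s] / total * 1e6
    return out


class TestCpm:
    def test_single_sample_arithmetic(self):
        cm = CountMatrix(pd.DataFrame({"s": [5, 15, 30]}, index=["a", "b", "c"]))
        np.testing.assert_allclose(
            cpm_normalize(cm)["s"], [100000.0, 300000.0, 600000.0]
        )

    def test_columns_sum_to_one_million(self, random_counts):
        nm = cpm_normalize(random_counts)
        np.testing.assert_allclose(nm.sum(axis=0), 1e6, rtol=1e-9)

    def test_matches_loop_oracle(self, random_counts):
        nm = cpm_normalize(random_counts)
        pd.testing.assert_frame_equal(nm, cpm_oracle(random_counts.counts))

    def test_zero_total_sample_named(self):
        cm = CountMatrix(pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="empty"):
            cpm_normalize(cm)


class TestMedianOfRatios:
    def test_identical_samples_give_unit_factors(self):
        cm = CountMatrix(pd.DataFrame({"s1": [4, 8, 2], "s2": [4, 8, 2]}, index=list("abc")))
        np.testing.assert_allclose(median_of_ratios_size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_splits_geometrically(self):
        # B = 2*A elementwise: geomean = a*sqrt(2), ratios 1/sqrt(2) and sqrt(2)
        cm = CountMatrix(pd.DataFrame({"A": [10, 20, 40], "B": [20, 40, 80]}, index=list("abc")))
        np.testing.assert_allclose(
            median_of_ratios_size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_equivariant_under_sample_permutation(self, random_counts):
        sf = median_of_ratios_size_factors(random_counts)
        perm = list(reversed(random_counts.sample_ids))
        sf_perm = median_of_ratios_size_factors(random_counts.subset_samples(perm))
        np.testing.assert_allclose(sf_perm.to_numpy(), sf[perm].to_numpy())

    def test_no_eligible_gene_rejected(self):
        cm = CountMatrix(pd.DataFrame({"s1": [0, 5], "s2": [3, 0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="size factors"):
            median_of_ratios_size_factors(cm)


class TestMinCpmFilter:
    def test_gene_below_threshold_everywhere_is_blocked(self):
        nm = pd.DataFrame([[1.9, 1.0, 0.5]], index=["g"], columns=list("abc"))
        assert not filter_min_cpm(nm, 2.0)["g"]

    def test_single_sample_at_threshold_keeps_gene(self):
        nm = pd.DataFrame([[1.9, 2.0, 0.5]], index=["g"], columns=list("abc"))
        assert filter_min_cpm(nm, 2.0)["g"]

    def test_zero_threshold_keeps_everything(self, random_counts):
        nm = cpm_normalize(random_counts)
        assert filter_min_cpm(nm, 0.0).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            filter_min_cpm(pd.DataFrame([[1.0]]), -1.0)


class TestPooling:
    def test_pooled_counts_are_gene_wise_sums(self, paired_meta):
        cols = {}
        for s in paired_meta.sample_ids:
            cols[s] = [3, 0] if s.endswith("LEp") else [2, 5]
        cm = CountMatrix(pd.DataFrame(cols, index=["g1", "g2"]))
        pooled, pmeta = pool_lineage_counts(cm, paired_meta)
        assert pooled.counts["A_standard_pooled"].tolist() == [5, 5]
        assert set(pmeta.table["lineage"]) == {"bulk"}

    def test_specimen_without_mep_skipped_with_warning(self, paired_meta, caplog):
        keep = [s for s in paired_meta.sample_ids if s != "B_standard_MEp"]
        cm = CountMatrix(
            pd.DataFrame({s: [1, 2] for s in keep}, index=["g1", "g2"])
        )
        meta = SampleMeta(paired_meta.table.loc[keep])
        with caplog.at_level("WARNING", logger="conflux"):
            pooled, _ = pool_lineage_counts(cm, meta)
        assert "B" in caplog.text and "standard" in caplog.text
        assert "B_standard_pooled" not in pooled.sample_ids

    def test_pool_then_normalize_matches_brute_force(self, paired_meta, rng):
        cm = CountMatrix(
            pd.DataFrame(
                rng.poisson(40, size=(10, len(paired_meta.sample_ids))),
                index=[f"g{i}" for i in range(10)],
                columns=paired_meta.sample_ids,
            )
        )
        pooled, _ = pool_lineage_counts(cm, paired_meta)
        nm = cpm_normalize(pooled)
        for col in pooled.sample_ids:
            spec, culture, _ = col.split("_")
            lep, mep = f"{spec}_{culture}_LEp", f"{spec}_{culture}_MEp"
            raw = cm.counts[lep] + cm.counts[mep]
            np.testing.assert_allclose(nm[col], raw / raw.sum() * 1e6)


class TestDeiComponents:
    def test_ratio_de_of_equal_means_is_zero(self):
        nm = pd.DataFrame({"a": [10.0], "b": [10.0]}, index=["g"])
        assert ratio_de(nm, ["a"], ["b"]).iloc[0] == 0.0

    def test_ratio_de_arithmetic_with_pseudocount(self):
        nm = pd.DataFrame({"a": [3.0], "b": [1.0]}, index=["g"])
        assert ratio_de(nm, ["a"], ["b"], pseudocount=1.0).iloc[0] == pytest.approx(1.0)

    def test_ratio_de_antisymmetric_under_group_swap(self, random_counts):
        nm = cpm_normalize(random_counts)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        np.testing.assert_allclose(ratio_de(nm, a, b), -ratio_de(nm, b, a))

    def test_overlapping_groups_rejected(self, random_counts):
        nm = cpm_normalize(random_counts)
        with pytest.raises(ValidationError, match="overlap"):
            ratio_de(nm, ["s0", "s1"], ["s1", "s2"])

    def test_difference_de_arithmetic_and_symmetry(self):
        nm = pd.DataFrame({"a": [300.0], "b": [100.0]}, index=["g"])
        assert difference_de(nm, ["a"], ["b"]).iloc[0] == 200.0
        assert difference_de(nm, ["b"], ["a"]).iloc[0] == 200.0

    def test_difference_de_matches_loop_oracle(self, random_counts):
        nm = cpm_normalize(random_counts)
        a, b = ["s0", "s1"], ["s2", "s3", "s4"]
        d = difference_de(nm, a, b)
        for g in nm.index:
            assert d[g] == pytest.approx(
                abs(sum(nm.loc[g, s] for s in a) / 2 - sum(nm.loc[g, s] for s in b) / 3)
            )

    @pytest.mark.parametrize(
        "r,d,expected", [(1.0, 4.0, 2.0), (0.0, 7.0, 0.0), (2.0, 8.0, 4.0), (-2.0, 8.0, 4.0)]
    )
    def test_dei_combine_geometric_mean(self, r, d, expected):
        rec = dei_combine(pd.Series({"g": r}), pd.Series({"g": d}))
        assert rec.loc["g", "dei"] == pytest.approx(expected)
        assert rec.loc["g", "sign"] == np.sign(r)

    def test_dei_combine_rejects_negative_difference(self):
        with pytest.raises(ValidationError):
            dei_combine(pd.Series({"g": 1.0}), pd.Series({"g": -1.0}))

    def test_compute_dei_invariant_under_group_swap(self, random_counts):
        nm = cpm_normalize(random_counts)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fwd = compute_dei(nm, a, b)
        rev = compute_dei(nm, b, a)
        np.testing.assert_allclose(fwd["dei"], rev["dei"], rtol=1e-12)
        np.testing.assert_array_equal(fwd["sign"], -rev["sign"])

    def test_compute_dei_flags_blocked_genes(self, paired_meta):
        counts = pd.DataFrame(
            {s: [1, 100000] for s in paired_meta.sample_ids}, index=["low", "high"]
        )
        cm = CountMatrix(counts)
        nm = cpm_normalize(cm)
        a = paired_meta.samples_where(culture="standard")
        b = paired_meta.samples_where(culture="postconfluent")
        out = compute_dei(nm, a, b, AnalysisConfig(min_cpm=2000.0))
        assert bool(out.loc["low", "blocked"]) and not bool(out.loc["high", "blocked"])


class TestRelativeExpression:
    def _nm_meta(self, values):
        nm = pd.DataFrame([values], index=["g"], columns=["x", "y", "z"])
        meta = SampleMeta(
            pd.DataFrame(
                {
                    "specimen": ["s", "s", "s"],
                    "lineage": ["LEp", "LEp", "LEp"],
                    "culture": ["primary", "standard", "postconfluent"],
                },
                index=pd.Index(["x", "y", "z"], name="sample_id"),
            )
        )
        return nm, meta

    def test_min_max_rescaling(self):
        # log2(CPM+1) of 3, 15, 63 -> 2, 4, 6 -> scaled 0, 0.5, 1
        nm, meta = self._nm_meta([3.0, 15.0, 63.0])
        out = relative_expression(nm, ["g"], meta)
        np.testing.assert_allclose(
            out.loc["g", ["primary", "standard", "postconfluent"]], [0.0, 0.5, 1.0]
        )

    def test_constant_gene_maps_to_zero(self):
        nm, meta = self._nm_meta([10.0, 10.0, 10.0])
        assert (relative_expression(nm, ["g"], meta).loc["g"] == 0.0).all()

    def test_absent_gene_reported(self, caplog):
        nm, meta = self._nm_meta([1.0, 2.0, 3.0])
        with caplog.at_level("WARNING", logger="conflux"):
            out = relative_expression(nm, ["g", "NOPE"], meta)
        assert "NOPE" in caplog.text and list(out.index) == ["g"]
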