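"""Spearman screening, BH adjustment, cross-dataset consistency, and the
label-shuffle permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import genephys as gp
from genephys.correlation_screen import RECORD_COLUMNS


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        r, p = gp.spearman_with_p([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == 1.0 and 0 < p < 1e-8
        r, _ = gp.spearman_with_p([1, 2, 3, 4], [40, 30, 20, 10])
        assert r == -1.0

    def test_textbook_rank_example(self):
        # d^2 sum = 8, no ties: r = 1 - 6*8/(5*24) = 0.6
        r, _ = gp.spearman_with_p([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert r == pytest.approx(0.6)

    def test_matches_reference_implementation_with_and_without_ties(self):
        rng = np.random.default_rng(0)
        for i in range(200):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if i % 2:  # inject ties
                x = np.round(x, 1)
                y = np.round(y, 1)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = gp.spearman_with_p(x, y)
            r_ref, p_ref = stats.spearmanr(x, y)
            assert r == pytest.approx(r_ref, abs=1e-10)
            if abs(r) < 0.9999:
                assert p == pytest.approx(p_ref, rel=1e-6)

    def test_zero_variance_flagged_undefined(self):
        r, p = gp.spearman_with_p([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)


class TestBHAdjust:
    def test_step_up_examples(self):
        np.testing.assert_allclose(
            gp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(gp.bh_adjust([0.05, 0.5]), [0.10, 0.5])
        np.testing.assert_allclose(gp.bh_adjust([0.7]), [0.7])

    def test_rejects_values_outside_unit_interval(self):
        with pytest.raises(ValueError):
            gp.bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            gp.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1, max_size=60,
        )
    )
    def test_adjusted_values_monotone_in_p_and_capped(self, ps):
        adj = gp.bh_adjust(ps)
        assert (adj <= 1.0 + 1e-15).all()
        assert (adj >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestScreen:
    def test_record_table_schema_and_fdr_ordering(self, discovery_bundle):
        records = discovery_bundle["records"]
        assert list(records.columns) == RECORD_COLUMNS
        assert (records["p_adj"] >= records["p_value"] - 1e-15).all()
        assert (records["r_s"].abs() <= 1).all()
        assert (records["n_celltypes"] >= 5).all()

    def test_planted_genes_dominate_the_top_of_the_screen(self, discovery_bundle):
        records = discovery_bundle["records"]
        truth = discovery_bundle["truth"]
        planted_vrest = {
            e.gene for e in truth.planted_effects if e.property == "Vrest"
        }
        top = (
            records[records["property"] == "Vrest"]
            .nsmallest(len(planted_vrest), "p_adj")["gene"]
        )
        assert len(set(top) & planted_vrest) >= len(planted_vrest) * 0.6

    def test_constant_gene_excluded_from_output(self, rc):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.normal(7, 1, size=(10, 3)),
            index=[f"T{i}" for i in range(10)],
            columns=["g1", "g2", "flat"],
        )
        expr["flat"] = 6.0
        ephys = pd.DataFrame({"Vrest": rng.normal(-65, 5, 10)}, index=expr.index)
        ds = gp.PairedCellTypeDataset(expression=expr, ephys=ephys)
        records = gp.screen(ds, rc)
        assert "flat" not in set(records["gene"])

    def test_property_below_min_celltypes_skipped(self, rc):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(
            rng.normal(size=(8, 4)), index=[f"T{i}" for i in range(8)],
            columns=[f"g{i}" for i in range(4)],
        )
        ephys = pd.DataFrame(
            {
                "Vrest": rng.normal(-65, 5, 8),
                "SFA": [0.5, 0.6, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan],
            },
            index=expr.index,
        )
        ds = gp.PairedCellTypeDataset(expression=expr, ephys=ephys)
        records = gp.screen(ds, rc)
        assert set(records["property"]) == {"Vrest"}

    def test_significance_counts_summary(self, discovery_bundle):
        counts = gp.significance_counts(discovery_bundle["records"])
        assert set(counts["per_property"].columns) == {0.01, 0.05, 0.1}
        # the per-property table is monotone across thresholds
        per = counts["per_property"]
        assert (per[0.01] <= per[0.05]).all() and (per[0.05] <= per[0.1]).all()


class TestConsistency:
    def _records(self, rows):
        return pd.DataFrame(
            [
                {
                    "gene": g, "property": "Vrest", "n_celltypes": 20,
                    "r_s": r, "p_value": p, "p_adj": p,
                }
                for g, r, p in rows
            ]
        )

    def test_per_gene_consistency_rules(self, rc):
        disc = self._records([("gA", 0.5, 0.01), ("gB", 0.5, 0.01), ("gC", 0.5, 0.01)])
        val = self._records([("gA", 0.4, 0.5), ("gB", 0.2, 0.5), ("gC", -0.6, 0.5)])
        consistent, pct, missing = gp.consistency_per_gene(disc, val, rc, "Vrest")
        assert consistent == ["gA"]  # sign match and |r| > 0.3
        assert pct == pytest.approx(100 / 3)
        assert missing == []

    def test_gene_absent_from_validation_counted_separately(self, rc):
        disc = self._records([("gA", 0.5, 0.01), ("gB", 0.5, 0.01)])
        val = self._records([("gA", 0.4, 0.5)])
        consistent, pct, missing = gp.consistency_per_gene(disc, val, rc, "Vrest")
        assert consistent == ["gA"] and missing == ["gB"]
        assert pct == 100.0

    def test_overall_rho_self_and_anti_consistency(self):
        rng = np.random.default_rng(3)
        rows = [(f"g{i}", float(r), 0.5) for i, r in enumerate(rng.uniform(-1, 1, 30))]
        disc = self._records(rows)
        anti = self._records([(g, -r, p) for g, r, p in rows])
        assert gp.consistency_overall(disc, disc, "Vrest") == pytest.approx(1.0)
        assert gp.consistency_overall(disc, anti, "Vrest") == pytest.approx(-1.0)

    def test_too_few_common_genes_is_an_error(self):
        disc = self._records([("g1", 0.5, 0.1)])
        with pytest.raises(ValueError, match="common"):
            gp.consistency_overall(disc, disc, "Vrest")


class TestPermutationNull:
    def test_p_bounds_and_strong_signal_minimum(self, discovery_bundle, validation_bundle):
        run = gp.RunConfig(seed=11, n_permutations=200)
        obs, null, p = gp.permutation_null(
            validation_bundle["dataset"], discovery_bundle["records"],
            "overall_rho", run, "Vrest",
        )
        assert len(null) == 200
        assert 1 / 201 <= p <= 1.0

    def test_observed_at_null_median_gives_p_about_half(self, rc):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(
            rng.normal(size=(12, 100)),
            index=[f"L{i}" for i in range(12)],
            columns=[f"g{i}" for i in range(100)],
        )
        ephys = pd.DataFrame({"Vrest": rng.normal(size=12)}, index=expr.index)
        vds = gp.PairedCellTypeDataset(expression=expr, ephys=ephys)
        disc = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(100)],
                "property": "Vrest",
                "n_celltypes": 20,
                "r_s": rng.uniform(-1, 1, 100),
                "p_value": 0.5,
                "p_adj": 0.5,
            }
        )
        run = gp.RunConfig(seed=5, n_permutations=400)
        _, _, p = gp.permutation_null(vds, disc, "overall_rho", run, "Vrest")
        assert 0.1 < p < 0.9  # a null-consistent observation is unremarkable

    def test_identical_seeds_reproduce_the_null(self, discovery_bundle, validation_bundle):
        run = gp.RunConfig(seed=21, n_permutations=150)
        r1 = gp.permutation_null(
            validation_bundle["dataset"], discovery_bundle["records"],
            "pct_consistent", run, "Vrest",
        )
        r2 = gp.permutation_null(
            validation_bundle["dataset"], discovery_bundle["records"],
            "pct_consistent", run, "Vrest",
        )
        np.testing.assert_array_equal(r1[1], r2[1])
        assert r1[2] == r2[2]

    def test_degenerate_permutation_space_rejected(self, discovery_bundle, rc):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(size=(3, 10)), index=list("ABC"),
            columns=[f"g{i}" for i in range(10)],
        )
        ephys = pd.DataFrame({"Vrest": [1.0, 2.0, 3.0]}, index=expr.index)
        vds = gp.PairedCellTypeDataset(expression=expr, ephys=ephys)
        run = gp.RunConfig(seed=0, n_permutations=100)
        with pytest.raises(ValueError, match="4"):
            gp.permutation_null(
                vds, discovery_bundle["records"], "overall_rho", run, "Vrest"
            )


def test_merged_screen_table_carries_both_screens_and_the_flag(
    discovery_bundle, validation_bundle, rc
):
    disc = discovery_bundle["records"]
    val = gp.screen(validation_bundle["dataset"], rc)
    merged = gp.merge_screen_tables(disc, val, rc)
    assert {"EphysProp", "Gene", "DiscCorr", "DiscFDR", "ValCorr", "Consistent"} <= set(
        merged.columns
    )
    flagged = merged[merged["Consistent"]]
    assert len(flagged) > 0
    assert (flagged["DiscFDR"] < 0.05).all()
    assert (flagged["ValCorr"].abs() > rc.consistency_abs_r).all()
    assert (np.sign(flagged["ValCorr"]) == np.sign(flagged["DiscCorr"])).all()


def test_compare_datasets_produces_table3_style_rows(discovery_bundle, validation_bundle):
    run = gp.RunConfig(seed=11, n_permutations=100)
    results = gp.compare_datasets(
        discovery_bundle["records"], validation_bundle["dataset"], run
    )
    by_prop = {r.property: r for r in results}
    assert "Vrest" in by_prop
    vrest = by_prop["Vrest"]
    # strong shared planted signal: high consistency, small p
    assert vrest.overall_rho > 0.2
    assert vrest.n_consistent <= vrest.n_discovered
    assert vrest.pct_consistent == pytest.approx(
        100 * vrest.n_consistent / vrest.n_discovered
    )
    # co-regulated planted genes make the null heavy-tailed; at B=100 the
    # replication p-value is small but not extreme
    assert vrest.overall_p <= 0.05
    assert vrest.consistency_p <= 0.2
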