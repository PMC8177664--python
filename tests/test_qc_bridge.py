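"""Bridging statistics, QC acceptance, PCA diagnostics, cohort tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pibridge as pb
from pibridge.qc_bridge import (
    anchor_variance_comparison,
    bridge_report,
    cohort_compare,
    longitudinal_summary,
    pca_batch_diagnostic,
    percent_difference,
    qc_acceptance,
    reference_range,
    welch_t,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected", [(8, 8, 0.0), (12, 8, 40.0), (8, 12, -40.0)])
    def test_hand_values(self, a, b, expected):
        assert percent_difference(a, b) == pytest.approx(expected)

    @given(a=positive, b=positive)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert percent_difference(a, b) == pytest.approx(-percent_difference(b, a))

    @given(a=positive, b=positive, k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, a, b, k):
        assert percent_difference(k * a, k * b) == pytest.approx(
            percent_difference(a, b), rel=1e-9, abs=1e-9
        )

    @given(a=positive, b=positive)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounded_and_zero_iff_equal(self, a, b):
        d = percent_difference(a, b)
        assert -200.0 < d < 200.0
        if a == b:
            assert d == 0.0

    def test_both_zero_is_missing(self):
        assert np.isnan(percent_difference(0.0, 0.0))


class TestQcAcceptance:
    @pytest.fixture()
    def qc_table(self):
        cfg = pb.SimulationConfig(
            n_samples=16, n_batches=1, seed=13, noise_cv=0.0,
            drift_amplitude=0.0, batch_effect_sd=0.0, is_area_cv=0.0,
            low_signal_noise=0.0,
        )
        return pb.simulate_study(cfg)[0].par_table()

    def test_designed_fold_passes(self, qc_table):
        acc = qc_acceptance(qc_table, expected_fold=8.0)
        assert acc["passed"].all()
        assert np.allclose(acc["ratio"], 8.0)

    def test_boundaries_inclusive(self):
        # ratio 10.4 = exactly 130% of 8 passes; 5.5 = 68.75% fails
        rows = []
        for i, (role, par) in enumerate([("LQC", 1.0), ("HQC", 10.4)]):
            rows.append({"injection_index": i + 1, "sample_id": role, "role": role,
                         "batch_id": "b", "study_id": "s", "analyte": "X",
                         "area": par, "is_area": 1.0})
        acc = qc_acceptance(pb.PeakTable(pd.DataFrame(rows)).par_table())
        assert acc["passed"].all()
        rows[1]["area"] = 5.5
        acc = qc_acceptance(pb.PeakTable(pd.DataFrame(rows)).par_table())
        assert not acc["passed"].any()
        assert (acc["reason"] == "outside window").all()


class TestPca:
    def test_large_offset_separates_batches(self):
        cfg = pb.SimulationConfig(
            n_samples=20, n_batches=2, seed=3, noise_cv=0.01,
            drift_amplitude=0.0, batch_effect_sd=1.5, is_area_cv=0.0,
            low_signal_noise=0.0, interindividual_sd=0.0, species_jitter_sd=0.0,
        )
        pt = pb.simulate_study(cfg)[0].par_table().rows_with_role("sample")
        diag = pca_batch_diagnostic(pt)
        assert diag.batch_separation > 0.95

    def test_single_batch_scores_zero(self):
        cfg = pb.SimulationConfig(n_samples=10, n_batches=1, seed=3)
        pt = pb.simulate_study(cfg)[0].par_table()
        assert pca_batch_diagnostic(pt).batch_separation == 0.0

    def test_separation_in_unit_interval(self, realistic_joint):
        _, joint, _ = realistic_joint
        sep = pca_batch_diagnostic(joint).batch_separation
        assert 0.0 <= sep <= 1.0

    def test_serrf_reduces_batch_separation(self, realistic_serrf):
        _, joint, _, res = realistic_serrf
        pre = pca_batch_diagnostic(joint).batch_separation
        post = pca_batch_diagnostic(res.normalized).batch_separation
        assert post < pre


class TestBridgeReport:
    def test_identical_tables_fully_concordant(self, batch_only_partable):
        pt, _ = batch_only_partable
        ids = pt.meta.loc[pt.meta["role"] == "sample", "sample_id"].unique()[:5]
        rep = bridge_report(pt, pt, list(ids))
        assert np.allclose(rep.per_sample["percent_difference"], 0.0)
        assert (rep.per_species["frac_within"] == 1.0).all()
        assert rep.per_species["accepted"].all()

    def test_constant_ratio_gives_forty_percent(self, batch_only_partable):
        pt, _ = batch_only_partable
        ids = pt.meta.loc[pt.meta["role"] == "sample", "sample_id"].unique()[:5]
        scaled = pt.with_par(pt.par * 1.5)
        rep = bridge_report(scaled, pt, list(ids))
        assert np.allclose(rep.per_sample["percent_difference"], 40.0)
        assert (rep.per_species["frac_within"] == 0.0).all()

    def test_label_exchange_symmetry(self, realistic_serrf):
        _, _, truth, res = realistic_serrf
        split = {
            s: res.normalized.subset((res.normalized.meta["study_id"] == s).to_numpy())
            for s in ("SAD", "MAD")
        }
        r1 = bridge_report(split["SAD"], split["MAD"], truth["shared_ids"])
        r2 = bridge_report(split["MAD"], split["SAD"], truth["shared_ids"])
        pd.testing.assert_series_equal(
            r1.per_species["frac_within"], r2.per_species["frac_within"]
        )

    def test_frac_within_matches_recount_oracle(self, realistic_serrf):
        _, _, truth, res = realistic_serrf
        split = {
            s: res.normalized.subset((res.normalized.meta["study_id"] == s).to_numpy())
            for s in ("SAD", "MAD")
        }
        rep = bridge_report(split["SAD"], split["MAD"], truth["shared_ids"])
        sp = rep.per_species["species"].iloc[7]
        sub = rep.per_sample[rep.per_sample["species"] == sp]
        manual = np.mean([abs(d) <= 35.0 for d in sub["percent_difference"]])
        assert rep.per_species.set_index("species").loc[sp, "frac_within"] == pytest.approx(manual)

    def test_no_shared_samples_is_error(self, batch_only_partable):
        pt, _ = batch_only_partable
        with pytest.raises(ValueError, match="shared"):
            bridge_report(pt, pt, ["nobody"])

    def test_outside_direction_flips_acceptance(self, batch_only_partable):
        pt, _ = batch_only_partable
        ids = pt.meta.loc[pt.meta["role"] == "sample", "sample_id"].unique()[:5]
        rep = bridge_report(pt, pt, list(ids), accept_direction="outside")
        assert not rep.per_species["accepted"].any()


class TestAnchorVariance:
    def test_identical_normalizations_zero_variance(self, batch_only_partable):
        pt, _ = batch_only_partable
        cmp_ = anchor_variance_comparison({"a": pt, "b": pt.copy(), "c": pt.copy()})
        assert np.allclose(cmp_["variance_pct2"], 0.0)

    def test_hand_computed_percent_diffs(self):
        # one sample, values {9, 10, 11}: avg 10, %diffs {-10, 0, +10}
        meta = pd.DataFrame({
            "injection_index": [1, 2], "sample_id": ["s1", "s2"],
            "role": ["sample", "sample"], "batch_id": ["b", "b"], "study_id": ["x", "x"],
        })
        mk = lambda v: pb.ParTable(meta=meta.copy(), par=pd.DataFrame({"X": v}))
        cmp_ = anchor_variance_comparison(
            {"L": mk([9.0, 9.0]), "H": mk([10.0, 10.0]), "M": mk([11.0, 11.0])},
            equalize_scale=False,
        )
        assert np.allclose(cmp_["variance_pct2"], 0.0)  # constant per anchor

    def test_designed_simulation_reproduces_anchor_ordering(self):
        """Samples sit near the LQC level, so the MAAQC-anchored correction
        tracks them best and LQC beats HQC (level-dependent drift penalizes
        the distant anchor; averaging two QC series halves anchor noise)."""
        cfg = pb.SimulationConfig(
            n_samples=60, n_batches=2, batch_effect_sd=0.3,
            drift_amplitude=0.2, noise_cv=0.10, seed=21,
        )
        pt = pb.simulate_study(cfg)[0].par_table()
        results = {
            k: pb.run_serrf(pt, anchor=k, n_trees=200, seed=3)
            for k in ("LQC", "HQC", "MAAQC")
        }
        med = anchor_variance_comparison(results).groupby("anchor")["variance_pct2"].median()
        assert med["MAAQC"] < med["LQC"] < med["HQC"]

    def test_shape_mismatch_rejected(self, batch_only_partable):
        pt, _ = batch_only_partable
        short = pt.subset(np.arange(len(pt.meta)) < 10)
        with pytest.raises(ValueError, match="different injection"):
            anchor_variance_comparison({"a": pt, "b": short})


class TestReferenceRange:
    def test_compositions_sum_to_one(self):
        pop, _ = pb.simulate_population(20, pb.SimulationConfig(seed=4))
        ref = reference_range(pop.par_table())
        assert np.allclose(ref.composition.sum(axis=1), 1.0, atol=1e-12)

    def test_constant_population_collapses(self):
        cfg = pb.SimulationConfig(
            seed=4, noise_cv=0.0, interindividual_sd=0.0, species_jitter_sd=0.0,
            is_area_cv=0.0, low_signal_noise=0.0,
        )
        pop, _ = pb.simulate_population(5, cfg)
        ref = reference_range(pop.par_table())
        assert np.allclose(ref.per_species["lo"], ref.per_species["hi"])

    def test_percentiles_match_sort_oracle(self):
        pop, _ = pb.simulate_population(49, pb.SimulationConfig(seed=6))
        pt = pop.par_table()
        ref = reference_range(pt)
        sp = pt.species[10]
        v = pt.par[sp].to_numpy()
        row = ref.per_species.set_index("species").loc[sp]
        assert row["lo"] == pytest.approx(np.percentile(v, 2.5), rel=1e-12)
        assert row["hi"] == pytest.approx(np.percentile(v, 97.5), rel=1e-12)


class TestCohortComparison:
    def test_identical_groups_null(self):
        g = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
        res = cohort_compare(g, g.copy())
        row = res.per_species.iloc[0]
        assert row["t"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        a = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"X": [101.0, 102.0, 103.0]})
        res = cohort_compare(a, b)
        assert res.per_species["p_value"].iloc[0] < 1e-3

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(12)
        a = rng.lognormal(0, 0.4, size=30)
        b = rng.lognormal(0.3, 0.7, size=22)
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert df == pytest.approx(ref.df, rel=1e-12)

    def test_type_i_error_calibrated_under_null(self):
        """Welch p-values are uniform under the null: the empirical
        rejection rate at alpha=0.05 over 2000 seeded null draws stays
        within the binomial confidence band around 0.05."""
        rng = np.random.default_rng(99)
        n_sims = 2000
        a = rng.normal(size=(n_sims, 12))
        b = rng.normal(size=(n_sims, 15))
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        # cross-check a handful against the package implementation
        for i in range(5):
            t, df, p = welch_t(a[i], b[i])
            assert p == pytest.approx(res.pvalue[i], rel=1e-9)
        rate = float(np.mean(res.pvalue < 0.05))
        half_width = 3 * np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < half_width

    def test_longitudinal_summary_median_and_sem(self):
        df = pd.DataFrame({
            "visit": [1, 1, 1, 2, 2, 2],
            "group": ["h"] * 6,
            "species": ["X"] * 6,
            "par": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        out = longitudinal_summary(df)
        v1 = out[out["visit"] == 1].iloc[0]
        assert v1["median"] == 2.0
        assert v1["sem"] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
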