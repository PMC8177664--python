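"""SERRF normalization: anchors, forests, correction quality, comparators."""

import numpy as np
import pandas as pd
import pytest

import pibridge as pb
from pibridge.serrf import (
    build_anchor,
    comparator_normalize,
    compute_maaqc,
    fit_serrf,
    run_serrf,
    serrf_normalize,
)


class TestMaaqc:
    def test_constant_series_gives_geometric_mean(self):
        out = compute_maaqc(np.array([[1.0], [1.0]]), np.array([[8.0], [8.0]]))
        assert np.allclose(out, np.sqrt(8.0))

    def test_concordant_drift_is_preserved(self):
        # both series drift up 10%: scaled series agree, average keeps the
        # drift profile {2/2.1, 2.2/2.1} around the geometric-mean scale
        lqc = np.array([[1.0], [1.1]])
        hqc = np.array([[8.0], [8.8]])
        out = compute_maaqc(lqc, hqc)
        scale = np.sqrt(1.05 * 8.4)
        assert np.allclose(out[:, 0] / scale, [1.0 / 1.05, 1.1 / 1.05])

    def test_discordant_drift_is_averaged(self):
        # LQC drifts up 10%, HQC flat: the pseudo-QC drift is half of LQC's
        lqc = np.array([[1.0], [1.1]])
        hqc = np.array([[8.0], [8.0]])
        out = compute_maaqc(lqc, hqc)
        rel = out[:, 0] / out[:, 0].mean()
        lqc_rel = np.array([1.0, 1.1]) / 1.05
        assert np.allclose(rel - 1.0, 0.5 * (lqc_rel - 1.0) / (1 + 0.5 * (lqc_rel - 1).mean()),
                           atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            compute_maaqc(np.ones((2, 1)), np.ones((3, 1)))

    def test_grand_mean_construction_also_mean_adjusted(self):
        rng = np.random.default_rng(0)
        lqc = rng.lognormal(0, 0.1, size=(6, 3))
        hqc = 8 * rng.lognormal(0, 0.1, size=(6, 3))
        a = compute_maaqc(lqc, hqc, "own_mean")
        b = compute_maaqc(lqc, hqc, "grand_mean")
        assert np.allclose(a.mean(axis=0), b.mean(axis=0), rtol=1e-12)


class TestFitting:
    def test_perfectly_correlated_companion_ranks_first(self):
        from pibridge.serrf import _select_predictors

        rng = np.random.default_rng(1)
        n = 12
        target = rng.normal(size=n)
        feats = pd.DataFrame({
            "T": target,
            "copy": target.copy(),
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
        })
        assert _select_predictors(feats, "T", 2)[0] == "copy"

    def test_seeded_determinism(self, batch_only_partable):
        pt, _ = batch_only_partable
        r1 = run_serrf(pt, anchor="MAAQC", n_trees=50, seed=7)
        r2 = run_serrf(pt, anchor="MAAQC", n_trees=50, seed=7)
        pd.testing.assert_frame_equal(r1.normalized.par, r2.normalized.par)

    def test_too_few_species_rejected(self, batch_only_partable):
        pt, _ = batch_only_partable
        small = pt.with_par(pt.par.iloc[:, :5])
        with pytest.raises(ValueError, match="n_predictors"):
            fit_serrf(small, "MAAQC", n_predictors=10, n_trees=10)

    def test_missing_anchor_batch_rejected(self, batch_only_partable):
        pt, _ = batch_only_partable
        keep = ~((pt.meta["batch_id"] == pt.batch_ids()[0])
                 & pt.meta["role"].isin(["LQC", "HQC"]))
        broken = pt.subset(keep.to_numpy())
        with pytest.raises(ValueError):
            fit_serrf(broken, "LQC", n_trees=10)


class TestCorrection:
    @pytest.mark.parametrize("anchor", ["LQC", "HQC", "MAAQC"])
    def test_pure_batch_offsets_fully_removed(self, batch_only_partable, anchor):
        """With only multiplicative batch factors and no noise, the forest
        reduces to per-batch constants and the post-normalization QC RSD
        collapses; the ground-truth oracle (dividing by the known batch
        factor) gives exactly zero."""
        pt, truth = batch_only_partable
        res = run_serrf(pt, anchor=anchor, n_trees=100, seed=1)
        assert res.diagnostics["qc_rsd"]["rsd_post_pct"].max() < 1.0
        # cross-check against the ground-truth division oracle
        bf = truth["batch_factors"]
        oracle = pt.par.to_numpy() / bf.loc[pt.meta["batch_id"]].to_numpy()[
            :, [list(bf.columns).index(c) for c in pt.species]
        ]
        h = pt.meta["role"] == "HQC"
        assert np.allclose(np.std(oracle[h.to_numpy()], axis=0), 0.0, atol=1e-12)

    def test_identity_data_left_essentially_unchanged(self, noise_free_config):
        table, _ = pb.simulate_study(noise_free_config)
        pt = table.par_table()
        res = run_serrf(pt, anchor="MAAQC", n_trees=100, seed=2)
        for sp in pt.species:
            r = np.corrcoef(pt.par[sp], res.normalized.par[sp])[0, 1]
            assert r > 0.99

    def test_qc_ratio_preserved(self, realistic_serrf):
        cfg, _, _, res = realistic_serrf
        rel = res.diagnostics["qc_ratio"] / cfg.qc_fold
        assert (rel >= 0.70).all() and (rel <= 1.30).all()

    def test_fold_change_recovery_improves(self, realistic_serrf):
        """Median absolute relative error of per-sample true PAR recovery
        (up to a per-species scale) shrinks after normalization."""
        cfg, joint, truth, res = realistic_serrf

        def median_rel_err(par_table):
            errs = []
            for study in ("SAD", "MAD"):
                tr = truth[study]["true_par"]
                sel = (par_table.meta["study_id"] == study).to_numpy()
                sub = par_table.par.loc[sel].reset_index(drop=True)
                roles = par_table.meta.loc[sel, "role"].reset_index(drop=True)
                samp = (roles == "sample").to_numpy()
                obs = sub.loc[samp, tr.columns].to_numpy()
                exp = tr.loc[samp].to_numpy()
                ratio = obs / exp
                ratio = ratio / np.median(ratio, axis=0, keepdims=True)
                errs.append(np.abs(ratio - 1.0))
            return float(np.median(np.concatenate(errs)))

        assert median_rel_err(res.normalized) < median_rel_err(joint)

    def test_joint_normalization_bridges_studies(self, realistic_serrf):
        """Shared individuals measured in both studies agree post-SERRF:
        the cross-study percent differences are centered at zero."""
        from pibridge.qc_bridge import bridge_report

        cfg, joint, truth, res = realistic_serrf
        split = {
            s: res.normalized.subset((res.normalized.meta["study_id"] == s).to_numpy())
            for s in ("SAD", "MAD")
        }
        rep = bridge_report(split["SAD"], split["MAD"], truth["shared_ids"])
        med = rep.per_sample.groupby("species")["percent_difference"].median()
        assert abs(med.median()) < 10.0


class TestComparators:
    def test_batch_median_exact_on_pure_offsets(self, batch_only_partable):
        pt, _ = batch_only_partable
        res = comparator_normalize(pt, "batch_median")
        assert res.diagnostics["qc_rsd"]["rsd_post_pct"].max() < 1e-8

    def test_loess_beats_batch_median_on_drift(self):
        cfg = pb.SimulationConfig(
            n_samples=60, n_batches=1, seed=31, noise_cv=0.0,
            batch_effect_sd=0.0, drift_amplitude=0.3, drift_level_gamma=0.0,
            is_area_cv=0.0, low_signal_noise=0.0,
        )
        pt = pb.simulate_study(cfg)[0].par_table()
        rsd_med = comparator_normalize(pt, "batch_median").diagnostics["qc_rsd"]
        rsd_lo = comparator_normalize(pt, "qc_loess").diagnostics["qc_rsd"]
        assert rsd_lo["rsd_post_pct"].median() < rsd_med["rsd_post_pct"].median()

    def test_none_is_identity(self, batch_only_partable):
        pt, _ = batch_only_partable
        res = comparator_normalize(pt, "none")
        pd.testing.assert_frame_equal(res.normalized.par, pt.par)
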