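"""Filtering, the two differential models, FDR and ranking."""

import numpy as np
import pandas as pd
import pytest

from splicequant import differential as D
from splicequant import simdata
from splicequant.quantify import Experiment


def count_experiment(inc, exc, conditions):
    inc = np.asarray(inc, float)
    ids = pd.Index([f"E{i}" for i in range(inc.shape[0])], name="event_id")
    cols = [f"s{j}" for j in range(inc.shape[1])]
    samples = pd.DataFrame({"condition": conditions, "batch": "", "cov_path": ""},
                           index=pd.Index(cols, name="sample_id"))
    return Experiment(
        events=pd.DataFrame(index=ids),
        samples=samples,
        inc=pd.DataFrame(inc, index=ids, columns=cols),
        exc=pd.DataFrame(np.asarray(exc, float), index=ids, columns=cols),
    )


def design_for(x, contrast=("A", "B")):
    return D.DesignSpec(condition=x.samples["condition"].to_dict(), contrast=contrast)


class TestFilterEvents:
    def test_group_depth_fraction_rule(self):
        # depths [25,30] in group 1 and [4,40] in group 2; with frac 0.5 each
        # group has at least one passing sample, so the event is kept
        x = count_experiment([[20, 25, 2, 30]], [[5, 5, 2, 10]],
                             ["A", "A", "B", "B"])
        keep = D.filter_events(x, design_for(x), min_depth=20,
                               min_samples_frac=0.5)
        assert keep.tolist() == [True]

    def test_all_zero_event_filtered(self):
        x = count_experiment([[0, 0, 0, 0], [9, 9, 9, 9]],
                             [[0, 0, 0, 0], [9, 9, 9, 9]], ["A", "A", "B", "B"])
        keep = D.filter_events(x, design_for(x), min_depth=10)
        assert keep.tolist() == [False, True]

    def test_zero_threshold_keeps_everything(self):
        x = count_experiment([[0, 0, 0, 0]], [[0, 0, 0, 0]], ["A", "A", "B", "B"])
        assert D.filter_events(x, design_for(x), min_depth=0).all()

    def test_invalid_threshold_rejected(self):
        x = count_experiment([[1, 1]], [[1, 1]], ["A", "B"])
        with pytest.raises(ValueError):
            D.filter_events(x, design_for(x), min_samples_frac=2.0)


class TestAdjustFdr:
    def test_bh_closed_form(self):
        q = D.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert D.adjust_fdr([0.2]).tolist() == [0.2]

    def test_all_ones_stay_ones(self):
        assert D.adjust_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_missing_values_propagate(self):
        q = D.adjust_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q.iloc[1]) and not np.isnan(q.iloc[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            D.adjust_fdr([0.5, 1.5])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert (D.adjust_fdr(p).to_numpy() >= p - 1e-12).all()


class TestStage1:
    def test_subset_specific_doubling_recovered_as_logfc_one(self):
        rng = np.random.default_rng(7)
        inc = rng.poisson(200, size=(300, 6)).astype(float)
        exc = rng.poisson(200, size=(300, 6)).astype(float)
        inc[:30, 3:] *= 2  # only 10% of events change: size factors stay ~1
        x = count_experiment(inc, exc, ["A"] * 3 + ["B"] * 3)
        res_inc = D.fit_stage1(x, design_for(x), "included")
        res_exc = D.fit_stage1(x, design_for(x), "excluded")
        assert res_inc["logFC"].iloc[:30].mean() == pytest.approx(1.0, abs=0.1)
        assert abs(res_exc["logFC"].iloc[:30].mean()) < 0.1
        assert (res_inc["p"].iloc[:30] < 0.05).mean() > 0.9

    def test_aliased_batch_rejected(self):
        x = count_experiment(np.ones((5, 4)), np.ones((5, 4)), ["A", "A", "B", "B"])
        spec = D.DesignSpec(condition=x.samples["condition"].to_dict(),
                            contrast=("A", "B"),
                            batch={"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        with pytest.raises(ValueError, match="aliased"):
            D.fit_stage1(x, spec, "included")

    def test_constant_counts_are_null(self):
        x = count_experiment(np.full((20, 6), 50.0), np.full((20, 6), 50.0),
                             ["A"] * 3 + ["B"] * 3)
        res = D.fit_stage1(x, design_for(x), "included")
        assert np.allclose(res["logFC"], 0, atol=1e-6)
        assert (res["p"] > 0.9).all()


class TestInteractionGlm:
    def test_expression_only_change_is_not_called_differential(self):
        rng = np.random.default_rng(5)
        inc = rng.poisson(80, size=(200, 6)).astype(float)
        exc = rng.poisson(160, size=(200, 6)).astype(float)
        inc[:, 3:] *= 4  # both isoforms scaled equally: no splicing change
        exc[:, 3:] *= 4
        x = count_experiment(inc, exc, ["A"] * 3 + ["B"] * 3)
        res = D.fit_interaction_glm(x, design_for(x))
        assert (res["p"] < 0.05).mean() < 0.1

    def test_strong_psi_shift_detected(self):
        rng = np.random.default_rng(6)
        n = rng.poisson(100, size=(80, 6))
        psi = np.where(np.arange(6) < 3, 0.2, 0.6)
        inc = rng.binomial(n, psi).astype(float)
        x = count_experiment(inc, n - inc, ["A"] * 3 + ["B"] * 3)
        res = D.fit_interaction_glm(x, design_for(x))
        assert (res["q"].iloc[:] < 0.05).mean() > 0.8
        assert res["delta_psi"].mean() == pytest.approx(0.4, abs=0.05)

    def test_sample_scaling_leaves_psi_and_ranking_stable(self):
        # scaling one sample's inc and exc by a common factor is an
        # expression change, not a splicing change: dPSI is exactly
        # invariant and the test ranking stays concordant (the statistic
        # itself shifts slightly because a deeper sample carries more
        # information in a count model)
        x1, _ = simdata.simulate_count_experiment(150, 3, diff_fraction=0.2, seed=9)
        x2, _ = simdata.simulate_count_experiment(150, 3, diff_fraction=0.2, seed=9)
        x2.inc.iloc[:, 0] *= 5
        x2.exc.iloc[:, 0] *= 5
        d = design_for(x1)
        r1 = D.fit_interaction_glm(x1, d)
        r2 = D.fit_interaction_glm(x2, d)
        assert np.allclose(r1["delta_psi"].dropna(), r2["delta_psi"].dropna())
        assert r1["stat"].corr(r2["stat"], method="spearman") > 0.95
        b1 = D.fit_betabin(x1, ("A", "B"))
        b2 = D.fit_betabin(x2, ("A", "B"))
        assert np.allclose(b1["delta_psi"].dropna(), b2["delta_psi"].dropna())

    def test_undefined_group_psi_gives_missing_result(self):
        inc = [[10, 12, 11, 0, 0, 0]]
        exc = [[10, 10, 10, 0, 0, 0]]
        x = count_experiment(inc, exc, ["A"] * 3 + ["B"] * 3)
        res = D.fit_interaction_glm(x, design_for(x))
        assert res["p"].isna().all()


class TestBetaBinomial:
    def test_moderate_psi_shift_at_depth_200_detected(self):
        # PSI 0.05 -> 0.15 with Y ~= 200 per sample is reliably significant
        # for differential events embedded in a mostly-null panel
        rng = np.random.default_rng(21)
        detected = 0
        for rep in range(10):
            n = rng.poisson(200, size=(200, 6))
            psi = np.tile(rng.uniform(0.05, 0.9, 200)[:, None], (1, 6))
            psi[:20, :3] = 0.05
            psi[:20, 3:] = 0.15
            inc = rng.binomial(n, psi).astype(float)
            x = count_experiment(inc, n - inc, ["A"] * 3 + ["B"] * 3)
            res = D.fit_betabin(x, ("A", "B"))
            detected += (res["q"].iloc[:20] < 0.05).mean() > 0.8
        assert detected >= 8

    def test_group_without_data_gives_missing_result(self):
        inc = [[10, 12, 11, 0, 0, 0]] * 30
        exc = [[10, 10, 10, 0, 0, 0]] * 30
        x = count_experiment(inc, exc, ["A"] * 3 + ["B"] * 3)
        res = D.fit_betabin(x, ("A", "B"))
        assert res["p"].isna().all()

    def test_contrast_swap_negates_delta_and_keeps_p(self):
        x, _ = simdata.simulate_count_experiment(150, 3, diff_fraction=0.2, seed=13)
        r_ab = D.fit_betabin(x, ("A", "B"))
        r_ba = D.fit_betabin(x, ("B", "A"))
        assert np.allclose(r_ab["delta_psi"].dropna(), -r_ba["delta_psi"].dropna())
        assert np.allclose(r_ab["p"].dropna(), r_ba["p"].dropna(), rtol=1e-6)

    def test_single_sample_group_rejected(self):
        x = count_experiment([[5, 5, 5]], [[5, 5, 5]], ["A", "A", "B"])
        with pytest.raises(ValueError, match=">= 2 samples"):
            D.fit_betabin(x, ("A", "B"))


class TestRankEvents:
    def make_results(self):
        return pd.DataFrame({
            "p": [0.001, 0.2, 0.0005, 0.01],
            "q": [0.01, 0.3, 0.01, 0.04],
            "delta_psi": [0.2, 0.5, -0.4, 0.01],
            "psi_A": 0.2, "psi_B": 0.4,
        }, index=pd.Index(["e1", "e2", "e3", "e4"], name="event_id"))

    def test_threshold_and_ordering(self):
        hits = D.rank_events(self.make_results())
        # e2 fails FDR, e4 fails dPSI; tie on q broken by larger |dPSI|
        assert list(hits.index) == ["e3", "e1"]

    def test_permissive_thresholds_keep_all_tested(self):
        hits = D.rank_events(self.make_results(), fdr=1.1, min_dpsi=0.0)
        assert len(hits) == 4

    def test_ranking_recovers_simulated_differential_set(self):
        x, truth = simdata.simulate_count_experiment(800, 3, diff_fraction=0.1,
                                                     seed=17)
        res = D.fit_betabin(x, ("A", "B"))
        from splicequant.util import auroc

        r = res.dropna(subset=["p"])
        assert auroc(truth.loc[r.index, "differential"].to_numpy(),
                     -r["p"].to_numpy()) >= 0.9
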