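"""Coverage normalization, group traces and the per-base T-score."""

import numpy as np
import pytest
from scipy import stats

from splicequant import covplot as V
from splicequant import simdata
from splicequant.reference import ASEvent


def event(etype="SE", region=(300, 350), **kw):
    defaults = dict(event_id=f"{etype}:x", type=etype, gene_id="G", chrom="c",
                    strand="+", region=region, inc_junctions=(),
                    exc_junctions=(), tscore_region=region)
    defaults.update(kw)
    return ASEvent(**defaults)


class TestNormalizationFactor:
    def test_ir_factor_is_spliceover_plus_introndepth(self):
        f, ok = V.normalization_factor(event("IR", uses_intron_depth=True), 0, 0,
                                       splice_over=40, intron_depth=10)
        assert (f, ok) == (50.0, True)

    def test_junction_event_factor_is_inc_plus_exc(self):
        f, ok = V.normalization_factor(event(), 20, 10)
        assert (f, ok) == (30.0, True)

    def test_zero_abundance_flags_ineligible(self):
        f, ok = V.normalization_factor(event(), 0, 0)
        assert not ok

    def test_normalized_trace_divides_by_factor(self):
        depths = np.array([50.0] * 10 + [10.0] * 5)
        tr = V.normalized_coverage(depths, event(), "s", 50.0, (0, 15))
        assert np.allclose(tr.values, np.r_[np.ones(10), np.full(5, 0.2)])

    def test_zero_depth_gives_zero_trace(self):
        tr = V.normalized_coverage(np.zeros(5), event(), "s", 30.0, (0, 5))
        assert not tr.values.any()


class TestPointwiseTTest:
    def test_matches_scipy_closed_form(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.2, 0.05, size=(3, 400))
        b = rng.normal(0.5, 0.08, size=(4, 400))
        ours = V.pointwise_ttest(a, b)
        ref = stats.ttest_ind(a, b, axis=0, equal_var=True).pvalue
        assert np.abs(ours - ref).max() < 1e-10

    def test_hand_computed_example(self):
        a = np.array([[0.10], [0.20], [0.15]])
        b = np.array([[0.50], [0.60], [0.55]])
        t = stats.ttest_ind(a, b, equal_var=True)
        p = V.pointwise_ttest(a, b)
        assert p[0] == pytest.approx(t.pvalue[0], rel=1e-12)
        assert -np.log10(p[0]) == pytest.approx(3.2, abs=0.1)

    def test_identical_groups_give_p_one(self):
        a = np.tile([0.5], (3, 10))
        assert (V.pointwise_ttest(a, a.copy()) == 1.0).all()

    def test_degenerate_unequal_means_hit_floor(self):
        a = np.tile([0.2], (3, 4))
        b = np.tile([0.8], (3, 4))
        assert (V.pointwise_ttest(a, b) == V.P_FLOOR).all()

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            V.pointwise_ttest(np.ones((1, 5)), np.ones((3, 5)))


class TestTscoreTrack:
    def traces(self, values, window=(0, 400)):
        return [V.NormalizedTrace("e", f"s{i}", "c", window, v, 1.0)
                for i, v in enumerate(values)]

    def test_boundary_exclusion_arithmetic(self):
        rng = np.random.default_rng(0)
        e = event(region=(50, 350), tscore_region=(50, 350))
        a = self.traces(rng.normal(0.2, 0.02, size=(3, 400)))
        b = self.traces(rng.normal(0.2, 0.02, size=(3, 400)))
        ts = V.tscore_track(a, b, e)
        scored = ts.neglog10p[55:345]
        assert ts.event_tscore == pytest.approx(scored.mean())
        assert len(scored) == 290

    def test_identical_groups_score_zero(self):
        vals = np.tile(np.linspace(0, 1, 400), (3, 1))
        e = event(region=(100, 300), tscore_region=(100, 300))
        ts = V.tscore_track(self.traces(vals), self.traces(vals.copy()), e)
        assert ts.event_tscore == 0.0

    def test_short_region_skips_exclusion(self, caplog):
        rng = np.random.default_rng(1)
        e = event(region=(10, 18), tscore_region=(10, 18))
        a = self.traces(rng.normal(0.2, 0.02, (3, 40)), window=(0, 40))
        b = self.traces(rng.normal(0.6, 0.02, (3, 40)), window=(0, 40))
        with caplog.at_level("INFO"):
            ts = V.tscore_track(a, b, e)
        assert ts.event_tscore == pytest.approx(ts.neglog10p[10:18].mean())

    def test_neglog_capped(self):
        a = self.traces(np.tile([0.0], (3, 10)), window=(0, 10))
        b = self.traces(np.tile([1.0], (3, 10)), window=(0, 10))
        e = event(region=(0, 10), tscore_region=(0, 10))
        ts = V.tscore_track(a, b, e)
        assert ts.neglog10p.max() <= V.NEGLOG_CAP


class TestEligibility:
    def test_mutually_exclusive_types_excluded(self, tmp_path):
        s = simdata.make_scenario("mxe", seed=1)
        ref = s.build_reference(tmp_path / "ref")
        mxe = [e for e in ref.events if e.type == "MXE"]
        assert mxe and all(not e.tscore_eligible for e in mxe)
        ok, reason = V.tscore_eligible(mxe[0], ref)
        assert not ok and "mutually exclusive" in reason

    def test_interfering_intron_disqualifies_alt_splice_site(self, tmp_path):
        s = simdata.make_scenario("a5ss_interfering", seed=1)
        ref = s.build_reference(tmp_path / "ref")
        target = [e for e in ref.events
                  if e.type == "A5SS" and e.region == (1200, 1400)]
        assert target and not target[0].tscore_eligible
        ok, reason = V.tscore_eligible(target[0], ref)
        assert not ok and "interfering" in reason

    def test_clean_se_is_eligible_with_region(self, tmp_path):
        s = simdata.make_scenario("simple_se", seed=1)
        ref = s.build_reference(tmp_path / "ref")
        (e,) = [e for e in ref.events if e.type == "SE"]
        assert e.tscore_eligible and e.tscore_region == e.region


class TestGroupTraces:
    def test_mean_and_sd_pointwise(self, simple_ir_run):
        x = simple_ir_run["experiment"]
        e = next(ev for ev in simple_ir_run["ref"].events if ev.type == "IR")
        g = V.group_traces(x, e, "A")
        assert g.n == 3
        assert g.mean.shape == g.sd.shape
        # constitutive flanks anchored near 1
        assert 0.85 <= g.mean[:100].mean() <= 1.15

    def test_two_value_sd_example(self):
        vals = np.array([[0.1], [0.3]])
        assert vals.std(ddof=1) == pytest.approx(0.1414, abs=1e-4)

    def test_missing_condition_rejected(self, simple_ir_run):
        x = simple_ir_run["experiment"]
        e = simple_ir_run["ref"].events[0]
        with pytest.raises(ValueError, match="nope"):
            V.group_traces(x, e, "nope")


class TestRenderEvent:
    def test_figure_and_tsv_export(self, simple_ir_run, tmp_path):
        x = simple_ir_run["experiment"]
        ref = simple_ir_run["ref"]
        e = next(ev for ev in ref.events if ev.type == "IR")
        _fig, ts = V.render_event(x, ref, e.event_id, ["A", "B"],
                                  tmp_path / "plot")
        assert (tmp_path / "plot.svg").exists()
        out = (tmp_path / "plot.tsv").read_text().splitlines()
        assert out[0].split("\t")[:2] == ["chrom", "position"]
        assert ts is not None and ts.event_tscore > 0

    def test_exported_intron_means_match_group_ir_ratios(self, simple_ir_run,
                                                         tmp_path):
        import pandas as pd

        x = simple_ir_run["experiment"]
        ref = simple_ir_run["ref"]
        e = next(ev for ev in ref.events if ev.type == "IR")
        V.render_event(x, ref, e.event_id, ["A", "B"], tmp_path / "p")
        df = pd.read_csv(tmp_path / "p.tsv", sep="\t")
        intron = df[(df.position >= e.region[0]) & (df.position < e.region[1])]
        psi = x.psi()
        for cond, truth_cols in (("A", ["A1", "A2", "A3"]),
                                 ("B", ["B1", "B2", "B3"])):
            group_ratio = psi.loc[e.event_id, truth_cols].mean()
            assert abs(intron[f"mean_{cond}"].mean() - group_ratio) <= 0.05

    def test_single_condition_renders_without_tscore(self, simple_ir_run, tmp_path):
        x = simple_ir_run["experiment"]
        ref = simple_ir_run["ref"]
        e = next(ev for ev in ref.events if ev.type == "IR")
        _fig, ts = V.render_event(x, ref, e.event_id, ["A"], tmp_path / "single")
        assert ts is None and (tmp_path / "single.svg").exists()

    def test_ineligible_event_refused_with_reason(self, tmp_path):
        import pandas as pd
        from splicequant import quantify

        ab = {f"s{i}": {"iso1": 20.0, "iso2": 20.0} for i in (1, 2, 3, 4)}
        s = simdata.make_scenario("mxe", abundances=ab, seed=6)
        ref = s.build_reference(tmp_path / "ref")
        bams = simdata.simulate_reads(s, tmp_path / "sim", seed=6)
        bundles = [quantify.process_sample(b, ref, tmp_path / sid, sample_id=sid,
                                           protocol="unstranded")
                   for sid, b in bams.items()]
        info = pd.DataFrame({"condition": ["A", "A", "B", "B"]},
                            index=pd.Index(sorted(bams), name="sample_id"))
        x = quantify.collate(bundles, ref, sample_info=info)
        mxe = next(e for e in ref.events if e.type == "MXE")
        with pytest.raises(ValueError, match="mutually exclusive"):
            V.render_event(x, ref, mxe.event_id, ["A", "B"], tmp_path / "no")
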