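import numpy as np
import pandas as pd
import pytest
from scipy import stats

from icmod import rhythm
from icmod.io import SampleMeta, TimeSeriesMatrix


class TestDetectRhythm:
    @pytest.mark.parametrize("phase", range(0, 24, 3))
    def test_noiseless_cosine_recovered(self, times, phase):
        y = 1.0 + 0.5 * np.cos(2 * np.pi * (times - phase) / 24.0)
        f = rhythm.detect_rhythm(y, times)
        assert f.period == pytest.approx(24.0, abs=0.1)
        err = abs(f.phase - phase) % 24
        assert min(err, 24 - err) <= 0.2
        assert f.amplitude == pytest.approx(0.5, rel=0.02)
        assert f.mesor == pytest.approx(1.0, abs=0.01)
        assert f.p < 1e-9 and f.cycling

    def test_constant_series_is_null(self, times):
        f = rhythm.detect_rhythm([5.0] * 16, times)
        assert f.amplitude == 0.0
        assert f.p == 1.0
        assert not f.cycling

    def test_alpha_boundary_is_strict(self):
        fits = pd.DataFrame({"feature_id": ["a", "b"], "p": [0.01, 0.0099]})
        assert rhythm.classify_cycling(fits, alpha=0.01) == {"b"}

    def test_shift_invariant_scale_equivariant(self, times):
        rng = np.random.default_rng(8)
        y = 1 + 0.3 * np.cos(2 * np.pi * (times - 4) / 24) * rng.lognormal(0, 0.05, 16)
        f0 = rhythm.detect_rhythm(y, times)
        f_shift = rhythm.detect_rhythm(y + 100.0, times)
        f_scale = rhythm.detect_rhythm(y * 7.0, times)
        assert f_shift.p == pytest.approx(f0.p, rel=1e-6)
        assert f_shift.amplitude == pytest.approx(f0.amplitude, rel=1e-6)
        assert f_scale.p == pytest.approx(f0.p, rel=1e-6)
        assert f_scale.amplitude == pytest.approx(7 * f0.amplitude, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rhythm.detect_rhythm([1, 2, 3], [0.0, 3.0, 6.0])


class TestClassifyAndCompare:
    def test_classify_examples(self):
        fits = pd.DataFrame({"feature_id": ["x", "y"], "p": [0.005, 0.02]})
        assert rhythm.classify_cycling(fits) == {"x"}
        assert rhythm.classify_cycling(pd.DataFrame({"feature_id": [], "p": []})) == set()

    def test_abolished_fraction(self):
        d = rhythm.compare_conditions({"x", "y", "z"}, {"x"})
        assert d.abolished_fraction == pytest.approx(2 / 3)
        assert d.abolished == {"y", "z"}
        assert d.retained == {"x"}

    def test_superset_condition_b(self):
        d = rhythm.compare_conditions({"x"}, {"x", "y"})
        assert d.abolished_fraction == 0.0

    def test_planted_damping_recovered(self, bundle, pipeline_run):
        """Measured abolished-cycling fractions track the planted damping."""
        rep, _ = pipeline_run
        truth_sets = {
            "mrna": bundle.truth.rhythmic_mrna,
            "protein": bundle.truth.rhythmic_protein,
            "phospho": bundle.truth.ncp_sites,
        }
        for level in ("mrna", "protein", "phospho"):
            realized = 100 * (
                1 - len(bundle.truth.per0_retained[level]) / len(truth_sets[level])
            )
            pct = rep["stages"]["damping"][level]["abolished_pct"]
            assert abs(pct - realized) <= 5.0


class TestPhaseEnrichment:
    def test_uniform_peaks_ratio_one(self):
        phases = np.repeat(np.arange(8) * 3 + 1.0, 10)
        out = rhythm.phase_enrichment(phases)
        assert np.allclose(out["ratio"], 1.0)

    def test_concentrated_peaks(self):
        out = rhythm.phase_enrichment([1.0] * 5)
        assert out["ratio"].iloc[0] == pytest.approx(8.0)
        assert np.allclose(out["ratio"].iloc[1:], 0.0)

    def test_mean_ratio_is_one_for_any_input(self):
        rng = np.random.default_rng(1)
        out = rhythm.phase_enrichment(rng.uniform(0, 24, 57))
        assert float(out["ratio"].mean()) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rhythm.phase_enrichment([])


class TestFoldChange:
    @pytest.mark.parametrize(
        "mesor,amp,expect", [(1.0, 0.0, 1.0), (1.0, 0.5, 3.0)]
    )
    def test_closed_form(self, mesor, amp, expect):
        f = rhythm.RhythmFit("f", 24, 0, amp, mesor, np.nan, 0.5, False)
        assert rhythm.fold_change(f) == pytest.approx(expect)

    def test_zero_trough_flagged(self):
        f = rhythm.RhythmFit("f", 24, 0, 1.0, 1.0, np.nan, 0.5, False)
        assert np.isnan(rhythm.fold_change(f))


def _two_day_matrix(day2_transform):
    rng = np.random.default_rng(11)
    vals_d1 = rng.lognormal(0, 1, (20, 8))
    vals_d2 = day2_transform(vals_d1)
    meta, cols = [], {}
    for j in range(8):
        for day, block in ((1, vals_d1), (2, vals_d2)):
            sid = f"s{day}_{j}"
            meta.append(SampleMeta(sid, "WT", 3.0 * j, day, "b1"))
            cols[sid] = block[:, j]
    return TimeSeriesMatrix(pd.DataFrame(cols, index=[f"f{i}" for i in range(20)]), meta, "protein")


class TestDayCorrelation:
    def test_identical_days(self):
        m = _two_day_matrix(lambda v: v.copy())
        assert rhythm.day_correlation(m) == pytest.approx(1.0)

    def test_rank_reversal(self):
        m = _two_day_matrix(lambda v: -v + 2 * v.max())
        assert rhythm.day_correlation(m) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(12)
        m = _two_day_matrix(lambda v: v * rng.lognormal(0, 0.5, v.shape))
        got = rhythm.day_correlation(m)
        d1 = m.values[[f"s1_{j}" for j in range(8)]].to_numpy().ravel()
        d2 = m.values[[f"s2_{j}" for j in range(8)]].to_numpy().ravel()
        expect = np.corrcoef(stats.rankdata(d1), stats.rankdata(d2))[0, 1]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_unmatched_cts_rejected(self):
        m = _two_day_matrix(lambda v: v.copy())
        m.values.drop(columns=["s2_3"], inplace=True)
        with pytest.raises(ValueError, match="do not match"):
            rhythm.day_correlation(m)


class TestChi2Periodogram:
    def test_constant_activity_below_line_everywhere(self):
        r = rhythm.chi2_periodogram(np.full(336, 3.0), 30.0)
        assert not r.rhythmic
        assert (r.qp < r.sig_line).all()

    def test_all_zero_gives_power_zero(self):
        r = rhythm.chi2_periodogram(np.zeros(336), 30.0)
        assert r.power == 0.0 and not r.rhythmic

    def test_power_threshold_is_inclusive_at_10(self):
        x = np.zeros(336)
        x[::48] = 50.0
        r = rhythm.chi2_periodogram(x, 30.0)
        assert r.rhythmic
        # verdict flips exactly when the required power exceeds the observed
        r_hi = rhythm.chi2_periodogram(x, 30.0, power_min=r.power + 0.1)
        r_eq = rhythm.chi2_periodogram(x, 30.0, power_min=r.power)
        assert not r_hi.rhythmic and r_eq.rhythmic

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="2 full days"):
            rhythm.chi2_periodogram(np.zeros(47), 60.0)
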