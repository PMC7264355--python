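import numpy as np
import pandas as pd
import pytest

from icmod import normalize
from icmod.io import SampleMeta, TimeSeriesMatrix


def _mat(values: np.ndarray, level="protein", features=None, samples=None, batches=None):
    n_feat, n_samp = values.shape
    features = features or [f"f{i}" for i in range(n_feat)]
    samples = samples or [f"s{j}" for j in range(n_samp)]
    batches = batches or ["b1"] * n_samp
    meta = [
        SampleMeta(s, "WT", 3.0 * (j % 8), 1 + j // 8 % 2, batches[j])
        for j, s in enumerate(samples)
    ]
    return TimeSeriesMatrix(pd.DataFrame(values, index=features, columns=samples), meta, level)


class TestGlobalCenter:
    def test_column_divided_by_its_mean(self):
        m = _mat(np.array([[2.0], [4.0], [6.0]]))
        out = normalize.global_center(m)
        assert np.allclose(out.values["s0"], [0.5, 1.0, 1.5])

    def test_idempotent_on_centered_input(self):
        m = _mat(np.array([[0.5], [1.0], [1.5]]))
        out = normalize.global_center(m)
        assert np.allclose(out.values["s0"], [0.5, 1.0, 1.5])

    def test_all_column_means_become_one(self):
        rng = np.random.default_rng(3)
        m = _mat(rng.lognormal(0, 1, (50, 8)))
        out = normalize.global_center(m)
        assert np.allclose(out.values.mean(axis=0), 1.0, atol=1e-12)

    def test_preserves_within_sample_rank_order(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 1, (30, 4))
        out = normalize.global_center(_mat(vals))
        for j, col in enumerate(out.values.columns):
            assert (np.argsort(out.values[col].to_numpy()) == np.argsort(vals[:, j])).all()

    def test_zero_mean_sample_rejected(self):
        with pytest.raises(ValueError, match="zero mean"):
            normalize.global_center(_mat(np.zeros((3, 1))))


class TestBridgeBatchCorrect:
    def _two_batch(self, bridge_ref=10.0, bridge_tgt=5.0, tgt_val=7.0):
        vals = np.array([[bridge_ref, 1.0, bridge_tgt, tgt_val]])
        return _mat(vals, samples=["br", "x1", "br4", "x4"], batches=["b1", "b1", "b4", "b4"])

    def test_ratio_applied_to_target_batch(self):
        out = normalize.bridge_batch_correct(self._two_batch(), "br", "br4", "b4")
        assert out.values.loc["f0", "x4"] == pytest.approx(14.0)
        assert out.values.loc["f0", "x1"] == 1.0  # reference batch untouched

    def test_identical_bridge_values_are_identity(self):
        m = self._two_batch(bridge_ref=5.0, bridge_tgt=5.0)
        out = normalize.bridge_batch_correct(m, "br", "br4", "b4")
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_features_without_bridge_ratio_dropped(self):
        vals = np.array([[10.0, 1.0, 5.0, 7.0], [0.0, 1.0, 5.0, 7.0], [np.nan, 1.0, 5.0, 7.0]])
        m = _mat(vals, samples=["br", "x1", "br4", "x4"], batches=["b1", "b1", "b4", "b4"])
        out = normalize.bridge_batch_correct(m, "br", "br4", "b4")
        assert list(out.values.index) == ["f0"]

    def test_planted_batch_effect_recovered(self, bundle):
        """A global 0.5x batch effect is exactly inverted via the bridge sample."""
        t = bundle.truth
        corrected = normalize.bridge_batch_correct(
            bundle.protein, t.bridge_ref_sample, t.bridge_tgt_sample, t.target_batch
        )
        b4_cols = [
            s.sample_id
            for s in bundle.samples
            if s.batch == t.target_batch and s.genotype != "bridge"
        ]
        # uncorrupted truth = stored values divided back by the batch factor
        expected = bundle.protein.values[b4_cols] / t.batch_factor
        got = corrected.values[b4_cols].loc[expected.index.intersection(corrected.values.index)]
        assert np.allclose(got, expected.loc[got.index], rtol=1e-9, equal_nan=True)


class TestNcpSeries:
    def _pair(self, ph, pr, sites=("P0:S1",), prots=("P0",)):
        phospho = _mat(np.asarray(ph, float), level="phospho", features=list(sites))
        protein = _mat(np.asarray(pr, float), level="protein", features=list(prots))
        return phospho, protein

    def test_constant_stoichiometry_gives_flat_series(self):
        ph, pr = self._pair([[2.0, 4.0]], [[1.0, 2.0]])
        out = normalize.compute_ncp_series(ph, pr)
        assert np.allclose(out.values.loc["P0:S1"], [2.0, 2.0])
        assert out.level == "phospho_normalized"

    def test_identity_ratio(self):
        ph, pr = self._pair([[3.0, 5.0]], [[3.0, 5.0]])
        out = normalize.compute_ncp_series(ph, pr)
        assert np.allclose(out.values.loc["P0:S1"], 1.0)

    def test_scale_invariance_under_joint_per_sample_factor(self):
        """Rhythmic protein abundance alone must not create a rhythmic ratio."""
        rng = np.random.default_rng(5)
        ph = rng.lognormal(0, 0.3, (4, 8))
        pr = rng.lognormal(0, 0.3, (1, 8))
        sites = [f"P0:S{i+1}" for i in range(4)]
        a, b = self._pair(ph, pr, sites=sites)
        base = normalize.compute_ncp_series(a, b).values
        factor = rng.lognormal(0, 1, 8)  # arbitrary positive per-sample factor
        a2, b2 = self._pair(ph * factor, pr * factor, sites=sites)
        scaled = normalize.compute_ncp_series(a2, b2).values
        assert np.allclose(scaled, base, rtol=1e-12)

    def test_zero_protein_excludes_site(self):
        ph, pr = self._pair([[2.0, 4.0]], [[1.0, 0.0]])
        out = normalize.compute_ncp_series(ph, pr)
        assert out.values.empty

    def test_log_ratio_option(self):
        ph, pr = self._pair([[2.0, 8.0]], [[1.0, 2.0]])
        out = normalize.compute_ncp_series(ph, pr, log_ratio=True)
        assert np.allclose(out.values.loc["P0:S1"], [1.0, 2.0])  # log2 of [2, 4]
        ph0, pr0 = self._pair([[0.0, 8.0]], [[1.0, 2.0]])
        with pytest.raises(ValueError, match="strictly positive"):
            normalize.compute_ncp_series(ph0, pr0, log_ratio=True)

    def test_absent_protein_excludes_site(self):
        ph, pr = self._pair([[2.0, 4.0]], [[1.0, 2.0]], sites=("PX:S1",))
        out = normalize.compute_ncp_series(ph, pr)
        assert out.values.empty
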