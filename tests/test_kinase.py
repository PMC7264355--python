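import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icmod import kinase
from icmod.io import SiteRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
PEP = "AAAAAAASAAAAAAA"  # S-centered, all-Ala flanks: self-similarity 14*4 + 4


class TestPeptideSimilarity:
    def test_self_similarity_of_ala_flank(self):
        assert kinase.peptide_similarity(PEP, PEP) == 60.0

    def test_padding_scores_zero(self):
        assert kinase.peptide_similarity(PEP, "*" * 15) == 0.0

    def test_negative_entries_floored(self):
        # W vs A is negative in BLOSUM62; floored contribution is 0
        a = "W" + PEP[1:]
        b = "A" + PEP[1:]
        assert kinase.peptide_similarity(a, b) == kinase.peptide_similarity(PEP, PEP) - 4.0

    @settings(deadline=None, max_examples=50)
    @given(st.tuples(*([st.sampled_from(AA + "*")] * 15)), st.tuples(*([st.sampled_from(AA + "*")] * 15)))
    def test_symmetric(self, a, b):
        a, b = "".join(a), "".join(b)
        assert kinase.peptide_similarity(a, b) == kinase.peptide_similarity(b, a)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kinase.peptide_similarity("AAA", PEP)


def _model(peptides, kinase_class="STK"):
    return kinase.KinaseModel("K1", "AGC", "fam", kinase_class, list(peptides))


class TestScoreSite:
    def test_single_training_peptide_gives_self_similarity(self):
        assert kinase.score_site(_model([PEP]), PEP) == 60.0

    def test_mean_over_training_set(self):
        m = _model([PEP, "T".join(["AAAAAAA", "AAAAAAA"])])  # S- and T-centered
        s1 = kinase.peptide_similarity(PEP, m.training_peptides[0])
        s2 = kinase.peptide_similarity(PEP, m.training_peptides[1])
        assert kinase.score_site(m, PEP) == pytest.approx((s1 + s2) / 2)

    def test_duplicate_training_peptides_do_not_bias(self):
        m1 = _model([PEP, "AAAAAAATAAAAAAA"])
        m2 = _model([PEP, PEP, "AAAAAAATAAAAAAA"])
        q = "RRRAAAASAAAAAAA"
        assert kinase.score_site(m1, q) == kinase.score_site(m2, q)

    def test_class_gating(self):
        stk = _model([PEP])
        with pytest.raises(ValueError, match="cannot score"):
            kinase.score_site(stk, "AAAAAAAYAAAAAAA")
        with pytest.raises(ValueError):
            kinase.KinaseModel("K2", "TK", "fam", "TK", [PEP])  # S-centered peptide in a TK


class TestCalibration:
    def test_order_statistics_on_constructed_background(self):
        scores = list(range(100))
        assert kinase.threshold_from_scores(scores, 0.10) == 90.0

    def test_fpr_one_passes_everything(self):
        assert kinase.threshold_from_scores([5.0, 7.0, 9.0], 1.0) == 5.0

    @settings(deadline=None, max_examples=40)
    @given(
        scores=st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=300),
        fpr=st.floats(0.01, 1.0),
    )
    def test_pass_fraction_never_exceeds_fpr(self, scores, fpr):
        thr = kinase.threshold_from_scores(scores, fpr)
        arr = np.asarray(scores)
        assert (arr >= thr).mean() <= fpr

    @settings(deadline=None, max_examples=40)
    @given(
        scores=st.lists(st.floats(0, 100, allow_nan=False), min_size=5, max_size=300),
        f1=st.floats(0.01, 1.0),
        f2=st.floats(0.01, 1.0),
    )
    def test_threshold_monotone_in_fpr(self, scores, f1, f2):
        """Raising the allowed FPR never raises the threshold."""
        lo, hi = sorted([f1, f2])
        assert kinase.threshold_from_scores(scores, hi) <= kinase.threshold_from_scores(scores, lo)

    def test_background_minimum_enforced(self):
        m = _model([PEP])
        with pytest.raises(ValueError, match="< 100"):
            kinase.calibrate_threshold(m, [PEP] * 50, 0.1)


class TestPredict:
    def test_pass_rule_is_greater_equal(self):
        m = _model([PEP])
        m.threshold = 60.0
        site_hit = SiteRecord("P1", "S", 8, 1.0, PEP)
        preds = kinase.predict_sskr([m], [site_hit])
        assert len(preds) == 1 and preds[0].passed
        m.threshold = 60.0001
        assert kinase.predict_sskr([m], [site_hit]) == []

    def test_planted_motif_recovery(self, bundle):
        """Kinases recover >=90% of their own-motif sites; motif-free sites
        pass at no more than FPR + 5 points."""
        seqs = [p.sequence for p in bundle.proteome]
        models = bundle.models
        for m in models:
            residues = "ST" if m.kinase_class == "STK" else "Y"
            fpr = 0.10 if m.kinase_class == "STK" else 0.15
            bg = kinase.sample_background(seqs, residues, n=10_000, seed=7)
            kinase.calibrate_threshold(m, bg, fpr)
        preds = kinase.predict_sskr(models, bundle.sites)
        hit: dict[str, set] = {}
        for p in preds:
            hit.setdefault(p.kinase_id, set()).add(p.site_id)
        own: dict[str, set] = {}
        for sid, kid in bundle.truth.site_kinase.items():
            own.setdefault(kid, set()).add(sid)
        for m in models:
            mine = own[m.kinase_id]
            others = {
                s.site_id for s in bundle.sites if m.compatible(s.flank)
            } - mine
            got = hit.get(m.kinase_id, set())
            assert len(got & mine) / len(mine) >= 0.90, m.kinase_id
            if others:
                assert len(got & others) / len(others) <= m.fpr + 0.05, m.kinase_id


class TestCoverage:
    def _preds(self, pairs):
        return [kinase.SsKsrPrediction(k, s, 10.0, 1.0) for k, s in pairs]

    def _models(self):
        m1 = _model([PEP])
        m2 = kinase.KinaseModel("K2", "CMGC", "fam2", "STK", [PEP])
        return [m1, m2]

    def test_single_family_share_100(self):
        cov = kinase.coverage_by_level(self._preds([("K1", "a"), ("K1", "b")]), self._models())
        assert cov.family_share == {"fam": 100.0}

    def test_site_with_two_kinases_in_ge2_bucket(self):
        cov = kinase.coverage_by_level(
            self._preds([("K1", "a"), ("K2", "a"), ("K1", "b")]), self._models()
        )
        assert cov.kinases_per_site["a"] == 2
        assert cov.frac_sites_ge2 == pytest.approx(0.5)
        assert cov.frac_sites_ge1 == 1.0

    def test_group_shares_sum_to_100(self):
        cov = kinase.coverage_by_level(
            self._preds([("K1", "a"), ("K2", "a"), ("K2", "b")]), self._models()
        )
        assert sum(cov.group_share.values()) == pytest.approx(100.0, abs=1e-9)
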