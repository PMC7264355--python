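import pytest

from icmod import web


PREDS = [
    ("KA", "P1:S10"),
    ("KA", "P2:S5"),
    ("KB", "P1:S10"),
    ("KX", "P3:S1"),  # kinase outside the set
    ("KA", "P4:S2"),  # site outside the NCP set
]
NCPS = {"P1:S10", "P2:S5", "P3:S1"}
KSET = {"KA", "KB"}


@pytest.fixture
def core():
    return web.build_ks_network(PREDS, KSET, NCPS)


class TestBuildKsNetwork:
    def test_edges_from_kinase_set_to_ncps_only(self, core):
        kinds = {k for (_, _, k) in core.edges}
        assert kinds == {"sskr"}
        assert ("KA", "P1:S10", "sskr") in core.edges
        assert ("KB", "P1:S10", "sskr") in core.edges
        assert ("KA", "P2:S5", "sskr") in core.edges
        assert len(core.edges) == 3

    def test_outside_kinase_and_non_ncp_excluded(self, core):
        assert "KX" not in core.nodes
        assert "P4:S2" not in core.nodes

    def test_parent_proteins_are_substrate_nodes(self, core):
        assert core.nodes["P1"] == "protein"
        assert core.nodes["P1:S10"] == "substrate_site"

    def test_empty_kinase_set_rejected(self):
        with pytest.raises(ValueError):
            web.build_ks_network(PREDS, set(), NCPS)


class TestExpandWithPpi:
    PPI = [("CYC1", "P1", "db"), ("CYC2", "ORPHAN", "db"), ("FLAT", "P1", "db")]

    def test_cyclic_protein_touching_web_added(self, core):
        out = web.expand_with_ppi(core, self.PPI, {"CYC1", "CYC2"})
        assert out.nodes.get("CYC1") == "protein"
        assert ("CYC1", "P1", "ppi") in out.edges

    def test_cyclic_without_partner_not_added(self, core):
        out = web.expand_with_ppi(core, self.PPI, {"CYC1", "CYC2"})
        assert "CYC2" not in out.nodes

    def test_non_cyclic_interactor_not_added(self, core):
        out = web.expand_with_ppi(core, self.PPI, {"CYC1"})
        assert "FLAT" not in out.nodes

    def test_single_pass_no_transitive_chaining(self, core):
        # CYC3 touches only CYC1 (itself newly added), so it must not join
        ppi = self.PPI + [("CYC3", "CYC1", "db")]
        out = web.expand_with_ppi(core, ppi, {"CYC1", "CYC3"})
        assert "CYC1" in out.nodes and "CYC3" not in out.nodes

    def test_monotone_growth(self, core):
        out = web.expand_with_ppi(core, self.PPI, {"CYC1"})
        assert set(core.nodes) <= set(out.nodes)
        assert set(core.edges) <= set(out.edges)


class TestAttachTfLayer:
    TF_TARGETS = [
        ("TF1", "gene_cyc", "tfbs"),
        ("TF2", "gene_cyc", "tfbs"),
        ("TF3", "gene_flat", "tfbs"),
    ]
    TF_SITES = {"TF1": ["TF1:S3"], "TF2": ["TF2:S9"], "TF3": ["TF3:S1"]}
    PREDS2 = PREDS + [("KA", "TF1:S3"), ("KA", "TF3:S1")]

    def test_qualifying_tf_added_with_both_edge_kinds(self, core):
        out = web.attach_tf_layer(
            core, self.TF_TARGETS, self.TF_SITES, self.PREDS2, {"gene_cyc"}, KSET
        )
        assert out.nodes["TF1"] == "tf"
        assert ("TF1", "gene_cyc", "tf_target") in out.edges
        assert ("KA", "TF1:S3", "sskr") in out.edges

    def test_tf_without_kinase_set_sskr_excluded(self, core):
        out = web.attach_tf_layer(
            core, self.TF_TARGETS, self.TF_SITES, self.PREDS2, {"gene_cyc"}, KSET
        )
        assert "TF2" not in out.nodes

    def test_tf_without_cyclic_target_excluded(self, core):
        out = web.attach_tf_layer(
            core, self.TF_TARGETS, self.TF_SITES, self.PREDS2, {"gene_cyc"}, KSET
        )
        assert "TF3" not in out.nodes


class TestHubRank:
    def test_star_center_first(self):
        w = web.SignalWeb()
        w.add_node("HUB", "kinase")
        for i in range(5):
            w.add_node(f"s{i}", "substrate_site")
            w.add_edge("HUB", f"s{i}", "sskr")
        ranked = web.hub_rank(w)
        assert ranked[0] == ("HUB", 5)

    def test_ties_broken_lexicographically(self):
        w = web.SignalWeb()
        w.add_node("b", "protein")
        w.add_node("a", "protein")
        w.add_edge("a", "b", "ppi")
        assert web.hub_rank(w) == [("a", 1), ("b", 1)]

    def test_handshake_identity(self, core):
        ranked = web.hub_rank(core)
        assert sum(d for _, d in ranked) == 2 * len(core.edges)


class TestDeterminism:
    def test_order_independent_construction(self):
        w1 = web.build_ks_network(PREDS, KSET, NCPS)
        w2 = web.build_ks_network(list(reversed(PREDS)), KSET, NCPS)
        assert w1.nodes == w2.nodes and w1.edges == w2.edges
        p = TestExpandWithPpi.PPI
        e1 = web.expand_with_ppi(w1, p, {"CYC1"})
        e2 = web.expand_with_ppi(w2, list(reversed(p)), {"CYC1"})
        assert e1.nodes == e2.nodes and e1.edges == e2.edges

    def test_json_roundtrip(self, core, tmp_path):
        p = tmp_path / "web.json"
        core.write_json(p)
        back = web.SignalWeb.read_json(p)
        assert back.nodes == core.nodes and back.edges == core.edges


class TestCoverageStats:
    def test_planted_coverage_exact(self, core):
        # 2 of 4 NCPs covered by KSET -> 0.5; construct 0.75 with 4 ncps, 3 covered
        preds = [("KA", "P1:S10"), ("KA", "P2:S5"), ("KB", "P3:S1")]
        ncps = {"P1:S10", "P2:S5", "P3:S1", "P9:S9"}
        w = web.build_ks_network(preds, KSET, ncps)
        cov = web.coverage_stats(w, ncps, set(), preds, KSET)
        assert cov.ncp_coverage == pytest.approx(0.75)

    def test_indirect_class_via_ppi_partner(self, core):
        out = web.expand_with_ppi(core, [("CYC1", "P1", "db")], {"CYC1"})
        cov = web.coverage_stats(out, NCPS, {"CYC1", "P1"}, PREDS, KSET)
        assert cov.protein_direct == pytest.approx(0.5)  # P1 contains covered NCP
        assert cov.protein_indirect == pytest.approx(0.5)  # CYC1 only via PPI
        assert cov.protein_union == pytest.approx(1.0)

    def test_all_covered(self):
        preds = [("KA", s) for s in NCPS]
        w = web.build_ks_network(preds, KSET, NCPS)
        cov = web.coverage_stats(w, NCPS, set(), preds, KSET)
        assert cov.ncp_coverage == 1.0
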