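"""Assembly of the multi-level circadian kinase signal web.

A typed graph built in three passes: (1) the kinase-substrate core — ssKSR
edges from a chosen kinase set to NCP sites; (2) single-pass PPI expansion —
cyclic proteins directly interacting with a member of the core are attached
(no transitive chaining); (3) a transcription-factor layer — TFs that both
target a cyclic mRNA and carry a predicted ssKSR from the kinase set.  Hub
ranking is by total degree over all edge kinds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import site_protein

NODE_KINDS = ("kinase", "substrate_site", "protein", "tf", "mrna")
EDGE_KINDS = ("sskr", "ppi", "tf_target")


@dataclass
class SignalWeb:
    """Typed node/edge graph with per-edge provenance.

    Nodes: id -> kind.  Edges: (src, dst, kind) -> provenance; ppi edges are
    undirected and stored with canonically ordered endpoints.
    """

    nodes: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        prev = self.nodes.get(node_id)
        if prev is not None and prev != kind:
            raise ValueError(f"node {node_id!r} already typed {prev!r}, not {kind!r}")
        self.nodes[node_id] = kind

    def add_edge(self, src: str, dst: str, kind: str, provenance: str = "") -> None:
        if kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {kind!r}")
        if kind == "ppi" and dst < src:
            src, dst = dst, src
        if src not in self.nodes or dst not in self.nodes:
            raise ValueError(f"edge endpoints {src!r}->{dst!r} must be nodes first")
        if kind == "sskr" and self.nodes[src] != "kinase":
            raise ValueError("sskr edges run kinase -> site only")
        self.edges.setdefault((src, dst, kind), provenance)

    def degree(self, node_id: str) -> int:
        return sum(1 for (a, b, _k) in self.edges for x in (a, b) if x == node_id)

    def copy(self) -> "SignalWeb":
        return SignalWeb(dict(self.nodes), dict(self.edges))

    # -- serialization ----------------------------------------------------
    def to_json_obj(self) -> dict:
        return {
            "nodes": [
                {"id": i, "kind": k} for i, k in sorted(self.nodes.items())
            ],
            "edges": [
                {"src": s, "dst": d, "kind": k, "provenance": prov}
                for (s, d, k), prov in sorted(self.edges.items())
            ],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "SignalWeb":
        web = cls()
        for nd in obj["nodes"]:
            web.add_node(nd["id"], nd["kind"])
        for ed in obj["edges"]:
            web.add_edge(ed["src"], ed["dst"], ed["kind"], ed.get("provenance", ""))
        return web

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "SignalWeb":
        return cls.from_json_obj(json.loads(Path(path).read_text()))

    def write_sif(self, path: str | Path) -> None:
        """SIF-style edge TSV: src <tab> kind <tab> dst."""
        lines = [f"{s}\t{k}\t{d}" for (s, d, k) in sorted(self.edges)]
        Path(path).write_text("\n".join(lines) + "\n")


def build_ks_network(
    predictions,  # Sequence[SsKsrPrediction] or iterable of (kinase_id, site_id)
    kinase_set: set[str],
    ncps: set[str],
) -> SignalWeb:
    """Kinase-substrate core: ssKSR edges from ``kinase_set`` to NCP sites,
    with parent proteins added as substrate nodes."""
    if not kinase_set:
        raise ValueError("kinase_set is empty")
    web = SignalWeb()
    pairs = [
        (p.kinase_id, p.site_id) if hasattr(p, "kinase_id") else tuple(p)
        for p in predictions
    ]
    for kinase_id, site_id in sorted(set(pairs)):
        if kinase_id not in kinase_set or site_id not in ncps:
            continue
        web.add_node(kinase_id, "kinase")
        web.add_node(site_id, "substrate_site")
        web.add_node(site_protein(site_id), "protein")
        web.add_edge(kinase_id, site_id, "sskr", "predicted")
    return web


def expand_with_ppi(
    web: SignalWeb,
    ppi: Iterable[tuple[str, str] | tuple[str, str, str]],
    cyclic_proteins: set[str],
) -> SignalWeb:
    """Attach cyclic proteins with >=1 PPI partner already in the web.

    Single pass against the membership snapshot taken on entry: newly added
    proteins do not recruit further proteins, and existing content is never
    removed.
    """
    out = web.copy()
    members = {
        i for i, k in web.nodes.items() if k in ("protein", "kinase", "tf")
    }
    to_add: dict[str, list[tuple[str, str, str]]] = {}
    for edge in ppi:
        a, b, *rest = edge
        src = rest[0] if rest else ""
        for prot, partner in ((a, b), (b, a)):
            if prot in cyclic_proteins and prot not in members and partner in members:
                to_add.setdefault(prot, []).append((prot, partner, src))
    for prot in sorted(to_add):
        out.add_node(prot, "protein")
        for a, b, src in to_add[prot]:
            out.add_edge(a, b, "ppi", src or "ppi")
    return out


def attach_tf_layer(
    web: SignalWeb,
    tf_targets: Iterable[tuple[str, str] | tuple[str, str, str]],
    tf_sites: Mapping[str, Iterable[str]],  # TF protein -> its site ids
    predictions,
    cyclic_mrnas: set[str],
    kinase_set: set[str],
) -> SignalWeb:
    """Add TFs that target a cyclic mRNA AND carry >=1 ssKSR from the kinase set,
    with both the qualifying sskr edges and the tf_target edges."""
    out = web.copy()
    pairs = {
        (p.kinase_id, p.site_id) if hasattr(p, "kinase_id") else tuple(p)
        for p in predictions
    }
    targets: dict[str, list[tuple[str, str]]] = {}
    for edge in tf_targets:
        tf, gene, *rest = edge
        src = rest[0] if rest else ""
        if gene in cyclic_mrnas:
            targets.setdefault(tf, []).append((gene, src))
    for tf in sorted(targets):
        site_ids = set(tf_sites.get(tf, ()))
        ksr = sorted(
            (k, s) for (k, s) in pairs if k in kinase_set and s in site_ids
        )
        if not ksr:
            continue
        # a TF that already sits in the web as a substrate protein keeps its
        # original node kind; the tf_target edges mark its regulator role
        out.nodes.setdefault(tf, "tf")
        for kinase_id, site_id in ksr:
            out.add_node(kinase_id, "kinase")
            out.add_node(site_id, "substrate_site")
            out.add_edge(kinase_id, site_id, "sskr", "predicted")
        for gene, src in sorted(set(targets[tf])):
            out.add_node(gene, "mrna")
            out.add_edge(tf, gene, "tf_target", src or "tf_target")
    return out


def hub_rank(web: SignalWeb) -> list[tuple[str, int]]:
    """Nodes by total degree, descending; ties broken lexicographically by id."""
    if not web.nodes:
        raise ValueError("empty web")
    degs: dict[str, int] = {i: 0 for i in web.nodes}
    for a, b, _k in web.edges:
        degs[a] += 1
        degs[b] += 1
    return sorted(degs.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class CoverageStats:
    ncp_coverage: float  # NCPs with >=1 kinase-set prediction
    protein_direct: float  # cyclic proteins containing such an NCP
    protein_indirect: float  # covered only via a PPI edge to a covering protein
    protein_union: float
    n_ncps: int
    n_cyclic_proteins: int


def coverage_stats(
    web: SignalWeb,
    ncps: set[str],
    cyclic_proteins: set[str],
    predictions,
    kinase_set: set[str],
) -> CoverageStats:
    """Fractions of NCPs and of cyclic proteins explained by the kinase set.

    Direct: the protein contains a kinase-set-predicted NCP.  Indirect: it has
    a ppi edge in the web to a protein that does.  The union is reported
    separately because the two classes overlap-free by construction.
    """
    pairs = {
        (p.kinase_id, p.site_id) if hasattr(p, "kinase_id") else tuple(p)
        for p in predictions
    }
    covered_sites = {s for (k, s) in pairs if k in kinase_set and s in ncps}
    covering_proteins = {site_protein(s) for s in covered_sites}
    direct = {p for p in cyclic_proteins if p in covering_proteins}
    indirect = set()
    for a, b, kind in web.edges:
        if kind != "ppi":
            continue
        for prot, partner in ((a, b), (b, a)):
            if prot in cyclic_proteins and prot not in direct and partner in covering_proteins:
                indirect.add(prot)
    n_ncp = len(ncps)
    n_cyc = len(cyclic_proteins)
    return CoverageStats(
        ncp_coverage=len(covered_sites) / n_ncp if n_ncp else 0.0,
        protein_direct=len(direct) / n_cyc if n_cyc else 0.0,
        protein_indirect=len(indirect) / n_cyc if n_cyc else 0.0,
        protein_union=len(direct | indirect) / n_cyc if n_cyc else 0.0,
        n_ncps=n_ncp,
        n_cyclic_proteins=n_cyc,
    )
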