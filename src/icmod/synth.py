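"""Synthetic circadian multi-omics generator with known ground truth.

Emulates the study design the pipeline expects: two genotypes (WT and the
clock-null ``per0``), heads pooled at CT0-21 in 3-h steps on 2 days of
constant darkness (16 samples per genotype), with transcript (FPKM), protein
and phosphosite intensity matrices, a protein FASTA carrying planted kinase
consensus motifs in the site flanks, a TMT-style batch effect with a bridge
sample, and a truth record of everything planted.

Planted rhythms are cosines, ``mesor * (1 + A * cos(2*pi*(t - phase)/24))``,
under multiplicative log-normal noise.  Noise for a protein and for the
phosphopeptides measured from the same sample shares a per-(protein, sample)
component (``noise_share`` of the log-variance): the two quantifications come
from one physical sample, so loading and biological variation are common to
both and cancel in the phospho/protein ratio.  With the default share of 0.5
the ratio series carries the nominal ``noise_cv``.

Two site classes make the occupancy normalization testable: "protein-driven"
sites (constant stoichiometry on a rhythmic protein — the raw phospho signal
cycles but the ratio must not) and true NCP sites (rhythmic ratio, flat or
rhythmic protein).  NCP sites are planted preferentially on substrates of the
designated circadian kinases, so that kinase enrichment is recoverable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ProteinRecord,
    SampleMeta,
    SiteRecord,
    TimeSeriesMatrix,
    flank_of,
    write_fasta,
    write_matrix,
    write_sample_meta,
    write_sites,
)
from .kinase import KinaseModel, write_kinase_models

AA = "ACDEFGHIKLMNPQRSTVWY"
CTS = [0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0]
DAYS = [1, 2]
BRIDGE_SUFFIX = "_b4"


@dataclass(frozen=True)
class KinaseSpec:
    kinase_id: str
    kinase_class: str  # STK / TK
    group: str
    family: str
    motif: dict[int, str]  # flank offset (-7..7, not 0) -> allowed residues
    circadian: bool

    def __post_init__(self):
        for off in self.motif:
            if not -7 <= off <= 7 or off == 0:
                raise ValueError(f"motif offset {off} outside the 15-mer flank")


def default_kinases() -> list[KinaseSpec]:
    """Six generic consensus classes; three designated circadian."""
    return [
        KinaseSpec("KIN_BASO_A", "STK", "AGC", "PKA-like", {-3: "R"}, True),
        KinaseSpec("KIN_PRO_B", "STK", "CMGC", "MAPK-like", {1: "P"}, True),
        KinaseSpec(
            "KIN_ACID_C", "STK", "CK2", "CK2-like", {1: "DE", 2: "E", 3: "D"}, True
        ),
        KinaseSpec("KIN_BASO_D", "STK", "CAMK", "CAMK-like", {-2: "K"}, False),
        KinaseSpec("KIN_HYD_E", "STK", "STE", "STE20-like", {2: "L", -5: "F"}, False),
        KinaseSpec("KIN_TYR_F", "TK", "TK", "SRC-like", {-1: "E", 1: "E"}, False),
    ]


@dataclass
class SynthConfig:
    seed: int = 42
    n_genes: int = 320
    n_low_expression: int = 20  # genes kept below FPKM 1 (proteins carry no sites)
    n_sites: int = 600
    frac_rhythmic_mrna: float = 0.15
    frac_rhythmic_protein: float = 0.15
    p_ncp_circadian: float = 0.45  # P(rhythmic ratio | substrate of circadian kinase)
    p_ncp_other: float = 0.04
    amplitude_rel: float = 0.3
    noise_cv: float = 0.1
    noise_share: float = 0.5  # protein<->site shared log-variance fraction
    per0_damping: float = 0.9
    tmt_compression: float = 1.0  # optional amplitude shrink (1 = off)
    night_bias: float = 0.0  # fraction of NCP phases forced into CT12-24
    frac_tyr_sites: float = 0.05
    frac_missing_features: float = 0.04  # features given missing cells (never rhythmic)
    batch_factor: float = 0.5  # multiplicative effect on batch b4 intensities
    n_ppi: int = 400  # random protein-protein interaction edges
    n_tfs: int = 8  # site-bearing proteins designated transcription factors
    n_targets_per_tf: int = 12
    n_train_peptides: int = 50
    protein_len: tuple[int, int] = (160, 360)
    kinases: list[KinaseSpec] = field(default_factory=default_kinases)

    def __post_init__(self):
        for name in (
            "frac_rhythmic_mrna",
            "frac_rhythmic_protein",
            "p_ncp_circadian",
            "p_ncp_other",
            "per0_damping",
            "noise_share",
            "frac_tyr_sites",
            "frac_missing_features",
            "night_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        n_bearing = self.n_genes - self.n_low_expression
        if n_bearing <= 0 or self.n_sites > 7 * n_bearing:
            raise ValueError("n_sites not assignable to the site-bearing proteins")
        if not any(k.kinase_class == "STK" for k in self.kinases):
            raise ValueError("need at least one STK")


@dataclass
class GroundTruth:
    rhythmic_mrna: dict[str, dict]  # gene -> {phase, amplitude_rel}
    rhythmic_protein: dict[str, dict]
    ncp_sites: dict[str, dict]  # site_id -> {phase, amplitude_rel}
    protein_driven_sites: list[str]  # constant stoichiometry on rhythmic proteins
    per0_retained: dict[str, list[str]]  # level -> ids keeping rhythm in per0
    site_kinase: dict[str, str]
    circadian_kinases: list[str]
    low_expression_genes: list[str]
    missing_features: dict[str, list[str]]  # level -> ids given missing cells
    batch_factor: float
    bridge_ref_sample: str
    bridge_tgt_sample: str
    target_batch: str

    def to_json_obj(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_obj(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Bundle:
    config: SynthConfig
    samples: list[SampleMeta]
    fpkm: TimeSeriesMatrix
    protein: TimeSeriesMatrix
    phospho: TimeSeriesMatrix
    proteome: list[ProteinRecord]
    gene_map: dict[str, list[str]]
    sites: list[SiteRecord]
    models: list[KinaseModel]
    ppi: list[tuple[str, str, str]]
    tf_targets: list[tuple[str, str, str]]
    tf_sites: list[tuple[str, str]]  # (tf protein, site_id)
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "samples": out / "samples.tsv",
            "fpkm": out / "fpkm.tsv",
            "protein": out / "protein.tsv",
            "phospho": out / "phospho.tsv",
            "proteome": out / "proteome.fasta",
            "gene_map": out / "gene_map.tsv",
            "sites": out / "sites.tsv",
            "kinases": out / "kinases.json",
            "ppi": out / "ppi.tsv",
            "tf_targets": out / "tf_targets.tsv",
            "tf_sites": out / "tf_sites.tsv",
            "truth": out / "truth.json",
        }
        write_sample_meta(self.samples, paths["samples"])
        write_matrix(self.fpkm, paths["fpkm"])
        write_matrix(self.protein, paths["protein"])
        write_matrix(self.phospho, paths["phospho"])
        write_fasta(self.proteome, paths["proteome"])
        rows = [
            {"gene_id": g, "protein_id": p}
            for g, ps in sorted(self.gene_map.items())
            for p in ps
        ]
        pd.DataFrame(rows).to_csv(paths["gene_map"], sep="\t", index=False)
        write_sites(self.sites, paths["sites"])
        write_kinase_models(self.models, paths["kinases"])
        pd.DataFrame(self.ppi, columns=["protein_a", "protein_b", "source"]).to_csv(
            paths["ppi"], sep="\t", index=False
        )
        pd.DataFrame(self.tf_targets, columns=["tf", "gene", "source"]).to_csv(
            paths["tf_targets"], sep="\t", index=False
        )
        pd.DataFrame(self.tf_sites, columns=["tf", "site_id"]).to_csv(
            paths["tf_sites"], sep="\t", index=False
        )
        self.truth.write_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_grid() -> list[tuple[str, float, int]]:
    return [
        (f"{geno}_d{day}_{int(ct):02d}", ct, day)
        for geno in ("WT", "per0")
        for day in DAYS
        for ct in CTS
    ]


def _cosine(t: np.ndarray, amp: float, phase: float) -> np.ndarray:
    return 1.0 + amp * np.cos(2.0 * np.pi * (t - phase) / 24.0)


def generate_multiomics(config: SynthConfig | None = None) -> Bundle:
    """Generate the full dataset bundle plus its ground truth (deterministic
    under the config seed)."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    t = np.array([(d - 1) * 24.0 + ct for d in DAYS for ct in CTS])
    nt = t.size

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    low_genes = genes[-cfg.n_low_expression :] if cfg.n_low_expression else []
    expressed = genes[: cfg.n_genes - cfg.n_low_expression]
    proteins = {g: f"P{g[1:]}" for g in genes}
    gene_map = {g: [p] for g, p in proteins.items()}

    stks = [k for k in cfg.kinases if k.kinase_class == "STK"]
    tks = [k for k in cfg.kinases if k.kinase_class == "TK"]

    # --- site layout: blocks of 20 residues, <=1 site per block -----------
    bearing = expressed
    n_each = np.full(len(bearing), cfg.n_sites // len(bearing))
    n_each[: cfg.n_sites - int(n_each.sum())] += 1
    lengths = rng.integers(cfg.protein_len[0], cfg.protein_len[1] + 1, len(genes))

    site_meta: list[dict] = []  # protein_id, position, residue, kinase
    sequences: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(genes):
        sequences[proteins[gene]] = rng.choice(list(AA), size=lengths[gi])
    # sites are assigned in a second pass so the number of RNG draws per
    # sequence does not depend on the site layout
    for bi, gene in enumerate(bearing):
        pid = proteins[gene]
        seq = sequences[pid]
        n_here = int(n_each[bi])
        if n_here == 0:
            continue
        n_blocks = (len(seq) - 20) // 20
        blocks = rng.choice(n_blocks, size=min(n_here, n_blocks), replace=False)
        for b in np.sort(blocks):
            pos = int(b) * 20 + 10 + int(rng.integers(0, 5))  # 1-based, >=10
            is_tyr = tks and rng.random() < cfg.frac_tyr_sites
            if is_tyr:
                kin = tks[int(rng.integers(len(tks)))]
                residue = "Y"
            else:
                kin = stks[int(rng.integers(len(stks)))]
                residue = "S" if rng.random() < 0.83 else "T"
            seq[pos - 1] = residue
            for off, allowed in sorted(kin.motif.items()):
                seq[pos - 1 + off] = allowed[int(rng.integers(len(allowed)))]
            site_meta.append(
                {"protein_id": pid, "position": pos, "residue": residue, "kinase": kin}
            )

    proteome = [
        ProteinRecord(proteins[g], "".join(sequences[proteins[g]]), g) for g in genes
    ]
    sites = [
        SiteRecord(
            protein_id=s["protein_id"],
            residue=s["residue"],
            position=s["position"],
            loc_prob=round(float(rng.uniform(0.75, 1.0)), 3),
            flank=flank_of("".join(sequences[s["protein_id"]]), s["position"]),
        )
        for s in site_meta
    ]

    # --- rhythm assignments ----------------------------------------------
    circadian = [k.kinase_id for k in cfg.kinases if k.circadian]
    site_kinase = {s.site_id: m["kinase"].kinase_id for s, m in zip(sites, site_meta)}

    mrna_rhythmic = {
        g: {"phase": float(rng.uniform(0, 24)), "amplitude_rel": cfg.amplitude_rel}
        for g in expressed
        if rng.random() < cfg.frac_rhythmic_mrna
    }
    prot_rhythmic = {
        proteins[g]: {"phase": float(rng.uniform(0, 24)), "amplitude_rel": cfg.amplitude_rel}
        for g in expressed
        if rng.random() < cfg.frac_rhythmic_protein
    }
    ncp_sites: dict[str, dict] = {}
    for s in sites:
        p_ncp = (
            cfg.p_ncp_circadian
            if site_kinase[s.site_id] in circadian
            else cfg.p_ncp_other
        )
        if rng.random() < p_ncp:
            if cfg.night_bias and rng.random() < cfg.night_bias:
                phase = float(rng.uniform(12, 24))
            else:
                phase = float(rng.uniform(0, 24))
            ncp_sites[s.site_id] = {
                "phase": phase,
                "amplitude_rel": cfg.amplitude_rel * cfg.tmt_compression,
            }
    protein_driven = [
        s.site_id
        for s in sites
        if s.site_id not in ncp_sites and s.protein_id in prot_rhythmic
    ]

    # per0 keeps 1 - per0_damping of each rhythmic set
    per0_retained = {
        "mrna": sorted(g for g in mrna_rhythmic if rng.random() > cfg.per0_damping),
        "protein": sorted(p for p in prot_rhythmic if rng.random() > cfg.per0_damping),
        "phospho": sorted(s for s in ncp_sites if rng.random() > cfg.per0_damping),
    }

    # --- matrices ----------------------------------------------------------
    grid = _sample_grid()
    sigma2 = np.log1p(cfg.noise_cv**2)
    sig_sh = np.sqrt(cfg.noise_share * sigma2)
    sig_te = np.sqrt((1.0 - cfg.noise_share) * sigma2)

    def series(mesor, rhythm: dict | None, damped: bool, geno: str):
        if rhythm is None or (geno == "per0" and damped):
            return np.full(nt, float(mesor))
        return mesor * _cosine(t, rhythm["amplitude_rel"], rhythm["phase"])

    mrna_mesor = {g: float(np.maximum(np.exp(rng.normal(np.log(30.0), 1.0)), 2.0)) for g in expressed}
    mrna_mesor.update({g: float(rng.uniform(0.05, 0.5)) for g in low_genes})
    prot_mesor = {proteins[g]: float(np.exp(rng.normal(np.log(100.0), 0.8))) for g in genes}
    ratio0 = {s.site_id: float(rng.uniform(0.1, 0.6)) for s in sites}

    fpkm_cols: dict[str, np.ndarray] = {}
    prot_cols: dict[str, np.ndarray] = {}
    phos_cols: dict[str, np.ndarray] = {}
    pid_list = [proteins[g] for g in genes]
    sid_list = [s.site_id for s in sites]
    site_parent_idx = np.array([pid_list.index(s.protein_id) for s in sites])

    for geno in ("WT", "per0"):
        # truth trajectories
        mrna_true = np.stack(
            [
                series(
                    mrna_mesor[g],
                    mrna_rhythmic.get(g),
                    g not in set(per0_retained["mrna"]),
                    geno,
                )
                for g in genes
            ]
        )
        prot_true = np.stack(
            [
                series(
                    prot_mesor[pid],
                    prot_rhythmic.get(pid),
                    pid not in set(per0_retained["protein"]),
                    geno,
                )
                for pid in pid_list
            ]
        )
        ratio_true = np.stack(
            [
                ratio0[sid]
                * series(
                    1.0,
                    ncp_sites.get(sid),
                    sid not in set(per0_retained["phospho"]),
                    geno,
                )
                for sid in sid_list
            ]
        )
        phos_true = prot_true[site_parent_idx] * ratio_true

        mrna_noise = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), mrna_true.shape)
        shared = rng.normal(0.0, sig_sh, prot_true.shape)
        prot_obs = prot_true * np.exp(
            shared + rng.normal(0.0, sig_te, prot_true.shape) - sigma2 / 2.0
        )
        phos_obs = phos_true * np.exp(
            shared[site_parent_idx]
            + rng.normal(0.0, sig_te, phos_true.shape)
            - sigma2 / 2.0
        )
        mrna_obs = mrna_true * mrna_noise

        for j, (sid_, ct, day) in enumerate(
            [(s, c, d) for (s, c, d) in grid if s.startswith(geno + "_")]
        ):
            fpkm_cols[sid_] = mrna_obs[:, j]
            prot_cols[sid_] = prot_obs[:, j]
            phos_cols[sid_] = phos_obs[:, j]

    # --- batch effect + bridge duplicate ----------------------------------
    b4_samples = ["WT_d1_00", "WT_d1_06", "WT_d1_12", "WT_d1_18", "per0_d1_06", "per0_d1_18"]
    bridge_ref = "WT_d1_03"
    bridge_tgt = bridge_ref + BRIDGE_SUFFIX
    samples = [
        SampleMeta(sid_, sid_.split("_")[0], ct, day, "b4" if sid_ in b4_samples else "b1")
        for sid_, ct, day in grid
    ]
    samples.append(SampleMeta(bridge_tgt, "bridge", 3.0, 1, "b4"))

    for cols in (prot_cols, phos_cols):
        cols[bridge_tgt] = cols[bridge_ref].copy()  # same measurement, re-run in b4
        for sid_ in b4_samples + [bridge_tgt]:
            cols[sid_] = cols[sid_] * cfg.batch_factor

    order = [sid_ for sid_, _, _ in grid]
    fpkm = TimeSeriesMatrix(
        pd.DataFrame(fpkm_cols, index=genes)[order], samples, "mrna"
    )
    protein = TimeSeriesMatrix(
        pd.DataFrame(prot_cols, index=pid_list)[order + [bridge_tgt]], samples, "protein"
    )
    phospho = TimeSeriesMatrix(
        pd.DataFrame(phos_cols, index=sid_list)[order + [bridge_tgt]], samples, "phospho"
    )

    # --- planted missingness (never on rhythmic features) ------------------
    missing: dict[str, list[str]] = {"protein": [], "phospho": []}
    # a protein with a missing cell loses all its sites to the completeness
    # filter, so parents of NCP sites are never given missing values either
    ncp_parents = {sid.rsplit(":", 1)[0] for sid in ncp_sites}
    flat_proteins = [
        p for p in pid_list if p not in prot_rhythmic and p not in ncp_parents
    ]
    flat_sites = [s for s in sid_list if s not in ncp_sites and s not in set(protein_driven)]
    wt_cols = [s.sample_id for s in samples if s.genotype == "WT"]
    for level, mat, pool in (
        ("protein", protein, flat_proteins),
        ("phospho", phospho, flat_sites),
    ):
        n_miss = int(round(cfg.frac_missing_features * len(pool)))
        if n_miss == 0:
            continue
        chosen = [pool[i] for i in rng.choice(len(pool), n_miss, replace=False)]
        for f in chosen:
            col = wt_cols[int(rng.integers(len(wt_cols)))]
            mat.values.loc[f, col] = np.nan
        missing[level] = sorted(chosen)

    models = [
        KinaseModel(
            kinase_id=k.kinase_id,
            group=k.group,
            family=k.family,
            kinase_class=k.kinase_class,
            training_peptides=_training_peptides(k, cfg.n_train_peptides, rng),
        )
        for k in cfg.kinases
    ]

    # --- PPI edges: random pairs, plus links from cyclic proteins without
    # their own NCP site to NCP-bearing proteins (exercises indirect coverage)
    ppi_edges: set[tuple[str, str]] = set()
    while len(ppi_edges) < cfg.n_ppi:
        a, b = (pid_list[i] for i in rng.integers(0, len(pid_list), 2))
        if a != b:
            ppi_edges.add((min(a, b), max(a, b)))
    cyclic_without_ncp = [
        p for p in sorted(prot_rhythmic) if p not in ncp_parents
    ]
    ncp_parent_list = sorted(ncp_parents)
    for p in cyclic_without_ncp[: len(cyclic_without_ncp) // 2]:
        q = ncp_parent_list[int(rng.integers(len(ncp_parent_list)))]
        ppi_edges.add((min(p, q), max(p, q)))
    ppi = [(a, b, "synthetic_ppi") for a, b in sorted(ppi_edges)]

    # --- TF layer: site-bearing proteins with targets among all genes,
    # enriched for rhythmic mRNAs so some TFs qualify for the web
    site_proteins = sorted({s.protein_id for s in sites})
    tfs = [site_proteins[i] for i in rng.choice(len(site_proteins), cfg.n_tfs, replace=False)]
    rhythmic_gene_list = sorted(mrna_rhythmic) or expressed[:1]
    tf_targets: list[tuple[str, str, str]] = []
    for tf in tfs:
        n_rhy = max(1, cfg.n_targets_per_tf // 3)
        chosen = {rhythmic_gene_list[int(i)] for i in rng.integers(0, len(rhythmic_gene_list), n_rhy)}
        chosen |= {genes[int(i)] for i in rng.integers(0, len(genes), cfg.n_targets_per_tf - n_rhy)}
        tf_targets += [(tf, g, "synthetic_tfbs") for g in sorted(chosen)]
    tf_sites = [(s.protein_id, s.site_id) for s in sites if s.protein_id in set(tfs)]

    truth = GroundTruth(
        rhythmic_mrna=mrna_rhythmic,
        rhythmic_protein=prot_rhythmic,
        ncp_sites=ncp_sites,
        protein_driven_sites=sorted(protein_driven),
        per0_retained=per0_retained,
        site_kinase=site_kinase,
        circadian_kinases=sorted(circadian),
        low_expression_genes=sorted(low_genes),
        missing_features=missing,
        batch_factor=cfg.batch_factor,
        bridge_ref_sample=bridge_ref,
        bridge_tgt_sample=bridge_tgt,
        target_batch="b4",
    )
    return Bundle(
        config=cfg,
        samples=samples,
        fpkm=fpkm,
        protein=protein,
        phospho=phospho,
        proteome=proteome,
        gene_map=gene_map,
        sites=sites,
        models=models,
        ppi=ppi,
        tf_targets=tf_targets,
        tf_sites=tf_sites,
        truth=truth,
    )


def pipeline_config(paths: dict[str, Path], out_dir: str | Path, seed: int = 42) -> dict:
    """Pipeline config dict pointing at a written bundle's files."""
    return {
        "inputs": {k: str(p) for k, p in paths.items() if k != "truth"},
        "bridge": {
            "ref_sample": "WT_d1_03",
            "target_sample": "WT_d1_03" + BRIDGE_SUFFIX,
            "target_batch": "b4",
        },
        "out": str(out_dir),
        "seed": seed,
    }


def _training_peptides(spec: KinaseSpec, n: int, rng: np.random.Generator) -> list[str]:
    centers = "ST" if spec.kinase_class == "STK" else "Y"
    peps = []
    for _ in range(n):
        p = list(rng.choice(list(AA), size=15))
        p[7] = centers[int(rng.integers(len(centers)))]
        for off, allowed in sorted(spec.motif.items()):
            p[7 + off] = allowed[int(rng.integers(len(allowed)))]
        peps.append("".join(p))
    return peps


def generate_activity(
    seed: int,
    rhythmic: bool = True,
    days: int = 7,
    bin_minutes: float = 30.0,
    period: float = 24.0,
    pulse_height: float = 50.0,
    baseline_rate: float = 1.0,
) -> np.ndarray:
    """Binned locomotor counts: Poisson baseline plus (optionally) a periodic
    activity pulse, mirroring beam-crossing monitor exports."""
    rng = np.random.default_rng(seed)
    n = int(round(days * 24 * 60 / bin_minutes))
    x = rng.poisson(baseline_rate, n).astype(float)
    if rhythmic:
        step = period * 60.0 / bin_minutes
        idx = np.round(np.arange(0, n, step)).astype(int)
        x[idx[idx < n]] += pulse_height
    return x


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    sensitivity: dict[str, float]  # per level
    fdr: dict[str, float]
    kinase_true_positive: list[str]
    kinase_false_positive: list[str]
    kinase_false_negative: list[str]
    phase_mae: dict[str, float]  # hours, over true positives with truth phases
    amplitude_rel_mae: dict[str, float]


def _circular_err(a: float, b: float) -> float:
    d = abs(a - b) % 24.0
    return min(d, 24.0 - d)


def truth_compare(
    detected: dict[str, set[str]],
    truth: GroundTruth,
    classified_kinases: set[str] | None = None,
    fits: dict[str, pd.DataFrame] | None = None,
    universe: dict[str, set[str]] | None = None,
) -> RecoveryReport:
    """Recovery of planted rhythms and kinases.

    ``detected`` maps level ('mrna'/'protein'/'phospho') to called feature
    sets; ``universe`` optionally restricts the truth to features that were
    actually analyzed (e.g. after completeness filtering).
    """
    truth_sets = {
        "mrna": set(truth.rhythmic_mrna),
        "protein": set(truth.rhythmic_protein),
        "phospho": set(truth.ncp_sites),
    }
    truth_params = {
        "mrna": truth.rhythmic_mrna,
        "protein": truth.rhythmic_protein,
        "phospho": truth.ncp_sites,
    }
    sens: dict[str, float] = {}
    fdr: dict[str, float] = {}
    phase_mae: dict[str, float] = {}
    amp_mae: dict[str, float] = {}
    for level, called in detected.items():
        tset = truth_sets[level]
        if universe and level in universe:
            tset = tset & universe[level]
            called = called & universe[level]
        sens[level] = len(called & tset) / len(tset) if tset else float("nan")
        fdr[level] = len(called - tset) / len(called) if called else 0.0
        if fits and level in fits:
            df = fits[level].set_index("feature_id")
            tp = sorted(called & tset & set(df.index))
            if tp:
                phase_mae[level] = float(
                    np.mean(
                        [_circular_err(df.loc[f, "phase"], truth_params[level][f]["phase"]) for f in tp]
                    )
                )
                amp_mae[level] = float(
                    np.mean(
                        [
                            abs(
                                df.loc[f, "amplitude"] / df.loc[f, "mesor"]
                                - truth_params[level][f]["amplitude_rel"]
                            )
                            for f in tp
                        ]
                    )
                )
    ck = set(truth.circadian_kinases)
    called_k = set(classified_kinases or set())
    return RecoveryReport(
        sensitivity=sens,
        fdr=fdr,
        kinase_true_positive=sorted(called_k & ck),
        kinase_false_positive=sorted(called_k - ck),
        kinase_false_negative=sorted(ck - called_k),
        phase_mae=phase_mae,
        amplitude_rel_mae=amp_mae,
    )
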