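"""Group-based site-specific kinase-substrate relation (ssKSR) prediction.

Each kinase model holds a set of known 15-mer substrate peptides.  A candidate
phosphosite flank is scored as the mean positional BLOSUM62 similarity to the
training peptides (negative substitution entries floored at 0, terminus
padding '*' scores 0), and passes when the score reaches the model's
threshold.  Thresholds are not universal constants: each one is calibrated on
background flanks drawn from the reference proteome so that a stated fraction
of background sites would pass — a false-positive-rate parameterization
(defaults: 10% for serine/threonine kinases, 15% for tyrosine kinases).

This follows the published group-based scoring scheme as an approximation; it
is not a bit-exact clone of any particular predictor release.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .io import FLANK_WIDTH, PAD, SiteRecord

log = logging.getLogger("icmod")

PEPTIDE_LEN = 2 * FLANK_WIDTH + 1
DEFAULT_FPR = {"STK": 0.10, "TK": 0.15}
CENTER_RESIDUES = {"STK": set("ST"), "TK": set("Y")}


def _similarity_table() -> np.ndarray:
    """128x128 lookup of max(BLOSUM62, 0) over ASCII codes; '*' rows/cols are 0."""
    blosum = substitution_matrices.load("BLOSUM62")
    table = np.zeros((128, 128))
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            if a == "*" or b == "*":
                continue
            table[ord(a), ord(b)] = max(float(blosum[a, b]), 0.0)
    return table


_SIM = _similarity_table()


def _encode(peptides: Iterable[str]) -> np.ndarray:
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    return arr.reshape(-1, PEPTIDE_LEN)


def peptide_similarity(a: str, b: str) -> float:
    """Positional substitution-score sum of two 15-mers (floored at 0, '*' -> 0)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return float(_SIM[_encode([a])[0], _encode([b])[0]].sum())


@dataclass
class KinaseModel:
    kinase_id: str
    group: str
    family: str
    kinase_class: str  # "STK" or "TK"
    training_peptides: list[str]
    threshold: float | None = None
    fpr: float | None = None

    def __post_init__(self):
        if self.kinase_class not in CENTER_RESIDUES:
            raise ValueError(f"kinase_class {self.kinase_class!r} not in STK/TK")
        # de-duplicate, preserving order, so repeated peptides do not bias the mean
        seen: set[str] = set()
        peps = []
        for p in self.training_peptides:
            if len(p) != PEPTIDE_LEN:
                raise ValueError(f"training peptide {p!r} not length {PEPTIDE_LEN}")
            if p[FLANK_WIDTH] not in CENTER_RESIDUES[self.kinase_class]:
                raise ValueError(
                    f"{self.kinase_id}: center {p[FLANK_WIDTH]!r} incompatible with "
                    f"{self.kinase_class}"
                )
            if p not in seen:
                seen.add(p)
                peps.append(p)
        if not peps:
            raise ValueError(f"{self.kinase_id}: empty training set")
        self.training_peptides = peps

    def compatible(self, flank: str) -> bool:
        return flank[FLANK_WIDTH] in CENTER_RESIDUES[self.kinase_class]


def score_site(model: KinaseModel, flank: str) -> float:
    """Mean similarity of ``flank`` to the model's training peptides.

    Raises for a flank whose center residue is incompatible with the kinase
    class (no prediction is defined there).
    """
    if len(flank) != PEPTIDE_LEN:
        raise ValueError(f"flank {flank!r} not length {PEPTIDE_LEN}")
    if not model.compatible(flank):
        raise ValueError(
            f"{model.kinase_id} ({model.kinase_class}) cannot score center "
            f"{flank[FLANK_WIDTH]!r}"
        )
    return float(score_flanks(model, [flank])[0])


def score_flanks(model: KinaseModel, flanks: Sequence[str]) -> np.ndarray:
    """Vectorized ``score_site`` over many flanks (all must be compatible)."""
    Q = _encode(flanks)
    T = _encode(model.training_peptides)
    total = np.zeros(Q.shape[0])
    for i in range(PEPTIDE_LEN):
        total += _SIM[Q[:, i][:, None], T[:, i][None, :]].sum(axis=1)
    return total / T.shape[0]


def threshold_from_scores(scores: Sequence[float], fpr: float) -> float:
    """Smallest observed score s with P(background >= s) <= fpr (conservative)."""
    arr = np.sort(np.asarray(scores, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("empty background")
    for s in np.unique(arr):
        if np.count_nonzero(arr >= s) / n <= fpr:
            return float(s)
    # even the maximum passes too often (massive ties): step above it
    return float(arr[-1]) + 1.0


def calibrate_threshold(
    model: KinaseModel, background: Sequence[str], fpr: float | None = None
) -> float:
    """Calibrate and store the model's score threshold at a false-positive rate.

    ``background`` are 15-mer flanks of the matching residue class sampled
    from the reference proteome; at least 100 are required.
    """
    if fpr is None:
        fpr = DEFAULT_FPR[model.kinase_class]
    bg = [f for f in background if model.compatible(f)]
    if len(bg) < 100:
        raise ValueError(
            f"{model.kinase_id}: background of {len(bg)} compatible flanks < 100"
        )
    scores = score_flanks(model, bg)
    model.threshold = threshold_from_scores(scores, fpr)
    model.fpr = fpr
    return model.threshold


def sample_background(
    reference_sequences: Iterable[str],
    residues: str,
    n: int = 10_000,
    seed: int = 0,
) -> list[str]:
    """Flanks centered on ``residues`` sampled uniformly without replacement
    from the reference proteome (all occurrences enumerated first)."""
    from .io import flank_of

    pool: list[str] = []
    for seq in reference_sequences:
        for i, aa in enumerate(seq):
            if aa in residues:
                pool.append(flank_of(seq, i + 1))
    if not pool:
        raise ValueError(f"no {residues}-centered flanks in reference")
    rng = np.random.default_rng(seed)
    if len(pool) <= n:
        return pool
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


@dataclass(frozen=True)
class SsKsrPrediction:
    kinase_id: str
    site_id: str
    score: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.score >= self.threshold


def predict_sskr(
    models: Sequence[KinaseModel], sites: Sequence[SiteRecord]
) -> list[SsKsrPrediction]:
    """One prediction per (kinase, site) whose score reaches the threshold."""
    out: list[SsKsrPrediction] = []
    for model in models:
        if model.threshold is None:
            raise ValueError(f"{model.kinase_id}: threshold not calibrated")
        compat = [s for s in sites if model.compatible(s.flank)]
        if not compat:
            continue
        scores = score_flanks(model, [s.flank for s in compat])
        for s, sc in zip(compat, scores):
            if sc >= model.threshold:
                out.append(SsKsrPrediction(model.kinase_id, s.site_id, float(sc), model.threshold))
    return out


@dataclass
class CoverageReport:
    group_share: dict[str, float]  # percent of predictions per kinase group
    family_share: dict[str, float]
    kinases_per_site: dict[str, int]
    frac_sites_ge1: float
    frac_sites_ge2: float


def coverage_by_level(
    predictions: Sequence[SsKsrPrediction],
    models: Sequence[KinaseModel],
    site_ids: Iterable[str] | None = None,
) -> CoverageReport:
    """Prediction shares per kinase group/family and per-site kinase counts.

    ``site_ids`` fixes the denominator for the >=k fractions (defaults to the
    sites appearing in the predictions).
    """
    meta = {m.kinase_id: m for m in models}
    n = len(predictions)
    group: dict[str, int] = {}
    family: dict[str, int] = {}
    per_site: dict[str, set[str]] = {}
    for p in predictions:
        m = meta[p.kinase_id]
        group[m.group] = group.get(m.group, 0) + 1
        family[m.family] = family.get(m.family, 0) + 1
        per_site.setdefault(p.site_id, set()).add(p.kinase_id)
    universe = set(site_ids) if site_ids is not None else set(per_site)
    counts = {s: len(per_site.get(s, ())) for s in universe}
    total = len(universe) or 1
    return CoverageReport(
        group_share={g: 100.0 * c / n for g, c in group.items()} if n else {},
        family_share={f: 100.0 * c / n for f, c in family.items()} if n else {},
        kinases_per_site=counts,
        frac_sites_ge1=sum(c >= 1 for c in counts.values()) / total,
        frac_sites_ge2=sum(c >= 2 for c in counts.values()) / total,
    )


# ---------------------------------------------------------------------------
# model file I/O
# ---------------------------------------------------------------------------

def read_kinase_models(path: str | Path) -> list[KinaseModel]:
    """JSON list of {kinase_id, group, family, class, peptides[, threshold, fpr]}."""
    data = json.loads(Path(path).read_text())
    return [
        KinaseModel(
            kinase_id=d["kinase_id"],
            group=d["group"],
            family=d["family"],
            kinase_class=d["class"],
            training_peptides=list(d["peptides"]),
            threshold=d.get("threshold"),
            fpr=d.get("fpr"),
        )
        for d in data
    ]


def write_kinase_models(models: Sequence[KinaseModel], path: str | Path) -> None:
    data = [
        {
            "kinase_id": m.kinase_id,
            "group": m.group,
            "family": m.family,
            "class": m.kinase_class,
            "peptides": m.training_peptides,
            **({"threshold": m.threshold} if m.threshold is not None else {}),
            **({"fpr": m.fpr} if m.fpr is not None else {}),
        }
        for m in models
    ]
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def predictions_frame(predictions: Sequence[SsKsrPrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "kinase_id": p.kinase_id,
                "site_id": p.site_id,
                "score": p.score,
                "threshold": p.threshold,
            }
            for p in predictions
        ],
        columns=["kinase_id", "site_id", "score", "threshold"],
    )
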