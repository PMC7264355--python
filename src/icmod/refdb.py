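"""Expression-informed reference proteome construction and completeness filtering.

The front end of the pipeline: mRNAs below an FPKM floor are not considered
reliably expressed, so their proteins are excluded from the search space;
reversed decoys accompany every retained target; phosphosites are validated
against the retained sequences; and only features quantified in every sample
of a scope survive.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .io import (
    FLANK_WIDTH,
    ProteinRecord,
    SiteRecord,
    TimeSeriesMatrix,
    flank_of,
)

log = logging.getLogger("icmod")

DECOY_PREFIX = "REV_"


def filter_expressed(
    fpkm: TimeSeriesMatrix,
    threshold: float = 1.0,
    scope: Iterable[str] | None = None,
) -> set[str]:
    """Genes with FPKM >= threshold in at least one sample of ``scope``.

    The comparison is inclusive: a gene touching the threshold in a single
    sample is expressed. Missing cells never satisfy the comparison.
    """
    if fpkm.level != "mrna":
        raise ValueError(f"filter_expressed expects an mRNA matrix, got {fpkm.level!r}")
    cols = list(fpkm.values.columns) if scope is None else list(scope)
    if not cols:
        raise ValueError("empty scope")
    unknown = [c for c in cols if c not in fpkm.values.columns]
    if unknown:
        raise KeyError(f"scope samples {unknown} not in matrix")
    sub = fpkm.values[cols]
    hit = (sub >= threshold).any(axis=1)  # NaN >= x is False
    return set(sub.index[hit])


def build_reference(
    genes: set[str],
    proteome: Sequence[ProteinRecord],
    gene_map: dict[str, list[str]],
) -> list[ProteinRecord]:
    """Target records for proteins of retained genes plus one reversed decoy each.

    Decoys carry the ``REV_`` id prefix. Genes with no protein mapping are
    skipped with a warning.
    """
    by_id = {p.protein_id: p for p in proteome}
    targets: list[ProteinRecord] = []
    seen: set[str] = set()
    for gene in sorted(genes):
        pids = gene_map.get(gene)
        if not pids:
            log.warning("gene %s has no protein mapping; skipped", gene)
            continue
        for pid in pids:
            if pid in seen:
                continue
            prot = by_id.get(pid)
            if prot is None:
                log.warning("protein %s of gene %s absent from proteome; skipped", pid, gene)
                continue
            seen.add(pid)
            targets.append(ProteinRecord(pid, prot.sequence, gene))
    decoys = [
        ProteinRecord(DECOY_PREFIX + t.protein_id, t.sequence[::-1], t.gene_id)
        for t in targets
    ]
    log.info("reference: %d targets + %d decoys", len(targets), len(decoys))
    return targets + decoys


def map_sites(
    sites: Sequence[SiteRecord], reference: Sequence[ProteinRecord]
) -> list[SiteRecord]:
    """Retain sites whose protein is in the reference and whose declared residue
    matches the sequence at the 1-based position; flanks are recomputed."""
    seqs = {p.protein_id: p.sequence for p in reference if not p.protein_id.startswith(DECOY_PREFIX)}
    kept: list[SiteRecord] = []
    for s in sites:
        seq = seqs.get(s.protein_id)
        if seq is None:
            log.debug("site %s dropped: protein not in reference", s.site_id)
            continue
        if not 1 <= s.position <= len(seq):
            log.debug("site %s dropped: position outside sequence", s.site_id)
            continue
        if seq[s.position - 1] != s.residue:
            log.debug(
                "site %s dropped: sequence has %s at position %d",
                s.site_id,
                seq[s.position - 1],
                s.position,
            )
            continue
        kept.append(
            SiteRecord(
                protein_id=s.protein_id,
                residue=s.residue,
                position=s.position,
                loc_prob=s.loc_prob,
                flank=flank_of(seq, s.position, FLANK_WIDTH),
            )
        )
    log.info("map_sites: %d/%d sites retained", len(kept), len(sites))
    return kept


def filter_complete(
    matrix: TimeSeriesMatrix, scope: Iterable[str]
) -> TimeSeriesMatrix:
    """Remove features with any missing value in ``scope``; columns unchanged.

    A quantified zero counts as present — only explicit missingness removes.
    """
    cols = list(scope)
    unknown = [c for c in cols if c not in matrix.values.columns]
    if unknown:
        raise KeyError(f"scope samples {unknown} not in matrix")
    ok = matrix.values[cols].notna().all(axis=1)
    out = matrix.values.loc[ok].copy()
    if out.empty:
        log.warning("filter_complete: no feature quantified in all %d samples", len(cols))
    return TimeSeriesMatrix(out, list(matrix.samples), matrix.level)
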