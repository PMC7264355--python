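"""Sample centering, bridge-sample batch correction, and phospho/protein ratios.

Three normalizations, in the order a multi-batch TMT design needs them:

1. ``bridge_batch_correct`` — a bridge sample measured in a reference batch and
   again in a drifted batch gives a per-feature correction ratio for the
   drifted batch; applied to raw intensities.
2. ``compute_ncp_series`` — phosphosite intensity divided by the parent
   protein's intensity, sample by sample.  A site whose phosphorylation simply
   tracks protein abundance becomes a flat ratio series; only occupancy
   changes survive.  Rhythmic ratio series are the NCP candidates.
3. ``global_center`` — per-sample scaling so the mean over features is 1,
   used on the protein matrix for protein-level rhythm analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import TimeSeriesMatrix, site_protein

log = logging.getLogger("icmod")


def global_center(matrix: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """Divide each sample column by its mean over nonmissing features."""
    means = matrix.values.mean(axis=0, skipna=True)
    if means.isna().any():
        bad = list(means.index[means.isna()])
        raise ValueError(f"samples with no nonmissing value: {bad}")
    if (means == 0).any():
        bad = list(means.index[means == 0])
        raise ValueError(f"samples with zero mean intensity: {bad}")
    return TimeSeriesMatrix(matrix.values / means, list(matrix.samples), matrix.level)


def bridge_batch_correct(
    matrix: TimeSeriesMatrix,
    bridge_ref_sample: str,
    bridge_tgt_sample: str,
    target_batch: str,
) -> TimeSeriesMatrix:
    """Rescale every sample of ``target_batch`` by the per-feature ratio
    bridge_ref / bridge_tgt.

    Features whose bridge value is missing or zero in either measurement have
    no defined ratio and are dropped (flagged in the log), not imputed.
    """
    vals = matrix.values
    for s in (bridge_ref_sample, bridge_tgt_sample):
        if s not in vals.columns:
            raise KeyError(f"bridge sample {s!r} not in matrix")
    tgt_cols = [
        c
        for c in vals.columns
        if matrix.sample(c).batch == target_batch
    ]
    if not tgt_cols:
        raise ValueError(f"no samples in batch {target_batch!r}")
    ref = vals[bridge_ref_sample]
    tgt = vals[bridge_tgt_sample]
    ok = ref.notna() & tgt.notna() & (ref != 0) & (tgt != 0)
    dropped = vals.index[~ok]
    if len(dropped):
        log.warning(
            "bridge_batch_correct: %d features lack a bridge ratio; dropped", len(dropped)
        )
    out = vals.loc[ok].copy()
    ratio = (ref / tgt)[ok]
    out[tgt_cols] = out[tgt_cols].mul(ratio, axis=0)
    return TimeSeriesMatrix(out, list(matrix.samples), matrix.level)


def compute_ncp_series(
    phospho_raw: TimeSeriesMatrix,
    protein_raw: TimeSeriesMatrix,
    site_map: dict[str, str] | None = None,
    log_ratio: bool = False,
) -> TimeSeriesMatrix:
    """Phospho/protein ratio series per site over the shared sample set.

    ``site_map`` maps site_id -> protein_id; by default the protein is parsed
    from the canonical ``PROTEIN:S123`` site id.  Sites whose protein is
    absent, incompletely quantified, or zero anywhere are excluded with a
    logged reason.  ``log_ratio`` replaces the plain ratio with log2(ratio)
    (requires strictly positive phospho values); default off — the plain
    ratio is the convention downstream rhythm analysis expects.
    """
    shared = [c for c in phospho_raw.values.columns if c in protein_raw.values.columns]
    if not shared:
        raise ValueError("phospho and protein matrices share no samples")
    ph = phospho_raw.values[shared]
    pr = protein_raw.values[shared]
    rows = {}
    n_absent = n_incomplete = n_zero = 0
    for site_id in ph.index:
        pid = (site_map or {}).get(site_id, site_protein(site_id))
        if pid not in pr.index:
            n_absent += 1
            continue
        prot = pr.loc[pid]
        if prot.isna().any():
            n_incomplete += 1
            continue
        if (prot == 0).any():
            n_zero += 1
            continue
        rows[site_id] = ph.loc[site_id] / prot
    if n_absent or n_incomplete or n_zero:
        log.info(
            "compute_ncp_series: excluded %d sites (protein absent), %d (protein "
            "incomplete), %d (protein zero)",
            n_absent,
            n_incomplete,
            n_zero,
        )
    out = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=shared)
    out = out.reindex(columns=shared)
    out.index.name = phospho_raw.values.index.name
    if log_ratio:
        if (out.to_numpy(dtype=float) <= 0).any():
            raise ValueError("log_ratio requires strictly positive ratios")
        out = np.log2(out)
    return TimeSeriesMatrix(out, list(phospho_raw.samples), "phospho_normalized")
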