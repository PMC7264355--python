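"""Data model and readers/writers for quantification tables, sequences and results.

Abundance matrices are features x samples pandas DataFrames bound to a sample
metadata table (genotype, circadian time, day, batch).  Missing values are
``NaN`` and are always distinct from an observed zero: a TMT channel that was
quantified at (near) zero intensity is evidence, an empty cell is not.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("icmod")

LEVELS = ("mrna", "protein", "phospho", "phospho_normalized")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
FLANK_WIDTH = 7  # residues each side of the phosphosite -> 15-mer windows
PAD = "*"


class FormatError(ValueError):
    """Malformed input file (duplicate ids, empty FASTA, bad cells...)."""


class MetadataError(ValueError):
    """Sample present in a matrix but absent from (or inconsistent with) metadata."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str  # "WT", "per0", or another condition label
    ct: float  # circadian time, hours in [0, 48)
    day: int  # 1 or 2
    batch: str

    def __post_init__(self):
        if not 0 <= self.ct < 48:
            raise MetadataError(f"ct {self.ct} outside [0, 48) for {self.sample_id}")
        if not self.batch:
            raise MetadataError(f"sample {self.sample_id} has no batch")

    @property
    def t(self) -> float:
        """Time on the concatenated 2-day axis (day 1 -> 0..21, day 2 -> 24..45)."""
        return (self.day - 1) * 24.0 + (self.ct % 24.0)


@dataclass
class TimeSeriesMatrix:
    """Nonnegative abundance matrix (features x samples) with sample metadata."""

    values: pd.DataFrame  # index: feature_id, columns: sample_id, NaN = missing
    samples: list[SampleMeta]
    level: str

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicated feature_id {dup!r}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicated sample_id in metadata")
        missing = [c for c in self.values.columns if c not in set(ids)]
        if missing:
            raise MetadataError(f"samples absent from metadata: {missing}")
        if self.level != "phospho_normalized":  # log-ratio series may go negative
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy(dtype=float) < 0).any():
                    raise FormatError("negative abundance value")

    # -- convenience ------------------------------------------------------
    @property
    def meta(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(s) for s in self.samples]).set_index(
            "sample_id"
        )
        return df.loc[list(self.values.columns)]

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise MetadataError(f"unknown sample {sample_id!r}")

    def sample_ids(self, genotype: str | None = None, batch: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if s.sample_id not in self.values.columns:
                continue
            if genotype is not None and s.genotype != genotype:
                continue
            if batch is not None and s.batch != batch:
                continue
            out.append(s.sample_id)
        return out

    def subset(
        self,
        features: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "TimeSeriesMatrix":
        vals = self.values
        if features is not None:
            vals = vals.loc[[f for f in vals.index if f in set(features)]]
        if sample_ids is not None:
            keep = [c for c in vals.columns if c in set(sample_ids)]
            vals = vals[keep]
        return TimeSeriesMatrix(vals.copy(), list(self.samples), self.level)

    def times(self, sample_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.sample(c).t for c in sample_ids])


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.protein_id}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(f"{self.protein_id}: non-amino-acid letters {sorted(bad)}")


@dataclass(frozen=True)
class SiteRecord:
    """One phosphosite: PSP(7,7) 15-mer flank around a 1-based S/T/Y position."""

    protein_id: str
    residue: str
    position: int  # 1-based
    loc_prob: float = 1.0
    flank: str = ""

    def __post_init__(self):
        if self.residue not in "STY":
            raise FormatError(f"residue {self.residue!r} not in S/T/Y")
        if self.position < 1:
            raise FormatError("position is 1-based and must be >= 1")
        if not 0 <= self.loc_prob <= 1:
            raise FormatError("localization probability outside [0,1]")
        if self.flank:
            if len(self.flank) != 2 * FLANK_WIDTH + 1:
                raise FormatError(f"flank {self.flank!r} not length 15")
            if self.flank[FLANK_WIDTH] != self.residue:
                raise FormatError(
                    f"flank center {self.flank[FLANK_WIDTH]!r} != residue {self.residue!r}"
                )

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}:{self.residue}{self.position}"


def site_protein(site_id: str) -> str:
    """Protein part of a canonical ``PROTEIN:S123`` site id."""
    return site_id.rsplit(":", 1)[0]


def flank_of(sequence: str, position: int, width: int = FLANK_WIDTH) -> str:
    """PSP(width,width) window around a 1-based position, '*'-padded at termini."""
    i = position - 1
    if not 0 <= i < len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    left = sequence[max(0, i - width) : i].rjust(width, PAD)
    right = sequence[i + 1 : i + 1 + width].ljust(width, PAD)
    return left + sequence[i] + right


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

META_COLUMNS = ["sample_id", "genotype", "ct", "day", "batch"]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"metadata missing columns {missing}")
    return [
        SampleMeta(
            sample_id=r.sample_id,
            genotype=r.genotype,
            ct=float(r.ct),
            day=int(r.day),
            batch=str(r.batch),
        )
        for r in df.itertuples()
    ]


def read_matrix(path: str | Path, meta_path: str | Path, level: str) -> TimeSeriesMatrix:
    """Read a TSV abundance matrix and join its sample metadata.

    First column is ``feature_id``; remaining columns are sample ids.
    Empty cells, ``NA`` and unparseable cells become missing (NaN), never 0.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicated feature_id {dup!r} in {path}")
    vals = raw.apply(lambda col: pd.to_numeric(col.replace({"": None, "NA": None}), errors="coerce"))
    samples = read_sample_meta(meta_path)
    known = {s.sample_id for s in samples}
    orphans = [c for c in vals.columns if c not in known]
    if orphans:
        raise MetadataError(f"samples {orphans} in {path} absent from metadata")
    return TimeSeriesMatrix(vals, samples, level)


def read_fasta(path: str | Path, gene_map: dict[str, str] | None = None) -> list[ProteinRecord]:
    """Read FASTA; the header token before the first whitespace is the protein id."""
    records = [
        ProteinRecord(
            protein_id=rec.id,
            sequence=str(rec.seq).upper(),
            gene_id=(gene_map or {}).get(rec.id, ""),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.protein_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_gene_map(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns gene_id, protein_id -> gene -> [protein ids]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_id, []).append(r.protein_id)
    return out


SITE_COLUMNS = ["site_id", "protein_id", "residue", "position", "loc_prob", "flank"]


def read_sites(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SiteRecord(
            protein_id=r.protein_id,
            residue=r.residue,
            position=int(r.position),
            loc_prob=float(r.loc_prob),
            flank=r.flank,
        )
        for r in df.itertuples()
    ]


def write_sites(sites: Sequence[SiteRecord], path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "protein_id": s.protein_id,
            "residue": s.residue,
            "position": s.position,
            "loc_prob": s.loc_prob,
            "flank": s.flank,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-like TSV: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(g for g in parts[2:] if g)
    return out


def read_edges(path: str | Path) -> list[tuple[str, str, str]]:
    """Edge-list TSV (a, b, source) used for PPI and TF-target inputs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return [(str(r[cols[0]]), str(r[cols[1]]), str(r[cols[2]]) if len(cols) > 2 else "") for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_matrix(matrix: TimeSeriesMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    if meta_path is not None:
        write_sample_meta(matrix.samples, meta_path)


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in samples])[META_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def write_results(obj, path: str | Path) -> None:
    """Write a result object: DataFrames as TSV, nested structures as JSON."""
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif hasattr(obj, "to_json_obj"):
        path.write_text(json.dumps(obj.to_json_obj(), indent=1, sort_keys=True) + "\n")
    else:
        path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
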