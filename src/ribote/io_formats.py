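"""Readers/writers for the formats the pipeline touches, and the in-memory types.

All internal coordinates are 0-based half-open.  GFF3's 1-based inclusive
convention is converted at the parsing boundary only, so off-by-one drift
cannot propagate into the analysis stages.

The annotation dialect carries the transcription start site (TSS) as a
dedicated ``TSS`` feature with ``Parent=<gene>``; genes without one keep an
empty 5'UTR and are flagged (``tss_known=False``) so UTR analyses can skip
them while count analyses keep them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONDITIONS = ("heterotrophic", "autotrophic")
ASSAYS = ("mRNA", "RPF")

_VALID_NT = set("ACGTUN")


class FormatError(ValueError):
    """A file does not parse under its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Coordinates and annotations of one gene.

    ``cds_interval``, ``utr5_interval`` and ``utr3_interval`` are 0-based
    half-open ``(start, end)`` tuples; an empty interval has start == end.
    """

    gene_id: str
    contig: str
    strand: str
    cds_interval: tuple[int, int]
    tss: int | None = None
    utr5_interval: tuple[int, int] = (0, 0)
    utr3_interval: tuple[int, int] = (0, 0)
    operon_id: str | None = None
    subunit_index: int | None = None
    terms: frozenset[str] = field(default_factory=frozenset)
    tss_known: bool = False

    def __post_init__(self) -> None:
        self.terms = frozenset(self.terms)
        self.validate()

    def validate(self) -> None:
        s, e = self.cds_interval
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not s < e:
            raise ValidationError(f"{self.gene_id}: CDS start must be < end")
        if (self.operon_id is None) != (self.subunit_index is None):
            raise ValidationError(
                f"{self.gene_id}: subunit_index present iff operon_id present")
        if self.subunit_index is not None and self.subunit_index < 1:
            raise ValidationError(f"{self.gene_id}: subunit_index must be >= 1")
        if self.tss is not None:
            if self.strand == "+":
                if self.tss > s:
                    raise ValidationError(
                        f"{self.gene_id}: TSS downstream of CDS start on + strand")
                if self.utr5_interval != (self.tss, s):
                    raise ValidationError(f"{self.gene_id}: utr5 != [tss, cds_start)")
            else:
                if self.tss < e - 1:
                    raise ValidationError(
                        f"{self.gene_id}: TSS upstream of CDS end on - strand")
                if self.utr5_interval != (e, self.tss + 1):
                    raise ValidationError(f"{self.gene_id}: utr5 != [cds_end, tss+1)")
        for name, (a, b) in (("utr5", self.utr5_interval), ("utr3", self.utr3_interval)):
            if a > b:
                raise ValidationError(f"{self.gene_id}: {name} interval inverted")

    @property
    def utr5_length(self) -> int:
        return self.utr5_interval[1] - self.utr5_interval[0]

    @property
    def leaderless(self) -> bool:
        return self.tss_known and self.utr5_length == 0

    @property
    def cds_length(self) -> int:
        return self.cds_interval[1] - self.cds_interval[0]


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    condition: str
    assay: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"{self.sample_id}: condition must be one of {CONDITIONS}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"{self.sample_id}: assay must be one of {ASSAYS}")
        if self.replicate < 1:
            raise ValidationError(f"{self.sample_id}: replicate must be >= 1")

    @property
    def sort_key(self) -> tuple[int, int, int]:
        return (CONDITIONS.index(self.condition), ASSAYS.index(self.assay),
                self.replicate)


@dataclass
class CountMatrix:
    """Genes x samples raw (un-normalized) integer counts."""

    gene_ids: list[str]
    samples: list[SampleInfo]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError(
                    "counts must be raw integers; normalized input is rejected")
            self.counts = self.counts.astype(np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError("count matrix shape does not match labels")
        if (self.counts < 0).any():
            raise ValidationError("negative counts")
        keys = [(s.condition, s.assay, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("(condition, assay, replicate) not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids,
                            columns=self.sample_ids)

    def sample_mask(self, condition: str | None = None,
                    assay: str | None = None) -> np.ndarray:
        mask = np.ones(len(self.samples), dtype=bool)
        if condition is not None:
            mask &= np.array([s.condition == condition for s in self.samples])
        if assay is not None:
            mask &= np.array([s.assay == assay for s in self.samples])
        return mask

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.flatnonzero(mask)
        return CountMatrix(list(self.gene_ids),
                           [self.samples[i] for i in idx],
                           self.counts[:, idx])


@dataclass
class CoverageTrack:
    """Per-base non-negative coverage over one contiguous 0-based interval."""

    contig: str
    strand: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("coverage values must be >= 0")
        if self.strand not in "+-":
            raise ValidationError("strand must be + or -")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside the track are 0."""
        out = np.zeros(end - start)
        lo, hi = max(start, self.start), min(end, self.end)
        if lo < hi:
            out[lo - start:hi - start] = self.values[lo - self.start:hi - self.start]
        return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _parse_gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k] = v
    return out


def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    """Read gene models (with TSS where present) from GFF3 or a BED12-like file."""
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12-like":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect: {dialect!r}")


def _read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    tss: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                                  f"got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start_i < 1 or end_i < start_i:
                raise FormatError(f"{path}:{lineno}: bad coordinate pair")
            a = _parse_gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                # GFF3 1-based inclusive -> 0-based half-open
                rec = {"contig": contig, "strand": strand,
                       "cds": (start_i - 1, end_i)}
                if "operon_id" in a:
                    rec["operon_id"] = a["operon_id"]
                    rec["subunit_index"] = int(a.get("subunit_index", 1))
                if "terms" in a and a["terms"]:
                    rec["terms"] = frozenset(a["terms"].split(","))
                genes[gid] = rec
            elif ftype == "TSS":
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: TSS without Parent")
                tss[parent] = start_i - 1
            elif ftype == "three_prime_UTR":
                parent = a.get("Parent")
                if parent in genes:
                    genes[parent]["utr3"] = (start_i - 1, end_i)
                elif parent is not None:
                    genes.setdefault(parent, {})["utr3"] = (start_i - 1, end_i)
    out = []
    for gid, rec in genes.items():
        if "cds" not in rec:
            raise ValidationError(f"{gid}: three_prime_UTR without gene record")
        model = _assemble_gene(gid, rec, tss.get(gid))
        out.append(model)
    return out


def _assemble_gene(gid: str, rec: dict, tss_pos: int | None) -> GeneModel:
    s, e = rec["cds"]
    strand = rec["strand"]
    if tss_pos is None:
        utr5 = (s, s) if strand == "+" else (e, e)
        known = False
    else:
        utr5 = (tss_pos, s) if strand == "+" else (e, tss_pos + 1)
        known = True
    return GeneModel(gene_id=gid, contig=rec["contig"], strand=strand,
                     cds_interval=(s, e), tss=tss_pos, utr5_interval=utr5,
                     utr3_interval=rec.get("utr3", (e, e) if strand == "+" else (s, s)),
                     operon_id=rec.get("operon_id"),
                     subunit_index=rec.get("subunit_index"),
                     terms=rec.get("terms", frozenset()),
                     tss_known=known)


def _read_bed12(path: str | Path) -> list[GeneModel]:
    """BED12-like: chromStart/End = transcript span, thickStart/End = CDS.

    The TSS is the 5' end of the transcript span (strand-aware); operon and
    term annotations are not representable in this dialect.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 BED12 columns")
            try:
                contig, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                thick_s, thick_e = int(f[6]), int(f[7])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            tss_pos = start if strand == "+" else end - 1
            rec = {"contig": contig, "strand": strand, "cds": (thick_s, thick_e)}
            if strand == "+":
                rec["utr3"] = (thick_e, end)
            else:
                rec["utr3"] = (start, thick_s)
            out.append(_assemble_gene(name, rec, tss_pos))
    return out


def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + TSS + three_prime_UTR features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.cds_interval
            attrs = [f"ID={g.gene_id}"]
            if g.operon_id is not None:
                attrs.append(f"operon_id={g.operon_id}")
                attrs.append(f"subunit_index={g.subunit_index}")
            if g.terms:
                attrs.append("terms=" + ",".join(sorted(g.terms)))
            fh.write(f"{g.contig}\tribote\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t."
                     f"\t{';'.join(attrs)}\n")
            if g.tss_known:
                fh.write(f"{g.contig}\tribote\tTSS\t{g.tss + 1}\t{g.tss + 1}\t."
                         f"\t{g.strand}\t.\tParent={g.gene_id}\n")
            u3s, u3e = g.utr3_interval
            if u3e > u3s:
                fh.write(f"{g.contig}\tribote\tthree_prime_UTR\t{u3s + 1}\t{u3e}"
                         f"\t.\t{g.strand}\t.\tParent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "assay", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: metadata missing columns {sorted(missing)}")
    return [SampleInfo(r.sample_id, r.condition, r.assay, int(r.replicate))
            for r in df.itertuples()]


def read_counts(path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV of raw integer counts plus sample metadata.

    Samples are ordered deterministically by (condition, assay, replicate);
    genes keep file order.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicated sample_id column(s): {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {s.sample_id: s for s in read_sample_metadata(metadata_path)}
    unknown = [s for s in sample_ids if s not in meta]
    if unknown:
        raise ValidationError(
            f"{path}: sample(s) absent from metadata: {unknown}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            gene = df.index[int(np.flatnonzero(bad.to_numpy())[0])]
            raise ValidationError(
                f"{path}: non-integer count at gene={gene!r}, sample={col!r}")
    samples = sorted((meta[s] for s in sample_ids), key=lambda s: s.sort_key)
    order = [sample_ids.index(s.sample_id) for s in samples]
    counts = df.to_numpy(dtype=np.int64)[:, order]
    return CountMatrix(list(df.index), samples, counts)


def write_counts(cm: CountMatrix, path: str | Path,
                 metadata_path: str | Path | None = None) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    if metadata_path is not None:
        pd.DataFrame([{"sample_id": s.sample_id, "condition": s.condition,
                       "assay": s.assay, "replicate": s.replicate}
                      for s in cm.samples]).to_csv(metadata_path, sep="\t",
                                                   index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {contig: uppercase sequence}; T and U both accepted."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, c in enumerate(seq):
            if c not in _VALID_NT:
                raise FormatError(
                    f"{path}: invalid character {c!r} at position {i} of "
                    f"record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.upper()), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path, strand: str) -> CoverageTrack:
    """Read a single-contig bedGraph, expanding intervals to per-base values."""
    intervals: list[tuple[int, int, float]] = []
    contig = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if contig is None:
                contig = c
            elif c != contig:
                raise FormatError(
                    f"{path}:{lineno}: multiple contigs in one track "
                    f"({contig!r}, {c!r})")
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty/inverted interval")
            intervals.append((start, end, value))
    if not intervals:
        raise FormatError(f"{path}: empty bedGraph")
    intervals.sort()
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if s1 < e0:
            raise FormatError(
                f"{path}: overlapping bedGraph intervals at {contig}:{s1}")
    lo = intervals[0][0]
    hi = intervals[-1][1]
    values = np.zeros(hi - lo)
    for s, e, v in intervals:
        values[s - lo:e - lo] = v
    return CoverageTrack(contig=contig, strand=strand, start=lo, values=values)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as run-length-merged bedGraph."""
    with open(path, "w") as fh:
        vals = track.values
        i = 0
        while i < len(vals):
            j = i
            while j < len(vals) and vals[j] == vals[i]:
                j += 1
            if vals[i] != 0:
                fh.write(f"{track.contig}\t{track.start + i}\t{track.start + j}"
                         f"\t{vals[i]:g}\n")
            i = j
        if not vals.any():
            # keep at least one record so the interval is recoverable
            fh.write(f"{track.contig}\t{track.start}\t{track.end}\t0\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_tsv_results(df: pd.DataFrame, path: str | Path, version: str = "",
                      config_hash: str = "") -> None:
    """Write a result table with a provenance comment header; '.' for missing."""
    with open(path, "w") as fh:
        fh.write(f"# ribote {version} config={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep=".")


def read_tsv_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["."])
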