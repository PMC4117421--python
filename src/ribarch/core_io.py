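"""I/O layer and coordinate conventions.

All public coordinates are 1-based inclusive on the forward strand of a
single (usually circular) bacterial chromosome; bedGraph files are read and
written in their native 0-based half-open dialect; GFF3 output is 1-based
inclusive.  Per-strand density arrays are stored 0-based internally
(``array[i]`` is genomic position ``i + 1``).

Three track flavours are used throughout the package:

``ribo``
    center-weighted ribosome-footprint density,
``rna_cov``
    full RNA-seq read coverage,
``rna_5p``
    counts of RNA-seq read 5' ends (TSS evidence lives here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "AlphabetError",
    "CoordinateError",
    "Genome",
    "GenomicInterval",
    "DensityTrack",
    "FootprintAlignment",
    "TSSRecord",
    "Peptide",
    "AnnotationRecord",
    "read_genome",
    "compute_gc",
    "center_weight_footprints",
    "read_track",
    "write_track",
    "read_tss",
    "read_peptides",
    "read_annotation",
    "write_annotation",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class AlphabetError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class CoordinateError(ValueError):
    """A coordinate falls outside the genome or violates an interval rule."""


_DNA = set("ACGT")
_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class Genome:
    """An immutable chromosome sequence with 1-based coordinates."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA
        if bad:
            raise AlphabetError(
                f"genome {self.id!r} contains non-ACGT characters: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of [start, end] (1-based inclusive).

        On a circular genome coordinates wrap modulo the length; on a linear
        genome out-of-range requests raise :class:`CoordinateError`.  Minus
        strand requests are reverse-complemented (read 5'->3').
        """
        n = self.length
        if start > end:
            raise CoordinateError(f"start {start} > end {end}")
        if self.circular:
            idx = [(p - 1) % n for p in range(start, end + 1)]
            seq = "".join(self.sequence[i] for i in idx)
        else:
            if start < 1 or end > n:
                raise CoordinateError(f"[{start},{end}] outside 1..{n}")
            seq = self.sequence[start - 1 : end]
        if strand == "-":
            seq = revcomp(seq)
        return seq


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive stranded interval; ``wrap`` marks origin-spanning
    features on a circular chromosome (then end < start numerically)."""

    start: int
    end: int
    strand: str = "+"
    wrap: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.wrap and self.end < self.start:
            raise CoordinateError(f"end {self.end} < start {self.start}")

    def length(self, genome_length: int | None = None) -> int:
        if not self.wrap:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError("wrap interval needs genome_length")
        return genome_length - self.start + 1 + self.end


@dataclass
class FootprintAlignment:
    interval: GenomicInterval
    count: int = 1


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: the 5'-triphosphorylated first nucleotide
    of a primary transcript, with read support."""

    position: int
    strand: str
    support: float = 1.0


@dataclass(frozen=True)
class Peptide:
    """An LC-MS-identified tryptic peptide mapped into an ORF.

    ``codon_offset`` is the 0-based codon index of the peptide's first
    residue within its ORF (0 = the initiator codon).  ``preceding_residue``
    is the amino acid immediately upstream in the protein, or ``None`` at
    the protein N-terminus.
    """

    sequence: str
    cds_id: str | None
    codon_offset: int
    preceding_residue: str | None = None

    @property
    def tryptic_internal(self) -> bool:
        """True when the upstream residue is Arg/Lys, i.e. the peptide is an
        ordinary internal trypsin product rather than an N-terminal anchor."""
        return self.preceding_residue in ("R", "K")


@dataclass
class AnnotationRecord:
    """A minimal annotation feature (input or output)."""

    locus: str
    start: int  # leftmost genomic position, 1-based
    end: int  # rightmost genomic position, inclusive
    strand: str
    feature: str = "CDS"
    hypothetical: bool = False
    attrs: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# genome


def read_genome(path: str | Path, replicon: str | None = None,
                circular: bool = True) -> Genome:
    """Read a (single-replicon) genome FASTA.

    Multi-record files are rejected unless ``replicon`` selects one record
    by id, which guards against silently mapping tracks onto the wrong
    replicon.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if replicon is not None:
        matches = [r for r in records if r.id == replicon]
        if not matches:
            raise FormatError(f"{path}: no record with id {replicon!r}")
        rec = matches[0]
    elif len(records) > 1:
        raise FormatError(
            f"{path}: {len(records)} records; pass replicon= to choose one"
        )
    else:
        rec = records[0]
    seq = str(rec.seq).upper()
    bad = set(seq) - _DNA
    if bad - _IUPAC_DNA:
        raise AlphabetError(f"{path}: non-IUPAC characters {sorted(bad - _IUPAC_DNA)!r}")
    if bad:
        # ambiguity codes are legal IUPAC but the downstream energy and ORF
        # logic is defined over ACGT only
        raise AlphabetError(f"{path}: ambiguity codes not supported: {sorted(bad)!r}")
    return Genome(id=rec.id, sequence=seq, circular=circular)


def compute_gc(genome: Genome | str) -> float:
    """G+C fraction of a genome or plain sequence."""
    seq = genome.sequence if isinstance(genome, Genome) else genome
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# density tracks


class DensityTrack:
    """Per-strand, per-nucleotide non-negative real coverage."""

    def __init__(self, length: int, label: str = "ribo",
                 plus: np.ndarray | None = None,
                 minus: np.ndarray | None = None) -> None:
        self.length = int(length)
        self.label = label
        self.plus = np.zeros(self.length) if plus is None else np.asarray(plus, float)
        self.minus = np.zeros(self.length) if minus is None else np.asarray(minus, float)
        for name, arr in (("plus", self.plus), ("minus", self.minus)):
            if arr.shape != (self.length,):
                raise ValueError(f"{name} array length {arr.shape} != {self.length}")
            if np.any(arr < 0):
                raise ValueError(f"{name} array has negative values")

    def array(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"bad strand {strand!r}")

    def total_mass(self) -> float:
        return float(self.plus.sum() + self.minus.sum())

    def slice(self, start: int, end: int, strand: str) -> np.ndarray:
        """Values over [start, end] 1-based inclusive, oriented 5'->3' on
        the requested strand."""
        if start < 1 or end > self.length or start > end:
            raise CoordinateError(f"[{start},{end}] outside 1..{self.length}")
        vals = self.array(strand)[start - 1 : end]
        return vals[::-1] if strand == "-" else vals

    def copy(self) -> "DensityTrack":
        return DensityTrack(self.length, self.label, self.plus.copy(), self.minus.copy())


def center_weight_footprints(alignments: Iterable[FootprintAlignment],
                             genome_length: int,
                             flank: int = 11,
                             fallback: str = "center",
                             label: str = "ribo") -> DensityTrack:
    """Convert footprint alignments to a center-weighted density track.

    Each read's unit weight is spread uniformly over its interval after
    trimming ``flank`` nt from both ends, which suppresses the fuzzy
    nuclease-determined fragment ends and leaves density over the nucleotides
    the ribosome actually covered.  Reads too short to trim keep their whole
    weight at the central nucleotide (``fallback='center'``) or are dropped
    (``fallback='drop'``).  Total track mass equals the summed counts of all
    non-dropped reads.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if fallback not in ("center", "drop"):
        raise ValueError(f"unknown fallback policy {fallback!r}")
    track = DensityTrack(genome_length, label=label)
    for aln in alignments:
        iv = aln.interval
        if iv.start < 1 or iv.end > genome_length:
            raise CoordinateError(f"footprint [{iv.start},{iv.end}] off genome")
        arr = track.array(iv.strand)
        lo, hi = iv.start + flank, iv.end - flank
        if hi >= lo:
            w = aln.count / (hi - lo + 1)
            arr[lo - 1 : hi] += w
        elif fallback == "center":
            center = iv.start + (iv.length() - 1) // 2  # position ceil(L/2) of the read
            arr[center - 1] += aln.count
        # 'drop': weight discarded
    return track


def _read_bedgraph(path: str | Path, length: int) -> np.ndarray:
    """Read one strand's bedGraph (0-based half-open) onto a 1-based array.

    Overlapping intervals sum, which makes write/read a clean round trip for
    any additive coverage decomposition.
    """
    arr = np.zeros(length)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage {value}")
            if start < 0 or end > length or end <= start:
                raise CoordinateError(f"{path}:{lineno}: [{start},{end}) outside genome")
            arr[start:end] += value
    return arr


def read_track(plus_path: str | Path, minus_path: str | Path,
               genome_length: int, label: str = "ribo") -> DensityTrack:
    """Read a stranded track from a pair of bedGraph files."""
    return DensityTrack(
        genome_length, label=label,
        plus=_read_bedgraph(plus_path, genome_length),
        minus=_read_bedgraph(minus_path, genome_length),
    )


def _write_bedgraph(arr: np.ndarray, path: str | Path, chrom: str) -> None:
    with open(path, "w") as fh:
        n = len(arr)
        i = 0
        while i < n:
            if arr[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and arr[j + 1] == arr[i]:
                j += 1
            fh.write(f"{chrom}\t{i}\t{j + 1}\t{arr[i]:.10g}\n")
            i = j + 1


def write_track(track: DensityTrack, plus_path: str | Path,
                minus_path: str | Path, chrom: str = "genome") -> None:
    """Write a stranded track as a pair of bedGraph files (zero runs omitted)."""
    _write_bedgraph(track.plus, plus_path, chrom)
    _write_bedgraph(track.minus, minus_path, chrom)


# ---------------------------------------------------------------------------
# evidence tables

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def read_tss(path: str | Path, genome_length: int | None = None) -> list[TSSRecord]:
    """Read a TSS table (TSV columns: position, strand, reads)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "strand", "reads"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    out: list[TSSRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            pos = int(row["position"])
            strand = str(row["strand"])
            support = float(row["reads"])
            if strand not in "+-":
                raise ValueError(f"bad strand {strand!r}")
            if genome_length is not None and not (1 <= pos <= genome_length):
                raise ValueError(f"position {pos} outside genome")
            out.append(TSSRecord(pos, strand, support))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    return out


def read_peptides(path: str | Path) -> list[Peptide]:
    """Read a tryptic-peptide table (TSV columns: peptide, cds_id,
    codon_offset, preceding_residue; '.' means none/unmapped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"peptide", "cds_id", "codon_offset", "preceding_residue"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    out: list[Peptide] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        try:
            seq = row["peptide"].strip().upper()
            if not seq or set(seq) - _AA:
                raise ValueError(f"bad peptide sequence {seq!r}")
            cds_id = row["cds_id"].strip() or None
            if cds_id == ".":
                cds_id = None
            prev = row["preceding_residue"].strip() or None
            if prev == ".":
                prev = None
            if prev is not None and prev not in _AA:
                raise ValueError(f"bad preceding residue {prev!r}")
            out.append(Peptide(seq, cds_id, int(row["codon_offset"]), prev))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    return out


def read_evidence(tss_path: str | Path, peptide_path: str | Path,
                  genome_length: int | None = None) -> tuple[list[TSSRecord], list[Peptide]]:
    return read_tss(tss_path, genome_length), read_peptides(peptide_path)


# ---------------------------------------------------------------------------
# annotation (GFF3 + summary TSV)

_GFF_ESCAPES = {";": "%3B", "=": "%3D", ",": "%2C"}


def _gff_escape(value: str) -> str:
    for ch, rep in _GFF_ESCAPES.items():
        value = value.replace(ch, rep)
    return value


def write_annotation(records: Sequence[AnnotationRecord], gff_path: str | Path,
                     summary_path: str | Path | None = None,
                     seqid: str = "genome") -> None:
    """Write features as GFF3 (1-based inclusive) plus an optional flat
    summary TSV (locus, start, end, strand, start_codon, leaderless,
    evidence, provenance)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            attrs = {"ID": rec.locus}
            for k, v in rec.attrs.items():
                if isinstance(v, (set, frozenset, list, tuple)):
                    v = ",".join(sorted(str(x) for x in v))
                attrs[k] = str(v)
            if rec.hypothetical:
                attrs["hypothetical"] = "true"
            attr_str = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\tribarch\t{rec.feature}\t{rec.start}\t{rec.end}"
                f"\t.\t{rec.strand}\t.\t{attr_str}\n"
            )
    if summary_path is not None:
        rows = []
        for rec in records:
            rows.append({
                "locus": rec.locus,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.strand,
                "start_codon": rec.attrs.get("start_codon", "."),
                "leaderless": rec.attrs.get("leaderless", "."),
                "evidence": ",".join(sorted(rec.attrs.get("evidence", []))) or ".",
                "provenance": rec.attrs.get("provenance", "."),
            })
        pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)


def read_annotation(gff_path: str | Path) -> list[AnnotationRecord]:
    """Read a GFF3 annotation written by this package (or any flat GFF3 of
    CDS/tRNA/ncRNA features)."""
    out: list[AnnotationRecord] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{gff_path}:{lineno}: expected 9 columns")
            _, _, feature, start, end, _, strand, _, attr_str = parts
            attrs: dict = {}
            for item in attr_str.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            locus = attrs.pop("ID", f"feat{lineno}")
            hyp = attrs.pop("hypothetical", "false") == "true"
            if "evidence" in attrs:
                attrs["evidence"] = set(attrs["evidence"].split(",")) - {""}
            out.append(AnnotationRecord(
                locus=locus, start=int(start), end=int(end), strand=strand,
                feature=feature, hypothetical=hyp, attrs=attrs,
            ))
    return out
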