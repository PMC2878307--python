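"""Genome, repeat and gene annotation I/O; Alu classification; masking.

Coordinates are 0-based half-open everywhere. RepeatMasker ``rmsk`` tables
already store ``genoStart`` 0-based, so both supported dialects (rmsk and
BED6) map onto the internal convention without shifting.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")

#: Accepted length windows (bp, inclusive) per Alu class. Elements outside
#: their class window are discarded.
DEFAULT_CLASS_WINDOWS: dict[str, tuple[int, int]] = {
    "dimer": (280, 320),
    "FLAM": (110, 150),
    "FRAM": (150, 190),
}

#: Default repName -> class patterns. A name containing "FLAM" or equal to
#: "FAM" is a free left Alu monomer; a name containing "FRAM" is a free
#: right monomer; any other name starting with "Alu" is a dimer candidate.
DEFAULT_NAME_MAP: tuple[tuple[str, str], ...] = (
    ("FLAM", "FLAM"),
    ("^FAM$", "FLAM"),
    ("FRAM", "FRAM"),
    ("^Alu", "dimer"),
)


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class GenomeSequence:
    """In-memory genome over the alphabet {A,C,G,T,N}."""

    _seqs: dict[str, str]

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def base_composition(self) -> dict[str, float]:
        """Genome-wide A/C/G/T frequencies, ignoring N."""
        counts = {b: 0 for b in "ACGT"}
        for s in self._seqs.values():
            for b in "ACGT":
                counts[b] += s.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("genome contains no ACGT bases")
        return {b: c / total for b, c in counts.items()}


@dataclass(frozen=True)
class RepeatFeature:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    rep_name: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}>={self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AluElement:
    """A repeat interval accepted into one of the three Alu classes."""

    feature: RepeatFeature
    alu_class: str  # dimer | FLAM | FRAM

    @property
    def chrom(self) -> str:
        return self.feature.chrom

    @property
    def start(self) -> int:
        return self.feature.start

    @property
    def end(self) -> int:
        return self.feature.end

    @property
    def strand(self) -> str:
        return self.feature.strand

    @property
    def center(self) -> int:
        return (self.feature.start + self.feature.end) // 2


@dataclass(frozen=True)
class GeneAnnotation:
    chrom: str
    tss: int
    strand: str


def _clean_seq(raw: str) -> str:
    s = raw.upper()
    if set(s) - _VALID:
        s = re.sub(r"[^ACGTN]", "N", s)
    return s


def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a FASTA file; uppercase residues, map non-ACGTN characters to N.

    Raises :class:`FormatError` on an empty file or a file that does not
    start with a header line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: not FASTA (no '>' header)")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = _clean_seq(str(rec.seq))
    if not seqs:
        raise FormatError(f"{path}: no sequences")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.seq(c)), id=c, description="")
        for c in genome.chrom_names
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# rmsk column indices (UCSC layout with leading bin column)
_RMSK_COLS = {"chrom": 5, "start": 6, "end": 7, "strand": 9, "name": 10}


def read_repeat_table(
    path: str | Path, dialect: str = "bed6"
) -> list[RepeatFeature]:
    """Read repeat intervals from an rmsk-style table or BED6.

    ``dialect``: ``"rmsk"`` for the UCSC RepeatMasker table (bin, swScore,
    milliDiv, milliDel, milliIns, genoName, genoStart, genoEnd, genoLeft,
    strand, repName, ...) or ``"bed6"`` (chrom, start, end, name, score,
    strand). Both emit 0-based half-open coordinates. Rows with
    ``start >= end`` are rejected; the rejection count is logged.
    """
    path = Path(path)
    feats: list[RepeatFeature] = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if dialect == "rmsk":
                chrom = f[_RMSK_COLS["chrom"]]
                start = int(f[_RMSK_COLS["start"]])
                end = int(f[_RMSK_COLS["end"]])
                strand = f[_RMSK_COLS["strand"]]
                name = f[_RMSK_COLS["name"]]
            elif dialect == "bed6":
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else "."
                strand = f[5] if len(f) > 5 else "+"
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if strand == "C":  # RepeatMasker minus-strand convention
                strand = "-"
            if start >= end:
                n_rejected += 1
                continue
            feats.append(RepeatFeature(chrom, start, end, strand, name))
    if n_rejected:
        logger.warning("%s: rejected %d rows with start >= end", path, n_rejected)
    return feats


def write_bed6(
    items: Iterable[RepeatFeature | AluElement], path: str | Path
) -> None:
    """Write features or classified elements as BED6 (name = repName or class)."""
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, AluElement):
                f, name = it.feature, f"{it.feature.rep_name}|{it.alu_class}"
            else:
                f, name = it, it.rep_name
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t0\t{f.strand}\n")


def read_name_map(path: str | Path) -> tuple[tuple[str, str], ...]:
    """Read a 2-column TSV ``pattern<TAB>class`` name map."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pat, cls = line.split("\t")[:2]
            if cls not in DEFAULT_CLASS_WINDOWS:
                raise ValueError(f"unknown Alu class {cls!r}")
            out.append((pat, cls))
    return tuple(out)


def classify_alu(
    feature: RepeatFeature,
    name_map: Sequence[tuple[str, str]] = DEFAULT_NAME_MAP,
    class_windows: Mapping[str, tuple[int, int]] = DEFAULT_CLASS_WINDOWS,
) -> AluElement | None:
    """Assign a repeat to an Alu class, or None.

    The first ``(pattern, class)`` pair whose regex matches ``rep_name``
    decides the class; the element is accepted only if its length falls in
    the class window (inclusive) — longer or shorter copies are discarded as
    incomplete.
    """
    for pat, cls in name_map:
        if re.search(pat, feature.rep_name):
            lo, hi = class_windows[cls]
            if lo <= feature.length <= hi:
                return AluElement(feature, cls)
            return None
    return None


def classify_alu_table(
    features: Iterable[RepeatFeature],
    name_map: Sequence[tuple[str, str]] = DEFAULT_NAME_MAP,
    class_windows: Mapping[str, tuple[int, int]] = DEFAULT_CLASS_WINDOWS,
) -> list[AluElement]:
    """Classify a whole table, dropping non-Alu and off-length features."""
    out = []
    for f in features:
        el = classify_alu(f, name_map, class_windows)
        if el is not None:
            out.append(el)
    return out


def mask_regions(
    genome: GenomeSequence, features: Iterable[RepeatFeature | AluElement]
) -> GenomeSequence:
    """Return a copy of the genome with the given intervals replaced by N.

    Features extending beyond a chromosome end are clipped (with a warning);
    overlapping features mask their union, so the operation is idempotent.
    """
    arrays = {
        c: np.frombuffer(genome.seq(c).encode(), dtype="S1").copy()
        for c in genome.chrom_names
    }
    n_clipped = 0
    for it in features:
        f = it.feature if isinstance(it, AluElement) else it
        if f.chrom not in arrays:
            raise KeyError(f"unknown chrom {f.chrom!r}")
        L = len(arrays[f.chrom])
        end = min(f.end, L)
        if f.end > L:
            n_clipped += 1
        arrays[f.chrom][f.start : end] = b"N"
    if n_clipped:
        logger.warning("mask_regions: clipped %d features at chrom ends", n_clipped)
    return GenomeSequence(
        {c: a.tobytes().decode() for c, a in arrays.items()}
    )


def read_genes(path: str | Path) -> list[GeneAnnotation]:
    """Read gene TSSs from a refGene-style table or a simple TSV.

    Accepts the UCSC ``refGene.txt`` layout (bin, name, chrom, strand,
    txStart, txEnd, ...) or a minimal 3+-column table (chrom, tss, strand).
    The TSS of a minus-strand refGene transcript is ``txEnd - 1``.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 6 and f[3] in "+-":  # refGene layout
                chrom, strand = f[2], f[3]
                tss = int(f[4]) if strand == "+" else int(f[5]) - 1
            elif len(f) >= 3 and f[2] in "+-":
                chrom, tss, strand = f[0], int(f[1]), f[2]
            else:
                raise FormatError(f"unrecognized gene table row: {line!r}")
            genes.append(GeneAnnotation(chrom, tss, strand))
    return genes
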