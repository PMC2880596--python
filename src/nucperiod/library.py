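"""Genome and nucleosome-library I/O.

A nucleosome library is a set of 147-bp sequences, each carrying an integer
read weight.  Sequences are extracted from a genome using per-read
coordinates that are either the 5' end of a sequenced fragment (strand
directed) or the nucleosome midpoint; midpoint extraction takes
``coord - 73 .. coord + 73`` so the dyad always lands at library position 74.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import _encoding as enc

log = logging.getLogger(__name__)

NUC_LENGTH = 147
DYAD_POSITION = 74  # 1-based library position of the dyad
HALF = NUC_LENGTH // 2  # 73

CoordKind = Literal["five_prime", "midpoint"]

_GENOME_ALPHABET = set("ACGTN")


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into an ordered ``{name: sequence}`` mapping.

    Sequences are uppercased and must be over {A,C,G,T,N}.  U (RNA) and X
    (reserved for masking) are rejected, as are duplicate record names.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name in FASTA: {record.id}")
        seq = str(record.seq).upper()
        bad = set(seq) - _GENOME_ALPHABET
        if bad:
            raise ValueError(
                f"record {record.id!r} contains non-nucleotide characters "
                f"{sorted(bad)} (only A/C/G/T/N are accepted)"
            )
        if not seq:
            raise ValueError(f"record {record.id!r} is empty")
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


@dataclass(frozen=True)
class ReadRecord:
    """One mapped nucleosome read: chromosome, 1-based coordinate, strand,
    read count, and whether the coordinate is a 5' end or a midpoint."""

    chrom: str
    coord: int
    strand: str
    reads: int = 1
    coord_kind: CoordKind = "five_prime"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.reads < 1:
            raise ValueError(f"reads must be >= 1, got {self.reads}")


@dataclass(frozen=True)
class TsvDialect:
    """Column layout of a coordinate table.

    ``columns`` maps the logical fields chrom/coord/strand/reads to column
    names (header present) or 0-based column indices (no header).  A missing
    ``reads`` entry defaults every record to weight 1.  ``zero_based`` input
    coordinates are converted to the 1-based convention used throughout.
    """

    columns: dict[str, str | int] = field(
        default_factory=lambda: {"chrom": 0, "coord": 1, "strand": 2, "reads": 3}
    )
    has_header: bool = False
    zero_based: bool = False
    strand_symbols: dict[str, str] = field(
        default_factory=lambda: {"+": "+", "-": "-", "F": "+", "R": "-", "W": "+", "C": "-"}
    )


def load_records(
    path: str | Path,
    coord_kind: CoordKind = "five_prime",
    dialect: TsvDialect | None = None,
) -> list[ReadRecord]:
    """Parse a BED-like TSV of mapped reads into :class:`ReadRecord` rows."""
    dialect = dialect or TsvDialect()
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if dialect.has_header else None,
        comment="#",
        dtype=str,
    )
    cols = dialect.columns

    def col(fieldname: str) -> pd.Series | None:
        key = cols.get(fieldname)
        if key is None:
            return None
        if isinstance(key, int):
            return df.iloc[:, key] if key < df.shape[1] else None
        return df[key] if key in df.columns else None

    chrom = col("chrom")
    coord = pd.to_numeric(col("coord"), errors="raise").astype(int)
    if dialect.zero_based:
        coord = coord + 1
    strand_raw = col("strand")
    try:
        strand = strand_raw.map(dialect.strand_symbols)
    except KeyError:  # pragma: no cover - map returns NaN instead
        strand = None
    if strand is None or strand.isna().any():
        bad = sorted(set(strand_raw[strand.isna()])) if strand is not None else []
        raise ValueError(f"unknown strand symbol(s): {bad}")
    reads_col = col("reads")
    if reads_col is None:
        reads = pd.Series(1, index=df.index)
    else:
        reads = pd.to_numeric(reads_col, errors="raise").astype(int)
    return [
        ReadRecord(c, int(p), s, int(r), coord_kind)
        for c, p, s, r in zip(chrom, coord, strand, reads)
    ]


@dataclass
class NucLibrary:
    """A nucleosome sequence library: fixed-length sequences + read weights.

    Sequences are stored encoded as a ``(n, 147)`` uint8 matrix (see
    :mod:`nucperiod._encoding`); the ``sequences`` property decodes back to
    strings over {A,C,G,T,N,X}.
    """

    codes: np.ndarray
    weights: np.ndarray
    label: str = ""
    include_revcomp: bool = False
    n_skipped: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        if self.codes.shape[0] != self.weights.shape[0]:
            raise ValueError("sequence/weight count mismatch")
        if (self.weights < 1).any():
            raise ValueError("weights must be positive integers")

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        weights: Iterable[int] | None = None,
        label: str = "",
        include_revcomp: bool = False,
        length: int | None = None,
    ) -> "NucLibrary":
        codes = enc.encode_matrix(list(sequences), length)
        w = np.ones(len(sequences), dtype=np.int64) if weights is None else np.asarray(list(weights))
        return cls(codes, w, label=label, include_revcomp=include_revcomp)

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    @property
    def sequences(self) -> list[str]:
        return enc.decode_matrix(self.codes)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    def __len__(self) -> int:
        return self.n

    def subset(self, mask: np.ndarray, label: str | None = None) -> "NucLibrary":
        return NucLibrary(
            self.codes[mask],
            self.weights[mask],
            label=label if label is not None else self.label,
            include_revcomp=self.include_revcomp,
            metadata=dict(self.metadata),
        )


def extract_library(
    genome: dict[str, str],
    records: Iterable[ReadRecord],
    length: int = NUC_LENGTH,
    label: str = "",
) -> NucLibrary:
    """Extract strand-aware fixed-length nucleosomal sequences.

    five_prime/+  : genome[coord .. coord+length-1]
    five_prime/-  : reverse complement of genome[coord-length+1 .. coord]
    midpoint      : genome[coord-length//2 .. coord+length//2], then strand

    Records whose window leaves the chromosome are dropped (counted in
    ``n_skipped``), never clipped.
    """
    chrom_codes = {name: enc.encode(seq) for name, seq in genome.items()}
    half = length // 2
    rows: list[np.ndarray] = []
    weights: list[int] = []
    skipped = 0
    for rec in records:
        try:
            chrom = chrom_codes[rec.chrom]
        except KeyError:
            raise KeyError(f"record chromosome {rec.chrom!r} not in genome")
        if rec.coord_kind == "midpoint":
            start = rec.coord - half  # 1-based inclusive
            end = rec.coord + half
        elif rec.strand == "+":
            start = rec.coord
            end = rec.coord + length - 1
        else:
            start = rec.coord - length + 1
            end = rec.coord
        if start < 1 or end > chrom.shape[0]:
            skipped += 1
            continue
        window = chrom[start - 1 : end]
        if rec.strand == "-":
            window = enc.revcomp_codes(window)
        rows.append(window)
        weights.append(rec.reads)
    if skipped:
        log.info("extract_library: dropped %d out-of-bounds record(s)", skipped)
    codes = np.vstack(rows) if rows else np.empty((0, length), dtype=np.uint8)
    lib = NucLibrary(codes, np.asarray(weights, dtype=np.int64), label=label)
    lib.n_skipped = skipped
    return lib


def add_reverse_complements(library: NucLibrary) -> NucLibrary:
    """Append the reverse complement of every sequence, with its weight.

    Profiles computed on the closed library count each motif together with
    its reverse complement, which is the convention used for all
    strand-symmetric statistics.
    """
    if library.include_revcomp:
        raise ValueError("library already includes reverse complements")
    rc = enc.revcomp_codes(library.codes)
    return NucLibrary(
        np.vstack([library.codes, rc]),
        np.concatenate([library.weights, library.weights]),
        label=library.label,
        include_revcomp=True,
        metadata=dict(library.metadata),
    )


def save_library(library: NucLibrary, path: str | Path) -> None:
    """Serialize as TSV: one header line, then sequence<TAB>weight rows."""
    with open(path, "w") as fh:
        fh.write(
            f"#label={library.label}\tinclude_revcomp={int(library.include_revcomp)}\n"
        )
        for seq, w in zip(library.sequences, library.weights):
            fh.write(f"{seq}\t{w}\n")


def load_library(path: str | Path) -> NucLibrary:
    """Read a library serialized by :func:`save_library`."""
    label, include_revcomp = "", False
    seqs: list[str] = []
    weights: list[int] = []
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for item in first[1:].strip().split("\t"):
                key, _, value = item.partition("=")
                if key == "label":
                    label = value
                elif key == "include_revcomp":
                    include_revcomp = bool(int(value))
        else:
            seq, _, w = first.strip().partition("\t")
            seqs.append(seq)
            weights.append(int(w or 1))
        for line in fh:
            if not line.strip():
                continue
            seq, _, w = line.strip().partition("\t")
            seqs.append(seq)
            weights.append(int(w or 1))
    lib = NucLibrary.from_sequences(seqs, weights, label=label)
    lib.include_revcomp = include_revcomp
    return lib
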