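"""Weighted motif occurrence profiles along nucleosomal DNA.

Every motif occurrence is tallied at a single *counting position* so that
motifs of different lengths can be compared on the same positional axis:
a motif of length L starting at 1-based position ``s`` is counted at
``s + (L - 1) // 2``.  Odd-length motifs are therefore counted at their
center base, and even-length motifs at the first base of their central
dinucleotide — e.g. CTAG starting at ``s`` and its central TA step starting
at ``s + 1`` land on the same position.

Counting is read-weighted: a sequence carrying ``w`` reads contributes
``w`` to every one of its motif occurrences.  Windows containing N or X
never match.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from . import _encoding as enc
from .library import NUC_LENGTH, NucLibrary

_CHUNK = 65536  # sequences per counting chunk (keeps code matrices small)


def counting_position(start: int, length: int, window: int = NUC_LENGTH) -> int:
    """1-based position at which a motif occurrence is counted."""
    if length < 1:
        raise ValueError("motif length must be >= 1")
    if start < 1 or start + length - 1 > window:
        raise ValueError(
            f"motif of length {length} at start {start} exceeds the "
            f"{window}-bp window"
        )
    return start + (length - 1) // 2


@dataclass(frozen=True)
class MotifSpec:
    """One or more same-length IUPAC patterns counted into a single profile."""

    patterns: tuple[str, ...]
    label: str = ""
    include_revcomp: bool = False

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("empty pattern set")
        lengths = {len(p) for p in self.patterns}
        if len(lengths) != 1:
            raise ValueError(f"patterns must share one length, got {sorted(lengths)}")
        if not self.label:
            object.__setattr__(self, "label", "+".join(self.patterns))

    @property
    def length(self) -> int:
        return len(self.patterns[0])

    def literals(self) -> list[str]:
        """IUPAC-expanded literal words (deduplicated, order preserved),
        including reverse complements when ``include_revcomp`` is set."""
        seen: dict[str, None] = {}
        for pattern in self.patterns:
            for word in enc.expand_iupac(pattern):
                seen.setdefault(word, None)
                if self.include_revcomp:
                    seen.setdefault(enc.revcomp(word), None)
        return list(seen)


def as_motif(motif: MotifSpec | str | Sequence[str]) -> MotifSpec:
    if isinstance(motif, MotifSpec):
        return motif
    if isinstance(motif, str):
        return MotifSpec((motif,))
    return MotifSpec(tuple(motif))


@dataclass
class OccurrenceProfile:
    """Positional occurrence counts ``f`` of one motif, f[i] <-> position i+1.

    ``fbar`` is the mean frequency over the spectral analysis window
    x = 3..144; normalization (display) divides by the mean over all 147
    positions, following the occurrence-profile convention.
    """

    motif_label: str
    f: np.ndarray
    total_weight: float
    smoothed: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.f.ndim != 1:
            raise ValueError("profile must be 1-D")
        if (self.f < 0).any():
            raise ValueError("occurrence counts must be nonnegative")

    @property
    def positions(self) -> np.ndarray:
        """1-based positions 1..L."""
        return np.arange(1, self.f.shape[0] + 1)

    @property
    def dyad_relative(self) -> np.ndarray:
        return self.positions - (self.f.shape[0] // 2 + 1)

    @property
    def fbar(self) -> float:
        """Mean frequency over the analysis window x = 3..144."""
        return float(self.f[2:144].mean())


def count_profile(
    library: NucLibrary,
    motif: MotifSpec | str | Sequence[str],
    weight_by_reads: bool = True,
) -> OccurrenceProfile:
    """Count weighted occurrences of ``motif`` at counting positions.

    All IUPAC-expanded literal patterns are summed into one profile.
    """
    spec = as_motif(motif)
    if library.n == 0:
        raise ValueError("empty library")
    L = library.length
    f = np.zeros(L, dtype=np.float64)
    weights = (
        library.weights.astype(np.float64)
        if weight_by_reads
        else np.ones(library.n, dtype=np.float64)
    )
    for word in spec.literals():
        f += _count_literal(library.codes, weights, word)
    return OccurrenceProfile(spec.label, f, total_weight=float(weights.sum()))


def _count_literal(codes: np.ndarray, weights: np.ndarray, word: str) -> np.ndarray:
    """Positional weighted counts of one literal word (no ambiguity codes)."""
    pattern = enc.encode(word)
    if (pattern >= 4).any():
        raise ValueError(f"literal pattern expected, got {word!r}")
    k = pattern.shape[0]
    L = codes.shape[1]
    nwin = L - k + 1
    offset = (k - 1) // 2
    f = np.zeros(L, dtype=np.float64)
    for lo in range(0, codes.shape[0], _CHUNK):
        chunk = codes[lo : lo + _CHUNK]
        w = weights[lo : lo + _CHUNK]
        match = chunk[:, 0:nwin] == pattern[0]
        for j in range(1, k):
            match &= chunk[:, j : j + nwin] == pattern[j]
        f[offset : offset + nwin] += match.astype(np.float64).T @ w
    return f


def count_all_kmers(
    library: NucLibrary, k: int, weight_by_reads: bool = True
) -> np.ndarray:
    """Weighted occurrence profiles of all 4**k literal k-mers at once.

    Returns a ``(4**k, length)`` matrix; row index is the base-4 code of the
    k-mer (A=0, C=1, G=2, T=3, most significant base first).  Windows that
    contain N or X are excluded everywhere.
    """
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    L = library.length
    nwin = L - k + 1
    offset = (k - 1) // 2
    nkmers = 4**k
    out = np.zeros((nkmers, L), dtype=np.float64)
    weights = (
        library.weights.astype(np.float64)
        if weight_by_reads
        else np.ones(library.n, dtype=np.float64)
    )
    for lo in range(0, library.n, _CHUNK):
        chunk = library.codes[lo : lo + _CHUNK].astype(np.int64)
        w = weights[lo : lo + _CHUNK]
        code = np.zeros((chunk.shape[0], nwin), dtype=np.int64)
        valid = np.ones((chunk.shape[0], nwin), dtype=bool)
        for j in range(k):
            col = chunk[:, j : j + nwin]
            valid &= col < 4
            code = code * 4 + np.where(col < 4, col, 0)
        # flat bin = kmer_code * nwin + window_start
        flat = (code * nwin + np.arange(nwin)[None, :])[valid]
        wflat = np.broadcast_to(w[:, None], valid.shape)[valid]
        counts = np.bincount(flat, weights=wflat, minlength=nkmers * nwin)
        out[:, offset : offset + nwin] += counts.reshape(nkmers, nwin)
    return out


def kmer_index(word: str) -> int:
    """Row index of a literal k-mer in the :func:`count_all_kmers` matrix."""
    pattern = enc.encode(word)
    if (pattern >= 4).any():
        raise ValueError(f"literal k-mer expected, got {word!r}")
    idx = 0
    for b in pattern:
        idx = idx * 4 + int(b)
    return idx


def all_kmers(k: int) -> list[str]:
    """All 4**k literal k-mers in :func:`count_all_kmers` row order."""
    bases = "ACGT"
    words = [""]
    for _ in range(k):
        words = [w + b for w in words for b in bases]
    return words


def count_isolated_run(
    library: NucLibrary,
    base: str = "A",
    n: int = 3,
    flank_class: str = "S",
    paired: bool = True,
    weight_by_reads: bool = True,
) -> OccurrenceProfile:
    """Count maximal homopolymer runs of exactly ``n`` bases isolated by a
    flanking class on both sides.

    With ``paired=True`` (the A/T-tract convention) runs of the complementary
    base are summed in.  Isolation by S = {C,G} excludes A/T-flanked runs, so
    e.g. TAAAC contributes no isolated A3 event.  Runs touching the window
    edge have an unverifiable flank and are discarded.
    """
    if not 1 <= n <= 10:
        raise ValueError("run length n must be in 1..10")
    flanks = enc.encode("".join(enc.IUPAC[flank_class.upper()]))
    targets = [base.upper()]
    if paired:
        comp = enc.revcomp(base.upper())
        if comp != base.upper():
            targets.append(comp)
    L = library.length
    f = np.zeros(L, dtype=np.float64)
    weights = (
        library.weights.astype(np.float64)
        if weight_by_reads
        else np.ones(library.n, dtype=np.float64)
    )
    offset = (n - 1) // 2
    for target in targets:
        b = int(enc.encode(target)[0])
        for lo in range(0, library.n, _CHUNK):
            chunk = library.codes[lo : lo + _CHUNK]
            w = weights[lo : lo + _CHUNK]
            is_b = chunk == b
            in_flank = np.isin(chunk, flanks)
            # run of exactly n starting at 0-based s: s-1 and s+n in flank class
            nstart = L - n - 1  # 0-based starts 1 .. L-n-1
            run = np.ones((chunk.shape[0], nstart), dtype=bool)
            for j in range(n):
                run &= is_b[:, 1 + j : 1 + j + nstart]
            run &= in_flank[:, 0:nstart]
            run &= in_flank[:, 1 + n : 1 + n + nstart]
            # counting position (1-based): (s+1) + offset, s = 1..L-n-1 0-based
            f[1 + offset : 1 + offset + nstart] += run.astype(np.float64).T @ w
    label = f"{flank_class}{base}{n}{flank_class}" + ("+rc" if paired else "")
    return OccurrenceProfile(label, f, total_weight=float(weights.sum()))


def smooth3(profile: OccurrenceProfile) -> OccurrenceProfile:
    """Three-bond running average; endpoints average available neighbors."""
    if profile.smoothed:
        raise ValueError("profile is already smoothed")
    f = profile.f
    out = np.empty_like(f)
    out[1:-1] = (f[:-2] + f[1:-1] + f[2:]) / 3.0
    out[0] = (f[0] + f[1]) / 2.0
    out[-1] = (f[-2] + f[-1]) / 2.0
    return replace(profile, f=out, smoothed=True)


def normalize(profile: OccurrenceProfile) -> OccurrenceProfile:
    """Divide by the mean occurrence over all positions (mean becomes 1)."""
    mean = profile.f.mean()
    if mean <= 0:
        raise ValueError("cannot normalize a zero-count profile")
    return replace(profile, f=profile.f / mean, normalized=True)


def profile_table(profile: OccurrenceProfile):
    """Profile as a DataFrame with 1-based and dyad-relative positions."""
    import pandas as pd

    smoothed = profile if profile.smoothed else smooth3(profile)
    return pd.DataFrame(
        {
            "position": profile.positions,
            "dyad_relative": profile.dyad_relative,
            "raw": profile.f,
            "smoothed": smoothed.f,
            "normalized": profile.f / profile.f.mean() if profile.f.any() else profile.f,
        }
    )
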