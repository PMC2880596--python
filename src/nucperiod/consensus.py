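"""Tetranucleotide selection, consensus grouping, and library masking.

The 256 tetranucleotides collapse to 136 unique species (16 palindromes plus
120 reverse-complement pairs, identified by the lexicographically smaller
member).  Tetranucleotides carrying a significant ~10-bp periodicity with a
defined rotational setting are grouped under 8 degenerate consensus
patterns; the member tetranucleotides of those groups can then be used to
split a library into a "consensus only" part (everything outside a member
occurrence replaced by X) and its exact complement, the "no consensus"
part.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from . import _encoding as enc
from .library import NucLibrary
from .profiles import OccurrenceProfile

Orientation = Literal["in", "out", "intermediate"]
Distribution = Literal["peripheral", "central", "uniform"]
MaskMode = Literal["consensus_only", "no_consensus"]


def canonical_tetra(tetra: str) -> str:
    """Lexicographically smaller of a 4-mer and its reverse complement."""
    word = tetra.upper()
    if len(word) != 4 or any(ch not in "ACGT" for ch in word):
        raise ValueError(f"literal ACGT 4-mer expected, got {tetra!r}")
    return min(word, enc.revcomp(word))


@dataclass(frozen=True)
class ConsensusGroup:
    """A named degenerate tetranucleotide pattern and its derived members."""

    name: str
    patterns: tuple[str, ...]
    orientation: Orientation
    distribution: Distribution
    members_override: tuple[str, ...] = ()

    def members(self) -> list[str]:
        """Literal member 4-mers, closed under reverse complement."""
        if self.members_override:
            literals = list(self.members_override)
        else:
            literals = [w for p in self.patterns for w in enc.expand_iupac(p)]
        seen: dict[str, None] = {}
        for w in literals:
            seen.setdefault(w, None)
            seen.setdefault(enc.revcomp(w), None)
        return list(seen)


def _antm_members() -> tuple[str, ...]:
    """A/T-only tetramers without a TA step: A-run followed by T-run."""
    words = []
    for word in ("".join(p) for p in itertools.product("AT", repeat=4)):
        if "TA" not in word:
            words.append(word)
    return tuple(words)


# Priority order resolves double matches (e.g. TTAA is both YTAR and WTAW).
DEFAULT_GROUPS: tuple[ConsensusGroup, ...] = (
    ConsensusGroup("AnTm", (), "in", "peripheral", members_override=_antm_members()),
    ConsensusGroup("YTAR", ("YTAR",), "in", "central"),
    ConsensusGroup("WTAW", ("WTAW",), "in", "uniform"),
    ConsensusGroup("YCAG+CTGR", ("YCAG", "CTGR"), "in", "central"),
    ConsensusGroup("RCAY+RTGY", ("RCAY", "RTGY"), "out", "central"),
    ConsensusGroup("RACY+RGTY", ("RACY", "RGTY"), "out", "uniform"),
    ConsensusGroup("RCGY", ("RCGY",), "out", "central"),
    ConsensusGroup("RGCY", ("RGCY",), "out", "central"),
)


def consensus_members(
    groups: Sequence[ConsensusGroup] = DEFAULT_GROUPS,
) -> list[str]:
    """Union of all groups' literal members (revcomp-closed, deduplicated)."""
    seen: dict[str, None] = {}
    for group in groups:
        for w in group.members():
            seen.setdefault(w, None)
    return list(seen)


def orientation_of(phase_deg: float, in_halfwidth: float = 45.0, out_halfwidth: float = 45.0) -> Orientation:
    """Rotational class from a phase angle: 'in' near +/-180, 'out' near 0."""
    if np.isnan(phase_deg):
        return "intermediate"
    if abs(phase_deg) > 180.0 - in_halfwidth:
        return "in"
    if abs(phase_deg) < out_halfwidth:
        return "out"
    return "intermediate"


def select_tetranucleotides(
    stats: pd.DataFrame,
    fvo_sd_factor: float = 0.5,
    fts_cut: float = 19.0,
    in_halfwidth: float = 45.0,
    out_halfwidth: float = 45.0,
    overrides: Iterable[str] = (),
) -> list[str]:
    """Unique tetranucleotides passing the periodicity/orientation filters.

    ``stats`` must be indexed by the 256 tetranucleotides with columns
    fvo_10_2, pct_fts_10_2, phase_deg.  A tetranucleotide is retained when

    * FVO_10.2 is no more than ``fvo_sd_factor`` SD below the mean FVO_10.2
      of all tetranucleotides,
    * %FTS_10.2 exceeds ``fts_cut``, and
    * the phase angle lies in the minor-groove-in window (|phase| > 135) or
      the minor-groove-out window (|phase| < 45).

    ``overrides`` are force-included.  The result is the sorted set of
    canonical (unique) tetranucleotides.
    """
    fvo_cut = stats["fvo_10_2"].mean() - fvo_sd_factor * stats["fvo_10_2"].std()
    selected: set[str] = set()
    for tetra, row in stats.iterrows():
        if row["fvo_10_2"] < fvo_cut or row["pct_fts_10_2"] <= fts_cut:
            continue
        if orientation_of(row["phase_deg"], in_halfwidth, out_halfwidth) == "intermediate":
            continue
        selected.add(canonical_tetra(str(tetra)))
    for tetra in overrides:
        selected.add(canonical_tetra(tetra))
    return sorted(selected)


def group_consensus(
    selected: Iterable[str],
    groups: Sequence[ConsensusGroup] = DEFAULT_GROUPS,
) -> tuple[dict[str, str], list[str]]:
    """Assign selected tetranucleotides to consensus groups.

    Each tetranucleotide (or its reverse complement) is matched against the
    groups' literal members in priority order; the first match wins.
    Returns (assignment mapping canonical tetra -> group name, unassigned).
    """
    membership = [(g.name, set(g.members())) for g in groups]
    assignment: dict[str, str] = {}
    unassigned: list[str] = []
    for tetra in selected:
        canon = canonical_tetra(tetra)
        for name, members in membership:
            if canon in members or enc.revcomp(canon) in members:
                assignment[canon] = name
                break
        else:
            unassigned.append(canon)
    return assignment, unassigned


def classify_distribution(
    profile: OccurrenceProfile,
    central_band: tuple[int, int] = (44, 104),
    peripheral_bands: tuple[tuple[int, int], tuple[int, int]] = ((1, 44), (104, 147)),
    ratio_cut: float = 1.15,
) -> Distribution:
    """Classify a profile as centrally/peripherally enriched or uniform.

    Compares the mean normalized occupancy over the dyad-centered band
    (default dyad +/- 30) with the mean over the two outer bands.
    """
    f = profile.f
    pos = profile.positions
    central = f[(pos >= central_band[0]) & (pos <= central_band[1])].mean()
    outer = np.concatenate(
        [f[(pos >= lo) & (pos <= hi)] for lo, hi in peripheral_bands]
    ).mean()
    if outer > 0 and central / outer >= ratio_cut:
        return "central"
    if central > 0 and outer / central >= ratio_cut:
        return "peripheral"
    if central == 0 and outer == 0:
        return "uniform"
    if outer == 0:
        return "central"
    if central == 0:
        return "peripheral"
    return "uniform"


def _member_coverage(codes: np.ndarray, members: Sequence[str]) -> np.ndarray:
    """Boolean (n, L) matrix: position lies inside >= 1 member occurrence."""
    n, L = codes.shape
    k = len(members[0])
    nwin = L - k + 1
    patterns = np.array([enc.encode(m) for m in members])  # (m, k)
    covered = np.zeros((n, L), dtype=bool)
    starts_hit = np.zeros((n, nwin), dtype=bool)
    for pattern in patterns:
        match = codes[:, 0:nwin] == pattern[0]
        for j in range(1, k):
            match &= codes[:, j : j + nwin] == pattern[j]
        starts_hit |= match
    for j in range(k):
        covered[:, j : j + nwin] |= starts_hit
    return covered


def mask_library(
    library: NucLibrary,
    members: Sequence[str] | None = None,
    mode: MaskMode = "consensus_only",
) -> NucLibrary:
    """X-mask a library with respect to a member tetranucleotide set.

    consensus_only: a position keeps its base iff it is covered by at least
    one (possibly overlapping) member occurrence; every other position
    becomes X.  no_consensus: the exact complement — covered positions
    become X, uncovered positions keep their base.  The X-position sets of
    the two modes therefore partition every sequence.  Weights are
    preserved.
    """
    if mode not in ("consensus_only", "no_consensus"):
        raise ValueError(f"unknown mask mode {mode!r}")
    if members is None:
        members = consensus_members()
    members = list(members)
    masked = library.codes.copy()
    if not members:
        covered = np.zeros(library.codes.shape, dtype=bool)
    else:
        # close under revcomp so both strands are treated symmetrically
        closed: dict[str, None] = {}
        for m in members:
            closed.setdefault(m.upper(), None)
            closed.setdefault(enc.revcomp(m.upper()), None)
        covered = np.zeros(library.codes.shape, dtype=bool)
        chunk = 65536
        for lo in range(0, library.n, chunk):
            covered[lo : lo + chunk] = _member_coverage(
                library.codes[lo : lo + chunk], list(closed)
            )
    to_mask = ~covered if mode == "consensus_only" else covered
    masked[to_mask] = enc.X
    out = NucLibrary(
        masked,
        library.weights.copy(),
        label=f"{library.label}[{mode}]" if library.label else mode,
        include_revcomp=library.include_revcomp,
        metadata=dict(library.metadata),
    )
    out.metadata["mask_mode"] = mode
    out.metadata["masked_fraction"] = float(to_mask.mean())
    return out
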