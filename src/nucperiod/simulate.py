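"""Synthetic nucleosome libraries with planted periodic motifs.

The generator emulates the statistical structure that the periodicity
analysis assumes in real MNase-derived libraries: fixed 147-bp fragments,
i.i.d. background base composition, motifs whose start positions follow a
sinusoidally modulated probability (the ~10.2-bp rotational preference),
and read counts that can be coupled to a fragment's planted-motif density
(emulating the enrichment of high-affinity sequences among highly-read
fragments).

Insertions overwrite the background so the 147-bp frame is preserved;
overlaps between planted footprints are resolved by rejection sampling.
Ground truth (per-motif true period/phase/amplitude and per-sequence
insertion positions and reads) is returned alongside the library, and the
"true phase" is computed by pushing the infinitely-sampled ideal profile
through the same phase-angle definition the analysis uses, so recovery is
convention-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _encoding as enc
from .library import NUC_LENGTH, NucLibrary
from .profiles import OccurrenceProfile, counting_position
from .spectrum import fourier_spectrum, phase_angle

_MAX_ROUNDS = 1000


@dataclass(frozen=True)
class PlantedMotif:
    """One motif planted with a sinusoidal positional preference.

    ``phase_position`` is the 1-based start position of maximal insertion
    probability; ``amplitude`` the fractional modulation depth a in
    p(start) proportional to 1 + a*cos(2*pi*(start - phase_position)/period);
    ``mean_insertions`` the Poisson mean number of insertions per sequence.
    """

    motif: str
    period: float = 10.204
    phase_position: float = 2.0
    amplitude: float = 0.3
    mean_insertions: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must be in [0, 1]")
        if self.period <= 1.0:
            raise ValueError("period must exceed 1 bp")
        if self.mean_insertions < 0:
            raise ValueError("mean_insertions must be >= 0")
        if any(ch not in "ACGT" for ch in self.motif.upper()):
            raise ValueError("planted motifs must be literal ACGT words")


@dataclass(frozen=True)
class ReadModel:
    """How per-sequence read counts are drawn.

    constant: every sequence gets ``base`` reads.
    geometric: reads ~ Geometric(p) on {1, 2, ...}.
    affinity: reads = 1 + Poisson(base + gain * n_insertions) — read depth
    increases stochastically with the sequence's planted-motif density.
    """

    kind: Literal["constant", "geometric", "affinity"] = "constant"
    base: float = 1.0
    p: float = 0.5
    gain: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    n_sequences: int
    length: int = NUC_LENGTH
    gc_content: float = 0.39
    planted: tuple[PlantedMotif, ...] = ()
    read_model: ReadModel = ReadModel()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        total_footprint = sum(len(m.motif) * m.mean_insertions for m in self.planted)
        if total_footprint > 0.8 * self.length:
            raise ValueError(
                f"expected planted footprint {total_footprint:.0f} bp cannot be "
                f"placed in a {self.length}-bp frame without unbounded resampling"
            )


@dataclass
class GroundTruth:
    """What was actually planted, sufficient to score recovery."""

    true_period: dict[str, float]
    true_phase_deg: dict[str, float]
    true_amplitude: dict[str, float]
    insertions: dict[str, tuple[np.ndarray, np.ndarray]]  # motif -> (seq_idx, start)
    reads: np.ndarray
    config: SimConfig = field(repr=False, default=None)

    def n_insertions_per_sequence(self, n: int) -> np.ndarray:
        out = np.zeros(n, dtype=np.int64)
        for seq_idx, _ in self.insertions.values():
            np.add.at(out, seq_idx, 1)
        return out


def _start_weights(motif: PlantedMotif, length: int) -> np.ndarray:
    """Insertion probability over valid 1-based starts."""
    nstart = length - len(motif.motif) + 1
    starts = np.arange(1, nstart + 1)
    w = 1.0 + motif.amplitude * np.cos(
        2.0 * np.pi * (starts - motif.phase_position) / motif.period
    )
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def ideal_profile(motif: PlantedMotif, length: int = NUC_LENGTH) -> OccurrenceProfile:
    """The infinitely-sampled occurrence profile a planted motif induces."""
    w = _start_weights(motif, length)
    L = len(motif.motif)
    f = np.zeros(length)
    for s0, weight in enumerate(w):
        f[counting_position(s0 + 1, L, length) - 1] += weight
    return OccurrenceProfile(motif.motif, f, total_weight=1.0)


def true_phase(motif: PlantedMotif, length: int = NUC_LENGTH) -> float:
    """Phase angle the analysis should report for a planted motif."""
    return phase_angle(fourier_spectrum(ideal_profile(motif, length)))


def simulate_library(config: SimConfig) -> tuple[NucLibrary, GroundTruth]:
    """Generate a library and its ground truth, reproducibly from the seed.

    Background bases are i.i.d. with the configured GC content; each
    planted motif gets Poisson(mean_insertions) insertions per sequence at
    sinusoidally modulated start positions, overwriting the background.
    Footprint collisions are resolved by rejection sampling (bounded
    rounds); an over-dense configuration raises with a diagnostic.
    """
    n, L = config.n_sequences, config.length
    root = np.random.SeedSequence(config.seed)
    # dedicated child streams: background, one per motif, reads
    children = root.spawn(len(config.planted) + 2)
    rng_bg = np.random.default_rng(children[0])

    at = (1.0 - config.gc_content) / 2.0
    gc = config.gc_content / 2.0
    codes = rng_bg.choice(
        np.arange(4, dtype=np.uint8), size=(n, L), p=[at, gc, gc, at]
    )

    occupied = np.zeros((n, L), dtype=bool)
    insertions: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for mi, motif in enumerate(config.planted):
        rng = np.random.default_rng(children[mi + 1])
        seq_idx, starts = _place_motif(codes, occupied, motif, rng)
        insertions[motif.motif] = (seq_idx, starts)

    rng_reads = np.random.default_rng(children[-1])
    n_ins = np.zeros(n, dtype=np.int64)
    for seq_idx, _ in insertions.values():
        np.add.at(n_ins, seq_idx, 1)
    reads = _draw_reads(config.read_model, n, n_ins, rng_reads)

    library = NucLibrary(
        codes,
        reads,
        label=f"sim(seed={config.seed},n={n})",
        metadata={"seed": config.seed},
    )
    truth = GroundTruth(
        true_period={m.motif: m.period for m in config.planted},
        true_phase_deg={m.motif: true_phase(m, L) for m in config.planted},
        true_amplitude={m.motif: m.amplitude for m in config.planted},
        insertions=insertions,
        reads=reads,
        config=config,
    )
    return library, truth


def _place_motif(
    codes: np.ndarray,
    occupied: np.ndarray,
    motif: PlantedMotif,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Place Poisson-many copies per sequence; returns (seq_idx, 1-based starts)."""
    n, L = codes.shape
    pattern = enc.encode(motif.motif.upper())
    k = pattern.shape[0]
    weights = _start_weights(motif, L)
    nstart = weights.shape[0]

    counts = rng.poisson(motif.mean_insertions, size=n)
    pending_seq = np.repeat(np.arange(n), counts)
    placed_seq: list[np.ndarray] = []
    placed_start: list[np.ndarray] = []

    for _ in range(_MAX_ROUNDS):
        if pending_seq.size == 0:
            break
        starts0 = rng.choice(nstart, size=pending_seq.size, p=weights)  # 0-based
        # conflict with already-placed footprints?
        conflict = np.zeros(pending_seq.size, dtype=bool)
        for j in range(k):
            conflict |= occupied[pending_seq, starts0 + j]
        # within-round conflicts: keep the first proposal per overlapping set
        order = np.lexsort((starts0, pending_seq))
        seq_o, st_o, keep_o = pending_seq[order], starts0[order], ~conflict[order]
        last_end = -1
        last_seq = -1
        for i in range(seq_o.size):
            if not keep_o[i]:
                continue
            if seq_o[i] == last_seq and st_o[i] < last_end:
                keep_o[i] = False
            else:
                last_seq = seq_o[i]
                last_end = st_o[i] + k
        keep = np.zeros_like(keep_o)
        keep[order] = keep_o
        ok_seq, ok_start = pending_seq[keep], starts0[keep]
        for j in range(k):
            codes[ok_seq, ok_start + j] = pattern[j]
            occupied[ok_seq, ok_start + j] = True
        placed_seq.append(ok_seq)
        placed_start.append(ok_start + 1)
        pending_seq = pending_seq[~keep]
    else:
        raise RuntimeError(
            f"could not place {pending_seq.size} copies of {motif.motif!r} after "
            f"{_MAX_ROUNDS} rejection rounds — planting density is too high"
        )
    if placed_seq:
        return np.concatenate(placed_seq), np.concatenate(placed_start)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def _draw_reads(
    model: ReadModel, n: int, n_insertions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if model.kind == "constant":
        return np.full(n, max(1, int(round(model.base))), dtype=np.int64)
    if model.kind == "geometric":
        return rng.geometric(model.p, size=n).astype(np.int64)
    if model.kind == "affinity":
        lam = model.base + model.gain * n_insertions
        return 1 + rng.poisson(lam).astype(np.int64)
    raise ValueError(f"unknown read model {model.kind!r}")


def simulate_mutation_panel(
    octamers: Sequence[str],
    stability_map: dict[str, float],
    n_sequences: int = 20000,
    mean_insertions: float = 0.15,
    period: float = 10.2,
    seed: int = 0,
    gc_content: float = 0.39,
) -> tuple[NucLibrary, GroundTruth]:
    """Library in which each octamer is planted with its assigned amplitude.

    All octamers share the rotational frame of the strongest natural
    positioning elements: insertion probability maxima at dyad-relative
    -25, -15, ... (counting positions 49, 59, ... for an 8-mer, i.e. start
    position 56 + multiples of the period).
    """
    planted = tuple(
        PlantedMotif(
            oct.upper(),
            period=period,
            phase_position=56.0,
            amplitude=float(stability_map[oct]),
            mean_insertions=mean_insertions,
        )
        for oct in octamers
    )
    config = SimConfig(
        n_sequences=n_sequences,
        gc_content=gc_content,
        planted=planted,
        seed=seed,
    )
    return simulate_library(config)
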