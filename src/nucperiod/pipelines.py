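"""Composite analyses built on the counting and spectral primitives.

These reproduce the full study designs: per-library k-mer statistic tables,
read-count stratification, decomposition of a library into consensus-only /
no-consensus parts, the nucleosome-positioning mutation panel around the
CTCTAGAG core, isolated A/T-tract analysis, probe-based phase adjustment,
and cross-library summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _encoding as enc
from .consensus import consensus_members, mask_library
from .library import NucLibrary
from .profiles import (
    MotifSpec,
    OccurrenceProfile,
    all_kmers,
    count_all_kmers,
    count_isolated_run,
    count_profile,
    normalize,
)
from .spectrum import (
    C_CONSTANT,
    H_GRID,
    N_WINDOW,
    batch_spectrum,
    batch_stats,
    fourier_spectrum,
    periodicity_stats,
    phase_angle,
)

log = logging.getLogger(__name__)


def _pearson(x, y) -> float:
    """Pearson r, NaN (without warning) for degenerate constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(sps.pearsonr(x, y)[0])

# ---------------------------------------------------------------------------
# The published nucleosome-positioning mutation panel around the CTCTAGAG
# core of positioning fragment 67: construct id, the 8-mer surrounding the
# central TA step, nucleosome-stability free-energy difference versus the
# wild type (cal/mol), positioning activity relative to wild type (%), and
# the octamer FVO_10.2 measured in the in vitro yeast library.
FRAGMENT67_PANEL = pd.DataFrame(
    [
        ("67", "CTCTAGAG", 0, 100, 0.256),
        ("67-m1", "CTCCAGAG", 586, 85, 0.233),
        ("67-m2", "CTCAAGAG", 678, 77, 0.143),
        ("67-m3", "CTCCCGAG", 956, 69, 0.083),
        ("67-m4", "CTCATGAG", 1195, 61, 0.079),
        ("67-m5", "CTCGAGAG", 974, 69, 0.018),
        ("67-m6", "CTCTCGAG", 1129, 61, 0.018),
        ("67-m7", "CTGTAGAG", 556, 84, 0.139),
        ("67-m8", "CTCTACAG", 556, 82, 0.139),
        ("67-m9", "CTGTACAG", 761, 68, 0.031),
        ("67-m10", "CAGTACTG", 1130, 58, 0.100),
        ("601+25", "TGCTAGAG", 31, 96, 0.143),
        ("601-39", "GACTAGGG", 92, 83, 0.130),
        ("5S-16", "CTTTAAAT", -140, 93, 0.156),
        ("601-16", "GGTTAAAA", 107, 80, 0.146),
        ("5S-7", "GCTTAACT", 171, 83, 0.066),
        ("601+16", "GTTTAAGC", -247, 88, 0.183),
    ],
    columns=["construct", "octamer", "dG", "pct67", "fvo_printed"],
)


# ---------------------------------------------------------------------------
# per-library k-mer statistic tables


def kmer_stats_table(
    library: NucLibrary, k: int = 4, weight_by_reads: bool = True
) -> pd.DataFrame:
    """Periodicity statistics for all 4**k k-mers of a library.

    One row per literal k-mer (period_max, FVO_MAX, FVO_10.2, %FTS_10.2,
    phase, mean frequency), plus FVO_10.2 normalized by the mean FVO_10.2
    over all k-mers.  Zero-occurrence k-mers report FVO 0 and NaN phase.
    """
    F = count_all_kmers(library, k, weight_by_reads=weight_by_reads)
    df = batch_stats(F, labels=all_kmers(k))
    mean_fvo = df["fvo_10_2"].mean()
    df["fvo_10_2_rel"] = df["fvo_10_2"] / mean_fvo if mean_fvo > 0 else np.nan
    return df


def tetra_stats_table(library: NucLibrary, weight_by_reads: bool = True) -> pd.DataFrame:
    return kmer_stats_table(library, 4, weight_by_reads)


def di_stats_table(library: NucLibrary, weight_by_reads: bool = True) -> pd.DataFrame:
    return kmer_stats_table(library, 2, weight_by_reads)


def mean_kmer_fvo(library: NucLibrary, k: int = 4, weight_by_reads: bool = True) -> float:
    """Mean FVO_10.2 over all 4**k k-mers (zero-occurrence k-mers count 0)."""
    return float(kmer_stats_table(library, k, weight_by_reads)["fvo_10_2"].mean())


# ---------------------------------------------------------------------------
# read stratification


def stratify_by_reads(
    library: NucLibrary,
    thresholds: Sequence[int] = (0, 1, 2, 4, 6),
    k: int = 4,
) -> pd.DataFrame:
    """Mean k-mer FVO_10.2 of the sub-libraries with reads > threshold.

    Thresholds beyond the maximum read count yield NaN (missing), not zero.
    """
    rows = []
    for thr in thresholds:
        keep = library.weights > thr
        if not keep.any():
            rows.append((thr, 0, 0, np.nan))
            continue
        sub = library.subset(keep)
        rows.append((thr, sub.n, sub.total_weight, mean_kmer_fvo(sub, k)))
    return pd.DataFrame(rows, columns=["threshold", "n_sequences", "total_weight", "mean_fvo"])


# ---------------------------------------------------------------------------
# consensus decomposition


def decomposition_analysis(
    library: NucLibrary,
    members: Sequence[str] | None = None,
    k: int = 4,
    weight_by_reads: bool = True,
) -> pd.DataFrame:
    """Mean k-mer FVO versus period for the unmodified library and its
    consensus-only / no-consensus X-masked derivatives.

    Returns a DataFrame indexed by period (bp) with one column per library
    mode.  K-mers with zero occurrences contribute FVO 0 (they carry no
    signal); a fully masked degenerate library is reported as all-zero and
    logged.
    """
    if members is None:
        members = consensus_members()
    libs = {
        "unmodified": library,
        "consensus_only": mask_library(library, members, "consensus_only"),
        "no_consensus": mask_library(library, members, "no_consensus"),
    }
    out = {}
    for mode, lib in libs.items():
        F = count_all_kmers(lib, k, weight_by_reads=weight_by_reads)
        coeff, fbar = batch_spectrum(F)
        safe = np.where(fbar > 0, fbar, np.inf)
        curves = 2.0 * np.abs(coeff) / (N_WINDOW * safe[:, None])
        if not (fbar > 0).any():
            log.warning("decomposition: %s library has no k-mer occurrences", mode)
        out[mode] = curves.mean(axis=0)
    df = pd.DataFrame(out, index=pd.Index(C_CONSTANT / H_GRID, name="period"))
    return df


# ---------------------------------------------------------------------------
# mutation panel


def kmers_centered(octamer: str) -> tuple[str, str, str, str]:
    """The centered 8-, 6-, 4- and 2-mers of an octamer (nested substrings)."""
    word = octamer.upper()
    if len(word) != 8:
        raise ValueError(f"octamer of length 8 expected, got {octamer!r}")
    return word, word[1:7], word[2:6], word[3:5]


def mutation_series(
    library: NucLibrary,
    rows: pd.DataFrame | None = None,
    lengths: tuple[int, ...] = (8, 6, 4, 2),
    subset: Sequence[str] | None = None,
    weight_by_reads: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FVO_10.2 of each construct's centered k-mers, with Pearson correlations.

    ``rows`` needs columns construct/octamer/dG/pct67 (defaults to the
    published fragment-67 panel).  Occurrences of the reverse complement
    are added for every non-palindromic k-mer.  Returns (per-construct
    table, correlation table with one row per k-mer length: Pearson r of
    dG vs FVO and pct67 vs FVO across constructs).
    """
    if rows is None:
        rows = FRAGMENT67_PANEL
    if subset is not None:
        rows = rows[rows["construct"].isin(subset)]
    if len(rows) < 3:
        raise ValueError("need at least 3 constructs for correlations")
    records = []
    for _, row in rows.iterrows():
        kmers = kmers_centered(row["octamer"])
        rec = {"construct": row["construct"], "octamer": row["octamer"],
               "dG": row["dG"], "pct67": row["pct67"]}
        for kmer in kmers:
            spec = MotifSpec((kmer,), include_revcomp=True)
            profile = count_profile(library, spec, weight_by_reads=weight_by_reads)
            stats = periodicity_stats(profile)
            rec[f"fvo_{len(kmer)}"] = stats.fvo_10_2
        records.append(rec)
    table = pd.DataFrame(records)
    corr_rows = []
    for L in lengths:
        col = table[f"fvo_{L}"]
        corr_rows.append((L, _pearson(table["dG"], col), _pearson(table["pct67"], col)))
    corrs = pd.DataFrame(corr_rows, columns=["length", "r_dG_vs_fvo", "r_pct67_vs_fvo"])
    return table, corrs


def panel_correlations(
    rows: pd.DataFrame | None = None, include_wild_type: bool = True
) -> tuple[float, float]:
    """Pearson correlations of the printed panel columns themselves:
    (dG vs printed FVO, pct67 vs printed FVO)."""
    if rows is None:
        rows = FRAGMENT67_PANEL
    if not include_wild_type:
        rows = rows[rows["construct"] != "67"]
    r_dg = sps.pearsonr(rows["dG"], rows["fvo_printed"])[0]
    r_pct = sps.pearsonr(rows["pct67"], rows["fvo_printed"])[0]
    return float(r_dg), float(r_pct)


# ---------------------------------------------------------------------------
# isolated A/T tracts


def atract_comparison(
    library: NucLibrary, weight_by_reads: bool = True
) -> dict[str, dict]:
    """Profiles and stats for the three A/T-step decompositions:

    all_steps      — every AA and TT dinucleotide, including those inside runs
    isolated_steps — AA/TT isolated by C or G on both sides
    oligo_tracts   — exact-length isolated A/T runs of 3, 4 and 5 summed

    Each entry holds the raw profile, the normalized profile (None when the
    profile has no counts, flagged ``empty``) and its periodicity stats.
    """
    all_steps = count_profile(library, MotifSpec(("AA", "TT"), label="AA/TT"),
                              weight_by_reads=weight_by_reads)
    isolated = count_isolated_run(library, "A", 2, "S", paired=True,
                                  weight_by_reads=weight_by_reads)
    tract_f = None
    for n in (3, 4, 5):
        p = count_isolated_run(library, "A", n, "S", paired=True,
                               weight_by_reads=weight_by_reads)
        tract_f = p.f if tract_f is None else tract_f + p.f
    tracts = OccurrenceProfile("oligo A3-A5/T3-T5", tract_f,
                               total_weight=all_steps.total_weight)
    out = {}
    for name, profile in (
        ("all_steps", all_steps),
        ("isolated_steps", isolated),
        ("oligo_tracts", tracts),
    ):
        empty = not profile.f.any()
        out[name] = {
            "profile": profile,
            "normalized": None if empty else normalize(profile),
            "stats": None if empty else periodicity_stats(profile),
            "empty": empty,
        }
        if empty:
            log.warning("atract_comparison: %s profile has no counts", name)
    return out


# ---------------------------------------------------------------------------
# phase adjustment


def phase_adjust(
    library: NucLibrary,
    probe: str = "AAAA",
    target: float = 180.0,
    shift: int = 5,
    tolerance: float = 45.0,
) -> NucLibrary:
    """Shift an out-of-phase library so the probe motif reaches the target
    phase (default: AAAA at +/-180 deg, the minor-groove-in setting).

    The probe is counted together with its reverse complement, so its phase
    is ~0 or ~+/-180 by construction.  If the phase is farther than
    ``tolerance`` from the target, every sequence is shifted by ``shift``
    bp in the direction that minimizes the residual, trimming one end and
    padding the other with N.  The applied shift lands in
    ``metadata['phase_shift']``.
    """

    def probe_phase(lib: NucLibrary) -> float:
        profile = count_profile(lib, MotifSpec((probe,), include_revcomp=True))
        return phase_angle(fourier_spectrum(profile))

    def distance(theta: float) -> float:
        d = abs((theta - target + 180.0) % 360.0 - 180.0)
        # target +/-180 is a single point on the circle
        if abs(target) == 180.0:
            d = min(d, abs((theta + target + 180.0) % 360.0 - 180.0))
        return d

    theta0 = probe_phase(library)
    if distance(theta0) <= tolerance:
        out = library.subset(np.ones(library.n, dtype=bool))
        out.metadata["phase_shift"] = 0
        return out

    candidates = {}
    for delta in (shift, -shift):
        shifted = _shift_library(library, delta)
        candidates[delta] = (distance(probe_phase(shifted)), shifted)
    best = min(candidates, key=lambda d: candidates[d][0])
    residual, out = candidates[best]
    if residual > tolerance:
        log.warning(
            "phase_adjust: residual probe misphase %.1f deg after %+d bp shift",
            residual, best,
        )
    out.metadata["phase_shift"] = best
    return out


def _shift_library(library: NucLibrary, delta: int) -> NucLibrary:
    """Shift sequence content by delta bp (positive: toward higher
    positions), trimming and padding with N."""
    codes = np.full_like(library.codes, enc.N)
    if delta >= 0:
        codes[:, delta:] = library.codes[:, : library.length - delta]
    else:
        codes[:, :delta] = library.codes[:, -delta:]
    return NucLibrary(
        codes,
        library.weights.copy(),
        label=library.label,
        include_revcomp=library.include_revcomp,
        metadata=dict(library.metadata),
    )


# ---------------------------------------------------------------------------
# cross-library summaries


def cross_library_summary(
    tetra_stats: Mapping[str, pd.DataFrame],
    reference: str,
    di_stats: Mapping[str, pd.DataFrame] | None = None,
    sd_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-library summary statistics with exclusion rules applied.

    * mean/median tetranucleotide period over tetranucleotides whose
      FVO_MAX is within ``sd_factor`` SD below the library mean;
    * Pearson correlation of phase angles against the reference library,
      over tetranucleotides similarly retained by FVO_10.2 in *both*
      libraries (NaN when fewer than 3 are shared);
    * mean +/- SD of FVO_10.2 over all tetranucleotides;
    * ratio of mean tetranucleotide FVO to mean dinucleotide FVO when
      dinucleotide tables are supplied.
    """
    if reference not in tetra_stats:
        raise KeyError(f"reference library {reference!r} missing from stats")

    def retained(df: pd.DataFrame, column: str) -> pd.Index:
        cut = df[column].mean() - sd_factor * df[column].std()
        return df.index[df[column] >= cut]

    ref_df = tetra_stats[reference]
    ref_phase_kept = retained(ref_df, "fvo_10_2")
    rows = []
    for label, df in tetra_stats.items():
        period_kept = retained(df, "fvo_max")
        periods = df.loc[period_kept, "period_max"]
        shared = retained(df, "fvo_10_2").intersection(ref_phase_kept)
        r = _pearson(df.loc[shared, "phase_deg"], ref_df.loc[shared, "phase_deg"])
        row = {
            "library": label,
            "mean_period": periods.mean(),
            "median_period": periods.median(),
            "phase_corr_vs_ref": r,
            "mean_tetra_fvo": df["fvo_10_2"].mean(),
            "sd_tetra_fvo": df["fvo_10_2"].std(),
        }
        if di_stats is not None:
            mean_di = di_stats[label]["fvo_10_2"].mean()
            row["fvo_ratio_tetra_over_di"] = (
                row["mean_tetra_fvo"] / mean_di if mean_di > 0 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("library")
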