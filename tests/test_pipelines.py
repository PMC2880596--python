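"""Composite study pipelines: panel correlations, stratification,
phase adjustment, A/T tracts, cross-library summaries."""

import numpy as np
import pandas as pd
import pytest

from nucperiod import (
    FRAGMENT67_PANEL,
    MotifSpec,
    NucLibrary,
    PlantedMotif,
    ReadModel,
    SimConfig,
    add_reverse_complements,
    atract_comparison,
    count_profile,
    cross_library_summary,
    di_stats_table,
    kmers_centered,
    mean_kmer_fvo,
    mutation_series,
    panel_correlations,
    phase_adjust,
    simulate_library,
    stratify_by_reads,
    tetra_stats_table,
)
from nucperiod.pipelines import FRAGMENT67_PANEL as PANEL

from conftest import random_library


class TestPanel:
    def test_printed_column_correlations(self):
        r_dg, r_pct = panel_correlations()
        assert r_dg == pytest.approx(-0.619, abs=0.005)
        assert r_pct == pytest.approx(0.755, abs=0.005)

    def test_wild_type_toggle_changes_values(self):
        with_wt = panel_correlations(include_wild_type=True)
        without = panel_correlations(include_wild_type=False)
        assert with_wt != without

    def test_panel_has_17_constructs(self):
        assert len(FRAGMENT67_PANEL) == 17


class TestKmersCentered:
    def test_fragment67_core_decomposition(self):
        assert kmers_centered("CTCTAGAG") == ("CTCTAGAG", "TCTAGA", "CTAG", "TA")

    def test_kmers_nest(self):
        kmers = kmers_centered("GGTTAAAA")
        for outer, inner in zip(kmers, kmers[1:]):
            assert inner in outer

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            kmers_centered("CTAG")


class TestMutationSeries:
    @staticmethod
    @pytest.fixture(scope="class")
    def library():
        # random background plus light planting of every octamer used in the
        # tests, so each one actually occurs in the library
        from nucperiod import simulate_mutation_panel

        octamers = ["CTCTAGAG", "GGTTAAAA", "TTTTAACC",
                    "CTCCAGAG", "CTCAAGAG", "CTCCCGAG", "CTCATGAG"]
        lib, _ = simulate_mutation_panel(
            octamers, {o: 0.3 for o in octamers},
            n_sequences=4000, mean_insertions=0.3, seed=77,
        )
        return lib

    def test_fvo_invariant_under_revcomp_of_octamer(self, library):
        rows = pd.DataFrame(
            {
                "construct": ["a", "b", "c"],
                "octamer": ["CTCTAGAG", "GGTTAAAA", "TTTTAACC"],
                "dG": [0, 100, 200],
                "pct67": [100, 80, 60],
            }
        )
        t1, _ = mutation_series(library, rows)
        rows2 = rows.copy()
        rows2["octamer"] = [
            o[::-1].translate(str.maketrans("ACGT", "TGCA")) for o in rows["octamer"]
        ]
        t2, _ = mutation_series(library, rows2)
        for L in (8, 6, 4, 2):
            np.testing.assert_allclose(t1[f"fvo_{L}"], t2[f"fvo_{L}"])

    def test_perfectly_linear_fvo_gives_unit_correlation(self, library):
        rows = PANEL.iloc[:5].copy()
        table, _ = mutation_series(library, rows)
        # substitute a synthetic response exactly linear in dG and recompute r
        table = table.copy()
        table["fvo_8"] = 1.0 - 0.001 * table["dG"]
        r = np.corrcoef(table["dG"], table["fvo_8"])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_too_few_constructs_rejected(self, library):
        with pytest.raises(ValueError):
            mutation_series(library, PANEL.iloc[:2])


class TestStratification:
    def test_threshold_zero_reproduces_full_library(self, rng):
        lib = random_library(40, rng)
        df = stratify_by_reads(lib, thresholds=(0,), k=2)
        assert df["mean_fvo"].iloc[0] == pytest.approx(mean_kmer_fvo(lib, 2))

    def test_threshold_beyond_max_reads_is_missing(self, rng):
        lib = random_library(10, rng, max_weight=3)
        df = stratify_by_reads(lib, thresholds=(0, 99), k=2)
        assert np.isnan(df["mean_fvo"].iloc[1])
        assert df["n_sequences"].iloc[1] == 0

    def test_affinity_coupled_reads_give_nondecreasing_mean_fvo(self):
        config = SimConfig(
            n_sequences=6000,
            planted=(PlantedMotif("CTAG", amplitude=0.4, mean_insertions=2.0),),
            read_model=ReadModel(kind="affinity", base=0.3, gain=1.2),
            seed=21,
        )
        lib, _ = simulate_library(config)
        df = stratify_by_reads(lib, thresholds=(0, 1, 2, 3), k=4)
        fvo = df["mean_fvo"].dropna().to_numpy()
        assert (np.diff(fvo) > -0.002).all()  # non-decreasing up to noise
        assert fvo[-1] > fvo[0]


def test_weighted_counting_equals_duplication(rng):
    """Multiplying a weight by k is the same as duplicating the sequence."""
    seqs = ["".join(rng.choice(list("ACGT"), size=147)) for _ in range(6)]
    lib_w = NucLibrary.from_sequences(seqs, [3, 1, 1, 1, 1, 1])
    lib_dup = NucLibrary.from_sequences([seqs[0]] * 3 + seqs[1:], [1] * 8)
    for motif in ("TA", "CTAG"):
        np.testing.assert_array_equal(
            count_profile(lib_w, motif).f, count_profile(lib_dup, motif).f
        )
    pd.testing.assert_frame_equal(tetra_stats_table(lib_w), tetra_stats_table(lib_dup))


class TestATracts:
    def test_gc_only_library_flagged_empty(self):
        lib = NucLibrary.from_sequences(["GC" * 73 + "G"], [1])
        result = atract_comparison(lib)
        assert all(entry["empty"] for entry in result.values())

    def test_planted_a5_tracts_dominate_isolated_aa(self):
        """Periodic isolated A5 tracts with uniform isolated AA steps:
        tract FVO far exceeds the flat AA signal."""
        rng = np.random.default_rng(5)
        period = 2000 / 196
        starts_a5 = (2 + period * np.arange(12)).astype(int)
        seqs = []
        for _ in range(600):
            arr = rng.choice(list("GC"), size=147).tolist()
            for s in starts_a5:
                arr[s : s + 5] = list("AAAAA")
            # uniformly placed isolated AA well away from the A5 comb
            pos = int(rng.integers(110, 140))
            arr[pos : pos + 2] = list("AA")
            seqs.append("".join(arr))
        lib = NucLibrary.from_sequences(seqs)
        result = atract_comparison(lib)
        tract_fvo = result["oligo_tracts"]["stats"].fvo_10_2
        aa_fvo = result["isolated_steps"]["stats"].fvo_10_2
        assert tract_fvo > 5 * aa_fvo

    def test_all_steps_counts_steps_inside_runs(self):
        # AAAA contains three AA steps; the all-steps profile counts each
        lib = NucLibrary.from_sequences(["G" * 40 + "AAAA" + "G" * 103], [1])
        result = atract_comparison(lib)
        assert result["all_steps"]["profile"].f.sum() == 3


class TestPhaseAdjust:
    def _library(self, x0, n=3000, seed=3):
        config = SimConfig(
            n_sequences=n,
            planted=(PlantedMotif("AAAA", phase_position=x0, amplitude=0.5,
                                  mean_insertions=1.5),),
            seed=seed,
        )
        lib, _ = simulate_library(config)
        return lib

    def test_in_phase_library_left_unshifted(self):
        # start phase chosen so the AAAA counting-position maxima land at
        # half a period past the reference: probe phase = +/-180 exactly
        lib = self._library(x0=1 + 2000 / 392)
        adjusted = phase_adjust(lib)
        assert adjusted.metadata["phase_shift"] == 0
        assert adjusted.sequences == lib.sequences

    def test_five_bp_offset_detected_and_corrected(self):
        lib = self._library(x0=1 + 2000 / 392 + 5)
        adjusted = phase_adjust(lib)
        assert adjusted.metadata["phase_shift"] in (-5, 5)
        # probe phase restored near +/-180 after the shift
        from nucperiod import fourier_spectrum, phase_angle

        p = count_profile(adjusted, MotifSpec(("AAAA",), include_revcomp=True))
        theta = phase_angle(fourier_spectrum(p))
        assert 180.0 - abs(theta) < 45.0


class TestCrossLibrary:
    def test_self_comparison_is_identity(self, rng):
        lib = random_library(60, rng)
        tetra = {"a": tetra_stats_table(lib), "b": tetra_stats_table(lib)}
        di = {"a": di_stats_table(lib), "b": di_stats_table(lib)}
        out = cross_library_summary(tetra, "a", di)
        assert out.loc["b", "phase_corr_vs_ref"] == pytest.approx(1.0)
        assert out.loc["a", "mean_tetra_fvo"] == out.loc["b", "mean_tetra_fvo"]
        assert out.loc["a", "fvo_ratio_tetra_over_di"] == pytest.approx(
            out.loc["b", "fvo_ratio_tetra_over_di"], abs=1e-12
        )

    def test_shared_phases_with_different_amplitudes_correlate(self):
        """Two libraries planted with the full consensus set at identical
        rotational phases but different modulation depths: phase angles of
        the retained tetranucleotides stay tightly correlated."""
        from nucperiod.consensus import DEFAULT_GROUPS, canonical_tetra

        in_canon, out_canon, seen = [], [], set()
        for g in DEFAULT_GROUPS:
            for t in g.members():
                c = canonical_tetra(t)
                if c not in seen:
                    seen.add(c)
                    (in_canon if g.orientation == "in" else out_canon).append(c)
        period = 10.204

        def build(amp, seed):
            planted = tuple(
                PlantedMotif(m, period=period, phase_position=2.0,
                             amplitude=amp, mean_insertions=0.42)
                for m in in_canon
            ) + tuple(
                PlantedMotif(m, period=period, phase_position=2.0 + period / 2,
                             amplitude=amp, mean_insertions=0.30)
                for m in out_canon
            )
            lib, _ = simulate_library(
                SimConfig(n_sequences=30000, planted=planted, seed=seed)
            )
            return add_reverse_complements(lib)

        strong = tetra_stats_table(build(0.4, 31), weight_by_reads=False)
        weak = tetra_stats_table(build(0.2, 32), weight_by_reads=False)
        out = cross_library_summary({"ref": strong, "other": weak}, "ref")
        assert out.loc["other", "phase_corr_vs_ref"] > 0.95
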