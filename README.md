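# nucperiod

Periodicity analysis of nucleosome positioning sequence libraries.

Nucleosomal DNA — the 147 bp wrapped around a histone octamer — carries
sequence signals that help decide where nucleosomes sit on a genome.  The
classic signal is a ~10.2-bp periodic preference of certain dinucleotides
(AA/TT/TA) that tracks the helical repeat of bent DNA; at the
tetranucleotide level the signal resolves into a small set of consensus
motifs (YTAR, A<sub>n</sub>T<sub>m</sub>, RCGY, ...) whose flanking bases
determine whether the minor groove faces toward or away from the histone
surface.  `nucperiod` implements the full analysis chain for such
libraries:

* strand-aware extraction of 147-bp nucleosomal sequences from a genome
  plus a mapped-read coordinate table (5′-end or dyad-midpoint
  conventions), with per-sequence read weights;
* weighted occurrence profiles of arbitrary IUPAC motifs along the
  nucleosome, counted at a common center-position convention so motifs of
  different lengths share one positional axis;
* Fourier statistics of those profiles — FVO (fractional variation of
  occurrence), %FTS<sub>10.2</sub>, peak period and rotational phase angle;
* consensus-tetranucleotide selection, grouping, and X-masked library
  decomposition ("consensus only" vs "no consensus");
* composite studies: read-count stratification, the fragment-67
  octamer-mutation panel, isolated A/T-tract analysis, probe-based phase
  adjustment, and cross-library summaries;
* a synthetic-library generator that plants motifs with known period,
  phase, and amplitude, so every stage is testable against ground truth.

## The statistics

For a motif profile $f_x$ (weighted occurrences at positions $x=1..147$,
each occurrence counted at $x_{\mathrm{count}} = s + \lfloor (L-1)/2 \rfloor$
for a length-$L$ motif starting at $s$), the spectrum is evaluated over the
window $x = 3..144$:

$$C_h=\sum_{x=3}^{144}\left(f_x-\bar f\right)\,e^{-2\pi i h x / c},
\qquad c = 2000,\; h = 150..250,$$

so the period $c/h$ sweeps ~13.33 down to 8.0 bp with $h=196$ at the
10.2-bp helical repeat.  Derived quantities:

* $\mathrm{FVO}_h = 2\,|C_h| / (142\,\bar f)$ — the fractional amplitude
  of the oscillation; a pure cosine of fractional amplitude $a$ at period
  $c/h$ returns $\mathrm{FVO}=a$.  $\mathrm{FVO}_{10.2}$ uses $h=196$,
  $\mathrm{FVO}_{\mathrm{MAX}}$ the maximal-amplitude harmonic.
* $\%\mathrm{FTS}_{10.2}$ — percent of total spectral amplitude within
  9.8–10.6 bp; a significance filter for ~10-bp periodicity (threshold 19%).
* phase angle $\theta = \arg C_{196} + 2\pi\cdot 196\cdot 2/c$ (principal
  value, degrees) — referenced to position 2 (dyad-relative −72), so maxima
  at −72, −61.8, −51.6, … give $\theta = 0°$.  $\theta$ near ±180° means
  the motif's minor groove faces the histone surface ("in"), near 0° away
  from it ("out").

## Worked example

Generate a synthetic library with CTAG planted at a 10.204-bp positional
preference (fractional amplitude 0.3), then recover the signal:

```python
from nucperiod import (SimConfig, PlantedMotif, simulate_library,
                       count_profile, periodicity_stats)

config = SimConfig(
    n_sequences=20000,
    gc_content=0.39,
    planted=(PlantedMotif("CTAG", period=10.204, phase_position=2.0,
                          amplitude=0.3, mean_insertions=1.0),),
    seed=42,
)
library, truth = simulate_library(config)
stats = periodicity_stats(count_profile(library, "CTAG", weight_by_reads=False))
print(f"planted phase : {truth.true_phase_deg['CTAG']:8.2f} deg")
print(f"FVO_10.2      : {stats.fvo_10_2:8.3f}")
print(f"FVO_MAX       : {stats.fvo_max:8.3f} at {stats.period_max:.2f} bp")
print(f"%FTS_10.2     : {stats.pct_fts_10_2:8.1f} %")
print(f"phase angle   : {stats.phase_deg:8.2f} deg")
```

prints

```
planted phase :   -35.58 deg
FVO_10.2      :    0.194
FVO_MAX       :    0.194 at 10.20 bp
%FTS_10.2     :     53.4 %
phase angle   :   -33.70 deg
```

The peak period lands on the planted 10.20 bp and the phase angle is
recovered within 2° of the generator's ground truth.  The measured FVO
(0.194) sits below the planted amplitude (0.3) because chance background
occurrences of CTAG dilute the planted, position-modulated ones — the
same dilution real libraries exhibit.

The same analyses are available from the shell:

```bash
nucperiod simulate --n 20000 --motif CTAG:10.204:2.0:0.3:1.0 --seed 42 --out lib.tsv
nucperiod spectrum --library lib.tsv --motif CTAG --out spectrum.tsv
nucperiod tetra-table --library lib.tsv --out tetra.tsv
nucperiod mask --library lib.tsv --mode no_consensus --out masked.tsv
```

For real data, `nucperiod extract` consumes a FASTA genome plus a
BED-like TSV of mapped read coordinates (chromosome, 1-based coordinate,
strand, reads) in either the 5′-end or midpoint convention and writes the
147-bp weighted library used by all other commands.

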