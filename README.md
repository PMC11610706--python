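# g4screen

Analysis pipeline for a ¹H NMR screen of a 496-member G-quadruplex (G4)
variant library.

## The problem

G-quadruplexes are four-stranded nucleic-acid structures built from stacked
guanine tetrads. The usual consensus motif (G₃₊N₁₋₇G₃₊N₁₋₇G₃₊N₁₋₇G₃₊) is too
coarse: sequences that violate it can still fold into G4s (via
multimerization or slow folding), and sequences that match it can have very
different structures and biochemical activities. One way to study this is a
systematic variant library of a 17-nt monomeric reference G4 with three
stacked tetrads: every substitution of the four positions forming the
*central* tetrad (positions 2, 6, 11, 15; 4⁴ = 256 variants), plus every
loop variant over {A, C, T} at positions 4, 8, 9, 13 (3⁴ = 81) in three
tetrad backgrounds — the unmutated reference, a dimer-forming G→A mutant at
position 2, and a tetramer-forming G→A mutant at position 11. After merging
the three duplicates this yields 496 unique sequences. Screening each one by
1D ¹H NMR (imino-proton region, 10–12 ppm) sorts the library into spectral
classes with simple mutational signatures:

* both tetrad halves intact (GGGG) → the monomeric class **17.3**;
* first half (2, 6) intact, second mutated → the tetramer class **17.63**;
* second half (11, 15) intact, first mutated → the dimer family **17.4 /
  17.4s26 / 17.4+17.4s26**, split by the number of adenosines at loop
  positions 4, 8, 9;
* specific cross-half double mutants → **17.49** (GHHG), **17.28/17.36**
  (HGGH, GHGH, TGGT);
* specific 3–4-mutation signatures → **17.180** (NAAA/AAAN), **17.154**
  (HAHG); most other heavily mutated sequences show no G4 signals.

Classes are also functionally coherent: five activities per sequence
(intrinsic fluorescence Flu, tetramer formation Tet, dimer formation Dim,
peroxidase-mimicking activity Per, GTP binding GTP) have much smaller
relative standard deviation within a class than across random groups.

The package is for structural-bioinformatics users who want to reproduce,
extend or stress-test this screen's analysis: it enumerates and classifies
the library exactly, and — because the raw spectra are not deposited — runs
every downstream stage (peak picking, spectral clustering, ion-exchange peak
typing, activity profiling) on class-conditioned synthetic data whose
qualitative structure matches the screen's description.

## What's inside

| module | role |
| --- | --- |
| `g4screen.library` | enumerate the 496-member library, annotate mutational signatures, assign rule-based classes, IUPAC pattern matching |
| `g4screen.simulate` | synthetic ¹H spectra (Lorentzian imino peaks + noise), ion-exchange chromatograms, five-activity tables, all class-conditioned and seed-reproducible |
| `g4screen.spectra` | trim to 10–12 ppm, 0–1 scaling, robust noise estimation, empty-spectrum filter, peak picking, two-timepoint comparison for slow folders |
| `g4screen.cluster` | distance matrices, agglomerative clustering, adjusted Rand index / purity vs rule classes |
| `g4screen.ionex` | chromatogram peak detection and elution-window typing (monomeric 7.7–9.0 mL, dimeric 6.1–6.7, tetrameric 6.8–7.4, non-G4 5.1–5.4, many-mutations 5.55–5.7) |
| `g4screen.profiles` | class activity means renormalized 0–100, radar export, within-class RSD permutation test |
| `g4screen.pipeline` / `g4screen.cli` | end-to-end orchestration with a YAML config and a `g4screen` command |

## Worked example

```python
from g4screen import enumerate_library, count_by_tetrad_mutations, match_tetrad_pattern
import collections

lib = enumerate_library()
print(f"library size: {len(lib)}")
print(f"unmutated central tetrad: {count_by_tetrad_mutations(lib, {0})}")
print(f"single tetrad mutation:   {count_by_tetrad_mutations(lib, {1})}")
print(f"three or four mutations:  {count_by_tetrad_mutations(lib, {3,4})}")
print(f"NAAA or AAAN signatures:  {len(match_tetrad_pattern(lib, 'NAAA', 'AAAN'))}")
for cls, n in collections.Counter(r.class_label.major.value for r in lib).most_common():
    print(f"  {cls:<14} {n}")
```

prints

```
library size: 496
unmutated central tetrad: 81
single tetrad mutation:   172
three or four mutations:  189
NAAA or AAAN signatures:  7
  no_G4_signals  174
  17.63          95
  17.3           81
  17.4s26        59
  17.4           18
  17.4+17.4s26   18
  17.36          10
  no_pattern     9
  17.49          9
  17.154         8
  17.28          8
  17.180         7
```

The counts are exact consequences of the design rules: 81 sequences keep the
central tetrad intact (the reference and 80 others, 16.3 % of the library),
172 carry exactly one tetrad mutation, 189 carry three or four, and exactly
seven match NAAA or AAAN at the tetrad positions. Note two known gaps
between the rule classifier and the experimentally curated classes: the
GHHG rule admits 9 candidates where the screen curated 6 members of 17.49,
and HAHG admits 8 (after NAAA/AAAN takes AAAG) where the screen curated 6 —
those memberships are data-driven and not derivable from sequence alone.

The full synthetic screen runs in a few seconds:

```sh
g4screen run --seed 1 --out-dir run1
```

which enumerates the library, simulates one spectrum per sequence from its
class template, filters the 174 no-signal spectra, clusters the remaining
322 and scores them against the rule classes (ARI ≈ 0.93 at seed 1), types
one chromatogram per class (12/12 state sets recovered), and writes
renormalized activity profiles plus a run manifest with per-file SHA-256
hashes.

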