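# Methods

## Library model

The library is defined over a 17-nt scaffold whose reference sequence folds
into a monomeric, three-tetrad G-quadruplex. Position conventions are
1-based: tetrad layers (1,5,10,14), (2,6,11,15), (3,7,12,16); loops at
(4,8,9,13); a 3′ tail at 17. The exact loop bases of the reference are a
configuration value; the default scaffold `GGGTGGGTTGGGTGGGA` uses T at the
loop positions and A at the tail. Every count the package reports (496
members, the 81/172/54/189 mutation partition, the 7 NAAA/AAAN matches) is
invariant to this choice because the design rules only constrain tetrad and
loop positions, not the identity of the reference loops.

Enumeration produces 256 central-tetrad variants plus 3 × 81 loop variants
(loops drawn from {A,C,T}; backgrounds GGGG, AGGG-at-2, GGAG-at-11) and
merges exact string duplicates — the all-reference-loop member of each loop
sub-library coincides with one tetrad-sub-library entry, so 499 raw records
collapse to 496. A merged record keeps the tetrad-library id as canonical
and all sub-library tags.

## Rule-based classification

Classes follow the mutational-signature rules, applied in a fixed priority:
GGGG → 17.3; first half (2,6) intact → 17.63; second half (11,15) intact →
the 17.4 family; then the cross-half double-mutant patterns GHHG → 17.49,
HGGH → 17.28, GHGH → 17.36; then NAAA/AAAN → 17.180 and HAHG → 17.154; then
any remaining 3–4-mutation sequence → no G4 signals; everything else → no
clear pattern. Decisions that the signature alone cannot settle are made
deterministically and the alternatives recorded on the label rather than
dropped:

* HGGH is claimed by both 17.28 and 17.36; we assign 17.28 and record 17.36
  as an ambiguous alternative. TGGT is a curated exception assigned to
  17.36 (configurable via `tggt_to_17_36`).
* Within the dimer-background loop sub-library, the adenosine count at loop
  positions 4, 8, 9 refines the 17.4 family. The curated ranges overlap
  (17.4s26: 0–1 A; mixed class: 1–2 A; 17.4: 2–3 A), so the classifier uses
  the deterministic split 0–1 → 17.4s26 (recording the mixed class as an
  alternative at 1 A), 2 → 17.4+17.4s26 (recording 17.4), 3 → 17.4. The
  refinement applies only to records whose primary sub-library is the
  dimer-background loop library; the canonical dimer-former itself (tetrad
  AGGG with reference loops) is a merged duplicate with the tetrad tag
  primary and stays plain 17.4.
* Because AAAG matches both AAAN and HAHG and the NAAA/AAAN rule fires
  first, the HAHG rule labels 8 sequences; the curated 17.154 class has 6
  and the curated 17.49 class has 6 of the 9 GHHG candidates. Those
  memberships are data-driven; no sequence-level criterion reproduces them,
  so the classifier reports the full combinatorial sets.

## Synthetic data

No raw screen data are deposited, so the generator produces
class-conditioned stand-ins sufficient to exercise and validate the
pipeline; the templates are caricatures of the described class spectra, not
spectral predictions.

**Spectra.** The imino region 10–12 ppm is simulated on a 2048-point grid
with Lorentzian lines (default FWHM 0.02 ppm) plus additive white Gaussian
noise (default SD 0.01; SNR is peak height over noise SD). Each class has a
fixed chemical-shift fingerprint derived by hashing the class name, so
members of one class share peak positions (±0.003 ppm per-sample jitter)
while classes differ — the separability the clustering stage relies on.
Fingerprint positions are spread evenly across the class span and perturbed
by at most 15 % of the spacing, which keeps every pair of peaks resolvable
at the default linewidth and keeps all positions inside the window (a peak
clipped to the window edge would not be a local maximum, silently breaking
count round-trips). Per-class parameters encode the described contrasts:
17.3 twelve sharp high-SNR peaks; 17.4 four-to-six peaks within ≤0.8 ppm;
17.4s26 eleven-to-thirteen weaker peaks over 1.5 ppm; the mixed class the
union of both parents' fingerprints (near-coincident peaks deduplicated at
0.05 ppm); 17.63 two-to-four broad (3× linewidth) weak peaks; 17.28 up to
eleven; 17.180/17.154 at most four; "no pattern" a fresh random fingerprint
per sample; "no G4 signals" pure noise. What passing tests show is that the
pipeline recovers class structure of this kind at these SNRs — not that it
would resolve the overlapping, ridge-lined spectra of real multimeric G4s,
which have baseline distortions, shift drift and salt/temperature effects
the generator does not model.

**Chromatograms.** One Gaussian peak (SD 0.05 mL) per multimeric state,
apex drawn uniformly inside the state's elution window shrunk by a small
margin (≤0.05 mL) so that grid snapping cannot push a detected apex across
a window edge; axis 4.5–10 mL, 1100 points; same noise model as spectra.

**Activities.** Five activities per sequence drawn
Normal(μ_class, RSD·μ_class), clipped at zero, default within-class RSD
0.1. Means are in arbitrary units with background 1.0 — only ratios and
orderings are meaningful. The default table encodes the screen's
qualitative profile: 17.3 maximal Flu and Per and high GTP; 17.63 high Tet
with GTP 12-fold that of 17.4 and Per 3-fold lower than 17.4; the 17.4
family high Dim; 17.49 intermediate Flu/Per/GTP; heavily mutated classes at
background.

All generators consume a caller-supplied `numpy.random.Generator`; identical
seed and config give bit-identical outputs. Class fingerprints deliberately
do not depend on the user seed, so "what does class X look like" is stable
across experiments.

## Preprocessing and detection choices

* Noise SD is estimated robustly as 1.4826 × MAD of first differences / √2,
  which ignores sparse peaks; on 2048 points of Gaussian noise it is within
  15 % of the true SD.
* The empty-spectrum filter and the peak picker measure height from the
  baseline (median intensity), not from zero, with a default threshold of
  5 × noise SD. Baseline-relative heights matter because 0–1 scaling maps
  the most negative noise excursion to zero, lifting the noise floor by
  roughly 3σ; an absolute threshold then misclassifies baseline noise as
  peaks. On raw, zero-baseline spectra the two conventions coincide. The
  5σ threshold and the 0.03 ppm merge radius are declared surrogates for
  the screen's manual "no signals" judgement and are exposed in config.
* Peaks closer than the merge radius are merged keeping the higher; the
  chromatogram analogue uses a 0.1 mL radius. Window bounds are inclusive
  and gap volumes are reported `unclassified` rather than snapped.
* Timepoint comparison interpolates both spectra linearly onto the coarser
  common grid and scores 1 − Pearson r, clipped to [0,1], flagging change
  above 0.2; flat-vs-structured pairs score 1. This flags slow folders
  without fitting kinetics.

## Clustering

Distances are Euclidean (default) or correlation (1 − r, affine-invariant)
over 0–1-scaled spectra on a shared grid; clustering is scipy agglomerative
(average linkage by default) on the precomputed matrix. The tree is cut
after exactly n − k merges (`cut_tree`), which yields k clusters even when
merge heights tie; ties merge the lowest-index pair first, so results are
deterministic. k is either supplied, set to the number of distinct rule
classes (pipeline default), or chosen by silhouette over 2–15. Agreement
with rule classes is reported as adjusted Rand index and purity. Spectra
failing the signal filter never enter the distance matrix.

## Homogeneity test

Within-class RSD (sample SD / mean) is compared against the RSD of
`n_perm` random same-size groups drawn without replacement from the whole
table; the one-sided p-value uses add-one smoothing,
(1 + #{null ≤ observed}) / (1 + n_perm). Under shuffled class labels the
p-values are approximately uniform (checked by a KS test across 200 runs).
Renormalization of class means anchors 0 at zero activity and 100 at the
maximum class mean per activity — pure scaling with no minimum subtraction,
since the activities are nonnegative with a meaningful zero; ties leave all
tied classes at 100.

## Problem sizes

Default test and validation sizes: 10 spectra per structured class × 10
classes over 20 seeds for clustering recovery; 200 simulated traces for
ion-exchange round-trips; 100 sequences per class for activity contrasts;
200 shuffled-label runs × 199 permutations for null calibration. The full
496-sequence pipeline runs end to end in a few seconds.

## Known limitations

* The rule classifier reproduces the combinatorial class definitions, not
  the curated memberships of 17.49/17.154/17.36 (data-driven) nor the
  once-mentioned class 17.118 (no defining pattern available).
* Spectral templates are qualitative; subclass structure (e.g. the four
  17.3 subclasses) is not modelled, and second-stage subclustering is
  provided but unvalidated.
* No folding-kinetics modelling: timepoints are compared, rates are not
  fitted. No baseline correction by default (synthetic spectra are
  baseline-free); `subtract_rolling_min` provides an optional
  rolling-minimum correction for instrument exports with slow drift.
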