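# Methods

This note documents the models, parameter choices and numerical details
behind `hismethyl`, and what the synthetic-data tests do and do not show
about real data.

## Mass chemistry

All masses derive from one table of elemental monoisotopic masses and
isotope abundances (`chem.ISOTOPES`); residue masses are summed from
elemental compositions, never hard-coded. The methyl-histidine
modification is modelled as a net CH₂ addition (the methyl replaces an
imidazole N–H hydrogen), so its delta is m(C) + 2·m(H) = 14.015650 Da by
construction. τ- and π-methylation are isobaric; the package makes no
isomer claim. The diagnostic immonium ion uses the standard a1-type
model, residue − CO + proton, which gives m/z 124.0869 for methyl-His.
Fragment ions are b/y only, consistent with CID/HCD of tryptic peptides;
a/c/x/z series, neutral losses and semi-tryptic peptides are out of
scope. Digestion follows the Trypsin/P convention (cleavage after K/R
even before proline) or LysC (after K), with 0–2 missed cleavages by
default. Coordinates are 1-based inclusive throughout so that the mature
N-terminus after signal-peptide trimming is His1.

Isotope envelopes are computed exactly by convolving per-element isotope
distributions (polynomial expansion) over the peptide's elemental
composition, truncated to the requested number of peaks; truncation does
not affect the retained probabilities, which therefore sum to ≤ 1.

## MS/MS site localization

The localizer scores a spectrum against the methylated-His1 and
unmethylated hypotheses. Score = matched theoretical ions / all
theoretical ions, with each theoretical ion matched to its nearest peak
within the fragment tolerance (default 20 ppm; one peak may satisfy
several isobaric ions). A probabilistic search-engine score is
deliberately not reimplemented: the localization argument rests on
fragment coverage plus the diagnostic ion, and the matched-ion fraction
captures both testably. The winning hypothesis must exceed the other by
a margin (default 0.25; the full b-series shift between the two
hypotheses separates clean spectra by ≈ 0.5, so 0.25 tolerates moderate
peak loss without allowing coin-flip calls), and a methylated call
additionally requires the diagnostic ion (policy flag, default on; the
diagnostic ion is corroborating rather than primary evidence, so the
flag can be disabled). Any matched diagnostic peak counts regardless of
intensity — no intensity threshold is imposed. Only singly charged
fragments are matched by default, matching the simulated spectra and
keeping the brute-force test oracle simple.

## PRM screen

Traces are integrated trapezoidally after subtracting the per-trace
minimum (the simplest shift-invariant baseline). Target quantities are
the sums of fragment peak areas. Detection uses an explicit threshold,
default 5× the median summed area of blank (noise-only) trace sets — an
auditable stand-in for manual "unambiguous observation". The decision
rule is total over the four (methylated, unmethylated) detection flag
combinations: methylated detected → not a hit; only unmethylated
detected → NHMT hit; neither → inconclusive (substrate not expressed).
No retention-time alignment across strains is performed; simulated
panels share an apex. Areas are reported unnormalized across strains.

## Stoichiometry

The methylated fraction is Σ(methylated M..M+2 areas) / Σ(both forms).
The first three isotopologues of a single charge state are used — they
dominate for tryptic peptides — and no envelope deconvolution between
forms is applied, since the precursor Δm/z at the peptide level is
large. Replicates are summarized per-sample-then-averaged (mean and
sample SD, ddof = 1); a pair with zero total area is flagged undefined
and excluded from the summary.

## Differential abundance

Proteins must be observed in ≥ 2 replicates of at least one condition;
intensities are log2-transformed; missing values are imputed per sample
from Normal(mean − 1.8·SD, 0.3·SD) computed on that sample's observed
values (a left-censoring model: intensity-dependent missingness is
drawn from the distribution's low tail). Reporter-intensity (isobaric)
matrices are quantile-normalized (tie-aware average ranks, per-rank row
means) before transformation instead of being imputed.

The test statistic is an equal-variance Student t with an s0 offset
added to the pooled standard error (default s0 = 0.1 on the log2 scale,
configurable; s0 = 0 recovers the textbook t for hand-checkable tests).
Student rather than Welch is used to match the conventional
implementation of this workflow. Significance is decided by permuting
condition labels (default 250 permutations, or all distinct assignments
when fewer; below 10 distinct assignments a warning is raised and the
space is enumerated): for a candidate cutoff c, FDR(c) = median over
permutations of #{|t_perm| ≥ c} divided by #{|t_obs| ≥ c}; the median
(not the mean) makes tests deterministic under seeding. The chosen
cutoff is the smallest c with FDR(c) ≤ α, i.e. the largest significant
set at that FDR; if none qualifies nothing is significant. Reported
p-values come from the t distribution of the (possibly s0-moderated)
statistic and are descriptive; significance flags come only from the
permutation FDR.

## Candidate funnel

The funnel applies, in order: keep annotated methyltransferases
(keyword ruleset over annotation terms, defaults "methyltransferase",
"SAM", "S-adenosyl", case-insensitive substring, user-editable); keep
proteins identified in the data; keep significantly upregulated ones
(significant flag AND positive log2 fold change toward the
cellulose-like condition); drop predicted O-acceptor methyltransferases
(unknown acceptor atoms are retained); drop candidates with homologs in
S. cerevisiae / K. phaffii (yeasts incapable of the modification); keep
candidates unique to LPMO-encoding fungi; finally union with manually
curated additions. Acceptor-atom, homology and uniqueness calls are
*inputs*: they derive from external annotation/BLAST/phylogeny
resources that are outside this package's scope, and treating them as
inputs keeps the funnel honest about provenance. The report chains
count_in/count_out per stage; counts are non-increasing except at the
manual-addition stage.

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
each emits a truth record consumed only by tests, never by the pipeline.

* **Spectra** — peaks at all 1+ b/y m/z with multiplicative log-normal
  intensity variation (CV 0.3), Gaussian m/z jitter (default 5 ppm SD,
  emulating Orbitrap-class accuracy against the 20 ppm tolerance), the
  diagnostic immonium peak for methylated peptides, and uniform random
  noise peaks (default 10).
* **PRM panels** — Gaussian peaks in retention time (σ = 0.05 min,
  sampled every 0.01 min, shared apex; Gaussian is the simplest shape
  with a closed-form area, enabling an exact integration oracle). The
  methylated-form amplitude is the strain's true methylated fraction ×
  1000 (reference strains 1.0, the causal knockout 0.0); baseline noise
  is folded-normal with SD 1, giving a wide margin between blank areas
  and true peaks.
* **MS1 pairs** — three-peak areas proportional to form fraction × the
  per-form isotope pattern normalized over the monitored peaks, with
  mean-one log-normal noise (default CV 5%). Normalizing per form makes
  the noise-free round trip exact.
* **Abundance matrices** — protein baselines Normal(25, 2) on the log2
  scale (typical LFQ intensity magnitudes), replicate noise SD 0.5,
  4 + 4 design, 50/1000 planted upregulated proteins at +2 log2 units in
  the cellulose-like condition; values below each sample's 10% quantile
  are censored to missing (hard left-censoring).
* **Funnel cohorts** — flags constructed to realize a prescribed stage
  profile, default 225 → 120 → 41 → 34 → 28 → 19 (+5 manual = 24); the
  yeast-homolog stage's intermediate count (28) is a free choice since
  only its neighbours are constrained.

These simulations establish correctness of the implementations under
their own generative assumptions — planted-truth recovery, FDR control
under the global null, estimator bias — not performance on real
LC-MS/MS data, which additionally has correlated noise, co-eluting
interferences, retention-time drift, charge-state heterogeneity and
peptide-dependent ionization that the generators deliberately omit.

## Problem sizes and tolerances

Default test-suite scales: 200 spectra for localization accuracy
(≥ 0.95), 50 knockout panels of 22 strains (recall 1.0, zero false
hits), 100 seeds per point on the stoichiometry grid {0, 0.15, 0.30,
0.5, 1} (absolute bias < 0.02), 20 global-null matrices of 1000
proteins for FDR control, and 1e5 draws for the imputation moment check
(within 1%). Mass arithmetic is checked against an independent
residue-summation oracle to 1e-5 Da and the b/y complementarity
identity to 1e-6 Da; numerical trace integration is checked against the
closed-form Gaussian area to 1%. These sizes make the whole suite run
in a few seconds while leaving the Monte-Carlo margins comfortable.

## Known limitations

No open or full-database search, no target-decoy PSM FDR, no
modifications in the search space other than methyl-His, no protein
inference from peptides, no multi-condition ANOVA, no retention-time
alignment or spectral-library scoring, no vendor/mzML I/O. The
two knockout candidates that cannot be assayed in a real screen
(knockout failure) correspond here to expression-lost strains, which
the decision rule reports as inconclusive rather than negative.
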