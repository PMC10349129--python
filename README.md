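# hismethyl

A mass-spectrometry analysis pipeline for discovering and quantifying
**N-terminal histidine methylation** of fungal lytic polysaccharide
monooxygenases (LPMOs), the post-translational modification that protects
the copper-binding His1 of these enzymes from auto-oxidative damage.

It is aimed at proteomics bioinformaticians who want a tested, scriptable
re-implementation of the computational workflow behind an
N-terminal-histidine-methyltransferase (NHMT) knockout screen:

1. **Peptide chemistry** (`hismethyl.chem`) — monoisotopic mass arithmetic
   from a single atomic mass table: peptide and fragment-ion masses,
   tryptic (Trypsin/P) and LysC in-silico digestion with missed cleavages,
   signal-peptide trimming, and isotope envelopes by polynomial expansion
   of elemental isotope distributions. The methyl-His modification is a net
   CH₂ addition computed from atomic masses
   (Δm = m(C) + 2·m(H) = 14.0157 Da), and the diagnostic immonium ion of
   methylated histidine evaluates to m/z 124.0869
   (residue − CO + proton + CH₂).
2. **MS/MS localization** (`hismethyl.localize`) — matched-ion-fraction
   scoring of both site hypotheses (methylated His1 vs unmethylated) at a
   20 ppm fragment tolerance; a methylated call requires both a score
   margin and the diagnostic immonium ion.
3. **PRM knockout screen** (`hismethyl.prm`) — fragment chromatogram
   integration (trapezoidal, baseline-subtracted), summed-area target
   quantification, and the screen decision rule: a strain is an NHMT hit
   iff the methylated target peptide is undetected while the unmethylated
   form is unambiguously observed; neither form detected is inconclusive.
4. **Stoichiometry** (`hismethyl.stoich`) — methylated fraction from the
   summed MS1 areas of the first three isotopologues of the paired
   precursors: f = Σmeth / (Σmeth + Σunmeth).
5. **Differential abundance** (`hismethyl.diffexpr`) — observation-count
   filtering, log2 transform, left-censored ("downshifted normal",
   width 0.3 / downshift 1.8 in sample-SD units) imputation, quantile
   normalization for reporter intensities, and a two-sided two-sample
   t-test with an s0 variance offset whose significance cutoff is set by a
   permutation-based FDR at α = 0.05.
6. **Candidate funnel** (`hismethyl.funnel`) — staged elimination of
   methyltransferase candidates (annotation → identification →
   cellulose-upregulation → N-acceptor → no yeast homolog → unique to
   LPMO-encoding fungi → manual additions) with per-stage accounting.
7. **Synthetic data** (`hismethyl.synth`) — generators for every input
   (MGF spectra, PRM trace tables, MS1 area pairs, abundance matrices,
   funnel cohorts) with planted ground truth, all seeded and
   bit-reproducible.

## Worked example

Run the whole pipeline on a freshly simulated dataset:

```bash
hismethyl run-all --outdir demo --seed 1
```

prints

```
wrote synthetic inputs to demo
20 spectra, 10 methylated_H1 calls -> demo/psms.tsv
calls: {'nhmt_hit': 1, 'not_nhmt': 21, 'inconclusive': 0}; hits: ['KO_07']
mean methylated fraction 0.304 (SD 0.004) -> demo/stoichiometry.tsv
49 significant proteins at permutation FDR 0.05 -> demo/volcano.tsv
pipeline complete; outputs in demo
```

Reading the output: of 20 simulated MS/MS spectra of the X325-type LPMO
N-terminal peptide HTVIVYPGYR (half methylated), exactly the 10 methylated
ones are called `methylated_H1`. In the simulated 22-strain knockout panel
the PRM decision rule nominates only the planted causal knockout `KO_07` —
loss of the methylated form with concomitant appearance of the unmethylated
peptide. The MS1 stoichiometry of the simulated triplicates recovers the
planted 30% methylated fraction (0.304 ± 0.004), and the permutation-FDR
test calls 49 significant proteins in a 1000-protein matrix with 50 planted
upregulated methyltransferases. Each subcommand (`simulate`, `localize`,
`prm-screen`, `stoich`, `diffexpr`, `funnel`) can also be run on its own
files; `demo/truth.json` records the planted ground truth.

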