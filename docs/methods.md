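# Methods

## Problem and model

A cysteine-reactive small molecule forms an irreversible thioether with
its target protein. After tryptic digestion, the modified peptide
appears in MS/MS with the intact molecule's mass added to the cysteine:
the epoxide opens on the thiol with no atom loss, so the adduct is
modeled as addition of C20H26O4 (monoisotopic 330.1831 Da). During
standard sample preparation the *unmodified* state of the same cysteine
is carbamidomethylated by iodoacetamide (+57.0215 Da), which gives two
exploitable signatures:

1. the parent-ion mass of the adducted peptide exceeds that of its
   alkylated counterpart by 330.1831 − 57.0215 = 273.162 Da, and
2. a cysteine genuinely hit by the drug should be seen alkylated in
   vehicle-treated samples and adducted in drug-treated samples
   (*identified both*), at the same site.

All masses are monoisotopic (element table from NIST via pyteomics;
proton 1.00727646688 Da); average masses are never used.

## Search engine

**Digestion.** Full trypsin (cleave after K/R except before P), up to 2
missed cleavages, peptide length 6–40 residues. The length range and
the variable-modification cap (4 per peptide) are conventional search-
engine defaults, declared here as package defaults; the cap must be
≥ 3 because adduct peptides with three modified cysteines occur.

**Peptidoforms.** Target-identification mode searches carbamidomethyl
(C), the adduct (C), oxidation (M) and acetyl (protein N-terminus) as
variable modifications, one per site; quantification mode applies TMT
(K, peptide N-terminus) and carbamidomethyl statically with
oxidation/acetyl variable.

**Scoring.** XCorr in the fast single-pass formulation. Preprocessing:
square-root intensities, the spectrum's m/z range split into 10 regions,
each region's maximum normalized to 50. Peaks are binned at the
fragment tolerance (0.02 Da); theoretical b/y ions (charge 1) are placed
at intensity 50; the score is the dot product with the mean-subtracted
experimental vector (mean over ±75 bin offsets, offset 0 excluded),
scaled by 1e-4. This is a published, testable variant; absolute score
parity with any commercial implementation is out of scope, so published
reliability thresholds are applied to *this* statistic, and the packaged
candidate-table worked example uses its printed scores as given inputs.

**Precursor matching and ties.** Candidates within 10 ppm of the
observed neutral mass at the spectrum's charge are scored; the best PSM
is kept with deterministic tie-breaking (higher XCorr, then fewer
modifications, then lexicographic peptidoform string), making results
independent of database order.

**FDR.** Decoys are whole-protein sequence reversals (length and
composition preserved), digested and enumerated identically and
competing in the same search. q-values use the cumulative
decoys/targets ratio down the score ranking with a running minimum from
the bottom; acceptance at q ≤ 0.01.

## Screening funnel

Proteins with ≥ 1 accepted adduct PSM become candidates; the
highest-XCorr adduct PSM defines each record. Filters:

- *Reliability*: XCorr strictly above the charge-specific threshold
  (2.2 at z = 2, 3.75 at z = 3). Charges without a stated threshold
  fail closed — a conservative choice that only ever shrinks the
  surviving set.
- *Identified both*: keyed on (protein, peptide sequence, cysteine
  position in the protein), i.e. site-level, because protein-level
  matching would let an alkylation anywhere in the protein vouch for an
  adduct anywhere else.
- *Phenotype localization*: case-insensitive substring match of a
  keyword (default `mitochond`) against a per-protein annotation from
  the FASTA description (`location=`) or a sidecar TSV. No live
  database lookup.

Prioritization sorts by (reliability, identified-both, localization
match, XCorr descending), ties by protein name. Manual spectra-quality
curation has no algorithmic definition; the package exposes a stand-in:
an optional minimum fraction of theoretical b/y ions matched within
tolerance (default 0.5) that can drop low-coverage adduct PSMs before
candidate collection.

**Verification.** The parent-ion shift between the paired alkylated and
adducted PSMs is compared with 273.162 Da within 10 ppm of the heavier
precursor. Spectral similarity is the cosine of greedily aligned peak
lists (closest m/z pairs first, each peak used once, alignment
tolerance 0.25 m/z — a value the similarity is insensitive to at
centroid accuracy), after normalizing relative intensities to a maximum
of 100; unmatched peaks pair with zero.

## TMT arm

Channels are normalized by equalizing per-channel log2 medians to the
grand median. Differential expression uses a moderated two-sample t on
log2 intensities: per-protein pooled variances (4 df at n = 3 + 3) are
shrunk toward the mean variance with a prior weight of 10
pseudo-replicates, and p-values use t with 14 df. The count-model
packages common for this step assume integer data; a variance-moderated
t on log-intensities is self-contained and its calibration is verified
by simulation in the test suite (null mean false-discovery proportion
≤ 0.05; ≥ 90% power for 2-fold effects at 10% CV). Calls require both
FDR < 0.05 (Benjamini–Hochberg) and the linear fold-change criterion,
with 1.5 and 0.67 both taken literally (0.67 ≠ 1/1.5).

ORA uses the hypergeometric upper tail with BH across terms. GSEA is
the weighted Kolmogorov–Smirnov running sum (weight = |log2fc|); NES and
p come from ≥ 1000 gene-label permutations — phenotype permutation is
degenerate at n = 3 + 3.

## Synthetic data

Generators are pure functions of (config, seed). Proteins are built
from tryptic segments (5–11 random residues, no internal K/R, no
P after a cleavage site, then K or R), so every protein is guaranteed
peptides in the searched length range; the planted target carries a
unique cysteine inside one segment, never palindromic (decoys are
reversals). Defaults: 20 proteins, 150 spectra per group of which 10
are the planted peptide, adduct fraction 0.5 in the treated group —
small enough that a full end-to-end run takes ~2 s and 20 replicates
stay within a few minutes on one CPU, large enough that the funnel has
background competition. Noise defaults: 90% fragment sampling, 20%
intensity CV, 30 uniform noise peaks on [100, precursor m/z], 0.004 Da
m/z jitter (≤ fragment tolerance / 3). The TMT generator plants 20
up (2-fold) and 20 down (0.5-fold) proteins among 500 at 10% intensity
CV; mitochondrial-provenance mode additionally halves a 30-protein
subset, mimicking coordinated loss of respiratory-chain subunits.

What the generator does **not** emulate: retention time and
chromatography, isotope envelopes, co-isolation/reporter-ion
interference, fragment-charge > 1 ions, semi-tryptic peptides, and
realistic protein sequence composition (residues are uniform outside
the K/R spacing). Passing tests therefore demonstrate the correctness
and calibration of the algorithms under the stated generative model,
not instrument-level performance on real acquisitions.

## Numerical choices and edge cases

- Bin index = floor(m/z / 0.02 + 0.5); empty spectra score 0; spectra
  with no candidate in tolerance are logged and skipped, not errors.
- Greedy peak alignment sorts candidate pairs by |Δm/z| with index
  tie-breaks, making the similarity symmetric and deterministic.
- BH q-values come from statsmodels; hypergeometric and t tails from
  scipy.
- `ppm_within` is an exact inclusive comparison; degenerate inputs
  (non-positive theoretical mass, all-zero intensities, empty peak
  lists, groups with < 2 replicates, zero-intensity channels) raise
  `ValueError` rather than returning sentinel values.
- GSEA with an all-hit or zero-weight ranking falls back to unweighted
  steps; the empirical p uses the (1 + k)/(1 + B) estimator on
  same-sign permutations.

## Known limitations

XCorr values are comparable only within this implementation. The
identified-both criterion needs the control arm to sample the target
peptide; at low spectral depth it can fail even for a true target (the
prioritization then still ranks on reliability and localization). The
moderated t assumes roughly log-normal reporter intensities and shared
variance scale; heavy-tailed real data would need robust alternatives.
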