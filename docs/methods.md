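# Methods

`covadduct` re-implements, as reusable and tested code, the computational
core of a chemoproteomics workflow for discovering protein targets of the
electrophile sulforaphane (SFN) and characterising the dithiolethione-type
modification it induces on the phosphatase Shp2: spectral-count
differential enrichment, in-silico tryptic digestion with crosslink mass
search, and activity-assay numerics. This note records the models, the
defaults and why they were chosen, and what the synthetic data do and do
not demonstrate.

## Spectral-count enrichment (volcano statistic)

One PSM (peptide-spectrum match) is one unit of evidence. Identifications
are accepted when peptide probability > 0.90 (strict), protein probability
> 0.999 (strict), and the protein retains at least two PSMs (inclusive);
every rejection is logged, never silently dropped.

For a two-group design (default four control and four treated biological
replicates) counts are tallied per protein per sample. Per protein:

- x = log2(T/C) where T and C are the group PSM totals, a zero total
  being replaced by the 0.1 pseudocount. The pseudocount applies to
  *totals only*; the per-sample counts fed to the t test are untouched.
- p from a two-sided two-sample t test on the per-sample counts. Default
  is the pooled-variance Student test (the classic equal-n design); Welch
  is selectable. Degenerate variance is handled explicitly: all eight
  counts equal gives p = 1; both within-group variances zero with unequal
  means gives p = 0, reported at the y cap (default 16) to avoid NaN/inf
  propagation while preserving ordering.
- y = −log10(p) by default. The printed significance rule (y ≥ 1.3 at 95%
  confidence) is only internally consistent on the log10 scale, since
  1.3 ≈ −log10(0.05); natural log is available by configuration for
  readers who prefer that axis convention.

Significance is one-directional and inclusive: x ≥ 2 AND y ≥ 1.3
(at-least-fourfold enrichment in the treated direction). Proteins absent
from both groups have an undefined ratio and are excluded with a log
entry rather than pinned at x = 0.

## In-silico digestion and mass arithmetic

Trypsin is modelled strictly: cleavage C-terminal to K or R, suppressed
before proline — the default convention of the common search engines.
Peptides carry 1-based inclusive protein coordinates (the field's residue
numbering, e.g. Cys333), a missed-cleavage count recomputable from their
internal sites, and the protein coordinates of their cysteines. Defaults:
up to 3 missed cleavages (bridged-cysteine peptides are often only
reachable with missed cleavages), length 4–60. All masses are
monoisotopic; a peptide's neutral mass is the standard residue-mass sum
plus one water, and m/z = (M + z·m_proton)/z. The residue table is pinned
to the standard monoisotopic values and cross-checked in tests against an
independent implementation to 1e-5 Da.

## Crosslink search (non-cleavable linker model)

The adduct chemistry: the isothiocyanate group of SFN adds to a cysteine
thiol giving a dithiocarbamate; a second cysteine thiol attacks the
thiocarbamoyl carbon, expelling the SFN amine and leaving a one-carbon
thiocarbonyl bridge between the two cysteines (the dithiolethione-type
product). The shipped linker deltas follow from elemental arithmetic:

- mono-adduct (intact SFN on one Cys): +C6H11NOS2 = +177.028206 Da;
- bridge (two Cys): net +C +S −2H = +41.956421 Da on the summed peptide
  masses.

Both are `LinkerSpec` configuration values, not constants baked into the
search, because the bridge's exact neutral-loss stoichiometry is a
mechanistic inference; alternative compositions can be supplied by config.

Candidates enumerate every unordered pair of cysteine-containing peptides
(homodimeric pairs included), every Cys-by-Cys placement, loop-links
within a peptide carrying two or more cysteines, and optionally a
mono-adduct pass. Cysteine-targeted fixed modifications (e.g. maleimide
alkylation) apply to non-bridged cysteines only — a bridged cysteine
cannot be alkylated — and alkylation is off by default for the
recombinant-protein search. The search is intra-protein by default (the
original experiment searched a single protein database).

MS1 matching is in ppm space on neutral masses (observed =
z·(m/z) − z·m_proton), default tolerance 10 ppm (Orbitrap-class); the
window is symmetric and inclusive at the boundary. MS2 annotation uses
the non-cleavable model: each peptide fragments on its own b/y backbone
while the partner peptide plus linker rides as one fixed mass on the
bridged cysteine; loop-linked peptides only yield fragments spanning
neither or both bridged residues (a cut inside the loop would have to
open the intact linker). Fragment charges 1–2, default 20 ppm. The score
is the matched/theoretical fragment fraction — deliberately simple
plumbing, since the original pipeline delegates scoring to a proprietary
node without printing a function; it suffices to rank planted versus
noise spectra in the synthetic studies. No target-decoy FDR is attempted.

## Activity-assay numerics

The product standard curve (fluorogenic phosphatase substrate) is an
ordinary least-squares line over 0–100 µM standards, inverted to convert
fluorescence to product concentration; readings outside the standard
range are flagged as extrapolated. Inhibition curves are fit to the
one-phase exponential decay Y(c) = plateau + (Y0 − plateau)·exp(−k·c)
with k ≥ 0 and plateau ≥ 0 by bounded nonlinear least squares. To avoid
local minima without user tuning, k is multi-started on a log-spaced grid
spanning the dose range with Y0/plateau taken from the data extremes, and
the best start by residual sum of squares wins. r² is 1 − SSres/SStot
about the mean (the graphing-software convention for nonlinear fits);
flat data have SStot = 0 and report r² = 0 by convention.

## Synthetic data: what it emulates, and what it does not

All generators hang off one integer seed with a named independent stream
per generator, so outputs are byte-identical for a fixed seed and
changing one generator's knobs never perturbs another's draws.

- **PSM tables** emulate the 4-vs-4 replicate design: per-protein
  per-sample counts are Poisson (negative binomial with configurable size
  available, since real spectral counts are overdispersed) at baseline
  mean 2, with 10 of 100 proteins planted at an 8-fold treated mean — an
  effect size representative of strong immuno-affinity enrichment. A 5%
  fraction of rows draws a peptide probability below the acceptance rule
  to exercise the filters.
- **Spectra** plant crosslink precursors at theoretical m/z with Gaussian
  5 ppm jitter (about half the 10 ppm matching tolerance, Orbitrap-like),
  charge 2–4, the b/y ladder thinned by 20% dropout, and 100 uniform-m/z
  noise peaks per spectrum. No isotope envelopes, retention times, or
  realistic intensity models are simulated — recovery results therefore
  speak to the mass-matching logic, not to spectral pre-processing.
- **Dose-response** curves use Y0 = 100, plateau = 10 (activity units),
  k = 2.5 µM⁻¹ over a 0–1.75 µM titration (a sub-micromolar-potency
  inhibitor), with Gaussian noise of sd 1 (1% of Y0).

The bundled Shp2-like record is a **synthetic stand-in**, not the real
protein: a deterministically generated 593-residue sequence whose only
designed features are cysteines at positions 333, 367 and 459 embedded in
tryptic contexts. It demonstrates that the digestion→candidate→search
chain reports a dithiolethione bridge at residues (333, 367) when a
precursor at the bridge mass is present; any biological use requires the
real sequence (UniProt Q06124), which the pipeline accepts as ordinary
FASTA input.

## Numerical and design choices

- Strict ">" for the probability filters and inclusive "≥" for the PSM
  floor and volcano gates, exactly as the rules are printed.
- Deterministic ordering everywhere (peptides by coordinates, candidates
  by peptide coordinates and bridged positions, reports by score then
  |ppm|), so fixed inputs give byte-identical outputs.
- The MS1 candidate prefilter window is widened by a second-order ppm
  factor so the exact ppm test, not floating-point truncation, decides
  boundary cases.
- Problem sizes in the test-suite simulations (2,000-protein null
  calibration, 20 seeds for stochastic checks, ~300 planted spectra per
  seed over three proteins) are desk-scale choices that keep the binomial
  error of the measured rates small relative to the thresholds being
  checked.

## Known limitations

- Spectral-count enrichment has no multiple-testing correction beyond the
  printed x/y gates; that mirrors the procedure being reproduced, not
  best current practice.
- The crosslink score ignores intensities and has no FDR; it cannot
  adjudicate co-eluting isobaric candidates.
- Precursor m/z is taken as monoisotopic; no isotope-envelope
  deconvolution is attempted.
- The one-phase decay model fits concentration-response at a fixed
  incubation time; it is not an IC50 or enzyme-kinetics (Km/kcat)
  parameterisation.
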