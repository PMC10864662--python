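# Methods

## Cleavage classification

A peptide observation is classified terminus by terminus. The N-terminal
cleavage site's P1 residue is the flanking residue preceding the peptide in
the protein; the C-terminal site's P1 is the peptide's own last residue.
P1 ∈ {K,R} ⇒ tryptic; a `-` flank ⇒ protein terminus; anything else ⇒
nontryptic, attributed to the first configured specificity class whose P1
set contains the residue (defaults: `ELANE_PRTN3` = {A,I,V} — elastase-like
proteases cleave after small aliphatics but not leucine — then `CTSG` =
{W,L,F,Y}; unmatched residues fall into `other`). The class map is ordered
precisely so overlaps, if a user configures any, resolve deterministically.

Three N-terminal states are translation artifacts, not proteolysis, and are
treated as tryptic-equivalent protein termini: peptide start at position 1;
start at position 2 behind an initiator methionine; and an N-terminally
acetylated peptide. A peptide is *nontryptic* (the category) when at least
one terminus is nontryptic, i.e. semi-tryptic peptides count; a strict
both-termini variant sits behind `RunConfig.strict_nontryptic`. A peptide
with two nontryptic termini contributes two events to class/P1 tallies but
its intensity once to nontryptic intensity, so intensity is conserved
exactly: tryptic + nontryptic = total.

Peptides mapping to several proteins take the most tryptic reading across
occurrences (tryptic > protein terminus > nontryptic), a conservative choice
against overcalling protease activity.

Percent nontryptic intensity uses aggregated-peptide feature areas (summed
over charge states/PSMs after zero-intensity filtering) as the denominator;
a PSM-level variant would be computable from the same inputs but the
aggregated level is the default and the one reported.

## Adduct occupancy

The DFP adduct is defined by its net composition C6H13O3P (diisopropyl
phosphate replacing the hydroxyl hydrogen of Ser/Thr/Tyr); its monoisotopic
mass, 164.0602 Da, is always derived from standard element masses rather
than stored as a rounded constant. Modifications on input peptides match the
adduct within 0.01 Da. Sites are keyed by (protein, position); the site
score is the best localization score among supporting peptides and must be
strictly greater than the threshold (default 20) when present — unscored
sites are kept but flagged. Occupancy pools all covering peptides (charge
states and missed-cleavage variants) without length normalization:
θ = ΣI_mod / (ΣI_mod + ΣI_unmod). Occupancy is scale-invariant by
construction; recovery to ±0.02 at ≥100 covering features and 10% intensity
noise is enforced by test.

## TMT chain

1. **Ratios.** Per PSM row, log2(channel / mean of reference channels).
   Rows with zero reference mean are dropped and counted; zero sample-channel
   intensities are missing values (the zero-feature-area convention), never
   floored.
2. **Dixon filtering.** Within each (peptide, channel) group of >2 PSM
   ratios, the two-sided Dixon ratio of the more extreme value is tested
   against the tabulated two-tailed critical value (Rorabacher 1991;
   α ∈ {0.05, 0.01}) with the variant schedule r10 (n 3–7), r11 (8–10),
   r21 (11–13), r22 (14–30); groups beyond n=30 are left unfiltered.
   Removal recurses and stops at the first non-rejection or when fewer than
   three values remain — pairs are never altered. On clean normal
   triplicates the false-removal rate empirically matches α (0.054 at
   α = 0.05 over 10,000 groups).
3. **Roll-up.** Peptide ratio = median of PSM ratios; protein ratio =
   median of peptide ratios. Mean reporter intensity is carried along for
   the intensity-trimmed scaling step.
4. **Alignment.** Per channel, a two-component Gaussian mixture is fitted by
   EM (tolerance 1e-8 on log-likelihood, ≤500 iterations, best of five
   seeded restarts, the first initialized by a quantile split) and the mode
   of the fitted density — located by a 2001-point grid search with bounded
   local refinement — is subtracted. The mode rather than the dominant
   component's mean is the default center because it is the density's
   maximum-likelihood point and degrades gracefully when components overlap;
   the component-mean variant is available (`center="major_mean"`).
   Channels with <20 entries fall back to median centering, flagged.
5. **Scaling.** Per channel, the SD of centered ratios over entries inside
   both the 5th–95th percentile band of ratios and of intensities; each
   channel is divided by (its trimmed SD / the median trimmed SD across
   channels). Trimmed SDs are thus exactly equalized while the cohort's
   median spread — and with it the natural effect-size scale — is
   preserved, instead of forcing SD = 1. One consequence: the output is
   invariant to pre-scaling a single channel only when that channel does not
   itself determine the median (generic for ≥3 channels).
6. **Differential test.** Pooled-variance two-sample t per protein with
   empirical-Bayes shrinkage: the prior (d₀, s₀²) is moment-matched on the
   log scale (digamma/trigamma inversion) under a scaled
   inverse-chi-square model; posterior variance (d₀s₀² + d s²)/(d₀ + d),
   p-values on d₀ + d df, BH adjustment across tested proteins. Proteins
   with <2 finite replicates per group are reported untested. Zero pooled
   variance with equal means gives p = 1; with unequal means the shrunken
   variance keeps the statistic finite unless the whole prior is degenerate.
   d₀ → 0 recovers the ordinary pooled t exactly (tested), and the
   statistics agree with an independent reference implementation of the
   moderated contrast fit to within 2% on shared data (tested). A Welch-t
   alternative is available (`moderated=False`).

## Synthetic generator

What it emulates: protein abundances are log-normal (default μ=13, σ=1, in
arbitrary intensity units); trypsin/P (LysC+trypsin collapses to one {K,R}
rule, no proline block) digests each protein, with missed-cleavage forms
down-weighted ×0.25 per missed site and a 6–45-residue observability filter.
Per sample, an endogenous protease (default P1 = {A,I,V}) redistributes a
fraction *a* — the activity, default 0.25 untreated, ×0.05 under simulated
DFP — of every cleavable tryptic peptide's intensity. A fraction
`tryptic_sparing_fraction` (default 0.8) of the carved intensity goes to the
peptide's internal endogenous fragments (length-proportional split), the
rest to one boundary-crossing semi-tryptic product running from the last
internal cleavage site to the end of the neighbouring tryptic peptide. The
carving conserves intensity exactly pre-noise, and the internal branch
reproduces the tryptic-sparing signature in which nontryptic sequences are
substrings of their suppressed tryptic parents; the crossing branch is a
modeling device for products that are not, not a mechanistic claim.
Active-site serines designated in the config emit modified/unmodified
feature pairs at θ/(1−θ) in inhibitor-treated samples (θ = 0 otherwise);
every tryptic form covering the site is routed through those pairs so
occupancy is well defined. Detectability dropout (default 0.1) and
multiplicative log-normal noise with unit mean (default CV 0.1) come last.
Reporter matrices put each peptide into 1+Poisson PSM rows, apply per-channel
condition fold changes (a seeded 10% of proteins at ±1 log2 by default) and
reporter noise, and fill reference channels with the pooled pre-noise mean
of the sample channels — the reference-pool construction (two reference
channels by default).

What it does not emulate: chromatography and retention time, co-isolation
interference, isotope-impurity spill-over, peptide-specific ionization
efficiency beyond the static missed-cleavage weights, inter-plex batch
structure (single plex by default), and any correlation between dropout and
intensity. Passing recovery tests therefore demonstrates correctness of the
analysis chain under these idealized conditions, not robustness to every
artifact of real data.

Problem sizes in the tests and the acceptance script (200 proteins for share
recovery, 500 for differential recovery, 40 × 20 replicates for the
activity-monotonicity check, 10,000 triplicates for the Dixon rate) are
chosen so each Monte-Carlo tolerance is comfortably met while the whole
suite stays quick; they are package defaults, not physical constants.

## Numerical and degenerate-input choices

- Dixon: constant-valued groups and groups with n ≤ 2 are returned
  unchanged; α is restricted to the tabulated {0.01, 0.05}.
- Mixture fit: <20 finite values is an error (callers fall back to median
  centering); zero-variance input returns a flagged single-point fit whose
  mode is the common value.
- Correlation: zero variance in either vector returns a flagged undefined
  result rather than NaN propagation.
- BH adjustment validates p ∈ [0,1] and preserves input order; ties are
  handled by the step-up minimum, making the adjustment monotone.
- All stochastic routines take explicit seeds; the package-wide default is
  20240112.

## Known limitations

- Protease-specificity classes are P1-only; subsite preferences (P2–P4,
  P1′) that distinguish real ELANE from PRTN3 are out of reach of this
  representation, which is why the two share one class. No residue set is
  shipped for NSP4, whose specificity is not reducible to a clean P1 set.
- The localization score is consumed, never computed: site-level confidence
  must come from upstream search engines.
- The moderated test covers the two-group contrast only; factorial designs
  would need a full linear-model layer.
- Dixon critical values stop at n = 30; larger PSM groups pass through
  unfiltered rather than extrapolating the table.
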