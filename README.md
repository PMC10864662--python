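# cleaveqc

Quality control for endogenous protease activity in bottom-up proteomics.

Myeloid cells carry large stores of azurophil-granule serine proteases —
neutrophil elastase (ELANE), proteinase 3 (PRTN3) and cathepsin G (CTSG) —
that survive standard protease-inhibitor cocktails and keep cleaving proteins
during sample preparation. Their products show up in nonspecific database
searches as *nontryptic* peptides: peptides with at least one terminus whose
P1 residue (the residue immediately N-terminal to the cleavage site) is not
Lys/Arg. `cleaveqc` turns that signal into numbers:

- **Cleavage classification.** Every observed peptide terminus is called
  tryptic (P1 ∈ {K,R}), nontryptic, or protein terminus; nontryptic events
  are attributed to protease-specificity classes by P1 residue
  (ELANE/PRTN3 = {A,I,V}, not Leu; CTSG = {W,L,F,Y}). Per sample the package
  reports percent nontryptic intensity
  (100·Σ I_nontryptic / Σ I_total), class fractions, P1-residue frequencies,
  and counts of proteins with ≥ 2 tryptic peptides.
- **Inhibitor-adduct occupancy.** Diisopropyl fluorophosphate (DFP) leaves a
  diisopropyl-phosphate adduct (net C6H13O3P, +164.060 Da monoisotopic) on
  the active-site serine of serine hydrolases. Per site the occupancy
  θ = I_mod / (I_mod + I_unmod) is computed from covering-peptide
  intensities, after an A-score-style localization filter (score > 20),
  as a direct readout of inhibition efficiency.
- **TMT quantitation chain.** Reporter intensities become log2 ratios
  against the mean of the reference-pool channels; recursive Dixon's Q test
  cleans (peptide, channel) PSM groups of size > 2; medians roll PSMs up to
  peptides and peptides to proteins; each channel's ratio distribution is
  centered at the mode of a fitted two-component Gaussian mixture and scaled
  so 5th–95th-percentile-trimmed SDs are equal across channels; an
  empirical-Bayes moderated t-test with Benjamini–Hochberg adjustment calls
  differential abundance (posterior variance (d₀s₀² + d s²)/(d₀ + d) on
  d₀ + d degrees of freedom).
- **Synthetic data with ground truth.** A seeded generator emulates the whole
  situation — log-normal protein abundances, trypsin digestion with missed
  cleavages, an endogenous protease that carves a fraction *a* (the
  activity) of each cleavable tryptic peptide's intensity into nontryptic
  sub-fragments ("tryptic sparing") or boundary-crossing products, DFP
  treatment attenuating that activity, adduct occupancy, TMT channels with
  reference pools — and emits a ledger of every pre-noise truth, so each
  pipeline stage is tested by parameter recovery.

## Worked example

The `analysis/` scripts run the full study on synthetic data. From the
repository root:

```bash
python analysis/01_simulate.py          # cohort: 3 untreated + 3 DFP samples
python analysis/02_classify_activity.py
python analysis/03_adduct_occupancy.py
```

`02_classify_activity.py` prints, for the default seed:

```
sample           pct_nontryptic   truth    |err|
dfp_1                    1.07     1.06     0.01
dfp_2                    1.06     1.06     0.00
dfp_3                    1.06     1.06     0.00
untreated_1             21.25    21.19     0.05
untreated_2             21.30    21.19     0.10
untreated_3             21.36    21.19     0.16
```

Untreated samples lose ~21% of their peptide intensity to endogenous
cleavage; simulated DFP treatment (activity × 0.05) drops that to ~1%, and
the classifier recovers the generator's true share to a fraction of a
percentage point. `03_adduct_occupancy.py` then reports the active-site
serine at occupancy 0.949 against a simulated truth of 0.95:

```
adduct delta mass: 164.0602 Da (rounds to 164.06)
SYN0001  position 6  S  score 40.0  occupancy 0.948914
share of adduct intensity on the active site: 100.0%
```

`04_tmt_quant.py` and `05_correlate_activity.py` finish the chain:
differential recovery of the true ±1 log2-fold changes (sensitivity 1.00,
observed false-discovery proportion 0.043 at BH q < 0.05) and the Pearson
correlation between protease abundance and nontryptic intensity across a
simulated cohort (r ≈ 1.0 at 10% noise).

A `cleaveqc` console script exposes the same steps
(`simulate`, `classify`, `quant`, `correlate`, `cluster-input`) for use on
externally produced PSM tables; see `cleaveqc --help`.

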