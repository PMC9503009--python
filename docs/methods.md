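# Methods

## The assay being modelled

`scamflux` implements a cell-based, fluorometric version of the
substituted-cysteine accessibility method (SCAM) for Na⁺/Cl⁻-coupled
monoamine transporters, using the serotonin transporter (SERT) as the study
system.  A reporter cysteine is engineered into one of the two substrate
permeation pathways — Cys107 or Cys404 facing the extracellular medium,
Cys277 facing the cytoplasm — and its solvent accessibility is read out by
how fast a methanethiosulfonate (MTS) reagent inactivates the transporter.
Activity is measured in single cells by confocal imaging of fluorescent
substrates: APP⁺ accumulates inside cells (transport), ASP⁺ additionally
binds the cell-surface transporter (membrane signal).  Because the two
reporter positions are exposed in opposite conformations of the alternating
access cycle, a ligand that *increases* extracellular reactivity while
*decreasing* cytoplasmic reactivity stabilizes the outward-open state, and
vice versa.

No image data are deposited for this assay type, so the package ships a
first-class synthetic-data generator whose defaults encode the published
quantitative behaviour, and every analysis stage is validated against that
generator's ground truth.

## Mechanistic model of the generator

For a condition (construct, substrate and concentration, MTS reagent dose
and exposure, ligand, ion medium, digitonin) the per-cell mean signal is
decomposed as:

* **Specific uptake** (interior): `v = Vmax·S/(Km+S)` in arbitrary
  fluorescence units accumulated over the standard 5-min window; the
  single-timepoint accumulation is modelled as initial-rate × time, i.e.
  the linear regime.  Uptake requires both Na⁺ and Cl⁻ (NaCl media only)
  and is suppressed by digitonin with a Hill curve (IC50 9 µg/mL, slope 3),
  so that at the reference 25 µg/mL less than 5% of uptake remains.
* **Specific surface binding** (membrane ring, ASP⁺ only):
  `b = Bmax·S/(Kd+S)`, retained under digitonin (90% at 25 µg/mL, with a
  mild linear decline at higher doses, floored at 50%).
* **Nonspecific components**: share the saturable concentration dependence
  of their specific counterparts, with amplitudes set so that 95% of the
  APP⁺ signal and 84% of the total ASP⁺ signal (at the standard 10 µM) is
  blockable by 10 µM fluoxetine.
* **Cysteine modification**: an MTS exposure at concentration `c` for time
  `t` leaves an active fraction `(1−m) + m·exp(−k_eff·c·t)` where `m` is
  the modifiable fraction and `k_eff` the pseudo-first-order rate constant
  (M⁻¹s⁻¹).  For cytoplasm-facing cysteines, `m` is capped by how
  completely digitonin has permeabilized the membrane (piecewise-linear:
  0.4 at 10 µg/mL, 0.5 at 15, 1.0 at 25); extracellular cysteines are
  always fully accessible to the membrane-impermeant MTSET in live cells,
  while MTSET never reaches the cytoplasmic pathway even after
  permeabilization.

Default kinetic constants (Km/Vmax per construct, the base rate constants
`k_base` per construct×reagent) are the published values of the assay this
generator emulates; the two extracellular MTSET rate constants
(70 and 308 M⁻¹s⁻¹) follow from the measured half-maximal concentrations
(0.011 mM and 0.0025 mM at 15 min) through `k = ln2/(t·c50)`.

Ligands and ions act purely as multiplicative fold factors on `k_base`
(the assays report fold-changes, not mechanism): antidepressants
1.7–2.2× on the extracellular reporters and 0.33–0.5× on the cytoplasmic
one; substrate 5-HT the mirror image (0.5× / 2×); the 5-HT precursors
5-HTP and tryptophan 1×; vilazodone patterns with the antidepressants.
Ion factors are stored normalized to the standard NaCl buffer (in which
`k_base` is defined); relative to the ion-free NMDG-gluconate baseline they
give Na⁺-alone 1.8×, NaCl 1.4×, NaCl+5-HT 0.7× extracellular, mirrored
cytoplasmically — reproducing the partial, Na⁺-dependent effect of Cl⁻.

Two fields were added beyond the minimal condition record. `uptake_blocked`
marks stacks in which fluoxetine is present *during the measurement* (the
operational definition of nonspecific signal), distinct from fluoxetine as
a conformational ligand present only during the MTS step and washed out
before uptake.  `cell_autofluorescence` (15 AFU) gives cells a
substrate-independent brightness: real cells remain visible and
segmentable even at full transport inhibition, and the offset cancels in
the blocked-stack subtraction exactly as nonspecific signal does.

## Image formation

Cells are non-overlapping ellipses (semi-axes 3.5–6.5 µm at 0.5 µm/px)
with a fixed 1.5 µm (3 px) membrane ring; interior and ring tile each cell
exactly.  Each cell carries a lognormal expression factor (σ = 0.15,
mean normalized to 1) on its specific signal — the cell-to-cell scatter
that motivates single-cell quantification.  Noise per page: Poisson shot
noise on photon-scaled intensities (5 photons/AFU), Gaussian read noise
(2 AFU), then a Gaussian PSF of σ = 0.4 px (0.2 µm, the lateral resolution
of a high-NA confocal at this sampling).  Pages are quantized to 16-bit
TIFF at 20 counts/AFU; quantization error is therefore 0.025 AFU and
overflow raises instead of clipping silently.  All randomness derives from
a single seed via spawned `SeedSequence`s, making stacks and downstream
CSVs byte-reproducible.

## Quantification

Segmentation is deliberately plain (it stands in for interactive ImageJ
analysis): Gaussian smoothing (σ = 1 px), Otsu threshold, hole filling and
an area filter, with an optional watershed split for touching cells.  A
frame whose threshold selects most of the image is treated as
cell-free.  Per cell, total fluorescence is background-corrected (median of
non-cell pixels) and normalized to cell area (mean fluorescence); the
interior level is estimated on the mask eroded by the ring width and
subtracted from the total to give the membrane signal, normalized to ring
area.  Cells touching the frame edge are excluded (truncated area); cells
whose interior erodes away are flagged and keep only whole-cell metrics.

In the pipeline the interior estimate is eroded 2 px deeper than the true
ring width: thresholded masks sit slightly outside the true boundary, and
without the guard the bright ring bleeds into the interior estimate and
inflates cytoplasmic rate constants by ~15%.  With it the residual bias is
a few percent.  Surface densities remain systematically *underestimated*
(ring dilution), which cancels in every ratio the analyses use
(activity relative to the zero-reagent control, fold-changes); absolute
Vmax values read from whole-cell means are similarly a few percent low.

Assay readouts: APP⁺ conditions use whole-cell mean fluorescence; ASP⁺
uptake (intact cells) uses the interior mean, because the surface-bound
component would contaminate a transport measurement; ASP⁺ binding
(permeabilized cells) uses the membrane surface signal.  Every activity
passed to a fit is *specific*: the matched fluoxetine-blocked stack (same
construct, substrate, concentration, digitonin, experiment) is subtracted
first.

## Fitting and statistics

**Michaelis–Menten**: unweighted least squares of `v = Vmax·S/(Km+S)` per
experiment on the specific series; cross-experiment values are the mean ±
SEM of per-experiment fits (not a pooled fit), matching the replicate
structure of the assay.  Fits with Km beyond the tested range are flagged
unreliable rather than extrapolated.

**Concentration–inhibition**: the default model fits
`A(c) = floor + (A0−floor)·exp(−k·c·t)` directly for `k`; the floor is
fixed at zero unless the terminal plateau exceeds 10% of A0 (partial
accessibility, e.g. sub-saturating digitonin).  The half-maximal
concentration is `ln2/(k·t)` regardless of floor.  An empirical
alternative fits an *asymmetric* (five-parameter) logistic in log10
concentration with the zero-concentration point anchoring the top plateau,
reporting `c50` where the fitted curve crosses half-activity; a symmetric
logistic midpoint is ~9% off on first-order data, the asymmetric form
agrees with the exponential route to <1% on clean data.  When the maximal
observed inhibition is below 20%, no rate is fitted; the result carries
only the detection bound `ln2/(t·c_max)`.

**Fixed-concentration protocol**: with MTS applied once near the control
IC50, the rate-constant fold is back-calculated as
`ln(A_lig/A0)/ln(A_ctrl/A0)`; remaining fractions at or above 1 are
reported as full protection, and a control far from half-inhibition
triggers a warning.

**Comparisons**: per-experiment rate constants are paired by experiment
and tested with Student's paired t-test (α = 0.05, no multiplicity
correction by default; Holm adjustment available).  The fold-change is the
geometric mean of per-experiment ratios, so exchanging condition and
control exactly inverts it.  A contrast is called `unchanged` unless it is
both significant and at least a 1.1-fold change.  Conformational calls:
extracellular↑ with cytoplasmic↓ → outward-open stabilized; the reverse →
inward-open shifted, downgraded to partial/intermediate when the folds
stay above 0.55 (extracellular) or below 1.8 (cytoplasmic); both
unchanged → no change; anything else → discordant.  The ion panel
additionally flags the Cl⁻ signature: the NaCl point lying between the
Na⁺-alone and substrate-shifted levels with a significant overall shift.

## Problem sizes and what the tests show

Default study conditions are one 384×384 px field with 30 cells per
condition and three experiments per design — the replicate structure of
the emulated assay ("n ≥ 30" cells, mean ± SEM of three experiments).
Parameter-recovery checks run the full image pipeline 100 times on the
8-concentration MTSET ladder; at the default noise the fitted rate
constant lands within 15% of truth in well over 90% of replicates, and the
Michaelis constant within 10%.

Passing these simulations demonstrates that the analysis chain is
*internally consistent and unbiased under the generator's assumptions*.
Real micrographs differ in ways the generator deliberately omits: no
z-structure or optically accurate PSF, no touching or motile cells, no
photobleaching, no time-resolved two-phase ASP⁺ traces (only the endpoint
membrane/interior decomposition), no spatial background gradients, and
ligand/ion effects enter only as fold factors rather than mechanism.
Conclusions about real data therefore rest on the segmentation and
background assumptions holding there.

## Known limitations

* Power at n = 3 experiments is marginal for fold-changes below ~1.4 in
  the fixed-concentration protocol; such contrasts can come out
  `unchanged`, which matches the "small but significant" character of the
  Cl⁻ effect rather than contradicting it.
* The generator's half-maximal digitonin behaviour between the published
  anchor points is linear interpolation, a modelling convenience.
* Absolute surface densities are estimator-biased low (see above); only
  ratios should be interpreted.
* Below-detection results are reported as bounds, never as rate constants;
  printed ">1000 mM" style entries in the emulated assay correspond to
  this below-detection convention here.
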