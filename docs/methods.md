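# Methods

## BRET saturation quantification

A BRET saturation experiment co-expresses a fixed NLuc-tagged donor
(bait) with increasing amounts of a Venus-tagged acceptor (prey). Each
well contributes

* BRET ratio = F535 / L460 (acceptor emission over donor luminescence,
  white plate);
* net BRET = pair ratio − donor-only control ratio. The donor-only
  baseline is estimated as the mean raw ratio of dedicated NLuc-alone
  wells (no acceptor plasmid), kept distinct from the two empty-vector
  control *series*. Subtracting a control series' own mean from itself
  would center that series at zero by construction and bias the pooled
  control comparison; dedicated baseline wells keep the two control
  series exchangeable with non-interacting candidates.
* acceptor/donor ratio X = Venus FI / L460, with Venus fluorescence
  measured on a black plate seeded and transfected side-by-side; wells
  are paired by identical plate coordinate, construct and replicate.

Net BRET versus X follows the one-site hyperbola
Y = B<sub>max</sub>·X/(B<sub>50</sub>+X): B<sub>max</sub> (unitless, the
donor-saturation plateau) scales with the interacting fraction, and
B<sub>50</sub> (same units as X) is the acceptor/donor ratio at
half-saturation, an inverse measure of apparent affinity. Raw values may
be negative through background subtraction noise; points with X < 0 or
Y < 0 are excluded before fitting and never enter a fit.

Fitting is bounded least squares (trust-region reflective, analytic
Jacobian, B<sub>max</sub> ≥ 0, B<sub>50</sub> > 0, tolerances 1e−10)
initialized at B<sub>max</sub>⁰ = max usable Y and B<sub>50</sub>⁰ = the
first X whose response reaches half that plateau (median X as a
fallback). A curve needs ≥ 3 usable points with ≥ 2 distinct X values.
If no usable response is positive, the plateau is pinned at 0 and
B<sub>50</sub> reported unidentifiable (`converged=False`) rather than
guessed.

### AUC scoring and hit calling

Each replicate curve is summarized by the exact integral of its fitted
hyperbola over [0, x<sub>max</sub>]:
AUC = B<sub>max</sub>(x<sub>max</sub> − B<sub>50</sub>·ln((B<sub>50</sub>+x<sub>max</sub>)/B<sub>50</sub>)).
Integrating the fitted curve (not a trapezoid of raw points) is exact
and noise-robust, and the AUC combines amplitude and shape in one
number.

The integration window is **per comparison**: for each candidate gene,
x<sub>max</sub> is the minimum, over that gene's replicate curves and
all control replicate curves, of each curve's largest non-excluded X.
A shared window within a comparison keeps FOC from confounding
expression range with affinity; making it per-comparison (rather than
screen-global) keeps one heavily-excluded series elsewhere in the
screen from collapsing everyone's window. Control AUCs are re-integrated
from their fitted parameters at each gene's window, which is free with
the closed form.

Scoring per gene, with four replicate AUCs per condition:

* FOC = mean(AUC<sub>PPI</sub>) / max(mean(AUC<sub>ctrl1</sub>), mean(AUC<sub>ctrl2</sub>));
* P<sub>FOC</sub> from a two-sample, two-tailed, equal-variance t-test
  of the PPI replicate AUCs against the pooled ctrl1+ctrl2 replicate
  AUCs (4 vs 8), unadjusted;
* hit ⇔ FOC ≥ 4.0 and P<sub>FOC</sub> ≤ 0.001, both inclusive. The hit
  table sorts by FOC descending, ties broken by smaller p then acceptor
  name.

Degenerate cases: a control condition with fewer than two usable
replicate AUCs is an error (the comparison has no denominator
distribution); a *candidate* whose series is consumed by the exclusion
rule is reported as a non-callable score instead of failing the screen;
a nonpositive control AUC scale flags the score non-callable rather than
inventing a sign convention for FOC.

## Immune co-culture screen

Percent of control normalizes each compound well against its own
plate's DMSO controls, %C = 100(S − S<sub>blank</sub>)/(S<sub>positive</sub> − S<sub>blank</sub>),
where S<sub>blank</sub> averages PBMC/medium-only DMSO wells and
S<sub>positive</sub> DMSO wells with cancer cells. %C is invariant under
common affine transforms of the signals and is reported unclamped —
values above 100 (proliferative) or below 0 (cytotoxic beyond blank) are
informative.

%C is computed per replicate well and averaged within each arm; the
selectivity index SI = %C<sub>−PBMC</sub>/%C<sub>+PBMC</sub> is the
ratio of arm means (means reduce ratio noise). SI > 1 means killing
requires immune cells. Two guards: a nonpositive +PBMC %C means killing
saturated the assay floor — the index is reported as +∞ and ranked above
all finite values rather than divided through; a negative −PBMC %C is
floored to 0 in the numerator, since a compound that kills without
immune cells is not immune-selective. Sensitizer nomination keeps
SI ≥ 2.0 by default (the screen equation defines the index but no
nomination cutoff is canonical; 2.0 — killing at least twice as strong
with immune cells — is exposed as a flag).

Viability against PBMC-alone background uses simple subtraction floored
at zero. The segmentation-derived area filter retains objects strictly
larger than 400 μm² (cancer cells are larger than effector immune
cells); only the tabular filter is implemented, segmentation itself is
upstream.

### Dose–response

The variable-slope sigmoid
y = bottom + (top − bottom)/(1 + 10^((log₁₀EC50 − log₁₀d)·hill)) is fit
by least squares in log-dose space, with log₁₀EC50 as the internal
parameter so the midpoint stays positive. One parameterization covers
activation and inhibition: the sign of `hill` distinguishes them, so the
midpoint reads as EC50 or IC50 accordingly. A fit requires ≥ 4 points
spanning ≥ 2 decades of dose; below that the sigmoid is not reliably
identifiable and the package refuses rather than returning a fragile
estimate. Concentrations are stored in molar.

Killing-curve AUC integrates viability against log₁₀ effector dose by
trapezoid and divides by the flat-100% reference over the same span, so
1 = no killing and 0 = complete killing, comparable across dose ranges.

## Downstream formulas

* 2^−ΔΔCt with replicate Ct values averaged per (gene, condition) before
  ΔCt; normalization is against a reference gene (GAPDH by default).
  Ct values outside 10–40 cycles warn.
* DEG filter: |log₂FC| ≥ 1 and p<sub>adj</sub> ≤ 0.05, both inclusive,
  on an externally produced differential-expression table (the DE model
  itself is out of scope).
* Tumor volume = length·width²/2 (mm³); if width exceeds length the
  arguments are swapped with a warning, making the result
  order-invariant. Percent reduction is relative to the
  treatment-start volume.

## Synthetic data

The generators reproduce the statistical structure the analyses assume,
with every draw governed by one seed (identical spec ⇒ byte-identical
tables).

**BRET screen.** Per gene, four replicate titration series over the
default grid X ∈ {0.25, 0.5, 1, 2, 4, 8} (the real titration design is
instrument-specific; this spans 1.5 decades around saturation). True
interactors draw B<sub>max</sub> ~ Uniform(0.1, 0.3); non-interactors
and both empty-vector control series share a nonspecific plateau of
0.02; B<sub>50</sub> ~ log-Uniform(0.5, 4) per series. Additive Gaussian
noise on net BRET has sd = 5% of the hit-plateau midpoint (0.01), a
*common* scale for every series — making noise proportional to each
gene's own plateau would render null genes nearly noiseless and break
the exchangeability between non-interactors and controls that the
t-test's calibration rests on. X carries 2% multiplicative jitter.
White-plate wells encode the signal as L460 = 10⁴ counts and
F535 = L460·(0.1 + Y) over a donor-background ratio of 0.1; black-plate
wells carry Venus FI = X·L460 at the same coordinates. Dedicated
donor-only baseline wells (white plate only) are emitted per screen, as
are one ctrl1 (empty donor vector) and one ctrl2 (empty acceptor vector)
series — the unit the 4-vs-8 pooled t-test compares against, even when a
screen spans several physical plates.

**Co-culture screen.** Signals are lognormal-multiplicative around a
cancer-cell scale of 10⁴ counts over a 500-count blank (luminescence and
fluorescence viability assays show roughly constant CV, default 10%).
Inert compounds keep the full cancer signal in both arms; planted
sensitizers divide the +PBMC-arm signal by their true SI (default 5).
Each 384-well plate carries its own 16 blank and 16 positive control
wells; with zero noise the computed SI equals the planted SI exactly.

**Dose–response.** 4PL samples over a log-spaced dose grid with
multiplicative Gaussian noise (default 5%).

What the generators deliberately omit: plate-position/edge effects,
transfection-efficiency drift, donor-saturation artifacts, bystander
BRET beyond the empty-vector level, PBMC-donor variability and
compound-plate batch structure. Passing the planted-truth tests
therefore demonstrates the *calculus* is correct and calibrated under
the assay's idealized noise model, not that real screens are free of the
spatial and biological artifacts the generators exclude.

## Problem sizes and calibration checks

The test suite exercises the scoring at the screen's native scale: an
85-gene screen with 16 planted interactors (and a 20-gene variant), a
500-compound co-culture screen with 3 planted sensitizers, 2000
simulated null comparisons for t-test calibration (expected ≤ 0.5%
reaching p ≤ 0.001), and ten 40-gene screens with a planted 8-fold AUC
effect for sensitivity/false-discovery checks. Exact-recovery checks
plant interactors at the strong-effect plateau (0.2); under the default
Uniform(0.1, 0.3) range a weak interactor with a high half-saturation
ratio can fall below FOC 4 — that is the cutoff's designed stringency,
not a defect.

The acceptance computation fits the mean of three independently noisy
8-dose reporter curves (reporter dose–response experiments are
summarized as means of n = 3 independent replicates) and recovers the
generating 0.2 μM midpoint; single noisy curves at 5% CV leave the EC50
estimate with a ~8% median relative error and occasional >25%
excursions, which the replicate mean removes.

## Known limitations

* The saturation model assumes one binding mode and no donor-saturation
  correction; strongly curved nonspecific backgrounds are only handled
  through the empty-vector controls.
* FOC is undefined when both control means are nonpositive; such scores
  are flagged, not ranked.
* The 4PL fit reports `converged=False` instead of raising when the
  optimizer stalls; callers should check the flag and r².
* No plate spatial normalization is applied anywhere — inputs are
  treated as background-corrected instrument counts.
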