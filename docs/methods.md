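# Methods

## Model family

All eleven models are closed mass-action reaction networks over pools of
molecules in a single platelet. A model is defined by a list of
reactions, each moving molecules from one pool to another at rate
`k · [source]`, optionally multiplied by a promoting species' abundance
(making `k` second order, units (molecules·platelet⁻¹)⁻¹·s⁻¹) and/or by
the dimensionless stimulus `s(t)`. The right-hand side is assembled
through a stoichiometry matrix, which makes two structural properties
hold by construction rather than by testing: the componentwise sum of
every derivative is exactly zero (conservation of the total count), and
every loss term carries its own species' abundance, so a pool at zero can
never be driven negative by the instantaneous dynamics.

The stimulus `s(t) = a1·t·exp(−a2·t²) + a3·tanh(a4·t)` summarises
receptor-proximal signalling (Syk/LAT/Btk/PLCγ2 phosphorylation after
GPVI engagement): a saturating plateau with an optional early transient.
The calibration values are a1 = 0.001 s⁻¹, a2 = 0.0002 s⁻²,
a3 = 1.0, a4 = 0.02 s⁻¹. `s(t)` is dimensionless and multiplies the
PLCγ2 (`s1`) and PI3K (`s2`) fluxes out of PtdIns(4,5)P2, so the rate
constants it scales keep first-order units.

The base model A0 has nine pools and 17 rate constants, of which
`theta1` = 0.04 s⁻¹ (IP3 → IP1) and `r3` = 0.0002 s⁻¹ (IP1 → Ip) are
fixed from literature kinetics, leaving K = 15 free. Variants either
promote an existing flux with the stimulus (A01) or with a metabolite as
a Ca²⁺ surrogate (A02, A06, A07, A08 — implemented as bilinear
mass-action, modifier abundance times substrate abundance, the same
pattern the stimulated fluxes use), add a sequestered pool (A03
cytosolic PtdIns, K = 17; A04 protein-bound PIP3, K = 17; A05
MARCKS-bound PIP2, K = 17), or add a conversion route (A09
PI4P → PI34P2, K = 16; A10 an IP3-promoted PI → Ip shunt, K = 16). In
A03 the recycling rate `theta2` is reassigned to the PIc → PI step, so
recycled inositol passes through the intracellular compartment instead
of feeding membrane PtdIns directly.

Initial conditions are basal copy numbers (PtdIns 2.7e6, PtdIns4P 6.4e4,
PtdIns(4,5)P2 3.1e5, PtdIns(3,4,5)P3 1.9e3, PtdIns(3,4)P2 5.2e3, lumped
phosphoinositides 2.5e4, soluble inositol 1e8, IP3 = IP1 = 0). A03
splits PtdIns evenly between the membrane and cytosolic pools, A05
splits PtdIns(4,5)P2 evenly between free and bound, and A04 starts with
no bound PIP3, so every variant starts from the same total
(103,106,100 molecules).

## Integration

LSODA (via `scipy.integrate.solve_ivp`) with rtol 1e-8 and atol 1e-6 by
default: fitted rate constants span 1e-4–1e2 s⁻¹, giving stiff timescale
separation, and abundances span 0–1e8, so an absolute tolerance of 1e-6
molecules is far below anything meaningful. These tolerances hold the
conserved total constant to better than 1e-6 relative over the 600 s
window for random prior-box parameters in every variant. Inside
optimisation loops a faster contract is used (rtol 1e-6, atol 1e-3),
still orders of magnitude below the data scale. Sub-tolerance negative
undershoots are clamped to zero in reported trajectories only, never fed
back to the solver. The observation grid is the experimental one
({0, 30, 60, 90, 120, 180, 600} s); the 600 s endpoint serves as the
steady-state surrogate because no claim is made about dynamics beyond
the data window.

## Synthetic data

The generator emulates the structure of the CRP-stimulation
measurements: six observed species on the seven-point grid, three
replicates. Noiseless means pass exactly through per-species anchors
(PtdIns 2.3e6 → 2.9e6 at 60 s → 1.5e6 at 600 s; PtdIns4P flat at 6.4e4;
PtdIns(4,5)P2 2.9e5 → 4.8e5 at 120 s, held; PtdIns(3,4,5)P3 2.2e3 →
5.8e3 at 180 s, held; PtdIns(3,4)P2 5e3 → 3e4 at 180 s, held; IP1
linear 0 → 2.1e3). Between anchors, curves follow exponential-saturation
segments (rate 3/Δt, covering ~95% of the span in the first third of
each interval) that pass through both endpoints exactly — a shape choice
matching the fast-rise/hold character of the measurements; IP1 is
linear and PtdIns4P constant. Plateaus are held to 600 s because no
post-plateau decline is quantified. The generator's basal values follow
the measured data (PtdIns 2.3e6) even where the model initial conditions
differ (2.7e6): the generator emulates the data, the simulator the
model.

Replicate noise is multiplicative lognormal with a common per-species
coefficient of variation of 0.20, consistent with the reported basal
scatter (e.g. 0.5/2.3 ≈ 0.22 for PtdIns); σ² = ln(1 + cv²) with a
−σ²/2 mean offset makes the multiplier unit-mean with exactly the
nominal cv. Fitting consumes the mean view (the protocol reports means
of three experiments); replicates exist for robustness checks. What the
generator does **not** emulate: donor-to-donor correlation structure,
timepoint-specific variances, inter-species noise correlations, and the
inhibitor dataset beyond qualitative flatness — so passing recovery
tests demonstrates correctness of the machinery under the stated noise
model, not robustness to real experimental error structure.

## Calibration and model comparison

Fitting minimises a species-normalised SSE: predictions and data means
for each species are divided by that species' maximum observed mean
before residuals are formed. The raw cost would be dominated entirely by
PtdIns (1e6) over PtdIns(3,4,5)P3 (1e3); normalisation makes the 42
cells commensurate and puts the attainable SSE/n in the few-percent
regime. In A04/A05 the measured PIP3/PIP2 are compared against free +
bound pool totals, since mass spectrometry cannot distinguish
protein-bound lipid.

Starts are Latin hypercube samples (`scipy.stats.qmc`) over log10
priors [−4, 2] for every free parameter; each start is refined by
trust-region-reflective bounded least squares (`scipy.optimize.
least_squares`) on the log10 scale, relative cost tolerance 1e-8 and an
evaluation budget of 500 residual calls per start — enough for the
optimiser's own convergence test to fire in the large majority of
starts at this problem size. Solver failures during optimisation score
as large constant residuals (and +inf SSE on report) rather than
aborting the run. The package default of 200 starts per variant keeps a
full eleven-variant comparison on a desktop; production-scale analyses
simply raise `n_starts` in the run configuration.

Models are compared by AICc with n = 42 (7 timepoints × 6 species
means — replicates are not separate observations) and K the variant's
free-parameter count. Ranking is ascending in minimum AICc, ties broken
by smaller K then variant id. Uncertainty reporting follows the
best-100 fits (5–95, 25–75, 45–55 quantiles of log10 parameters); a
parameter whose 5–95 band spans at least five of the six prior decades
is flagged non-identifiable. Simulation ensembles use the best-10 fits.

## Perturbations

Local sensitivity scales one rate constant at a time by (1 ± factor)
(default 50%) and scores each state's 600 s endpoint as
(O_a − O_i)/O_a, with O_i the baseline endpoint and O_a the perturbed
one. Normalising by the adapted value (rather than the more conventional
baseline) keeps the score bounded when a perturbation collapses an
endpoint towards zero; scores are NaN when the perturbed endpoint is
itself zero. The default parameter subset is
the forward-rate panel (r1, r2, r3, r4, theta1–theta6 where present).

The GSK-A1 inhibitor (a PI4KA inhibitor) is modelled as scaling the
PtdIns → PtdIns4P rate `r1` to 10% of its fitted value. Stimulus
scenarios replace the calibration stimulus with (i) a halved plateau
(a3 = 0.5), (ii) an early transient peak (a1 = 0.03, a2 = 0.002), or
(iii) both (a1 = 0.03, a2 = 0.0002, a3 = 0.5). Scenario machinery never
breaks closure: stimulus and parameter scaling only modulate conversion
rates.

## Reference calibrations

`ppiflux.refparams` freezes two multistart calibrations against the
bundled synthetic mean curves (300 starts each): `REFERENCE_A0` is the
unconstrained best fit of the base model, and `REFERENCE_A03` the best
fit of the secondary-pool variant with the DTS-exchange rates
(`theta6`, `theta-6`) constrained to the slow decade range
1e-4–1e-2 s⁻¹. The slow-pool constraint selects the regime that makes
A03 a distinct hypothesis: with fast exchange the cytosolic pool merely
shadows `Ip` and A03 degenerates towards A0's behaviour. These reference
sets drive the examples and serve as generating truths for the
parameter- and model-recovery experiments; they are calibrations to the
synthetic curves, not to any experimental dataset.

## Numerical and design choices

* Optimisation in log10 space because priors span six decades; box
  bounds equal the priors.
* `PriorBounds` refuses bounds for the fixed `theta1`/`r3`; the
  optimiser never sees them.
* Grid validation requires strictly increasing times starting at the
  first observation; degenerate (all-zero-rate) systems integrate to
  constant trajectories and are valid inputs.
* A zero species-maximum in the normalisation falls back to a scale of
  1 to avoid division by zero (only possible for a degenerate dataset).
* Ranking ties (identical AICc) are broken deterministically (smaller
  K, then variant id) so comparisons are submission-order invariant.
* Seeds: dataset noise and LHS sampling are separately seeded
  `numpy.random.Generator` streams; a fixed configuration is
  bit-reproducible apart from floating-point reproducibility of the
  optimiser across platforms.

## Known limitations

* Variant right-hand sides beyond A0 are reconstructions of one-line
  mechanism descriptions as bilinear mass-action promotions; other
  functional forms (saturating, cooperative) are plausible but
  unidentifiable at this data density.
* The 600 s endpoint is a steady-state surrogate; several solutions are
  still slowly evolving there.
* Best-10 ensemble envelopes understate predictive uncertainty: tightly
  converged multistart optima cluster around the (noise-perturbed)
  data, so the envelope can narrowly miss the generating truth at a
  minority of grid cells even when every individual fit is accurate.
  The best-100 envelope is a more conservative band.
* No Bayesian posterior, profile likelihood, or global (Sobol)
  sensitivity — the uncertainty statements here are multistart
  dispersion, not calibrated credible intervals.
* Combinations of the ten regulatory mechanisms in one variant are out
  of scope, as are explicit Ca²⁺/DAG/receptor-proximal kinetics and
  spatial (PDE) modelling.
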