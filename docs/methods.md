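# Methods

## Model

The model is a deterministic mass-action description of bivalent IgG-type
antibodies binding cell-surface receptors in a stirred well. Species are
free antibody (solution, nM), free receptors, binary antibody–receptor
complexes and ternary receptor–antibody–receptor complexes (all surface,
receptors/cell). Every reaction is a reversible elementary step; there is
no receptor synthesis, internalization or degradation (the assays the model
emulates are run at 4 °C, where trafficking is suppressed), no ligand
competition, no receptor dimerization and no cross-cell bridging.

Two unit systems coexist. First-arm association couples a solution
concentration to a surface density, so kon carries nM⁻¹s⁻¹; cross-linking
is surface–surface, so kon* carries (receptors/cell)⁻¹s⁻¹. The bridge is

    α = cells_per_well · 10⁹ / (N_A · well_volume)   [nM per receptor/cell]

which is the nM depletion caused by one molecule binding per cell. With the
assay defaults (10⁵ cells, 200 µL) α ≈ 8.3×10⁻⁷. The well volume is not
stated alongside the cell count in the source material; 200 µL is the
standard 96-well assay volume and is exactly consistent with the published
α, so it is the default and remains configurable.

### Thermodynamic cycle and parameter reduction

For a bispecific antibody the two association orders (R1 first or R2 first)
form a closed cycle, and detailed balance requires the product of the
equilibrium constants around it to be one. Assuming koff is shared between
the first and second dissociation steps of a given receptor, the constraint
reduces to equality of the cross-arm binding efficiencies:

    χ = kon,R1*/(α·kon,R1) = kon,R2*/(α·kon,R2)

Because the three antibodies share binding domains (BS1 is built from the
tocilizumab and 10H2 domains) and similar IgG geometry, first- and
second-step rate constants are shared per receptor across antibodies. The
free parameters are therefore kon,6R, kon,8R, kon,6R*, koff,6R, koff,8R,
with kon,8R* derived. `complete_rates` performs the completion and records
χ; `detailed_balance_residual` reports K₁K₄/(K₂K₃) − 1 for any rate set
(zero by construction for completed sets, and a useful diagnostic for
hand-assembled ones).

### Statistical factors for homobivalent antibodies

A monospecific antibody has two identical arms, so its first association
carries a statistical factor 2 (either arm may bind), and its homoternary
complex carries factor 2 on dissociation (either of two identical bonds may
break). The cross-linking association and the binary dissociation carry
factor 1. This convention reproduces the observed behaviour that, at low
dose on a single-positive line, a monospecific out-binds the effectively
monovalent bispecific ("two binding sites double the likelihood of
binding") and converges with it at saturating dose. The homobivalent
cross-link reuses the same kon,R* as the bispecific for that receptor, per
the shared-geometry assumption.

### Combinations and degenerate cell lines

A combination treatment is modelled as independent antibody pools competing
for shared receptor pools; a "1:1 ratio" means equal nM of each antibody
summing to the stated total dose. If an arm's target receptor is absent
from a cell line, the corresponding reactions and complex species are
omitted entirely rather than simulated at zero receptor, keeping the state
vector minimal (a bispecific on a single-positive line reduces to one
reversible monovalent reaction).

## Assay protocol simulation

The in-vitro protocol is simulated as: dose at t = 0, stiff integration
over the association window (default 2 h), then — if washing is part of
the schedule — the free-antibody pool is zeroed and held at zero while the
surface species evolve for the detection window (default 15 min). The
clamp treats the washed medium as a sink: antibody that dissociates leaves
the system instead of rebuilding a free pool. This matches the
dissociation-only reading of the protocol; without the clamp a ~10⁻² nM
free pool re-accumulates, which is kinetically negligible but breaks the
free-antibody-stays-zero invariant the washout is meant to encode.

Integration uses LSODA (via `scipy.integrate.odeint`, which exposes the
same core as `solve_ivp` with less per-call overhead) with an analytic
Jacobian assembled from the reaction list. Default tolerances: rtol 10⁻⁸,
atol 10⁻⁶ receptors/cell for surface species and 10⁻¹² nM for solution
species. The fitting loop uses a relaxed profile (rtol 10⁻⁶, endpoint-only
output); tiny negative solver excursions are clipped to zero on output.
Dense trajectories use 200 log-spaced output points per phase; summaries
interpolate linearly between output points, and AUCs are trapezoidal on
that grid (within 0.1% of a 10× finer grid in the refinement test).

Summary accounting: binary-bound receptor is the sum of binary complexes;
ternary-bound receptor is twice the ternary complex count; the
bound-antibody signal counts each antibody scaffold once regardless of
valence engaged and is the quantity comparable to a flow-cytometry MFI
readout. Fractional occupancy is bound receptor over total receptor, per
type or pooled (the pooled value is the expression-weighted mean).

Endpoint sweeps ("24 h after dosing") run without washout. A caveat
documented here because it shapes several tests: with the calibrated rates,
sub-nM doses do *not* reach equilibrium within 24 h (the association
timescale 1/(kon·[Ab] + koff) is days at 0.1–1 nM). Agreement with the
algebraic steady state (0.5% in the test suite, against an independently
solved equilibrium system) therefore holds for doses ≥ 10 nM; low-dose
24 h endpoints are genuine transients, and statements about "slow
dissociation having little effect" likewise apply in the saturating-dose
regime.

## Calibration

The readout is in arbitrary fluorescence units, so data are normalized per
cell line by the mean BS1 signal at the saturation doses (default: the top
two doses of the series, configurable — the source protocol says only
"where binding reached saturation"). Simulated signals are normalized by
one of four schemes (reference BS1 or each antibody individually;
denominator at the data's saturation doses or at the maximum dose); the
BS1-at-saturation scheme is the default, as it gives the tightest
multi-start convergence. The cost is the plain sum of squared differences
between the normalized simulated signal and every normalized replicate row
(no per-dose weighting, residuals per replicate rather than per mean).

Optimization runs in log10 parameter space — the five parameters span nine
decades — with box bounds, using trust-region-reflective least squares from
Latin-hypercube starts drawn log-uniformly from the documented guess
ranges. Runs that do not converge, or whose optimum moved less than 10⁻³
log10 units from the guess (i.e. the optimizer never left the start), are
discarded; the reported fit is the lowest-cost survivor, and the standard
deviation of log10 optima across survivors measures identifiability per
parameter. The movement threshold and the optimizer tolerances (ftol =
xtol = gtol = 10⁻⁸, max 80 residual evaluations per start) are package
choices; only the discard outcome, not the criterion, is documented in the
source material. Conditions with no antibody target on the cell line
(10H2 on IL-6R⁺, tocilizumab on IL-8R⁺) carry no information and are
excluded, leaving seven (cell line, antibody) sets.

## Synthetic data

The generator forward-simulates the assay timeline for every feasible
condition, takes the bound-antibody signal at the final time, scales by an
arbitrary gain (default 1 — normalization removes it, which is exactly why
the real assay normalizes MFI), and applies mean-preserving multiplicative
log-normal noise per replicate (default CV 0.05; fluorescence intensities
are positive and roughly scale-proportional). Defaults mirror the assay:
the three transduced HEK 293T lines with their measured expression levels,
three antibodies, ten log-spaced doses over 10⁻²–10³ nM, three replicates.

What passing recovery tests show: the five parameters are identifiable from
noiseless data of this design, and the pipeline (generate → normalize →
fit) is self-consistent. What they do not show: anything about real
cytometer noise (the CV is a free knob, not a claim), detection-antibody
kinetics, gating artefacts, or biological replicate variability — so
recovery tolerances here do not bound the uncertainty of fits to real data.

## Sensitivity analyses

Local: baseline 10 nM BS1 on 5×10⁴/cell of each receptor, 2 h horizon; each
of the six rate constants and three initial concentrations is raised 10%
one at a time, and the coefficient is %ΔAUC (ternary-bound and total-bound
receptor over [0, 2 h]) per %Δparameter. A halved (5%) perturbation changes
each coefficient by < 20%, the smoothness check for the finite-difference
design. When a first-step on-rate is perturbed, the cycle-derived kon,8R*
is held at baseline by default (exactly one constant changes per
simulation); `rederive_dependent=True` propagates the cycle constraint
instead — whether the original analysis re-derived it is not stated, so
both are available.

Global: each rate constant is swept over 10⁻²–10²× its calibrated value
(9 log-spaced multipliers) at 24 h across doses {0.1, 1, 10, 100, 1000} nM,
reporting ternary and total fractional occupancy of IL-6R + IL-8R.

## Problem sizes used in the tests and reproduction script

The recovery test fits 30 Latin-hypercube starts against a noiseless
dataset with a 6-dose series (the other design defaults unchanged) — the
dose series is thinned because parameter information saturates well before
10 doses for noiseless data, and the fit remains over-determined (126 rows
for 5 parameters). Qualitative sweep tests use 3×3 dose/receptor subgrids
of the full ranges. The reproduction script's derived-constant computation
is closed-form algebra on the calibrated rate set and involves no
simulation.

## Known limitations

- Equilibrium claims are dose-regime dependent (see the 24 h caveat above).
- The statistical-factor convention for homobivalent antibodies is an
  assumption consistent with the described low-dose behaviour; the full
  supplementary equation set it would be checked against is not reproduced
  here.
- No spatial effects: cross-linking treats receptors as well-mixed on the
  surface, so receptor-density-dependent reach limits enter only through
  the lumped χ.
- The fitted-parameter dispersion (S.D. of log optima) measures multi-start
  spread, not statistical confidence; no likelihood model is attached to
  the residuals.
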