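# Methods

## Model and regimes

The two-state protein motif is a linear (first-order) reaction network:
synthesis of P at rate ks, interconversion P ⇌ Pm with basal rates kf
(forward) and kr (reverse), an additional signal-coupled conversion at rate
ka·A(t), and state-specific degradation dP, dPm. All macroscopic rates are
in µM and 1/time; the stochastic regime counts molecules in a fixed volume
(default 1 fL), so zeroth-order rates are multiplied by V·Av per µM,
second-order rates divided by it, and first-order rates are unchanged. The
signal-coupled channel is special: ka is second-order macroscopically, but
because the signal A enters in µM as an external level (not a species), the
product ka·A is already a first-order per-molecule rate and needs no volume
scaling.

The external signal is piecewise constant on half-open intervals. In the
linear model it is *not* a molecular species — steps are instantaneous
changes of a rate constant. In the mediator extension (kinase A_kin binds P,
the complex AP unbinds or converts to Pm catalytically; phosphatase B_phos
acts symmetrically on Pm) the signal *is* a species: a step sets the free
kinase copy number, leaving complexes untouched, so mediator molecules can
accumulate in bound form across steps. The 11-reaction mediator scheme and
its rate assignment (ka2 unbinding, ka3 catalysis, symmetrically kd2/kd3)
follow the trapping behaviour the scheme must reproduce: with
(ka1, ka2, ka3) = (10³, 0.1, 0.1) the high ka1/ka2 ratio locks P in AP
complexes and the response correlates negatively with the signal. Initial
conditions for mediator scenarios put (P, Pm) at the equilibrium of the
uncoupled linear part and expose the phosphatase initial (default 0.1 µM)
as a named setting.

Four solution regimes are implemented and cross-checked:

1. **ODE** — per constant-signal interval the system is affine-linear,
   dx/dt = M(A)x + b, solved exactly as x(t) = x* + e^{Mt}(x0 − x*) via
   eigendecomposition (the 2×2 matrix has real distinct eigenvalues
   whenever kr(kf + ka·A) > 0; degenerate rate sets fall back to `expm`).
   No numerical integrator is involved; the test suite verifies agreement
   with an adaptive integrator to 1e-8 and with brute-force Euler.
2. **CME/FSP** — probabilities over the rectangle P ∈ [0, MP],
   Pm ∈ [0, MPm] (defaults 110 × 30, 3441 states), enumerated as
   j(MP+1) + i + 1. The sparse generator keeps the *full* outflow of every
   state on the diagonal while dropping jumps that leave the rectangle, so
   columns sum to zero in the interior and the lost mass 1 − Σp bounds the
   truncation error. We use the column convention with ṗ = Gp (the
   row-sum phrasing describes the transposed operator). Propagation is
   `expm_multiply` on the sparse generator per output time; probabilities
   are never renormalized (truncation error stays visible), while first
   moments are renormalized by the retained mass.
3. **SSA** — Gillespie's direct method. At each signal switch the pending
   reaction time is discarded and re-drawn, which is exact because
   exponential waiting times are memoryless. Single runs store
   event-compressed (time, state) pairs with left-hold querying; ensembles
   sample on a caller grid without storing events. Per-cell seeds are
   master_seed + cell_index (mod 2³¹), making ensembles reproducible and
   invariant to chunking.
4. **CLE** — Euler–Maruyama on the chemical Langevin equation with six
   independent noise channels of amplitude √propensity, signed so that the
   conversion channels move P and Pm oppositely. Propensity arguments are
   clamped at zero (no reflection); the linear drift makes the ensemble
   first moment equal to the ODE solution. Default dt = 1e-3 (the fastest
   rate is ~11/time; a warning fires above a tenth of that timescale). The
   integrator steps *exactly onto* requested sample times: a left-hold lag
   of up to dt would otherwise bias fast transients (dPm/dt ≈ 66/time at
   signal onset) by a visible fraction of a molecule.

## Scenario generator

`twostate.scenarios` constructs every input used in the analyses. The step
protocol runs S = (0, 1, 0, 1, 2, 3, 4) on 50-unit intervals, scaled by
F_i ∈ {0.01, 0.1, 1, 10, 100}; outputs are taken at nine per-interval
offsets 50/2^14 … 25, 50 (63 grid points over t ≤ 350). Initial counts are
the printed (60, 6) molecules — the equilibrium of the dP = 0.01 variant;
the dP = 0 variant equilibrates P slightly higher, at 66. The doubling
profiles A1 = [2⁰ … 2¹⁰] µM and A2 = 2·A1 run on identical consecutive
50-unit intervals preceded by one zero-level interval so a pre-stimulus
equilibrium exists; an optional relaxation gap between fold steps is
supported and defaults to zero.

What the generator emulates is exactly the study's idealized conditions:
well-mixed single cells with identical parameters, no cell growth,
division, or extrinsic noise, and noiseless instantaneous signal steps.
Passing tests therefore demonstrate properties of the model and solvers,
not of any measured cell population; in real data, extrinsic parameter
variability and measurement noise would widen every distribution here.

## Fold-change detection

Per stimulation interval j the raw peak y_j of the response (not
baseline-subtracted) is located on a dense evaluation grid (default 4000
points/interval; the nine-point output grid can miss maxima). The three
ratio statistics |y¹_{j+1}/y¹_j|, |y¹_j/y¹_{j+1}|, |y¹_j/y²_j| and the
equivalent relative differences are computed over the *fold transitions*:
the onset-from-zero interval establishes the adapted baseline and is
excluded by default (`skip_onset`), because the 0 → 1 and 0 → 2 steps are
unequal folds — including them produces a 27% cross difference that says
nothing about fold-change detection, while the ten genuine 2-fold steps
stay within 8.6%. The verdict passes iff every per-interval value is at or
below the threshold (default 10%); violating intervals are named. The
statistics operate on whatever unit the trajectories carry and refuse
mixed-unit comparisons implicitly by working on plain peak arrays.

## Adaptation metrics and verdicts

Sensitivity is the largest excursion of the (smoothed) response from its
pre-stimulus equilibrium within a stimulation interval; the precision gap
is the distance between post- and pre-stimulus equilibria. Equilibria are
trailing-window means over the final 10% of an interval, and the same
trailing window (10% of the interval length, i.e. 5 time units) smooths
the trace before peak extraction. The smoothing is essential for
classifying stochastic traces: the raw maximum of ~500 correlated Poisson
samples per interval is biased upward by several molecules, which would
label even unstimulated cells responsive. A 5-unit window suppresses that
bias while preserving genuine responses — the slow response mode at
F_i = 1 has timescale ≈ 6.4 time units and the tall spike at F_i = 100
carries enough area to survive averaging.

Verdicts compare sensitivity and precision to a noise floor of two
standard deviations of a matched unstimulated (A ≡ 0) run of equal length:
pooled over cells for single-cell classification (≈ 2√6 ≈ 4.9 molecules,
the Poisson scale of the stationary law), and the standard deviation of
the matched unstimulated population-mean trace for population
classification. A trace is *adaptive* on an interval if sensitivity
exceeds the floor and the precision gap stays within it, *non-responsive*
if sensitivity does not clear the floor, *responsive-non-adapting*
otherwise. The trace-level label used in cross-scale comparisons is the
verdict of the first stimulation episode — the canonical step-response
test; per-interval labels and the majority label are also reported, since
later fold steps (2 → 3 → 4) are genuinely weaker stimuli that lose
response at every scale. These thresholds are conventions of this package,
chosen a priori from the model's timescales and calibrated only against
the unstimulated control; the qualitative pattern they expose — population
mean adaptive at F_i = 1 while ≥ 80% of single cells are non-responsive,
nothing responsive at F_i = 0.01, everything adaptive at F_i = 100 — is
robust to moderate changes of the window.

The ergodicity comparison builds the two sampling schemes — n independent
cells observed once at T*, versus one cell observed at n equally spaced
times beyond T* — histograms both on a common integer support and reports
their total-variation distance. T* has no privileged value and is a
required argument. Under a constant signal both histograms converge to the
same stationary law (the positive control); under the stepping signal they
need not, which is the rupture of biological ergodicity.

## Numerical choices and problem sizes

- `expm_multiply` tolerance is scipy's default (well below 1e-10 here);
  propagation of the 3441-state flagship run over all 63 grid points takes
  ~35 s on one CPU.
- The FSP mass threshold defaults to 0.9999 and raises a `TruncationError`
  naming the worst time point. On the published 110 × 30 bounds the
  *near-perfect* variant (dP = 0.01, stationary P mean 59.7) retains
  ≥ 99.99% throughout, but the *perfect-adaptation* variant equilibrates P
  at 66.2 molecules and leaks through the P = 110 boundary at
  ~1.3e-6/time during the A = 0 stretches, bottoming out at 99.980% by
  t = 350. Analyses of that scenario therefore pass an explicit working
  threshold of 0.999 and report the honest minimum mass; the acceptance
  suite keeps the stricter published bound as a failing assertion rather
  than hiding the discrepancy.
- Small negative probability entries from roundoff are floored at zero on
  output; vectors are validated against a −1e-12 floor.
- Oracle cross-checks: FSP vs dense explicit Euler (dt = 1e-5, reduced
  6 × 4 space with ks scaled to 5e-4 so the box holds the mass) agree to
  8e-7 per entry; SSA pure-birth waiting times pass a KS test against
  Exp(ks·V·Av) at n = 10⁴; a mid-flight signal switch is distributionally
  identical to a restarted process (5000 runs per construction).
- Ensemble sizes: 10,000 SSA cells for the regime-agreement check (3
  Monte-Carlo standard errors at every grid time), 10,000 CLE paths
  (dt = 1e-3, horizon through the first signal onset) against the ODE,
  10,000 draws per sampling scheme for the ergodicity positive control,
  and 200 classified cells (population mean over 50) per signal scale for
  the verdict study. These sizes keep the full suite around ten minutes on
  one CPU while leaving the statistical margins comfortable.

## Limitations

- No FSP for the mediator model: its reachable state space explodes and a
  Krylov-subspace or adaptive projection would be needed; the mediator
  model is simulated by SSA only.
- No tau-leaping, delays, or spatial effects; signals are piecewise
  constant only (arbitrary waveforms would require Magnus-type solvers).
- The CLE clamps propensities at zero rather than modelling boundary
  behaviour exactly; near-zero copy numbers it is a rough approximation,
  as is generic for Langevin treatments of discrete systems.
- Verdict thresholds (2σ floor, 10% window, first-episode rule) are stated
  conventions, not measured properties; conclusions should be read
  relative to them.
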