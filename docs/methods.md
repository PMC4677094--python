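# Methods

## The model

`mockloop` simulates a CMR-compatible mock circulatory loop at the
lumped-parameter (0D) level. The physical rig consists of a pulsatile piston
pump driving water through an aortic-arch phantom whose four outlets
(innominate, carotid, subclavian, descending aorta) each pass through a
calibrated needle tap, connecting tubing, and an air-chamber compliance
before returning through a common line to an open atrial reservoir held at a
constant 8 mmHg head.

Each branch *j* is modelled as

- a non-linear tap resistance with drop law ΔP₁ = a_j·Q² + b_j·Q
  (quadratic calibration of the physical tap; b_j may be negative),
- a linear tube resistance R_j2 in series, and
- a Windkessel compliance C_j to ground at the branch node,

and the four branches drain into a common node carrying a terminal
compliance C_t and a terminal resistance R_t to the atrial pressure source
P_at. Because b_j is negative, ΔP₁ alone is negative for
0 < Q < |b_j|/a_j (below ≈0.05 L/min for every branch); the solver only
ever evaluates the series combination a·Q² + (b + R₂)·Q, which is strictly
increasing for all four parameter rows (b + R₂ > 0), so no clamping is
needed. For reverse flow the laws are extended antisymmetrically
(ΔP(−Q) = −ΔP(Q)): the calibration covered forward flow only, taps resist
reverse flow as well, and oddness keeps the law total and monotone.

The multi-scale coupling of the original study attached this network as the
outflow boundary condition of a 3D finite-volume aortic domain. Here the 3D
domain is replaced by an **algebraic junction surrogate**: the prescribed
inlet flow Q_in(t) splits over the four branches through small linear
internal resistances r_int,j (default 1·10⁶ Pa·s/m³ each, ≈0.4 mmHg drop at
descending-aorta flow), representing the modest viscous loss of the aortic
lumen. The junction node is massless, so the junction pressure is closed
form:

    p_a = (Q_in + Σ_j p_j/r_int,j) / (Σ_j 1/r_int,j),
    q_j = (p_a − p_j)/r_int,j ,   Σ_j q_j = Q_in  (exactly).

Everything that depends on the 3D geometry (streamline patterns, velocity
asymmetry, local wall-shear concentrations) is consequently out of reach;
the surrogate preserves the quantities the network itself determines:
pressures, mean flows, and flow splits.

### Governing equations and integration

State variables are the five node pressures (four branch nodes, one common
node):

    C_j dp_j/dt = q_j − q_out,j ,   q_out,j = f_j⁻¹(p_j − p_c)
    C_t dp_c/dt = Σ_j q_out,j − (p_c − P_at)/R_t

where f_j⁻¹ is the closed-form inverse of the series branch law (quadratic
formula, odd extension). Integration is explicit forward Euler with
Δt = 1e-4 s, the scheme and step of the original computational model,
marched over repeated cardiac cycles from a uniform 80 mmHg initial state
(near the operating point; tests confirm the same periodic cycle is reached
from 40 mmHg) until the maximum node-pressure change between consecutive
cycle ends falls below the periodicity tolerance (default 0.1 mmHg,
at most 50 cycles). The default run converges in 7 cycles, ≈1 s on one CPU
core.

**Stiffness.** The terminal compliance C_t = 3.6·10⁻¹² m³/Pa makes the
common node marginally stiff: its local time constant at the operating
point is C_t/(Σ g_j + 1/R_t) ≈ 1.2·10⁻⁴ s (g_j the tangent conductances of
the branch laws at the operating flows), so Δt = 1e-4 s sits inside but
near the explicit stability bound 2τ. Two safeguards apply: (i) a guard
refuses any Δt above 0.8·2τ evaluated at the steady operating point for the
waveform's mean flow; (ii) an automatic sub-stepping fallback divides any
individual step whose *instantaneous* time constant (from the current branch
flows) would violate the bound — this engages only near zero-flow states
(start-up transients, the zero-inflow test case) and never in the periodic
regime of the default runs, which therefore remain plain Euler at Δt.

**Numerical behaviour.** Instantaneous mass conservation at the junction
holds to ~1e-13 relative (closed form). Halving Δt changes the converged
cycle-mean junction pressure by ~1e-5 mmHg. The periodicity tolerance
couples to flow balance: a residual cycle-end pressure drift δ leaves a net
compliance in/outflow imbalance ≈ ΣC_j·δ/T, about 0.14% of mean flow at the
default 0.1 mmHg tolerance and <0.01% at 0.005 mmHg; invariants that measure
the quality of the periodic regime itself are therefore checked on runs
relaxed to 0.005 mmHg. Pressures beyond 1e6 Pa abort the run as divergence.

### Steady-state oracle

For constant inflow the network has an algebraic solution used as an
independent cross-check of the integrator: p_c = P_at + R_t·Q_in, and the
common junction-to-common drop D solves Σ_j Q_j(D) = Q_in by bisection,
with r_int,j folded into each branch's linear term. At the 5.48 L/min
operating point this gives p_a ≈ 83.9 mmHg and splits ≈
(16.2, 10.6, 18.2, 55.0)%; the time-marched constant-inflow solution agrees
to <0.1 mmHg and <0.5% per branch.

## The inlet waveform generator

The study drove the loop with a Harvard-type piston pump and imposed the
2D phase-contrast-MR-measured inlet curve on the simulation; neither the
pump programme nor the curve itself was published. The generator therefore
emulates the waveform class rather than reproducing a specific trace:

- **Shape**: half-sine ejection over the systolic fraction of the cycle,
  optionally followed by a brief negative lobe (valve-closure backflow,
  amplitude ≤15% of peak, default 0 — a plain half-sine), zero flow in
  diastole. Samples are rescaled so the discrete cycle mean equals the
  configured cardiac output exactly.
- **Defaults**: period T = 0.8 s and systolic fraction 0.5, consistent with
  the comparison instants used in the study (0.1/0.2/0.4 s labelled
  early/peak/late systole, 0.6 s diastole, implying systole ending near
  0.4 s); cardiac output 5.48 L/min for the TGA run and 5.25 L/min for the
  control run, the sums of the respective mean outlet flows of the
  reference table. The network preset is identical for both runs, as in
  the study; the runs differ only through the inlet flow.
- **Measurement chain**: gated-PCMR acquisition is emulated by averaging
  the native samples into uniform phase bins at the requested temporal
  resolution (29.9 ms for the 2D sequence; retrospective gating averages
  within phase bins, so bin-averaging rather than decimation), plus
  optional additive Gaussian noise from a seeded generator — the only
  source of randomness in the package. 29.9 ms does not divide T = 0.8 s;
  the bin count is round(T/Δt_sample) and the effective resolution T/n.
  The fixtures use noise of 2% of mean flow, a typical PC-MRI flow
  repeatability figure.
- **Solver grid**: periodic linear interpolation onto the uniform Δt grid,
  wrapping at T.

What the generator does **not** emulate: the true (unpublished) pump
waveform shape, beat-to-beat variability, background-phase offsets, or
partial-volume effects of PC-MRI. Passing tests therefore demonstrate that
the network and solver reproduce the reference operating point *given a
physiologically plausible waveform of the correct mean flow*, with peak and
minimum pressures understood as waveform-shape-dependent (the acceptance
bands for them are correspondingly wide, ±10 mmHg).

## Derived mechanical quantities

- **Wall shear stress**: τ_w = 4μQ/(πr³), the Poiseuille cross-section
  estimate (≈0.54 Pa at mean inlet flow in the 12 mm inlet). It is a
  bulk-flow quantity and deliberately does not attempt the localized 3D
  wall-shear peaks, which are an order of magnitude larger.
- **Power dissipation index**: cycle-mean total-pressure flux balance
  across the whole network, mean[(p_a + ½ρv_in²)·Q_in] − P_at·mean[Q_t] −
  Σ_j mean[½ρv_out,j²·q_out,j], with outlet velocities from areas that
  default to the inlet area scaled by the branch mean-flow fractions
  (outlet diameters are not part of the network description; configurable).
  At periodicity this equals the per-element ΔP·Q dissipation sum plus the
  boundary kinetic fluxes to within the residual compliance storage (<1%),
  which is exactly what the energy-bookkeeping test asserts; it is
  non-negative for this passive network. It requires a converged result.

## Validation statistics

The comparison module mirrors the study's data analysis: cycle-mean/peak/
minimum waveform features with periodic linear interpolation at the four
comparison instants; outlet flow splits as percentages of a reference flow
(for simulations the cycle-mean inlet flow, which equals the outlet sum at
periodicity; for printed tables an explicit reference, because the
published bracketed percentages are normalised by the unprinted inlet mean
rather than the outlet sum); percent error 100·|sim − meas|/|meas|; the
largest per-branch split discrepancy with ties broken in canonical branch
order; squared Pearson correlation; and Bland-Altman bias with
bias ± 1.96·SD (n−1) limits of agreement (the conventional multiplier; the
study does not state one). Report display rounds to one decimal for % and
mmHg and two for L/min, matching the reference precision; full precision is
kept internally. The published reference tables (mean outlet flows and
splits for both anatomies, and the measured/computed mean pressures) ship
with the package so the in-study statistics can be recomputed offline
(`mockloop paper-stats`).

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| Δt | 1e-4 s | reference scheme's step; guard + sub-stepping above |
| samples per cycle | 8000 | T/Δt |
| max cycles | 50 | default runs converge in ~7 |
| periodicity tol | 0.1 mmHg | 0.005 mmHg for regime-quality invariants |
| initial pressure | 80 mmHg | near operating point; result independent of it |
| r_int | 1e6 Pa·s/m³ ×4 | junction surrogate loss, ≈0.4 mmHg at 3 L/min |
| atrial pressure | 8 mmHg | reservoir head |
| cardiac output | 5.48 / 5.25 L/min | TGA / control run |

## Known limitations

- No 3D (or 1D wave-propagation) fluid dynamics: streamlines, velocity
  symmetry, local WSS maps and mesh-sensitivity behaviour cannot be and are
  not reproduced.
- No inertance elements (the reference network has none), so the model
  cannot capture inertial pressure-flow phase lags in the tubing.
- The pump waveform shape is configuration, not measurement; peak/minimum
  pressures inherit that uncertainty.
- The element order around each compliance (compliance upstream of the
  metered tap, terminal compliance at the common node) follows the classic
  Windkessel reading of the rig schematic; the physical chamber positions
  are not fully documented, and a different ordering would alter waveform
  details though not mean splits.
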