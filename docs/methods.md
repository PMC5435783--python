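# Methods

## Flow model and discretization

The blood is treated as an incompressible Newtonian fluid (ρ = 1.0×10³
kg/m³, μ = 4.0×10⁻³ Pa·s) in a rigid 2D channel: the longitudinal section
of a carotid-like vessel, axis aligned with x, depth with y. Wall motion,
three-dimensionality and non-Newtonian rheology are outside the model.

The domain is an orthogonal, equidistant staggered grid whose spacing
matches the spatial resolution of the ultrasound measurement (reference
layout 36×86 cells, Δx = 163 μm, Δy = 173 μm, lumen diameter 6.4 mm).
Walls are stair-step (cell-aligned, no cut cells): each column carries the
first and last fluid row. x-velocity u lives on x-faces, y-velocity v on
y-faces, pressure at cell centers.

Finite-volume discretization:

- **Convection**: first-order upwind in the implicit operator plus a
  deferred-correction QUICK term (quadratic upstream-biased interpolation)
  evaluated from the previous outer iterate, falling back to upwind where
  the stencil would cross a wall. The deferred source is blended 50/50
  with its previous value between outer iterations; the fixed point — and
  hence the converged field — is the undamped QUICK discretization. This
  damping suppresses a sustained outer-iteration oscillation that
  otherwise appears when the deferred source interacts with a strong
  feedback force at frame-rate CFL numbers (u·Δt/Δx ≈ 50).
- **Diffusion**: central; wall-normal fluxes use the half-cell distance to
  the no-slip wall. With the one-sided wall-shear estimator
  τ = 2 μ u₁ / Δy this pair makes the discrete fully-developed Poiseuille
  wall shear exact up to the O((Δy/h)²) flux-normalisation term; measured
  error on the 36×86 layout is ≈0.3%.
- **Time**: second-order implicit backward differences (BDF2), backward
  Euler on the first step. Default Δt = 29.075 ms = one color-Doppler
  frame at 34.394 Hz.
- **Coupling**: SIMPLE-family outer iteration. The momentum predictor
  carries all body forces, so forcing enters the pressure-correction
  source through the provisional velocity and is not projected out. The
  pressure-correction Poisson is assembled from the momentum diagonal;
  its LU factorization is reused across outer iterations (refreshed every
  25, or every iteration in steady solves and when feedback is active,
  where a stale operator was observed to destabilize the iteration).
- **Linear solves**: scipy's sparse direct solver (SuperLU). The converged
  field is solver-independent to within the residual tolerance.

Boundary conditions: prescribed inlet profile (parabolic 6y(1−y) by
default; any shape function can be supplied), renormalised so the discrete
inlet flux equals `mean velocity × lumen height` exactly; no-slip walls;
"free-flow" outlet implemented as zero streamwise gradient with an
additive global mass correction, so inlet and outlet fluxes balance to
machine precision at every iterate.

Convergence is declared when the scaled momentum and continuity residuals
fall below 10⁻² (non-dimensional, the reference operating point;
configurable). Both momentum residuals are normalised by the *dominant*
momentum scale: in channel-like flows the transverse momentum is near
zero, and a self-normalised v-residual would gate convergence on numerical
dust. Under-relaxation defaults are 0.7 (momentum) and 0.3 (pressure);
on oscillatory stagnation (a strong-feedback regime) the factors decay by
0.6 every 80 outer iterations.

## Measurement integration (UMI)

The feedback body force inside the feedback domain (x from 1/36 to 29/36
of the domain by default) is

    f = −K_v* (ρU/L) (V_c − V_m) ê,

with characteristic velocity U = 0.1 m/s, length L = 6.4 mm (the inlet
diameter), beam unit vector ê, and non-dimensional gain K_v* (reference
value 500; 0 = ordinary simulation). V_c is the computed velocity
projected on ê at cell centers (bilinear interpolation when the
measurement grid differs; the default twin uses identical grids, matching
an acquisition whose resolution equals the grid spacing). At K_v* = 500
the force is stiff (an explicit update would scale velocity errors by
G·Δt/ρ ≈ 226), so inside the momentum solve the self-component is treated
implicitly (diagonal ê_i² term) with the cross component lagged; on outer
convergence this equals the explicit formula. Momentum equations are
solved sequentially (v assembled after the u update) to halve the
cross-term lag.

Per-frame agreement is the error norm e(t) = (1/N_e) Σ |V_c − V_m| /
V_type over feedback-domain points with valid measurement (N_e counts
exactly those points; V_type = 0.39 m/s, a typical carotid speed).

The mean inlet velocity is estimated each frame by a golden-section search
on e(t), each candidate performing one fully converged implicit step; the
bracket (default ±0.2 m/s) is re-centered on the previous frame's
estimate, and the termination tolerance is the 10⁻³ non-dimensional value
(10⁻⁴ m/s at U = 0.1). Unimodality of e over the bracket is assumed. The
first frame has no predecessor; it is initialised by a steady solve at an
inlet velocity back-projected from the first Doppler frame (mean of
V_m/ê_x over the inlet-adjacent feedback columns) — a pragmatic choice for
a quantity the procedure does not otherwise define.

No measurement-error compensation model is applied to V_m; robustness to
noise is assessed empirically with the noisy twins instead.

## Pressure channel and synchronization

- **ECG**: 50 Hz zero-phase IIR notch (Q = 5, i.e. 10 Hz bandwidth; the
  forward-backward pass places a spectral zero at 50 Hz, exceeding the
  −90 dB target), then linear-phase equiripple FIR high-pass (order 250,
  stop 2 Hz / pass 5 Hz) and low-pass (order 200, pass 20 Hz / stop
  30 Hz) at 200 Hz, each applied centered with reflection padding so the
  integer group delay is exactly compensated. R peaks are per-cycle
  maxima with a refractory constraint (default 0.4 s); equal candidates
  tie-break toward the earlier peak.
- **PPG**: normalized to [0,1] by the record min/max, then affinely
  calibrated to cuff systolic/diastolic pressures — this rides on a linear
  lumen-size/pressure relation; whether lumen *area* or *diameter* should
  carry the linearity is an open question of the measurement principle
  itself, and the pixel-area signal is used as-is.
- **Image pulse**: per-frame lumen pixel area. Each frame is smoothed,
  Otsu-thresholded, and segmented by marker-based watershed on the
  gradient image (lumen marker: the darkest connected region; background:
  bright tissue plus the frame border). Frames with no component are
  interpolated with a warning. The pulse is least-squares affine-scaled
  onto the normalized PPG.
- **Coarse synchronization**: exhaustive 1-ms scan of the clock shift
  (search range ±500 ms) minimising the mean squared difference of paired
  per-cycle peak times over six cardiac cycles; peak trains are paired
  greedily one-to-one by time distance. Ties prefer the smaller |shift|.
- **Fine synchronization**: the PU loop (pressure vs velocity) over one
  beat. Its systolic limb — from the velocity foot, located by the
  intersecting-tangents construction, to the velocity peak — is a straight
  line under the water-hammer relation only at exact synchrony. A ±30 ms
  scan in 5-ms steps maximises the linear-fit R²; curvature is classified
  from the sign of a quadratic fit in min-max-normalized coordinates
  (|coefficient| < 0.05 counts as straight). The sign convention — a
  *delayed* pressure channel makes the limb sag below its chord
  ("concave"), an advanced one bulge above ("convex") — is pinned by the
  synthetic water-hammer regression tests rather than by geometric
  intuition.

## Wave intensity

WI = (dP/dt)(dU/dt) pointwise; derivatives are 5-point local-quadratic
(Savitzky–Golay) at 200 Hz, with the 34.394 Hz inflow series linearly
resampled to 200 Hz first. Units follow the inputs (mmHg/s · m/s² by
default; a mmHg→Pa helper is provided). Samples are labelled forward
(both derivatives positive), backward (WI negative), or absorption (both
derivatives negative with WI positive, the flow-stopping end-systolic
wave); the significance threshold is 5% of the record's max |WI|, and
derivative values at the round-off floor are flushed to zero so constant
channels yield no labels.

## Synthetic twins: what they emulate and what they do not

The default scenario mirrors a clinical carotid acquisition: straight
6.4-mm channel on the 36×86 grid, 34.394 Hz frames, beam 20° from the
depth axis, inlet mean velocity 0.25 m/s with three harmonics sweeping
≈0.10–0.47 m/s over a 0.933 s period (a generic carotid-like waveform —
the exact clinical waveform is not published in tabular form), biosignals
at 200 Hz, pressures spanning 80–120 mmHg. Skewed-profile truths provide
model error that the parabolic-inlet control cannot represent, which is
what makes the assimilation benefit measurable.

Simplifications to keep in mind when generalising twin results to real
data: Doppler noise is i.i.d. Gaussian (no speckle correlation, no
aliasing); B-mode frames are smooth ellipses with multiplicative speckle
(no point-spread function or attenuation); the ECG template carries only
R-peak fidelity; truth and assimilated runs share the same discretization,
so twin errors measure observability and model error, not discretization
error. All generators are bit-reproducible under a fixed seed.

## Numerical choices and degenerate inputs

- Zero flow is an exact fixed point of the solver; empty/constant signals
  are rejected (normalization, PPG) or return empty results with warnings
  (flat ECG).
- The golden-section bracket is clipped to [−0.2, 1.5] m/s overall.
- Problem sizes in the test-suite twins (16×30 to 36×86 grids, 8–35
  frames, 100 synchronization trials) were chosen as the smallest runs
  that exercise the full pipeline at the reference operating point.
- The acceptance driver (`scripts/acceptance.py`) seeds every random
  stream from its `--seed` argument.

## Known limitations

Rigid walls and 2D flow (no out-of-plane motion); stair-step walls limit
formal spatial order near boundaries to first order; the inlet profile
family must contain or approximate the true profile for the *ordinary*
simulation to be meaningful (the UMI run corrects interior model error but
not the inlet family itself); pulse-wave velocity and augmentation index
are not computed; no Doppler aliasing correction or multi-beam
compounding.
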