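# Methods

## Model and integration

The chain is the discrete free-draining harmonic ("Rouse-type") model: N
point beads with friction coefficient f, consecutive beads joined by
Hookean springs of constant k, immersed in a linear shear flow of rate
G = dv_x/dy and a heat bath of temperature kBT.  The overdamped equations
of motion are

    dR_i/dt = −(k/f)(2R_i − R_{i−1} − R_{i+1}) + G (y_i − y_cm) x̂ + F_i(t),

with one-sided spring terms −(k/f)(R_1 − R_2) and −(k/f)(R_N − R_{N−1})
at the ends (the symmetric end form is forced by Newton's third law: the
spring drift must sum to zero over beads).  The shear drift is measured
from the instantaneous center of mass, recomputed every step, so the flow
describes motion relative to the chain center and never advects the COM.
Assumptions: no hydrodynamic interactions between beads (free-draining),
no excluded volume, no bending or torsional stiffness, no inertia.

Integration is explicit Euler–Maruyama: each step displaces the beads by
Δt times the deterministic drift plus an i.i.d. Gaussian displacement of
per-component standard deviation Δr = √(2 kBT Δt / f).  Drifts are
re-evaluated every step.  The scheme is stable for Δt < 2/Γ_max with
Γ_max = (4k/f) sin²((N−1)π/2N) ≈ 4k/f; a divergence (non-finite
positions) raises an error naming the step index.  The integrator is a
compiled (numba) kernel fed by chunked, seeded NumPy Gaussian streams, so
runs are bit-reproducible from the seed; a 2.2×10⁶-step run of a 16-bead
chain takes a few seconds on one core.

Initial condition: a Gaussian random walk with per-bond component
standard deviation √(kBT/k) — the equilibrium bond distribution at G=0 —
followed by a discarded thermalization segment that erases any residual
transient (under shear, the stationary state differs from the G=0 start;
thermalization lengths are chosen ≥ 10 relaxation times of the slowest
mode).

### Default parameters

| parameter | default | units | why |
|---|---|---|---|
| n_beads N | 16 | — | smallest chain with a rich mode spectrum and a power-of-two length for the wavelet pyramid |
| spring_constant k | 1 | force/length | sets the unit system |
| friction f | 1 | force·time/length | unit system |
| thermal_energy kBT | 1 | energy | unit system; bond length scale √(kBT/k)=1 |
| time_step Δt | 10⁻³ | time | ≈ 1/500 of the stability limit; halving it leaves fitted rates unchanged within errors |
| sample_stride | 10 | steps | frames every 0.01 time units, ≫ finer than any mode period of interest |
| production / thermalization | 2×10⁶ / 2×10⁵ | steps | desk-scale default (seconds); all statistics modules accept arbitrarily longer runs |

## Trajectory convention

Frames are recorded every `sample_stride` steps, the first at step
`stride` (the initial configuration is not stored); frame j therefore
sits at time (j+1)·stride·Δt after the end of thermalization.  Each frame
stores both the positions and that *single step's* displacement array.
The rotation estimator needs the instantaneous velocity proxy
displacement/Δt; reconstructing velocities from consecutive stored frames
would average over `stride` steps and is wrong for this purpose, so a
trajectory without the displacement channel refuses to compute rotation
diagnostics rather than silently substituting frame differences.
Positions are stored in the lab frame; every diagnostic that needs them
re-centers on the per-frame center of mass.

## Rouse modes

C_{nα}(t) = (1/N) Σ_i r_{iα}(t) cos(nπ(i−½)/N), n = 0..N−1, with inverse
x_i = C_0 + 2 Σ_{n≥1} C_n cos(nπ(i−½)/N).  The cosine vectors are exact
eigenvectors of the tridiagonal connectivity matrix M (free ends), so at
G=0 each internal mode is an Ornstein–Uhlenbeck process with rate

    Γ_n = (4k/f) sin²(nπ/2N)    (→ k n²π²/(f N²) for n ≪ N),

the eigenvalue of (k/f)M, and stationary variance ⟨C_n²⟩ = kBT/(2NfΓ_n)
(equipartition over the mode coordinates; verified in the tests against
both an eigen-decomposition oracle and an independent single-mode OU
recursion).  For a two-bead chain Γ_1 = 2k/f, the textbook bond
relaxation rate — a useful end-member check of the normalization.
Mode series are computed from COM-relative coordinates, which leaves all
internal modes unchanged (the n ≥ 1 cosine rows sum to zero) and makes
C_0 an identically-zero null channel.

## Rotation diagnostics

The whole-body rotation test treats the beads as if in circular motion:
ω_z Σ_i⟨x_i² + y_i²⟩ = ⟨Σ_i x_i ẏ_i − Σ_i y_i ẋ_i⟩, with cyclic
analogues for the x and y axes, positions COM-relative and velocities
the recorded single-step displacements over Δt (with the COM displacement
subtracted).  ω is computed as a **ratio of time averages**, not an
average of per-frame ratios: per-frame ratios are dominated by the
thermal noise in the velocity proxy, whose per-component standard
deviation is √(2kBT/(fΔt)) ≈ 45 in reduced units.  That noise also sets
the statistical error of L = term_xy − term_yx, which is why resolving
the rotation signal needs long runs (see problem sizes below).  For an
undistorted coil, advection balance gives ω_z = −G⟨y²⟩/⟨x²+y²⟩ → −G/2:
clockwise rotation in the x–y plane.

Errors: block averaging with 20 contiguous blocks (block length well
above the slowest relaxation time in all shipped run sizes); ω errors
from per-block ratios.  Zero-consistency is declared when |mean| <
3 × block error.

## Spectral and local coordinates

Spatial Fourier components a_{k,α} = Σ_i cos(k r_{iα}) (COM-relative) are
bounded by N and equal N at k=0.  Default wavenumbers k ∈ {0.5, 1, 2, 4}
in reduced length units span scales from the coil size to the bond
length; any set shows the same qualitative behavior.  The Haar pyramid
for N = 2^m beads defines level-1 channels as pairwise means c and
half-differences d of consecutive bead coordinates (bead 1 ↔ j = 1), and
level n > 1 by recursing on the level-(n−1) means; non-power-of-two
chains are rejected rather than padded.  A reconstruction inverse is
provided and exact to machine precision, which pins the conventions.

## Correlation analysis and fits

Stationary correlators ⟨a(t)b(t+τ)⟩ are estimated over all admissible
origins (FFT-accelerated), after subtracting sample means — except the
end-to-end correlators ⟨R_e(0)·R_e(t)⟩ and its unit-vector analogue,
which are conventional raw dot-product averages (so the unit correlator
is exactly 1 at lag 0).  The early-time single-exponential fit is
unweighted least squares on log values over lags from 0 up to the first
crossing of 1/e of the lag-0 value (truncated at the first non-positive
estimate, minimum 3 points); the fit reports amplitude, rate, window,
whether the 1/e crossing was actually reached, and the log-space rms
residual.  The window rule is scale-free and matches the region where a
single exponential is a valid description; no weighting is applied, and
the residual summary is reported so alternatives can be compared.

Estimator statistics dictate problem sizes.  For an OU channel of rate γ
observed for total time T, no estimator beats a relative rate error of
about √(2/(γT)), and ACF-plus-fit estimates also acquire a positive
finite-T bias of order the variance of the sample mean (measured at
+17 ± 21% for γT ≈ 77 on synthetic OU series).  The shipped test sizes
follow from this: the zero-shear rate-recovery run uses 1.6×10⁷ steps
(T = 16000, pooled-axis error ≈ 3–4% on Γ_1) and the shear sweep uses
1.2×10⁷ stride-10 steps per shear rate for the mode statistics.  The
rotation estimator is different: its error is dominated by the white
thermal noise of the velocity proxy, so it scales with the number of
*sampled* steps, not elapsed time, and stride-sampled frames discard most
of the information.  The sweep therefore measures rotation from dedicated
every-step-sampled segments (20 contiguous segments of 5×10⁵ steps per
shear rate, segment scatter giving the errors), at which the L(G)
linearity across G ∈ [0, 0.15] is resolvable.  Null-channel checks over
the ~100 cross-correlation channels use a family-wise criterion (no
channel beyond 5 block-error sigma, at most 5% beyond 3 sigma): a
per-channel 3-sigma rule applied to that many correlated channels
rejects a true null with substantial probability.

The sweep driver assigns each shear rate the seed base+index, fits every
mode autocorrelation per axis, measures equal-time cross amplitudes
⟨C_{n,a}C_{m,b}⟩ for same-n axis pairs (xy, yz, zx) and a set of
differing-mode pairs, and aggregates rotation and shape diagnostics, all
with block errors (rate errors from independent per-block fits).

## Synthetic fixtures

The fixtures module validates every diagnostic without the physical
simulator.  The rigid-motion generator emits exact rigid rotations
(inter-bead distances preserved to machine precision) and records the
instantaneous rigid-body velocity times Δt as the per-frame displacement
— the ideal limit of a vanishing integration step — so the rotation
estimator must recover the angular rate exactly, not through a
finite-angle chord.  The OU generator uses exact discretization
(a' = a e^{−γΔt} + matched noise), making its ground truth independent
of Euler integration error; at γ = 0 it degenerates to a driven random
walk.  The single-mode chain realizes one cosine eigenvector, tying the
transform conventions to the spring dynamics.  What these fixtures do
not emulate: thermal noise in the velocity channel (rigid fixture),
multi-exponential decays and cross-correlated channels (OU fixture) —
so passing them validates estimator correctness, not the statistical
resolution of the physical runs, which the long-run tests cover.

## Numerical choices and limitations

* COM-relative referencing throughout the diagnostics; lab-frame storage.
* Histograms: 100 uniform bins from 0 to 1.05× the observed maximum per
  category, overridable by a fixed bin width.
* Degenerate inputs: chains need ≥ 2 beads; zero-length end-to-end
  vectors are skipped as unit-correlator origins; constant correlators
  fit to rate ≈ 0 with the crossing flag unset.
* The model is free-draining with Hookean springs: no hydrodynamic
  coupling (so no Zimm-type mode mixing), no excluded volume, no
  finite extensibility.  Quantities tied to those physics (e.g.
  intrinsic viscosity) are out of scope.
* Fits are single-exponential by design; channels with visibly bimodal
  decay (inner-block wavelet details under shear) are compared by 1/e
  decorrelation times instead.
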