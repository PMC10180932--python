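# shearchain

Brownian dynamics of a free-draining harmonic bead-spring chain in a
linear shear field, with the full diagnostic kit needed to decide a
classic question of polymer physics: **does a flexible coil in shear flow
rotate as a body, or does it merely deform affinely?**

The package is for polymer and soft-matter physicists who want a small,
fully reproducible simulation in which the two historic pictures of
dilute-solution chain dynamics can be told apart:

* the **Rouse picture** — internal normal modes relax independently,
  their amplitudes and rates unaffected by shear, and the coil does not
  rotate;
* the **Kirkwood–Riseman picture** — the coil responds to shear by
  whole-body rotation (plus translation), with internal motions on top.

## Model

N beads with friction f are joined by Hookean springs of constant k and
driven by a linear flow v_x = G·y and Gaussian thermal kicks:

    dR_i/dt = −(k/f)(2R_i − R_{i−1} − R_{i+1}) + G (y_i − y_cm) x̂ + F_i(t)

(one-sided spring terms at the two ends; the shear is measured from the
chain's instantaneous center of mass, so it exerts no net force).
Integration is explicit Euler–Maruyama with per-step thermal displacement
of standard deviation √(2 kBT Δt / f) per component.

Diagnostics:

* **Rouse modes** C_{nα} = (1/N) Σ_i r_{iα} cos(nπ(i−½)/N), whose
  zero-shear autocorrelations decay at the connectivity-matrix
  eigenvalue rates Γ_n = (4k/f) sin²(nπ/2N);
* **rotation estimator** ω_z = ⟨Σ_i x_i ẏ_i − y_i ẋ_i⟩ / Σ_i⟨x_i²+y_i²⟩,
  with velocities taken from the recorded single-step displacements;
* shape moments ⟨x_α x_β⟩, ⟨x_α² x_β²⟩, distance distributions and
  end-to-end correlators;
* spatial Fourier components a_{k,α} = Σ_i cos(k r_{iα}) and a Haar
  wavelet pyramid c/d(n, α, j) of the bead coordinates — local collective
  coordinates that resolve end-vs-center mobility;
* stationary correlation estimation with early-time single-exponential
  fits and block-averaged errors, aggregated over a shear sweep.

## Worked example

```python
import shearchain as sc

cfg = sc.SimulationConfig(n_beads=16, shear_rate=0.1, seed=1)  # k=f=kBT=1, dt=1e-3
traj = sc.simulate(cfg)                     # 2e5 + 2e6 steps, ~5 s
rot = sc.rotation_diagnostics(traj)
print(f"omega_z = {rot.z.omega:.4f} +/- {rot.z.omega_err:.4f}")
print(f"term_xy = {rot.z.term_ab:.2f}, -term_yx = {-rot.z.term_ba:.2f}")

modes = sc.mode_trajectory(traj)
cf = sc.correlate(modes[:, 1, 0], None, 4000, traj.frame_spacing)
fit = sc.fit_initial_exponential(cf)
print(f"Gamma_1x = {fit.rate:.4f}  (zero-shear value "
      f"{sc.analytic_rates(cfg).rates[1]:.4f})")
```

prints (seed 1):

```
omega_z = -0.0269 +/- 0.0087
term_xy = -2.00, -term_yx = -2.00
Gamma_1x = 0.0304  (zero-shear value 0.0384)
```

The chain rotates clockwise (ω_z < 0, about −G/2 for a weakly distorted
coil), the two angular-momentum term sums agree within their noise —
whole-body rotation, not affine drift — and the slowest x-mode relaxes
markedly slower than its zero-shear rate: shear softens the mode
spectrum, which the independent-mode picture forbids.

The same pipeline is available from the shell:

```bash
shearchain simulate --n-beads 16 --shear-rate 0.1 --output-dir run/
shearchain analyze run/trajectory.xyz --displacement-file run/displacements.xyz
shearchain sweep --shear-list 0,0.05,0.1,0.15 --output-dir sweep/
```

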