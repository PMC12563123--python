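# itwater

Information-theoretic comparison of rigid water force fields.

Rigid three-site water models — TIP3P, SPC, SPC/ε — differ in monomer
geometry, point charges and Lennard-Jones parameters, and those differences
propagate to the electronic structure of the water clusters they generate.
`itwater` quantifies that propagation with five descriptors of a 3D
probability density ρ, computed in both position (r) and momentum (p) space:

| measure | definition | meaning |
|---|---|---|
| Shannon entropy | S = −∫ ρ ln ρ | global dispersion (nats) |
| Fisher information | I = ∫ \|∇ρ\|²/ρ | local sharpness (a.u.) |
| disequilibrium | D = ∫ ρ² | deviation from uniformity (a.u.) |
| LMC complexity | C_LMC = D·e^S | order–disorder balance, ≥ 1 |
| Fisher–Shannon complexity | C_FS = I·e^(2S/3)/(2πe) | local–global balance, ≥ 3 |

The package is aimed at force-field developers and molecular-simulation
practitioners who want a desk-scale, statistically disciplined way to ask
whether two water models are distinguishable — and by which descriptors —
without running MD or DFT. It provides:

* **synthetic densities** — analytic Gaussian-mixture surrogates of
  water-cluster electron densities, conditioned on each force field's
  geometry and charges, with seeded jittered ensembles emulating per-frame
  descriptor tables;
* **a density engine** — analytic mixtures and CUBE-backed grids, adaptive
  tensor-trapezoid quadrature, and the position→momentum conjugation for
  isotropic Gaussian primitives (σ_p = 1/(2σ_r));
* **descriptors** — the five measures above in both spaces, with quadrature
  error estimates and the universal bounds C_LMC ≥ 1, C_FS ≥ 3 as built-in
  sanity oracles;
* **cluster identification** — the Sevick O–O distance criterion
  (transitive linkage, default cutoff 3.5 Å) with a size-class harvester
  and multi-frame XYZ I/O;
* **a statistics suite** — Shapiro–Wilk (Royston), Filliben probability-plot
  R², Welch's unequal-variance t-test with Welch–Satterthwaite degrees of
  freedom, and box-plot summaries;
* **a pipeline + CLI** — `itwater all` runs
  generate → descriptors → normality screen → Welch matrices → scaling
  report, writing appendix-style CSVs named `{size}M_{space}_{model}.csv`.

## Worked example

```python
from itwater import (SPC, SPCE_EPS, TIP3P, EnsembleSpec, QuadratureSpec,
                     descriptor_set, make_descriptor_samples,
                     make_monomer_density, welch_t)

ds = descriptor_set(make_monomer_density(SPC))
print(f"SPC monomer:   S_r = {ds.S_r:.4f} nats   I_r = {ds.I_r:.4f}   D_r = {ds.D_r:.6f}")
print(f"               C_LMC_r = {ds.C_LMC_r:.4f}   C_FS_r = {ds.C_FS_r:.4f}")
dt = descriptor_set(make_monomer_density(TIP3P))
print(f"TIP3P monomer: S_r = {dt.S_r:.4f} nats   I_r = {dt.I_r:.4f}   D_r = {dt.D_r:.6f}")

quad = QuadratureSpec(base_points_per_axis=32, refinement_levels=2)
tables = {
    ff.name: make_descriptor_samples(
        ff, EnsembleSpec(n_molecules=1, n_frames=30, seed=s), quad=quad)
    for s, ff in ((1, SPC), (2, SPCE_EPS), (3, TIP3P))
}
def s_r(name):
    t = tables[name]
    return t[(t.space == "r") & (t.measure == "S")]["value"].to_numpy()

null = welch_t(s_r("SPC"), s_r("SPC/e"))
alt = welch_t(s_r("TIP3P"), s_r("SPC"))
print(f"Welch S_r  SPC vs SPC/e : t = {null.t:+.3f}  df = {null.df:.1f}  p = {null.p_value:.3f}")
print(f"Welch S_r  TIP3P vs SPC : t = {alt.t:+.3f}  df = {alt.df:.1f}  p = {alt.p_value:.2e}")
```

prints

```
SPC monomer:   S_r = 2.6261 nats   I_r = 12.0109   D_r = 0.161665
               C_LMC_r = 2.2342   C_FS_r = 4.0499
TIP3P monomer: S_r = 2.6109 nats   I_r = 11.9154   D_r = 0.162311
Welch S_r  SPC vs SPC/e : t = -0.851  df = 56.1  p = 0.398
Welch S_r  TIP3P vs SPC : t = -20.206  df = 51.4  p = 4.23e-26
```

Read this as: SPC and SPC/ε share a monomer geometry, so their 30-frame
jittered ensembles are two draws from the same S_r distribution — Welch's
test rightly finds nothing (p = 0.40). TIP3P's shorter O–H bond and
narrower angle (0.9572 Å / 104.52° vs 1.0 Å / 109.45°) make its monomer
density slightly more compact — lower entropy, and a difference that
dwarfs the jitter noise (p ≈ 4·10⁻²⁶). The complexities sit above their
universal bounds (C_LMC ≥ 1, C_FS ≥ 3), as they must for any density.

The same analysis across cluster sizes, from the shell:

```sh
itwater all --sizes 1,3,5 --n-frames 30 --seed 1 --out-dir runs/demo
```

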