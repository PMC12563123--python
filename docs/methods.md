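# Methods

## Scope and model

`itwater` compares rigid three-site water force fields (TIP3P, SPC, SPC/ε)
through five information-theoretic descriptors of a 3D probability density
ρ, evaluated in position space and in the momentum-space conjugate γ:

* Shannon entropy `S = -∫ ρ ln ρ` (nats) — global dispersion / delocalization;
* Fisher information `I = ∫ |∇ρ|²/ρ` (a.u.) — local sharpness / localization;
* disequilibrium `D = ∫ ρ²` (a.u.) — deviation from uniformity;
* LMC complexity `C_LMC = D·e^S` (dimensionless, ≥ 1 for any 3D density);
* Fisher–Shannon complexity `C_FS = I·J`, `J = e^(2S/3)/(2πe)`
  (dimensionless, ≥ 3, equality attained exactly by isotropic Gaussians).

Both complexities are invariant under translation and dilation; the other
three transform as `S → S + 3 ln λ`, `I → I/λ²`, `D → D/λ³` under dilation
by λ. These transformation laws and the two universal bounds are the
package's principal machine-checkable oracles.

All internal lengths are bohr, momenta bohr⁻¹, entropies nats. Geometry
interfaces accept angstrom.

## Synthetic densities

Real per-frame descriptor data would come from MD snapshots fed through DFT.
To make every downstream stage testable at desk scale, the `synthetic`
module builds analytic surrogates: each atom carries one isotropic Gaussian
(defaults O: 0.45 bohr, H: 0.65 bohr — arbitrary but fixed, since only
*relative* model differences are interpreted), and a configuration's density
is the unit-normalized mixture over all atoms. Two weighting modes:

* `electron_count`: weights ∝ neutral-atom electron counts (8, 1, 1)/10.
  Models sharing a geometry — SPC and SPC/ε — produce *identical* densities,
  which makes that pair an exact statistical null.
* `charge_perturbed`: weights ∝ Z − q with q the force-field partial charge
  (SPC oxygen 8.82, SPC/ε oxygen 8.89, renormalized), a linear surrogate
  that separates the SPC family while sharing its geometry. This is a
  device for exercising the statistics, not a claim about real electron
  densities.

Frame-to-frame variability is isotropic Gaussian jitter of the atomic
centers, default σ = 0.01 Å, standing in for the constraint-algorithm and
integration noise that perturbs nominally rigid monomers in MD. Small
jitter acts linearly on each descriptor, so per-frame descriptor samples
are approximately normal — matching the data regime the statistical
protocol assumes for small clusters.

Cluster configurations are grown by seeded rigid-body attachment: each new
molecule is placed at a distance drawn from `oo_distance_range`
(default 2.6–3.2 Å, bracketing the first O–O coordination shell) from a
random existing oxygen, rejecting candidates that bring any O–O pair below
the range minimum (retry budget 1000 per molecule, then a loud
`GenerationError`). Every nearest-neighbor O–O distance therefore lies in
the range and the configuration is connected at any cutoff ≥ the range
maximum.

What the generator does **not** emulate: hydrogen-bond directionality,
realistic cluster geometry statistics, coupling between molecules beyond
placement constraints, and real electronic structure (no covalent/H-bond
redistribution). Passing tests therefore demonstrate the correctness of the
descriptor/statistics machinery and the *logic* of the force-field
comparison (geometry-driven separation, same-geometry nulls, entropy growth
with size), not quantitative agreement with DFT-based descriptor values.

## Quadrature

Functionals of Gaussian mixtures are integrated by tensor-product trapezoid
rule on a box covering every component center ± k·σ, with k set so each
component leaves tail mass below `extent_rule` per axis (default 1e-10,
k ≈ 6.5). Isotropic Gaussians factor along axes, so grid evaluation uses
1D exponentials and rank-1 accumulation, never 3D exponentials. Refinement
proceeds by point doubling from `base_points_per_axis` (default 64); the
integral is accepted when the inter-level relative change drops below
`tolerance` (default 1e-4), and exhausting `refinement_levels` raises an
error carrying the last two estimates.

Two numerical subtleties are deliberate:

* The inter-level difference is dominated by the *coarser* level's error —
  trapezoid sums of smooth, fast-decaying integrands converge
  super-algebraically under point doubling — so the accepted value is
  typically several orders of magnitude more accurate than the reported,
  conservative error (measured: single-Gaussian closed forms agree to
  ~1e-7 at defaults).
* Reported errors are floored at a truncation-bias bound
  (`5·k²·extent_rule`): cutting the box biases the gradient-weighted
  integrand low by ~k² times the omitted mass, and this bias is invisible
  to inter-level differences since both levels share the box. The floor
  matters exactly where it must: an isotropic Gaussian sits *on* the
  C_FS = 3 bound, so any unreported negative bias would appear as a bound
  violation.

`ρ ln ρ` is evaluated with the `ρ → 0` limit convention (`xlogy`); the
Fisher integrand guards the division at a 1e-300 floor. Grid densities
(CUBE files) are integrated once by Riemann sum at native resolution, with
gradients from second-order central differences (one-sided at boundaries)
— momentum-space descriptors are emitted as absent for grids, since no
analytic conjugate exists.

## Momentum conjugation

Position→momentum conjugation is restricted to isotropic Gaussian
primitives: the modulus of the Fourier transform of a displaced real s-type
primitive is displacement-independent, so each position component of width
σ maps to a momentum component at the origin with width 1/(2σ) and the same
weight. This preserves normalization and yields the closed-form identity
`S_r + S_p = 3(1 + ln π) ≈ 6.434190` for any single-Gaussian pair, used as
an acceptance oracle. General contracted-GTO transforms are out of scope.

## Cluster identification

The Sevick criterion links two molecules when their O–O distance is at most
`r_cut`; clusters are connected components (scipy `csgraph`, cross-checked
in tests against a hand-written BFS oracle). The cutoff is not dictated by
the underlying protocol, so it is a required visible parameter defaulting
to 3.5 Å — the conventional first minimum of g_OO(r) in liquid water.
Minimum-image convention applies on orthorhombic boxes only. Cutoff
monotonicity (clusters at a smaller cutoff refine those at a larger one)
is a tested invariant.

## Statistical protocol

Normality is screened by Shapiro–Wilk *and* a Filliben probability plot;
normality is "supported" only when p > 0.05 and R² > 0.9. Shapiro–Wilk
uses Royston's AS R94 coefficient and p-value approximations throughout
3 ≤ n ≤ 5000 (exact at n = 3), verified in tests to agree with an
independent reference implementation to ≤ 1e-6 on W and ≤ 1e-4 on p.
Filliben probabilities follow the ascending standard convention
(`p_1 = 1 − 0.5^{1/n}`, interior `(i − 0.3175)/(n + 0.365)`,
`p_n = 0.5^{1/n}`); ordered statistics must map to increasing probabilities
for the plot regression to be meaningful, so the occasionally-seen reversed
indexing of the two edge branches is not offered.

Mean comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom and two-sided p-values at α = 0.05.
No multiple-testing correction is applied by default (per-pair thresholds);
a Holm step-down helper exists for callers who want one. Box-plot summaries
use linear interpolation between closest ranks for quartiles (the single
supported convention) and the 1.5·IQR outlier rule.

## Pipeline seeding

`run_pipeline` derives a CRC32 sub-seed per (model, size) from the top-level
seed. Consequences, both intentional: (a) the whole run is bit-reproducible
from one seed; (b) different models receive independent jitter streams, so
the SPC vs SPC/ε comparison in `electron_count` mode is an honest null —
two independent samples from the same distribution, with the nominal ~5%
false-significance rate — rather than two copies of the same sample. At
the library level, `make_descriptor_samples` is a pure function of
(force field, spec), so identical-geometry models under the *same*
`EnsembleSpec` yield bit-identical tables, which tests exploit as an exact
equality oracle.

Discrimination checks are stated on S_r for the same-geometry null pair
(testing all five strongly correlated position-space measures jointly would
mechanically inflate the null failure rate above the nominal level), and on
all five position-space measures for the TIP3P-vs-SPC-family alternative,
where geometric separation dominates jitter noise by orders of magnitude.

## Problem sizes

Default test and acceptance workloads: 100 random mixtures (1–12
components) for the complexity-bound sweep; 50 independently seeded
30-frame monomer ensembles for the discrimination check; 4-frame ensembles
across sizes 1–11 for the entropy-scaling check (means under 0.01 Å jitter
are stable to ~1e-3 nats, far below the ~ln-size growth being tested);
coarser 32-point base grids for many-sample statistical runs, where the
~1e-7 per-value accuracy of the default grid is not needed.

## Known limitations

* Absolute descriptor scales depend on the arbitrary atomic widths; only
  relative model comparisons are meaningful, and no attempt is made to
  match descriptor magnitudes from multi-electron DFT densities.
* The momentum leg of a multi-atom configuration piles all conjugate
  components at the origin (the s-type displacement-independence), so
  momentum-space descriptors saturate with cluster size rather than
  resolving structure — consistent with momentum space being the less
  discriminating representation.
* Gridded (CUBE) densities support position-space descriptors only.
* Periodic minimum-image clustering assumes orthorhombic boxes.
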