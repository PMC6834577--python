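# Methods

## Signal model

All imaging is modelled as steady-state spoiled gradient echo (SPGR):

    S = M0 · sin α · (1 − E1) / (1 − E1 cos α),   E1 = e^(−TR·R1)

with TR = 54.24 ms and α ∈ {10°, 30°} by default, matching a small-animal
protocol at 9.4 T. Relaxation rates are kept in s⁻¹ throughout the
relaxometry and concentration stages; time is converted to minutes (and
rates to min⁻¹) only at the kinetic-fitting boundary, so that K^trans and
the plasma rates come out in the units in which they are conventionally
reported.

Phantom relaxometry uses the saturation-recovery model
`S = S0(1 − e^(−TR/T1))` over seven TR values (200–2000 ms in 300 ms
steps). The T1 fit is nonlinear least squares initialized at
`T1 = TR_max/2`, `S0 = max S`, bounded to T1 ∈ (1 ms, 20 s); a signal set
with no TR dependence is returned flagged unidentifiable rather than as a
silent NaN. Relaxivity is the ordinary-least-squares slope of `R1 = 1/T1`
against concentration (≥ 3 tubes required); the intercept absorbs the
solvent rate, so the slope is invariant to any constant offset in R1.

With exactly two baseline flip angles the variable-flip-angle relation is
solved in closed form: the two points `(S/tan α, S/sin α)` define a line
whose slope is E1 and whose intercept is `M0(1 − E1)`. No iterative
multi-angle regression is implemented because the acquisition uses exactly
two angles. Voxels whose implied E1 leaves (0, 1) — air, noise-dominated,
or saturated — are masked invalid and counted. The same closed-form
inversion applied at the single dynamic angle gives R1(t), and
`C(t) = (R1(t) − R1_0)/r1` gives concentration. ΔR1 maps are carried
alongside C so the two are always related by the exact scalar r1.

Negative concentrations produced by noise are deliberately *not* clipped
before kinetic fitting — clipping at zero biases small-K^trans estimates
upward even further than the non-negativity bound of the fit already does —
and are clipped only for display purposes. The "final concentration" of an
ROI is its mean over the last acquired frame (~57 min post injection).

## Reference-region K^trans

The fitted model is the reference-region form of the Tofts model (no
plasma-volume term), with skeletal muscle as the reference tissue. The
absolute K^trans scale rests on the assumed muscle constants; the defaults
K^trans_RR = 0.1 min⁻¹ and ve_RR = 0.1 follow the common literature
convention for muscle, are exposed in configuration, and the dimensionless
ratio K^trans_TOI/K^trans_RR is always reported alongside so results stay
interpretable under any other assumed constants. Because the model is
homogeneous in the shared concentration scale, fitted K^trans values are
invariant to multiplying both curves by a positive constant — which is why
agents quantified in mM and in mg/mL remain comparable through K^trans.

Numerics, in fitting order:

- **Convolution.** The integral `∫ C_RR(t)·e^(−kep(T−t)) dt` treats its
  input as piecewise linear between samples and integrates each segment
  against the exponential kernel in closed form (`expconv`). This is exact
  for piecewise-linear input at *any* kernel rate; naive trapezoidal
  weighting of the kernel overshoots by a factor ~kΔt/2 once the washout
  time constant drops below the 34 s frame spacing.
- **Sub-frame reference shape.** At fast washout (kep ≳ 2 min⁻¹) even the
  exact piecewise-linear treatment is biased, because C_RR itself curves
  within the first frames. Before voxel fitting the sampled muscle curve
  is therefore refined by fitting the muscle compartment model driven by a
  biexponential plasma curve — the same plasma family the pharmacokinetics
  stage fits — and evaluating the fitted model on a fine internal grid
  (34 substeps per frame ≈ 1 s). If that parametric fit fails or misfits
  (relative residual > 25 %), the fit falls back to plain piecewise-linear
  interpolation. On noiseless synthetic studies this reduces the
  worst-case K^trans recovery error over
  ktrans ∈ [0.001, 0.5] min⁻¹ × ve ∈ [0.05, 0.5] from ~55 % to < 2 %.
- **Parameterization.** Internally (ktrans, kep = ktrans/ve) for
  conditioning; reported as (ktrans, ve). Bounds: ktrans ∈ [0, 5] min⁻¹,
  kep ∈ [10⁻⁵, 10³] min⁻¹.
- **Initialization.** The linearized reference-region solution — the
  least-squares solve of `C_TOI = x1·C_RR + x2·∫C_RR − x3·∫C_TOI`, whence
  ktrans = x1·K^trans_RR and kep = x3 — with fallback start values
  (0.05 min⁻¹, ve 0.2) when the linear system is singular or out of range.
- **Fitting grid.** Dynamic frame times in minutes with the injection
  instant (t = 0, C = 0) prepended to anchor the integrals.
- **Degeneracies.** An all-zero tissue curve short-circuits to
  ktrans = 0, flagged; fits pinned at the ktrans upper bound or with ve
  outside (0, 1] are flagged and excluded from ROI means, with exclusion
  counts reported.

## Plasma pharmacokinetics

The vessel-ROI mean curve is fitted to `Cp(t) = A e^(−αt) + B e^(−βt)`
from the observed peak frame onward (the rising limb reflects injection
duration, not disposition). Start values come from curve stripping: a
log-linear fit of the final third of the curve gives (B, β), a log-linear
fit of the positive residual gives (A, α). If the optimizer returns the
phases mislabelled (α < β) they are swapped and logged; if a single
exponential matches the biexponential residual within 1 % the phases are
declared unidentifiable and a single-phase fit is reported. Half-lives and
elimination constants are derived per phase as t½ = ln2/rate and
K_el = ln2/t½ — an exact identity by construction in every emitted fit.
Group tables are built by computing per-subject parameters first and
averaging afterwards; group means of half-lives and of rate constants do
not satisfy the ln2 identity between themselves because means do not
commute through the reciprocal, and no attempt is made to force them to.

AUC is the trapezoidal integral of the vessel curve over a window inside
the acquired times (endpoints linearly interpolated), in min × concentration
unit. Concentration units (mM for the small-molecule agent, mg/mL for
particles quantified that way) are carried as tags and never converted
between agents.

## Group statistics

`compare_groups` runs one-way ANOVA followed by Tukey's HSD (the
studentized-range test with Tukey–Kramer adjustment for unequal group
sizes, via `scipy.stats.tukey_hsd`), significance at p < 0.05. Groups with
n < 2 are excluded with a warning rather than refused — tiny, unbalanced
groups are the norm in animal studies. Under the null (simulated
identically distributed groups) the rejection rate is verified to sit at
the nominal 5 %.

## Synthetic data generator

The generator emulates the measurement process, not the scanner: per-voxel
tissue curves `Ct(T) = ktrans·∫ Cp(t)·e^(−(ktrans/ve)(T−t)) dt` driven by
a biexponential plasma function on a 1 s internal grid, vessel voxels
carrying Cp itself, SPGR signal formation per frame (two pre-injection
baselines at 10°/30°, dynamic frames at 30°), and seeded additive Gaussian
noise on the magnitude (Rician available behind a flag; at the simulated
SNR ≈ 50 the difference is negligible). Injection occurs immediately after
the baseline frames; Cp = 0 at and before t = 0. The tissue model contains
no plasma-volume term, deliberately matching the fitted reference-region
equation.

Default scene: 64×64×3 voxels with block ROIs (focal injury 0.170 min⁻¹ /
ve 0.30; contralateral 0.00135 min⁻¹ / ve 0.05; muscle 0.1 min⁻¹ / 0.1,
equal to the assumed reference constants; a small vessel), T1 ≈ 1.8–2.4 s
by tissue, 100 frames at 34 s, plasma half-lives 3.12 / 44.02 min with
amplitudes A = 0.5, B = 0.25 (concentration units), noise σ = 0.002 of M0
(baseline tissue SNR ≈ 50). The shape is a downsampled version of a
128×128×10 acquisition, chosen so that full-study tests run in seconds to
minutes on one CPU; phantom simulations use σ = 0.005 with 25-voxel tube
ROIs.

What passing recovery tests on these data do **not** show: robustness to
B0/B1 field inhomogeneity (no B1 correction is implemented; the two-angle
baseline is assumed accurate), motion, water-exchange and T2* effects on
the signal model, partial-volume contamination of the vessel and muscle
ROIs, or physiological deviation of muscle from the assumed reference
constants — all of which affect real studies and none of which the
generator simulates.

## Known limitations

- Very small K^trans (~0.001 min⁻¹) is positively biased under noise:
  estimates are bounded below by zero, so noise cannot average out
  symmetrically. Noisy focal/contralateral fold ratios are therefore
  conservative (smaller than truth); fold-change validation uses noiseless
  scenes, and contralateral means under noise should be read as upper
  bounds.
- The parametric reference-curve refinement assumes the muscle curve is
  well described by biexponential-plasma-driven single-compartment
  kinetics; for reference tissues that violate this the fit falls back to
  piecewise-linear interpolation and fast-washout voxels lose accuracy.
- The plasma elimination phase is observed for only ~1–4 half-lives within
  the ~57-minute session; elimination rates at the slow end (t½ ≈ 45 min)
  carry proportionally larger uncertainty.
- ve is weakly identified where ktrans is tiny (the tissue curve is nearly
  flat); only K^trans should be interpreted in such regions.
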