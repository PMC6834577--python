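# nanoktrans

Quantifying nanoparticle delivery to injured brain tissue from dynamic
contrast-enhanced MRI (DCE-MRI), without an arterial input function.

After a traumatic brain injury the blood–brain barrier opens transiently,
letting circulating nanoparticles (NPs) accumulate in the damaged tissue —
an EPR-like effect that can be exploited for drug delivery. This package
implements the full image-analysis chain needed to measure that delivery
with T1-weighted DCE-MRI in small animals, where arterial blood sampling is
impractical:

1. **Relaxivity calibration** — per-tube T1 from multi-TR phantom scans by
   saturation recovery, `S = S0 (1 − e^(−TR/T1))`, then the agent's
   relaxivity `r1` as the slope of `R1 = r1·C + b`.
2. **Baseline mapping** — per-voxel pre-contrast `R1_0` and `M0` from two
   spoiled-gradient-echo (SPGR) baselines at flip angles 10°/30°, solved in
   closed form from the variable-flip-angle relation
   `S/sin α = E1 · S/tan α + M0(1 − E1)`, `E1 = e^(−TR·R1)`.
3. **Concentration mapping** — dynamic frames inverted to `R1(t)` and
   converted by `C(t) = (R1(t) − R1_0)/r1`.
4. **K^trans mapping** — the reference-region model (RRM), derived from the
   Tofts model with a muscular reference region replacing the arterial
   input function:

   ```
   C_TOI(T) = (K^trans_TOI / K^trans_RR) · C_RR(T)
            + (K^trans_TOI / K^trans_RR) · (K^trans_RR/ve_RR − K^trans_TOI/ve_TOI)
              · ∫₀ᵀ C_RR(t) · e^(−(K^trans_TOI/ve_TOI)(T−t)) dt
   ```

   fitted voxel-wise by nonlinear least squares for `(K^trans_TOI, ve_TOI)`.
5. **Plasma pharmacokinetics** — the vessel-ROI curve fitted to
   `Cp(t) = A e^(−αt) + B e^(−βt)` (distribution + elimination phases),
   with per-phase half-lives `t½ = ln2 / rate`, elimination constants
   `K_el = ln2 / t½`, and the trapezoidal AUC of the imaging session.
6. **Group statistics** — one-way ANOVA with Tukey HSD post-test across
   agents or injection times, and focal/contralateral fold-change tables.

Because no public animal data exist for this protocol, the package ships a
first-class synthetic study generator (`nanoktrans.synth`): SPGR signal
formation at the real acquisition parameters (TR = 54.24 ms, 10°/30°
baselines, ~100 frames at 34 s), tissue curves driven by a biexponential
plasma function with distinct kinetics per region, and seeded magnitude
noise — so every stage is validated by parameter recovery against known
ground truth.

## Worked example

Simulate a small noiseless study of a PLGA nanoparticle with a strong
focal/contralateral permeability contrast and run the whole pipeline:

```sh
cat > scene.yaml <<EOF
scene:
  tracer: PLGA
  shape: [24, 24, 1]
  noise_sigma: 0.0
EOF
nanoktrans run --config scene.yaml --seed 1 --out demo_out
```

prints

```
          roi  n_voxels  n_used  n_excluded  ktrans_mean  ktrans_sd  ve_mean  ratio_mean  fold_vs_contralateral
        focal        16      16           0     0.170001        0.0     0.30    1.700015               125.9265
contralateral        16      16           0     0.001350        0.0     0.05    0.013500                 1.0000
{
  "auc": 11.217827177701269
}
```

The scene was generated with focal `K^trans` = 0.170 min⁻¹ and
contralateral 0.00135 min⁻¹; the fitted maps recover both to better than
0.1 % and the fold ratio 125.9 — a two-orders-of-magnitude uptake contrast
between injured and intact tissue. `ratio_mean` is the dimensionless
`K^trans_TOI / K^trans_RR`, which stays meaningful whatever absolute
muscle constants are assumed. The AUC (min·mM) is the integral of the
vessel concentration curve over the ~57-minute session. `demo_out/`
additionally contains the `K^trans`/`ve`/ratio volumes (NIfTI), ROI
time-course tables and figure, the biexponential plasma fit
(`pk_table.csv`), and a JSON manifest that makes the run bit-reproducible.

The same machinery is available as a library:

```python
from nanoktrans.report import run_pipeline
results = run_pipeline({"scene": {"tracer": "PLGA"}}, "out/", seed=1)
print(results["ktrans"].summary)
```

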