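# dysmorph

Robust superimposition of homologous landmark configurations with explicit
outlier processes, and per-landmark maps of detected form abnormalities
(*dysmorphograms*).

## The problem

Geometric morphometrics studies *typical* variation of biological form.
Clinical practice constantly meets the opposite: localized, atypical form
differences — a surgical change, a unilateral overgrowth, a syndromic
deformation.  Such differences wreck the standard least-squares (Procrustes)
superimposition through the **Pinocchio effect**: a large change confined to
a few landmarks contaminates the fitted pose, smearing residual error onto
perfectly normal regions, so the residuals no longer reflect true form
difference.  And even a robust fit, by itself, gives no principled answer to
the question clinicians actually ask: *which* landmarks are abnormal, and
with what confidence?

`dysmorph` treats abnormalities as **outliers against a norm**.  Landmark
displacements after superimposition are modelled as a two-component mixture:
an inlier process of additive white Gaussian noise (AWGN) with scale σ, and
a uniform outlier process.  A latent indicator `z_j` per landmark selects
the component; superimposition and outlier detection become one joint
estimation problem, solved by Expectation–Maximization.  The E-step yields
the posterior **inlier belief**

    b_j = Pr_i(d_j) / (Pr_i(d_j) + λ),      λ = exp(−κ²/2) / (√(2π)·σ),

which crosses ½ exactly at Mahalanobis distance ‖d_j‖/σ = κ, so the single
tuning constant κ is a per-landmark significance level (κ = 2 by default).
The M-step is a belief-weighted Procrustes fit plus a noise-scale update
σ̂² = Σ b_j‖d_j‖² / Σ b_j.  The map `1 − b_j ∈ [0, 1]` is the dysmorphogram.

Three assessment protocols are built on this engine:

| protocol | norm | question |
|---|---|---|
| `assess_change(pre, post)` | earlier state | what changed between two time points? |
| `assess_asymmetry(config, bmap)` | the form itself vs. its mirror | which regions break bilateral symmetry? (also returns a robust midsagittal plane) |
| `assess_discordancy(config, pdm)` | population PDM | where does a form leave its population's range? |

For discordancy the norm is a point distribution model (PDM): consensus
shape plus principal-component modes of within-population variation.  The
modes join the transformation model, so typical population variation is
compensated exactly like pose, and the fitted PDM instance is the
**norm-equivalent** — the harmonious counterpart of the assessed form.

## Worked example

The classic toy experiment: Pinocchio's nose tip grows forward by 30 mm,
the lying face is additionally rotated and translated arbitrarily, and
0.3 mm of scan noise is added.

```python
import numpy as np
from dysmorph import assess_change
from dysmorph.synthetic import pinocchio_pair

honest, lying, bmap, regions, truth = pinocchio_pair(1000, seed=1, noise_sigma=0.3)
dg, result = assess_change(honest, lying, kappa=2.0)

print(f"converged: {result.converged} after {result.n_iter} iterations")
print(f"estimated noise sigma: {result.sigma_per_coord:.3f} mm per coordinate")
print(f"flagged landmarks: {int(dg.flagged.sum())} of {len(dg.labels)}")
print(f"largest residual: {dg.magnitudes.max():.2f} mm "
      f"at {dg.labels[int(np.argmax(dg.magnitudes))]}")
```

prints

```
converged: True after 12 iterations
estimated noise sigma: 0.288 mm per coordinate
flagged landmarks: 131 of 1000
largest residual: 30.83 mm at nose_tip_020R
```

The fit recovers the injected noise level (0.288 vs 0.3 mm), flags the
entire 120-landmark nose-tip region (the 11 extra flags are the expected
per-landmark false-positive rate at κ = 2 under noise), and reads off the
30 mm displacement directly from the residual of the flagged region — an
ordinary least-squares fit instead smears several millimetres of spurious
difference over the whole face.

The same pipelines are scriptable from the shell:

```
dysmorph simulate pinocchio --seed 1 --out-dir demo
dysmorph change demo/honest.csv demo/lying.csv --out demo/dysmorphogram.csv
dysmorph asymmetry demo/honest.csv --pairs demo/pairs.csv
dysmorph build-norm cohort_dir/ --variance 0.98 --out norm.json
dysmorph discordancy face.csv --norm norm.json --format ply --out face_dg.ply
```

Landmark files are labelled CSV (`label,x,y,z`, mm) or TPS; dysmorphograms
export as CSV or ASCII PLY point clouds (score in the `quality` channel).

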