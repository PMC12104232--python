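# contourvar

Inter-observer variability (IOV) in radiotherapy contouring — different
clinicians delineating the same tumor and organs at risk on the same
images — propagates into the treatment plan: an under-contoured target
receives a conformal dose that leaves part of the *true* target cold, and
a mis-drawn organ boundary shifts its reported dose. `contourvar` is a
pipeline for quantifying that chain on voxelized structure sets and dose
grids, aimed at medical physicists and radiation oncology researchers
studying delineation quality assurance:

1. **Geometric variability** between observer contours and a gold
   standard: signed volume difference ΔV = V_M − V_S, max/min volume
   ratio (MMR), coefficient of variation (CV), Dice similarity
   coefficient (DSC) and the symmetric 95th-percentile Hausdorff distance
   (HD95), plus a STAPLE expectation-maximization consensus for building
   gold standards from observer panels.
2. **Dosimetric impact**, evaluating each observer's dose grid on the
   gold-standard structures: cumulative DVHs, prescription dose coverage
   PDC = 100 · |PTV ≥ Rx| / |PTV|, Dmax/Dmean/D1cc summaries by organ
   class (serial vs parallel), and relative differences
   ΔD_diff = 100 · (D_M − D_S)/D_S.
3. **Radiobiological endpoints**: equivalent uniform dose
   EUD = (Σᵢ vᵢ dᵢᵃ)^(1/a) with a = −8 for targets (cold-spot
   sensitive), the Schultheiss logistic tumor control probability
   TCP = 1 / (1 + (TCD50/EUD)^(4γ₅₀)) with TCD50 = 61.69 Gy, γ₅₀ = 3.38,
   and a modified linear-quadratic NTCP
   exp[−N₀ V^(−k) exp(−αDΓ)], Γ = 1 + d_f/(α/β).
4. **Risk-predictor screening**: paired observer-vs-standard tests,
   Spearman correlations between geometric metrics and ΔPDC/ΔTCP pooled
   over patients × observers, and selection of predictors with
   **|R| > 0.4 and P < 0.05**.

Because clinical structure sets are rarely shareable, the package
includes a first-class synthetic cohort generator: a head-and-neck-like
phantom, simulated observers with controlled volume bias and smooth
surface noise, and a conformal Gaussian-penumbra dose surrogate, so the
whole chain is testable and reproducible end to end. See
`docs/methods.md` for the models, conventions, and what the synthetic
validation does and does not establish.

## Worked example

```python
from contourvar import RunConfig, run_all, report

# 12 synthetic patients, 4 observers with systematic volume biases of
# -4, -2, +1 and +3 mm plus 1 mm surface noise (the defaults)
outputs = run_all(RunConfig(out_dir="demo_run", seed=0))
print(outputs["predictors"][["x_name", "y_name", "n", "r", "p"]])
```

prints

```
           x_name           y_name   n         r             p
0    dV_cc(GTVnx)  dPDC_pct(PTVnx)  48  0.922709  1.144376e-20
1    dV_cc(GTVnx)      dTCP(PTVnx)  48  0.917379  5.003876e-20
2      DSC(GTVnx)  dPDC_pct(PTVnx)  48  0.589209  1.053703e-05
3  HD95_mm(GTVnx)      dTCP(PTVnx)  48 -0.583008  1.372319e-05
4      DSC(GTVnx)      dTCP(PTVnx)  48  0.582972  1.374359e-05
5  HD95_mm(GTVnx)  dPDC_pct(PTVnx)  48 -0.575781  1.854480e-05
```

Reading this: over 48 pooled (patient, observer) pairs, the signed
target volume difference ΔV correlates strongly and positively with both
the loss of prescription coverage on the gold-standard PTV (ΔPDC,
R = 0.92) and the loss of tumor control (ΔTCP, R = 0.92) — observers who
under-contour the target produce plans that underdose the true target —
so ΔV passes the |R| > 0.4, P < 0.05 gate and is flagged as a
delineation-risk predictor. DSC and HD95 carry the same signal more
weakly. `report(outputs)` renders per-structure mean ± SD summary tables;
`demo_run/` holds the per-stage CSVs (`metrics.csv`, `dose_metrics.csv`,
`radbio.csv`, `corr.csv`, `predictors.csv`) and a `manifest.json` that
makes the run byte-reproducible.

The same stages are scriptable from the shell:

```
contourvar simulate --out cohort/ --n-patients 12 --seed 0
contourvar run --out demo_run --seed 0
contourvar geom --structures cohort/patient_001/observer_A \
                --structures cohort/patient_001/observer_B \
                --reference cohort/patient_001/standard --out geom.csv
```

## Library layout

| module | contents |
|---|---|
| `contourvar.core` | `VoxelGrid`, `StructureMask`, `DoseGrid`, NIfTI I/O, trilinear dose resampling, exact-EDT margin expansion |
| `contourvar.geometry` | ΔV, MMR, CV, DSC, HD95 (symmetric + directed), STAPLE consensus, group reports |
| `contourvar.dosimetry` | DVH, PDC, Dmax/Dmean/D1cc, ΔD_diff, plan-onto-standard mapping |
| `contourvar.radiobiology` | EUD, TCP, NTCP, endpoint deltas, `RadiobioParams` |
| `contourvar.statistics` | paired t / Wilcoxon choice, Spearman (exact p at small n), correlation matrices, predictor selection |
| `contourvar.synthetic` | phantom, observer models, dose surrogate, cohort generation |
| `contourvar.pipeline` | `RunConfig`, `run_all`, `report` |

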