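# glioshape

Boundary-shape morphometrics and progression-risk modeling for WHO grade
II–III insular glioma.

Insular gliomas grow against the basal ganglia, and the shape of that
medial interface on the standardized axial slice carries prognostic
information: a tumor that spreads along the natural anatomy leaves a smooth
**curved** boundary, while a tumor that compresses the deep nuclei leaves a
sharp **linear** one. `glioshape` quantifies this boundary from a 2D binary
segmentation mask and carries the result through the downstream clinical
analysis:

1. **Boundary geometry** — extract the medial arc of the tumor contour
   (marching squares + outward-normal selection around a user-supplied
   medial direction), then compute six descriptors:
   box-counting fractal dimension `FD = lim log N(ε) / log (1/ε)`,
   total curvature `∫|κ(s)| ds`, maximum and average `|κ(s)|`, the RMS of
   `dκ/ds`, and tortuosity `L/D` (arc length over endpoint chord).
   The boundary is classified **L** when FD ≤ 1 and **C** when FD > 1;
   the curvature suite is evaluated only for curved boundaries.
2. **Cohort association** — marker calling from raw assay fractions
   (inclusive thresholds: IDH1 30%, ATRX/TP53/MGMT 10%, 1p/19q 25%),
   per-variable 2×2 tables against the shape label, cross-product odds
   ratios with Woolf 95% intervals, chi-square tests, and a Spearman/VIF
   collinearity screen.
3. **Survival models** — Kaplan–Meier, Mantel–Cox and Breslow–Wilcoxon
   tests, Cox proportional hazards (Efron ties), stepwise-Wald selection,
   the two published risk scores

       Risk_L = 0.78·Ki67 + 0.54·epilepsy − 0.77·TP53 − 0.90·1p/19q + 0.55·volume
       Risk_C = 0.04·Ki67 − 0.86·IDH1 + 1.31·age + 1.39·volume + 1.19·tortuosity − 1.70·1p/19q

   (each term a 0/1 adverse indicator), a nomogram-style integer points
   scale, log-rank-optimal score thresholds, and internal validation:
   bootstrap optimism-corrected C-index and 5-fold cross-validated C with
   calibration (ICI / E50) at a fixed horizon.
4. **Synthetic data** — masks whose medial edge is an analytic curve
   (straight edge, circular arc, sinusoid, Koch polyline, clothoid) with
   closed-form descriptor values, and cohorts with the published marginal
   frequencies whose PFS is drawn from a proportional-hazards model using
   the published coefficients — so every stage is testable without any
   patient data.

## Worked example

```python
>>> import glioshape as g
>>> from glioshape.simulate import ShapeSpec, CohortSpec, make_shape, make_cohort

>>> mask, truth, analytic = make_shape(ShapeSpec(family="arc", radius=20, angle=180))
>>> report = g.measure_boundary(mask)
>>> report.fd, report.shape_label
(1.1143, 'C')
>>> round(report.tortuosity, 3), round(report.total_curvature, 3)
(1.167, 1.634)
```

The 90° medial window of a disk boundary subtends roughly a quarter turn,
so the measured total curvature ≈ π/2 = 1.571 rad (1.634 with the extra
pixel steps at the arc ends); the pixelated arc's FD of 1.11 exceeds 1,
classifying the boundary as curved, and tortuosity 1.167 is the
staircase-inflated estimate of the analytic (π/4)/sin(π/4) ≈ 1.111.

```python
>>> cohort = make_cohort(CohortSpec(n=2000, include_missing=False, seed=3))
>>> coded = g.code_covariates(g.RISK_L, cohort)
>>> data = cohort[["pfs_months", "event"]].join(coded)
>>> g.cox_fit(data, list(coded.columns)).params.round(2).to_dict()
{'ki67_high': 0.79, 'epilepsy_yes': 0.53, 'tp53_mutant': -0.78,
 'chr1p19q_codel': -0.87, 'volume_high': 0.58}
```

The refit recovers the generating Risk_L coefficients (0.78, 0.54, −0.77,
−0.90, 0.55) to within sampling error at n = 2000.

The same workflow is scriptable from the shell:

```bash
glioshape simulate cohort --n 330 --seed 7 --out cohort.csv
glioshape associate --cohort cohort.csv --out association.csv
glioshape survfit --cohort cohort.csv --model riskL --out model.json
glioshape validate --cohort cohort.csv --model riskL --bootstrap 200 --cv 5 \
    --seed 17 --out validation.json
```

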