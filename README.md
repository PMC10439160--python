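# capsulezone

Quantitative analysis of growth patterns and perimetastatic capsule zonation
in liver metastases, from whole-slide annotation data.

Colorectal-cancer liver metastases meet the surrounding liver in
histologically distinct ways: in the **replacement** pattern tumor cells
contact and replace hepatocytes; in the **encapsulated** (desmoplastic)
pattern a fibrotic rim separates tumor from liver; the rare **pushing**
pattern flattens the perimetastatic liver plates. The degree of encapsulation
carries prognostic information, and the capsule itself is zonated — benign-
fibrosis-like stroma (NGFR⁺/ASMA⁺) and portal-tract remnants at its liver
side, injury-type fibroblasts (FAP⁺) at its tumor side.

`capsulezone` is a Python library for pathologists and computational-biology
groups who quantify these features from digital slide annotations:

* **Growth-pattern scoring** — the fraction of each pattern on a slide is its
  total annotated interface length over the total interface length,
  `pct_p = 100 · Σ len(segments_p) / Σ len(segments)`; patient scores pool raw
  lengths across slides. Strata: low (<33%), medium (33–<100%), high (100%)
  encapsulation. Inter-rater agreement via Cohen's κ; viability coupling via
  Spearman/Pearson correlation.
* **Capsule zonation** — the desmoplastic rim (DR), the perimetastatic liver
  parenchyma (PLP; DR expanded outward by 1500 µm for IHC/IF or 1000 µm for
  ISH) and the tumor center (TC) are tiled at 25 µm; tile distances are
  normalized per case to a standardized-distance axis
  (`s = 100·d/d_max`, with the liver–tumor interface at 0%, PLP width at
  +100%, DR width at −100%, TC depth at −200%), binned at 5%, cohort-averaged
  with a t-based 95% CI and smoothed with a 5-bin rolling window. Helpers for
  color deconvolution from given stain vectors and autofluorescence
  subtraction are included.
* **Portal-tract remnants** — pin-to-interface minimal distances, rim density
  (pins/mm²), and the relative distance `d_liver/(d_liver+d_tumor)` comparing
  isolated-artery (A) vs artery-plus-bile-duct (A+BD) remnants with a
  two-sided Wilcoxon rank-sum test (exact for small samples).
* **Survival analysis** — Kaplan–Meier, log-rank, and uni-/multivariate Cox
  models in which encapsulation enters as strata or continuously per
  0.1-fraction increment (HR per 10 percentage points).
* **Power calculation** — the two-mean normal-approximation sample size
  `n = ⌈(z₁₋α + z_power)² (σ_a² + σ_b²/r) / (μ_a − μ_b)²⌉`.
* **Synthetic cohorts** — clinical annotation data of this kind are
  access-restricted, so a seeded generator emulates the full study structure
  (labeled interface arcs with prescribed fractions, rim/PLP/TC geometry,
  zonal marker gradients, pin patterns with subtype enrichment, cohorts with
  encapsulation-dependent hazard) and every analysis stage is validated as a
  round-trip against that ground truth.

Annotations are exchanged as GeoJSON FeatureCollections in micrometer
coordinates (image convention: origin top-left, y downward) with
`properties.role ∈ {interface, zone, pin, border}` — see
`capsulezone.annotations_io`.

## Worked example

```bash
python examples/survival_analysis.py
```

generates 250 synthetic patients whose true hazard ratio is 0.91 per
0.1-fraction encapsulation increment and prints:

```
n = 250 patients, 138 deaths (45% censored)
strata sizes: {'medium': 125, 'low': 64, 'high': 61}

log-rank across encapsulation strata: chi2 = 10.3, p = 5.83e-03
Cox, encapsulation per 0.1 fraction: HR = 0.93 (95% CI 0.89-0.98), p = 6.0e-03  [truth: 0.91]
```

The recovered HR of 0.93 (CI covering 0.91) shows the protective,
proportion-dependent effect of encapsulation being estimated back from the
generated cohort; the stratum models in the same report order the hazards
low > medium > high. The other scripts in `examples/` demonstrate scoring
(`score_growth_patterns.py`), zonation profiling (`zonation_profile.py`,
where the smoothed NGFR curve climbs from 16.7 to 84.2 across the rim while
FAP peaks at the inner rim), portal-tract statistics
(`portal_tract_stats.py`: A median relative distance 0.73 vs A+BD 0.23,
p ≈ 7e-10), the power calculation (`power_calculation.py`: n = 7 per group)
and the reproducible end-to-end pipeline (`run_full_pipeline.py`).

A thin CLI wraps the same functions:

```bash
capsulezone run --out run_dir --seed 11      # full synthetic pipeline
capsulezone score --annotations slides/      # GeoJSON -> fractions.csv
capsulezone power --mean-a 95 --sd-a 5 --mean-b 80 --sd-b 15
```

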