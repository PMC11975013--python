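# isofinger

Compound-specific carbon-isotope fingerprinting of essential amino acids
(δ¹³C-EAA) for detecting and quantifying **gut-microbial amino-acid
provisioning to a host**.

Essential amino acids (EAAs: Ile, Leu, Lys, Phe, Thr, Val) cannot be
synthesized by mammals, so the δ¹³C value of an EAA in host tissue traces
its biosynthetic origin — the diet, or de-novo synthesis by gut microbes.
`isofinger` implements the full inference chain used in germ-free (GF) vs
conventionalized (CVZ) feeding designs:

1. **Diet-normalized offsets.** Δδ¹³C = δ¹³C(consumer EAA) −
   δ¹³C(dietary EAA), with replicate aggregation and QC (replicate SD vs a
   ±0.4 ‰ bound). Offsets beyond ~1 ‰ are the conventional flag for a
   non-dietary EAA source; the pipeline screens the *differential* offset
   (CVZ referenced to the GF control) so diet-memory and trophic effects
   cancel.
2. **LDA fingerprinting.** Canonical linear discriminant axes fitted from
   first principles on endmember reference classes (bacteria / fungi /
   plants): generalized eigenvectors of the between-class vs pooled
   within-class covariance, scaled to unit pooled within-class variance.
   Consumer tissues are projected onto the axes; Gaussian posteriors and
   95 % confidence ellipses are available.
3. **Bhattacharyya overlap.** For two Gaussians,
   D_B = ⅛ (μ₁−μ₂)ᵀ Σ̄⁻¹ (μ₁−μ₂) + ½ ln( det Σ̄ / √(det Σ₁ det Σ₂) ) with
   Σ̄ = (Σ₁+Σ₂)/2 and BC = exp(−D_B) ∈ (0, 1]. The headline summary is the
   median BC over matched GF/CVZ organ pairs.
4. **Group statistics.** Two-way ANOVA with interaction, one-way MANOVA by
   Pillai's trace V = tr(H(H+E)⁻¹), Tukey–Kramer mean separation with
   compact letter display, and a box-constrained least-squares estimator
   of the microbial contribution fraction *f* from
   Δδ¹³Cₐ = f · (δ¹³C(microbe)ₐ − δ¹³C(diet)ₐ) + εₐ.
5. **Synthetic studies.** A generator with known ground truth emulating
   the study design: two arms × four organs (carbon replacement fractions
   0.75 / 0.60 / 0.45 / 0.30 for liver / kidney / muscle / brain over the
   feeding window) × 5 animals × 6 EAAs × duplicate analyses with 0.2 ‰
   analytical noise, plus diet and endmember tables.

The package is aimed at isotope ecologists and microbiome researchers who
want a tested, reproducible version of this workflow, and at method
developers who need a ground-truthed simulator for power and calibration
studies.

## Worked example

Run the full pipeline on a self-generated study with a true microbial
contribution of 40 % in the CVZ arm:

```yaml
# study.yaml
simulation:
  f_microbial: {GF: 0.0, CVZ: 0.4}
  seed: 11
seed: 11
out_dir: out
```

```text
$ isofinger run --config study.yaml
isofinger provisioning report
  verdict: evidence
  median Bhattacharyya coefficient (matched_organ): 0.000
  per-organ GF-vs-CVZ MANOVA (Pillai's trace):
      liver: V = 1.000, F = 4641.43, p = < 0.0001 (Holm-adjusted < 0.0001)
     kidney: V = 0.999, F = 763.19, p = < 0.0001 (Holm-adjusted 0.0002197)
     muscle: V = 0.998, F = 223.66, p = 0.0004597 (Holm-adjusted 0.0009193)
      brain: V = 0.986, F = 33.99, p = 0.007504 (Holm-adjusted 0.007504)
  differential offset screen (CVZ - GF, permil):
      liver: Ile, Leu, Lys, Phe, Thr, Val
     kidney: Ile, Leu, Lys, Phe, Thr, Val
     muscle: Ile, Leu, Lys, Phe, Thr, Val
      brain: none exceed
  microbial contribution estimate: f = 0.400 [0.388, 0.411]
```

Every organ separates multivariately, the differential screen fires on
all six EAAs in the fast-turnover organs (the slow-turnover brain dilutes
the signal below 1 ‰), and the turnover-corrected estimator recovers the
simulated fraction (f̂ = 0.400, bootstrap 95 % interval [0.388, 0.411]).

The same pipeline on a truly null study (`f_microbial: {GF: 0, CVZ: 0}`,
seed 1) prints `verdict: no_evidence` with a median BC of 0.955, no
significant organ MANOVA, no screen exceedance, and f̂ = 0.000 — the
GF and CVZ distributions overlap almost completely in fingerprint space.

Library use mirrors the CLI:

```python
from isofinger import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(seed=1), seed=1)
report = run_pipeline(cfg)
print(report.verdict, report.median_bc)
```

Measured data are supplied as delimited long-format tables
(`sample_id, group, organ, analyte, delta13C, replicate`) via
`consumers_path` / `diet_path` / `training_path` instead of `simulation`;
`isofinger fixture --seed 0 --out DIR` writes a complete example study in
that format.

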