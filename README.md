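# eaafinger

Stable-isotope inference of gut-microbial essential amino acid (EAA)
provisioning to a host, built around compound-specific δ¹³C analysis of amino
acids (CSIA-AA).

## The scientific problem

Gut microbes can synthesize the essential amino acids their host cannot
(Ile, Leu, Lys, Phe, Thr, Val). Whether those microbial EAAs actually reach
host tissues is hard to establish. Natural-abundance carbon isotopes give a
direct readout: under pure dietary routing a tissue's δ¹³C-EAA values track the
diet's, so the diet-normalized offset

```
Δδ¹³C = δ¹³C(consumer EAA) − δ¹³C(dietary EAA)
```

stays within the ~1‰ margin of analytical and biological variability. If the
host also assimilates microbially resynthesized EAAs — typically ¹³C-enriched
because they are rebuilt from dietary carbohydrate carbon — tissue values move
toward the microbial endmember, following the two-endmember mixing relation

```
δ_host = (1 − f) · δ_diet + f · δ_microbe
```

with `f` the microbial contribution fraction. The strongest experimental
design contrasts germ-free (GF) mice with conventionalized (CVZ) mice carrying
a reconstituted microbiome: any CVZ−GF excess beyond 1‰, in the enriching
direction, is attributable to microbial provisioning.

The package implements that inference end to end:

- **Offsets and tests** — Δδ¹³C computation against a replicate-averaged diet
  profile; Welch's t per organ × EAA (raw data or printed summary statistics);
  Fligner–Killeen variance homogeneity; one-way MANOVA with Pillai's trace;
  the directional >1‰ detection rule.
- **Fingerprinting** — within-sample mean-centring into zero-sum "fingerprints"
  diagnostic of biosynthetic origin, inter-laboratory calibration, and a
  from-scratch linear discriminant analysis (class means, pooled within-class
  covariance, generalized between/within eigenproblem) trained on a
  bacteria/fungi/plants reference library, with leave-one-out cross-validation,
  posterior classification and 95% confidence ellipses.
- **Overlap** — closed-form Bhattacharyya coefficients between Gaussian fits of
  group score clouds in discriminant space, with a within-group bootstrap
  distribution (BC = 1 identical, 0 disjoint).
- **Mixing** — per-EAA, per-organ estimates of `f` using the GF cohort as the
  zero-contribution baseline (so organ-specific trophic enrichment cancels),
  corrected for finite tissue carbon turnover (`f = f_raw / ρ`, with ρ the
  organ's 20-day replacement fraction: liver 0.75, kidney 0.60, muscle 0.45,
  brain 0.30) and bracketed by a mouse-resampling bootstrap CI.
- **Simulation** — a forward generator of GF/CVZ feeding experiments
  (diet switch, organ turnover, per-mouse biological scatter, ±0.2‰ analytical
  noise) and of classifier training libraries, so every stage is testable
  without any external download.

## Worked example

Simulate the null scenario — microbiome present but contributing nothing
(`f = 0`) — under the study's design (5 mice/group, four organs, 20-day diet
switch), then run the full analysis:

```python
import eaafinger as ef

table = ef.simulate_experiment(ef.study_conditions(f=0.0, seed=17))
cfg = ef.RunConfig(measurements=table, out_dir="demo", seed=17, n_boot=1000)
res = ef.run_pipeline(cfg)
for d in res["decisions"]:
    print(f"{d.organ:>7s}: CVZ-GF = {d.difference:+.2f} permil -> detected={d.detected}")
print("pooled BC:", {k: round(v, 3) for k, v in res["bc_pooled"].items()})
```

prints

```
  brain: CVZ-GF = +0.01 permil -> detected=False
 kidney: CVZ-GF = -0.25 permil -> detected=False
  liver: CVZ-GF = -0.06 permil -> detected=False
 muscle: CVZ-GF = -0.27 permil -> detected=False
pooled BC: {'median': 0.947, 'q25': 0.909, 'q75': 0.968, 'min': 0.583, 'max': 0.996, 'n': 1000}
```

Every organ's CVZ−GF contrast sits far below the 1‰ threshold (and mostly in
the wrong direction), so no provisioning is detected; the pooled
GF-vs-CVZ Bhattacharyya median of ~0.95 quantifies the near-total overlap of
the two groups' fingerprint clouds in discriminant space. The same run writes
a report bundle (`table1_rendered.csv`, `manova.csv`, `ld_scores.csv`,
`bc_summary.json`, `mixing.csv`, `decisions.csv`, `manifest.json`) to
`demo/`. Simulating instead with `f=0.25` and a +8‰ microbial endmember flips
every decision to detected and the mixing stage recovers `f ≈ 0.25` per organ
after turnover correction.

The same stages are scriptable from the shell:

```
eaa-finger simulate --out sim.csv --seed 17 --f 0.0
eaa-finger run --measurements sim.csv --out report/ --seed 17
```

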