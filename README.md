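# swampdendro

Dendrochronology and tree-ring stable-isotope analysis for subtropical
seasonally flooded forests — built for studies like those of pond cypress
(*Taxodium ascendens*), bald cypress (*T. distichum*) and slash pine
(*Pinus elliottii*) growing at the hot, wet southern edges of their ranges,
where standing-water depth rather than temperature or rainfall often
governs radial growth.

The package covers the full desk workflow:

- **Chronology building** — age-dependent-spline detrending (50%
  frequency cutoff growing as max(20, cambial age) yr), ring-width index
  RWI = w / fit, AIC-selected AR prewhitening, Tukey-biweight robust
  averaging, and the quality statistics MS, rbar (r_xy) and
  EPS = n·rbar / (n·rbar + 1 − rbar).
- **Climate/hydrology–growth correlation functions** — Pearson r of the
  chronology against 24 monthly and 4 seasonal windows (previous/current
  year; winter Jan–Mar, summer Jun–Sep) per variable, with
  Politis–Romano stationary-bootstrap percentile confidence intervals.
- **Growth geometry** — basal area increments
  BAI_t = π(r_t² − r_{t−1}²), Age Class Isolation trend regressions
  (5-yr cambial-age classes centred every 10 yr vs calendar year), and
  spatial regressions of age-detrended BAI residuals on landscape
  distances.
- **Isotope chain** — δ¹³C_wood − 2‰ → Δ¹³C = (δₐ − δ_leaf)/(1 + δ_leaf/1000)
  → Cᵢ = Cₐ(Δ − a)/(b − a) with a = 4.4‰, b = 27‰ →
  iWUE = A/g_s = (Cₐ − Cᵢ)/1.6, plus age-effect removal and
  iWUE–climate regressions, under a packaged (synthetic, documented)
  atmospheric Cₐ/δ¹³Cₐ history.
- **A synthetic-data generator** reproducing the statistical structure
  these analyses assume (ontogeny × log-linear climate response ×
  lognormal noise; monthly AR(1) climate and hydrology; decadal isotope
  censuses), with ground truth returned for every dataset.

See `docs/methods.md` for the models, assumptions and caveats.

## Worked example

```python
import swampdendro as sd

cfg = sd.study_config(seed=1)            # three species, 22/26/26 trees
env = sd.gen_environment(cfg)            # monthly climate + water depth
trees, _ = sd.gen_ring_series(cfg, env)

tadi = [t for t in trees if t.species_code == "TADI"]
detrended = [sd.detrend_series(t) for t in tadi]
chron = sd.build_chronology(detrended, flavor="residual")
quality = sd.chronology_quality(detrended)
print(f"TADI: n={quality.n_series}  MS={quality.mean_sensitivity:.3f} "
      f"({quality.sensitivity_class})  rbar={quality.rbar:.3f}  "
      f"EPS={quality.eps:.3f}")

table = sd.correlation_function(chron.series.loc[1896:],
                                [env["water_depth"]], n_boot=1000, seed=1)
print(table.sort_values("r", ascending=False).head(3)
      [["variable", "window", "r", "ci_low", "ci_high", "significant"]]
      .to_string(index=False))
```

prints

```
TADI: n=26  MS=0.473 (ideal)  rbar=0.697  EPS=0.984
   variable      window        r   ci_low  ci_high  significant
water_depth curr:summer 0.698957 0.621321 0.765053         True
water_depth    curr:Jul 0.673831 0.579525 0.753500         True
water_depth    curr:Aug 0.655638 0.561576 0.722911         True
```

Read: the 26 bald-cypress series crossdate well (rbar 0.70 is far above
the 0.40 working floor; EPS 0.98 means the chronology captures nearly all
of the population signal; MS 0.47 sits in the 0.2–0.6 "ideal" band), and
the chronology correlates most strongly with June–September water depth —
the planted summer-flooding response, recovered with a bootstrap CI well
clear of zero. Continuing with the isotope chain,

```python
samples, _ = sd.gen_isotope_series(cfg, trees, environment=env)
records = sd.iwue_pipeline(samples, sd.default_atmosphere())
species = {t.series_id: t.species_code for t in trees}
fits = sd.age_detrend_iwue(records, species)
```

yields 133 TADI samples (the configured decadal census) with mean iWUE
66.0 μmol mol⁻¹ and a fitted age slope of +0.062 μmol mol⁻¹ yr⁻¹ — note
the *two-stage* age slope absorbs part of the rising-Cₐ time trend
because cambial age and calendar year are correlated in a decadal census
(see `docs/methods.md`).

The same workflow is available from the shell:

```sh
swampdendro simulate --seed 1 --out-dir fixtures/
swampdendro chronology --rwl fixtures/tadi.rwl --flavor residual \
    --out chron.csv --stats stats.json
swampdendro climcorr --chron chron.csv --env fixtures/water_depth.csv \
    --nboot 1000 --seed 1 --out corr.csv
swampdendro run-all --config run.yaml --out-dir results/
```

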