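# trophoflow

Trophodynamic indicators of marine food-web functioning, computed from
per-taxon fisheries catch time series and life-history traits.

Fisheries and other stressors reshape species assemblages, and with them
the two quantities that define how biomass moves up a food web: how
*fast* it is transferred (the residence time of biomass at each trophic
level) and how *much* of it survives each step (the trophic transfer
efficiency). `trophoflow` estimates both at the scale of a whole
ecosystem — typically a Large Marine Ecosystem (LME) — and year by year,
so that long-term changes in trophic functioning ("fishing down the food
web" and its consequences) can be quantified, tested for trend, and
compared across ecosystems. It is aimed at trophic ecologists and
fisheries scientists working with reconstructed catch data (e.g. *Sea
Around Us*-style tables) plus FishBase/SeaLifeBase-style traits.

## The method

For each taxon *i* in ecosystem *j*, the speed of the biomass flow and
the consumption rate are predicted from life-history traits and the
ecosystem's mean sea-surface temperature *T* (°C):

```
(P/B)_ij = 1.06 · e^(0.018·T_j) · K_ij^0.75                      (fish)
(Q/B)_ij = 10^(7.964 − 0.204·log10 W_ij − 1.965·(1000/(T_j+273.15))
               + 0.083·A_i + 0.532·h_i + 0.398·d_i)              (fish)
```

with *K* the von Bertalanffy growth coefficient, *W∞* the asymptotic
weight (g), *A* the caudal-fin aspect ratio and *h*, *d* herbivory /
detritivory flags. Invertebrates carry directly estimated P/B and Q/B.
The ratio **P/Q = (P/B)/(Q/B)** is the gross food-conversion efficiency,
used as a partial trophic transfer efficiency.

Per-taxon values are distributed over trophic classes of width Δτ = 0.1
with a log-normal kernel in (TL − 1), and combined per class τ as
catch-weighted averages (Y = catch):

```
(P/B)_τ = Σ_i (P/B)_i·Y_iτ / Σ_i Y_iτ
(P/Q)_τ = Σ_i (P/B)_i·Y_iτ / Σ_i (Q/B)_i·Y_iτ
```

These *trophic spectra* are cumulated over the twenty classes of the
half-open window [2.0, 4.0):

```
TCI = Σ_τ Δτ / (P/B)_τ        residence time of biomass TL 2 → 4, years
ECI = Π_τ (P/Q)_τ^Δτ          fraction of secondary production reaching TL 4
```

`ECI^(1/2)` is the equivalent per-trophic-level efficiency (the window
spans 2.0 TL). Both indicators are also expressed relative to a baseline
year (1950) for cross-ecosystem comparison. Around them the package
provides the classic fishing-pressure indices (catch MTL, FiB, Shannon
diversity, PPR/PP, the loss-in-production L-index, stock-status-plot
fractions), bootstrap confidence bands of the cross-ecosystem mean
trend, PCA + Ward clustering of indicator trajectories, and one-tailed
hypergeometric characterisation of clusters by qualitative modalities.
A seeded synthetic scenario generator produces catch/trait/ecosystem
tables with realistic trait–TL correlations for testing and simulation
studies.

## Worked example

Simulate a "fishing-down" ecosystem (catch composition sliding toward
low-TL, short-lived taxa over 1950–2010) and compute the indicators:

```python
import trophoflow as tf

catch, traits, eco = tf.generate_scenario(tf.preset_fishing_down(seed=7))
ind = tf.compute_indicator_series(catch, traits, eco).set_index("year")
print(ind.loc[[1950, 1980, 2010],
              ["tci", "eci", "tci_r", "eci_r", "per_tl_efficiency"]].round(4))
```

```
         tci     eci   tci_r   eci_r  per_tl_efficiency
year
1950  3.2450  0.0145  1.0000  1.0000             0.1206
1980  3.2334  0.0143  0.9964  0.9806             0.1194
2010  3.1268  0.0149  0.9636  1.0276             0.1223
```

The residence time of biomass between TL 2 and 4 falls from 3.25 to
3.13 years (TCI_R 0.96 in 2010: transfers become faster as short-lived
taxa take over the catch), while the fraction of production reaching
TL 4 rises to 1.49% (ECI_R 1.03), i.e. from 12.1% to 12.2% per trophic
level. The trends are significant:

```python
tr = tf.trend_significance(ind["tci"])
te = tf.trend_significance(ind["eci"])
```

```
TCI slope -0.0020 yr/yr (Kendall p = 2.57e-10)
ECI slope 1.04e-05 /yr (Kendall p = 6.47e-05)
```

The same pipeline runs from the shell on CSV inputs:

```sh
trophoflow simulate --preset fishing_down --seed 7 --out-dir sim/
trophoflow indicators --catch sim/catch.csv --traits sim/traits.csv \
    --ecosystems sim/ecosystems.csv --out indicators.csv
trophoflow indices --catch sim/catch.csv --traits sim/traits.csv \
    --ecosystems sim/ecosystems.csv --out indices.csv
```

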