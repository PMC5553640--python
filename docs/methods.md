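# Methods

## Model overview

`trophoflow` treats an ecosystem's exploited community as a biomass flow
ascending the food web from trophic level (TL) 2 (herbivores and
detritivores feeding on TL-1 producers/detritus) toward top predators.
Two community parameters describe the flow: the production-to-biomass
ratio P/B, read as the speed at which biomass moves up (its inverse per
trophic class is a residence time), and the gross conversion efficiency
P/Q, the fraction of consumed food turned into production, used as a
partial transfer efficiency (it bounds losses to respiration and
excretion but not non-predation mortality — see Limitations).

The pipeline is: taxon traits → per-taxon P/B, Q/B → log-normal
smoothing onto 0.1-TL classes → catch-weighted class rates → cumulated
indicators TCI and ECI over TL 2–4 → relative series, trends,
clustering.

## Empirical rate equations

Fish P/B is `1.06·exp(0.018·T)·K^0.75` (T mean SST in °C, K the von
Bertalanffy coefficient, yr⁻¹); Q/B is the log-linear regression on
asymptotic weight, temperature, caudal-fin aspect ratio and feeding
flags. The temperature term of the Q/B regression is `1000/(T + 273.15)`
— inverse absolute temperature, the convention of the source
regression. A Celsius denominator is sometimes seen in transcriptions of
this equation; it yields rates of order 10⁻¹²³ at 15 °C and is therefore
not a plausible reading. The Kelvin form reproduces consumption rates of
3–10 yr⁻¹ for typical temperate fish, the magnitude reported in the
literature. Temperature is held constant per ecosystem over time (the
method isolates composition-driven change in the community, not
physiological responses), and growth parameters are likewise fixed per
taxon.

Invertebrate rates cannot be predicted from these equations and must be
supplied directly (`direct_pb`, `direct_qb`); direct rates also override
the empirical path for fish when present. A P/Q ≥ 1 (production
exceeding consumption) is biologically implausible: it is logged and,
only under `strict=True`, clamped below 1 — the default keeps the raw
value so data problems stay visible.

An optional helper converts asymptotic length (cm) to weight via
`W = a·L^b`, default (a, b) = (0.01, 3).

## Smoothing and spectra

The within-taxon spread of trophic levels is mimicked by a log-normal
kernel in (TL − 1) — TL 1 being the food-web origin — with median at the
taxon's mean TL and shape σ = 0.12 by default. σ is a free parameter of
the method (no published value pins it); 0.12 gives a mode-to-tail decay
over roughly ±0.4 TL, consistent with published catch spectra, and is
exposed in `IndexConfig`. Weights are the density evaluated at class
midpoints, renormalised to sum to one over the grid: conservation of the
smoothed quantity takes precedence over exact density shape where the
grid truncates the tails. The grid spans [1.0, 5.5) in 45 classes of
width 0.1; classes are half-open `[τ, τ+0.1)` and bounds are built from
integers so class membership is exact under floating point.

Class rates are catch-weighted: class P/B is the weighted arithmetic
mean of taxon P/B, while class P/Q is a ratio of weighted sums
(`Σ pb·Y / Σ qb·Y`), *not* the mean of taxon ratios — the class is
treated as one aggregate consumer. Any non-negative weight vector can
replace catch (e.g. biomass from an ecosystem model), which is how the
catch-vs-biomass sensitivity analysis is run; the code path is
identical.

Classes with zero smoothed catch have undefined rates. Inside the
cumulation window they are filled by linear interpolation in class
midpoint from the nearest non-empty classes (constant extrapolation at
the edges) — the least-structured completion of the spectrum; an
ecosystem-year with no defined class at all yields a missing indicator
rather than a guess.

## Indicators and the class-count convention

TCI sums `0.1 / (P/B)_τ` and ECI multiplies `(P/Q)_τ^0.1` over the
window [2.0, 4.0). The window is half-open — twenty classes, total
measure exactly 2.0 TL — so a uniform spectrum with per-class efficiency
q gives ECI = q² exactly, and the per-TL equivalent of a cumulated value
is its square root. This convention is pinned by the test suite (a
21-class closed window would make the exponent 2.1 and break the
q ↔ q² pairing). Relative series divide by the 1950 value, falling back
to the first valid year when 1950 is missing (logged). Partial
indicators cumulate from TL 2.0 to a variable upper bound b to locate
which compartment drives a change. The finfish-only mode drops
invertebrates and by default cumulates from TL 2.5, since the lowest
classes of a fish-only catch are sparse.

## Fishing-pressure indices

MTL, FiB, Shannon diversity, PPR and the L-index follow their standard
formulations; transfer efficiency TE = 0.1 and a wet-weight:carbon
ratio CR = 9 are the conventional defaults, both configurable. The
L-index is `PPR·TE^(MTLc−1) / (PP_total·ln(1/TE))` with MTLc the catch
MTL and PP_total the ecosystem's areal primary production times area.
Note the aggregate MTLc couples the catches: the index is linear under
uniform catch scaling and increasing for added catch at or below the
current MTLc, but adding catch slightly above MTLc can reduce it
marginally — a property of the published formula, not a bug.

Stock-status plots classify each stock-year relative to the stock's
peak catch C_max (earliest year of the maximum on ties): catch > 50%
C_max is *exploited* anywhere; at or before the peak, ≤ 50% is
*developing*; after the peak, ≤ 10% is *collapsed*, 10–50% is
*overexploited*, or *rebuilding* once a collapsed year has occurred. A
series only counts as a stock with ≥ 10 years of positive catch and
≥ 1000 t cumulative catch (configurable; the thresholds keep sporadic
bycatch records from diluting the fractions). The headline fraction
(overexploited + collapsed) excludes rebuilding stocks by default, with
a toggle.

## Trends and clustering

The worldwide trend of an indicator is the cross-ecosystem mean per
year with a percentile bootstrap CI from resampling ecosystems with
replacement (B = 1000, 95% by default). Trend significance combines an
OLS slope (magnitude per year) with a Kendall rank correlation against
year (a Mann-Kendall-style monotonic test robust to non-linearity); the
rank test's p-value is the significance criterion at α = 0.05.

Trajectory clustering standardises the ecosystems × years matrix by
column (population variance, so the eigenvalues of the scaled data sum
to the number of retained variables), extracts principal components by
SVD, and applies Ward-criterion agglomerative clustering on all
component scores — equivalently on the standardised trajectories, since
the full score space preserves Euclidean geometry. Constant columns
(e.g. the all-ones baseline year of a relative series) cannot be
standardised and are dropped with a log message. k defaults to 4
clusters but is a user choice; no automatic selection rule is applied.

Cluster characterisation uses the hypergeometric law: with N ecosystems,
K carrying a binary modality, a cluster of size n containing k carriers,
the over-representation tail is P(X ≥ k) and the under-representation
tail P(X ≤ k); the smaller tail is reported with its direction. The
reported percentages (occurrence overall, share of carriers selected,
occurrence within the cluster) reconstruct the integer counts exactly.
Modalities are produced by small declarative rules over the
fishing-index table (trend sign at α = 0.05 over the full period, window
means against thresholds, ecosystem type), configurable from YAML.

## Synthetic scenarios

The generator emulates the statistical structure of reconstructed catch
data for one ecosystem over 61 years (1950–2010, 25 taxa by default):

* taxon TLs cover 2.05–4.5; the lowest-TL 20% are invertebrates with
  direct rates (P/B 2.5 yr⁻¹ at TL 2 decaying in TL, P/Q 0.25);
* fish traits are TL-correlated, `K = 0.5·e^(−0.5(TL−2))` yr⁻¹ and
  `W∞ = 50·e^(1.5(TL−2))` g with taxon-level log-normal noise — i.e.
  K ≈ 0.5 yr⁻¹ / 50 g forage fish at TL 2 down to K ≈ 0.14 yr⁻¹ / 2 kg
  predators at TL 4.5. The correlation is essential: the mechanism under
  study is catch-weighted class rates changing as the catch mix shifts,
  which requires traits to covary with TL;
* catch shares follow a softmax over a random base attractiveness plus
  a tilt `−r·(year−1950)·TL`; the shift rate r (yr⁻¹ per TL) drives
  "fishing down": r = 0.02 makes the catch MTL fall ≈ r·Var(TL) ≈ 0.01
  TL yr⁻¹, ~0.6 TL over the period — the magnitude of strong observed
  fishing-down trajectories. Total catch (3·10⁵ t scale) follows a
  named trajectory (constant / logistic growth / late development), and
  every catch carries multiplicative log-normal noise (σ = 0.2);
* presets: `fishing_down` (constant total, r = 0.02), `stable` (r = 0),
  `late_development` (negligible catch before 1960, then logistic
  growth, mild shift).

Under these defaults the baseline community sits at TCI ≈ 3 years and
ECI ≈ 0.01–0.015 (10–12% per TL), the observed range for temperate
shelves. What the generator deliberately omits: population dynamics and
stock–recruitment (catch is exogenous), spatial structure, diet shifts,
environmental forcing of rates, and reporting artefacts. Passing
end-to-end tests therefore demonstrate that the estimator recovers
composition-driven functional change from catch data with realistic
noise — not that real catch reconstructions are unbiased samples of the
community, which is the method's main caveat with real data too.

## Numerical choices

* Class membership and the cumulation window use integer-derived bounds;
  `[2.0, 4.0)` always selects exactly 20 classes.
* ECI is computed as `exp(0.1·Σ ln pq)` for numerical stability.
* Smoothing weights that underflow everywhere (σ → 0) degrade to a
  delta at the taxon's class, preserving conservation.
* The bootstrap, the generator and clustering are deterministic under a
  fixed seed / fixed row order; Ward labels are renumbered in order of
  first appearance.
* FiB's baseline is the first year with positive catch at or after the
  configured baseline year.

## Limitations

* Catch-based spectra see only the exploited part of the food web; low
  trophic classes are under-represented and regulation-driven changes
  in fishing strategy masquerade as functional change. The biomass
  weighting mode exists precisely to gauge this on ecosystems with an
  independent biomass estimate.
* ECI ignores non-predation natural mortality and fishing mortality, so
  it over-states absolute transfer efficiency; its *trends* are the
  meaningful signal.
* The empirical rate equations carry their regression uncertainty,
  which is not propagated.
* The smoothing shape σ is a modelling choice; indicator levels (not
  signs of trends) depend on it moderately.
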