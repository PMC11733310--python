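# batscape

Weather-surveillance radar incidentally detects flying animals, and for
colonial insectivores like the Mexican free-tailed bat (*Tadarida
brasiliensis*) a season of nightly radar scans can be turned into a map
of where the animals actually forage. `batscape` implements that
analysis as a tested, reusable pipeline for aeroecologists and
agroecologists who already have (or want to simulate) per-scan binary
bat-presence rasters:

1. **Seasonal aggregation** — per-scan binary presence scenes on a 70 m
   grid are summed into per-pixel occurrence counts and normalized to
   the standard activity unit, occurrences·ha⁻¹·night⁻¹:
   `rate = count / (pixel_area_ha × n_nights)` (a 70 m pixel is 0.49 ha).
2. **Roost commute correction** — detections near roosts are inflated by
   commuting (not foraging) bats; each pixel is down-weighted by
   `1 / (1 + A·e^{−d/λ})` with `d` the distance to the nearest roost.
3. **Land-cover statistics** — two land-cover sources (natural
   vegetation + crop parcels) are harmonized into 13 classes nested in 4
   types, and per-class activity is summarized as area-weighted parcel
   means, `Σᵢ mᵢaᵢ / Σᵢ aᵢ`, with seeded bootstrap 95% CIs.
4. **Prey proxy** — a relative mosquito-abundance index built from
   thermal performance curves (Briere `cT(T−T₀)√(Tₘ−T)` and quadratic
   `c(T−T₀)(Tₘ−T)` trait curves),
   `M(T) = EFD·pEA·MDR / max(μ, floor)²`, averaged over a seasonal
   temperature stack — a stand-in for flying-insect prey density.
5. **Association model** — everything is block-averaged to ~1 km cells
   and a Gaussian GAM is fit:
   `activity ~ s(mosquito) + lights + irrigated + C(landcover) + s(lat) + s(lon)`
   with penalized cubic B-splines.

Because no public archive of the radar-derived bat product exists, the
package ships a first-class synthetic-data module that generates every
input with known ground truth (patch-tessellated land cover, Bernoulli
presence scenes carrying a known commute plume and prey association,
co-registered covariates), so every stage is testable end to end.

The estimators follow scikit-learn conventions (`fit`/`transform`/
`predict`, `get_params`, fitted attributes with trailing underscores)
and compose with sklearn pipelines; module-level functions are thin
wrappers over them.

## Worked example

Run the whole pipeline on the default synthetic landscape (224×224
pixels of 70 m, a 152-night season at 126 scans/night, 8 roosts, rice
foraging weight twice grassland's):

```bash
batscape run --out run1 --seed 1
```

The land-cover ranking (`run1/class_ranking.csv`) puts rice on top —
the generator made rice twice as attractive, and the area-weighted
statistics recover that:

```
 rank     lc_class  mean_rate  ratio_to_study_mean  ratio_to_next
    1         rice      30.96                 1.90           1.56
    2 barren/other      19.88                 1.22           1.02
    3   herbaceous      19.40                 1.19           1.05
```

`mean_rate` is in occurrences·ha⁻¹·night⁻¹; rice activity is 1.56× the
next-highest class and 1.9× the study-wide mean (16.28). The GAM report
(`run1/gam_report.txt`) ends with

```
LULC: rice                            9.30            7.77 – 10.83   < 0.001
...
Smooth term: mosquito abundance                                         0.421
Smooth term: Lat./Long.                                              < 0.001
Observations: 256
R2 (adjusted): 0.781   R2: 0.801
Reference land-cover class: miscellaneous
```

i.e. a strongly positive rice contrast against the "miscellaneous"
reference class and a significant spatial smooth; at this landscape
size the (real, simulated) mosquito association is largely absorbed by
the spatial term — see `docs/methods.md` for why.

Each stage is also callable on its own (`batscape simulate`,
`aggregate`, `correct`, `landcover`, `mosquito`, `gam`) or from Python:

```python
from batscape import LandscapeConfig, simulate_landcover, simulate_activity, to_rate

cfg = LandscapeConfig(seed=1)
layer = simulate_landcover(cfg)
rate = to_rate(simulate_activity(cfg, layer))   # occurrences/ha/night
```

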