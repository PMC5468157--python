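# habshift

Presence–background habitat suitability modelling and climate-driven
range-shift vulnerability assessment on equal-area raster landscapes, with
protected-area gap analysis. The package reimplements, as a tested and
reusable pipeline, the kind of assessment used for the giant panda
(*Ailuropoda melanoleuca*) in the Qinling Mountains: a maximum-entropy
suitability model built from sign-survey presences and a forest
target-group background, projected onto a mid-century climate scenario, and
summarized as vulnerability indicators and reserve-network protection
percentages.

It is aimed at conservation biogeographers and quantitative ecologists who
want the full chain — occurrence thinning, correlation/importance variable
screening, an L1-regularized maxent engine, max-SSS thresholding, patch
filtering, four-category change mapping, and reserve overlay — as plain,
inspectable Python over `numpy`/`scipy`/`pandas`/`shapely`, working on
ESRI ASCII grids, CSV point tables, and GeoJSON polygons.

## The model

The maxent engine finds the distribution q_λ over a background sample that
is as close to uniform as possible while matching the presence sample's
feature means, by maximizing the penalized log-likelihood

```
J(λ) = mean_presence[λ·f(x)] − log Σ_background exp(λ·f(x)) − Σ_j β_j |λ_j|
```

with linear, quadratic, and forward/reverse hinge features scaled to [0, 1]
over the background, penalties β_j = β × s_j/√n, and a deterministic cyclic
coordinate-ascent optimizer (every feature lies in [0, 1], so the fixed
majorizer h = 1/4 on the per-coordinate curvature guarantees monotone
convergence). The logistic output p = e^H q/(1 + e^H q), with H the entropy
of the fitted distribution, rescales raw densities to [0, 1].

Suitability is binarized at the threshold maximizing training sensitivity +
specificity (averaged over 15 subsample replicates of a 75/25 presence
split), patches smaller than the minimum home range (4 km²) that are also
farther than the daily dispersal distance (0.5 km) from any retained patch
are removed, and current/future maps are compared cell by cell. With A_c,
A_f, A_fc the current, future, and overlapping suitable areas:

```
AC   = (A_f − A_c)/A_c × 100     percentage area change
SH_c = (A_c − A_fc)/A_c × 100    % of current suitable habitat lost
SH_f = (A_f − A_fc)/A_f × 100    % of future habitat newly gained
```

A tie-corrected Mann–Whitney test contrasts the elevations of suitable
cells between scenarios, and the reserve overlay reports per-reserve
suitable areas, per-reserve AC, and the percentage of suitable habitat the
reserve network protects under each scenario.

Because the original survey occurrences and climate layers are not
redistributable, the package ships a seed-reproducible synthetic landscape
generator (`habshift.synthetic_landscape`) with a known true suitability
surface; model quality is assessed by recovering that truth.

## Worked example

Run the whole pipeline on the default synthetic landscape (100×100 km at
1 km resolution, six climate layers, elevation, three infrastructure
density layers; 273 occurrences; 10,000 background points; +1.5 °C and
×0.9 precipitation by mid-century):

```
$ habshift run-all --seed 1 --out-dir run/
test AUC 0.892; A_c 2558 km², A_f 1068 km², AC -58.25%
```

`run/report.json` then contains (abridged):

```
model:     train AUC 0.895 ± 0.003, test AUC 0.892 ± 0.010
           mean max-SSS threshold 0.398, Spearman rho vs truth 0.973
           final variables: temp1, temp3, prec1
habitat:   A_c 2558 km², A_f 1068 km², A_fc 775 km²
           AC −58.25 %, SH_c 69.70 %, SH_f 27.43 %
elevation: suitable habitat 2146 m (current) → 2402 m (future),
           Mann–Whitney z = −23.94, p < 1e-100
reserves:  network protects 31.39 % (current) / 32.02 % (future)
```

Reading: the fitted ensemble discriminates presences from background well
(test AUC 0.892) and ranks cells almost exactly like the generating truth
(ρ 0.97). Under the warming scenario this synthetic montane specialist
loses 58 % of its suitable area and the surviving habitat sits ~255 m
higher — the classic upslope contraction signature. The same stages are
available individually (`make-fixtures`, `prep thin`, `prep background`,
`screen`, `sdm`, `change`, `gap`) and as library functions.

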