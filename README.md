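# denscape

Alpine brown-bear (*Ursus arctos*) den-site selection modelling and
heli-ski disturbance-risk mapping.

Brown bears hibernate for up to six months in excavated dens, and in coastal
mountain ranges those dens sit in exactly the steep, snow-loaded alpine
terrain that helicopter-skiing operators use. `denscape` implements the full
analysis chain a wildlife agency needs to quantify that conflict:

1. derive terrain and climate covariates from a digital terrain/surface
   model pair — elevation, slope, topographic position index (TPI), vector
   ruggedness measure (VRM), topographic wetness index (TWI), clear-sky
   1 April solar radiation, a snow-load index, and a vegetation height
   index (VHI);
2. fit and rank used–available **resource selection functions (RSF)**,
   `w(x) = exp(β₁x₁ + … + βₙxₙ)`, by logistic regression of den locations
   against availability points (500 per km², Design II pooling), with AICc
   model selection over an a-priori 18-model candidate set;
3. validate the top model by binned k-fold cross-validation (Spearman rank
   correlation of observed vs expected den proportions over ten
   equal-count RSF bins);
4. map five equal-area habitat classes and delineate *prime* denning
   habitat (the top two classes, 40% of the study area by construction);
5. convert helicopter flight-track fixes to a kernel-density intensity
   surface (least-squares cross-validation bandwidth), multiply it with the
   RSF into a disturbance-risk surface, and summarise den/permit overlap.

Because real den coordinates are confidential and the source rasters are not
public, the package ships a first-class synthetic-landscape module: a
spectral-synthesis alpine DEM, canopy below a noisy forest line, glaciers,
a survey route, heliports with flight tracks, and dens placed by *exact*
weighted sampling from a known selection function — so parameter recovery,
model selection, and every downstream map are testable end to end.

## Worked example

```python
import numpy as np
import denscape as dn
from denscape import rsf_model as rm, validation as val, habitat_map as hm

cfg = dn.LandscapeConfig(seed=5, extent=(128, 128))
study = dn.simulate_study(cfg, dn.reference_truth(n_dens=89))

fits = [rm.fit(study.design, s) for s in rm.candidate_set()]
table = rm.rank_models(fits)
print(table.head(3)[["model", "K", "aicc", "delta", "weight"]].to_string(index=False))
```

```
 model  K       aicc    delta   weight
    14  8 251.575034 0.000000 0.654997
    13  9 253.464601 1.889567 0.254639
    17 10 255.605293 4.030259 0.087313
```

The generating model (id 14: elevation, slope and their quadratics,
snow load, TWI, VHI, VRM) wins with 65% of the Akaike weight. Its
coefficients recover the simulated selection — strong avoidance of high
elevations (negative linear and quadratic elevation terms), preference for
steeper slopes, smooth terrain:

```python
top = next(f for f in fits if f.spec.id == int(table["model"].iloc[0]))
print(top.beta.round(2).to_string())
res = val.kfold_validate(study.design, top.spec, iterations=20, seed=1)
print(f"cross-validation rho: {res.mean_rho:.2f} "
      f"(range {res.range[0]:.2f} to {res.range[1]:.2f})")
```

```
dtm         -2.08
dtm_sq      -1.98
slope        0.66
slope_sq    -1.37
snow.load    0.14
twi         -0.17
vhi          0.33
vrm         -1.28
cross-validation rho: 0.88 (range 0.83 to 0.92)
```

A mean Spearman ρ of 0.88 across 20 fold-resampling iterations says the
model ranks habitat essentially in the order dens actually use it. Mapping
the RSF into five equal-area classes and tallying the dens:

```python
rsf = rm.predict_surface(study.stack, top)
masked = rsf.like(np.where(study.mask.data == 1, rsf.data, np.nan))
print(hm.tally_dens(hm.equal_area_classify(masked), study.dens).to_string(index=False))
```

```
        class  count  percent
          low      0        0
 low-moderate      0        0
     moderate      5        6
moderate-high     29       33
         high     55       62
```

94% of the dens (84 of 89) fall in prime habitat (the top two classes), which by
construction covers only 40% of the study area — the spatial concentration
that makes set-back management around prime habitat meaningful.

## Command line

The same pipeline is scriptable via the `denscape` entry point:

```sh
denscape simulate   --config cfg.yaml --out sim/
denscape covariates --dtm sim/dtm.asc --dsm sim/dsm.asc --out stack/
denscape design     --stack stack/ --route sim/route.geojson \
                    --glaciers sim/glaciers.asc --dens sim/dens.csv \
                    --seed 1 --out design/
denscape fit        --design design/design_table.csv \
                    --stack design/stack_standardized --out fit/
denscape validate   --design design/design_table.csv --model 14 \
                    --iters 100 --seed 1 --out validation.json
denscape classify   --rsf fit/rsf.asc --dens sim/dens.csv --out classes/
denscape risk       --rsf fit/rsf.asc --flights sim/flights.csv \
                    --permits sim/permits.geojson --dens sim/dens.csv --out risk/
```

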