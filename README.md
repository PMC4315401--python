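# riversdm

Habitat modelling and population estimation for riverine waterbirds —
a presence-background maximum-entropy species distribution model (SDM)
chained with a stream-order-filtered river overlay and line-transect
density extrapolation.

The package was built around a concrete conservation problem: censusing
a scarce, linearly distributed wintering duck (the endangered
Scaly-sided Merganser *Mergus squamatus* on the middle-Yangtze
tributaries) where direct counts cover only a handful of river
sections. The workflow:

1. derive the 19 bioclimatic variables (BIO1–BIO19) from monthly
   temperature/precipitation grids and assemble an aligned predictor
   stack;
2. fit an L1-regularized Gibbs distribution over background cells,
   q(x) = exp(λ·f(x))/Z, maximizing λ·f̄ − ln Z − Σβ_j|λ_j| (f̄ = presence
   feature means; linear/quadratic/product/hinge/threshold features),
   and report the logistic index p = q·e^H/(1+q·e^H);
3. evaluate by replicate train/test AUC, jackknife and permutation
   importance (pruning variables under 1%);
4. threshold the averaged map at the mean predicted probability of the
   presence cells, polygonize suitable habitat, clip the river network
   (Strahler order ≥ 6 by default) to it, and sum great-circle lengths
   → suitable river length L;
5. extrapolate the population as N_c = D_r · L from surveyed
   section densities D_r, with a between-section spread.

A synthetic-data module generates complete inputs with known ground
truth — gradient + random-field climate, dendritic Strahler-ordered
river networks, occurrences drawn from a known logistic niche, Poisson
survey counts — so the whole pipeline is testable end to end without
any external rasters.

## Worked example

The published eight-section winter survey ships with the package
(`examples/04_population_estimate.py`):

```text
     river      section  length_km  count  density  density_rounded
  Li River      Xieshui         47     27 0.574468             0.57
Yuan River      Youshui         30     12 0.400000             0.40
Yuan River      Taoyuan         99     42 0.424242             0.42
 Xiu River  Upper reach         71     43 0.605634             0.61
 Xiu River Middle reach         63     32 0.507937             0.51
  Fu River      Yihuang         65     31 0.476923             0.48
 Xin River       Luxihe         43     23 0.534884             0.53
 Rao River       Leanhe         57     31 0.543860             0.54

density range: 0.40–0.61 birds/km across 8 sections
unweighted-mean estimate:       N_c = 3,551 ± 498 birds (unweighted-mean; L = 6,984 km)
length-weighted-pooled variant: N_c = 3,543 ± 228 birds (length-weighted-pooled; L = 6,984 km)
```

Each density is birds counted per surveyed kilometre; the estimate
multiplies the mean density by the 6,984 km of river the habitat model
classified as suitable, and the spread scales the between-section
density SD by the same length.

The other examples cover the remaining capabilities — bioclim
derivation (`01`), SDM fitting and evaluation on a synthetic landscape
(`02`, test AUC ≈ 0.92 against a known niche), thresholding and river
overlay (`03`), and the full seeded pipeline (`05`). A thin CLI mirrors
the stages:

```sh
riversdm estimate --length 6984          # the worked example above
riversdm synth --out fixture --seed 1    # a complete synthetic fixture
riversdm run --config cfg.yaml --out run # the whole pipeline
```

## Layout

```
src/riversdm/
  grid.py        grid geometry + ESRI ASCII raster I/O
  bioclim.py     BIO1–BIO19 from monthly climate
  stack.py       layer alignment, occurrence cleaning, extraction
  maxent.py      features, L1-regularized Gibbs fit, prediction
  evaluation.py  AUC, replicates, jackknife, permutation importance
  habitat.py     thresholding, binarization, polygonization
  rivers.py      order filter, haversine lengths, polygon clipping
  population.py  survey densities, N_c = D_r · L estimators
  synthetic.py   ground-truth generators for every input
  pipeline.py    seeded end-to-end orchestration (YAML config)
  cli.py         thin click wrapper
docs/methods.md  model details, defaults, assumptions, limitations
```
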