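# pteromorph

Cranial shape, diet, and biome-level morphological disparity in flying
squirrels (tribe Pteromyini), as a tested and reusable Python pipeline.

Flying squirrels span tropical rainforests to the taiga, and their diets
range from flesh fruit to conifer needles. Two questions drive this
package: *how do diet and size shape the cranium* within the tribe, and
*is cranial disparity in species-rich tropical biomes higher than their
richness alone predicts*? The pipeline answers them with 2D geometric
morphometrics of ventral-cranium landmark configurations:

1. **Superimposition.** One-sided digitizations (19 landmarks, four
   semilandmark curves, 81 points) are mirrored across the mid-sagittal
   axis into 157-point bilateral configurations and superimposed by
   Generalised Procrustes Analysis (GPA), with semilandmarks slid along
   their curve tangents to minimise thin-plate-spline bending energy.
   Centroid size CS = √Σᵢ‖xᵢ − x̄‖² is the size measure; shapes enter the
   statistics as Procrustes coordinates.
2. **Morphospace.** PCA of species-mean shapes, with deformation shapes
   at the extremes of each axis.
3. **Comparative models.** Procrustes PGLS of *size ~ diet*,
   *shape ~ diet × size* and *shape ~ size* under a Brownian-motion
   covariance **C** (Cᵢⱼ = depth of the most recent common ancestor),
   rescaled by a maximum-likelihood Pagel's λ estimated from the
   residuals of the non-phylogenetic fit. Sums of squares are sequential
   Procrustes SS; significance comes from RRPP (randomisation of
   reduced-model residuals), with effect size Z measured on ln F.
   Pairwise diet comparisons of dispersion around mean shapes and
   allometric regression scores complete the picture.
4. **Disparity.** Per-biome Procrustes variance of shape (and variance of
   log CS for size) is compared with a Monte Carlo null built by drawing
   the same number of species at random from the full pool, so richness
   alone cannot masquerade as disparity. Tropical biomes are tested
   one-sided for *higher*-than-expected disparity, temperate/boreal for
   *lower*, with the reverse tail reported as a check.

The museum-specimen coordinates behind the original study are not
publicly deposited, so a first-class synthetic-data module generates
datasets with the same statistical structure (Brownian shape evolution on
a phylogeny, additive diet and allometric effects, log-normal sizes,
biome occupancy with the study's richness gradient) for testing,
calibration, and method development. The published sampling table
(35 of the tribe's 52 species, 151 specimens, per-species diet and Walter
biome occupancy) ships with the package.

## Worked example

```python
from pteromorph.pipeline import RunConfig, run_pipeline, summarize_run

cfg = RunConfig(simulate={}, seed=1, outdir="demo", n_perm=999, n_rep=1000)
run_pipeline(cfg)
print(summarize_run("demo"))
```

which prints (abridged):

```
Pagel's lambda (residuals of the full model): 0.5764

shape ~ diet + size + diet:size
     term  Df         SS         MS       r2      F       Z        p
     diet   4  0.0019624  0.0004906  0.25241 2.7383  3.6571 0.001001
     size   1 0.00053323 0.00053323 0.068585 2.9762  2.3774 0.009009
diet:size   4 0.00079995 0.00019999  0.10289 1.1162 0.46467  0.33934
Residuals  25  0.0044791 0.00017916  0.57611    ...
    Total  34  0.0077747

shape disparity by biome (richness-conditioned null)
 biome  n_species          D  side       p  reverse_p  significant
     I         26 0.00017099 upper 0.91708   0.083916        False
    II         17 0.00016433 upper 0.87912    0.12188        False
     ...
ANOVA of shape distances across biomes: F = 1.718, p = 0.1414
```

Reading this: diet explains ~25% of among-species cranial shape variance
and is highly significant under RRPP; size adds a significant allometric
component; their interaction does not improve the model. No biome's shape
disparity departs from what its species richness alone predicts — the
generator builds in exactly this structure (diet- and size-driven shape,
disparity tied to richness), and the pipeline recovers it.

The same stages are available on the command line:

```bash
pteromorph simulate --seed 1 --out data/
pteromorph run-all --config run.yaml --seed 1
pteromorph report demo/
```

or individually as `align`, `pca`, `pgls`, `disparity`, `null`. Every
run writes per-stage CSV artifacts and a `manifest.json` with seeds and
checksums; the same seed reproduces every byte.

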