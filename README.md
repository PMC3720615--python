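# latgrad

Latitudinal gradients in species richness and assemblage evolutionary
derivedness, from range maps and a phylogeny.

## The problem

The increase of species richness from the poles to the equator is the
oldest pattern in biogeography, and one way to probe its causes is to ask
*how old* the species are that make up local faunas at each latitude.
`latgrad` implements the full analysis chain used in macroecological
studies of this question (its design case is the New World bat fauna,
~300 species over a continent-spanning domain):

1. **Gridding** — species range polygons are rasterized onto a 100 × 100 km
   equal-area grid, giving a cells × species presence–absence matrix and
   per-cell species richness *S*.
2. **Root distances** — each species *i* gets a root distance RD*ᵢ*, the
   number of nodes separating its tip from the root of a supplied
   phylogeny (a purely topological proxy for how derived the lineage is).
   Per cell, the **mean root distance** MRD = (1/S) Σ RD*ᵢ* summarizes the
   evolutionary derivedness of the local assemblage.
3. **Smooth latitude models** — richness and MRD are regressed on latitude
   with a penalized cubic-spline generalized additive model (second-order
   difference penalty, GCV-selected smoothing); fit is reported as
   deviance explained, 1 − D/D₀, with an approximate smooth-term test.
4. **Spatial diagnostics** — Moran's *I* correlograms (10 distance
   classes, binary weights per class) of the model residuals, with
   per-class Monte-Carlo permutation p-values (200 permutations,
   two-sided, +1-corrected).
5. **Basal/derived decomposition** — species at or below the 25th RD
   percentile (basal) and at or above the 75th (derived) define quartile
   richness surfaces; these are compared to total richness by per-cell
   Pearson correlation, and their correlograms are regressed on the
   total's with model-II regression (reduced major axis,
   slope = sign(r)·sd(y)/sd(x), or major axis) with one-delete jackknife
   standard errors.

Because the range maps and supertrees such analyses consume are not
redistributable, the package includes a first-class synthetic generator:
pure-birth (Yule) tree topologies with optional polytomies, and
rectangular species ranges whose centroid latitudes carry a controllable
equator-ward concentration and a controllable correlation between RD and
distance from the equator. Every downstream stage is therefore testable
end to end, with known truth.

## Worked example

```python
import numpy as np
from latgrad import (ScenarioConfig, generate_scenario, build_grid,
                     rasterize, richness, root_distances, match_species,
                     mean_root_distance, fit_smooth)

# 305 species; derived species concentrated toward the equator
sc = ScenarioConfig(n_species=305, rd_latitude_coupling=-0.8, seed=1)
tree, ranges, truth = generate_scenario(sc)

grid = build_grid(sc.bbox, cell_km=100)      # 82 x 122 cells, equal-area
pm = rasterize(ranges, grid)                 # presence-absence matrix
rd, report = match_species(root_distances(tree), pm.species)
mrd = mean_root_distance(pm, rd)

occ = pm.occupied & np.isfinite(mrd)
print("occupied cells:", int(occ.sum()))
print("corr(MRD, -|lat|): %.3f"
      % np.corrcoef(mrd[occ], -np.abs(grid.lat_deg[occ]))[0, 1])
fit = fit_smooth(grid.lat_deg[occ], richness(pm)[occ])
print("richness ~ s(latitude): deviance explained %.3f, p = %.2g"
      % (fit.deviance_explained_, fit.p_value_))
```

Output:

```
occupied cells: 9745
corr(MRD, -|lat|): 0.886
richness ~ s(latitude): deviance explained 0.601, p = 0
```

The simulated coupling of −0.8 between root distance and absolute
latitude surfaces as a strong positive correlation between cell MRD and
proximity to the equator (derived assemblages in the tropics), and the
richness gradient is detected by the smooth model at p below numerical resolution (reported as 0).

The same chain runs from a single YAML config, including per-family
subsetting, residual and richness correlograms, and the model-II
comparison stage:

```bash
latgrad run --config analysis.yaml
```

or stage by stage (`latgrad synth | grid | metrics | gam | correlogram |
compare`); see `--help` on each subcommand.

## Layout

- `src/latgrad/synthetic.py` — scenario generator (trees, ranges, truth)
- `src/latgrad/projection.py`, `grid.py` — equal-area projection, gridding,
  rasterization, richness
- `src/latgrad/phylo.py` — Newick reading, root distances, MRD, quartiles
- `src/latgrad/gam.py` — penalized-spline smoother (sklearn estimator)
- `src/latgrad/spatial.py` — distance classes, Moran's *I*, permutation tests
- `src/latgrad/compare.py` — Pearson, model-II regression, jackknife
- `src/latgrad/pipeline.py`, `cli.py` — orchestration and command line
- `docs/methods.md` — modelling choices, defaults and limitations
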