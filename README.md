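# phyloskew

Community phylogenetics of presence grids on time-scaled trees: from an
ultrametric phylogeny in relative time units plus geo-referenced species
occurrences, compute per-grid-cell species richness (SR), Faith's
phylogenetic diversity (PD), average taxonomic distinctness (AvTD), and the
birth–death skew pair — phylogenetic skew (PS) and phylogenetic-clade
evenness (PE) — then rank cells by percentile and select priority areas for
conservation. It is written for biogeographers and conservation analysts who
have a dated tree for a species pool (e.g. a barcode-based tree for a few
hundred marine species) and a presence database rasterized to 1×1-degree
cells.

## The model

Let the meta-community tree have S species and let a local community of
s members have ordered divergence times **t** = (t₁, …, t₍ₛ₋₁₎),
t₁ > … > t₍ₛ₋₁₎ — the node ages of the induced subtree spanned by its
members. Under a generalized birth–death process with speciation rate λ,
extinction rate μ and species sampling proportion ρ, conditional on t₁ the
remaining ages are i.i.d. with density λ p₁(t)/v_{t₁}, where

    P(0,t) = ρ(λ−μ) / (ρλ + (λ(1−ρ)−μ) e^{(μ−λ)t})
    p₁(t)  = (1/ρ) P(0,t)² e^{(μ−λ)t}
    v_t    = 1 − (1/ρ) P(0,t) e^{(μ−λ)t},

giving the likelihood L(**t** | λ, μ, ρ) = (s−2)! ∏ⱼ λ p₁(tⱼ)/v_{t₁}.

Estimation is two-step. Step one: fit (λ̂, μ̂) to the meta-tree's divergence
times with ρ fixed at 1. Step two: per cell, hold (λ̂, μ̂) fixed and fit the
effective sampling proportion ρ̂_E from the cell's own induced-subtree ages.
With ρ₀ = s/S the cell's actual sampling fraction,

    PS = ρ̂_E / ρ₀      PE = 1 / PS.

A community whose members concentrate in few clades has young divergences,
looks "fully sampled" to the model (large ρ̂_E), and gets PS ≫ 1; a random
draw from the pool gets PS ≈ 1. PD and AvTD are computed on the same tree:
PD as the branch-length sum of the minimum spanning path connecting the
members, AvTD as the mean pairwise patristic distance (twice the mean MRCA
age on an ultrametric tree).

Cells with more than 10 species enter the maps; each index is ranked in
mid-rank percentiles, and a cell is a priority cell when an index value
reaches the empirical 95th-percentile threshold. The phylogenetic priority
set is the union of the PD, AvTD and PE flags; the full priority set adds SR.

## Worked example

Everything is runnable without downloads via the synthetic-data module,
which plants a latitudinal skew gradient (tropical cells drawn from few
clades, temperate cells drawn uniformly):

```python
from phyloskew import CommunityPhylogenyModel, GridScenario, generate_grid

grid = generate_grid(GridScenario(seed=11))   # 236 species, 100 cells
model = CommunityPhylogenyModel(grid.tree, grid.occurrences)
results = model.fit(seed=0)
print(results.summary())
```

```
Community phylogenetic diversity analysis
=========================================================
meta-community: 236 species, 236 on tree, root age 1
cells analysed: 100 (>= 11 species; 0 cells dropped)
---------------------------------------------------------
step one (rho fixed at 1):
  lambda = 15.9 +/- 2.07   mu = 2.993 +/- 3.33   logL = 1435.71
step two, per-cell indices:
  SR    range 21 .. 46
  PD    range 2.489 .. 8.225
  AvTD  range 0.3538 .. 1.109
  PS    range 0.8085 .. 6.425
---------------------------------------------------------
priority selection at quantile 0.95:
  phylogenetic priority cells (PD|AvTD|PE): 15
  full priority cells (+SR): 17
=========================================================
```

Step one recovers rates near the generating (λ=17, μ=6) from a single
235-age realization; the per-cell PS range (0.81–6.4) separates the planted
regimes: tropical cells average PS ≈ 3.9, temperate cells PS ≈ 1.1.
`results.cell_table` is a pandas DataFrame (one row per cell with sr, pd,
avtd, rho0, rhoE, ps, pe, percentile ranks and fit flags);
`results.correlations()`, `results.latitude_profile("pe")` and
`results.priority` summarize it. The same pipeline runs from the shell:

```
phyloskew simulate-grid --seed 11 --out-dir grid/
phyloskew indices --tree grid/tree.nwk --occurrences grid/occurrences.csv --out cells.csv
phyloskew prioritize --tree grid/tree.nwk --occurrences grid/occurrences.csv \
    --out priority.csv --geojson priority.geojson
```

For real data, point `CommunityPhylogenyModel.from_files` at your own Newick
or NEXUS tree and an occurrence CSV with `species,latitude,longitude`
columns.

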