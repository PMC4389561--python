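# geoshift

Range shifts and state-dependent diversification on dated phylogenies,
starting from raw geo-referenced occurrence records.

`geoshift` is a toolkit for a common macroevolutionary study design in
biogeography: take a fossil-calibrated, ultrametric phylogeny (a
*chronogram*, branch lengths in Myr), code every species into a small set
of large regions (e.g. the American, African and Asian tropics plus a
pooled non-tropical unit) from noisy occurrence data, and then ask

1. **Are regions phylogenetically clustered?** Tip-significance tests
   (parsimony score *PS*, association index *AI*, maximum exclusive
   single-state clade *MC*) against a tip-permutation null.
2. **When and in which direction did lineages shift ranges?** An Mk model
   of region evolution is fitted by maximum likelihood, stochastic
   character maps are drawn conditional on the tip states, and mapped
   transitions are binned through time as a *relative* rate: transitions
   per 5-Myr bin divided by the number of lineages available in the bin,
   with empirical 95% bands across 100 replicate maps.
3. **Do speciation and extinction rates differ among regions?** The MuSSE
   (multi-state speciation and extinction) likelihood is computed by
   integrating, along every branch, the standard equations for
   D<sub>i</sub> (probability density of the observed clade data given a
   lineage in state *i*) and E<sub>i</sub> (probability that a lineage in
   state *i* leaves no sampled descendants), with per-state sampling
   fractions ρ<sub>i</sub> entering through the tip conditions
   D<sub>i</sub> = ρ<sub>i</sub>·1[state = i], E<sub>i</sub> = 1 − ρ<sub>i</sub>.
   Per-clade fits are normalized across regions (each rate divided by the
   clade's across-region sum) and compared with one-way ANOVA and Tukey's
   HSD, treating clades as observations.

Every input the pipeline consumes can be simulated: the
`geoshift.simulate` module generates state-dependent birth–death trees
with the *true* timed transition history recorded on every surviving
branch, toy region polygons, and occurrence tables with controlled
contamination (duplicates, zero or swapped coordinates, missing names,
stray points). That makes the whole analysis testable end to end with
ground truth in hand, with no downloads.

## Worked example

```python
import numpy as np
from geoshift import (SimConfig, simulate_musse_tree, fit_mk, fit_musse)

# simulate a 2-state tree: state 0 speciates twice as fast as state 1
cfg = SimConfig(n_states=2, lam=[0.2, 0.1], mu=[0.05, 0.05], q=0.02,
                max_taxa=250, seed=21)
tree, history, states = simulate_musse_tree(cfg)
print(tree.n_tips, round(tree.root_age, 1), history.n_events)
# 250 78.4 33

res = fit_musse(tree, states, constraints={"q": "sym"}, state_names=[0, 1])
print(res.params.lam.round(3))        # [0.203 0.085] — true (0.2, 0.1)

mk = fit_mk(tree, states, model="ER")
rates = mk.relative_shift_rates(n_maps=100, bin_width=5, seed=1)
print(rates.to_frame().head(3).round(4))
#    bin_start  bin_end direction    mean    lo95    hi95  denominator
# 0        0.0      5.0      0->1  0.0299  0.0196  0.0394        381.0
# 1        5.0     10.0      0->1  0.0306  0.0092  0.0562        160.0
# 2       10.0     15.0      0->1  0.0249  0.0000  0.0566        106.0
```

The MuSSE fit recovers the factor-2 speciation difference; the shift-rate
table gives, per 5-Myr bin and direction, the mean number of mapped
transitions per available lineage with its empirical 95% band.

A complete synthetic analysis — occurrence cleaning and region coding,
tiered presence filters, name matching, sampling fractions, clustering
tests, shift rates, per-clade MuSSE and the cross-region comparison —
runs with one command and is byte-reproducible under a fixed seed:

```bash
geoshift demo --out demo_run --seed 1
```

Individual stages are exposed as `geoshift simulate | geocode | signal |
shift-rates | fit-musse | compare | run`.

## Presence filters

Species are coded present in a region from record counts with tiered
criteria: level 1 requires ≥ 3 records in the region, level 2 additionally
≥ 10% of the species' assigned records, and level 3 restricts each species
to the single region with the most records. Range-shift analyses default
to the filter-2 coding (reduced to one state per species by the top-count
rule), diversification analyses to filter 3.

## Layout

```
src/geoshift/
  trees.py      array-backed chronograms (Newick I/O via dendropy)
  simulate.py   state-dependent birth-death simulator, toy geography,
                contaminated occurrence tables
  regions.py    named polygons (WKT/GeoJSON), point-in-polygon labels
  geocode.py    cleaning, region coding, presence filters, sampling
                fractions
  markov.py     MkModel/MkResults, stochastic mapping, binned shift rates
  musse.py      MusseModel/MusseResults, per-clade fits, normalization,
                ANOVA + Tukey HSD comparison
  signal.py     PS / AI / MC clustering statistics, permutation test
  pipeline.py   orchestration, manifest, synthetic demo
  cli.py        `geoshift` command-line interface
```

See `docs/methods.md` for the models, numerical choices and limitations.
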