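# glandphylo

Somatic-mutation lineage tracing for branching glandular epithelium.

Normal tissues accumulate somatic mutations throughout life at a
roughly constant rate, so whole-genome sequencing of small
laser-capture microdissections (a few hundred contiguous epithelial
cells) turns every patch of tissue into a molecular clock and every
shared mutation into a lineage marker. In the prostate — a tree of
24–30 independent ductal subunits draining into the urethra — this
makes it possible to reconstruct tissue dynamics across the whole
lifespan: how many embryonic cells founded each subunit, where pubertal
branching morphogenesis placed new side branches, and how spatially
confined adult clonal expansions are.

`glandphylo` implements that analysis as a tested Python library:

* **burden clock** — per-sample clonality *c* (median VAF of reported
  calls), the depth-inclusion rule *d* ≥ 4/*c* over ≥ 75 % of the
  genome, detection sensitivity *s* (exact binomial tail
  P(X ≥ 4), X ~ Bin(*d*, VAF), or a calibrated logistic GLM), the
  corrected burden *b*<sub>c</sub> = *b*<sub>r</sub>/*s*, and the
  linear mixed-effects clock *b*<sub>c</sub> ~ *a* + (1 | donor) whose
  slope is the mutation rate in mutations/year/clone;
* **VAF clustering** — a Dirichlet-process mixture of per-sample
  Beta–Binomials over each mutation's VAF vector (collapsed Gibbs with
  split/merge moves), clusters of ≥ 10 mutations interpreted as
  ancestral lineage branches, with cellular contribution
  *cc* = min(2 *m*, 1) from each cluster's per-sample median VAF *m*;
* **pigeonhole phylogeny** — since disjoint clones cannot sum above
  100 % of a microdissection, overlapping contributions force nesting
  (certainty when two clusters both exceed 95 % in one sample, strong
  evidence from matching contribution patterns summing to ≥ 75 %);
  branch lengths are mutation counts, so nodes date to developmental
  epochs (embryonic < 20 mutations, pubertal 300–500, adult > 500);
* **spatial cartography** — ductal path distances, classical MDS
  projections, gradient regressions (burden vs distance, telomere vs
  burden), clone territories with ductal contiguity, the multiclonal
  microdissection fraction, and flagging of anomalously wide adult
  clones (candidate driver expansions);
* **synthetic gland** — a generative model of the whole system
  (branching ductal tree, 5–10 embryonic founders, pubertal subclones,
  dominant adult lineages, ~30× read counts with four-alt-read
  censoring) with complete ground truth, used to validate every
  recovery step.

## Worked example

```python
import glandphylo as gp

# clock on a simulated eight-donor cohort (ages 22-78)
cohort = gp.simulate_clock_cohort(seed=7)
fit = gp.fit_clock(cohort)
print(f"{fit.slope:.1f} mutations/year/clone "
      f"(CI {fit.slope_ci[0]:.1f}-{fit.slope_ci[1]:.1f}), "
      f"intercept {fit.intercept:.0f}")
# -> 15.9 mutations/year/clone (CI 11.4-20.4), intercept -31

lo, hi = gp.age_bracket(300, 400, 130, 16.4)
print(f"burden 300-400 is reached between ages {lo} and {hi}")
# -> burden 300-400 is reached between ages 10 and 17
```

The slope is the somatic mutation rate of the epithelium (the fitted
CI covers the generative 16.4, and the intercept is indistinguishable
from zero at this noise level, as in tissue data). Inverting the clock
with the canonical parameters (intercept ~130, rate 16.4) dates
lineage coalescences: clusters of 300–500 mutations trace back to
puberty, which is when the second wave of coalescences (new side
branches formed by local stem cells) occurs.

```python
sim = gp.simulate_gland(gp.SimulationConfig(seed=11, n_terminal_acini=6,
                                            n_microdissections=16))
clusters = gp.cluster_mutations(sim.vaf_matrix,
                                gp.ClusterConfig(seed=11)).filtered(10)
evidence, conflicts = gp.infer_nesting(clusters.cc)
tree = gp.build_tree(clusters.cc,
                     clusters.clusters.set_index("cluster_id")["n_mutations"],
                     evidence)
gp.classify_tree_epochs(tree)
print(tree.to_newick())
```

Each `examples/*.py` script is a narrative walk through one capability
(simulation, clock, clustering + tree, spatial maps, full pipeline) and
prints the numbers it computes with a line on what they mean.

A thin CLI mirrors the pipeline stages:

```bash
glandphylo run --seed 5 --out pipeline_out   # simulate -> ... -> report.json
glandphylo simulate|burden|cluster|tree|spatial --help
```

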