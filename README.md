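# nichecov

Niche interactions and cell-state covariation for single-cell-resolution
spatial transcriptomics.

Imaging-based spatial transcriptomics (MERFISH, seqFISH, MERSCOPE, ...)
measures a few hundred genes per segmented cell together with its centroid.
`nichecov` integrates such data with a matched scRNA-seq reference to ask
how a cell's tissue neighbourhood shapes its identity and state:

1. **Annotation** — transfer cell-type labels from the reference to the
   spatial cells via soft mutual-nearest-neighbour anchors in a shared PC
   space, pruned by Leiden guide clusters and completed by iterative
   majority voting (unmappable cells get the sentinel `NM`).
2. **Interaction** — for every "central" cell type, an L2-penalised
   multinomial logistic regression predicts the type from the enrichment
   X_ij = Lambda_ij / (f_j sum_k Lambda_ik) of cell types in its niche
   (Delaunay contacts within 100 units, or a radius R). The cross-fold
   averaged coefficients beta rank which niche types co-localise with (or
   avoid) each central type, and define a directed interaction graph.
3. **Covariation** — per cell type, non-negative latent factors are learned
   across both modalities (integrative NMF with heterogeneity terms, or
   reference-only KL-NMF with a fixed-basis transfer), ordered by entropy,
   and each central-cell factor is ridge-regressed on neighbourhood-averaged
   factors of its niche types (penalty by leave-one-out CV, two-tailed
   t-statistic p-values). Factors are annotated transcriptome-wide by
   Spearman correlation, and ligand-receptor pairs consistent with a
   covarying factor pair are nominated from a TSV database.

A Lennard-Jones particle simulator (`tissue_sim`) generates ground-truth
tissues in which the attraction strength eps between cell-type pairs is
known, plus synthetic negative-binomial expression with a planted
cross-type factor coupling — so every claim the package makes is testable
without downloading data. See `docs/methods.md` for the model details.

## Worked example

Simulate the harder benchmark scenario (six types, 200 cells each, in a
periodic box; elevated affinities eps(T0,T2)=3, eps(T3,T5)=5, eps(T2,T3)=10,
eps(T1,T3)=8) and ask which niche types predict central type T3:

```python
import numpy as np
import nichecov as nc

snap = nc.simulate_tissue(nc.scenario_config("scenario2", seed=1))
print("final kinetic temperature:", round(snap.final_temperature, 3))

model, graph, feat = nc.run_interaction(snap.coords, snap.type_labels, seed=1)
i = list(model.type_names).index("T3")
for j in np.argsort(-model.beta[i])[:3]:
    print(f"T3 <- {model.type_names[j]}: beta = {model.beta[i, j]:+.2f} "
          f"(sd {model.beta_sd[i, j]:.2f}), simulated eps = {snap.config.eps[3, j]:g}")
print("selected C:", model.C, "| T3 held-out recall:", round(model.class_accuracy[i], 2))
```

prints

```
final kinetic temperature: 1.0
T3 <- T2: beta = +1.85 (sd 0.11), simulated eps = 10
T3 <- T1: beta = +1.24 (sd 0.10), simulated eps = 8
T3 <- T5: beta = +0.71 (sd 0.05), simulated eps = 5
selected C: 10.0 | T3 held-out recall: 0.9
```

The thermostat held the reduced temperature at 1.0, and the ranking of the
classifier coefficients for T3 reproduces the ranking of the simulated
attraction strengths (10 > 8 > 5): the niche composition alone identifies
T3's interaction partners in the right order, with fold-to-fold standard
deviations well below the coefficients themselves. A cutoff on the
normalised coefficients (`nc.build_interaction_graph(model, 0.01)`) turns
this into the directed cell-type interaction graph.

The same objects feed the covariation step: `nc.annotate` labels real
spatial data, `nc.fit_factor_models` learns per-type factors, and
`nc.regress_covariation` returns the table of ridge coefficients linking a
central type's factors to its niche types' factors with p-values and
normalised scores.

A thin CLI wraps these steps
(`nichecov simulate|annotate|interact|covary|lrpairs`, see `--help`).

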