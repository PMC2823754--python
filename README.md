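# hme3m

Supervised classification of paths through gene-labeled metabolic networks
with a Markov mixture of experts (HME3M), plus the surrounding machinery:
expression-to-path extraction, a simulation benchmark with planted dominant
paths, cross-validated evaluation against PLR/SVM baselines, and exportable
per-component pathway diagnostics.

## Who this is for

Systems biologists who have (a) a directed metabolic network — compounds as
nodes, one edge per catalyzing gene — (b) expression data for those genes,
and (c) a binary condition per sample, and who want to know *which routes
through the network* distinguish the conditions, not just which genes do.

## The model

Paths between fixed start and end compounds are encoded as binary vectors
`x ∈ {0,1}^P` over the network's `P` edges. HME3M is a two-layer mixture of
experts:

    p(y | x) = Σ_{m=1..M}  p(m | x, θ) · p(y | x, β_m)

The gate `p(m | x, θ)` is a mixture of first-order Markov chains over
paths: component `m` has prior `π_m` and transition probabilities `θ_tm`
that sum to one over each compound's outgoing edges, so
`p(x | θ_m) = Π_{t: x_t = 1} θ_tm` and each component concentrates on a
*dominant path* cluster. Each expert is a ridge-penalized logistic
regression (`λ` controls shrinkage, learning rate `α` damps its IRLS
updates). The whole thing is fitted by EM on responsibilities
`h_im ∝ π_m p(x_i|θ_m) p(y_i|x_i, β_m)`; see `docs/methods.md` for the
estimation details and numerical safeguards.

Because the gate is a path model, a fitted component is directly readable:
its `θ` values trace the dominant route through the network, and its expert
says how predictive that route is for the response.

## Worked example

```python
import numpy as np
import hme3m

# benchmark generator: layered network, 2 dominant paths per class,
# 200 paths per class, 20% uniform noise paths
cfg = hme3m.SimulationConfig(network_size="small", noise_fraction=0.2, seed=7)
sim = hme3m.simulate_pathways(cfg)
print("dataset:", sim.dataset.n, "paths over", sim.dataset.p, "edges")

model = hme3m.fit_hme3m(sim.dataset.X, sim.dataset.y, sim.network,
                        n_components=2, lam=1.0, alpha=0.5, seed=7)
print("final penalized log-likelihood:", round(model.history[-1], 2))
print("component priors:", np.round(model.mixture.pi, 3))
print("training CCR:", hme3m.ccr(sim.dataset.y, hme3m.predict(model, sim.dataset.X)))
print(hme3m.dominant_path_report(model, m=0, threshold=0.5))
```

prints

```
dataset: 400 paths over 12 edges
final penalized log-likelihood: -823.97
component priors: [0.492 0.508]
training CCR: 92.0
  source target gene  edge     theta
0  start   n1_2   g2     2  0.502538
1   n1_1   n2_2   g4     4  0.816326
2   n1_2   n2_1   g5     5  0.808082
3   n2_1   n3_1   g7     7  1.000000
4   n2_2   n3_1   g9     9  1.000000
5   n3_1    end  g11    11  1.000000
6   n3_2    end  g12    12  1.000000
```

The report lists, per source compound, the transitions carrying at least
the threshold probability under component 1 — the dominant routes that
component has locked onto (edge numbers are 1-based). Training CCR of 92%
on a 20%-noise design is close to the ≈ 90% an ideal classifier can reach,
since uniform noise paths carry no class signal.

The same flow works from the shell:

```sh
hme3m simulate --size small --noise 0.2 --seed 7 --outdir sim
hme3m fit --pathways sim/pathways.tsv --network sim/network.tsv \
          --start start --end end -m 2 --seed 7 --outdir fit
hme3m export --model fit/model.json --outdir figs   # GraphML + DOT with theta
```

and `hme3m extract` turns a network TSV + expression TSV + labels TSV into
a pathway dataset (z-score the genes, threshold at a tolerance, enumerate
all valid start→end paths per sample). `hme3m evaluate` runs the
cross-validation benchmark against the PLR and SVM baselines.

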