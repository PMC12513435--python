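# concise-networks

Concise, interpretable memory-network models of path data.

Trajectory data — passenger itineraries through airports, information
relayed through a social network, click streams — often violate the
first-order Markov assumption: where flow goes next depends on where
it came from.  Full second-order models capture this with one state
node per (predecessor, node) pair, but they explode in size and
overfit wherever coverage is thin.  This package builds models that
interpolate between the two extremes: each node `j` is split into a
small number `r` of *state nodes* that represent coarse behavioral
modes (for a hub airport: "eastbound transit" vs "westbound transit")
rather than individual predecessors.

For each node the pipeline is:

1. **Trigram counts** `A` — `A[k,i]` counts observed two-step paths
   `i -> j -> k` (optionally excluding return transits `i -> j -> i`).
2. **Regularized target dynamics** — the posterior mean under a
   Dirichlet prior toward the memoryless distribution `M1`:

       X[k,i] = (A[k,i] + mu * M1[k]) / (n_i + mu)

   with prior strength `mu` chosen by closed-form leave-one-out
   cross-validation when not supplied.
3. **Convex NMF** — `X ~ Xout @ Xin.T` via `X W G.T` with nonnegative
   factors and multiplicative updates, so every state's
   out-distribution is a convex combination of observed behavior.
4. **Model selection by flow overlap** — the shared probability mass
   `sum min(p, q)` between model and target, flow-weighted across
   predecessors; the selected rank is the smallest one reaching a
   threshold.

The resulting state networks support trimming of low-importance
edges, disparity-filter backboning with weak-connectivity repair,
export to the Infomap state-network format, and random-walk analytics
(three-leg connectivity and expected geographic displacement).  A
synthetic benchmark with planted behavioral modes and a two-layer
social relay generator are included as first-class, tested modules.

## Worked example

Generate a synthetic node with two planted behavioral modes, select
the prior strength automatically, and sweep the number of state
nodes:

```python
from concise_networks import (
    SyntheticNodeSpec, generate_mode_mixture_node, posterior_dynamics, rank_sweep,
)

node = generate_mode_mixture_node(SyntheticNodeSpec(n_modes=2, concentration=0.5, seed=42))
dyn = posterior_dynamics(node.counts, "auto")
print(f"selected prior strength mu = {dyn.mu:.1f}")
for r, split in zip([1, 2, 3], rank_sweep(dyn, [1, 2, 3], seed=0)):
    print(f"r={r}: flow overlap = {split.overlap:.3f}, loss = {split.loss:.4f}")
```

prints

```
selected prior strength mu = 38.5
r=1: flow overlap = 0.686, loss = 0.5041
r=2: flow overlap = 0.922, loss = 0.0435
r=3: flow overlap = 0.925, loss = 0.0415
```

A single state (a first-order model) captures 69% of the flow through
the node; two states — the planted number of modes — jump to 92%, and
a third adds almost nothing.  The elbow at `r = 2` is exactly the
signal used to pick model size.

The same workflow from the shell:

```sh
concise extract --paths itineraries.txt --exclude-returns --out counts.tsv
concise fit     --counts counts.tsv --threshold 0.7 --max-rank 12 --seed 1
concise build   --counts counts.tsv --split-nodes top:10 --threshold 0.7 \
                --sigma 0.05 --backbone 0.01 --out net/
concise synth modes --nm 5 --c 1.0 --reps 25 --seed 7 --out bench.tsv
```

`concise build` writes an edge list, a state map, and an Infomap
state-network file for downstream community detection.

## Library map

| module | contents |
| --- | --- |
| `concise_networks.corpus` | path files, trigram counting, hub ranking, TSV IO |
| `concise_networks.dynamics` | MLE rates, Dirichlet posterior, LOO-CV `mu`, flow overlap |
| `concise_networks.nmf` | convex NMF, restarts, rank sweeps and selection |
| `concise_networks.network` | state-network assembly, trimming, disparity backbone, Infomap export |
| `concise_networks.synthetic` | mode-mixture and two-layer generators, benchmark, baselines |
| `concise_networks.flow` | walk matrices, three-leg connectivity/displacement, haversine |

See `docs/methods.md` for the full model description, numerical
choices, and known limitations.
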