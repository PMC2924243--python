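# netwalk

Score genes and interactions in a molecular interaction network by how
coherently experimental data flows through it.

Given (a) an interaction network — protein–protein, signaling, transcription
factor→target and functional-similarity edges — and (b) per-gene positive
ratio values **w** (e.g. treated/control expression), the package runs a
**data-biased random walk with restart**: the walker steps from node *i* to a
downstream neighbor *j* with probability

```
p_ij = w_j / Σ_{k∈N_i} w_k
```

and with probability *q* per step (default 0.01) restarts at a node drawn
proportionally to the data. The stationary visitation frequency **g** solves
`g = (1−q)·gP + q·r` and scores each node by its data value, its neighbors'
values, and the local connectivity. A background walk with all `w_i = 1`
yields **g_r**, pure topological centrality; the **relative visitation**
`g′ = g/g_r` removes hub bias. Each interaction gets an **Edge Flux**
`e_ij = g_i·p_ij` (walker mass per step through the edge) and a normalized
score

```
s_ij = log2(e_ij / e_r,ij)
```

centered at 0: positive on coherently up-regulated neighborhoods, negative
on coherently down-regulated ones. The full distribution of *s* supports
subnetwork extraction at any cutoff, cross-condition comparison by Ward
clustering of edge-score profiles, and seeded robustness experiments. It is
aimed at anyone turning omics ratio data plus a prior-knowledge interactome
into concrete, data-coherent subnetwork hypotheses.

## Worked example

A 12-node didactic network ships with the package: node A has value 5, the
interconnected cluster G–L has value 2, the rest 1.

```python
from netwalk import WalkConfig, run_netwalk
from netwalk.synthetic import make_toy_network

net, w = make_toy_network()
visit, ef = run_netwalk(net, w, WalkConfig(q=0.01), winsorize_data=False)
for gene, rel in sorted(visit.as_dict("g_rel").items(), key=lambda kv: -kv[1])[:3]:
    print(f"{gene}  g_rel = {rel:.3f}")
print(ef.sorted_by_score().head(3)[["source", "target", "s"]].to_string(index=False))
```

prints

```
A  g_rel = 2.392
J  g_rel = 1.512
G  g_rel = 1.366
source target        s
     A      B 1.253536
     G      H 0.864800
     G      L 0.864533
```

Node A visits 2.4× more often than topology alone predicts, the cluster
nodes ~1.4×, and the top-scoring edges are exactly A's attachment and the
intra-cluster interactions — the neighborhoods where data and wiring agree.
Every value-1 background node scores below 1.

The same pipeline is available from the shell:

```
netwalk simulate --kind planted --out fixture/
netwalk run --network fixture/network.tsv --data fixture/data.tsv \
            --q 0.01 --top-k 100 --out results/
```

which writes the node table, the full edge-flux table, top/bottom-k
subnetworks, a GraphML export, and a provenance record. Other subcommands:
`build-fs` (functional-similarity edges from annotation overlap), `merge`,
`cluster` (Ward over conditions), `robustness`.

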