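# cldkit

Analysis of **signed causal loop diagrams (CLDs)** produced by group
model-building workshops — the participatory method in which community
stakeholders jointly map the factors driving a complex health problem
(here, dementia risk) and the causal links between them.

`cldkit` is for researchers running community-based system dynamics (CBSD)
studies who end up with several hand-drawn causal maps of *the same*
system, one per workshop group, and need to answer, reproducibly:

- which **feedback loops** does each map contain, and are they reinforcing
  or balancing?
- what does the **union** of all groups' maps look like, and which edges do
  multiple groups agree on?
- what is the **consensus core model** around the focal problem variable?
- where do participants' proposed **action ideas** gain leverage on that
  core?

## The model

A CLD is a signed digraph $G = (V, E)$ with edges
$(u, v, s)$, $s \in \{+, -\}$: a `+` edge means $u$ and $v$ move in the
same direction, `-` in opposite directions.  A feedback loop is a simple
directed cycle; by the standard sign-product rule a loop with an even
number of negative links is **reinforcing (R)** and one with an odd number
is **balancing (B)**.

Given group models $G_1, \dots, G_k$ over standardized factor labels, the
union model assigns each distinct edge $(u, v, s)$ its *support*
$\sigma(u,v,s) = |\{i : (u,v,s) \in E_i\}|$.  The **core model** is the
fixed point of: keep edges with $\sigma \ge m$ (default $m = 2$), then
repeatedly keep only edges lying on a simple cycle or on a directed path
to/from the focal variable, finally dropping isolated nodes.  Indirect-path
consensus additionally credits a group with an edge when its own map
contains a short same-sign path from cause to effect.  Action-idea leverage
enumerates bounded simple signed paths from each action node into the core.

A synthetic-battery generator (`cldkit.synthetic`) plants a latent system
with known core structure, samples imperfect group observations of it
(miss rate, sign flips, group-specific noise), and scores how well core
extraction recovers the latent core — the validation route when real
workshop transcripts are unavailable.  See `docs/methods.md` for details
and assumptions.

## Worked example

The package ships a one-group demo CLD transcribed from narrated workshop
loops around dementia risk:

```python
import cldkit as ck

models = ck.load_demo_models()
stats = ck.summary_stats(models).summary()
print(f"factors={stats['n_factors']['mean']}  edges={stats['n_edges']['mean']}  "
      f"action_ideas={stats['n_action_ideas']['mean']}")

loops = ck.enumerate_simple_cycles(ck.build_graph(models[0].edges), max_len=12)
n_r = sum(l.classification is ck.LoopClass.REINFORCING for l in loops)
print(f"{len(loops)} loops: {n_r} reinforcing, {len(loops)-n_r} balancing")
for loop in loops[:2]:
    signs = "".join(p.symbol for p in loop.polarities)
    print(" ", " -> ".join(loop.nodes), f"[{signs}]", loop.classification.value)

agg = ck.union_models(models)
core = ck.extract_core(agg, min_support=1)   # single group: keep support-1 edges
print(f"core: {core.n_nodes} nodes, {core.n_edges} edges")
for inf in ck.action_influence(agg, core, max_path_len=3):
    print(f"  {inf.action}: reaches {inf.n_pairs} core nodes via {inf.n_pathways} pathways")
```

prints

```
factors=36.0  edges=50.0  action_ideas=2.0
15 loops: 9 reinforcing, 6 balancing
  domestic_violence -> trauma -> substance_abuse [+++] reinforcing
  access_to_quality_jobs -> crime -> criminal_justice_bias -> convictions [-++-] reinforcing
core: 36 nodes, 50 edges
  dementia_information_campaign: reaches 6 core nodes via 6 pathways
  voter_mobilization: reaches 3 core nodes via 3 pathways
```

The first loop is the all-positive trauma → substance-abuse →
domestic-violence triangle (reinforcing: a shock anywhere amplifies around
the cycle).  The second shows the sign-product rule at work: two negative
links make the criminal-justice/jobs cycle reinforcing.  With one group
every edge trivially has support 1, so the core at `min_support=1` keeps
the whole connected map; with a multi-group battery the default
`min_support=2` keeps only cross-group consensus structure.

The same stages are available as a CLI:

```sh
cldkit summarize src/cldkit/data/demo_workshop.csv --focal dementia
cldkit loops     src/cldkit/data/demo_workshop.csv --focal dementia
cldkit run       src/cldkit/data/demo_workshop.csv --focal dementia --min-support 1 --out demo_run/
cldkit simulate --seed 1 --out battery.csv     # synthetic 8-group battery
cldkit recover --seed 1 --reps 50              # core-recovery experiment
```

`cldkit run` writes per-group statistics, the union support table, loop
inventories, the core model (CSV/DOT/GraphML), indirect-path consensus,
action-influence tables, and a manifest into one run directory; identical
inputs and configuration always produce byte-identical reports.

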