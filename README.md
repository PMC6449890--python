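# t2dm-boolnet

Asynchronous Boolean network analysis of beta-cell fate in type 2 diabetes
mellitus (T2DM).

T2DM arises from insulin resistance combined with pancreatic beta-cell
dysfunction and apoptosis, driven by endoplasmic-reticulum (ER) stress,
oxidative stress and inflammatory cytokines. This package implements a
72-node logical model that integrates the insulin-resistance arm
(PI3K–AKT, mTOR, JAK–STAT and insulin signaling, controlling GLUT4,
glycogen synthesis and gluconeogenesis) with the beta-cell apoptosis arm
(the unfolded protein response, oxidative-stress kinases, and the
FasL/TNFα death-receptor cascades converging on the caspases). Five input
signals — ER stress, oxidative stress, TNFα, FasL and IL-6 — drive the
network; one node reports Apoptosis.

## The method

Each gene holds a binary state. A gene's update rule combines its
activators with OR and its inhibitors with AND-NOT: the gene switches on
when at least one activator is expressed and no inhibitor is, i.e.

    g = (a₁ ∨ a₂ ∨ …) ∧ ¬h₁ ∧ ¬h₂ ∧ …

Dynamics use **random-order asynchronous updating**: each time step draws
a uniformly random permutation of all 72 nodes and updates them
sequentially in that order, every update immediately visible to the later
ones in the same sweep. Many seeded runs per input condition are pooled
into a sampled **state-transition graph** (STG); the **attractors** are
its terminal strongly connected components (SCCs) — state sets the
dynamics enter and never leave. Within an attractor the probability of
state Sᵢ is its visit share,

    P(Sᵢ) = count(Sᵢ) / Σⱼ count(Sⱼ),

and the expression level of gene g is the probability mass of states
where g is ON:

    Exp(g) = Σ_{Sⱼ : g(Sⱼ)=1} P(Sⱼ)  ∈ [0, 1].

Levels above 0.50 are called "expressed" and can be scored against a
literature truth table (precision, recall, specificity, F1). Companion
tools rewire the model into degree-matched random Boolean networks for
comparison, clamp genes to 0/1 for virtual knockout and overexpression
experiments, and — for small toy networks — enumerate the exact
transition relation over all n! update orders as a brute-force oracle.

## Worked example

```python
import t2dm_boolnet as tb

net = tb.load_t2dm_model()
print(net.n_nodes, sorted(net.input_nodes), sorted(net.undefined_refs))

result = tb.run_case(net, case=8, n_runs=200, n_steps=300, seed=1)
print(result.n_attractors, result.apoptosis_on)
for a in result.attractors:
    print(f"{a.size:5d} states  Apoptosis={a.expression['Apoptosis']:.2f}"
          f"  CHOP={a.expression['CHOP']:.2f}"
          f"  GLUT4={a.expression['GLUT4']:.2f}"
          f"  AKT={a.expression['AKT']:.2f}")
```

prints

```
72 ['ER', 'FasL', 'IL6', 'OS', 'TNFA'] ['CASP12', 'GADD45', 'P53']
2 2
 2297 states  Apoptosis=1.00  CHOP=0.00  GLUT4=0.66  AKT=0.51
  142 states  Apoptosis=1.00  CHOP=1.00  GLUT4=0.50  AKT=0.00
```

With all five stress signals on (case 8), every run commits to apoptosis
(Apoptosis = 1 in both attractors) while the insulin arm keeps oscillating:
the two attractors are distinguished by the ATF4/CHOP/EIF2S1/GADD34/TRB3
positive-feedback loop being locked OFF or ON. In the loop-OFF attractor
GLUT4 sits near 0.65 and AKT near 0.50 — partial glucose-uptake capacity
under insulin resistance; when the loop is ON, TRB3 suppresses AKT
entirely.

The same pipeline is scriptable from the shell:

```sh
t2dm-boolnet run --case 8 --runs 200 --steps 300 --seed 1 --out results/
t2dm-boolnet knockout --gene CASP3 --case 8 --runs 200 --steps 300 --seed 1
t2dm-boolnet random-compare --case 8 --n 5 --runs 100 --steps 200 --seed 1
t2dm-boolnet validate --attractors results/case8_attractors.csv \
    --truth src/t2dm_boolnet/data/truth_example.csv
```

`run` writes per-case attractor tables (nodes × attractors CSV), the STG
in GraphML, and a JSON summary.

## Caveats

The bundled rule file is a faithful transcription of the published rule
table, quirks included; `docs/methods.md` documents the update semantics,
the design decisions behind the pipeline, and known discrepancies between
that printed rule table and the originally reported attractor structure.
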