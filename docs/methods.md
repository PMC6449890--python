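# Methods

## Model

The bundled network has 72 nodes: five environmental input signals (ER
stress `ER`, oxidative stress `OS`, `TNFA`, `FasL`, `IL6`), one `Apoptosis`
read-out, and 66 gene/protein nodes spanning the unfolded protein response
(GRP78, IRE1/XBP1, PERK/EIF2S1/ATF4, ATF6, CHOP), the stress kinases
(ASK1, JNK, p38), the mitochondrial and death-receptor apoptosis cascades
(BCL2/BAX/BAK, cytochrome c/APAF1, FADD/RAIDD, caspases 3/6/7/8/9, XIAP
and its antagonists), and the insulin arm (INS/INSR/IRS, PI3K–AKT, mTORC1/
S6K/mTORC2, JAK–STAT–SOCS3, GLUT4, GSK3B/GS, FOXO1 targets).

Rules are kept in the activator/inhibitor canonical form: a node is ON
after update iff at least one activator is ON (vacuously true when it has
no activators) and every inhibitor is OFF. The bundled rule file is a
transcription of the published rule table with its printed spellings; the
parser canonicalizes names (Greek letters, hyphens, `TSC1/2` → `TSC2`),
reads adjacent parenthesized terms with a missing operator as AND, and
normalizes mixed and/or expressions to the canonical form. Three names —
`P53`, `GADD45`, `CASP12` — are referenced by rules but have no update
function and are not among the 72 nodes; they are treated as constant
FALSE, which keeps the printed node count and is the only reading under
which, e.g., APAF1 simply follows cytochrome c.

## Update semantics

One time step is a full random-order sweep: draw a uniformly random
permutation of all nodes, update them sequentially in that order, each
update immediately visible to later updates of the same sweep. One
recorded state per sweep (not per single node update); the three-gene
worked example in `fixtures/three_gene_cascade.rules` pins this semantics
in the tests. There is no burn-in discard — transients are separated from
recurrent behaviour downstream by the SCC analysis.

## Initial conditions

Per experimental case the five signals are fixed (eight published
combinations, from ER-stress-only through all-five-on). Apoptosis and
caspases 3/6/7/8/9 start OFF so that any apoptosis observed is
input-driven. All remaining free nodes are i.i.d. Bernoulli(1/2), with one
exception: `INS` starts ON. INS is a frozen self-copy node (`INS = INS`),
so its initial value persists forever; the modeled scenario is a beta cell
with insulin present (the reported attractors all carry INS = INSR = 1),
and a random INS would merely duplicate every attractor into a biologically
meaningless INS=0 twin.

## Attractors from sampled dynamics

Each case pools `n_runs` seeded trajectories into one state-transition
graph: a vertex per distinct visited state, an edge per observed
consecutive pair, visit counts pooled across runs. Attractors are the
terminal SCCs of this graph, with one correction for finite sampling:
because every trajectory is truncated at `n_steps`, its final state can
dangle off its recurrent region with no observed successor, so states
without outgoing edges are peeled off iteratively before the SCC pass.
Attractor state probabilities are visit shares within the component
(integer-accumulated, so a gene ON in every state gets expression exactly
1.0), and the attractor label is the lexicographically smallest member
bit-string, making report order deterministic.

Sampled attractors are sound (every reported one is a true terminal SCC of
the exact dynamics — checked against the brute-force oracle on toy
networks) but complete only asymptotically: covering an attractor state
requires sampling proportional to its inverse stationary probability. The
shipped five-node oscillator has a state visited ~4·10⁻⁵ of the time, so
the exact-equality tests run 600 runs × 300 sweeps on the fixtures.

## Seeding

A single experiment seed plus the case id feed a `SeedSequence`; per-run
generators are spawned children, so cases are independent streams, runs
are reproducible in any order, and the whole experiment is a pure function
of `(network, case, n_runs, n_steps, seed)`.

## Protocol sizes

The original protocol is 1000 runs × 1000 sweeps per case. Transients in
this model settle within a few tens of sweeps, and attractor counts and
expression levels are stable across seeds at 200 runs × 300 sweeps for
cases 2, 3, 4, 5, 7 and 8; the default protocol in the acceptance script
therefore uses 200 × 300, raised to 1000 runs for cases 1 and 6 whose
quiescent basins are entered by only a small fraction of random initial
conditions.

## Validation metrics and random-network comparison

Expression levels discretize at a strict 0.50 threshold. Discretized calls
are scored against a user-supplied truth table (`gene,expected,source`
CSV) by the four confusion-based metrics; zero-denominator ratios are
reported as NaN with a warning. The shipped `truth_example.csv` is a
curation assembled by this package from the modeled interactions'
published directions — the original study did not publish its truth
labels, so no claim is made that scores on this file reproduce the
originally reported averages (only the F1 = 2pr/(p+r) identity is
checkable, and is).

Random comparison networks preserve each non-input node's in-degree,
resample its regulators uniformly without replacement from the non-input
nodes, and assign activator/inhibitor roles by fair coin; input nodes keep
their rules so the same experimental protocol applies.

## Virtual perturbations

Knockout replaces a gene's rule with constant 0 (overexpression with 1);
clamped genes are also pinned in the initial state. The Apoptosis read-out
cannot be clamped. Systematic single/double-knockout scans are left to
user scripts looping over `knockout` + `run_case`.

## Exact oracle for small networks

For n ≤ 8 nodes the exact transition relation is enumerated: every one of
the 2ⁿ states × n! permutations, one sweep each. True attractors are the
terminal SCCs of this graph. Shipped fixtures: the toggle switch (two
fixed points), the three-gene cascade (two fixed points), the
GADD34→EIF2S1→ATF4→CHOP positive loop with upstream sensors held FALSE
(bistable — the motif behind the full model's paired ON/OFF attractors),
and a five-node negative-feedback ring (one 24-state cyclic attractor,
exercising fractional expression levels).

## Known discrepancies with the published rule table

The printed rule table is internally inconsistent with the originally
reported attractor tables, and this package implements the rules as
printed. Three load-bearing examples:

- `ATF6 = GRP78`, yet the reported attractors all have GRP78 = 1 and
  ATF6 = 0. Under the printed rule ATF6 follows GRP78, and since GRP78 is
  driven ON through XBP1 ← IRE1 ← BAX whenever ER = 0, ATF6 — and with it
  the whole CHOP loop — is forced ON in cases 2, 4, 5 and 7. Those cases
  therefore yield one attractor here, not the reported ON/OFF pair. With
  ER = 1 (cases 3 and 8) GRP78 is held OFF by its ER inhibitor, the loop
  is bistable, and the reported two-attractor structure is reproduced
  exactly.
- ER stress appears in exactly one rule, as an inhibitor of GRP78, so
  ER stress alone (case 1) cannot force the death cascade; this package
  finds both apoptotic and quiescent attractors for case 1, where the
  original reports two apoptotic ones.
- In case 6 (IL-6 only) this package finds a single quiescent attractor
  (XIAP = 1, BCL2 = 1, GLUT4 up to ~0.80) plus apoptotic ones — not the
  reported 4-ON/2-OFF structure, which requires loop bistability that the
  printed `ATF6` rule removes.

The original simulation code evidently used update functions differing
from the printed table in ways that cannot be recovered from the
publication; where the two conflict, the attractor-level tests record the
difference rather than paper over it. Orientation oddities in the printed
rules (e.g. `PERK = GRP78 and (not DNAJC3)` and `IRE1 = BAX or BAK or
GRP78`, where the biology has GRP78 sequestering and *inactivating* both
sensors) are likewise implemented exactly as printed.

## Limitations

- Attractor detection is sampling-based; exhaustive or symbolic (BDD)
  analysis of the 72-node state space is out of scope.
- The random-network comparison depends on the (unpublished) generation
  procedure of the original study; with the degree-preserving scheme here,
  random networks often produce one enormous chaotic recurrent set that a
  union-graph SCC counts as a single attractor, so their attractor counts
  are small — the originally reported 25–180 range is not reproduced.
- Toy fixtures exercise every pipeline stage, but passing them shows
  correctness of the machinery, not biological validity of the model.
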