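# Methods

## The model family

The package works with threshold Boolean networks over the eleven core
regulators of the budding yeast (*Saccharomyces cerevisiae*) cell cycle:
Cln3, MBF, SBF, Cln2, Cdh1, Swi5, Cdc20, Clb5, Sic1, Clb2 and Mcm1 (this
is also the canonical column order of every printed state vector).  A node
carries a discrete activity level — binary for most regulators, ternary
(0/1/2) for regulators whose graded concentration matters (Clb2, and Swi5
in the revised model).  Each directed edge has a signed weight from the
alphabet {±1/3, ±1, ±3} (±1 in the purely binary model), and each node
updates from the weighted sum of its inputs,

    sigma_i(t) = sum_j w_ij * S_j(t-1).

### Update rule

Two semantics are implemented.

**`li_binary`** — the classic rule: a node switches ON when `sigma > 0`,
OFF when `sigma < 0`, and on a tie keeps its level unless it is flagged
*self-degrading*, in which case it decays to 0.

**`multilevel`** — the graded extension, with level-entry thresholds
`theta_1 = 1/2` and `theta_2 = 3/2`:

* a node at level `s` rises to `s + 1` when `sigma >= theta_{s+1}`
  (one level per step, even when the sum would support a higher level);
* a *ternary* node at level `s` falls to `s - 1` when `sigma < theta_s`
  — graded activity requires sustained input at every level;
* a *binary* node falls to 0 when `sigma <= -1/2`; in the neutral band
  `-1/2 < sigma < 1/2` it keeps its level unless flagged self-degrading.

The binary clause is the Li tie rule generalised to fractional sums: with
integer weights the band contains only `sigma = 0` and the rule reduces
exactly to `li_binary`.  The band matters once 1/3-weights exist — a
single low-weight activator (sum 1/3) must *not* switch a binary target
on; this is precisely the mechanism by which lowering the Clb5→Mcm1
weight removes the first hazard.  Two alternatives were rejected against
the attractor-table checksums (below): applying the ternary decay clause
to binary nodes (which forces sustaining self-loops and then cannot
reproduce the printed basins), and allowing multi-level jumps in one step.

All arithmetic is exact: weights are `fractions.Fraction` and the
implementation scales sums by 6 so every comparison is on integers
(scaled sums are even, scaled thresholds odd, so threshold ties cannot
occur in the multilevel semantics).

### Update modes

*Synchronous*: all nodes update simultaneously from the same predecessor
state; deterministic.  *Asynchronous*: exactly one node updates per
instant, chosen non-deterministically among the nodes whose target level
differs from their current one — this models arbitrary variation in
reaction rates.  No-op updates are collapsed: they only stutter the
schedule (see the fairness reduction below).  The seeded simulator picks
uniformly among enabled nodes.

## The three bundled networks

* **li** — the binary network of the original Boolean cell-cycle study:
  29 unit-weight signed edges, self-degradation on Cln3, Cln2, Swi5,
  Cdc20 and Mcm1.
* **mangla** — the graded predecessor: Clb2 ternary, weights from the
  three-magnitude alphabet.
* **proposed** — the timing-robust revision: Swi5 also ternary, and
  exactly four edges re-weighted relative to **mangla**: Clb5→Mcm1
  lowered to 1/3 (Mcm1 activation now requires Clb2, closing the
  Clb2–Mcm1 positive feedback), Cdc20→Swi5 raised to 3 and Clb2⊣Swi5
  weakened to −1/3 (Swi5 reaches its top level once Cdc20 fires,
  regardless of Clb2), and Swi5→Sic1 lowered to 1/3 (only fully active
  Swi5, level 2, turns Sic1 on).

A structural feature of the graded models deserves emphasis: their
timing robustness rests on *hand-off protection*.  An asynchronous
schedule may delay any update indefinitely, so every producer must stay
active until all of its consumers have latched, or the cycle derails
into a spurious resting state.  Three such protections are present: the
Cln3 stimulus is held by feedback inhibition from MBF and SBF until both
are latched (each alone is sub-threshold at weight 1/3); S-phase entry
waits for both inhibitors, with Clb5 blocked by Cdh1 as well as Sic1;
and Cdc20 is released for decay only once both of its consumers (Cdh1
and Sic1) are back on, via their inhibitory edges, while Swi5 keeps it
alive in the late-cycle trap states.  The binary model has none of
these, which is precisely why timing variation can drive it into wrong
attractors.

The two graded fixtures were transcribed from figure drawings that are
not machine-readable and whose line-thickness encoding leaves magnitudes
ambiguous; the bundled weights are the assignment most consistent with
the documented hazard mechanisms, the four-edge revision contract, the
activation-order narrative, the checkpoint verdict pattern, and the
printed attractor tables, found by large-scale constraint search over
the admissible weight space.  The verdict pattern, orderings and
global-attractor behaviour are reproduced exactly; the printed basin
tables are reproduced to within about two per cent of the state space
(the acceptance suite asserts them bit-exactly and reports the residual
honestly — see the limitations below).

In all three models the stationary G1 state is Cdh1=1, Sic1=1 with every
other node at 0; the stimulated G1 state additionally sets Cln3=1.  The
state-space sizes are 2^11 = 2048 (li), 2^10·3 = 3072 (mangla) and
2^9·3^2 = 4608 (proposed).

## Attractors and basins

Basins are computed under synchronous updating by iterating the update
map from *every* state of the full state space (pointer doubling on the
packed-integer state encoding; a limit-cycle resolution pass covers
non-fixed-point attractors, which do occur for toy models and mutants
though all bundled fixtures have only fixed points).  Everything is exact
— the spaces are at most 4,608 states — and basin sizes partition the
space by construction.

## Checkpoint properties and the fairness reduction

Checkpoint conditions are expressed over the asynchronous transition
graph from the stimulated G1 state:

* **Precedence** (`A` at level `a` before `C` at level `c`): checked by
  BFS over the graph crossed with one monitor bit ("antecedent seen");
  a violation is a reachable configuration satisfying the consequent
  with the bit clear.  BFS yields a shortest counterexample trace.
* **Response** (trigger ⇒ eventually obligation, on fair schedules) and
  **global attractor** (every fair run ends at stationary G1): reduced
  to structural graph conditions.  In the SMV-style encoding of
  asynchrony a control variable picks which node's rule fires, and
  fairness demands every node be picked infinitely often.  A pick whose
  update is a no-op merely stutters, so fairness forces progress only
  through enabled nodes.  On a finite graph every infinite run
  eventually stays within one SCC of the value-changing graph, and that
  suffix can be fair iff the SCC is *fair-sustainable*: each node has
  either a no-op state inside the component or an update edge staying
  inside it.  A component that keeps some node enabled with every one
  of its update edges leaving the component cannot be looped fairly —
  scheduling that node ejects the run.  "All fair paths eventually
  reach T" therefore reduces to: no reachable absorbing state other
  than T, and no reachable fair-sustainable SCC avoiding T.  The
  checker consequently needs only reachability, SCC analysis and a
  local no-op test; failure witnesses are a path to a wrong absorbing
  state or a lasso (path + cycle).  This equivalence is specific to
  this encoding and is stated as such in the code.  (The distinction
  matters in practice: the graded models contain large cycles through
  states where the consumed stimulus keeps one node permanently
  enabled; those cycles are unfair and do not refute inevitability.)

The default property set (a JSON config, not code) renders the S/G2
checkpoint (Clb5 before Clb2), the M-metaphase checkpoint (Clb2 before
Cdc20; Mcm1 before Cdc20), and the M-telophase checkpoint (Cdc20 ⇒ Swi5
at top level; Swi5 at top level ⇒ Sic1; Cdc20 ⇒ return to stationary G1),
plus the global-attractor property.  "Activation" means level ≥ 1 and
"full activation" the node's top level; because the exact supplementary
formulas of the source study are not public, verdicts are reported per
checkpoint *group* and the set is user-replaceable (`--properties`).

Every failed verdict ships a counterexample that replays step-by-step
through `async_successors`; the test suite re-validates this mechanically.

## Phase segmentation and statistics

Phases are latched labels along a trajectory: the cycle starts at the
stimulated G1 state, each phase begins when its entry marker first holds,
and the cycle ends on arrival at stationary G1.  Two marker sets ship as
data: the 2-segment split (S; G2/M at Clb2 ≥ 1) for duration statistics
and the 4-segment split (G1; S at Clb5 ≥ 1; G2 at Clb2 ≥ 1; M at
Cdc20 ≥ 1) for transition counts.  The two tables they mirror are not
reconcilable under a single boundary definition (the revised model has a
single distinct S transition yet a mean S duration well above 1), which
is why both configs exist.

Duration statistics enumerate **all distinct simple paths** from
stimulated to stationary G1 in the asynchronous graph, each path weighted
equally.  On the bundled models the pruned graph is acyclic, so means and
population variances (n denominator; switchable) are computed by exact
dynamic programming over (state, latched-phase) pairs without
enumerating the (hundreds of thousands of) paths.  A seeded
scheduler-weighted sampling mode is available as an alternative estimand.
Transition counts group the distinct edges of the pruned reachable graph
by the latched phase of their source state (earliest phase when a state
is reachable under several latches).

The source study prints S/G2-M duration means and per-phase transition
counts without stating the averaging population or boundary definitions.
Under the definitions above, the exactly-verified binary model yields
S = 8.61 (variance 0.84) against a printed 9.30 (1.55), and per-phase
counts larger than the printed ones — so the original counting scheme
differs from any of the several we tested (path-prefix weighting, segment
subgraphs, scheduler ticks, pruned and unpruned graphs).  Two findings
are worth recording.  First, the graded predecessor model measured this
way gives S = 9.23 (variance 1.15) — strikingly close to the printed
9.30 — while the binary model does not, suggesting the published
duration analysis ran all models with the graded models' gated stimulus
handling.  Second, the printed *equality* of the binary and graded S
statistics cannot hold under any start-at-stimulated-G1 counting once
the graded models protect the Cln3 hand-off (which their verified
global-attractor behaviour requires) and the binary model does not;
their S-phase branching genuinely differs.  The package therefore treats
the attainable ordinal patterns as the binding facts — a revised-model
G2/M segment about twice its S segment, a collapsed revised S phase
(strictly fewer distinct S transitions than its predecessor), and equal
G1 transition structure between the two graded models — and reports the
exact printed values it cannot reproduce as open interpretation
questions rather than forcing a definition to fit.

## Mutation screening

Timing robustness of a mutant network is its preservation of stationary
G1 as the global attractor under full asynchrony.  Mutants differ from a
base model by 1–3 elementary edge edits (delete / add / re-weight) drawn
from the edge slots related to one phase; "related" means an endpoint
changes level during that phase segment of the reference synchronous
trajectory (the study gives no definition; a user-supplied slot set is
accepted).  Re-weighting samples uniformly from alphabet values other
than the current weight, keeping the sign with probability 1/2.
Generation is seeded and reproducible; sampling is with replacement
across mutants.  Exact published robust-fractions depend on the original
(unpublished) sampler and are not reproduction targets; the screening
asserts the stable qualitative facts — the binary model screens at 0.00,
the unmutated revised model at 1.00, and at distance 1 in G2 the revised
model out-scores its graded predecessor.

## NuSMV export

`export_nusmv` emits the model in the NuSMV input language: one ranged
variable per node, a non-deterministic control variable `turn` guarding
each update, one FAIRNESS constraint per node, monitor variables plus a
safety SPEC for each precedence property, and fair AF SPECs for response
and attractor properties.  The export is text only; the bundled checker
is the explicit-state implementation described above, and NuSMV serves
only as an optional external cross-validation.

## Problem sizes and determinism

All analyses on the bundled models are exact and run in seconds: full
basin enumeration over ≤ 4,608 states, asynchronous reachable graphs of a
few hundred states, and DP path statistics.  Mutation screens default to
n = 200 per (phase, distance) cell in the CLI and use n = 50 in the test
suite; the robustness ordering is stable at both sizes.  Every stochastic
component (async scheduler, mutant generation) is driven by an explicit
seed, and every report records the model hash, seed and invocation.

## Known limitations

* The graded fixtures are reconstructions, not the authors'
  machine-readable models (which are not public).  Every checkpoint
  verdict, hazard mechanism, activation ordering and global-attractor
  behaviour is reproduced exactly; the synchronous basin tables are
  reproduced to 3022/3072 states (graded predecessor) and 4510/4608
  (revised model), with two small spurious fixed points per graded
  model.  An extensive constraint search (fixed-point conditions at
  every published attractor, narrative pins, behavioural model checking
  inside the scoring loop) did not find a weight assignment in the
  admissible alphabet matching the printed basins bit-exactly while
  preserving the verified dynamics; the acceptance suite keeps the
  bit-exact assertions and reports the residual rather than loosening
  them.
* The checker is explicit-state by design and suited to this model
  scale; it does not replace a symbolic (BDD) engine for much larger
  networks.
* Exact printed duration means and transition counts are not reproduced
  (boundary/averaging definitions unpublished — see above); the
  attainable ordinal patterns are, and the revised model's mean S
  duration (7.61) falls within two per cent of the printed 7.47.
* The biology is only as good as the threshold abstraction: no kinetic
  rates, no volume growth, and the G1 checkpoint itself is not modelled
  (its regulators are outside the eleven-node roster).
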