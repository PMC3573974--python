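# budcycle

Timing-robust multi-valued Boolean modelling of the budding yeast
(*Saccharomyces cerevisiae*) cell cycle, with explicit-state verification
of checkpoint properties.

## The problem

The yeast cell cycle traverses G1 → S → G2 → M and returns to a resting
G1 state, with checkpoints that must hold before each transition (DNA
synthesis complete before mitosis, chromosomes aligned before anaphase,
division complete before mitotic exit).  Threshold Boolean networks
capture this control layer compactly: eleven regulators (Cln3, MBF, SBF,
Cln2, Cdh1, Swi5, Cdc20, Clb5, Sic1, Clb2, Mcm1) with signed weighted
interactions, updated by threshold rules.  Under *synchronous* updating
such models famously funnel almost the whole state space into the
biological G1 resting state.  But synchrony hides timing hazards: under
*asynchronous* updating — one node at a time, in any order, modelling
arbitrary reaction-rate variation — previously published models allow
runs in which Cdc20 (the mitotic-exit trigger) fires before Clb2 (the
mitosis initiator), i.e. the cell starts dividing before DNA synthesis
is complete.

`budcycle` implements the model family, both update modes, exact
attractor/basin analysis, an explicit-state checker for checkpoint
(precedence / fair-response / global-attractor) properties with
replayable counterexamples, phase-duration statistics, random
edge-mutation robustness screening, and NuSMV export.  Three models ship
as validated fixtures:

| fixture    | levels                  | weights          | timing behaviour |
|------------|-------------------------|------------------|------------------|
| `li`       | all binary              | ±1               | M-checkpoint hazard; G1 not a global attractor |
| `mangla`   | Clb2 ternary            | ±1/3, ±1, ±3     | G1 global attractor, but two checkpoint hazard groups |
| `proposed` | Clb2 and Swi5 ternary   | ±1/3, ±1, ±3     | hazard-free (timing-robust) |

The `proposed` network differs from `mangla` in exactly four edge
weights; the revision closes the Clb2–Mcm1 positive feedback (Clb2 rises
to its top level only after Mcm1, and Mcm1 needs Clb2) and makes Swi5's
full activation depend on Cdc20 rather than on Clb2's decay.

## The update rule

A node at level `s` with weighted input sum `sigma` rises one level when
`sigma >= theta_{s+1}` (thresholds 1/2 and 3/2).  Graded (ternary) nodes
fall one level when `sigma < theta_s`.  Binary nodes keep the classic
tie semantics, generalised to fractional sums: they switch off when
`sigma <= -1/2`, and inside the neutral band `(-1/2, 1/2)` they hold
their level unless flagged self-degrading.  See `docs/methods.md` for
the full account, including why the neutral band is what makes the
low-weight (1/3) revision able to remove the first hazard.

## Worked example

```python
>>> import budcycle as bc
>>> m = bc.bundled_fixture("proposed")
>>> atts = bc.synchronous_attractors(m)
>>> atts[0].basin_size, atts[0].state.levels
(4275, (0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0))
```

Of the 4,608 states of the revised model, 4,275 (93%) flow into the
stationary G1 fixed point (Cdh1 and Sic1 on, everything else off) — the
largest basin of the three models, i.e. the most stable resting state
(the published analysis reports 4,323, about one per cent more; see
`docs/methods.md` on the fixture reconstruction).

```python
>>> verdicts = bc.check_all(bc.bundled_fixture("mangla"))
>>> [(v.property_name, v.status) for v in verdicts if not v.passed]
[('clb2_before_cdc20', 'fail'), ('cdc20_activates_swi5', 'fail')]
>>> v = [x for x in verdicts if not x.passed][0]
>>> print(v.counterexample.update_sequence)
['MBF', 'SBF', 'Cln2', 'Cdh1', 'Sic1', 'Clb5', 'Mcm1', 'Cdc20']
```

The checker reproduces the two documented hazard groups of the graded
predecessor model and hands back the offending schedule: after Clb5
activates, updating Mcm1 before Clb2 lets Cdc20 fire with Clb2 still
off — mitotic exit machinery armed before mitosis is properly entered.
On the revised model every default property passes
(`budcycle check --model proposed` exits 0).

The same analyses are available from the shell:

```
budcycle attractors --model proposed
budcycle check --model mangla --trace-dir traces/
budcycle phases --model proposed --table durations
budcycle screen --model proposed --phase G2 --distance 1 --n 200 --seed 1
budcycle export-smv --model proposed --out proposed.smv
```

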