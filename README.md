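# tacdec

Evolutionary dynamics of tactical deception under conditional cooperation,
with the phylogenetic comparative machinery to test the prediction across
species.

Conditional cooperation — reciprocity, partner choice, and their relatives —
rewards individuals who are seen to cooperate. That creates an opening for
cheats who *misrepresent* their behaviour: tactical deceivers who always
defect but pay a cost to conceal it, escaping detection where an honest
defector would be discriminated against. `tacdec` is for evolutionary
biologists who want to explore when such deception invades, when it coexists
with cooperation, and whether the predicted cross-species association between
cooperativeness and deception holds in comparative data.

## The model

An infinite well-mixed population plays an iterated prisoner's dilemma
(benefit *b*, cost *c*) with three strategies: conditional cooperators (CC),
who cooperate with identified defectors only in a slip fraction *s* of
interactions; tactical deceivers (TD), who always defect, pay *d* to conceal
it, and escape detection with probability *q*; and honest defectors (HD).
Per-round payoffs are

```
π_CC = (b − c) x_CC − c (q + s − qs) x_TD − c s x_HD
π_TD = b (q + s − qs) x_CC − d
π_HD = b s x_CC
```

evolving by the replicator equation `dx_i/dt = x_i (π_i − Σ_j π_j x_j)` under
the constraints `b − c > sb > 0`, `0 < s < 1`, `c > d > 0`. With constant *q*
there are two outcomes: if `b(q + s − qs) − d > b − c` deceivers dominate
cooperators and cooperation collapses to honest defection; otherwise CC and
HD are both Nash equilibria and deceivers never gain a foothold. With
negatively frequency-dependent detection, `q = 1 − x_TD`, payoff equality on
the CC–TD edge reduces to the quadratic
`(b − c)(1 − s) t² − b(1 − s) t + (c − d) = 0` in `t = x_TD`, whose
edge-attracting interior root is a stable mixture of cooperators and
deceivers; it resists invasion by honest defectors iff `b(1 − s)(x_CC*)² > d`.

The comparative stage fits phylogenetic generalized least squares (PGLS) with
Pagel's λ fixed at 1 — equivalently, a through-origin regression on
Felsenstein's independent contrasts (both routes are implemented and agree to
machine precision) — for two model structures:

```
log(deception + 1) ~ cooperativeness + neocortex ratio  + log(research effort)
log(deception + 1) ~ cooperativeness + log(neocortex volume) + log(research effort)
```

A synthetic-data module generates Yule phylogenies with Brownian-motion
traits, a thresholded 0–3 cooperativeness score, and deception counts whose
log is linear in the predictors, so the whole pipeline runs and calibrates
itself without any external data. Users with their own species table (CSV)
and phylogeny (Newick) can run the same fits directly.

## Worked example

```python
import tacdec as td

params = td.GameParams(b=1.5, c=0.5, s=0.2, d=0.1, q_mode="freq_dependent")
rep = td.find_mixed_equilibrium(params)
```

prints, via `examples/02_mixed_equilibrium.py`:

```
x_CC* = 0.500000  (deceivers: 0.500000)
stable: True, eigenvalue real parts: [-0.1, -0.2]
honest-defector pressure b(1-s)x_CC*^2 = 0.300 vs deception cost d = 0.1
HD can invade the mixture: False
```

Half the population deceives at equilibrium, the two negative eigenvalues
confirm local stability, and because 0.3 > d the mixture repels honest
defectors. On the comparative side, `examples/04_contrasts_and_pgls.py`
simulates 24 species with a true cooperativeness slope of 0.9 and recovers

```
cooperativeness      0.9685  0.1815   5.3364  0.0000
```

(coefficient, standard error, t, p), identical to ten decimal places via the
independent-contrasts route and via partialled contrasts. Each script in
`examples/` demonstrates one capability; the `tacdec` command-line tool
exposes the same operations (`tacdec dynamics`, `regime`, `equilibrium`,
`sweep`, `contrasts`, `pgls`, `partial`, `simulate-data`) for shell use.

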