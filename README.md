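# gamcs — genetic-algorithm search for constrained minimal cut sets

`gamcs` designs minimal microbial strains: given a stoichiometric metabolic
network, it enumerates the network's elementary flux modes (EFMs), then uses
a genetic algorithm over keep/kill partitions of the EFM set to find the
smallest reaction-knockout sets that force the cell into a desired
engineering objective — high product yield, growth-coupled productivity, or
a composite non-linear objective. It is aimed at metabolic engineers and
systems biologists working with desk-scale models who want *all* minimal
knockout strategies for an objective, not a single FBA-style optimum.

## The model

A network with m internal metabolites and r reactions at steady state
satisfies **N·v = 0** with v_j ≥ 0 for every irreversible reaction j. An
*elementary flux mode* **e** is a nonzero admissible flux vector whose
support supp(**e**) = {j : e_j ≠ 0} is minimal: removing any of its
reactions blocks it. The full set **E** = {E_1, …, E_n} of EFM supports
spans every steady-state behaviour.

A *cut set* C kills a set of target modes **T** when C ∩ T ≠ ∅ for every
T ∈ **T**; it is a *minimal cut set* (MCS) when no proper subset does. A
*constrained* MCS additionally keeps at least k modes of a desired set
**D** untouched: |**D**^C| ≥ k, where **D**^C = {D ∈ **D** : C ∩ D = ∅}
are the survivors.

Which modes to keep and which to kill is the hard question: there are 2^n
partitions. `gamcs` encodes each partition as a binary individual
S = (s^1, …, s^n) coding the intervention problem
I[**T**(S), **D**(S), k(S)] with k(S) = ⌈w_k·|**D**(S)|⌉, solves it exactly
(Berge transversals over the target hypergraph), groups the resulting cut
sets by their survivor *pattern* P, and scores each pattern with one of

| objective | fitness |
|---|---|
| F1 | w₁·min Y + w₃·(1 − \|C\|/n) |
| F2 | w₂·min η + w₃·(1 − \|C\|/n) |
| F3 | w₁·min Y × w₂·max η + w₃·(1 − \|C\|/n) + w₄·\|**D**^C\|/\|**E**\| |

where Y is the (optionally C-mol normalised) product yield of a surviving
mode, η = Y·Y_biomass its growth-coupling "efficiency", and |C| the number
of knockouts among the n reactions. The GA evolves individuals with
fitness-proportionate selection, elitism, 1-point/2-point/uniform
crossover, a mutation flipping round(ρ·r_m) bits (ρ = number of modes with
desirable characteristics), and pattern-based regeneration that resamples
bits in proportion to how often each mode survived in previously found
patterns. All evaluations are cached, and the output lists every pattern
attaining the best fitness together with all of its minimal-cardinality
cut sets.

## Worked example

```python
from gamcs import (FitnessSpec, GAConfig, enumerate_efms,
                   make_cell_factory, run_ga)

net, truth = make_cell_factory()          # 13-reaction toy cell factory
efms = enumerate_efms(net)                # 8 EFMs, known analytically
spec = FitnessSpec(objective="F1", network=net, w1=1, w3=1,
                   total_modes=efms.n)
config = GAConfig(t=50, p=30, r_m=0.4, elit=0.1, new_S=0.1, t_stop=15,
                  min_1s=0.9, w_k=0.03, seed=0)
result = run_ga(efms, spec, config)
print(result.best_fitness)                # 1.2051282051282053
for pat in result.best_patterns:
    print(sorted(pat.survivors), [sorted(c.reactions) for c in pat.cutsets])
```

prints

```
1.2051282051282053
[0, 1] [[3, 4, 5, 6, 7, 9], [3, 4, 5, 6, 7, 10], [3, 4, 5, 6, 8, 9], [3, 4, 5, 6, 8, 10]]
```

The best design keeps exactly the two maximum-yield producer modes
(Y = 2·2/6 = 0.6667 C-mol/C-mol): fitness 1.2051 = 0.6667 + (1 − 6/13),
achieved by four alternative 6-reaction knockout sets. An exhaustive scan
over all 2^8 partitions (`gamcs.oracle.exhaustive_best_fitness`) confirms
this is the global optimum. The scripts in `examples/` walk through
enumeration, cut-set solving, the GA and the command-line pipeline; the
`gamcs` console command exposes the same steps as `make-toy`, `enumerate`,
`solve` and `run-ga` subcommands.

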