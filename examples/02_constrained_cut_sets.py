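"""Solve one intervention problem: kill unwanted modes, keep the best ones.

Keeps the two maximum-yield producer modes of the toy factory, targets the
other six, and requires at least one kept mode to survive (k=1).  The
solver returns every minimal knockout set achieving this; role reactions
(uptake, product exporter, biomass drain) are never knockout candidates.
"""

from gamcs import (
    InterventionProblem,
    default_forbidden,
    enumerate_efms,
    make_cell_factory,
    solve_intervention,
)

net, _ = make_cell_factory()
efms = enumerate_efms(net)
supports = efms.supports()

keep = [0, 1]                      # the two 0.6667-yield modes
kill = [i for i in range(efms.n) if i not in keep]
problem = InterventionProblem(
    targets=[supports[i] for i in kill],
    desired=[supports[i] for i in keep],
    keep_min=1,
)
solutions = solve_intervention(problem, max_cardinality=8,
                               forbidden=default_forbidden(net))

print(f"{len(solutions)} constrained minimal cut sets "
      f"(killing modes {kill}, keeping >=1 of {keep}):")
for cut, surv in solutions:
    ids = " ".join(net.reaction_ids[j] for j in cut.sorted())
    print(f"  |C|={cut.cardinality}  survivors={len(surv)}  knock out: {ids}")

# Every line is one minimal strain design: deleting those reactions blocks
# all six unwanted modes while at least one max-yield route keeps running.
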