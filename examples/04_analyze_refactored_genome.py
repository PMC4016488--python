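"""Score a refactored genome: complexity, adaptation, functional similarity.

Refactors a small genome, then computes the evaluation metrics: the
complexity ratios Xi (regulatory interactions) and Theta (operons)
relative to the wild type, the optimality degree xi under perturbed
environments, the per-operon functional-similarity score Phi_op, and the
TF co-regulation clustering coefficient.
"""

import numpy as np

from gtrn_refactor import (
    AnnealingSchedule,
    FitnessSpec,
    adaptation_report,
    anneal,
    complexity_ratios,
    functional_similarity,
    generate_environments,
    generate_gtrn,
    profile_function,
    SynthesisSpec,
    topology_stats,
)

wildtype = generate_gtrn(SynthesisSpec(n_genes=50, redundancy=5, seed=11))
envs = generate_environments("oxygen", 4, seed=11)
spec = FitnessSpec(environments=envs)
best = anneal(wildtype, spec,
              AnnealingSchedule(iterations=10_000, population=1, seed=2),
              log_every=0)[0].best

comp = complexity_ratios(best, wildtype)
print(f"Xi (interaction ratio)  = {comp.xi:.3f}")
print(f"Theta (operon ratio)    = {comp.theta:.3f}")
print("Values below 1 mean the refactored genome needs fewer regulatory "
      "interactions / operons than the wild type.")

report = adaptation_report(best, profile_function(wildtype), spec,
                           [e for e in envs if e.id != "optimal"])
print(f"\nmean optimality degree <xi> = {report.mean_xi:.3g}")
print("xi = S_exp(optimal) - S_exp(perturbed); positive values mean the "
      "genome adapts sub-optimally away from the optimal environment, "
      "negative values over-optimally.")

funcs = {gid: g.functions for gid, g in best.genes.items()}
phi = [functional_similarity(op, funcs) for op in best.operons.values()
       if len(op.genes) >= 2]
print(f"\nmean Phi_op over multi-gene operons = {np.mean(phi):.3f}")
print("Phi_op is the largest fraction of an operon's genes sharing one "
      "GO-style function label.")

topo = topology_stats(best)
print(f"\nTF co-regulation clustering coefficient = "
      f"{topo.clustering_coefficient:.3f}")
print(f"tandem promoters per operon: {dict(sorted(topo.tandem_histogram.items()))}")
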