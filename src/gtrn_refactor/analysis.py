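"""Evaluation metrics for refactored genomes.

* Complexity ratios: Xi = regulatory interactions (refactored / wild type),
  Theta = operon count ratio.  An interaction is an (operon, TF) pair with
  a nonzero effective beta coefficient; environmental (gamma) edges are
  counted separately as a diagnostic and excluded from the headline Xi.
* Optimality degree xi: S_exp evaluated at the optimal environment
  (dv = 0) minus S_exp at a target environment; positive = sub-optimal
  adaptation, negative = over-optimal.
* Functional similarity Phi_op: largest fraction of an operon's genes
  sharing one function label; defined as 0 for singleton operons (a single
  gene cannot exhibit shared function).
* Topology: per-promoter load (operons and genes driven), tandem-usage
  histogram, and the average clustering coefficient of the TF
  co-regulation projection (two TFs linked iff some operon's effective
  regulation contains both).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping

import networkx as nx
import pandas as pd

from ._errors import ValidationError
from .fitness import FitnessSpec, expression_score
from .model import Environment, Gtrn, Operon, effective_regulation

__all__ = [
    "ComplexityReport",
    "AdaptationReport",
    "TopologyStats",
    "complexity_ratios",
    "optimality_degree",
    "adaptation_report",
    "functional_similarity",
    "topology_stats",
    "profile_function",
]


@dataclass(frozen=True)
class ComplexityReport:
    xi: float  # regulatory-interaction ratio (beta edges), refactored / wild type
    theta: float  # operon-count ratio
    xi_env: float  # gamma-edge ratio, diagnostic only
    interactions_refactored: int
    interactions_wildtype: int


@dataclass(frozen=True)
class AdaptationReport:
    xi_per_env: dict  # environment id -> optimality degree
    mean_xi: float


@dataclass(frozen=True)
class TopologyStats:
    promoter_load: dict  # promoter id -> (n_operons, n_genes) it drives
    tandem_histogram: dict  # tandem count -> number of operons
    clustering_coefficient: float


def _interaction_counts(gtrn: Gtrn) -> tuple:
    n_beta = n_gamma = 0
    for op in gtrn.operons.values():
        reg = effective_regulation(gtrn, op)
        n_beta += sum(1 for c in reg.beta.values() if c != 0)
        n_gamma += sum(1 for c in reg.gamma.values() if c != 0)
    return n_beta, n_gamma


def complexity_ratios(refactored: Gtrn, wildtype: Gtrn) -> ComplexityReport:
    """Xi and Theta of a refactored genome relative to the wild type."""
    ref_b, ref_g = _interaction_counts(refactored)
    wt_b, wt_g = _interaction_counts(wildtype)
    if wt_b == 0:
        raise ValidationError(
            "wild-type genome has no regulatory interactions; Xi is undefined"
        )
    return ComplexityReport(
        xi=ref_b / wt_b,
        theta=len(refactored.operons) / len(wildtype.operons),
        xi_env=(ref_g / wt_g) if wt_g else float("nan"),
        interactions_refactored=ref_b,
        interactions_wildtype=wt_b,
    )


def profile_function(wildtype: Gtrn) -> Callable[[Environment], pd.Series]:
    """Wild-type steady-state profile as a function of the environment."""
    from .model import steady_state

    return lambda env: steady_state(wildtype, env)


def _optimal_of(env: Environment) -> Environment:
    return Environment(id=f"{env.id}__optimal", v=dict(env.v_opt),
                       v_opt=dict(env.v_opt))


def _s_exp_at(gtrn, wildtype_profile_fn, spec, env) -> float:
    wt_col = wildtype_profile_fn(env)
    wt = pd.DataFrame({env.id: wt_col})
    one_env = replace(spec, environments=[env])
    return expression_score(gtrn, wt, one_env)


def optimality_degree(
    gtrn: Gtrn,
    wildtype_profile_fn: Callable[[Environment], pd.Series],
    spec: FitnessSpec,
    target_env: Environment,
) -> float:
    """xi = S_exp(optimal, dv=0) - S_exp(target environment).

    Antisymmetric under swapping the two evaluation environments; exactly 0
    when the target is the optimal environment.
    """
    s_opt = _s_exp_at(gtrn, wildtype_profile_fn, spec, _optimal_of(target_env))
    s_tgt = _s_exp_at(gtrn, wildtype_profile_fn, spec, target_env)
    return s_opt - s_tgt


def adaptation_report(
    gtrn: Gtrn,
    wildtype_profile_fn: Callable[[Environment], pd.Series],
    spec: FitnessSpec,
    environments: Iterable[Environment],
) -> AdaptationReport:
    xi = {
        env.id: optimality_degree(gtrn, wildtype_profile_fn, spec, env)
        for env in environments
    }
    if not xi:
        raise ValidationError("no environments to evaluate")
    return AdaptationReport(xi_per_env=xi, mean_xi=sum(xi.values()) / len(xi))


def functional_similarity(operon: Operon, functions: Mapping) -> float:
    """Phi_op: max fraction of the operon's genes sharing one function.

    ``functions`` maps gene id -> set of function labels (possibly empty).
    Singleton operons score 0 by convention.
    """
    if len(operon.genes) < 2:
        return 0.0
    counts: Counter = Counter()
    for gid in operon.genes:
        try:
            labels = functions[gid]
        except KeyError:
            raise ValidationError(
                f"gene {gid!r} of operon {operon.id!r} has no function annotation"
            ) from None
        counts.update(set(labels))
    if not counts:
        return 0.0
    return max(counts.values()) / len(operon.genes)


def topology_stats(gtrn: Gtrn) -> TopologyStats:
    n_ops: Counter = Counter()
    n_genes: Counter = Counter()
    tandem_hist: Counter = Counter()
    graph = nx.Graph()
    for op in gtrn.operons.values():
        for pid in [op.primary_promoter, *op.tandem_promoters]:
            n_ops[pid] += 1
            n_genes[pid] += len(op.genes)
        tandem_hist[len(op.tandem_promoters)] += 1
        tfs = sorted(
            tf for tf, c in effective_regulation(gtrn, op).beta.items() if c != 0
        )
        graph.add_nodes_from(tfs)
        for i, a in enumerate(tfs):
            for b in tfs[i + 1:]:
                graph.add_edge(a, b)
    clustering = nx.average_clustering(graph) if graph.number_of_nodes() else 0.0
    return TopologyStats(
        promoter_load={p: (n_ops[p], n_genes[p]) for p in n_ops},
        tandem_histogram=dict(tandem_hist),
        clustering_coefficient=float(clustering),
    )
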