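"""Objective function for genome refactoring.

The total score ``S = w_exp * S_exp + w_mod * S_mod`` (higher is better)
combines:

* ``S_exp`` — expression similarity to the wild type over a set of
  environments, restricted to a critical gene subset:

      S_exp = -(1 / (|G| |E|)) * sum_{g,e} (y_cand - y_wt)^2 / (y_wt^2 + eps)

  ``S_exp <= 0`` always, with equality iff the profiles match exactly on
  the subset.

* ``S_mod`` — genome modularity, measured as the negative normalized
  entropy of the operon-size distribution:

      S_mod = -H / ln(N),   H = -sum_op p_op ln p_op,   p_op = |op| / N

  with N the total gene count.  S_mod is 0 when all genes share one operon
  (maximal modularity), -1 when every gene sits in its own operon, and
  strictly increases whenever two operons are merged (entropy decreases
  under coarsening).  The entropy form is this package's choice of
  modularity measure; see docs/methods.md for the rationale, including the
  choice of the fixed ln(N) normalization.

The default weights (1.0, 1e-6) make modularity a tie-breaker among
expression-equivalent genomes: preserving the wild-type phenotype is the
constraint, consolidation the preference.  See docs/methods.md for the
calibration argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._errors import ValidationError
from .model import ExpressionProfile, Gtrn, expression_profile

__all__ = [
    "FitnessSpec",
    "FitnessValue",
    "resolve_gene_subset",
    "expression_score",
    "modularity_score",
    "total_fitness",
]

#: named gene subsets -> category tag carried by Gene.categories
SUBSET_TAGS = {"stress": "stress", "defense": "defense", "enzymes": "enzyme"}


@dataclass
class FitnessSpec:
    """What to score: gene subset, environments, weights.

    ``gene_subset`` is one of ``{"all", "stress", "defense", "enzymes"}``
    or an explicit collection of gene ids.
    """

    environments: list
    gene_subset: object = "all"
    weight_expression: float = 1.0
    weight_modularity: float = 1e-6
    epsilon_norm: float = 1e-6

    def __post_init__(self) -> None:
        if self.weight_expression < 0 or self.weight_modularity < 0:
            raise ValidationError("fitness weights must be non-negative")
        if self.weight_expression == 0 and self.weight_modularity == 0:
            raise ValidationError("fitness weights must not both be zero")
        if self.epsilon_norm < 0:
            raise ValidationError("epsilon_norm must be >= 0")


@dataclass(frozen=True)
class FitnessValue:
    s_exp: float
    s_mod: float
    s_total: float


def resolve_gene_subset(gtrn: Gtrn, subset) -> tuple:
    """Resolve a subset spec to a sorted tuple of existing gene ids."""
    if isinstance(subset, str):
        if subset == "all":
            return tuple(sorted(gtrn.genes))
        try:
            tag = SUBSET_TAGS[subset]
        except KeyError:
            raise ValidationError(
                f"unknown gene subset {subset!r}; expected 'all', "
                f"{sorted(SUBSET_TAGS)} or an explicit id collection"
            ) from None
        ids = tuple(sorted(g for g, gene in gtrn.genes.items()
                           if tag in gene.categories))
        if not ids:
            raise ValidationError(f"no gene carries the {tag!r} category tag")
        return ids
    ids = tuple(sorted(subset))
    missing = [g for g in ids if g not in gtrn.genes]
    if missing:
        raise ValidationError(f"subset genes not in genome: {missing}")
    if not ids:
        raise ValidationError("explicit gene subset is empty")
    return ids


def _subset_profiles(
    candidate: Gtrn, wildtype_profile: ExpressionProfile, spec: FitnessSpec
) -> tuple:
    genes = resolve_gene_subset(candidate, spec.gene_subset)
    env_ids = [e.id for e in spec.environments]
    missing_g = [g for g in genes if g not in wildtype_profile.index]
    missing_e = [e for e in env_ids if e not in wildtype_profile.columns]
    if missing_g or missing_e:
        raise ValidationError(
            "wild-type profile is missing "
            f"genes {missing_g} and environments {missing_e}"
        )
    cand = expression_profile(candidate, spec.environments)
    return (cand.loc[list(genes), env_ids].to_numpy(),
            wildtype_profile.loc[list(genes), env_ids].to_numpy())


def expression_score(
    candidate: Gtrn, wildtype_profile: ExpressionProfile, spec: FitnessSpec
) -> float:
    """Normalized negative squared deviation from the wild-type profile."""
    yc, yw = _subset_profiles(candidate, wildtype_profile, spec)
    return float(-np.mean((yc - yw) ** 2 / (yw ** 2 + spec.epsilon_norm)))


def operon_size_entropy_score(sizes: Iterable[int], n_genes: int) -> float:
    """S_mod from a multiset of operon sizes (invariant to labeling)."""
    sizes = np.asarray(list(sizes), dtype=float)
    if n_genes <= 0 or sizes.sum() != n_genes:
        raise ValidationError("operon sizes must sum to the gene count")
    if len(sizes) == 1:
        return 0.0
    p = sizes / n_genes
    h = float(-np.sum(p * np.log(p)))
    return -h / np.log(n_genes)


def modularity_score(gtrn: Gtrn) -> float:
    """Negative normalized operon-size entropy; in [-1, 0], higher = fewer operons."""
    n = len(gtrn.genes)
    if n == 0 or not gtrn.operons:
        raise ValidationError("cannot score an empty genome")
    return operon_size_entropy_score(
        (len(op.genes) for op in gtrn.operons.values()), n
    )


def total_fitness(
    candidate: Gtrn, wildtype_profile: ExpressionProfile, spec: FitnessSpec
) -> FitnessValue:
    s_exp = expression_score(candidate, wildtype_profile, spec)
    s_mod = modularity_score(candidate)
    return FitnessValue(
        s_exp=s_exp,
        s_mod=s_mod,
        s_total=spec.weight_expression * s_exp + spec.weight_modularity * s_mod,
    )
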