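"""Mutation moves and Monte Carlo Simulated Annealing over GTRN space.

Four mutation operators rearrange transcriptional regulation without ever
touching gene content or sequences:

* ``move_gene``     — move a gene to another operon (both operons must be
                      driven by non-constitutive primary promoters); the
                      gene is appended as the last cistron and adopts the
                      destination's effective regulation.
* ``add_tandem``    — fuse a candidate promoter in tandem upstream of an
                      operon (at most 3 tandems per operon); its
                      (alpha, beta, gamma) terms add to the operon's ODEs.
* ``remove_tandem`` — delete a tandem promoter's additive term.  The
                      primary promoter is never removable.
* ``replace_tandem``— substitute one tandem promoter's term for another
                      candidate's.

Every applied move returns a :class:`MoveRecord` whose ``inverse`` is
sufficient to undo it exactly; annealing uses apply/undo instead of
copying genomes.

The annealer runs ``population`` independent Metropolis chains under an
exponentially decaying temperature ``T(n) = t0 * cooling**n``.  A proposal
with score ``S_new >= S`` is always accepted; otherwise it is accepted
with probability ``exp((S_new - S)/T)``.  By default each chain starts
from the singleton-operon genome (every gene alone under its natural
promoter, tandems carried over), so the start expresses exactly like the
wild type; ``start="wildtype"`` keeps the wild-type operon structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg as sla

from ._errors import MoveError, NoLegalMoveError, ValidationError
from .fitness import FitnessSpec, FitnessValue, modularity_score, resolve_gene_subset
from .model import (
    Gtrn,
    Operon,
    build_linear_system,
    expression_profile,
)

__all__ = [
    "MoveRecord",
    "AnnealingSchedule",
    "ChainResult",
    "move_gene",
    "add_tandem",
    "remove_tandem",
    "replace_tandem",
    "undo",
    "propose",
    "accept",
    "singletonize",
    "anneal",
]

logger = logging.getLogger(__name__)

MOVE_KINDS = ("move_gene", "add_tandem", "remove_tandem", "replace_tandem")


@dataclass(frozen=True)
class MoveRecord:
    """One applied mutation: its kind, actors, and how to undo it."""

    kind: str
    actors: dict
    inverse: dict


@dataclass
class AnnealingSchedule:
    """Cooling schedule, move mixture, and chain bookkeeping.

    Defaults: t0 = 1e-5 (fitness units), cooling 0.999 per iteration, 2e4
    iterations, 10 chains.  The move mixture honors a 10:1 ratio between
    (add + remove) and replace proposals.

    t0 is calibrated to the scale of a single move's change in the
    normalized expression score (~ relative-error^2 / N), not to the O(1)
    range of the total score: emptied operons are deleted together with
    access to their promoters, so a temperature large relative to per-move
    score changes ratchets the genome irreversibly into a few arbitrarily
    regulated operons.  See docs/methods.md.
    """

    t0: float = 1e-5
    cooling: float = 0.999
    iterations: int = 20_000
    population: int = 10
    p_move_gene: float = 0.6
    p_add: float = 2.0 / 11.0
    p_remove: float = 2.0 / 11.0
    p_replace: float = 0.4 / 11.0
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValidationError("t0 must be > 0")
        if not 0 < self.cooling < 1:
            raise ValidationError("cooling must be in (0, 1)")
        if self.iterations < 0 or self.population < 1:
            raise ValidationError("iterations >= 0 and population >= 1 required")
        probs = self.move_probabilities()
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValidationError(
                f"move probabilities must be non-negative and sum to 1, got {probs}"
            )

    def move_probabilities(self) -> tuple:
        return (self.p_move_gene, self.p_add, self.p_remove, self.p_replace)

    def temperature(self, iteration: int) -> float:
        return self.t0 * self.cooling ** iteration


def _operon_or_error(gtrn: Gtrn, operon_id: str) -> Operon:
    try:
        return gtrn.operons[operon_id]
    except KeyError:
        raise MoveError(f"unknown operon {operon_id!r}") from None


def _require_regulated(gtrn: Gtrn, op: Operon, why: str) -> None:
    if gtrn.promoters[op.primary_promoter].is_constitutive:
        raise MoveError(
            f"operon {op.id!r} is driven by a constitutive promoter; {why}"
        )


def move_gene(gtrn: Gtrn, gene_id: str, dest_operon_id: str):
    """Move a gene to the end of another operon's cistron list (in place).

    Both the source and the destination primary promoters must be
    non-constitutive.  If the source operon is emptied it is deleted.
    """
    if gene_id not in gtrn.genes:
        raise MoveError(f"unknown gene {gene_id!r}")
    dest = _operon_or_error(gtrn, dest_operon_id)
    src = gtrn.operon_of(gene_id)
    if src.id == dest.id:
        raise MoveError(f"gene {gene_id!r} is already in operon {dest.id!r}")
    _require_regulated(gtrn, src, "its genes are excluded from the design")
    _require_regulated(gtrn, dest, "genes may not move onto it")
    index = src.genes.index(gene_id)
    src.genes.pop(index)
    deleted = None
    if not src.genes:
        deleted = gtrn.operons.pop(src.id)
    dest.genes.append(gene_id)
    return gtrn, MoveRecord(
        kind="move_gene",
        actors={"gene": gene_id, "source": src.id, "dest": dest.id},
        inverse={"index": index, "deleted_operon": deleted},
    )


def add_tandem(gtrn: Gtrn, operon_id: str, promoter_id: str):
    """Fuse a candidate promoter in tandem upstream of an operon (in place)."""
    op = _operon_or_error(gtrn, operon_id)
    if promoter_id not in gtrn.tandem_candidates:
        raise MoveError(
            f"promoter {promoter_id!r} is not a tandem candidate"
        )
    if len(op.tandem_promoters) >= Operon.MAX_TANDEM:
        raise MoveError(
            f"operon {operon_id!r} already has {Operon.MAX_TANDEM} tandem promoters"
        )
    if promoter_id == op.primary_promoter or promoter_id in op.tandem_promoters:
        raise MoveError(
            f"promoter {promoter_id!r} already drives operon {operon_id!r}"
        )
    op.tandem_promoters.append(promoter_id)
    return gtrn, MoveRecord(
        kind="add_tandem",
        actors={"operon": operon_id, "promoter": promoter_id},
        inverse={},
    )


def remove_tandem(gtrn: Gtrn, operon_id: str, promoter_id: str):
    """Delete a tandem promoter's additive term (in place)."""
    op = _operon_or_error(gtrn, operon_id)
    if promoter_id == op.primary_promoter:
        raise MoveError(
            f"promoter {promoter_id!r} is the primary promoter of "
            f"{operon_id!r} and cannot be removed"
        )
    if promoter_id not in op.tandem_promoters:
        raise MoveError(
            f"promoter {promoter_id!r} is not in tandem on operon {operon_id!r}"
        )
    index = op.tandem_promoters.index(promoter_id)
    op.tandem_promoters.pop(index)
    return gtrn, MoveRecord(
        kind="remove_tandem",
        actors={"operon": operon_id, "promoter": promoter_id},
        inverse={"index": index},
    )


def replace_tandem(gtrn: Gtrn, operon_id: str, old_id: str, new_id: str):
    """Substitute one tandem promoter's term for another candidate's (in place)."""
    op = _operon_or_error(gtrn, operon_id)
    if old_id not in op.tandem_promoters:
        raise MoveError(
            f"promoter {old_id!r} is not in tandem on operon {operon_id!r}"
        )
    if new_id not in gtrn.tandem_candidates:
        raise MoveError(f"promoter {new_id!r} is not a tandem candidate")
    if new_id != old_id and (
        new_id == op.primary_promoter or new_id in op.tandem_promoters
    ):
        raise MoveError(
            f"promoter {new_id!r} already drives operon {operon_id!r}"
        )
    index = op.tandem_promoters.index(old_id)
    op.tandem_promoters[index] = new_id
    return gtrn, MoveRecord(
        kind="replace_tandem",
        actors={"operon": operon_id, "old": old_id, "new": new_id},
        inverse={"index": index},
    )


def undo(gtrn: Gtrn, record: MoveRecord) -> Gtrn:
    """Revert an applied move; restores a genome equal to the original."""
    a, inv = record.actors, record.inverse
    if record.kind == "move_gene":
        dest = gtrn.operons[a["dest"]]
        if dest.genes[-1] != a["gene"]:
            raise MoveError("undo out of order: gene is not the last cistron")
        dest.genes.pop()
        deleted = inv["deleted_operon"]
        if deleted is not None:
            gtrn.operons[deleted.id] = deleted
            src = deleted
        else:
            src = gtrn.operons[a["source"]]
        src.genes.insert(inv["index"], a["gene"])
    elif record.kind == "add_tandem":
        op = gtrn.operons[a["operon"]]
        if not op.tandem_promoters or op.tandem_promoters[-1] != a["promoter"]:
            raise MoveError("undo out of order: promoter is not the last tandem")
        op.tandem_promoters.pop()
    elif record.kind == "remove_tandem":
        gtrn.operons[a["operon"]].tandem_promoters.insert(
            inv["index"], a["promoter"]
        )
    elif record.kind == "replace_tandem":
        gtrn.operons[a["operon"]].tandem_promoters[inv["index"]] = a["old"]
    else:
        raise MoveError(f"unknown move kind {record.kind!r}")
    return gtrn


def _regulated_operons(gtrn: Gtrn) -> list:
    return [
        oid
        for oid, op in gtrn.operons.items()
        if not gtrn.promoters[op.primary_promoter].is_constitutive
    ]


def _pick(rng: np.random.Generator, seq: list):
    return seq[int(rng.integers(len(seq)))]


def propose(gtrn: Gtrn, schedule: AnnealingSchedule, rng: np.random.Generator):
    """Draw and apply one random legal move; returns ``(gtrn, record)``.

    The move kind is drawn from the schedule's mixture; actors are chosen
    uniformly among valid ones.  If the drawn kind has no valid actor the
    kind is resampled, up to ``schedule.max_retries`` times, after which a
    :class:`NoLegalMoveError` is raised.
    """
    probs = np.cumsum(schedule.move_probabilities())
    candidates = sorted(gtrn.tandem_candidates)
    for _ in range(schedule.max_retries):
        kind = MOVE_KINDS[int(np.searchsorted(probs, rng.random(), side="right"))]
        if kind == "move_gene":
            ops = _regulated_operons(gtrn)
            if len(ops) < 2:
                continue
            src_id = _pick(rng, ops)
            gene = _pick(rng, gtrn.operons[src_id].genes)
            dest = _pick(rng, [o for o in ops if o != src_id])
            return move_gene(gtrn, gene, dest)
        if kind == "add_tandem":
            if not candidates:
                continue
            ops = [
                oid for oid, op in gtrn.operons.items()
                if len(op.tandem_promoters) < Operon.MAX_TANDEM
            ]
            if not ops:
                continue
            oid = _pick(rng, ops)
            op = gtrn.operons[oid]
            free = [
                p for p in candidates
                if p != op.primary_promoter and p not in op.tandem_promoters
            ]
            if not free:
                continue
            return add_tandem(gtrn, oid, _pick(rng, free))
        ops = [oid for oid, op in gtrn.operons.items() if op.tandem_promoters]
        if not ops:
            continue
        oid = _pick(rng, ops)
        op = gtrn.operons[oid]
        old = _pick(rng, op.tandem_promoters)
        if kind == "remove_tandem":
            return remove_tandem(gtrn, oid, old)
        free = [
            p for p in candidates
            if p == old or (p != op.primary_promoter
                            and p not in op.tandem_promoters)
        ]
        if not free:
            continue
        return replace_tandem(gtrn, oid, old, _pick(rng, free))
    raise NoLegalMoveError(
        f"no legal move found after {schedule.max_retries} resampling attempts"
    )


def accept(s_old: float, s_new: float, t: float,
           rng: np.random.Generator) -> bool:
    """Metropolis rule for maximization: always accept improvements,
    otherwise accept with probability ``exp((s_new - s_old)/t)``."""
    if t <= 0:
        raise ValidationError("temperature must be > 0")
    if s_new >= s_old:
        return True
    return rng.random() < math.exp((s_new - s_old) / t)


def singletonize(gtrn: Gtrn) -> Gtrn:
    """Split every operon into singletons under its natural promoter(s).

    Tandem promoters and the terminator reference are carried over, so the
    singletonized genome has exactly the wild-type expression profile.
    Genes' ``native_operon`` is re-pointed at the new singleton so native
    RBS assignments survive compilation.
    """
    out = Gtrn(
        genes={},
        operons={},
        promoters=dict(gtrn.promoters),
        tandem_candidates=set(gtrn.tandem_candidates),
        sequence_store=gtrn.sequence_store,
    )
    rank = 0
    for op in sorted(gtrn.operons.values(), key=lambda o: o.rank):
        for gid in op.genes:
            new_id = op.id if len(op.genes) == 1 else f"{op.id}__{gid}"
            out.operons[new_id] = Operon(
                id=new_id,
                genes=[gid],
                primary_promoter=op.primary_promoter,
                tandem_promoters=list(op.tandem_promoters),
                terminator_ref=op.terminator_ref,
                strand=op.strand,
                rank=rank,
            )
            out.genes[gid] = replace(gtrn.genes[gid], native_operon=new_id)
            rank += 1
    return out


@dataclass
class ChainResult:
    """Outcome of one annealing chain."""

    best: Gtrn
    best_fitness: FitnessValue
    trace: np.ndarray  # s_total of the current genome, one entry per iteration
    accepted: int
    proposed: int


class _Evaluator:
    """Incrementally maintained fitness of a genome being annealed.

    Keeps the assembled linear system in sync with the mutating genome;
    a move only requires recomputing the regulation rows of the genes it
    touched, after which the steady-state solve is redone from scratch
    (one LU factorization per evaluation).  The assembly path is shared
    with :func:`gtrn_refactor.model.expression_profile`, so a genome whose
    effective regulation matches the wild type bitwise also reproduces the
    wild-type profile bitwise.
    """

    def __init__(self, gtrn: Gtrn, wildtype_profile, spec: FitnessSpec):
        self.g = gtrn
        self.spec = spec
        self.sys = build_linear_system(gtrn)
        genes = resolve_gene_subset(gtrn, spec.gene_subset)
        self._sub = np.array([self.sys.gene_index[g] for g in genes])
        env_ids = [e.id for e in spec.environments]
        missing = [e for e in env_ids if e not in wildtype_profile.columns]
        if missing:
            raise ValidationError(f"wild-type profile lacks environments {missing}")
        self._wt = wildtype_profile.loc[list(self.sys.gene_ids),
                                        env_ids].to_numpy()[self._sub]
        self._denom = self._wt ** 2 + spec.epsilon_norm
        self._dv = (
            np.column_stack([self.sys.delta_v(e) for e in spec.environments])
            if spec.environments
            else np.zeros((len(self.sys.factor_ids), 0))
        )
        self._norm = 1.0 / max(1, self._wt.size)

    def refresh(self, record: MoveRecord) -> None:
        """Re-derive the regulation rows touched by an (un)applied move."""
        if record.kind == "move_gene":
            gid = record.actors["gene"]
            self.sys.refresh_operon(self.g, self.g.operon_of(gid))
        else:
            self.sys.refresh_operon(self.g, record.actors["operon"])

    def fitness(self) -> FitnessValue:
        A = self.sys.system_matrix()
        try:
            lu = sla.lu_factor(A)
            Y = sla.lu_solve(lu, self.sys.alpha[:, None] + self.sys.G @ self._dv)
        except (sla.LinAlgError, ValueError):
            return FitnessValue(-np.inf, -np.inf, -np.inf)
        if not np.all(np.isfinite(Y)):
            return FitnessValue(-np.inf, -np.inf, -np.inf)
        Y = np.clip(Y, 0.0, None)
        s_exp = float(
            -self._norm * np.sum((Y[self._sub] - self._wt) ** 2 / self._denom)
        )
        s_mod = modularity_score(self.g)
        return FitnessValue(
            s_exp,
            s_mod,
            self.spec.weight_expression * s_exp
            + self.spec.weight_modularity * s_mod,
        )


def anneal(
    wildtype: Gtrn,
    spec: FitnessSpec,
    schedule: AnnealingSchedule,
    *,
    start: str = "singletons",
    log_every: int = 1000,
) -> list:
    """Run independent annealing chains; returns one ChainResult per chain.

    The wild-type expression profile (the design target) is computed once
    from ``wildtype`` under ``spec.environments``.  Each chain draws from
    its own RNG stream spawned from ``schedule.seed`` and tracks the
    best-so-far genome by total fitness.
    """
    if start not in ("singletons", "wildtype"):
        raise ValidationError("start must be 'singletons' or 'wildtype'")
    wt_profile = expression_profile(wildtype, spec.environments)
    base = singletonize(wildtype) if start == "singletons" else wildtype.copy()
    results = []
    streams = np.random.SeedSequence(schedule.seed).spawn(schedule.population)
    for chain, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        g = base.copy()
        ev = _Evaluator(g, wt_profile, spec)
        current = ev.fitness()
        best_val = current
        best = g.copy()
        trace = np.empty(schedule.iterations)
        accepted = proposed = 0
        window_accepted = 0
        for n in range(schedule.iterations):
            t = schedule.temperature(n)
            _, record = propose(g, schedule, rng)
            proposed += 1
            ev.refresh(record)
            cand = ev.fitness()
            if accept(current.s_total, cand.s_total, t, rng):
                current = cand
                accepted += 1
                window_accepted += 1
                if current.s_total > best_val.s_total:
                    best_val = current
                    best = g.copy()
            else:
                undo(g, record)
                ev.refresh(record)
            trace[n] = current.s_total
            if log_every and (n + 1) % log_every == 0:
                logger.info(
                    "chain %d iter %d T=%.4g S=%.6g best=%.6g acc=%.1f%%",
                    chain, n + 1, t, current.s_total, best_val.s_total,
                    100.0 * window_accepted / log_every,
                )
                window_accepted = 0
        results.append(
            ChainResult(
                best=best,
                best_fitness=best_val,
                trace=trace,
                accepted=accepted,
                proposed=proposed,
            )
        )
    return results
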