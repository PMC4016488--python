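"""Linear ODE model of a genomic transcriptional regulatory network (GTRN).

Each gene ``i`` carries one mRNA variable ``y_i`` with dynamics

    dy_i/dt = alpha_i + sum_j beta_ij * y_j + sum_k gamma_ik * dv_k - delta_i * y_i

where ``alpha_i`` is the constitutive transcription rate contributed by the
promoter(s) driving gene *i*'s operon (expression h^-1), ``beta_ij`` the
signed regulatory effect of transcription factor *j* (h^-1), ``gamma_ik``
the effect of environmental factor *k* entering through the uptake-flux
deviation ``dv_k = v_k - v_k_opt`` (mmol g^-1 h^-1), and ``delta_i`` the
degradation/dilution rate constant (h^-1).

All genes of an operon share one regulatory function: the elementwise sum of
the (alpha, beta, gamma) parameter sets of the primary promoter and of any
tandem promoters fused upstream of it.  Moving a gene between operons or
editing an operon's tandem promoter list therefore only rewrites that
gene's regulation terms; ``delta`` is a gene-intrinsic constant.

The phenotype of a genome is its steady-state expression profile: the
solution of ``(D - B) y = alpha + G dv`` with ``D = diag(delta)``.  The
linear model can produce negative steady states; those are clipped to zero
after solving and reported in the diagnostics record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.integrate import solve_ivp

from ._errors import NumericalError, StabilityWarning, ValidationError

__all__ = [
    "Gene",
    "RegulatoryFunction",
    "Operon",
    "Environment",
    "Gtrn",
    "ExpressionProfile",
    "SteadyStateInfo",
    "LinearSystem",
    "effective_regulation",
    "build_linear_system",
    "steady_state",
    "expression_profile",
    "simulate_dynamics",
    "response_time",
]

#: default condition-number threshold above which a system is declared
#: ill-conditioned
COND_THRESHOLD = 1e12

#: An expression profile is a plain DataFrame: one row per gene (sorted gene
#: ids), one column per environment id, steady-state mRNA levels (clipped at
#: zero).
ExpressionProfile = pd.DataFrame


@dataclass(frozen=True)
class Gene:
    """A gene: one mRNA species, member of exactly one operon.

    ``native_operon`` records the operon the gene belonged to before any
    refactoring move; the compiler uses it to decide whether the gene still
    carries its native ribosome binding site.
    """

    id: str
    delta: float
    categories: frozenset = frozenset()
    functions: frozenset = frozenset()
    orf_seq_ref: str = ""
    native_rbs_ref: str = ""
    strand: str = "+"
    native_operon: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("gene id must be non-empty")
        if not self.delta > 0:
            raise ValidationError(
                f"gene {self.id!r}: delta must be > 0, got {self.delta}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id!r}: strand must be '+' or '-'")
        object.__setattr__(self, "categories", frozenset(self.categories))
        object.__setattr__(self, "functions", frozenset(self.functions))


@dataclass
class RegulatoryFunction:
    """One promoter's parameter set (alpha, beta, gamma).

    A promoter is constitutive iff it has no regulator and no environmental
    input.  ``region_ref`` points into the genome's sequence store at the
    promoter-region nucleotide sequence (operator sites included).
    """

    alpha: float = 0.0
    beta: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    region_ref: str | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")

    @property
    def is_constitutive(self) -> bool:
        return not self.beta and not self.gamma


@dataclass
class Operon:
    """A transcription unit: ordered cistrons behind a shared promoter region.

    ``rank`` is the chromosomal rank of the primary promoter's original
    locus; the compiler lays surviving operons out in rank order.
    """

    id: str
    genes: list
    primary_promoter: str
    tandem_promoters: list = field(default_factory=list)
    terminator_ref: str = ""
    strand: str = "+"
    rank: int = 0

    #: maximum number of promoters that may be fused in tandem upstream of
    #: the primary promoter
    MAX_TANDEM = 3

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"operon {self.id!r}: gene list must be non-empty")
        if len(self.tandem_promoters) > self.MAX_TANDEM:
            raise ValidationError(
                f"operon {self.id!r}: at most {self.MAX_TANDEM} tandem promoters"
            )
        if self.primary_promoter in self.tandem_promoters:
            raise ValidationError(
                f"operon {self.id!r}: primary promoter cannot also be in tandem"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"operon {self.id!r}: strand must be '+' or '-'")


@dataclass
class Environment:
    """Uptake fluxes ``v`` and their optima ``v_opt`` (mmol g^-1 h^-1).

    A factor present in ``v_opt`` but absent from ``v`` is taken at its
    optimum (``dv = 0``).
    """

    id: str
    v: dict
    v_opt: dict

    def __post_init__(self) -> None:
        missing = set(self.v) - set(self.v_opt)
        if missing:
            raise ValidationError(
                f"environment {self.id!r}: factors {sorted(missing)} have v "
                "but no v_opt"
            )

    def delta_v(self, factor: str) -> float:
        if factor not in self.v_opt:
            raise ValidationError(
                f"environment {self.id!r}: unknown factor {factor!r}"
            )
        return self.v.get(factor, self.v_opt[factor]) - self.v_opt[factor]


@dataclass
class Gtrn:
    """The full genotype: genes, operons, promoters, and sequences.

    This is the unit that is mutated, scored, and compiled.  The sequence
    store maps part keys to nucleotide strings and is treated as immutable
    during refactoring (moves rearrange references, never edit sequences).
    """

    genes: dict
    operons: dict
    promoters: dict
    tandem_candidates: set = field(default_factory=set)
    sequence_store: dict = field(default_factory=dict)

    def validate(self) -> None:
        """Check all structural invariants; raise ValidationError on failure."""
        seen: dict = {}
        for oid, op in self.operons.items():
            if op.id != oid:
                raise ValidationError(f"operon key {oid!r} != operon id {op.id!r}")
            for pid in [op.primary_promoter, *op.tandem_promoters]:
                if pid not in self.promoters:
                    raise ValidationError(
                        f"operon {oid!r} references unknown promoter {pid!r}"
                    )
            for gid in op.genes:
                if gid not in self.genes:
                    raise ValidationError(
                        f"operon {oid!r} references unknown gene {gid!r}"
                    )
                if gid in seen:
                    raise ValidationError(
                        f"gene {gid!r} appears in operons {seen[gid]!r} and {oid!r}"
                    )
                seen[gid] = oid
        orphans = set(self.genes) - set(seen)
        if orphans:
            raise ValidationError(
                f"genes {sorted(orphans)} belong to no operon"
            )
        stray = set(self.tandem_candidates) - set(self.promoters)
        if stray:
            raise ValidationError(
                f"tandem candidates {sorted(stray)} are not known promoters"
            )

    def operon_of(self, gene_id: str) -> Operon:
        for op in self.operons.values():
            if gene_id in op.genes:
                return op
        raise ValidationError(f"gene {gene_id!r} not found in any operon")

    def copy(self) -> "Gtrn":
        """Structural copy sharing immutable leaves.

        ``Gene`` objects, ``RegulatoryFunction`` objects and the sequence
        store are shared (they are never mutated by refactoring moves);
        operons and container dicts are copied.
        """
        return Gtrn(
            genes=dict(self.genes),
            operons={
                oid: replace(op, genes=list(op.genes),
                             tandem_promoters=list(op.tandem_promoters))
                for oid, op in self.operons.items()
            },
            promoters=dict(self.promoters),
            tandem_candidates=set(self.tandem_candidates),
            sequence_store=self.sequence_store,
        )


@dataclass
class SteadyStateInfo:
    """Diagnostics from one steady-state solve."""

    raw: pd.Series  # un-clipped algebraic solution
    clipped_genes: tuple  # gene ids whose value was negative pre-clip
    condition_number: float


def effective_regulation(gtrn: Gtrn, operon: Operon | str) -> RegulatoryFunction:
    """Summed (alpha, beta, gamma) of an operon's primary + tandem promoters.

    Tandem promoters contribute strictly additively; the result governs
    every gene of the operon.  Addition commutes, so the function is
    independent of the tandem list order.
    """
    if isinstance(operon, str):
        try:
            operon = gtrn.operons[operon]
        except KeyError:
            raise ValidationError(f"unknown operon {operon!r}") from None
    alpha = 0.0
    beta: dict = {}
    gamma: dict = {}
    for pid in [operon.primary_promoter, *operon.tandem_promoters]:
        try:
            prom = gtrn.promoters[pid]
        except KeyError:
            raise ValidationError(
                f"operon {operon.id!r} references unknown promoter {pid!r}"
            ) from None
        alpha += prom.alpha
        for j, c in prom.beta.items():
            beta[j] = beta.get(j, 0.0) + c
        for k, c in prom.gamma.items():
            gamma[k] = gamma.get(k, 0.0) + c
    return RegulatoryFunction(alpha=alpha, beta=beta, gamma=gamma)


@dataclass
class LinearSystem:
    """Assembled matrices of the ODE, with row-level refresh for fast edits."""

    gene_ids: tuple
    gene_index: dict
    factor_ids: tuple
    factor_index: dict
    alpha: np.ndarray  # (n,)
    B: np.ndarray  # (n, n)
    G: np.ndarray  # (n, m)
    delta: np.ndarray  # (n,)

    def set_row(self, gene_id: str, reg: RegulatoryFunction) -> None:
        i = self.gene_index[gene_id]
        self.alpha[i] = reg.alpha
        self.B[i, :] = 0.0
        for j, c in reg.beta.items():
            try:
                self.B[i, self.gene_index[j]] = c
            except KeyError:
                raise ValidationError(
                    f"regulator {j!r} of gene {gene_id!r} is not a gene"
                ) from None
        self.G[i, :] = 0.0
        for k, c in reg.gamma.items():
            self.G[i, self.factor_index[k]] = c

    def refresh_operon(self, gtrn: Gtrn, operon: Operon | str) -> None:
        if isinstance(operon, str):
            operon = gtrn.operons[operon]
        reg = effective_regulation(gtrn, operon)
        for gid in operon.genes:
            self.set_row(gid, reg)

    def delta_v(self, env: Environment) -> np.ndarray:
        return np.array([env.delta_v(k) for k in self.factor_ids], dtype=float)

    def system_matrix(self) -> np.ndarray:
        """A = D - B, the matrix of the steady-state system A y = rhs."""
        return np.diag(self.delta) - self.B


def build_linear_system(gtrn: Gtrn) -> LinearSystem:
    gene_ids = tuple(sorted(gtrn.genes))
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    factor_ids = tuple(
        sorted({k for p in gtrn.promoters.values() for k in p.gamma})
    )
    factor_index = {k: i for i, k in enumerate(factor_ids)}
    n, m = len(gene_ids), len(factor_ids)
    sys = LinearSystem(
        gene_ids=gene_ids,
        gene_index=gene_index,
        factor_ids=factor_ids,
        factor_index=factor_index,
        alpha=np.zeros(n),
        B=np.zeros((n, n)),
        G=np.zeros((n, m)),
        delta=np.array([gtrn.genes[g].delta for g in gene_ids]),
    )
    for op in gtrn.operons.values():
        sys.refresh_operon(gtrn, op)
    return sys


def _check_condition(A: np.ndarray, gene_ids: Sequence[str],
                     threshold: float) -> float:
    s = np.linalg.svd(A, compute_uv=False)
    cond = np.inf if s[-1] == 0 else s[0] / s[-1]
    if cond > threshold:
        # name the genes dominating the near-null direction
        _, _, vt = np.linalg.svd(A)
        v = np.abs(vt[-1])
        implicated = [gene_ids[i] for i in np.argsort(v)[::-1][:5]]
        raise NumericalError(
            f"steady-state system ill-conditioned (cond={cond:.3g} > "
            f"{threshold:.1g}); implicated genes: {implicated}"
        )
    return cond


def steady_state(
    gtrn: Gtrn,
    env: Environment,
    *,
    return_diagnostics: bool = False,
    cond_threshold: float = COND_THRESHOLD,
):
    """Solve dy/dt = 0 for the expression column under one environment.

    Returns a Series indexed by sorted gene id (negative components clipped
    to zero); with ``return_diagnostics=True`` also returns a
    :class:`SteadyStateInfo` holding the raw solution, the clipped gene
    ids, and the condition number.
    """
    sys = build_linear_system(gtrn)
    A = sys.system_matrix()
    cond = _check_condition(A, sys.gene_ids, cond_threshold)
    rhs = sys.alpha + sys.G @ sys.delta_v(env)
    y = sla.solve(A, rhs)
    resid = np.max(np.abs(A @ y - rhs))
    if resid > 1e-9 * max(1.0, np.max(np.abs(rhs))):
        raise NumericalError(
            f"steady-state residual {resid:.3g} exceeds tolerance"
        )
    raw = pd.Series(y, index=list(sys.gene_ids), name=env.id)
    clipped = tuple(g for g, v in zip(sys.gene_ids, y) if v < 0)
    col = raw.clip(lower=0.0)
    if return_diagnostics:
        return col, SteadyStateInfo(raw=raw, clipped_genes=clipped,
                                    condition_number=cond)
    return col


def expression_profile(
    gtrn: Gtrn,
    environments: Iterable[Environment],
    *,
    clip: bool = True,
    cond_threshold: float = COND_THRESHOLD,
) -> ExpressionProfile:
    """Steady-state profile (genes x environments) sharing one factorization."""
    envs = list(environments)
    ids = [e.id for e in envs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate environment ids in {ids}")
    sys = build_linear_system(gtrn)
    A = sys.system_matrix()
    _check_condition(A, sys.gene_ids, cond_threshold)
    DV = np.column_stack([sys.delta_v(e) for e in envs]) if envs else \
        np.zeros((len(sys.factor_ids), 0))
    rhs = sys.alpha[:, None] + sys.G @ DV
    lu = sla.lu_factor(A)
    Y = sla.lu_solve(lu, rhs)
    if clip:
        Y = np.clip(Y, 0.0, None)
    return pd.DataFrame(Y, index=list(sys.gene_ids), columns=ids)


def simulate_dynamics(
    gtrn: Gtrn,
    env: Environment,
    y0: Sequence[float] | Mapping[str, float],
    t_grid: Sequence[float],
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Integrate the linear ODE from ``y0`` over ``t_grid``.

    ``t_grid`` must be strictly increasing and start at 0.  ``y0`` may be a
    vector in sorted-gene order or a mapping gene id -> level.  Warns (does
    not fail) if the system matrix has an eigenvalue with non-negative real
    part, in which case the trajectory diverges from any fixed point.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValidationError("t_grid must be strictly increasing and start at 0")
    sys = build_linear_system(gtrn)
    if isinstance(y0, Mapping):
        y0 = [y0.get(g, 0.0) for g in sys.gene_ids]
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (len(sys.gene_ids),):
        raise ValidationError(
            f"y0 has shape {y0.shape}, expected ({len(sys.gene_ids)},)"
        )
    M = sys.B - np.diag(sys.delta)
    if len(sys.gene_ids) and np.max(np.linalg.eigvals(M).real) >= 0:
        warnings.warn(
            "system matrix B - D has an eigenvalue with non-negative real "
            "part; dynamics are unstable",
            StabilityWarning,
            stacklevel=2,
        )
    c = sys.alpha + sys.G @ sys.delta_v(env)
    sol = solve_ivp(
        lambda _t, y: M @ y + c,
        (0.0, float(t[-1])),
        y0,
        t_eval=t,
        method="LSODA",
        jac=lambda _t, _y: M,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise NumericalError(f"ODE integration failed: {sol.message}")
    return pd.DataFrame(sol.y.T, index=t, columns=list(sys.gene_ids))


def response_time(
    gtrn: Gtrn,
    env_from: Environment,
    env_to: Environment,
    epsilon: float = 0.05,
    *,
    max_horizon_factor: float = 50.0,
) -> float:
    """Time (h) to settle within ``epsilon`` of the new steady state.

    The trajectory starts at the steady state of ``env_from`` after a step
    change to ``env_to``; the response time is the first time after which
    the max-norm distance to the new steady state stays below
    ``epsilon * ||y_to - y_from||_inf``.  Returns 0 if both environments
    yield identical steady states.
    """
    if not 0 < epsilon < 1:
        raise ValidationError("epsilon must be in (0, 1)")
    sys = build_linear_system(gtrn)
    A = sys.system_matrix()
    _check_condition(A, sys.gene_ids, COND_THRESHOLD)
    y_from = sla.solve(A, sys.alpha + sys.G @ sys.delta_v(env_from))
    y_to = sla.solve(A, sys.alpha + sys.G @ sys.delta_v(env_to))
    w = y_from - y_to
    scale = np.max(np.abs(w)) if len(w) else 0.0
    if scale == 0.0:
        return 0.0
    M = sys.B - np.diag(sys.delta)
    lam, V = np.linalg.eig(M)
    rate = np.max(lam.real)
    if rate >= 0:
        raise NumericalError(
            "dynamics do not converge (non-negative eigenvalue of B - D)"
        )
    coeff = np.linalg.solve(V, w.astype(complex))

    def dist(t: float) -> float:
        return float(np.max(np.abs((V @ (coeff * np.exp(lam * t))).real)))

    thr = epsilon * scale
    t_max = max_horizon_factor * np.log(1.0 / epsilon) / abs(rate)
    if dist(t_max) >= thr:
        raise NumericalError("trajectory did not settle within the horizon")
    grid = np.linspace(0.0, t_max, 4097)
    above = np.array([dist(t) >= thr for t in grid])
    if not above.any():
        return 0.0
    i = int(np.nonzero(above)[0][-1])
    lo, hi = grid[i], grid[i + 1]
    for _ in range(60):  # bisect the last crossing
        mid = 0.5 * (lo + hi)
        if dist(mid) >= thr:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
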