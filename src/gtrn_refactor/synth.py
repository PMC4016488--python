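"""Synthetic GTRNs, sequences and environment sets for end-to-end testing.

The generator emulates the structure the refactoring method assumes at the
scale of the bacterial wild type it targets (thousands of genes, a TF
fraction of roughly 330/4298 ~ 7.7%, GO-style annotations drawn from a
184-label vocabulary), but at configurable desk scale.  Key properties of
generated genomes:

* singleton operons — every gene under its own (natural) promoter, the
  optimizer's canonical starting condition;
* promoter redundancy — promoters come in groups of ``redundancy``
  members sharing an identical (alpha, beta, gamma) parameter set, so a
  ground-truth consolidation exists: merging each group's genes into one
  operon changes no gene's expression and reduces the operon count by the
  designed factor;
* guaranteed stability — regulatory couplings are globally rescaled until
  the spectral abscissa of B - D is at most ``-0.1 * min(delta)``;
* full sequence parts (ORF with start codon and length divisible by 3,
  RBS, promoter region, terminator) so every genome compiles and parses.

Environment sets mirror the single- and multi-perturbation designs used to
probe biochemical adaptation: oxygen uptake varied from fully anaerobic to
4-fold the optimal flux of 75 mmol g^-1 h^-1, glucose uptake varied from
-20 to +20 mmol g^-1 h^-1 around its optimum of 20, or both jointly; the
optimal environment is always element 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .model import Environment, Gene, Gtrn, Operon, RegulatoryFunction

__all__ = ["SynthesisSpec", "generate_gtrn", "generate_environments",
           "OXYGEN_OPTIMUM", "GLUCOSE_OPTIMUM"]

OXYGEN_OPTIMUM = 75.0  # mmol g^-1 h^-1
GLUCOSE_OPTIMUM = 20.0  # mmol g^-1 h^-1

#: wild-type scale reference: 330 putative TFs among 4298 genes
TF_FRACTION = 330 / 4298

#: typical |delta v| scale per environmental factor, used to size gamma so
#: environmental effects are commensurate with constitutive transcription
_FACTOR_SCALE = {"O2": 150.0, "glc": 20.0}

_BASES = np.array(list("ACGT"))


@dataclass
class SynthesisSpec:
    """Parameters of a synthetic genome.

    ``redundancy`` is the number of promoters per identical-parameter
    group (1 = all promoters distinct).  ``n_tfs`` defaults to the
    wild-type TF fraction of ``n_genes``.
    """

    n_genes: int = 100
    n_tfs: int | None = None
    n_efs: int = 2
    regulators_per_promoter_mean: float = 1.5
    redundancy: int = 5
    tandem_candidate_fraction: float = 0.15
    function_vocabulary_size: int = 184
    functions_per_gene_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs is None:
            self.n_tfs = max(2, round(TF_FRACTION * self.n_genes))
        if not 0 < self.n_tfs < self.n_genes:
            raise ValidationError("need 0 < n_tfs < n_genes")
        if self.redundancy < 1:
            raise ValidationError("redundancy must be >= 1")
        if self.n_efs < 0:
            raise ValidationError("n_efs must be >= 0")
        if not 0 <= self.tandem_candidate_fraction <= 1:
            raise ValidationError("tandem_candidate_fraction must be in [0, 1]")


def factor_ids(n_efs: int) -> list:
    ids = ["O2", "glc"] + [f"EF{k}" for k in range(3, n_efs + 1)]
    return ids[:n_efs]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _spectral_abscissa(B: np.ndarray, delta: np.ndarray) -> float:
    return float(np.max(np.linalg.eigvals(B - np.diag(delta)).real))


def generate_gtrn(spec: SynthesisSpec) -> Gtrn:
    """Deterministically generate a stable singleton-operon genome."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    width = max(4, len(str(n)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]
    tf_ids = gene_ids[: spec.n_tfs]
    efs = factor_ids(spec.n_efs)

    # per-group regulatory parameters (identical within a group)
    n_groups = math.ceil(n / spec.redundancy)
    groups = []
    for _ in range(n_groups):
        alpha = float(np.exp(rng.uniform(np.log(0.5), np.log(5.0))))
        k = int(min(3, 1 + rng.poisson(max(spec.regulators_per_promoter_mean - 1,
                                           0.0))))
        regs = rng.choice(spec.n_tfs, size=min(k, spec.n_tfs), replace=False)
        beta = {
            tf_ids[j]: float(rng.uniform(0.05, 0.5)
                             * (1 if rng.random() < 0.6 else -1))
            for j in sorted(regs)
        }
        gamma = {}
        for ef in efs:
            if rng.random() < 0.6:
                scale = _FACTOR_SCALE.get(ef, 10.0)
                gamma[ef] = float(rng.uniform(0.1, 1.0) * alpha / scale
                                  * (1 if rng.random() < 0.5 else -1))
        groups.append((alpha, beta, gamma))

    delta = np.exp(rng.uniform(np.log(0.1), np.log(2.0), size=n))
    group_of = [i // spec.redundancy for i in range(n)]

    # enforce stability: shrink all couplings until B - D is safely Hurwitz
    gi = {g: i for i, g in enumerate(gene_ids)}
    B = np.zeros((n, n))
    for i in range(n):
        for tf, c in groups[group_of[i]][1].items():
            B[i, gi[tf]] = c
    target = -0.1 * float(delta.min())
    scale = 1.0
    for _ in range(100):
        if _spectral_abscissa(scale * B, delta) <= target:
            break
        scale *= 0.7
    else:
        raise ValidationError(
            "could not stabilize the generated network by rescaling"
        )
    if scale != 1.0:
        groups = [
            (a, {k: scale * v for k, v in b.items()}, g) for a, b, g in groups
        ]

    categories_pool = ["enzyme", "stress", "defense"]
    vocab = [f"GO:F{j:04d}" for j in range(1, spec.function_vocabulary_size + 1)]

    genes: dict = {}
    operons: dict = {}
    promoters: dict = {}
    store: dict = {}
    for i, gid in enumerate(gene_ids):
        strand = "+" if rng.random() < 0.5 else "-"
        cats = {categories_pool[int(rng.choice(3, p=[0.5, 0.3, 0.2]))]}
        if gid in tf_ids:
            cats.add("TF")
        n_fun = int(rng.integers(1, spec.functions_per_gene_max + 1))
        funcs = frozenset(
            vocab[j] for j in rng.choice(len(vocab), size=n_fun, replace=False)
        )
        pid = f"P{i + 1:0{width}d}"
        oid = f"op{i + 1:0{width}d}"
        orf_key, rbs_key = f"orf:{gid}", f"rbs:{gid}"
        prom_key, term_key = f"prom:{pid}", f"term:{oid}"
        store[orf_key] = "ATG" + _random_seq(rng, int(rng.integers(9, 30)) * 3)
        store[rbs_key] = _random_seq(rng, 20)
        store[prom_key] = _random_seq(rng, 40)
        store[term_key] = _random_seq(rng, 30)
        alpha, beta, gamma = groups[group_of[i]]
        promoters[pid] = RegulatoryFunction(
            alpha=alpha, beta=dict(beta), gamma=dict(gamma), region_ref=prom_key
        )
        genes[gid] = Gene(
            id=gid,
            delta=float(delta[i]),
            categories=frozenset(cats),
            functions=funcs,
            orf_seq_ref=orf_key,
            native_rbs_ref=rbs_key,
            strand=strand,
            native_operon=oid,
        )
        operons[oid] = Operon(
            id=oid,
            genes=[gid],
            primary_promoter=pid,
            terminator_ref=term_key,
            strand=strand,
            rank=i,
        )

    n_cand = round(spec.tandem_candidate_fraction * len(promoters))
    pids = sorted(promoters)
    cand = set(
        pids[j] for j in rng.choice(len(pids), size=n_cand, replace=False)
    )
    gtrn = Gtrn(
        genes=genes,
        operons=operons,
        promoters=promoters,
        tandem_candidates=cand,
        sequence_store=store,
    )
    gtrn.validate()
    return gtrn


def generate_environments(kind: str, n: int, seed: int = 0) -> list:
    """Optimal environment plus ``n`` random perturbations of the given kind.

    ``oxygen``: O2 uptake ~ Uniform(0, 4 x 75), glucose held optimal.
    ``glucose``: glucose uptake ~ Uniform(-20, 20), oxygen held optimal.
    ``multi``: both factors perturbed jointly (dv != 0 for every factor).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    v_opt = {"O2": OXYGEN_OPTIMUM, "glc": GLUCOSE_OPTIMUM}
    rng = np.random.default_rng(seed)
    envs = [Environment(id="optimal", v=dict(v_opt), v_opt=dict(v_opt))]

    def draw(lo: float, hi: float, avoid: float) -> float:
        x = float(rng.uniform(lo, hi))
        while x == avoid:  # dv must be nonzero for a perturbation
            x = float(rng.uniform(lo, hi))
        return x

    for i in range(1, n + 1):
        v = dict(v_opt)
        if kind == "oxygen":
            v["O2"] = draw(0.0, 4 * OXYGEN_OPTIMUM, OXYGEN_OPTIMUM)
        elif kind == "glucose":
            v["glc"] = draw(-GLUCOSE_OPTIMUM, GLUCOSE_OPTIMUM, GLUCOSE_OPTIMUM)
        elif kind == "multi":
            v["O2"] = draw(0.0, 4 * OXYGEN_OPTIMUM, OXYGEN_OPTIMUM)
            v["glc"] = draw(-GLUCOSE_OPTIMUM, GLUCOSE_OPTIMUM, GLUCOSE_OPTIMUM)
        else:
            raise ValidationError(
                f"unknown environment kind {kind!r}; expected "
                "'oxygen', 'glucose' or 'multi'"
            )
        envs.append(Environment(id=f"{kind}_{i:03d}", v=v, v_opt=dict(v_opt)))
    return envs
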