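"""Shared fixtures: small hand-built genomes and environments."""

import pytest

from gtrn_refactor.model import (
    Environment,
    Gene,
    Gtrn,
    Operon,
    RegulatoryFunction,
)


def make_gtrn(genes, operons, promoters, tandem_candidates=(), store=None):
    """Assemble and validate a Gtrn from terse specs.

    ``genes``: {gene_id: delta or dict of Gene kwargs}
    ``operons``: {operon_id: (gene_id_list, primary_promoter)
                  or dict of Operon kwargs}
    ``promoters``: {promoter_id: RegulatoryFunction or (alpha, beta, gamma)}
    """
    g_objs = {}
    for gid, spec in genes.items():
        if isinstance(spec, dict):
            g_objs[gid] = Gene(id=gid, **spec)
        else:
            g_objs[gid] = Gene(id=gid, delta=spec)
    p_objs = {}
    for pid, spec in promoters.items():
        if isinstance(spec, RegulatoryFunction):
            p_objs[pid] = spec
        else:
            alpha, beta, gamma = spec
            p_objs[pid] = RegulatoryFunction(alpha=alpha, beta=dict(beta),
                                             gamma=dict(gamma))
    o_objs = {}
    for rank, (oid, spec) in enumerate(operons.items()):
        if isinstance(spec, dict):
            spec.setdefault("rank", rank)
            o_objs[oid] = Operon(id=oid, **spec)
        else:
            gene_list, primary = spec
            o_objs[oid] = Operon(id=oid, genes=list(gene_list),
                                 primary_promoter=primary, rank=rank)
    gtrn = Gtrn(
        genes=g_objs,
        operons=o_objs,
        promoters=p_objs,
        tandem_candidates=set(tandem_candidates),
        sequence_store=dict(store or {}),
    )
    gtrn.validate()
    return gtrn


@pytest.fixture
def env_neutral():
    """An environment with every deviation at zero."""
    return Environment(id="optimal", v={"O2": 75.0}, v_opt={"O2": 75.0})


@pytest.fixture
def single_gene_gtrn():
    """One gene, alpha=2, delta=1: steady state y = 2."""
    return make_gtrn(
        genes={"gA": 1.0},
        operons={"op1": (["gA"], "P1")},
        promoters={"P1": (2.0, {}, {})},
    )


@pytest.fixture
def cascade_gtrn():
    """Two-gene cascade: y_a = 1, y_b = (0.5 + 0.5*y_a) = 1."""
    return make_gtrn(
        genes={"gA": 1.0, "gB": 1.0},
        operons={"opA": (["gA"], "PA"), "opB": (["gB"], "PB")},
        promoters={"PA": (1.0, {}, {}), "PB": (0.5, {"gA": 0.5}, {})},
    )
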