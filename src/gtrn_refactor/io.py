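"""Readers and writers for the on-disk genome bundle and run manifests.

The canonical interchange format for a GTRN is a directory of TSV tables
plus a FASTA of sequence parts:

* ``genes.tsv``      — id, delta, categories, functions, strand,
                       orf_seq_ref, native_rbs_ref, native_operon
* ``promoters.tsv``  — id, alpha, constitutive, region_ref, tandem_candidate
* ``beta.tsv``       — promoter_id, regulator_gene_id, beta (long format)
* ``gamma.tsv``      — promoter_id, factor_id, gamma (long format)
* ``operons.tsv``    — operon_id, operon_rank, rank (cistron position),
                       gene_id, primary_promoter, tandem_promoters
                       (semicolon-separated), terminator_ref, strand
* ``sequences.fasta``— one record per sequence-store part key

Floats are serialized with ``repr`` so a save/load round trip is exact.
``environments.tsv`` holds env_id, factor_id, v, v_opt in long format.
All validation errors name the offending file, row and identifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._errors import ValidationError
from .model import Environment, Gene, Gtrn, Operon, RegulatoryFunction

__all__ = [
    "save_genome",
    "load_genome",
    "save_environments",
    "load_environments",
    "RunManifest",
]

_GENOME_FILES = ("genes.tsv", "promoters.tsv", "beta.tsv", "gamma.tsv",
                 "operons.tsv", "sequences.fasta")


def _read_tsv(path: Path, required: tuple) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing table {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    return df


def _float(path: str, row: int, col: str, value: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"{path} row {row + 2}: column {col!r} is not a number: {value!r}"
        ) from None


def save_genome(gtrn: Gtrn, directory) -> None:
    """Write the TSV/FASTA bundle; ``load_genome`` inverts it exactly."""
    gtrn.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": g.id,
                "delta": repr(g.delta),
                "categories": ";".join(sorted(g.categories)),
                "functions": ";".join(sorted(g.functions)),
                "strand": g.strand,
                "orf_seq_ref": g.orf_seq_ref,
                "native_rbs_ref": g.native_rbs_ref,
                "native_operon": g.native_operon,
            }
            for g in (gtrn.genes[k] for k in sorted(gtrn.genes))
        ]
    ).to_csv(d / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": pid,
                "alpha": repr(p.alpha),
                "constitutive": "yes" if p.is_constitutive else "no",
                "region_ref": p.region_ref or "",
                "tandem_candidate": "yes" if pid in gtrn.tandem_candidates
                else "no",
            }
            for pid, p in sorted(gtrn.promoters.items())
        ]
    ).to_csv(d / "promoters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"promoter_id": pid, "regulator_gene_id": j, "beta": repr(c)}
            for pid, p in sorted(gtrn.promoters.items())
            for j, c in sorted(p.beta.items())
        ],
        columns=["promoter_id", "regulator_gene_id", "beta"],
    ).to_csv(d / "beta.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"promoter_id": pid, "factor_id": k, "gamma": repr(c)}
            for pid, p in sorted(gtrn.promoters.items())
            for k, c in sorted(p.gamma.items())
        ],
        columns=["promoter_id", "factor_id", "gamma"],
    ).to_csv(d / "gamma.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "operon_id": op.id,
                "operon_rank": op.rank,
                "rank": i,
                "gene_id": gid,
                "primary_promoter": op.primary_promoter,
                "tandem_promoters": ";".join(op.tandem_promoters),
                "terminator_ref": op.terminator_ref,
                "strand": op.strand,
            }
            for op in sorted(gtrn.operons.values(), key=lambda o: (o.rank, o.id))
            for i, gid in enumerate(op.genes)
        ]
    ).to_csv(d / "operons.tsv", sep="\t", index=False)
    records = [
        SeqRecord(Seq(seq), id=key, description="")
        for key, seq in sorted(gtrn.sequence_store.items())
    ]
    with open(d / "sequences.fasta", "w") as fh:
        SeqIO.write(records, fh, "fasta")


def load_genome(directory) -> Gtrn:
    """Read a genome bundle with strict schema validation."""
    d = Path(directory)
    genes_df = _read_tsv(d / "genes.tsv",
                         ("id", "delta", "categories", "functions", "strand",
                          "orf_seq_ref", "native_rbs_ref", "native_operon"))
    prom_df = _read_tsv(d / "promoters.tsv",
                        ("id", "alpha", "constitutive", "region_ref",
                         "tandem_candidate"))
    beta_df = _read_tsv(d / "beta.tsv",
                        ("promoter_id", "regulator_gene_id", "beta"))
    gamma_df = _read_tsv(d / "gamma.tsv",
                         ("promoter_id", "factor_id", "gamma"))
    op_df = _read_tsv(d / "operons.tsv",
                      ("operon_id", "operon_rank", "rank", "gene_id",
                       "primary_promoter", "tandem_promoters",
                       "terminator_ref", "strand"))
    fasta = d / "sequences.fasta"
    if not fasta.exists():
        raise ValidationError(f"missing {fasta}")
    store = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}

    genes: dict = {}
    for row, rec in genes_df.iterrows():
        gid = rec["id"]
        if gid in genes:
            raise ValidationError(f"genes.tsv row {row + 2}: duplicate gene {gid!r}")
        genes[gid] = Gene(
            id=gid,
            delta=_float("genes.tsv", row, "delta", rec["delta"]),
            categories=frozenset(c for c in rec["categories"].split(";") if c),
            functions=frozenset(c for c in rec["functions"].split(";") if c),
            strand=rec["strand"],
            orf_seq_ref=rec["orf_seq_ref"],
            native_rbs_ref=rec["native_rbs_ref"],
            native_operon=rec["native_operon"],
        )

    beta_map: dict = {}
    for row, rec in beta_df.iterrows():
        pid, j = rec["promoter_id"], rec["regulator_gene_id"]
        if j not in genes:
            raise ValidationError(
                f"beta.tsv row {row + 2}: unknown regulator gene {j!r}"
            )
        beta_map.setdefault(pid, {})[j] = _float("beta.tsv", row, "beta",
                                                 rec["beta"])
    gamma_map: dict = {}
    for row, rec in gamma_df.iterrows():
        gamma_map.setdefault(rec["promoter_id"], {})[rec["factor_id"]] = \
            _float("gamma.tsv", row, "gamma", rec["gamma"])

    promoters: dict = {}
    candidates: set = set()
    for row, rec in prom_df.iterrows():
        pid = rec["id"]
        if pid in promoters:
            raise ValidationError(
                f"promoters.tsv row {row + 2}: duplicate promoter {pid!r}"
            )
        prom = RegulatoryFunction(
            alpha=_float("promoters.tsv", row, "alpha", rec["alpha"]),
            beta=beta_map.pop(pid, {}),
            gamma=gamma_map.pop(pid, {}),
            region_ref=rec["region_ref"] or None,
        )
        declared = rec["constitutive"] == "yes"
        if declared != prom.is_constitutive:
            raise ValidationError(
                f"promoters.tsv row {row + 2}: promoter {pid!r} constitutive "
                f"flag {rec['constitutive']!r} contradicts its beta/gamma tables"
            )
        promoters[pid] = prom
        if rec["tandem_candidate"] == "yes":
            candidates.add(pid)
    for pid in (*beta_map, *gamma_map):
        raise ValidationError(
            f"beta/gamma tables reference unknown promoter {pid!r}"
        )

    operons: dict = {}
    for (oid,), block in op_df.groupby(["operon_id"], sort=False):
        block = block.sort_values("rank", key=lambda s: s.astype(int))
        first = block.iloc[0]
        row = int(block.index[0])
        gene_list = list(block["gene_id"])
        if len(set(gene_list)) != len(gene_list) or "" in gene_list:
            raise ValidationError(
                f"operons.tsv near row {row + 2}: operon {oid!r} has empty or "
                "duplicate gene rows"
            )
        operons[oid] = Operon(
            id=oid,
            genes=gene_list,
            primary_promoter=first["primary_promoter"],
            tandem_promoters=[p for p in first["tandem_promoters"].split(";")
                              if p],
            terminator_ref=first["terminator_ref"],
            strand=first["strand"],
            rank=int(first["operon_rank"]),
        )

    gtrn = Gtrn(
        genes=genes,
        operons=operons,
        promoters=promoters,
        tandem_candidates=candidates,
        sequence_store=store,
    )
    gtrn.validate()
    return gtrn


def save_environments(environments, path) -> None:
    pd.DataFrame(
        [
            {"env_id": e.id, "factor_id": k, "v": repr(e.v[k])
             if k in e.v else "", "v_opt": repr(vo)}
            for e in environments
            for k, vo in sorted(e.v_opt.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def load_environments(path) -> list:
    df = _read_tsv(Path(path), ("env_id", "factor_id", "v", "v_opt"))
    envs: dict = {}
    order: list = []
    for row, rec in df.iterrows():
        eid = rec["env_id"]
        if eid not in envs:
            envs[eid] = ({}, {})
            order.append(eid)
        v, v_opt = envs[eid]
        if rec["v"] != "":
            v[rec["factor_id"]] = _float("environments", row, "v", rec["v"])
        v_opt[rec["factor_id"]] = _float("environments", row, "v_opt",
                                         rec["v_opt"])
    return [Environment(id=eid, v=envs[eid][0], v_opt=envs[eid][1])
            for eid in order]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Snapshot sufficient to re-execute a run reproducibly."""

    config: dict
    seed: int
    input_digests: dict = field(default_factory=dict)
    artifact_version: str = "0.1.0"
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    @classmethod
    def for_inputs(cls, config: dict, seed: int, inputs) -> "RunManifest":
        digests = {}
        for item in inputs:
            p = Path(item)
            if p.is_dir():
                for f in sorted(p.rglob("*")):
                    if f.is_file():
                        digests[str(f)] = _digest(f)
            elif p.is_file():
                digests[str(p)] = _digest(p)
        return cls(config=config, seed=seed, input_digests=digests)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
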