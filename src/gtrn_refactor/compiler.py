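"""Compile a GTRN into a concrete nucleotide sequence, and parse it back.

Layout rules
------------
Each operon is assembled 5'->3' on its coding strand as

    [tandem promoter region + isolation spacer]*  primary promoter region
    RBS_1 ORF_1+TAA  RBS_2 ORF_2+TAA ... terminator

* Every ORF gets a TAA stop codon appended unconditionally (double stops
  are accepted) so the ORF becomes a self-contained rearrangeable module.
* The first cistron keeps its native RBS (part of the fixed intergenic
  spacer).  A cistron that still sits in its native operon keeps its own
  RBS; a cistron that arrived by a refactoring move receives the same RBS
  as every other arrival: either the destination's first-cistron RBS
  (policy ``first_orf_rbs``, default) or a configured standardized RBS
  (policy ``standard_rbs``).
* Tandem promoter regions are separated from each other and from the
  primary promoter region by a fixed isolation spacer.
* Reverse-strand operons are assembled on the coding strand and
  reverse-complemented into the chromosome; coordinates are 1-based
  inclusive (GenBank convention).
* Surviving operons are laid out in the rank order of their primary
  promoter's original locus.

The emitted GenBank record carries ``operon``, ``promoter``, ``RBS``,
``CDS``, ``terminator`` and spacer features whose qualifiers embed part
keys and the numeric model parameters, which makes :func:`parse_genome`
an exact inverse on genomes that contain no moved genes:
``parse_genome(compile_genome(g)) == g`` and compile is deterministic, so
compile∘parse∘compile is byte-identical.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._errors import GenomeParseError, ValidationError
from .model import Gene, Gtrn, Operon, RegulatoryFunction

__all__ = [
    "SequencePart",
    "IntergenicSpacer",
    "infer_rbs",
    "prepare_orf",
    "resolve_overlap",
    "assign_rbs",
    "compile_genome",
    "parse_genome",
    "write_genbank",
    "write_fasta",
    "DEFAULT_ISOLATION_SPACER",
    "DEFAULT_STANDARD_RBS",
]

logger = logging.getLogger(__name__)

#: neutral 20 bp spacer inserted between tandem promoter regions
DEFAULT_ISOLATION_SPACER = "GCTTCCTCGCTCACTGACTC"
#: standardized RBS used under the ``standard_rbs`` assignment policy
DEFAULT_STANDARD_RBS = "AAAGAGGAGAAA"

_DNA = set("ACGT")


@dataclass(frozen=True)
class SequencePart:
    """A rearrangeable sequence module (5'->3' on its coding strand)."""

    key: str
    seq: str
    role: str  # orf | rbs | promoter_region | terminator | isolation_spacer

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValidationError(f"part {self.key!r}: empty sequence")
        bad = set(self.seq) - _DNA
        if bad:
            raise ValidationError(
                f"part {self.key!r}: non-ACGT characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class IntergenicSpacer:
    """Fixed region: promoter region + first-cistron RBS + upstream terminator."""

    promoter_region: str
    rbs: str
    upstream_terminator: str  # may be empty if annotated absent


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def infer_rbs(
    tss: int | None,
    start_codon: int,
    genome_seq: str,
    strand: str = "+",
    *,
    min_utr: int = 15,
    fallback: int = 60,
    key: str = "rbs",
) -> SequencePart:
    """Extract the RBS region upstream of a start codon (1-based positions).

    Three rules: (a) with a known transcription start site (TSS) and a
    5'UTR of at least ``min_utr`` bp, the RBS is the fragment from the +1
    position to the base before the start codon; (b) with an unknown TSS,
    the 60 bp immediately upstream of the start codon; (c) with a known
    TSS but a 5'UTR shorter than ``min_utr`` bp, the 5'UTR enlarged by an
    additional 60 bp upstream (total length utr + 60).  Leaderless 5'UTRs
    (length 0) fall under rule (c).

    For a minus-strand gene pass the reverse-complemented contig and
    positions on that strand (the caller resolves orientation).
    """
    if strand not in ("+", "-"):
        raise ValidationError("strand must be '+' or '-'")
    if strand == "-":
        n = len(genome_seq)
        genome_seq = _revcomp(genome_seq)
        start_codon = n - start_codon + 1
        tss = None if tss is None else n - tss + 1
    if not 1 <= start_codon <= len(genome_seq):
        raise ValidationError("start codon position outside the contig")
    if tss is None:
        lo = start_codon - fallback
        if lo < 1:
            raise ValidationError(
                f"start codon within {fallback} bp of the contig edge and "
                "TSS unknown; cannot infer an RBS"
            )
        seq = genome_seq[lo - 1 : start_codon - 1]
    else:
        if not 1 <= tss < start_codon:
            raise ValidationError("TSS must lie strictly upstream of the start codon")
        utr = start_codon - tss
        if utr >= min_utr:
            seq = genome_seq[tss - 1 : start_codon - 1]
        else:
            lo = tss - fallback
            if lo < 1:
                raise ValidationError(
                    f"5'UTR shorter than {min_utr} bp within {fallback} bp of "
                    "the contig edge; cannot enlarge the RBS"
                )
            seq = genome_seq[lo - 1 : start_codon - 1]
    return SequencePart(key=key, seq=seq, role="rbs")


def prepare_orf(orf_seq: str, *, key: str = "orf") -> SequencePart:
    """Append a TAA stop codon (unconditionally) to make the ORF a module."""
    if not orf_seq:
        raise ValidationError("empty ORF sequence")
    bad = set(orf_seq) - _DNA
    if bad:
        raise ValidationError(f"ORF contains non-ACGT characters {sorted(bad)}")
    if len(orf_seq) % 3:
        warnings.warn(
            f"ORF {key!r} length {len(orf_seq)} is not divisible by 3",
            stacklevel=2,
        )
    return SequencePart(key=key, seq=orf_seq + "TAA", role="orf")


def resolve_overlap(
    genome_seq: str,
    span_a: tuple,
    span_b: tuple,
    strand_a: str,
    strand_b: str,
    *,
    orf_spans_a: tuple = (),
    orf_spans_b: tuple = (),
) -> tuple:
    """Separate two opposite-strand operon regions that share bases.

    ``span_a``/``span_b`` are 1-based inclusive (start, end) chromosome
    spans of the two operons; ``orf_spans_*`` list the ORF spans they
    contain.  Each operon receives an independent, fully oriented copy of
    its region including the shared bases, so both become standalone
    rearrangeable modules; total part length = unique bases + duplicated
    overlap.  Same-strand overlaps and overlaps engulfing a whole ORF are
    errors (the rule only covers small promoter-region/ORF overlaps).
    """
    if strand_a == strand_b:
        raise ValidationError(
            "overlap resolution only applies to operons on opposite strands"
        )
    (sa, ea), (sb, eb) = span_a, span_b
    if not (1 <= sa <= ea <= len(genome_seq) and 1 <= sb <= eb <= len(genome_seq)):
        raise ValidationError("operon spans must lie within the genome")
    lo, hi = max(sa, sb), min(ea, eb)
    if lo <= hi:
        for s, e in (*orf_spans_a, *orf_spans_b):
            if lo <= s and e <= hi:
                raise ValidationError(
                    f"overlap [{lo},{hi}] engulfs the entire ORF [{s},{e}]; "
                    "not a small promoter-region overlap"
                )
        logger.info("duplicating %d shared bases between operon regions",
                    hi - lo + 1)
    seq_a = genome_seq[sa - 1 : ea]
    seq_b = genome_seq[sb - 1 : eb]
    if strand_a == "-":
        seq_a = _revcomp(seq_a)
    if strand_b == "-":
        seq_b = _revcomp(seq_b)
    return seq_a, seq_b


def assign_rbs(
    gtrn: Gtrn,
    dest_operon: Operon,
    incoming_gene: Gene,
    policy: str = "first_orf_rbs",
    *,
    standard_rbs: str = DEFAULT_STANDARD_RBS,
) -> SequencePart:
    """RBS for an ORF arriving at ``dest_operon``; same output for every arrival."""
    if policy == "standard_rbs":
        return SequencePart(key="standard_rbs", seq=standard_rbs, role="rbs")
    if policy != "first_orf_rbs":
        raise ValidationError(
            f"unknown RBS policy {policy!r}; expected 'first_orf_rbs' or "
            "'standard_rbs'"
        )
    first = gtrn.genes[dest_operon.genes[0]]
    try:
        seq = gtrn.sequence_store[first.native_rbs_ref]
    except KeyError:
        raise ValidationError(
            f"operon {dest_operon.id!r}: first-cistron RBS part "
            f"{first.native_rbs_ref!r} missing from the sequence store"
        ) from None
    return SequencePart(key=first.native_rbs_ref, seq=seq, role="rbs")


def _fmt_float(x: float) -> str:
    return repr(float(x))


def _fmt_map(d: dict) -> str:
    return ";".join(f"{k}:{_fmt_float(v)}" for k, v in sorted(d.items()))


def _parse_map(s: str) -> dict:
    out = {}
    for item in s.split(";"):
        if not item:
            continue
        k, _, v = item.rpartition(":")
        out[k] = float(v)
    return out


def _store_get(gtrn: Gtrn, key: str, context: str) -> str:
    try:
        return gtrn.sequence_store[key]
    except KeyError:
        raise ValidationError(
            f"{context}: sequence part {key!r} missing from the store"
        ) from None


def compile_genome(
    gtrn: Gtrn,
    *,
    isolation_spacer: str = DEFAULT_ISOLATION_SPACER,
    rbs_policy: str = "first_orf_rbs",
    standard_rbs: str = DEFAULT_STANDARD_RBS,
    record_id: str = "refactored_genome",
) -> SeqRecord:
    """Assemble the full annotated chromosome for a GTRN.

    Deterministic: an identical GTRN compiles to identical bytes.
    """
    gtrn.validate()
    chrom: list = []
    features: list = []
    offset = 0
    for op in sorted(gtrn.operons.values(), key=lambda o: (o.rank, o.id)):
        segments: list = []  # (seq, feature_key, qualifiers)

        def prom_qualifiers(pid: str, role: str) -> dict:
            prom = gtrn.promoters[pid]
            q = {
                "label": [pid],
                "role": [role],
                "alpha": [_fmt_float(prom.alpha)],
                "constitutive": ["yes" if prom.is_constitutive else "no"],
                "part_key": [prom.region_ref or ""],
            }
            if prom.beta:
                q["beta"] = [_fmt_map(prom.beta)]
            if prom.gamma:
                q["gamma"] = [_fmt_map(prom.gamma)]
            if pid in gtrn.tandem_candidates:
                q["tandem_candidate"] = ["yes"]
            return q

        for pid in op.tandem_promoters:
            region = _store_get(gtrn, gtrn.promoters[pid].region_ref or "",
                                f"tandem promoter {pid!r}")
            segments.append((region, "promoter", prom_qualifiers(pid, "tandem")))
            segments.append(
                (isolation_spacer, "misc_feature",
                 {"role": ["isolation_spacer"]})
            )
        pid = op.primary_promoter
        region = _store_get(gtrn, gtrn.promoters[pid].region_ref or "",
                            f"primary promoter {pid!r}")
        segments.append((region, "promoter", prom_qualifiers(pid, "primary")))

        for idx, gid in enumerate(op.genes):
            gene = gtrn.genes[gid]
            native = idx == 0 or gene.native_operon == op.id
            if native:
                rbs = SequencePart(
                    key=gene.native_rbs_ref,
                    seq=_store_get(gtrn, gene.native_rbs_ref,
                                   f"gene {gid!r} RBS"),
                    role="rbs",
                )
            else:
                rbs = assign_rbs(gtrn, op, gene, rbs_policy,
                                 standard_rbs=standard_rbs)
            segments.append(
                (rbs.seq, "RBS",
                 {"part_key": [rbs.key],
                  "assigned": ["no" if native else "yes"]})
            )
            orf = prepare_orf(_store_get(gtrn, gene.orf_seq_ref,
                                         f"gene {gid!r} ORF"),
                              key=gene.orf_seq_ref)
            segments.append(
                (orf.seq, "CDS",
                 {
                     "gene": [gid],
                     "delta": [_fmt_float(gene.delta)],
                     "categories": [";".join(sorted(gene.categories))],
                     "functions": [";".join(sorted(gene.functions))],
                     "orig_strand": [gene.strand],
                     "native_operon": [gene.native_operon],
                     "part_key": [gene.orf_seq_ref],
                     "native_rbs": [gene.native_rbs_ref],
                 })
            )
        if op.terminator_ref:
            segments.append(
                (_store_get(gtrn, op.terminator_ref,
                            f"operon {op.id!r} terminator"),
                 "terminator", {"part_key": [op.terminator_ref]})
            )

        block = "".join(seq for seq, _, _ in segments)
        # local (start, end) of each segment on the coding strand
        spans = []
        pos = 0
        for seq, ftype, quals in segments:
            spans.append((pos, pos + len(seq), ftype, quals))
            pos += len(seq)
        if op.strand == "-":
            block = _revcomp(block)
            n = len(block)
            spans = [(n - e, n - s, ftype, quals)
                     for s, e, ftype, quals in spans]
        feat_strand = 1 if op.strand == "+" else -1
        features.append(
            SeqFeature(
                FeatureLocation(offset, offset + len(block), strand=feat_strand),
                type="operon",
                qualifiers={
                    "label": [op.id],
                    "rank": [str(op.rank)],
                    "primary_promoter": [op.primary_promoter],
                    "tandem_promoters": [";".join(op.tandem_promoters)],
                    "terminator_ref": [op.terminator_ref],
                },
            )
        )
        for s, e, ftype, quals in spans:
            features.append(
                SeqFeature(
                    FeatureLocation(offset + s, offset + e, strand=feat_strand),
                    type=ftype,
                    qualifiers=quals,
                )
            )
        chrom.append(block)
        offset += len(block)

    record = SeqRecord(
        Seq("".join(chrom)),
        id=record_id,
        name=record_id[:16],
        description="refactored genome compiled from a GTRN",
        features=features,
        annotations={
            "molecule_type": "DNA",
            "topology": "linear",
            "date": "01-JAN-1980",
            "data_file_division": "BCT",
        },
    )
    return record


def write_genbank(record: SeqRecord, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def write_fasta(record: SeqRecord, path) -> None:
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "fasta")


def genbank_bytes(record: SeqRecord) -> bytes:
    buf = _io.StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue().encode()


def _q1(feature: SeqFeature, key: str, default: str | None = None) -> str:
    vals = feature.qualifiers.get(key)
    if not vals:
        if default is not None:
            return default
        raise GenomeParseError(
            f"{feature.type} feature at {feature.location} lacks "
            f"qualifier {key!r}"
        )
    return vals[0]


def parse_genome(source) -> Gtrn:
    """Reconstruct a GTRN from a compiled GenBank record, file or handle.

    Accepts a :class:`SeqRecord`, a path, or a text handle.  Raises
    :class:`GenomeParseError` (with coordinates) on truncated files or
    annotation inconsistencies rather than returning a partial genome.
    """
    if isinstance(source, SeqRecord):
        record = source
    else:
        try:
            record = SeqIO.read(source, "genbank")
        except Exception as exc:  # Biopython raises bare ValueError
            raise GenomeParseError(f"cannot read GenBank input: {exc}") from exc

    genes: dict = {}
    operons: dict = {}
    promoters: dict = {}
    candidates: set = set()
    store: dict = {}

    def store_put(key: str, seq: str, where) -> None:
        if not key:
            raise GenomeParseError(f"feature at {where} has an empty part key")
        if key in store and store[key] != seq:
            raise GenomeParseError(
                f"part {key!r} at {where} conflicts with an earlier copy"
            )
        store[key] = seq

    op_feats = [f for f in record.features if f.type == "operon"]
    if not op_feats:
        raise GenomeParseError("no operon features found")
    op_feats.sort(key=lambda f: int(f.location.start))
    for op_feat in op_feats:
        o_start, o_end = int(op_feat.location.start), int(op_feat.location.end)
        strand = "+" if op_feat.location.strand >= 0 else "-"
        inner = [
            f for f in record.features
            if f.type in ("promoter", "RBS", "CDS", "terminator")
            and o_start <= int(f.location.start) and int(f.location.end) <= o_end
        ]
        inner.sort(key=lambda f: int(f.location.start),
                   reverse=(strand == "-"))
        prom_ids: list = []
        gene_ids: list = []
        pending_rbs: str | None = None
        for f in inner:
            seq = str(f.extract(record.seq))
            where = f"{int(f.location.start) + 1}..{int(f.location.end)}"
            if f.type == "promoter":
                pid = _q1(f, "label")
                prom = RegulatoryFunction(
                    alpha=float(_q1(f, "alpha")),
                    beta=_parse_map(_q1(f, "beta", "")),
                    gamma=_parse_map(_q1(f, "gamma", "")),
                    region_ref=_q1(f, "part_key"),
                )
                if pid in promoters and promoters[pid] != prom:
                    raise GenomeParseError(
                        f"promoter {pid!r} at {where} conflicts with an "
                        "earlier definition"
                    )
                promoters[pid] = prom
                if _q1(f, "tandem_candidate", "no") == "yes":
                    candidates.add(pid)
                store_put(prom.region_ref, seq, where)
                prom_ids.append(pid)
            elif f.type == "RBS":
                store_put(_q1(f, "part_key"), seq, where)
                pending_rbs = _q1(f, "part_key")
            elif f.type == "CDS":
                gid = _q1(f, "gene")
                if not seq.endswith("TAA"):
                    raise GenomeParseError(
                        f"CDS {gid!r} at {where} does not end in the "
                        "compiler-appended TAA stop"
                    )
                orf_key = _q1(f, "part_key")
                store_put(orf_key, seq[:-3], where)
                if pending_rbs is None:
                    raise GenomeParseError(
                        f"CDS {gid!r} at {where} is not preceded by an RBS"
                    )
                if gid in genes:
                    raise GenomeParseError(f"duplicate gene {gid!r} at {where}")
                cats = _q1(f, "categories", "")
                funcs = _q1(f, "functions", "")
                genes[gid] = Gene(
                    id=gid,
                    delta=float(_q1(f, "delta")),
                    categories=frozenset(c for c in cats.split(";") if c),
                    functions=frozenset(c for c in funcs.split(";") if c),
                    orf_seq_ref=orf_key,
                    native_rbs_ref=_q1(f, "native_rbs"),
                    strand=_q1(f, "orig_strand"),
                    native_operon=_q1(f, "native_operon"),
                )
                gene_ids.append(gid)
                pending_rbs = None
            else:  # terminator
                store_put(_q1(f, "part_key"), seq, where)

        oid = _q1(op_feat, "label")
        declared_primary = _q1(op_feat, "primary_promoter")
        declared_tandem = [
            p for p in _q1(op_feat, "tandem_promoters", "").split(";") if p
        ]
        if not prom_ids or prom_ids[-1] != declared_primary or \
                prom_ids[:-1] != declared_tandem:
            raise GenomeParseError(
                f"operon {oid!r} at {o_start + 1}..{o_end}: promoter features "
                f"{prom_ids} disagree with the operon annotation"
            )
        if not gene_ids:
            raise GenomeParseError(f"operon {oid!r} contains no CDS")
        if oid in operons:
            raise GenomeParseError(f"duplicate operon {oid!r}")
        operons[oid] = Operon(
            id=oid,
            genes=gene_ids,
            primary_promoter=declared_primary,
            tandem_promoters=declared_tandem,
            terminator_ref=_q1(op_feat, "terminator_ref", ""),
            strand=strand,
            rank=int(_q1(op_feat, "rank")),
        )

    gtrn = Gtrn(
        genes=genes,
        operons=operons,
        promoters=promoters,
        tandem_candidates=candidates,
        sequence_store=store,
    )
    try:
        gtrn.validate()
    except ValidationError as exc:
        raise GenomeParseError(str(exc)) from exc
    return gtrn
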