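"""Annotated allele database for star-allele gene families.

Builds a PharmVar-style database from a plain multi-FASTA of allele
sequences: every allele is anchored to its gene's reference allele by
global alignment, the resulting edit script is stored as a variant list,
and each variant is classified as *core* (required to distinguish the
functionality encoded by the first three name digits) or *silent*.

Coordinates are 0-based half-open on the gene's reference-allele
sequence.  Variant operations are one of ``"X>Y"`` (substitution),
``"ins<SEQ>"`` (insertion before the stated position) and ``"del<N>"``
(deletion of N bases starting at the stated position).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "Variant",
    "Allele",
    "Gene",
    "AlleleDB",
    "DatabaseError",
    "derive_variants",
    "apply_variants",
    "classify_core",
    "load_db",
    "save_db",
]

# Global-alignment scoring used for reference anchoring.  Ties are broken
# by the aligner's deterministic enumeration order, which places gaps
# leftmost on the target.
MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1

# Records shorter than this fraction of the reference are treated as
# partial (e.g. coding-only) sequences and imputed onto the reference
# backbone.
PARTIAL_FRACTION = 0.8

_NAME_RE = re.compile(r"^(?P<gene>[A-Za-z0-9_.-]+)\*(?P<digits>\d{3}|\d{5}|\d{7})$")


class DatabaseError(ValueError):
    """Raised for malformed allele databases or unparsable records."""


@dataclass(frozen=True)
class Variant:
    """A single edit relative to the gene's reference allele.

    ``is_core`` does not participate in equality/hashing so that the same
    edit observed in different alleles compares equal regardless of its
    classification state.
    """

    location: int
    op: str
    is_core: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.location < 0:
            raise ValueError(f"negative variant location {self.location}")
        if self.kind == "sub":
            ref, alt = self.op.split(">")
            if ref == alt:
                raise ValueError(f"substitution {self.op} is a no-op")

    @property
    def kind(self) -> str:
        if ">" in self.op:
            return "sub"
        if self.op.startswith("ins"):
            return "ins"
        if self.op.startswith("del"):
            return "del"
        raise ValueError(f"unrecognized operation {self.op!r}")

    @property
    def key(self) -> tuple[int, str]:
        return (self.location, self.op)

    @property
    def del_length(self) -> int:
        return int(self.op[3:]) if self.kind == "del" else 0

    @property
    def ins_seq(self) -> str:
        return self.op[3:] if self.kind == "ins" else ""


@dataclass
class Allele:
    gene_id: str
    name: str  # digit string, 3/5/7 digits
    sequence: str
    variants: set[Variant] = field(default_factory=set)
    is_reference: bool = False
    imputed_spans: list[tuple[int, int]] = field(default_factory=list)
    # optional exon coordinates (reference-anchored); informational only —
    # core classification is name-structural and never consults them
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def major(self) -> str:
        """Three-digit functional (major-allele) prefix."""
        return self.name[:3]

    @property
    def full_name(self) -> str:
        return f"{self.gene_id}*{self.name}"

    def lift(self, ref_pos: int) -> int | None:
        """Map a reference-allele position onto this allele's sequence.

        Returns ``None`` when the position falls inside a deletion.
        Substitutions do not shift coordinates; insertions and deletions
        upstream of ``ref_pos`` shift it by their net length.
        """
        shift = 0
        for v in sorted(self.variants, key=lambda v: v.location):
            if v.kind == "ins":
                if v.location <= ref_pos:
                    shift += len(v.ins_seq)
            elif v.kind == "del":
                if v.location + v.del_length <= ref_pos:
                    shift -= v.del_length
                elif v.location <= ref_pos:
                    return None
        return ref_pos + shift


@dataclass
class Gene:
    gene_id: str
    alleles: list[Allele]
    variants: set[Variant] = field(default_factory=set)
    core_locations: set[int] = field(default_factory=set)

    @property
    def reference(self) -> Allele:
        return self.alleles[0]

    def allele_by_name(self, name: str) -> Allele:
        for a in self.alleles:
            if a.name == name or a.full_name == name:
                return a
        raise KeyError(name)


@dataclass
class AlleleDB:
    genes: list[Gene]
    locus_reference: str | None = None

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def all_alleles(self) -> list[Allele]:
        return [a for g in self.genes for a in g.alleles]


def _aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="global",
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )


def derive_variants(ref_seq: str, allele_seq: str) -> set[Variant]:
    """Derive the edit script turning ``ref_seq`` into ``allele_seq``.

    One optimal global alignment under the module's fixed scoring scheme
    is decomposed into substitutions, insertions and deletions.  Applying
    the returned set left-to-right to ``ref_seq`` reconstructs
    ``allele_seq`` exactly (see :func:`apply_variants`).
    """
    if not ref_seq or not allele_seq:
        raise DatabaseError("cannot derive variants from an empty sequence")
    if ref_seq == allele_seq:
        return set()
    aln = _aligner().align(ref_seq, allele_seq)[0]
    variants: set[Variant] = set()
    tblocks, qblocks = aln.aligned
    prev_t = prev_q = 0
    for (tstart, tend), (qstart, qend) in zip(tblocks.tolist(), qblocks.tolist()):
        if tstart > prev_t and qstart > prev_q:
            # simultaneous gap on both sides: decompose as del + ins
            variants.add(Variant(prev_t, f"del{tstart - prev_t}"))
            variants.add(Variant(tstart, f"ins{allele_seq[prev_q:qstart]}"))
        elif tstart > prev_t:
            variants.add(Variant(prev_t, f"del{tstart - prev_t}"))
        elif qstart > prev_q:
            variants.add(Variant(tstart, f"ins{allele_seq[prev_q:qstart]}"))
        for off in range(tend - tstart):
            r, a = ref_seq[tstart + off], allele_seq[qstart + off]
            if r != a:
                variants.add(Variant(tstart + off, f"{r}>{a}"))
        prev_t, prev_q = tend, qend
    if prev_t < len(ref_seq):
        variants.add(Variant(prev_t, f"del{len(ref_seq) - prev_t}"))
    if prev_q < len(allele_seq):
        variants.add(Variant(len(ref_seq), f"ins{allele_seq[prev_q:]}"))
    return variants


def apply_variants(ref_seq: str, variants: set[Variant] | list[Variant]) -> str:
    """Apply a variant set to a reference sequence.

    Variants are applied in position order; at equal positions insertions
    are emitted before the (possibly substituted) reference base, matching
    the convention used by :func:`derive_variants`.
    """
    order = {"ins": 0, "sub": 1, "del": 1}
    events = sorted(variants, key=lambda v: (v.location, order[v.kind]))
    out: list[str] = []
    pos = 0
    for v in events:
        if v.location < pos:
            raise DatabaseError(f"overlapping variants at {v.location}")
        out.append(ref_seq[pos : v.location])
        pos = v.location
        if v.kind == "ins":
            out.append(v.ins_seq)
        elif v.kind == "sub":
            out.append(v.op.split(">")[1])
            pos += 1
        else:
            pos += v.del_length
    out.append(ref_seq[pos:])
    return "".join(out)


def _group_key_sets(alleles: list[Allele]) -> dict[str, set[tuple[int, str]]]:
    """Per 3-digit group, the intersection of member variant key sets."""
    groups: dict[str, set[tuple[int, str]]] = {}
    for a in alleles:
        keys = {v.key for v in a.variants}
        if a.major in groups:
            groups[a.major] &= keys
        else:
            groups[a.major] = set(keys)
    return groups


def classify_core(gene: Gene) -> Gene:
    """Mark core variants from the 3-digit star-allele name structure.

    A variant is core iff it is shared by every member of some 3-digit
    (major allele) group and absent from the reference group's consensus:
    these are exactly the edits required to distinguish that group's
    functionality.  Everything else is silent.  The marking is a pure
    function of names and variant sets, hence deterministic.
    """
    for a in gene.alleles:
        if not _NAME_RE.match(f"{a.gene_id}*{a.name}") and len(a.name) not in (3, 5, 7):
            raise DatabaseError(f"unparsable allele name {a.gene_id}*{a.name}")
    groups = _group_key_sets(gene.alleles)
    ref_major = gene.reference.major
    ref_consensus = groups.get(ref_major, set())
    core_keys: set[tuple[int, str]] = set()
    for major, shared in groups.items():
        if major == ref_major:
            continue
        core_keys |= shared - ref_consensus

    def flag(vs: set[Variant]) -> set[Variant]:
        return {replace(v, is_core=v.key in core_keys) for v in vs}

    for a in gene.alleles:
        a.variants = flag(a.variants)
    gene.variants = flag(gene.variants) if gene.variants else {
        v for a in gene.alleles for v in a.variants
    }
    gene.core_locations = {v.location for v in gene.variants if v.is_core}
    return gene


def _parse_record_name(name: str, name_map: dict | None) -> tuple[str, str]:
    if name_map and name in name_map:
        return name_map[name]
    m = _NAME_RE.match(name)
    if not m:
        raise DatabaseError(f"record name {name!r} does not follow GENE*digits convention")
    return m.group("gene"), m.group("digits")


def _impute_partial(ref_seq: str, fragment: str) -> tuple[str, list[tuple[int, int]]]:
    """Place a partial (e.g. coding-only) sequence on the reference backbone.

    The fragment is locally aligned to the reference; flanks outside the
    aligned span are copied from the reference and reported as imputed.
    """
    aligner = _aligner()
    aligner.mode = "local"
    aln = aligner.align(ref_seq, fragment)[0]
    tblocks, qblocks = aln.aligned
    tstart, tend = int(tblocks[0][0]), int(tblocks[-1][1])
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    full = ref_seq[:tstart] + fragment[qstart:qend] + ref_seq[tend:]
    spans = []
    if tstart > 0:
        spans.append((0, tstart))
    if tend < len(ref_seq):
        spans.append((tend, len(ref_seq)))
    return full, spans


def _pick_reference_name(names: list[str]) -> str:
    in_001 = sorted(n for n in names if n.startswith("001"))
    return in_001[0] if in_001 else sorted(names)[0]


def load_exon_table(tsv_path: str | Path) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Parse the optional exon TSV (gene_id, allele_name, exon_coords with
    comma-separated start-end pairs)."""
    out: dict[tuple[str, str], list[tuple[int, int]]] = {}
    with open(tsv_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("gene"):
                continue
            gene_id, allele_name, coords = line.rstrip("\n").split("\t")[:3]
            spans = []
            for part in coords.split(","):
                a, b = part.split("-")
                spans.append((int(a), int(b)))
            out[(gene_id, allele_name)] = spans
    return out


def load_db(
    fasta_path: str | Path,
    name_map: dict | None = None,
    locus_reference: str | None = None,
    exon_tsv: str | Path | None = None,
) -> AlleleDB:
    """Build an :class:`AlleleDB` from a multi-FASTA of allele sequences.

    Record names must read ``GENE*DIGITS`` (3, 5 or 7 digits) unless
    overridden through ``name_map``.  Within each gene the reference
    anchor is the lexicographically smallest *001-family allele (or the
    smallest name if no *001 exists).  Records much shorter than the
    reference are imputed onto the reference backbone and their imputed
    spans recorded.  Problematic records are collected and reported
    together rather than silently dropped.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise DatabaseError(f"no FASTA records in {fasta_path}")
    by_gene: dict[str, dict[str, str]] = {}
    problems: list[str] = []
    for rec in records:
        try:
            gene_id, digits = _parse_record_name(rec.id, name_map)
        except DatabaseError as exc:
            problems.append(str(exc))
            continue
        seqs = by_gene.setdefault(gene_id, {})
        if digits in seqs:
            problems.append(f"duplicate allele {gene_id}*{digits}")
            continue
        seqs[digits] = str(rec.seq).upper()
    if problems:
        raise DatabaseError("; ".join(problems))

    exon_table = load_exon_table(exon_tsv) if exon_tsv else {}
    genes: list[Gene] = []
    for gene_id in sorted(by_gene):
        seqs = by_gene[gene_id]
        ref_name = _pick_reference_name(list(seqs))
        ref_seq = seqs[ref_name]
        alleles = [Allele(gene_id, ref_name, ref_seq, set(), is_reference=True)]
        for name in sorted(seqs):
            if name == ref_name:
                continue
            seq = seqs[name]
            imputed: list[tuple[int, int]] = []
            if len(seq) < PARTIAL_FRACTION * len(ref_seq):
                seq, imputed = _impute_partial(ref_seq, seq)
            variants = derive_variants(ref_seq, seq)
            alleles.append(Allele(gene_id, name, seq, variants, imputed_spans=imputed))
        for a in alleles:
            a.exons = exon_table.get((gene_id, a.name), [])
        gene = Gene(gene_id, alleles)
        gene.variants = {v for a in alleles for v in a.variants}
        genes.append(classify_core(gene))
    return AlleleDB(genes, locus_reference=locus_reference)


def save_db(db: AlleleDB, outdir: str | Path) -> None:
    """Serialize the database: per-gene FASTA plus a variant table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "variants.tsv", "w") as tsv:
        tsv.write("gene\tallele\tpos\top\tcore\n")
        for gene in db.genes:
            with open(outdir / f"{gene.gene_id}.fasta", "w") as fa:
                for a in gene.alleles:
                    fa.write(f">{a.full_name}\n{a.sequence}\n")
            for a in gene.alleles:
                for v in sorted(a.variants, key=lambda v: v.key):
                    tsv.write(
                        f"{gene.gene_id}\t{a.name}\t{v.location}\t{v.op}\t{int(v.is_core)}\n"
                    )


def validate_db(db: AlleleDB) -> None:
    """Assert the round-trip invariant over the whole database."""
    for gene in db.genes:
        ref = gene.reference.sequence
        for a in gene.alleles:
            rebuilt = apply_variants(ref, a.variants)
            if rebuilt != a.sequence:
                raise DatabaseError(
                    f"variant round-trip failed for {a.full_name}"
                )
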