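"""Stage 1: exhaustive read-to-allele alignment and coverage calibration.

Every read is aligned against every allele sequence in the database and
*all* plausible placements are retained — in a locus of mutually similar
paralogs most reads align to many alleles across many genes, and the
ambiguity is resolved only by the downstream optimization, never here.

The built-in aligner is a seed-and-extend scheme with an exact guarantee:
a read chunked into ``max_edits + 1`` non-overlapping seeds must place at
least one seed exactly wherever the read aligns with at most ``max_edits``
errors (pigeonhole), so no admissible placement is missed.  A placement
is reported at start position ``s`` when the semi-global edit distance
``d(s)`` (read fully consumed, alignment anchored at ``s`` on the allele)
is at most ``max_edits`` and is a leftmost local minimum of ``d`` — the
canonical representative of the run of equivalent shifted alignments.

Coverage calibration aligns the same reads to a copy-number-neutral
region and converts its depth into the expected per-haploid-copy depth
``xi`` used by the copy-number model.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .alleledb import AlleleDB, Allele

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "Hit",
    "ReadHits",
    "CoverageModel",
    "load_reads",
    "all_hits",
    "filter_hits",
    "estimate_xi",
]

# Alignment scoring shared with the database anchoring step: a gap of
# length k costs GAP_OPEN + (k-1) * GAP_EXTEND.
MATCH = 1
MISMATCH = 2
GAP_OPEN = 4
GAP_EXTEND = 1

_CIG_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str


@dataclass
class Hit:
    """One placement of a read on one allele sequence."""

    read_id: str
    gene_id: str
    allele_index: int
    start: int  # 0-based on the allele sequence
    matches: int  # p: matching bases
    aligned_len: int  # l: read bases placed on the allele
    edit_ops: str  # =/X/I/D run-length string (read vs allele)
    score: int
    clipped_bases: int = 0
    clip_left: int = 0  # read bases clipped before `start`

    @property
    def end(self) -> int:
        """End (exclusive) on the allele: start + reference-consumed length."""
        consumed = 0
        for n, op in _CIG_RE.findall(self.edit_ops):
            if op in "=XD":
                consumed += int(n)
        return self.start + consumed

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def difference_spans(self) -> list[tuple[int, int]]:
        """Allele-coordinate spans where the read differs from the allele.

        Mismatches yield length-1 spans; deletions their own span; an
        insertion in the read yields the length-1 span of the allele
        position it interrupts.
        """
        spans = []
        pos = self.start
        for n, op in _CIG_RE.findall(self.edit_ops):
            n = int(n)
            if op == "=":
                pos += n
            elif op == "X":
                spans.append((pos, pos + n))
                pos += n
            elif op == "D":
                spans.append((pos, pos + n))
                pos += n
            else:  # I: read insertion between allele positions
                spans.append((pos, pos + 1))
        return spans


@dataclass
class ReadHits:
    read_id: str
    sequence: str
    hits: list[Hit] = field(default_factory=list)

    def multiplicity(self, gene_id: str, allele_index: int) -> int:
        """m_ki: the number of valid placements on one allele."""
        return sum(
            1 for h in self.hits if h.gene_id == gene_id and h.allele_index == allele_index
        )

    def best_hit(self, gene_id: str, allele_index: int) -> Hit | None:
        cands = [
            h for h in self.hits if h.gene_id == gene_id and h.allele_index == allele_index
        ]
        return max(cands, key=lambda h: (h.score, -h.start)) if cands else None


@dataclass
class CoverageModel:
    xi: float  # expected depth contributed by a single allele copy
    neutral_region_id: str = "neutral"

    def __post_init__(self) -> None:
        if not self.xi > 0:
            raise ValueError("xi must be positive")


# ---------------------------------------------------------------------------
# read input


def load_reads(path: str | Path) -> list[Read]:
    """Load reads from FASTQ (optionally gzipped) or SAM/BAM/CRAM.

    For alignment files every record of a read is collapsed to one entry;
    name-sorting is not required.
    """
    path = Path(path)
    suffixes = {s.lower() for s in path.suffixes}
    if suffixes & {".sam", ".bam", ".cram"}:
        import pysam

        seen: dict[str, str] = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_secondary or rec.is_supplementary or rec.query_sequence is None:
                    continue
                name = rec.query_name
                if rec.is_paired:
                    name = f"{name}/{1 if rec.is_read1 else 2}"
                seq = rec.query_sequence
                if rec.is_reverse:
                    seq = _revcomp(seq)
                seen.setdefault(name, seq)
        return [Read(n, s) for n, s in seen.items()]
    opener = gzip.open if ".gz" in suffixes else open
    reads = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip().upper()
            fh.readline()
            fh.readline()
            reads.append(Read(header[1:].split()[0], seq))
    return reads


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# built-in seed-and-extend aligner


class KmerIndex:
    """Exact k-mer index over a set of target sequences."""

    def __init__(self, targets: list[tuple[str, int, str]], k: int):
        # targets: (gene_id, allele_index, sequence)
        self.k = k
        self.targets = targets
        self.index: dict[str, list[tuple[int, int]]] = {}
        for t, (_, _, seq) in enumerate(targets):
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((t, pos))

    def seed_diagonals(self, read: str) -> set[tuple[int, int]]:
        """Candidate (target, diagonal) pairs from non-overlapping seeds."""
        k = self.k
        out: set[tuple[int, int]] = set()
        if len(read) < k:
            return out
        offsets = list(range(0, len(read) - k + 1, k))
        if offsets and offsets[-1] != len(read) - k:
            offsets.append(len(read) - k)
        for off in offsets:
            for t, pos in self.index.get(read[off : off + k], ()):
                out.add((t, pos - off))
        return out


def _shw_distance(read: str, target: str, start: int, max_edits: int):
    """Semi-global distance of `read` anchored at `start` on `target`.

    The read must be fully consumed; the alignment starts exactly at
    ``start`` and may end anywhere within the lookahead window.  Returns
    (distance, cigar) with distance None when it exceeds ``max_edits``.
    """
    window = target[start : start + len(read) + max_edits]
    if len(window) < len(read) - max_edits:
        return None, None
    res = edlib.align(read, window, mode="SHW", task="path", k=max_edits)
    if res["editDistance"] < 0:
        return None, None
    return res["editDistance"], res["cigar"]


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, read_bases_consumed, score) from an =/X/I/D cigar."""
    matches = read_len = 0
    score = 0
    for n, op in _CIG_RE.findall(cigar):
        n = int(n)
        if op == "=":
            matches += n
            read_len += n
            score += MATCH * n
        elif op == "X":
            read_len += n
            score -= MISMATCH * n
        else:
            if op == "I":
                read_len += n
            score -= GAP_OPEN + GAP_EXTEND * (n - 1)
    return matches, read_len, score


def _align_read_to_target(
    read: str,
    gene_id: str,
    allele_index: int,
    target: str,
    diagonals: set[int],
    max_edits: int,
    read_id: str,
) -> list[Hit]:
    """Evaluate candidate diagonals; emit hits at leftmost local minima of d."""
    hits: list[Hit] = []
    rl = len(read)
    # Fast path: exact placement at the seeded diagonal.
    exact_starts = set()
    scan_diags = []
    for g in diagonals:
        if 0 <= g <= len(target) - rl and target[g : g + rl] == read:
            exact_starts.add(g)
        else:
            scan_diags.append(g)
    for s in sorted(exact_starts):
        hits.append(Hit(read_id, gene_id, allele_index, s, rl, rl, f"{rl}=", MATCH * rl))

    cache: dict[int, tuple] = {}

    def dist(s: int):
        if s in cache:
            return cache[s]
        if s < 0 or s >= len(target):
            cache[s] = (None, None)
        else:
            cache[s] = _shw_distance(read, target, s, max_edits)
        return cache[s]

    starts_done = set(exact_starts)
    for g in scan_diags:
        lo, hi = g - max_edits, g + max_edits
        # one infix alignment over the whole neighborhood window: if even
        # its best placement exceeds the edit budget, no start in
        # [lo, hi] can harbor a hit and the per-start scan is skipped
        wlo = max(0, lo)
        window = target[wlo : hi + rl + max_edits]
        probe = edlib.align(read, window, mode="HW", k=max_edits)
        if probe["editDistance"] < 0:
            continue
        for s in range(lo, hi + 1):
            if s in starts_done:
                continue
            d, cig = dist(s)
            if d is None or d == 0 and s in exact_starts:
                continue
            dl = dist(s - 1)[0]
            dr = dist(s + 1)[0]
            left_ok = dl is None or dl > d
            right_ok = dr is None or dr >= d
            if left_ok and right_ok:
                starts_done.add(s)
                matches, rb, score = _cigar_stats(cig)
                hits.append(
                    Hit(read_id, gene_id, allele_index, s, matches, rb, cig, score)
                )
    return hits


def _clipped_hits(
    read: str,
    gene_id: str,
    allele_index: int,
    target: str,
    diagonals: set[int],
    max_edits: int,
    read_id: str,
) -> list[Hit]:
    """Placements hanging off either allele end; overhang is soft-clipped."""
    hits = []
    rl = len(read)
    for g in sorted(diagonals):
        clip_left = max(0, -g)
        clip_right = max(0, g + rl - len(target))
        if clip_left == 0 and clip_right == 0:
            continue
        core = read[clip_left : rl - clip_right]
        if len(core) < max_edits + 2:
            continue
        s = max(0, g)
        sub_edits = min(max_edits, max(1, len(core) // 10))
        d, cig = _shw_distance(core, target, s, sub_edits)
        if d is None:
            continue
        matches, rb, score = _cigar_stats(cig)
        hits.append(
            Hit(
                read_id,
                gene_id,
                allele_index,
                s,
                matches,
                rb,
                cig,
                score,
                clipped_bases=clip_left + clip_right,
                clip_left=clip_left,
            )
        )
    return hits


class BuiltinAligner:
    """Seed-and-extend all-hits aligner over an allele database."""

    def __init__(self, db: AlleleDB, seed_len: int = 14, max_edits: int | None = None):
        self.seed_len = seed_len
        self.max_edits = max_edits
        targets = [
            (g.gene_id, i, a.sequence)
            for g in db.genes
            for i, a in enumerate(g.alleles)
        ]
        self.targets = targets
        self.index = KmerIndex(targets, seed_len)

    def _edits_for(self, read_len: int) -> int:
        if self.max_edits is not None:
            return self.max_edits
        return max(1, read_len // self.seed_len - 1)

    def align(self, read: Read) -> list[Hit]:
        max_edits = self._edits_for(len(read.sequence))
        hits: list[Hit] = []
        for strand, seq in (("+", read.sequence), ("-", _revcomp(read.sequence))):
            per_target: dict[int, set[int]] = {}
            for t, diag in self.index.seed_diagonals(seq):
                per_target.setdefault(t, set()).add(diag)
            for t, diags in per_target.items():
                gene_id, allele_index, target = self.targets[t]
                interior = {g for g in diags if 0 <= g <= len(target) - len(seq)}
                boundary = diags - interior
                hits.extend(
                    _align_read_to_target(
                        seq, gene_id, allele_index, target, interior, max_edits, read.read_id
                    )
                )
                hits.extend(
                    _clipped_hits(
                        seq, gene_id, allele_index, target, boundary, max_edits, read.read_id
                    )
                )
        return hits


def all_hits(
    reads: list[Read],
    db: AlleleDB,
    engine: str | BuiltinAligner = "builtin",
    seed_len: int = 14,
    max_edits: int | None = None,
) -> list[ReadHits]:
    """Align every read against every allele; keep all placements.

    ``engine`` is ``"builtin"`` (default), a pre-built
    :class:`BuiltinAligner`, or ``"minimap2"`` for the external adapter.
    Hit ordering is deterministic: (read order, gene, allele, start).
    """
    if engine == "minimap2":
        from .extalign import minimap2_all_hits

        return minimap2_all_hits(reads, db)
    if engine == "builtin":
        engine = BuiltinAligner(db, seed_len=seed_len, max_edits=max_edits)
    elif not isinstance(engine, BuiltinAligner):
        raise ValueError(
            f"unknown alignment engine {engine!r}; use 'builtin' (no external "
            "binary required) or 'minimap2'"
        )
    out = []
    for read in reads:
        hits = engine.align(read)
        hits.sort(key=lambda h: (h.gene_id, h.allele_index, h.start))
        if hits:
            out.append(ReadHits(read.read_id, read.sequence, hits))
    return out


def write_hits_sam(
    read_hits: list[ReadHits], db: AlleleDB, path: str | Path
) -> None:
    """Debug dump: all hits as SAM records against per-allele references.

    The first hit of each read is primary; further placements are
    flagged secondary.  Alignments are encoded with =/X/I/D plus
    soft-clips, so the dump is directly inspectable with samtools.
    """
    import pysam

    refs = [(a.full_name, len(a.sequence)) for g in db.genes for a in g.alleles]
    rid = {name: i for i, (name, _) in enumerate(refs)}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in refs],
    }
    name_of = {
        (g.gene_id, i): a.full_name
        for g in db.genes
        for i, a in enumerate(g.alleles)
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rh in read_hits:
            for n, h in enumerate(rh.hits):
                rec = pysam.AlignedSegment()
                rec.query_name = rh.read_id
                rec.reference_id = rid[name_of[(h.gene_id, h.allele_index)]]
                rec.reference_start = h.start
                rec.mapping_quality = 0
                rec.flag = 0x100 if n else 0
                cigar = h.edit_ops
                if h.clip_left:
                    cigar = f"{h.clip_left}S" + cigar
                clip_right = h.clipped_bases - h.clip_left
                if clip_right:
                    cigar += f"{clip_right}S"
                rec.cigarstring = cigar
                if n == 0:
                    rec.query_sequence = rh.sequence
                rec.set_tag("AS", h.score)
                out.write(rec)


# ---------------------------------------------------------------------------
# Stage-1 filters


def _core_positions_by_allele(db: AlleleDB) -> dict[tuple[str, int], set[int]]:
    """Gene core locations lifted into each allele's own coordinates."""
    lifted: dict[tuple[str, int], set[int]] = {}
    for gene in db.genes:
        for i, allele in enumerate(gene.alleles):
            pos = set()
            for loc in gene.core_locations:
                p = allele.lift(loc)
                if p is not None:
                    pos.add(p)
            lifted[(gene.gene_id, i)] = pos
    return lifted


def filter_hits(
    read_hits: list[ReadHits],
    db: AlleleDB,
    min_score_frac: float = 0.85,
    max_clip_frac: float = 0.25,
) -> list[ReadHits]:
    """Discard hits that contradict core variants, are severely clipped,
    or score poorly.

    A hit *contradicts* an allele's core state when its edit string
    places a difference (mismatch or indel) overlapping a core location
    of that allele: the read then disagrees with the allele's defined
    base at a functionality-bearing site.  Reads left with no hits are
    dropped with a logged count.
    """
    lifted = _core_positions_by_allele(db)
    out: list[ReadHits] = []
    dropped_reads = 0
    for rh in read_hits:
        survivors = []
        read_len = len(rh.sequence)
        for h in rh.hits:
            if h.clipped_bases / read_len > max_clip_frac:
                continue
            max_attainable = MATCH * (read_len - h.clipped_bases)
            if h.score < min_score_frac * max_attainable:
                continue
            core_pos = lifted[(h.gene_id, h.allele_index)]
            if core_pos and any(
                any(a <= p < b for p in core_pos) for a, b in h.difference_spans()
            ):
                continue
            survivors.append(h)
        if survivors:
            out.append(ReadHits(rh.read_id, rh.sequence, survivors))
        else:
            dropped_reads += 1
    if dropped_reads:
        logger.info("filter_hits: dropped %d reads with no surviving hits", dropped_reads)
    return out


# ---------------------------------------------------------------------------
# coverage calibration


def estimate_xi(
    reads: list[Read],
    neutral_fasta: str | Path | tuple[str, str],
    copy_number: int = 2,
    seed_len: int = 14,
    max_edits: int | None = None,
) -> CoverageModel:
    """Estimate expected per-copy depth from a copy-number-neutral region.

    ``xi`` is the median per-position depth over the neutral region
    divided by its copy number (2 for an autosomal diploid region), i.e.
    the depth one haploid allele copy is expected to contribute.
    """
    if isinstance(neutral_fasta, tuple):
        region_id, seq = neutral_fasta
    else:
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(neutral_fasta), "fasta"))
        region_id, seq = rec.id, str(rec.seq).upper()
    if reads and len(seq) < 10 * len(reads[0].sequence):
        raise ValueError("neutral region must be at least 10x the read length")
    fake_db = _single_target_db(region_id, seq)
    depth = np.zeros(len(seq), dtype=np.int64)
    aligner = BuiltinAligner(fake_db, seed_len=seed_len, max_edits=max_edits)
    for read in reads:
        for h in aligner.align(read):
            depth[h.start : h.end] += 1
    med = float(np.median(depth))
    if med <= 0:
        raise ValueError("no coverage on the copy-number-neutral region")
    return CoverageModel(xi=med / copy_number, neutral_region_id=region_id)


def _single_target_db(region_id: str, seq: str) -> AlleleDB:
    from .alleledb import AlleleDB, Gene

    allele = Allele(region_id, "001", seq, set(), is_reference=True)
    return AlleleDB([Gene(region_id, [allele])])
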