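"""Stage 2a: deterministic allele filtering and landmark generation.

Candidate alleles must show adequate read support at every
functionality-bearing (core) site.  The retained, core-relevant read
placements are then organized into per-allele overlap graphs whose
connected components delimit *landmark regions*; the gene's core
locations, augmented with a minimal set of extra positions (greedy
interval point-stabbing, optimal in one dimension), become the landmark
location set L_g at which coverage is later scored.  The point of the
augmentation is that paralogous alleles without core variants of their
own must still be able to "catch" reads that cover core variants
elsewhere — otherwise every ambiguous read would be forced onto the
variant-bearing allele.

The overlap relation between placements is symmetric, so the strongly
connected components of the (conceptually directed) overlap graph are
exactly the connected components of its undirected counterpart; we
compute the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .alleledb import AlleleDB, Allele
from .align import Hit, ReadHits

__all__ = [
    "LandmarkSet",
    "coverage_prefilter",
    "build_overlap_graph",
    "landmark_regions",
    "greedy_stab",
    "project_landmarks",
    "generate_landmarks",
    "select_landmark_hits",
]


@dataclass
class LandmarkSet:
    gene_id: str
    locations: list[int]  # reference-allele coordinates, sorted
    region_spans: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    # region_spans keyed by allele index, spans in allele coordinates

    def lifted(self, allele: Allele) -> list[int]:
        out = []
        for loc in self.locations:
            p = lift_or_junction(allele, loc)
            if p is not None:
                out.append(p)
        return sorted(set(out))


def lift_or_junction(allele: Allele, ref_pos: int) -> int | None:
    """Lift a reference position; positions inside a deletion map to the
    deletion junction so that reads spanning the junction still count."""
    p = allele.lift(ref_pos)
    if p is not None:
        return p
    for v in sorted(allele.variants, key=lambda v: v.location):
        if v.kind == "del" and v.location <= ref_pos < v.location + v.del_length:
            if v.location == 0:
                return 0
            left = allele.lift(v.location - 1)
            return None if left is None else left + 1
    return None


def unlift(allele: Allele, allele_pos: int) -> int:
    """Inverse coordinate lift: map an allele position back to the
    reference allele.  Positions inside an insertion map to the
    insertion's anchor location."""
    shift = 0
    for v in sorted(allele.variants, key=lambda v: v.location):
        a_loc = v.location + shift
        if v.kind == "ins":
            n = len(v.ins_seq)
            if allele_pos >= a_loc + n:
                shift += n
            elif allele_pos >= a_loc:
                return v.location
        elif v.kind == "del":
            if a_loc <= allele_pos:
                shift -= v.del_length
    return allele_pos - shift


# ---------------------------------------------------------------------------
# coverage prefilter


def _hits_by_allele(read_hits: list[ReadHits]) -> dict[tuple[str, int], list[Hit]]:
    out: dict[tuple[str, int], list[Hit]] = {}
    for rh in read_hits:
        for h in rh.hits:
            out.setdefault((h.gene_id, h.allele_index), []).append(h)
    return out


def coverage_prefilter(
    read_hits: list[ReadHits], db: AlleleDB, min_cov: int = 3
) -> dict[str, set[int]]:
    """Retain alleles whose every core site has >= min_cov agreeing reads.

    Stage-1 filtering already removed placements that contradict an
    allele's core state, so any retained placement covering a core site
    agrees with the allele there.  Alleles without a core variant at a
    gene core location must likewise show >= min_cov reads supporting
    their (reference) state at that site.  Returns surviving allele
    indices per gene; reference alleles of genes with no core locations
    survive trivially.
    """
    by_allele = _hits_by_allele(read_hits)
    surviving: dict[str, set[int]] = {}
    for gene in db.genes:
        keep: set[int] = set()
        for i, allele in enumerate(gene.alleles):
            hits = by_allele.get((gene.gene_id, i), [])
            ok = True
            for loc in gene.core_locations:
                p = lift_or_junction(allele, loc)
                if p is None:
                    ok = False
                    break
                cov = sum(1 for h in hits if h.start <= p < h.end)
                if cov < min_cov:
                    ok = False
                    break
            if min_cov == 0 or (ok and (gene.core_locations or hits)):
                keep.add(i)
        surviving[gene.gene_id] = keep
    return surviving


# ---------------------------------------------------------------------------
# overlap graphs and landmark regions


def build_overlap_graph(relevant_hits: list[Hit]) -> nx.Graph:
    """Undirected graph over placements; edge iff intervals intersect.

    Built with a left-to-right sweep instead of all-pairs testing; node
    labels are indices into ``relevant_hits``.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(relevant_hits)))
    order = sorted(range(len(relevant_hits)), key=lambda i: relevant_hits[i].start)
    active: list[int] = []
    for i in order:
        s, e = relevant_hits[i].interval()
        active = [j for j in active if relevant_hits[j].end > s]
        g.add_edges_from((i, j) for j in active)
        active.append(i)
    return g


def landmark_regions(graph: nx.Graph, hits: list[Hit]) -> list[tuple[int, int]]:
    """Connected components' spans: union of member hit intervals."""
    spans = []
    for comp in nx.connected_components(graph):
        starts = [hits[i].start for i in comp]
        ends = [hits[i].end for i in comp]
        spans.append((min(starts), max(ends)))
    return sorted(spans)


# ---------------------------------------------------------------------------
# landmark projection


def greedy_stab(
    intervals: list[tuple[int, int]], preplaced: list[int] | None = None
) -> list[int]:
    """Minimum points stabbing every half-open interval (greedy, optimal).

    Pre-placed points are honored first; remaining intervals are scanned
    in order of right endpoint and each uncovered one is stabbed at its
    last position (``end - 1``).
    """
    pre = sorted(preplaced or [])
    added: list[int] = []
    for s, e in sorted(intervals, key=lambda iv: (iv[1], iv[0])):
        if any(s <= p < e for p in pre) or any(s <= p < e for p in added):
            continue
        added.append(e - 1)
    return added


def project_landmarks(
    db: AlleleDB,
    surviving: dict[str, set[int]],
    relevant: dict[tuple[str, int], list[Hit]],
) -> dict[str, LandmarkSet]:
    """Build L_g per gene: core locations plus greedily-added positions
    so that every relevant placement covers at least one landmark."""
    out: dict[str, LandmarkSet] = {}
    for gene in db.genes:
        alive = surviving.get(gene.gene_id, set())
        if not alive:
            continue
        locations = set(gene.core_locations)
        region_spans: dict[int, list[tuple[int, int]]] = {}
        for i in sorted(alive):
            allele = gene.alleles[i]
            hits = relevant.get((gene.gene_id, i), [])
            if not hits:
                continue
            graph = build_overlap_graph(hits)
            region_spans[i] = landmark_regions(graph, hits)
            pre = [p for p in (lift_or_junction(allele, l) for l in locations) if p is not None]
            added = greedy_stab([h.interval() for h in hits], preplaced=pre)
            for p in added:
                locations.add(unlift(allele, p))
        out[gene.gene_id] = LandmarkSet(
            gene.gene_id, sorted(locations), region_spans
        )
    return out


def _core_relevant_hits(
    read_hits: list[ReadHits], db: AlleleDB, surviving: dict[str, set[int]]
) -> dict[tuple[str, int], list[Hit]]:
    """Placements that cover a core location, or whose read covers a core
    location through another placement (the "mirror" rule)."""
    core_pos: dict[tuple[str, int], set[int]] = {}
    for gene in db.genes:
        for i in surviving.get(gene.gene_id, set()):
            allele = gene.alleles[i]
            core_pos[(gene.gene_id, i)] = {
                p
                for p in (lift_or_junction(allele, l) for l in gene.core_locations)
                if p is not None
            }

    def covers_core(h: Hit) -> bool:
        pos = core_pos.get((h.gene_id, h.allele_index))
        return bool(pos) and any(h.start <= p < h.end for p in pos)

    out: dict[tuple[str, int], list[Hit]] = {}
    for rh in read_hits:
        alive_hits = [h for h in rh.hits if (h.gene_id, h.allele_index) in core_pos]
        if not alive_hits:
            continue
        read_touches_core = any(covers_core(h) for h in alive_hits)
        for h in alive_hits:
            if covers_core(h) or read_touches_core:
                out.setdefault((h.gene_id, h.allele_index), []).append(h)
    return out


def select_landmark_hits(
    read_hits: list[ReadHits],
    db: AlleleDB,
    surviving: dict[str, set[int]],
    landmark_sets: dict[str, LandmarkSet],
) -> list[ReadHits]:
    """Keep only placements that cover >= 1 landmark position (on a
    surviving allele); reads with none left are discarded."""
    lifted: dict[tuple[str, int], list[int]] = {}
    for gene in db.genes:
        ls = landmark_sets.get(gene.gene_id)
        if ls is None:
            continue
        for i in surviving.get(gene.gene_id, set()):
            lifted[(gene.gene_id, i)] = ls.lifted(gene.alleles[i])
    out = []
    for rh in read_hits:
        kept = [
            h
            for h in rh.hits
            if (h.gene_id, h.allele_index) in lifted
            and any(h.start <= p < h.end for p in lifted[(h.gene_id, h.allele_index)])
        ]
        if kept:
            out.append(ReadHits(rh.read_id, rh.sequence, kept))
    return out


def write_landmarks_bed(
    landmark_sets: dict[str, LandmarkSet], db: AlleleDB, path
) -> None:
    """Dump landmark positions per allele as BED for inspection."""
    with open(path, "w") as fh:
        for gene in db.genes:
            ls = landmark_sets.get(gene.gene_id)
            if ls is None:
                continue
            for allele in gene.alleles:
                for p in ls.lifted(allele):
                    fh.write(f"{allele.full_name}\t{p}\t{p + 1}\tlandmark\n")


def generate_landmarks(
    read_hits: list[ReadHits],
    db: AlleleDB,
    min_cov: int = 3,
) -> tuple[dict[str, set[int]], dict[str, LandmarkSet], list[ReadHits]]:
    """Run the full Stage-2a chain: coverage prefilter, overlap graphs,
    landmark projection, and landmark-based hit selection."""
    surviving = coverage_prefilter(read_hits, db, min_cov=min_cov)
    relevant = _core_relevant_hits(read_hits, db, surviving)
    landmark_sets = project_landmarks(db, surviving, relevant)
    retained = select_landmark_hits(read_hits, db, surviving, landmark_sets)
    return surviving, landmark_sets, retained
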