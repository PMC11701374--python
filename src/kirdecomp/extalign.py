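"""Optional external alignment adapter (minimap2 subprocess).

The built-in seed-and-extend aligner needs no external binary and is the
default; this adapter accelerates large inputs by delegating candidate
generation to minimap2 in short-read mode with secondary alignments
enabled, parsed back into the same :class:`~kirdecomp.align.Hit` model.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .alleledb import AlleleDB
from .align import Hit, Read, ReadHits, _cigar_stats

__all__ = ["minimap2_all_hits"]


def minimap2_all_hits(
    reads: list[Read], db: AlleleDB, extra_args: tuple[str, ...] = ()
) -> list[ReadHits]:
    """All read-to-allele hits via ``minimap2 -a -x sr --eqx -N <big>``.

    Raises a RuntimeError naming the built-in fallback when the binary is
    unavailable.
    """
    if shutil.which("minimap2") is None:
        raise RuntimeError(
            "minimap2 not found on PATH; rerun with engine='builtin' "
            "(the built-in aligner needs no external binary)"
        )
    import pysam

    name_of = {}
    with tempfile.TemporaryDirectory() as tmp:
        ref = Path(tmp) / "alleles.fa"
        with open(ref, "w") as fh:
            for g in db.genes:
                for i, a in enumerate(g.alleles):
                    name_of[a.full_name] = (g.gene_id, i)
                    fh.write(f">{a.full_name}\n{a.sequence}\n")
        query = Path(tmp) / "reads.fa"
        with open(query, "w") as fh:
            for r in reads:
                fh.write(f">{r.read_id}\n{r.sequence}\n")
        sam = Path(tmp) / "out.sam"
        cmd = [
            "minimap2", "-a", "-x", "sr", "--eqx", "-N", "200",
            "--secondary=yes", *extra_args, str(ref), str(query),
        ]
        with open(sam, "w") as out:
            subprocess.run(cmd, stdout=out, stderr=subprocess.DEVNULL, check=True)
        by_read: dict[str, list[Hit]] = {}
        with pysam.AlignmentFile(str(sam), check_sq=False) as af:
            for rec in af.fetch(until_eof=True):
                if rec.is_unmapped:
                    continue
                if rec.reference_name not in name_of:
                    continue
                gene_id, idx = name_of[rec.reference_name]
                cigar = rec.cigarstring or ""
                clip = sum(n for op, n in (rec.cigartuples or []) if op in (4, 5))
                core_cigar = "".join(
                    f"{n}{'=XIDN'[op - 7] if op >= 7 else 'MIDNS'[op]}"
                    for op, n in (rec.cigartuples or [])
                    if op in (1, 2, 7, 8)
                )
                matches, read_bases, score = _cigar_stats(core_cigar)
                by_read.setdefault(rec.query_name, []).append(
                    Hit(
                        rec.query_name, gene_id, idx, rec.reference_start,
                        matches, read_bases, core_cigar, score, clipped_bases=clip,
                    )
                )
    seq_of = {r.read_id: r.sequence for r in reads}
    out = []
    for r in reads:
        hits = by_read.get(r.read_id)
        if hits:
            hits.sort(key=lambda h: (h.gene_id, h.allele_index, h.start))
            out.append(ReadHits(r.read_id, seq_of[r.read_id], hits))
    return out
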