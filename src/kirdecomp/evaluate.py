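"""Copy-number-aware genotype concordance metrics.

Calls are scored at functional (three-digit, major-allele) resolution:
allele names are truncated to their first three digits and compared as
*multisets* per gene, so copy-number errors count as misses.  TP is the
multiset intersection, FP the called surplus, FN the truth surplus;
misses = FP + FN.  Precision, recall and F1 follow the usual
definitions, with the overall row pooled over genes (micro-average).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = ["EvalResult", "GeneScore", "truncate_functional", "score_calls"]


@dataclass
class GeneScore:
    total: int  # true alleles (with copies) for the gene
    tp: int
    fp: int
    fn: int

    @property
    def misses(self) -> int:
        return self.fp + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalResult:
    per_gene: dict[str, GeneScore] = field(default_factory=dict)

    @property
    def overall(self) -> GeneScore:
        return GeneScore(
            total=sum(s.total for s in self.per_gene.values()),
            tp=sum(s.tp for s in self.per_gene.values()),
            fp=sum(s.fp for s in self.per_gene.values()),
            fn=sum(s.fn for s in self.per_gene.values()),
        )

    def to_tsv(self) -> str:
        lines = ["Gene\tTotal\tMisses\tPrecision\tRecall\tF1"]
        rows = sorted(self.per_gene.items()) + [("All", self.overall)]
        for gene, s in rows:
            lines.append(
                f"{gene}\t{s.total}\t{s.misses}\t{100 * s.precision:.1f}%\t"
                f"{100 * s.recall:.1f}%\t{s.f1:.2f}"
            )
        return "\n".join(lines) + "\n"


def truncate_functional(allele_name: str) -> str:
    """Reduce an allele name to its three-digit functional prefix.

    ``"*0010101" -> "*001"``; gene prefixes and star markers survive:
    ``"GENE1*0020102" -> "GENE1*002"``.
    """
    if "*" in allele_name:
        head, digits = allele_name.rsplit("*", 1)
        return f"{head}*{digits[:3]}"
    return allele_name[:3]


def _functional_multiset(alleles: dict[str, int]) -> Counter:
    """Normalize to bare 3-digit keys: gene prefixes are redundant here
    because genotypes are already keyed by gene."""
    out: Counter = Counter()
    for name, cn in alleles.items():
        digits = name.rsplit("*", 1)[-1]
        out[digits[:3]] += cn
    return out


def score_calls(
    truth: dict[str, dict[str, int]],
    calls: dict[str, dict[str, int]],
    candidates: list[dict[str, dict[str, int]]] | None = None,
) -> EvalResult:
    """Score called against true genotypes at functional resolution.

    ``truth`` and ``calls`` map gene -> {allele_name: copy_number}.  When
    a caller emits multiple candidate solutions (``candidates``), the one
    closest to the truth (fewest misses) is scored — mirroring how tools
    with ambiguous output are conventionally credited.  Genes present
    only in the call are scored as pure false positives.
    """
    if candidates:
        options = [calls] + list(candidates)
        scored = [score_calls(truth, opt) for opt in options]
        return min(scored, key=lambda r: r.overall.misses)

    result = EvalResult()
    for gene in sorted(set(truth) | set(calls)):
        t = _functional_multiset(truth.get(gene, {}))
        c = _functional_multiset(calls.get(gene, {}))
        inter = t & c
        tp = sum(inter.values())
        fp = sum((c - t).values())
        fn = sum((t - c).values())
        result.per_gene[gene] = GeneScore(total=sum(t.values()), tp=tp, fp=fp, fn=fn)
    return result
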