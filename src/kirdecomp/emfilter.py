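"""Stage 2b: expectation-maximization over allele abundances.

A finite mixture over the n candidate alleles generates the retained
reads: read r_k drawn from allele i with probability phi_i and observed
through a symmetric per-base error channel with rate eps,

    P(r_k | Z_k = i) = m_ki * eps^(l_ki - p_ki) * (1 - eps)^p_ki / l_i

where p_ki counts matching bases, l_ki the read bases placed on the
allele, l_i the allele length, and m_ki the number of valid placements
of the read within that allele.  Both phi and eps are estimated by EM;
the result is used purely as a *filter* — alleles with abundance at or
below a small threshold gamma are discarded — never as the final call,
which avoids committing to an EM local optimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alleledb import AlleleDB
from .align import ReadHits

logger = logging.getLogger(__name__)

__all__ = ["EMState", "HitStats", "read_likelihood", "em_fit", "prune_by_abundance"]

EPS_FLOOR = 1e-9
EPS_CEIL = 0.5


@dataclass
class EMState:
    allele_keys: list[tuple[str, int]]  # (gene_id, allele_index) per column
    phi: np.ndarray  # abundances, sums to 1
    eps: float  # sequencing error rate
    mu: np.ndarray  # responsibilities, reads x alleles
    loglik: float
    n_iter: int
    trace: list[tuple[int, float, float]]  # (iteration, loglik, eps)

    def phi_of(self, key: tuple[str, int]) -> float:
        return float(self.phi[self.allele_keys.index(key)])


@dataclass(frozen=True)
class HitStats:
    """Sufficient statistics of one read on one allele."""

    m: int  # placement multiplicity m_ki
    p: int  # matching bases of the scored placement
    l: int  # read bases placed
    allele_len: int


def read_likelihood(stats: HitStats, eps: float) -> float:
    """P(r_k | Z_k = i) for one read/allele pair, computed in log space."""
    if not 0.0 < eps < 1.0:
        raise ValueError(f"eps must lie in (0, 1), got {eps}")
    if stats.m == 0:
        return 0.0
    return float(np.exp(_log_likelihood(stats, eps)))


def _log_likelihood(stats: HitStats, eps: float) -> float:
    return (
        np.log(stats.m)
        + (stats.l - stats.p) * np.log(eps)
        + stats.p * np.log1p(-eps)
        - np.log(stats.allele_len)
    )


def collect_stats(
    read_hits: list[ReadHits],
    db: AlleleDB,
    candidates: list[tuple[str, int]],
    placement: str = "best",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (m, p, l, allele_len) matrices, reads x candidates.

    ``placement="best"`` scores each read/allele pair by its single
    highest-scoring placement (multiplicity still enters through m_ki);
    ``placement="sum"`` instead sums p and l over all placements, an
    alternative treatment of within-allele multi-mapping.
    """
    col = {key: j for j, key in enumerate(candidates)}
    lens = np.array(
        [len(db.gene(g).alleles[i].sequence) for g, i in candidates], dtype=float
    )
    n_reads = len(read_hits)
    m = np.zeros((n_reads, len(candidates)))
    p = np.zeros((n_reads, len(candidates)))
    l = np.zeros((n_reads, len(candidates)))
    for k, rh in enumerate(read_hits):
        per: dict[int, list] = {}
        for h in rh.hits:
            j = col.get((h.gene_id, h.allele_index))
            if j is not None:
                per.setdefault(j, []).append(h)
        for j, hits in per.items():
            m[k, j] = len(hits)
            if placement == "sum":
                p[k, j] = sum(h.matches for h in hits)
                l[k, j] = sum(h.aligned_len for h in hits)
                m[k, j] = 1
            else:
                best = max(hits, key=lambda h: (h.score, -h.start))
                p[k, j] = best.matches
                l[k, j] = best.aligned_len
    return m, p, l, np.broadcast_to(lens, m.shape).copy()


def em_fit(
    read_hits: list[ReadHits],
    db: AlleleDB,
    candidates: list[tuple[str, int]] | None = None,
    init_eps: float = 0.01,
    max_iter: int = 1000,
    tol: float = 1e-6,
    placement: str = "best",
) -> EMState:
    """Fit allele abundances phi and error rate eps by EM.

    Initialization is uninformative (uniform phi); the log-likelihood is
    asserted non-decreasing at every iteration, and iteration stops when
    its gain falls below ``tol`` or after ``max_iter`` rounds.
    """
    if candidates is None:
        keys = sorted({(h.gene_id, h.allele_index) for rh in read_hits for h in rh.hits})
    else:
        keys = list(candidates)
    if not keys:
        raise ValueError("no candidate alleles for EM")
    m, p, l, lens = collect_stats(read_hits, db, keys, placement=placement)
    has_hit = m.sum(axis=1) > 0
    if not has_hit.all():
        raise ValueError("every read entering EM must have at least one placement")

    n = len(keys)
    phi = np.full(n, 1.0 / n)
    eps = float(np.clip(init_eps, EPS_FLOOR, EPS_CEIL))
    prev_ll = -np.inf
    trace: list[tuple[int, float, float]] = []
    mu = np.zeros_like(m)
    ll = prev_ll
    with np.errstate(divide="ignore"):
        log_m = np.where(m > 0, np.log(np.maximum(m, 1)), -np.inf)
        for it in range(1, max_iter + 1):
            log_like = log_m + (l - p) * np.log(eps) + p * np.log1p(-eps) - np.log(lens)
            log_joint = log_like + np.log(phi + 1e-300)
            log_norm = logsumexp(log_joint, axis=1, keepdims=True)
            ll = float(log_norm.sum())
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite log-likelihood at iteration {it}: eps={eps}, "
                    f"phi={phi.tolist()}"
                )
            if ll + 1e-9 < prev_ll:
                raise AssertionError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev_ll} -> {ll}"
                )
            mu = np.exp(log_joint - log_norm)
            trace.append((it, ll, eps))
            if abs(ll - prev_ll) < tol:
                break
            prev_ll = ll
            phi = mu.sum(axis=0) / mu.shape[0]
            denom = float((mu * l).sum())
            if denom > 0:
                eps = float(np.clip((mu * (l - p)).sum() / denom, EPS_FLOOR, EPS_CEIL))
    return EMState(keys, phi, eps, mu, ll, len(trace), trace)


def prune_by_abundance(
    state: EMState,
    gamma: float = 1e-3,
    core_support: dict[tuple[str, int], int] | None = None,
    min_cov: int = 3,
) -> list[tuple[str, int]]:
    """Keep alleles with abundance strictly above gamma.

    A safety rail guards against EM local optima dropping a whole gene:
    if pruning would remove every allele of a gene that still has at
    least ``min_cov`` core-supporting reads (per ``core_support``), the
    gene's highest-abundance allele is retained.
    """
    kept = [key for key, f in zip(state.allele_keys, state.phi) if f > gamma]
    removed = [key for key in state.allele_keys if key not in kept]
    if core_support:
        kept_genes = {g for g, _ in kept}
        by_gene: dict[str, list[tuple[str, int]]] = {}
        for key in state.allele_keys:
            by_gene.setdefault(key[0], []).append(key)
        for gene_id, keys in by_gene.items():
            if gene_id in kept_genes:
                continue
            support = max(core_support.get(key, 0) for key in keys)
            if support >= min_cov:
                best = max(keys, key=lambda key: state.phi_of(key))
                kept.append(best)
                removed.remove(best)
    if removed:
        logger.info(
            "EM pruning removed %d alleles (gamma=%g): %s",
            len(removed),
            gamma,
            ", ".join(f"{g}[{i}]" for g, i in removed),
        )
    return sorted(kept)


def write_trace(state: EMState, path) -> None:
    """Dump the EM trajectory as TSV (iteration, loglik, eps)."""
    with open(path, "w") as fh:
        fh.write("iteration\tloglik\teps\n")
        for it, ll, eps in state.trace:
            fh.write(f"{it}\t{ll:.10g}\t{eps:.10g}\n")
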