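"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* (plain
DP recursions, exhaustive enumeration) rather than reusing any code path
from the package, so agreement is evidence of correctness rather than
tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

# scoring constants restated independently (match the documented scheme)
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -4, -1


def gotoh_global_score(a: str, b: str) -> int:
    """Optimal global alignment score under the affine scheme, by an
    independent Gotoh DP (gap of length k costs 4 + (k-1))."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (delete from a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (insert from b)
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] + GAP_OPEN, X[i - 1][j] + GAP_EXTEND)
            Y[i][j] = max(M[i][j - 1] + GAP_OPEN, Y[i][j - 1] + GAP_EXTEND)
    return max(M[n][m], X[n][m], Y[n][m])


def variant_set_score(ref: str, variants) -> int:
    """Global-alignment score implied by an edit script on ``ref``."""
    score = MATCH * len(ref)
    for v in variants:
        if v.kind == "sub":
            score += MISMATCH - MATCH
        elif v.kind == "del":
            n = v.del_length
            score += GAP_OPEN + GAP_EXTEND * (n - 1) - MATCH * n
        else:
            n = len(v.ins_seq)
            score += GAP_OPEN + GAP_EXTEND * (n - 1)
    return score


def semiglobal_distance_profile(read: str, target: str) -> list[int]:
    """d(s) for every start s: edit distance of the full read anchored at
    s on the target with a free end.

    Row-wise DP with the prefix-scan trick: the in-row dependence
    ``cur[j] = min(base[j], cur[j-1] + 1)`` equals
    ``min.accumulate(base[j] - j) + j``.
    """
    out = []
    rl = len(read)
    rvec = np.frombuffer(read.encode(), dtype="S1")
    tvec = np.frombuffer(target.encode(), dtype="S1")
    for s in range(len(target)):
        window = tvec[s : s + 2 * rl]
        w = len(window)
        prev = np.arange(w + 1)
        idx = np.arange(w + 1)
        for i in range(rl):
            cost = (rvec[i] != window).astype(int)
            base = np.empty(w + 1, dtype=int)
            base[0] = i + 1
            base[1:] = np.minimum(prev[:-1] + cost, prev[1:] + 1)
            cur = np.minimum.accumulate(base - idx) + idx
            prev = cur
        out.append(int(prev.min()))
    return out


def expected_hit_starts(read: str, target: str, max_edits: int) -> set[int]:
    """The documented placement rule, recomputed from the d(s) profile:
    every exact start, plus leftmost-local-minimum inexact starts."""
    d = semiglobal_distance_profile(read, target)
    n = len(d)
    starts = set()
    for s in range(n):
        if s <= len(target) - len(read) and target[s : s + len(read)] == read:
            starts.add(s)
    for s in range(n):
        if s in starts or d[s] == 0 or d[s] > max_edits:
            continue
        dl = d[s - 1] if s > 0 else None
        dr = d[s + 1] if s + 1 < n else None
        if (dl is None or dl > d[s]) and (dr is None or dr >= d[s]):
            starts.add(s)
    return starts


def min_stab_size(intervals: list[tuple[int, int]], preplaced: list[int]) -> int:
    """Minimum number of extra points stabbing all half-open intervals,
    by exhaustive subset search over candidate points."""
    todo = [
        iv
        for iv in intervals
        if not any(s <= p < e for p in preplaced for s, e in [iv])
    ]
    if not todo:
        return 0
    candidates = sorted({e - 1 for _, e in todo})
    for k in range(1, len(todo) + 1):
        for combo in itertools.combinations(candidates, k):
            if all(any(s <= p < e for p in combo) for s, e in todo):
                return k
    return len(todo)


def em_one_step(m, p, l, lens, phi0, eps0):
    """One EM iteration written directly from the update formulas."""
    m, p, l, lens = (np.asarray(x, dtype=float) for x in (m, p, l, lens))
    like = np.where(
        m > 0,
        m * eps0 ** (l - p) * (1 - eps0) ** p / lens,
        0.0,
    )
    joint = like * phi0
    mu = joint / joint.sum(axis=1, keepdims=True)
    loglik = float(np.log(joint.sum(axis=1)).sum())
    phi1 = mu.sum(axis=0) / mu.shape[0]
    eps1 = float((mu * (l - p)).sum() / (mu * l).sum())
    return mu, loglik, phi1, eps1


def enumerate_ilp_optimum(instance) -> float:
    """Exhaustive optimum of the read-assignment / copy-number program.

    Enumerates every read assignment (each read: one admissible allele
    or dropped) and, per assignment, scans all feasible copy numbers per
    allele; returns the minimum objective.  Only viable for tiny
    instances.
    """
    n_reads = len(instance.read_ids)
    n_alleles = len(instance.allele_keys)
    xi = instance.xi
    lm_count = {a: instance.landmark_counts[instance.gene_of[a]] for a in range(n_alleles)}
    choices = []
    for k in range(n_reads):
        opts = [None] + [a for a in range(n_alleles) if (k, a) in instance.covered]
        choices.append(opts)

    best = np.inf
    for combo in itertools.product(*choices):
        n_drop = sum(1 for c in combo if c is None)
        total = instance.drop_cost * n_drop
        feasible = True
        for a in range(n_alleles):
            assigned = [k for k, c in enumerate(combo) if c == a]
            cov = [0] * lm_count[a]
            for k in assigned:
                for j in instance.covered[(k, a)]:
                    cov[j] += 1
            S = sum(cov)
            best_a = np.inf
            lo_A = 1 if assigned else 0
            hi_A = min(instance.max_copy, len(assigned)) if assigned else 0
            for A in range(lo_A, hi_A + 1):
                if A >= 1:
                    if S < instance.cov_lo * A * xi * lm_count[a] - 1e-9:
                        continue
                    if S > instance.cov_hi * A * xi * lm_count[a] + 1e-9:
                        continue
                cost = sum(abs(c / xi - A) for c in cov) + instance.sel_cost * A
                best_a = min(best_a, cost)
            if not np.isfinite(best_a):
                feasible = False
                break
            total += best_a
        if feasible:
            best = min(best, total)
    return float(best)


def random_tiny_instance(rng: np.random.Generator):
    """A random small ILP instance with admissible incidence."""
    from kirdecomp.ilpcall import ILPInstance

    n_alleles = int(rng.integers(1, 4))
    n_reads = int(rng.integers(1, 9))
    n_genes = int(rng.integers(1, n_alleles + 1))
    gene_of = [f"g{int(rng.integers(0, n_genes))}" for _ in range(n_alleles)]
    lm = {g: int(rng.integers(1, 5)) for g in set(gene_of)}
    xi = float(rng.choice([1.0, 2.0, 3.0]))
    covered = {}
    for k in range(n_reads):
        n_cand = int(rng.integers(1, n_alleles + 1))
        for a in rng.choice(n_alleles, size=n_cand, replace=False):
            a = int(a)
            g = gene_of[a]
            n_l = int(rng.integers(1, min(2, lm[g]) + 1))
            lms = tuple(sorted(int(x) for x in rng.choice(lm[g], size=n_l, replace=False)))
            covered[(k, a)] = lms
    positions = {g: list(range(lm[g])) for g in lm}
    return ILPInstance(
        allele_keys=[(gene_of[a], a) for a in range(n_alleles)],
        allele_names=[f"{gene_of[a]}*{a:03d}" for a in range(n_alleles)],
        gene_of=gene_of,
        landmark_counts=lm,
        landmark_positions=positions,
        read_ids=[f"r{k}" for k in range(n_reads)],
        covered=covered,
        xi=xi,
        cov_lo=0.5,
        cov_hi=1.5,
        sel_cost=0.1,
        drop_cost=0.08,
        max_copy=3,
    )
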