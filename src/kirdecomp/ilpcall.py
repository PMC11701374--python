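"""Stage 3: joint copy-number and allele calling by integer programming.

Each surviving read is either assigned to exactly one candidate allele
(through its best placement on that allele) or dropped at cost beta; an
integer variable A_a counts how many genome copies of allele ``a`` are
selected.  The objective charges, at every landmark position l of the
allele's gene, the absolute deviation between the number of assigned
reads covering l and the coverage xi * A_a expected from A_a copies,
plus a selection cost gamma per copy and the drop costs:

    minimize  sum_a sum_{l in L_g} | sum_{k covers l} V_ka / xi - A_a |
              + gamma sum_a A_a + beta sum_k D_k

The coverage error is measured in *copy units* (observed depth divided
by the per-copy depth xi) so that the per-read drop cost beta and the
per-copy selection cost gamma are commensurate with it: one landmark
missing an entire copy's worth of reads costs 1, one dropped read saves
about 1/xi per landmark it covers.  Charging raw read counts instead
would let counting noise (~sqrt(xi) per landmark) dominate both
penalties and push the optimum toward dropping whole genes.

subject to per-allele coverage sanity bounds
``cov_lo * A_a * xi * |L_g| <= sum_l sum_k V_ka <= cov_hi * A_a * xi * |L_g|``,
the linking constraints ``A_a >= V_ka`` and ``sum_k V_ka >= A_a``, and
``sum_a V_ka + D_k = 1`` per read.  Absolute values are linearized with
auxiliary continuous variables.

The model is solver-agnostic; the bundled backend is HiGHS via
``scipy.optimize.milp`` (open source, deterministic, proven optimal at
the default zero MIP gap).  Any callable with the same contract can be
plugged in instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alleledb import AlleleDB
from .align import Read, ReadHits, all_hits, filter_hits, estimate_xi, CoverageModel
from .landmarks import LandmarkSet, generate_landmarks, lift_or_junction
from .emfilter import em_fit, prune_by_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "CallConfig",
    "ILPInstance",
    "ILPModel",
    "GenotypeCall",
    "build_instance",
    "build_ilp",
    "solve_ilp",
    "solve_instance",
    "call_sample",
]


@dataclass
class CallConfig:
    """Tunable parameters of the whole pipeline."""

    min_cov: int = 3  # reads required at every core site
    min_score_frac: float = 0.85
    max_clip_frac: float = 0.25
    seed_len: int = 14
    max_edits: int | None = None  # None: read_len // seed_len - 1
    em_gamma: float = 1e-3  # abundance pruning threshold
    em_init_eps: float = 0.01
    em_max_iter: int = 1000
    em_tol: float = 1e-6
    cov_lo: float = 0.5  # minimum coverage fraction per selected copy
    cov_hi: float = 1.5  # maximum coverage fraction per selected copy
    sel_cost: float = 0.1  # gamma: cost per selected allele copy
    drop_cost: float = 0.08  # beta: cost per dropped read
    max_copy: int = 4  # copy-number upper bound per allele
    # a read may only be assigned through placements tied for its best
    # score; relaxing this lets imperfect cross-gene placements absorb
    # reads and fund phantom copies
    assign_best_only: bool = True
    neutral_copy_number: int = 2
    solver: str = "scipy"


@dataclass
class ILPInstance:
    """Read-allele incidence restricted to landmark-covering placements."""

    allele_keys: list[tuple[str, int]]  # (gene_id, allele_index)
    allele_names: list[str]
    gene_of: list[str]
    landmark_counts: dict[str, int]  # |L_g| per gene
    landmark_positions: dict[str, list[int]]  # reference coords
    read_ids: list[str]
    # covered[(k, a)] = tuple of landmark ordinals (within the gene's L_g)
    covered: dict[tuple[int, int], tuple[int, ...]]
    xi: float
    cov_lo: float = 0.5
    cov_hi: float = 1.5
    sel_cost: float = 0.1
    drop_cost: float = 0.08
    max_copy: int = 4
    equivalent: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.xi > 0:
            raise ValueError("xi must be positive")
        if not 0 < self.cov_lo < 1 < self.cov_hi:
            raise ValueError("need 0 < cov_lo < 1 < cov_hi")
        if not self.allele_keys:
            raise ValueError("empty candidate allele set")
        for (k, a), lms in self.covered.items():
            if not lms:
                raise ValueError(f"pair ({k},{a}) covers no landmark")
            if a >= len(self.allele_keys) or k >= len(self.read_ids):
                raise ValueError("incidence refers to unknown read or allele")


@dataclass
class Variable:
    name: str
    kind: str  # 'B' binary, 'I' integer, 'C' continuous
    lb: float
    ub: float
    obj: float


@dataclass
class ILPModel:
    variables: list[Variable]
    # each constraint: ({var_index: coef}, lower, upper)
    constraints: list[tuple[dict[int, float], float, float]]
    v_index: dict[tuple[int, int], int]  # (read, allele) -> V variable
    d_index: dict[int, int]  # read -> D variable
    a_index: dict[int, int]  # allele -> A variable
    e_index: dict[tuple[int, int], int]  # (allele, landmark ordinal) -> aux

    def write_lp(self, path: str | Path) -> None:
        """Export in LP format for audit."""
        lines = ["Minimize", " obj: " + " + ".join(
            f"{v.obj:g} {v.name}" for v in self.variables if v.obj
        ), "Subject To"]
        for c, (coefs, lb, ub) in enumerate(self.constraints):
            expr = " + ".join(
                f"{coef:g} {self.variables[j].name}" for j, coef in sorted(coefs.items())
            ).replace("+ -", "- ")
            if lb == ub:
                lines.append(f" c{c}: {expr} = {lb:g}")
            else:
                if np.isfinite(ub):
                    lines.append(f" c{c}u: {expr} <= {ub:g}")
                if np.isfinite(lb):
                    lines.append(f" c{c}l: {expr} >= {lb:g}")
        lines.append("Bounds")
        for v in self.variables:
            lines.append(f" {v.lb:g} <= {v.name} <= {v.ub:g}")
        lines.append("General")
        lines.append(" " + " ".join(v.name for v in self.variables if v.kind == "I"))
        lines.append("Binary")
        lines.append(" " + " ".join(v.name for v in self.variables if v.kind == "B"))
        lines.append("End")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GenotypeCall:
    """Final per-gene multisets of alleles with copy numbers."""

    genotype: dict[str, dict[str, int]]  # gene -> {allele_name: copies}
    assignments: dict[str, str]  # read_id -> full allele name
    dropped: list[str]
    objective: float
    residuals: dict[tuple[str, int], float]  # (allele name, landmark pos) -> |residual|
    status: str = "optimal"
    warnings: list[str] = field(default_factory=list)
    # alleles indistinguishable from a called one on the landmark evidence
    equivalent: dict[str, list[str]] = field(default_factory=dict)

    def copy_number(self, gene_id: str) -> int:
        return sum(self.genotype.get(gene_id, {}).values())

    def as_multiset(self, truncate: int | None = None) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for gene, alleles in self.genotype.items():
            agg: dict[str, int] = {}
            for name, cn in alleles.items():
                digits = name.split("*")[1] if "*" in name else name
                if truncate:
                    digits = digits[:truncate]
                agg[digits] = agg.get(digits, 0) + cn
            out[gene] = agg
        return out


# ---------------------------------------------------------------------------
# instance and model construction


def build_instance(
    read_hits: list[ReadHits],
    db: AlleleDB,
    candidates: list[tuple[str, int]],
    landmark_sets: dict[str, LandmarkSet],
    xi: float,
    cfg: CallConfig | None = None,
    priority: dict[tuple[str, int], float] | None = None,
    merge_equivalent: bool = True,
) -> ILPInstance:
    """Attach each read to its best placement per candidate allele and
    record which landmarks that placement covers.

    Candidate alleles of a gene whose landmark-incidence columns are
    identical (they differ only outside the landmark set, e.g. by silent
    variants) are interchangeable in the optimization; they are merged
    to one representative — the highest ``priority`` (EM abundance),
    ties to the smallest name — and recorded in ``equivalent``.
    """
    cfg = cfg or CallConfig()
    keys = sorted(candidates)
    names = []
    gene_of = []
    lifted: dict[int, list[int]] = {}
    for a, (gene_id, idx) in enumerate(keys):
        gene = db.gene(gene_id)
        allele = gene.alleles[idx]
        names.append(allele.full_name)
        gene_of.append(gene_id)
        ls = landmark_sets[gene_id]
        lifted[a] = [lift_or_junction(allele, loc) for loc in ls.locations]
    counts = {g: len(ls.locations) for g, ls in landmark_sets.items()}
    positions = {g: list(ls.locations) for g, ls in landmark_sets.items()}

    covered: dict[tuple[int, int], tuple[int, ...]] = {}
    read_ids = []
    col = {key: a for a, key in enumerate(keys)}
    k = 0
    for rh in read_hits:
        cand_scores = [
            h.score for h in rh.hits if (h.gene_id, h.allele_index) in col
        ]
        top = max(cand_scores) if cfg.assign_best_only and cand_scores else None
        row: dict[int, tuple[int, ...]] = {}
        for key in {(h.gene_id, h.allele_index) for h in rh.hits}:
            a = col.get(key)
            if a is None:
                continue
            best = rh.best_hit(*key)
            if top is not None and best.score < top:
                continue
            lms = tuple(
                j
                for j, p in enumerate(lifted[a])
                if p is not None and best.start <= p < best.end
            )
            if lms:
                row[a] = lms
        if row:
            read_ids.append(rh.read_id)
            for a, lms in row.items():
                covered[(k, a)] = lms
            k += 1

    equivalent: dict[str, list[str]] = {}
    if merge_equivalent and keys:
        columns: dict[int, tuple] = {a: [] for a in range(len(keys))}
        for (kk, a), lms in sorted(covered.items()):
            columns[a].append((kk, lms))
        groups: dict[tuple, list[int]] = {}
        for a in range(len(keys)):
            sig = (gene_of[a], tuple(columns[a]))
            groups.setdefault(sig, []).append(a)
        keep: list[int] = []
        drop: set[int] = set()
        for sig, members in groups.items():
            rep = max(
                members,
                key=lambda a: (
                    (priority or {}).get(keys[a], 0.0),
                    [-ord(ch) for ch in names[a]],
                ),
            )
            keep.append(rep)
            rest = [a for a in members if a != rep]
            if rest:
                equivalent[names[rep]] = sorted(names[a] for a in rest)
            drop.update(rest)
        keep.sort()
        remap = {a: n for n, a in enumerate(keep)}
        covered = {
            (kk, remap[a]): lms for (kk, a), lms in covered.items() if a not in drop
        }
        keys = [keys[a] for a in keep]
        names = [names[a] for a in keep]
        gene_of = [gene_of[a] for a in keep]

    inst = ILPInstance(
        keys,
        names,
        gene_of,
        counts,
        positions,
        read_ids,
        covered,
        xi,
        cov_lo=cfg.cov_lo,
        cov_hi=cfg.cov_hi,
        sel_cost=cfg.sel_cost,
        drop_cost=cfg.drop_cost,
        max_copy=cfg.max_copy,
        equivalent=equivalent,
    )
    inst.validate()
    return inst


def build_ilp(instance: ILPInstance) -> ILPModel:
    """Materialize the MILP: V/D binaries, integer A, continuous abs-aux."""
    instance.validate()
    variables: list[Variable] = []
    constraints: list[tuple[dict[int, float], float, float]] = []

    v_index: dict[tuple[int, int], int] = {}
    for (k, a) in sorted(instance.covered):
        v_index[(k, a)] = len(variables)
        variables.append(Variable(f"V_{k}_{a}", "B", 0, 1, 0.0))
    d_index: dict[int, int] = {}
    for k in range(len(instance.read_ids)):
        d_index[k] = len(variables)
        variables.append(Variable(f"D_{k}", "B", 0, 1, instance.drop_cost))
    a_index: dict[int, int] = {}
    for a in range(len(instance.allele_keys)):
        a_index[a] = len(variables)
        variables.append(Variable(f"A_{a}", "I", 0, instance.max_copy, instance.sel_cost))
    e_index: dict[tuple[int, int], int] = {}
    for a, gene in enumerate(instance.gene_of):
        for j in range(instance.landmark_counts[gene]):
            e_index[(a, j)] = len(variables)
            variables.append(Variable(f"E_{a}_{j}", "C", 0, np.inf, 1.0))

    # each read: assigned once or dropped
    by_read: dict[int, list[tuple[int, int]]] = {}
    for (k, a) in instance.covered:
        by_read.setdefault(k, []).append((k, a))
    for k in range(len(instance.read_ids)):
        coefs = {v_index[pair]: 1.0 for pair in by_read.get(k, [])}
        coefs[d_index[k]] = 1.0
        constraints.append((coefs, 1.0, 1.0))

    # absolute-value linearization per (allele, landmark)
    cover_lists: dict[tuple[int, int], list[int]] = {}
    for (k, a), lms in instance.covered.items():
        for j in lms:
            cover_lists.setdefault((a, j), []).append(v_index[(k, a)])
    inv_xi = 1.0 / instance.xi
    for a, gene in enumerate(instance.gene_of):
        for j in range(instance.landmark_counts[gene]):
            e = e_index[(a, j)]
            vs = cover_lists.get((a, j), [])
            # E - sum V / xi + A >= 0
            coefs = {e: 1.0, a_index[a]: 1.0}
            for v in vs:
                coefs[v] = coefs.get(v, 0.0) - inv_xi
            constraints.append((coefs, 0.0, np.inf))
            # E + sum V / xi - A >= 0
            coefs = {e: 1.0, a_index[a]: -1.0}
            for v in vs:
                coefs[v] = coefs.get(v, 0.0) + inv_xi
            constraints.append((coefs, 0.0, np.inf))

    # per-allele coverage sanity bounds over the gene's landmark set
    for a, gene in enumerate(instance.gene_of):
        n_l = instance.landmark_counts[gene]
        coefs: dict[int, float] = {}
        for j in range(n_l):
            for v in cover_lists.get((a, j), []):
                coefs[v] = coefs.get(v, 0.0) + 1.0
        lo = dict(coefs)
        lo[a_index[a]] = -instance.cov_lo * instance.xi * n_l
        constraints.append((lo, 0.0, np.inf))
        hi = dict(coefs)
        hi[a_index[a]] = -instance.cov_hi * instance.xi * n_l
        constraints.append((hi, -np.inf, 0.0))

    # linking: A_a >= V_ka ; sum_k V_ka >= A_a
    for (k, a), vi in v_index.items():
        constraints.append(({a_index[a]: 1.0, vi: -1.0}, 0.0, np.inf))
    by_allele: dict[int, list[int]] = {}
    for (k, a), vi in v_index.items():
        by_allele.setdefault(a, []).append(vi)
    for a in range(len(instance.allele_keys)):
        coefs = {vi: 1.0 for vi in by_allele.get(a, [])}
        coefs[a_index[a]] = coefs.get(a_index[a], 0.0) - 1.0
        constraints.append((coefs, 0.0, np.inf))

    return ILPModel(variables, constraints, v_index, d_index, a_index, e_index)


# ---------------------------------------------------------------------------
# aggregated (read-bundled) formulation

def solve_instance(
    instance: ILPInstance,
    solver: str = "scipy",
    mip_rel_gap: float = 0.0,
    time_limit: float | None = None,
) -> GenotypeCall:
    """Solve an instance via the read-bundled exact reformulation.

    Reads with identical incidence rows (same admissible alleles, same
    covered landmarks on each) are interchangeable in the per-read model;
    bundling them into integer count variables projects the feasible set
    and objective exactly while removing the read-permutation symmetry
    that otherwise dominates branch-and-bound time.  Optima coincide
    with :func:`build_ilp` + :func:`solve_ilp`; assignments of reads
    within a bundle are distributed deterministically (sorted read ids).
    """
    instance.validate()
    groups: dict[tuple, list[int]] = {}
    for k in range(len(instance.read_ids)):
        row = tuple(
            sorted((a, instance.covered[(k, a)]) for (kk, a) in instance.covered if kk == k)
        )
        groups.setdefault(row, []).append(k)
    rows = sorted(groups)
    sizes = [len(groups[r]) for r in rows]
    n_alleles = len(instance.allele_keys)

    variables: list[Variable] = []
    constraints: list[tuple[dict[int, float], float, float]] = []
    n_index: dict[tuple[int, int], int] = {}
    for gi, row in enumerate(rows):
        for a, _ in row:
            n_index[(gi, a)] = len(variables)
            variables.append(
                Variable(f"N_{gi}_{a}", "I", 0, sizes[gi], 0.0)
            )
    d_index: dict[int, int] = {}
    for gi in range(len(rows)):
        d_index[gi] = len(variables)
        variables.append(Variable(f"D_{gi}", "I", 0, sizes[gi], instance.drop_cost))
    a_index: dict[int, int] = {}
    for a in range(n_alleles):
        a_index[a] = len(variables)
        variables.append(Variable(f"A_{a}", "I", 0, instance.max_copy, instance.sel_cost))
    e_index: dict[tuple[int, int], int] = {}
    for a, gene in enumerate(instance.gene_of):
        for j in range(instance.landmark_counts[gene]):
            e_index[(a, j)] = len(variables)
            variables.append(Variable(f"E_{a}_{j}", "C", 0, np.inf, 1.0))

    for gi, row in enumerate(rows):
        coefs = {n_index[(gi, a)]: 1.0 for a, _ in row}
        coefs[d_index[gi]] = 1.0
        constraints.append((coefs, float(sizes[gi]), float(sizes[gi])))

    cover_lists: dict[tuple[int, int], list[int]] = {}
    for gi, row in enumerate(rows):
        for a, lms in row:
            for j in lms:
                cover_lists.setdefault((a, j), []).append(n_index[(gi, a)])
    inv_xi = 1.0 / instance.xi
    for a, gene in enumerate(instance.gene_of):
        for j in range(instance.landmark_counts[gene]):
            e = e_index[(a, j)]
            vs = cover_lists.get((a, j), [])
            coefs = {e: 1.0, a_index[a]: 1.0}
            for v in vs:
                coefs[v] = coefs.get(v, 0.0) - inv_xi
            constraints.append((coefs, 0.0, np.inf))
            coefs = {e: 1.0, a_index[a]: -1.0}
            for v in vs:
                coefs[v] = coefs.get(v, 0.0) + inv_xi
            constraints.append((coefs, 0.0, np.inf))

    for a, gene in enumerate(instance.gene_of):
        n_l = instance.landmark_counts[gene]
        coefs = {}
        for j in range(n_l):
            for v in cover_lists.get((a, j), []):
                coefs[v] = coefs.get(v, 0.0) + 1.0
        lo = dict(coefs)
        lo[a_index[a]] = -instance.cov_lo * instance.xi * n_l
        constraints.append((lo, 0.0, np.inf))
        hi = dict(coefs)
        hi[a_index[a]] = -instance.cov_hi * instance.xi * n_l
        constraints.append((hi, -np.inf, 0.0))

    # selection linking: N_{g,a} <= n_g * A_a  and  sum_g N_{g,a} >= A_a
    by_allele: dict[int, list[tuple[int, int]]] = {}
    for (gi, a), vi in n_index.items():
        constraints.append(({a_index[a]: float(sizes[gi]), vi: -1.0}, 0.0, np.inf))
        by_allele.setdefault(a, []).append(vi)
    for a in range(n_alleles):
        coefs = {vi: 1.0 for vi in by_allele.get(a, [])}
        coefs[a_index[a]] = coefs.get(a_index[a], 0.0) - 1.0
        constraints.append((coefs, 0.0, np.inf))

    model = ILPModel(variables, constraints, {}, d_index, a_index, e_index)
    backend = BACKENDS[solver] if isinstance(solver, str) else solver
    status, x, obj = backend(model, mip_rel_gap=mip_rel_gap, time_limit=time_limit)
    warnings = [] if status == "optimal" else [f"solver returned {status} solution"]

    genotype: dict[str, dict[str, int]] = {}
    for a, (gene_id, _idx) in enumerate(instance.allele_keys):
        cn = int(round(x[a_index[a]]))
        if cn > 0:
            genotype.setdefault(gene_id, {})[instance.allele_names[a]] = cn
    assignments: dict[str, str] = {}
    dropped: list[str] = []
    for gi, row in enumerate(rows):
        members = sorted(groups[row], key=lambda k: instance.read_ids[k])
        pos = 0
        for a, _ in row:
            cnt = int(round(x[n_index[(gi, a)]]))
            for k in members[pos : pos + cnt]:
                assignments[instance.read_ids[k]] = instance.allele_names[a]
            pos += cnt
        dropped.extend(instance.read_ids[k] for k in members[pos:])
    residuals: dict[tuple[str, int], float] = {}
    for (a, j), ei in e_index.items():
        if x[a_index[a]] > 0.5 or x[ei] > 1e-9:
            gene = instance.gene_of[a]
            pos = instance.landmark_positions[gene][j]
            residuals[(instance.allele_names[a], pos)] = float(x[ei])
    relevant_eq = {
        name: instance.equivalent[name]
        for alleles in genotype.values()
        for name in alleles
        if name in instance.equivalent
    }
    return GenotypeCall(
        genotype, assignments, sorted(dropped), obj, residuals, status, warnings,
        relevant_eq,
    )


# ---------------------------------------------------------------------------
# solver backends


def _solve_scipy(model: ILPModel, mip_rel_gap: float = 0.0, time_limit: float | None = None):
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import lil_matrix

    n = len(model.variables)
    c = np.array([v.obj for v in model.variables])
    integrality = np.array(
        [1 if v.kind in "BI" else 0 for v in model.variables]
    )
    bounds = Bounds(
        np.array([v.lb for v in model.variables]),
        np.array([v.ub for v in model.variables]),
    )
    m = len(model.constraints)
    A = lil_matrix((m, n))
    lb = np.empty(m)
    ub = np.empty(m)
    for r, (coefs, lo, hi) in enumerate(model.constraints):
        for j, coef in coefs.items():
            A[r, j] = coef
        lb[r], ub[r] = lo, hi
    options = {"mip_rel_gap": mip_rel_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c,
        constraints=LinearConstraint(A.tocsc(), lb, ub),
        integrality=integrality,
        bounds=bounds,
        options=options,
    )
    if res.status == 0:
        status = "optimal"
    elif res.x is not None:
        status = "feasible"
    else:
        raise RuntimeError(f"MILP solve failed: {res.message}")
    return status, np.asarray(res.x), float(res.fun)


BACKENDS = {"scipy": _solve_scipy}


def solve_ilp(
    model: ILPModel,
    instance: ILPInstance,
    solver: str = "scipy",
    mip_rel_gap: float = 0.0,
    time_limit: float | None = None,
) -> GenotypeCall:
    """Solve the model and extract the genotype call.

    The default backend proves optimality (zero MIP gap) and is
    deterministic.  A timeout returns the best incumbent with a warning
    recorded on the call.
    """
    backend = BACKENDS[solver] if isinstance(solver, str) else solver
    status, x, obj = backend(model, mip_rel_gap=mip_rel_gap, time_limit=time_limit)
    warnings = [] if status == "optimal" else [f"solver returned {status} solution"]

    genotype: dict[str, dict[str, int]] = {}
    for a, (gene_id, _idx) in enumerate(instance.allele_keys):
        cn = int(round(x[model.a_index[a]]))
        if cn > 0:
            genotype.setdefault(gene_id, {})[instance.allele_names[a]] = cn
    assignments: dict[str, str] = {}
    dropped: list[str] = []
    for k, read_id in enumerate(instance.read_ids):
        chosen = [
            a for (kk, a), vi in model.v_index.items() if kk == k and x[vi] > 0.5
        ]
        if chosen:
            assignments[read_id] = instance.allele_names[chosen[0]]
        else:
            dropped.append(read_id)
    residuals: dict[tuple[str, int], float] = {}
    for (a, j), ei in model.e_index.items():
        if x[model.a_index[a]] > 0.5 or x[ei] > 1e-9:
            gene = instance.gene_of[a]
            pos = instance.landmark_positions[gene][j]
            residuals[(instance.allele_names[a], pos)] = float(x[ei])
    relevant_eq = {
        name: instance.equivalent[name]
        for alleles in genotype.values()
        for name in alleles
        if name in instance.equivalent
    }
    return GenotypeCall(
        genotype, assignments, dropped, obj, residuals, status, warnings, relevant_eq
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def call_sample(
    reads: list[Read],
    db: AlleleDB,
    neutral: str | tuple[str, str],
    cfg: CallConfig | None = None,
    coverage: CoverageModel | None = None,
) -> GenotypeCall:
    """Run alignment, filtering, landmarking, EM pruning and the ILP.

    ``neutral`` is the copy-number-neutral region (FASTA path or
    ``(id, sequence)``) used to calibrate xi unless ``coverage`` is
    given directly.
    """
    cfg = cfg or CallConfig()
    if not reads:
        logger.warning("call_sample: no reads supplied; returning empty call")
        return GenotypeCall({}, {}, [], 0.0, {}, "empty", ["no reads supplied"])
    try:
        if coverage is None:
            coverage = estimate_xi(
                reads,
                neutral,
                copy_number=cfg.neutral_copy_number,
                seed_len=cfg.seed_len,
                max_edits=cfg.max_edits,
            )
    except ValueError as exc:
        raise RuntimeError(f"[stage 1] coverage calibration failed: {exc}") from exc

    hits = all_hits(reads, db, seed_len=cfg.seed_len, max_edits=cfg.max_edits)
    hits = filter_hits(
        hits, db, min_score_frac=cfg.min_score_frac, max_clip_frac=cfg.max_clip_frac
    )
    if not hits:
        return GenotypeCall({}, {}, [r.read_id for r in reads], 0.0, {}, "empty",
                            ["no read aligned to the allele database"])

    surviving, landmark_sets, retained = generate_landmarks(hits, db, min_cov=cfg.min_cov)
    if not retained:
        return GenotypeCall({}, {}, [r.read_id for r in reads], 0.0, {}, "empty",
                            ["no placement covered a landmark"])

    candidates = sorted(
        {(h.gene_id, h.allele_index) for rh in retained for h in rh.hits}
    )
    try:
        state = em_fit(
            retained,
            db,
            candidates,
            init_eps=cfg.em_init_eps,
            max_iter=cfg.em_max_iter,
            tol=cfg.em_tol,
        )
    except (FloatingPointError, AssertionError) as exc:
        raise RuntimeError(f"[stage 2] EM failed: {exc}") from exc
    core_support = _core_support_counts(retained, db, candidates)
    kept = prune_by_abundance(
        state, gamma=cfg.em_gamma, core_support=core_support, min_cov=cfg.min_cov
    )
    if not kept:
        return GenotypeCall({}, {}, [r.read_id for r in reads], 0.0, {}, "empty",
                            ["EM pruned every candidate allele"])

    phi = {key: float(f) for key, f in zip(state.allele_keys, state.phi)}
    instance = build_instance(
        retained, db, kept, landmark_sets, coverage.xi, cfg, priority=phi
    )
    try:
        return solve_instance(instance, solver=cfg.solver)
    except RuntimeError as exc:
        raise RuntimeError(f"[stage 3] {exc}") from exc


def _core_support_counts(
    read_hits: list[ReadHits], db: AlleleDB, candidates: list[tuple[str, int]]
) -> dict[tuple[str, int], int]:
    counts: dict[tuple[str, int], int] = {key: 0 for key in candidates}
    core_pos = {}
    for gene_id, idx in candidates:
        gene = db.gene(gene_id)
        allele = gene.alleles[idx]
        core_pos[(gene_id, idx)] = {
            p
            for p in (lift_or_junction(allele, l) for l in gene.core_locations)
            if p is not None
        }
    for rh in read_hits:
        for h in rh.hits:
            pos = core_pos.get((h.gene_id, h.allele_index))
            if pos and any(h.start <= p < h.end for p in pos):
                counts[(h.gene_id, h.allele_index)] += 1
    return counts


def write_report(call: GenotypeCall, tsv_path: str | Path, json_path: str | Path | None = None,
                 sample: str = "sample") -> None:
    """Emit the call report: TSV summary plus JSON with read assignments."""
    import json

    with open(tsv_path, "w") as fh:
        fh.write("sample\tgene\tallele\tcopy_number\tn_reads\tmean_landmark_residual\n")
        for gene, alleles in sorted(call.genotype.items()):
            for name, cn in sorted(alleles.items()):
                n_reads = sum(1 for v in call.assignments.values() if v == name)
                res = [r for (nm, _), r in call.residuals.items() if nm == name]
                mean_res = sum(res) / len(res) if res else 0.0
                fh.write(f"{sample}\t{gene}\t{name}\t{cn}\t{n_reads}\t{mean_res:.3f}\n")
    if json_path:
        payload = {
            "sample": sample,
            "genotype": call.genotype,
            "objective": call.objective,
            "status": call.status,
            "warnings": call.warnings,
            "assignments": call.assignments,
            "dropped": call.dropped,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
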