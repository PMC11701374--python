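"""EM abundance filter: likelihood model, update steps, pruning."""

import numpy as np
import pytest

from kirdecomp.alleledb import Allele, AlleleDB, Gene
from kirdecomp.align import Hit, ReadHits
from kirdecomp.emfilter import (
    EMState,
    HitStats,
    em_fit,
    prune_by_abundance,
    read_likelihood,
)
from oracles import em_one_step

DNA = "ACGT"


def _db_of_lengths(lengths: dict[str, int], seed=0) -> AlleleDB:
    rng = np.random.default_rng(seed)
    genes: dict[str, list[Allele]] = {}
    for full, n in lengths.items():
        gene_id, name = full.split("*")
        seq = "".join(rng.choice(list(DNA), size=n))
        genes.setdefault(gene_id, []).append(
            Allele(gene_id, name, seq, set(), is_reference=not genes.get(gene_id))
        )
    return AlleleDB([Gene(g, alleles) for g, alleles in genes.items()])


def _rh(read_id, placements):
    """placements: list of (gene, allele_idx, start, matches, aligned)."""
    hits = [
        Hit(read_id, g, a, s, p, l, f"{l}=", p - (l - p) * 3)
        for (g, a, s, p, l) in placements
    ]
    return ReadHits(read_id, "N" * placements[0][4], hits)


class TestReadLikelihood:
    def test_perfect_hit_closed_form(self):
        stats = HitStats(m=1, p=50, l=50, allele_len=500)
        eps = 0.02
        assert read_likelihood(stats, eps) == pytest.approx((1 - eps) ** 50 / 500)

    def test_zero_multiplicity_is_zero(self):
        assert read_likelihood(HitStats(0, 50, 50, 500), 0.01) == 0.0

    def test_scalar_example_direct_arithmetic(self):
        """m=2, p=98, l=100, l_i=1000, eps=0.01 recomputed digit by digit."""
        got = read_likelihood(HitStats(2, 98, 100, 1000), 0.01)
        expected = 2 * (0.01**2) * (0.99**98) / 1000
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eps", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_eps_rejected(self, eps):
        with pytest.raises(ValueError):
            read_likelihood(HitStats(1, 10, 10, 100), eps)


class TestEMFit:
    def test_single_candidate_degenerate_simplex(self):
        db = _db_of_lengths({"G1*001": 300})
        reads = [_rh(f"r{i}", [("G1", 0, 0, 100, 100)]) for i in range(5)]
        state = em_fit(reads, db)
        assert state.phi[0] == pytest.approx(1.0)

    def test_first_iteration_matches_one_step_oracle(self):
        """E- and M-steps agree exactly with the update formulas on a
        10-read x 3-allele instance."""
        rng = np.random.default_rng(17)
        db = _db_of_lengths({"G1*001": 400, "G1*002": 420, "G2*001": 380})
        keys = [("G1", 0), ("G1", 1), ("G2", 0)]
        reads = []
        m = np.zeros((10, 3))
        p = np.zeros((10, 3))
        l = np.zeros((10, 3))
        for k in range(10):
            placements = []
            for j, (g, a) in enumerate(keys):
                if rng.random() < 0.7:
                    mm = int(rng.integers(1, 3))
                    ll = 100
                    pp = int(rng.integers(90, 101))
                    m[k, j], p[k, j], l[k, j] = mm, pp, ll
                    for rep in range(mm):
                        placements.append((g, a, rep * 120, pp, ll))
            if not placements:
                placements = [("G1", 0, 0, 100, 100)]
                m[k, 0], p[k, 0], l[k, 0] = 1, 100, 100
            reads.append(_rh(f"r{k}", placements))
        lens = np.broadcast_to([400.0, 420.0, 380.0], (10, 3))
        eps0 = 0.01
        phi0 = np.full(3, 1 / 3)
        mu_o, ll_o, phi_o, eps_o = em_one_step(m, p, l, lens, phi0, eps0)

        state = em_fit(reads, db, candidates=keys, init_eps=eps0, max_iter=1)
        np.testing.assert_allclose(state.mu, mu_o, atol=1e-12)
        assert state.loglik == pytest.approx(ll_o, abs=1e-9)
        np.testing.assert_allclose(state.phi, phi_o, atol=1e-12)
        assert state.eps == pytest.approx(eps_o, abs=1e-12)

    def test_responsibilities_normalized(self):
        rng = np.random.default_rng(21)
        db = _db_of_lengths({"G1*001": 300, "G1*002": 310})
        reads = [
            _rh(f"r{k}", [("G1", 0, 0, int(rng.integers(95, 101)), 100),
                          ("G1", 1, 0, int(rng.integers(95, 101)), 100)])
            for k in range(20)
        ]
        state = em_fit(reads, db)
        np.testing.assert_allclose(state.mu.sum(axis=1), 1.0, atol=1e-12)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(22)
        db = _db_of_lengths({"G1*001": 300, "G1*002": 310, "G1*003": 320})
        reads = []
        for k in range(30):
            placements = [
                ("G1", a, 0, int(rng.integers(92, 101)), 100)
                for a in range(3)
                if rng.random() < 0.8
            ] or [("G1", 0, 0, 100, 100)]
            reads.append(_rh(f"r{k}", placements))
        state = em_fit(reads, db)
        lls = [ll for _, ll, _ in state.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_error_free_single_source_concentrates(self):
        """Perfect reads private to one allele drive phi to its
        indicator."""
        db = _db_of_lengths({"G1*001": 300, "G1*002": 300})
        reads = [_rh(f"r{k}", [("G1", 1, 0, 100, 100)]) for k in range(10)]
        state = em_fit(reads, db, candidates=[("G1", 0), ("G1", 1)])
        assert state.phi[1] == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_two_of_five(self):
        """Reads from 2 of 5 alleles at 2:1 abundance with eps=0.01:
        the ratio and the error rate are both recovered."""
        ratio, eps_err = _recovery_replicate(1234)
        assert abs(ratio - 2.0) / 2.0 < 0.15
        assert eps_err < 0.30


def _recovery_replicate(seed, n_reads=2500, eps_true=0.01):
    """Simulate reads from alleles 0 and 1 at 2:1 among 5 candidates,
    fit, and report the recovered phi ratio and relative eps error.

    The read count keeps binomial sampling noise on the 2:1 ratio
    (~1/sqrt(n)) well below the tolerance being asserted, so a failure
    reflects the estimator rather than the draw.  Alleles 2-4 are
    paralog-like decoys (8% diverged copies of the true pair), giving
    real multi-mapping placements the likelihood model must down-weight.
    """
    rng = np.random.default_rng(seed)
    lengths = {f"G1*{i + 1:03d}": 1000 for i in range(5)}
    db = _db_of_lengths(lengths, seed=seed)
    alleles = [a for g in db.genes for a in g.alleles]
    for i, src in ((2, 0), (3, 1), (4, 0)):
        seq = list(alleles[src].sequence)
        for p in rng.choice(len(seq), size=int(0.08 * len(seq)), replace=False):
            seq[p] = "ACGT"[("ACGT".index(seq[p]) + 1 + rng.integers(0, 3)) % 4]
        alleles[i].sequence = "".join(seq)
    keys = [("G1", i) for i in range(5)]
    reads = []
    for k in range(n_reads):
        src = 0 if rng.random() < 2 / 3 else 1
        start = int(rng.integers(0, 1000 - 100))
        frag = list(alleles[src].sequence[start : start + 100])
        n_err = rng.binomial(100, eps_true)
        for pos in rng.choice(100, size=n_err, replace=False):
            frag[pos] = "ACGT"[("ACGT".index(frag[pos]) + 1 + rng.integers(0, 3)) % 4]
        frag = "".join(frag)
        placements = []
        for i, allele in enumerate(alleles):
            window = allele.sequence[start : start + 100]
            matches = sum(a == b for a, b in zip(frag, window))
            if matches >= 85:
                placements.append(("G1", i, start, matches, 100))
        reads.append(_rh(f"r{k}", placements))
    state = em_fit(reads, db, candidates=keys)
    phi = state.phi
    ratio = phi[0] / phi[1] if phi[1] > 0 else np.inf
    eps_err = abs(state.eps - eps_true) / eps_true
    return ratio, eps_err


class TestPrune:
    def _state(self, phi, keys=None):
        phi = np.asarray(phi, dtype=float)
        keys = keys or [("G1", i) for i in range(len(phi))]
        return EMState(keys, phi, 0.01, np.zeros((1, len(phi))), 0.0, 1, [])

    def test_threshold_arithmetic(self):
        state = self._state([0.7, 0.29, 0.0005, 0.0095])
        kept = prune_by_abundance(state, gamma=1e-3)
        assert kept == [("G1", 0), ("G1", 1), ("G1", 3)]

    def test_gamma_zero_keeps_all(self):
        state = self._state([0.5, 0.5, 0.0])
        # phi must be strictly above gamma; an exactly-zero component is
        # never "present"
        assert len(prune_by_abundance(state, gamma=0.0)) == 2

    def test_safety_rail_keeps_supported_gene(self):
        """A gene whose every allele falls below gamma keeps its best
        allele when core-supporting reads remain."""
        keys = [("G1", 0), ("G2", 0), ("G2", 1)]
        state = self._state([0.999, 0.0002, 0.0008], keys)
        kept = prune_by_abundance(
            state, gamma=1e-3, core_support={("G2", 0): 1, ("G2", 1): 8}, min_cov=3
        )
        assert ("G2", 1) in kept and ("G2", 0) not in kept

    def test_planted_alleles_survive(self, small_db, small_sample, small_reads):
        from kirdecomp.align import all_hits, filter_hits
        from kirdecomp.landmarks import generate_landmarks

        hits = filter_hits(all_hits(small_reads, small_db), small_db)
        _, _, retained = generate_landmarks(hits, small_db, min_cov=3)
        cands = sorted({(h.gene_id, h.allele_index) for rh in retained for h in rh.hits})
        state = em_fit(retained, small_db, cands)
        kept = set(prune_by_abundance(state, gamma=1e-3))
        for gene_id, alleles in small_sample.truth.genotype.items():
            gene = small_db.gene(gene_id)
            names_kept = {gene.alleles[i].major for g, i in kept if g == gene_id}
            for name in alleles:
                assert name[:3] in names_kept, f"{gene_id}*{name} pruned"
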