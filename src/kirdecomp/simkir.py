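"""Synthetic locus generator for a KIR-like family of paralogous genes.

Emulates the properties that make the real locus hard: several mutually
similar genes (descended here from a common ancestor sequence mutated to
a configurable identity, which forces ambiguous read mapping), per-gene
allele sets structured by the star-allele digit convention (3-digit
groups separated by planted *core* variants, trailing digits by *silent*
ones), diploid samples built as unions of two haplotype assemblies with
gene absence and duplication, and uniform-coverage paired-end reads with
an optional per-base substitution error rate.

All randomness flows through one ``numpy`` integer-protocol generator
seeded from the config, so every artifact is bit-reproducible across
platforms.  The ground truth (planted variants with core flags, per-gene
copy numbers, haplotype sequences) is carried alongside the observable
data and is consumed only by evaluation code, never by the caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alleledb import Variant, derive_variants

__all__ = [
    "SimConfig",
    "Truth",
    "SimulatedSample",
    "make_database",
    "make_diploid",
    "random_haplotype_spec",
    "simulate_reads",
    "simulate_sample",
    "write_sample",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    n_genes: int = 5
    gene_len: int = 4000  # scaled-down gene length; real KIR genes run ~13.4 kb
    alleles_per_gene: int = 6
    inter_gene_identity: float = 0.92
    n_core: int = 3  # core variants per non-reference major group
    n_silent: int = 2  # silent variants per minor allele
    core_indel_prob: float = 0.1  # chance a core variant is a short indel
    read_len: int = 100
    coverage: float = 20.0  # per haplotype assembly
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    error_rate: float = 0.0  # 0 = perfect reads
    spacer_len: int = 500
    neutral_len: int = 3000
    p_absent: float = 0.2  # per haplotype, chance a gene is missing
    p_duplicate: float = 0.1  # per haplotype, chance a gene appears twice
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.inter_gene_identity < 1:
            raise ValueError("inter_gene_identity must lie in (0, 1)")
        for name in ("n_genes", "gene_len", "alleles_per_gene", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Truth:
    """Planted ground truth serialized alongside the observable data."""

    variants: dict[str, dict[str, list[dict]]]  # gene -> allele -> variant dicts
    genotype: dict[str, dict[str, int]] = field(default_factory=dict)
    haplotypes: list[dict[str, list[str]]] = field(default_factory=list)

    def copy_number(self, gene_id: str) -> int:
        return sum(self.genotype.get(gene_id, {}).values())

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SimulatedSample:
    db_fasta: str  # multi-FASTA text of all alleles
    gene_sequences: dict[str, dict[str, str]]  # gene -> allele digits -> seq
    truth: Truth
    haplotype_seqs: list[str] = field(default_factory=list)
    reads: list[tuple[str, str, str]] = field(default_factory=list)  # (id, r1, r2)
    neutral: tuple[str, str] = ("neutral", "")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate_to_identity(rng: np.random.Generator, seq: str, identity: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(arr), 1.0 - identity)
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[p]]
        arr[p] = bytes([choices[rng.integers(0, 3)]])
    return arr.tobytes().decode()


def _plant_variant(
    rng: np.random.Generator, ref: str, taken: set[int], allow_indel: float
) -> Variant:
    """Draw one variant at a fresh, alignment-unambiguous position."""
    margin = 200
    while True:
        pos = int(rng.integers(margin, len(ref) - margin))
        if any(abs(pos - t) < 12 for t in taken):
            continue
        if rng.random() < allow_indel:
            if rng.random() < 0.5:
                n = int(rng.integers(1, 4))
                # avoid homopolymer edges so the leftmost-gap alignment
                # reproduces the planted coordinates exactly
                if ref[pos - 1] == ref[pos] or ref[pos + n] == ref[pos]:
                    continue
                v = Variant(pos, f"del{n}", is_core=True)
            else:
                ins = _random_seq(rng, int(rng.integers(1, 4)))
                if ins[0] == ref[pos] or ins[-1] == ref[pos - 1]:
                    continue
                v = Variant(pos, f"ins{ins}", is_core=True)
        else:
            old = ref[pos]
            alts = [b for b in "ACGT" if b != old]
            v = Variant(pos, f"{old}>{alts[rng.integers(0, 3)]}", is_core=True)
        taken.update(range(pos - 4, pos + 4 + v.del_length))
        return v


def _allele_names(count: int) -> list[tuple[str, list[str]]]:
    """Major-group layout: group -> member digit names.

    The first group (001) is the reference group; every group's first
    member carries exactly the group's core variants, later members add
    silent variants (and extend the digit string).
    """
    groups: list[tuple[str, list[str]]] = []
    major = 1
    remaining = count
    while remaining > 0:
        name = f"{major:03d}"
        members = [f"{name}0101"] if major == 1 else [name]
        remaining -= 1
        if remaining > 0:
            members.append(f"{name}0102" if major == 1 else f"{name}01")
            remaining -= 1
        groups.append((name, members))
        major += 1
    return groups


def make_database(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate the allele FASTA and the planted-variant truth tables.

    Genes descend from one ancestor mutated to the target identity; the
    planted edit script of every allele is verified to round-trip through
    alignment-based variant derivation (positions are re-drawn when a
    planted indel would be ambiguous), so the truth tables are exact.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    # each gene diverges from the ancestor by half the target pairwise
    # divergence, so gene-vs-gene identity lands on inter_gene_identity
    per_gene_identity = 1.0 - (1.0 - cfg.inter_gene_identity) / 2.0
    for _attempt in range(10):
        ancestor = _random_seq(rng, cfg.gene_len)
        refs = {
            f"GENE{g + 1}": _mutate_to_identity(rng, ancestor, per_gene_identity)
            for g in range(cfg.n_genes)
        }
        if len(set(refs.values())) == len(refs):
            break
    else:
        raise RuntimeError("could not generate distinct gene references")

    from .alleledb import apply_variants

    fasta_parts: list[str] = []
    gene_sequences: dict[str, dict[str, str]] = {}
    truth_variants: dict[str, dict[str, list[dict]]] = {}
    for gene_id, ref in refs.items():
        taken: set[int] = set()
        seqs: dict[str, str] = {}
        tv: dict[str, list[dict]] = {}
        for major, members in _allele_names(cfg.alleles_per_gene):
            core: list[Variant] = []
            if major != "001":
                while True:
                    core = [
                        _plant_variant(rng, ref, taken, cfg.core_indel_prob)
                        for _ in range(cfg.n_core)
                    ]
                    seq = apply_variants(ref, core)
                    if derive_variants(ref, seq) == set(core):
                        break
                    taken.update(v.location for v in core)
            for rank, name in enumerate(members):
                silent: list[Variant] = []
                if rank > 0:
                    while True:
                        silent = [
                            Variant(v.location, v.op, is_core=False)
                            for v in (
                                _plant_variant(rng, ref, taken, 0.0)
                                for _ in range(cfg.n_silent)
                            )
                        ]
                        seq = apply_variants(ref, core + silent)
                        if derive_variants(ref, seq) == set(core) | set(silent):
                            break
                planted = core + silent
                seq = apply_variants(ref, planted)
                seqs[name] = seq
                tv[name] = [
                    {"pos": v.location, "op": v.op, "core": v.is_core}
                    for v in sorted(planted, key=lambda v: v.location)
                ]
                fasta_parts.append(f">{gene_id}*{name}\n{seq}\n")
        gene_sequences[gene_id] = seqs
        truth_variants[gene_id] = tv
    return "".join(fasta_parts), gene_sequences, Truth(truth_variants)


def random_haplotype_spec(
    cfg: SimConfig, gene_sequences: dict[str, dict[str, str]], rng: np.random.Generator
) -> list[dict[str, list[str]]]:
    """Two haplotypes; per gene 0, 1 or 2 copies with random alleles."""
    spec = []
    for _hap in range(2):
        choice: dict[str, list[str]] = {}
        for gene_id, seqs in gene_sequences.items():
            u = rng.random()
            if u < cfg.p_absent:
                n = 0
            elif u < cfg.p_absent + cfg.p_duplicate:
                n = 2
            else:
                n = 1
            names = sorted(seqs)
            choice[gene_id] = [names[rng.integers(0, len(names))] for _ in range(n)]
        spec.append(choice)
    return spec


def make_diploid(
    cfg: SimConfig,
    gene_sequences: dict[str, dict[str, str]],
    truth: Truth,
    haplotype_spec: list[dict[str, list[str]]],
    rng: np.random.Generator,
) -> tuple[list[str], Truth, tuple[str, str]]:
    """Assemble two haplotype sequences from chosen alleles with random
    spacers and a shared copy-number-neutral segment; fill the truth
    genotype (copy numbers reflect both haplotypes)."""
    haplotypes = []
    genotype: dict[str, dict[str, int]] = {}
    neutral_seq = _random_seq(rng, cfg.neutral_len)
    for hap in haplotype_spec:
        parts = []
        for gene_id in sorted(gene_sequences):
            for name in hap.get(gene_id, []):
                parts.append(_random_seq(rng, cfg.spacer_len))
                parts.append(gene_sequences[gene_id][name])
                genotype.setdefault(gene_id, {})
                genotype[gene_id][name] = genotype[gene_id].get(name, 0) + 1
        parts.append(_random_seq(rng, cfg.spacer_len))
        parts.append(neutral_seq)
        parts.append(_random_seq(rng, cfg.spacer_len))
        haplotypes.append("".join(parts))
    truth.genotype = genotype
    truth.haplotypes = haplotype_spec
    return haplotypes, truth, ("neutral", neutral_seq)


_COMP = str.maketrans("ACGTN", "TGCAN")


def simulate_reads(
    haplotypes: list[str], cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[str, str, str]]:
    """Uniform paired-end fragments at cfg.coverage per haplotype.

    Pair count per haplotype is ``coverage * len / (2 * read_len)`` so the
    two mates together deliver the requested depth; fragment lengths are
    normal around ``insert_mean`` and starts uniform.  With a non-zero
    ``error_rate`` each base substitutes uniformly to another base.
    """
    pairs = []
    rl = cfg.read_len
    for h, seq in enumerate(haplotypes):
        n_pairs = int(round(cfg.coverage * len(seq) / (2 * rl)))
        for j in range(n_pairs):
            frag_len = int(np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd), rl, len(seq)))
            start = int(rng.integers(0, len(seq) - frag_len + 1))
            frag = seq[start : start + frag_len]
            r1 = frag[:rl]
            r2 = frag[-rl:].translate(_COMP)[::-1]
            if cfg.error_rate > 0:
                r1 = _add_errors(r1, cfg.error_rate, rng)
                r2 = _add_errors(r2, cfg.error_rate, rng)
            pairs.append((f"hap{h}_frag{j}", r1, r2))
    return pairs


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    for p in rng.choice(len(arr), size=n_err, replace=False):
        arr[p] = "ACGT"[(("ACGT".index(arr[p]) + 1 + rng.integers(0, 3)) % 4)]
    return "".join(arr)


def simulate_sample(cfg: SimConfig, haplotype_spec=None) -> SimulatedSample:
    """End-to-end convenience: database, diploid and reads in memory."""
    rng = np.random.default_rng(cfg.seed)
    db_fasta, gene_sequences, truth = make_database(cfg, rng)
    if haplotype_spec is None:
        haplotype_spec = random_haplotype_spec(cfg, gene_sequences, rng)
    haplotypes, truth, neutral = make_diploid(cfg, gene_sequences, truth, haplotype_spec, rng)
    reads = simulate_reads(haplotypes, cfg, rng)
    return SimulatedSample(db_fasta, gene_sequences, truth, haplotypes, reads, neutral)


def simulate_diploid(
    cfg: SimConfig,
    db_fasta: str,
    gene_sequences: dict[str, dict[str, str]],
    truth_variants: dict[str, dict[str, list[dict]]],
    sample_seed: int,
    haplotype_spec=None,
) -> SimulatedSample:
    """Draw one diploid sample (spec, haplotypes, reads) against a
    previously generated database; ``sample_seed`` drives everything
    sample-specific, so many samples can share one database."""
    rng = np.random.default_rng(sample_seed)
    truth = Truth(truth_variants)
    if haplotype_spec is None:
        haplotype_spec = random_haplotype_spec(cfg, gene_sequences, rng)
    haplotypes, truth, neutral = make_diploid(cfg, gene_sequences, truth, haplotype_spec, rng)
    reads = simulate_reads(haplotypes, cfg, rng)
    return SimulatedSample(db_fasta, gene_sequences, truth, haplotypes, reads, neutral)


def write_sample(sample: SimulatedSample, outdir: str | Path) -> dict[str, Path]:
    """Emit alleles FASTA, haplotype FASTA, paired FASTQ, neutral FASTA,
    variant TSV and truth JSON; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alleles": outdir / "alleles.fasta",
        "haplotypes": outdir / "haplotypes.fasta",
        "reads1": outdir / "reads_1.fastq",
        "reads2": outdir / "reads_2.fastq",
        "neutral": outdir / "neutral.fasta",
        "variants": outdir / "variants.tsv",
        "truth": outdir / "truth.json",
    }
    paths["alleles"].write_text(sample.db_fasta)
    with open(paths["haplotypes"], "w") as fh:
        for i, seq in enumerate(sample.haplotype_seqs):
            fh.write(f">hap{i}\n{seq}\n")
    with open(paths["reads1"], "w") as f1, open(paths["reads2"], "w") as f2:
        for rid, r1, r2 in sample.reads:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    paths["neutral"].write_text(f">{sample.neutral[0]}\n{sample.neutral[1]}\n")
    with open(paths["variants"], "w") as fh:
        fh.write("gene\tallele\tpos\top\tcore\n")
        for gene, alleles in sample.truth.variants.items():
            for name, vs in alleles.items():
                for v in vs:
                    fh.write(f"{gene}\t{name}\t{v['pos']}\t{v['op']}\t{int(v['core'])}\n")
    paths["truth"].write_text(sample.truth.to_json())
    return paths
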