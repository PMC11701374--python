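# Methods

## Model and pipeline

`kirdecomp` decomposes short-read data over a family of similar,
copy-number-variable paralogs into per-gene multisets of star-alleles.
The decomposition rests on three ideas: (i) allele identity is carried
by *core variants* — the edits shared by every member of a 3-digit
functional group and absent from the reference group — while silent
variants are ignored for identity; (ii) read ambiguity is resolved
globally, not per read: all plausible placements are enumerated and a
combinatorial optimization chooses one consistent explanation; (iii)
copy number is read off coverage at a small set of *landmark* positions,
calibrated against a copy-number-neutral region.

### Database construction (`alleledb`)

Input is a plain multi-FASTA of allele sequences named `GENE*DIGITS`
(3, 5 or 7 digits). Within each gene, alleles are anchored to the
*001-family reference by global alignment (Biopython `PairwiseAligner`,
match +1 / mismatch −2 / gap open −4 / extend −1, one extend unit
included in the open cost; ties resolved by the aligner's deterministic
leftmost-gap enumeration). The resulting edit scripts are stored as
variant sets `(location, operation)` in 0-based reference coordinates;
applying a script to the reference must reproduce the allele
byte-exactly, and this invariant is asserted over every database.
Records shorter than 80% of the reference are treated as partial
(e.g. coding-only) sequences, locally aligned onto the reference
backbone, and their imputed flanks recorded.

Core classification is purely name-structural: for each non-reference
3-digit group, the variants present in *every* member and absent from
the reference group's consensus are core; everything else is silent.
This is deliberately independent of exon annotations (a synthetic
database has none); when annotations exist they could refine the same
partition but are not required. A consequence worth knowing: in a group
with a single catalogued member, that member's private silent variants
are indistinguishable from core ones — real nomenclature avoids this by
cataloguing the group's base allele, and the synthetic generator does
the same.

### Stage 1 — alignment and calibration (`align`)

The built-in aligner is seed-and-extend with an exactness guarantee:
a read is chunked into non-overlapping `seed_len`-mers (default 14), so
any placement with at most `max_edits` errors (default
`read_len // seed_len − 1`, i.e. 6 at 100 bp) leaves at least one chunk
intact (pigeonhole) and is therefore seeded. Around each seeded
diagonal, the semi-global distance profile d(s) (read fully consumed,
start anchored at s) is evaluated with edlib; a hit is reported at every
exact start and at every leftmost local minimum of d with d ≤
`max_edits`. This rule is deliberately simple enough to recompute by
brute-force DP, which the test suite does. Reads overhanging allele ends
are soft-clipped. An optional minimap2 subprocess adapter accelerates
large inputs; the builtin engine defines the semantics.

Filters: clipped fraction > 0.25; score < 0.85 × attainable
(score = matches − 2·mismatches − gaps at 4 + length−1); and core
contradiction — any mismatch or indel in the read-to-allele alignment
overlapping a core location, including indels that merely span one.
Since hits are against the allele's own sequence, "contradiction" simply
means the read disagrees with the allele at a functionality-bearing
site.

ξ, the expected depth of a single allele copy, is the median
per-position depth over the neutral region divided by its copy number
(2 for an autosomal diploid region). The convention is per-haploid-copy:
a gene present once in the genome should show depth ≈ ξ.

### Stage 2 — landmarks and EM pruning (`landmarks`, `emfilter`)

An allele survives the coverage prefilter iff every core location of
its gene has ≥ `min_cov` (default 3) retained reads agreeing with the
allele's state there (variant or reference alike). Placements that cover
a core location, or whose read covers one through another placement,
form per-allele overlap graphs (undirected; the overlap relation is
symmetric, so strongly connected components coincide with connected
components, which is what we compute). Component spans are landmark
regions; the gene's landmark set L_g is its core locations plus the
minimum number of extra positions such that every relevant placement
covers at least one — placed greedily by right endpoint, which is
provably optimal for 1-D intervals. Landmarks live in reference
coordinates and are lifted through each allele's variant list, so
indel-bearing alleles shift them consistently; positions inside a
deletion map to the deletion junction. Placements covering no landmark
are then discarded. Landmark generation runs before the EM and its L_g
are reused by the ILP.

The EM treats reads as draws from a mixture over candidate alleles with
abundance φ and a symmetric per-base error channel ε:
P(r_k | Z_k=i) = m_ki ε^(l_ki−p_ki) (1−ε)^p_ki / l_i, with p the
matching bases, l the read bases placed, l_i the allele length and m_ki
the placement multiplicity within allele i (the scored p, l come from
the best placement; a config switch sums over placements instead).
Updates: μ_ki ∝ P(r_k|Z_k=i)φ_i; φ_i ← Σ_k μ_ki/m;
ε ← Σμ(l−p)/Σμl, clamped to [10⁻⁹, 0.5] so error-free data cannot
drive log ε to −∞. Initialization is uninformative (uniform φ,
ε = 0.01), tolerance 10⁻⁶ on the log-likelihood, at most 1000
iterations; monotonicity of the log-likelihood is asserted at every
step. Pruning removes alleles with φ ≤ γ = 10⁻³. This stage only
narrows the candidate set; a safety rail keeps the best allele of a gene
that still owns ≥ `min_cov` core-supporting reads, so an EM local
optimum cannot silently delete a gene.

### Stage 3 — ILP calling (`ilpcall`)

Binary V_ka assigns read k to candidate allele a through its
best-scoring placement; a read is only assignable to alleles tied for
its top score among surviving candidates. This restriction matters:
without it, reads whose sole landmark-covering placement is an imperfect
cross-gene one get herded onto paralogs and can fund phantom copies.
D_k = 1 − Σ_a V_ka drops the read at cost β = 0.08. Integer A_a ≥ 0
(default cap 4) counts copies. The objective is

    Σ_a Σ_{l∈L_g}  | Σ_{k covers l} V_ka / ξ  −  A_a |
        + γ Σ_a A_a + β Σ_k D_k,     γ = 0.1,

with absolute values linearized by continuous auxiliaries. The coverage
error is measured in copy units (divided by ξ): this makes the three
cost scales commensurate — a landmark missing a whole copy of coverage
costs 1, a dropped read saves ≈ 1/ξ per covered landmark — whereas raw
read-count residuals would let counting noise (~√ξ per landmark)
drown both β and γ and bias the optimum toward dropping entire genes.
Constraints: Σ_a V_ka + D_k = 1; per-copy coverage sanity bounds
0.5·A_a·ξ·|L_g| ≤ Σ_l Σ_k V_ka ≤ 1.5·A_a·ξ·|L_g| (aggregated over the
gene's landmark set, in raw counts, as the bound is a sanity envelope
rather than a fit term); linking A_a ≥ V_ka and Σ_k V_ka ≥ A_a. The
coverage bound binds per allele (no free read index appears in it).

Two exact solver paths exist. The per-read model is the reference
formulation, exported as an LP file for audit. At scale, reads with
identical incidence rows (same admissible alleles and covered landmarks)
are interchangeable, so they are bundled into integer count variables —
an exact reformulation verified objective-equal to both the per-read
model and brute-force enumeration on hundreds of random tiny instances.
Candidate alleles of a gene with identical incidence *columns*
(differing only by silent variants outside L_g) are provably
interchangeable too and are merged to one representative (highest EM
abundance, then lexicographic), recorded on the call as `equivalent`.
The backend contract is a callable returning (status, values,
objective); the bundled backend is HiGHS via `scipy.optimize.milp`,
single-threaded, zero MIP gap (proven optimality) by default.

## Synthetic data (`simkir`)

The generator emulates the features that make the real locus hard:

- genes descend from one random ancestor, each diverging by half the
  target pairwise divergence so gene-vs-gene identity matches
  `inter_gene_identity` (default 0.92, enough that reads cross-map);
- per-gene allele sets follow the digit scheme: each non-reference
  3-digit group carries `n_core` = 3 planted core variants (10% short
  indels, the rest substitutions) shared by all members; minor members
  add `n_silent` = 2 private silent variants. Every group's base member
  carries exactly the core set, so planted flags are recoverable from
  the name structure. Planted positions are re-drawn if the leftmost-gap
  alignment convention would not reproduce them exactly — the generator
  verifies its own truth tables by re-deriving them;
- diploid samples are two haplotypes, each a concatenation of chosen
  allele copies with random 500 bp spacers plus one shared neutral
  segment (3 kb); per haplotype and gene, absence has probability 0.2
  and duplication 0.1, emulating the locus's structural diversity, so a
  20-sample batch contains 0-copy and multi-copy gene instances;
- reads are uniform paired-end fragments (normal insert 350 ± 50),
  100 bp mates, `coverage` (default 20×) per haplotype, with optional
  uniform substitution errors (default 0 — perfect reads).

Default gene length is 4 kb, scaled down from the ~13.4 kb of real KIR
genes to keep a 20-sample batch within minutes on one CPU; nothing in
the pipeline depends on this scale. All randomness flows through a
single `numpy` generator seeded from the config, making every artifact
reproducible bit-for-bit.

What the generator does *not* emulate — and what passing tests therefore
do not establish — includes: empirical error and quality profiles,
indel sequencing errors, GC- and mappability-dependent coverage, novel
(uncatalogued) alleles, fusion alleles, and the segmental-duplication
structure of a real reference. Results on this simulator bound the
method's behavior under its own model assumptions, not its field
accuracy.

## Evaluation (`evaluate`, `cli`)

Calls are scored at functional resolution: names truncated to the first
three digits, then per-gene *multiset* comparison, so copy-number errors
count. TP = |truth ∩ call|, FP = |call − truth|, FN = |truth − call|,
misses = FP + FN; precision, recall and F1 from pooled counts
(micro-average) for the overall row. When a caller emits several
candidate solutions the one with fewest misses is scored. The CLI
(`kirdecomp db build | sim make | call | eval`) is a thin layer over
these functions with YAML config and per-stage timing logs.

## Numerical and degenerate-input choices

- EM in log space with `logsumexp`; responsibilities renormalized per
  read; non-finite likelihood aborts with the iteration dump.
- ε clamped to [10⁻⁹, 0.5]; φ floor 10⁻³⁰⁰ only inside logs.
- Zero reads, zero surviving hits, or an empty candidate set yield an
  explicit empty call with a warning rather than an error; zero neutral
  coverage is an error (ξ undefined).
- Solver determinism: HiGHS single-threaded, fixed variable order,
  zero gap; read-bundle assignment back to concrete reads follows
  sorted read ids.
- Reads shorter than `seed_len` produce no seeds and hence no hits.

## Known limitations

- Core classification cannot separate silent from core variants in
  3-digit groups whose only member also carries private silent variants.
- The best-score assignment restriction assumes the true placement is
  never outscored; at high error rates a read's placement on its source
  allele can lose the tie and the read is then only droppable.
- Copy-number resolution degrades when a gene's landmarks lie entirely
  within segments shared across paralogs; the coverage bounds then
  constrain the gene total more than the per-allele split.
- No novel-allele discovery: calls are confined to the database.
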