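# Methods

Precise definitions of the quantities `dbgfeat` computes, the numerical
conventions behind its byte-reproducibility guarantees, and its known
limitations.

## 1. Canonical k-mers

A k-mer is canonical if it is the lexicographic minimum of itself and its
reverse complement. `k` must be odd and ≤ 31 (default 31): odd length
guarantees no k-mer equals its own reverse complement, so every k-mer has
exactly one canonical representative. K-mers are packed 2 bits/base into
`uint64` such that numeric order equals lexicographic string order;
counting, set operations and serialization all operate on sorted code
arrays, which is why every dump is lexicographically sorted and every
operation is order-independent.

Windows containing a non-ACGT character are skipped (only those
windows). Per-sample k-mers with multiplicity < `min_count` (default 2)
are discarded: isolated singleton k-mers are overwhelmingly sequencing
errors, and removing them needs no quality model.

## 2. Pivot selection (supervised, one-vs-rest per category)

All selectors operate on the *presence matrix*: for each k-mer supported
by ≥ 1 sample, the number of samples of each category containing it.

**unique** — a k-mer is a pivot for category *C* if present in ≥ G
samples of *C* and in zero samples elsewhere. When G is not given it is
chosen automatically: prefer the largest G (most stringent) whose pivot
count lands in `target_range` (default 1 000–10 000); if no G lands
inside, take the G whose count is closest to the range, breaking ties
toward larger G.

**chisq** — per k-mer, the 2×2 category-vs-rest presence table
`[[a, b], [c, d]]` is scored with Yates's continuity correction:

    chi2 = N * (max(0, |ad − bc| − N/2))^2 / ((a+b)(c+d)(a+c)(b+d))

with any zero margin defined as statistic 0, p = 1. p-values are
Bonferroni-corrected over the number of k-mers actually tested (all
supported k-mers — not 4^k). Survivors must additionally be
over-represented in the target (a/(a+b) > c/(c+d)); they are ranked by
statistic descending (ties by k-mer) and truncated to `top_n`.

The closed form above clips the corrected deviation at zero. Note that
`scipy.stats.chi2_contingency(correction=True)` does *not* clip, so the
two disagree when |ad − bc| < N/2; the clipped form (which R's
`chisq.test` also uses) is the contract here, and tests verify it
against an independently computed per-cell clipped reference.

**stats** — conjunction of two Bonferroni-corrected tests: the chisq
presence test above AND a two-sided Mann–Whitney U test on the per-sample
abundance vectors (absent ⇒ 0). The U test uses midranks for ties; for
n + m ≤ 12 samples the p-value is exact by full permutation enumeration
(conditional on the pooled values), otherwise a normal approximation
with tie-corrected variance and continuity correction (matching scipy's
asymptotic mode). Both corrections use the number of tested k-mers.

### Sample-size floor under strict Bonferroni

With n samples split G-vs-rest, the smallest achievable Yates p-value is
attained at a perfect split and is bounded below — 0.10 at 3 v 3,
3.9 × 10⁻³ at 6 v 6, 5.7 × 10⁻⁵ at 10 v 10. Multiplied by the number
of tested k-mers (typically 10³–10⁶), **no k-mer can reach significance
at α = 0.05 with fewer than roughly a dozen samples per group**. This is
an honest property of strict Bonferroni control, not a bug; the `unique`
and `colored` modes have no such floor. Tests and examples demonstrate
the statistical modes with 16 samples per group.

## 3. De Bruijn graph and components

Nodes are canonical k-mers; two nodes are adjacent if any strand
orientations overlap by k−1 characters. Adjacency is implicit (≤ 8
candidate neighbors per node via both orientations), so the graph is
just the sorted code array plus per-k-mer summed abundances.

**local_search** (pivot expansion) — breadth-first from each unassigned
pivot. Pivot-bearing neighbors are always taken; at most `branch_limit`
(default 1) non-pivot continuations are taken per direction per node;
expansion stops at `max_radius` (default 100) from the seed or at
`max_component_size` (default 10 000) nodes. At finalization, pivot-free
subtrees hanging off junction nodes (induced degree ≥ 3) are pruned, and
components sharing any k-mer are merged, so every pivot lands in exactly
one component. With unlimited radius/branches and every node a pivot,
the result equals plain connected components (verified against a
union-find oracle).

**colored** — for each k-mer, the color vector over groups G:

    V_G(km) = (# samples of G containing km) / (# samples containing km)   (Eq. 1)

so ΣG V_G = 1 exactly. Limited to 2–3 groups by default (the vectors
become uninformative as groups multiply; override with
`allow_many_groups`). Two extraction modes: *threshold* keeps the
connected components of the subgraph {km : V_G(km) ≥ t} for each G
(t ∈ (0.5, 1], default 0.9); *top_n* grows components from the
best-colored seeds (highest V_G, then abundance) inside the V_G > 0.5
subgraph, keeping `n_per_group` per group.

**condense** (unsupervised) — drop k-mers with abundance below a
threshold, take connected components, keep those within `size_bounds`
(default 5–10 000); oversized components are re-split with a doubled
threshold, up to `max_iterations` (default 10) rounds, after which
still-oversized uniform components are accepted as-is.

## 4. Contigs and features

Each component is decomposed into unitigs — maximal non-branching
oriented paths; a unitig of m k-mers spells a contig of length
k + m − 1. Every component k-mer appears in exactly one contig
(cycles handled by a second pass), so the stored FASTA
(`>component_<id>_contig_<j> category=<c> size=<n>`) is a lossless
encoding of the component k-mer sets.

For component C and sample S:

* **breadth**(C, S) = |kmers(C) ∩ kmers(S)| / |kmers(C)| ∈ [0, 1]
* **depth**(C, S) = Σ_{km ∈ C ∩ S} count_S(km) / |kmers(C)|

Both denominators count distinct canonical k-mers. Tables are written as
TSV at 6 decimals — this precision is the round-trip contract.
`calc_features` re-k-merizes the stored contigs and recounts samples with
the same parameters, so recomputing training-set features from the FASTA
alone reproduces the training table **bit-exactly**; novel samples are
scored on exactly the same footing.

## 5. Machine learning

Random Forest (scikit-learn, 100 trees, `random_state = seed`) on the
feature matrix (samples × components). Cross-validation uses seeded
stratified K-fold; when the fold count exceeds the smallest class size
stratification is impossible, and the default policy (`stratified="auto"`)
falls back to plain shuffled K-fold rather than failing — the paper-style
default of 10 folds with 6 samples per class hits exactly this case.
`stratified="require"` turns the fallback into an error. Metrics:
accuracy, macro-F1 and Matthews correlation, per fold, averaged, and
pooled over all held-out predictions. PCA (full SVD) is made
deterministic by fixing each component's sign so its largest-magnitude
loading is positive.

A note on permuted-label baselines: pooled CV accuracy under label
permutation is *below* 0.5 in expectation for small n (training and test
folds are anticorrelated under permutation); with 12 samples the binomial
chance band 0.5 ± 3·sqrt(0.25/12) ≈ [0.07, 0.93] accommodates this, and
the acceptance checks interpret "chance level" via that band.

## 6. Synthetic communities

The generator plants known structure so recovery is measurable:
`n_background_genomes` uniform-random genomes shared by every sample,
plus `markers_per_group` group-exclusive marker sequences,
rejection-sampled so that no marker k-mer collides with any background
or other-group marker k-mer (truth sets are exact by construction).
Reads of fixed length are drawn uniformly with overhanging starts (ends
get full coverage), with optional i.i.d. substitution errors (≤ 5%).
Defaults — 2 groups × 6 samples, five 5 kb backgrounds, two 2 kb markers
per group, 150 bp reads at 30×, error 0, seed 42 — are chosen so the
whole study runs in seconds on one CPU while leaving each marker
recoverable as a single component. Output (gzip with zeroed mtime,
sorted iteration everywhere) is byte-deterministic given the seed.

These problem sizes are this package's own desk-scale choices; published
studies of this design run on hundreds of real samples and terabases of
reads, far beyond what a test suite can reproduce.

## 7. Limitations

* Strict Bonferroni gives the statistical modes a hard sample-size floor
  (§2); FDR-style alternatives are deliberately out of scope.
* k ≤ 31 (single machine word). Counting is in-memory; per-sample
  spectra of hundreds of millions of distinct k-mers will need sharding.
* The Mann–Whitney exact path enumerates all label assignments and is
  limited to n + m ≤ 12; beyond that the normal approximation is used.
* The synthetic generator models substitution errors only — no indels,
  no coverage bias, no strain mixtures.
* Depth features are raw mean abundances; no between-sample
  normalization (e.g. library-size scaling) is applied.
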