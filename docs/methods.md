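# Methods

## Model

`fflnet` analyses TF–miRNA co-regulation one developmental stage at a
time. The inputs are a stage's candidate sets — TFs and miRNAs nominated
for that transition, plus the genes differentially expressed across it —
and a typed catalog of directed regulatory edges with evidence labels
(`verified` > `chip` > `predicted`; duplicates collapse to the strongest
label). A feed-forward loop is a triple (TF, miRNA, gene) in which both
regulators target the gene and the regulators are linked in at least one
direction. The link direction defines three disjoint motif classes:
TF-FFL (TF→miRNA only), miRNA-FFL (miRNA→TF only) and composite (mutual
regulation). Mutual pairs are counted *only* as composite so the three
tallies partition the motif set; counting them additionally as TF- and
miRNA-FFLs would inflate those columns. The joint target must be a
candidate *gene*: loops closing on a TF are four-node structures and out
of scope. Evidence labels do not affect enumeration — filtering by
evidence is an upstream decision.

Enumeration walks candidate (TF, miRNA) pairs, classifies the pair link,
and intersects the two regulators' candidate-gene target sets; output is
deterministic in (tf, mirna, gene) lexicographic order.

## Evidence filters

* **Differential expression.** The two-group screen uses Welch's t-test
  per gene on log2 intensities with Benjamini–Hochberg correction, the
  standard choice for two-condition microarray comparisons; the test is a
  thin function (`welch_p_values`) that users may substitute. Fold change
  is 2^(mean log2 difference) and both directions count: a gene passes
  when |FC| > 2 **and** FDR < 0.01 (strict inequalities). Genes with zero
  variance in both groups get p = 1 when the means are equal (no evidence)
  and p = 0 otherwise (infinite t statistic). Whether fold change should
  be computed on linear intensities instead of log2 means is a genuinely
  open choice; log2 is used and flagged here for users with linear-scale
  data.
* **TFBS z-scores.** Predicted TF→gene edges keep records with
  z ≥ 2.33, boundary inclusive; the one-sided standard-normal tail at
  2.33 is 0.0099 < 0.01. Non-finite scores are rejected with a warning.
* **miRNA-target merge.** Experimentally verified targets pass
  unconditionally (evidence `verified`). Targets supported only by
  anti-correlated expression must additionally be predicted by both
  required sequence tools (TargetScan and miRanda by default; the labels
  are configurable) and enter as `predicted`.

Identifiers are canonicalised on input — TF/gene symbols upper-cased,
miRNA identifiers lower-cased, typographic dashes converted to ASCII —
because literature-derived tables mix forms. Precursor-to-arm miRNA
matching happens only through an explicit alias table; nothing is fuzzy-
matched, to avoid inventing regulations.

## Permutation enrichment test

The observed statistic is a stage's **total** FFL count (a single p-value
is reported per resampling axis, so the three types are summed). One axis
at a time, the candidate regulator set is replaced by a uniform
without-replacement sample of equal size from the corresponding universe
pool — the original candidates are not excluded from the pool — and the
motif count recomputed; p = (#{permuted ≥ observed} + c)/(n_perm + c)
with pseudocount c ∈ {0, 1} (default 0, so a reported 0 means "no
permutation reached the observed count"; use c = 1 when feeding p-values
downstream). The enrichment tail (≥) is the default because small
p-values are meant to flag enrichment; the opposite convention (fraction
of permuted counts *below* the observed) is available as
`tail="depletion_literal"` for completeness.

Because each triple contains exactly one TF and one miRNA, the total
count of any resampled set is a sum of fixed per-regulator contributions.
These are computed once per pool member and each permutation reduces to a
subset sum; a test asserts bit-equality with full re-enumeration. With
the default n_perm = 10,000 a stage test runs in well under a second.
The two axes use independent sub-seeds derived from the master seed, so
results are exactly reproducible from (inputs, seed).

## Networks, hubs, cross-stage structure

The stage network is the union of FFL edges (3 per one-way motif, 4 per
composite), nodes typed by role. Hub regulators: per node, degree and
out-degree are counted within the network; candidates of each class (TF,
miRNA separately, since hubs are reported per class) must have
out-degree/degree strictly greater than the class mean, are ranked by
out-degree (desc), then degree (desc), then identifier, and truncated at
five. When the strict filter eliminates an entire class — a single node,
or all proportions tied — the implementation falls back to plain
out-degree ranking and logs a warning; without the fallback, small stage
networks (a class of one or two nodes) could never report the hubs they
plainly have. Hub TF–miRNA pairs are ranked the same way on the number of
distinct genes the pair co-regulates in FFLs, mean taken over co-occurring
pairs, with a `mutual` flag for reciprocal regulation. Alternative
readings of "average" (over all regulators, or all nodes) are possible;
the class mean is the most direct and is what the code implements.

Common modules are computed on **edges**: each edge is assigned the
maximal set of stages whose networks contain it, and one module (edge set
plus induced nodes) is reported per distinct maximal stage set of size
≥ 2 — shared regulatory relationships, not merely shared nodes. Stage
comparison intersects regulator node sets (shared / A-only / B-only) and
reports genes targeted in both networks.

## Synthetic data

The generator emulates the *shape* of a curated stage dataset, not its
content: background pools of 200 TFs / 150 miRNAs / 1000 genes; candidate
sets of 13 TFs, 11 miRNAs and 48 genes (the scale of one B-lineage
transition); sparse background edges drawn independently per type
(defaults d_tg = 0.15, d_tm = 0.10, d_mg = 0.15, d_mt = 0.02 — miRNA→TF
edges are the rarest class in curated catalogs); and planted motifs
(10 TF-FFL / 3 miRNA-FFL / 1 composite by default, echoing TF-FFL
dominance). Planted triples use pairwise-distinct (TF, miRNA) pairs and
pairwise-distinct target genes: the pair constraint keeps planted types
from colliding, and the gene constraint guarantees that unions of planted
edges cannot close an unplanted triple, so at zero background density
enumeration returns exactly the planted list. Under background density a
reverse background edge can legitimately upgrade a planted one-way motif
to composite, so completeness is a triple-level (not type-level)
guarantee.

Background edges live on candidate × candidate pairs by default, matching
the shape of a catalog restricted to candidates. For permutation-null
studies that is the wrong universe — resampled regulators would have no
edges at all — so `edge_scope="universe"` draws the background across the
full pools instead; the calibration experiments use it.

The expression generator produces log2 intensities: per-gene baseline
uniform on [4, 12], plus the configured log2 fold change (default 2)
added to group 2 for a random planted subset (default 50 of 1000 genes),
plus Gaussian noise (default sd 0.25), with 10 samples per group. It
emulates only a two-group mean shift: no probe-level structure, no
correlation between genes, no realistic (scale-free) degree
distributions, no miRNA family structure. Passing tests on these data
therefore demonstrate correctness of the computations, not robustness to
the messiness of real microarray or curation data.

## Numerical and calibration choices

* All randomness flows through `numpy.random.default_rng`; dataset
  generation and permutation testing accept independent seeds, and the
  two permutation axes derive sub-seeds from the master seed.
* Monte-Carlo p-values with pseudocount 0 are slightly super-uniform
  under the null (ties between permuted and observed counts count as
  hits). The calibration study uses a configuration rich enough that ties
  are rare — pools of 40 TFs / 15 miRNAs / 120 genes, 12/10/60
  candidates, densities 0.2 (0.05 for miRNA→TF), universe-wide edges —
  and 200 replicate null p-values at n_perm = 500, checked against
  uniformity by Kolmogorov–Smirnov; the power study plants enrichment by
  taking the most FFL-participating TFs as candidates.
* Deterministic tie-breaks everywhere a ranking is produced (statistic
  desc, degree desc, identifier asc), so outputs are invariant to input
  row order. Synthetic identifiers are zero-padded so lexicographic order
  equals numeric order.
* Test-suite problem sizes are kept small (≤ 15 nodes per class for
  brute-force comparisons, n_perm ≤ 6000) — the oracles are exhaustive
  scans whose cost grows as the product of the class sizes.

## Known limitations

* SIF files carry no node-class attribute; classes are reconstructed from
  relation tokens, which is exact for FFL-union networks (every regulator
  has an out-edge) but would misclassify an isolated regulator in a
  hand-edited file. GraphML carries explicit attributes and round-trips
  any network.
* The permutation test resamples regulator identity labels only; it does
  not preserve degree structure (no rewiring null), which is the intended
  test here but a known stricter alternative exists.
* The DE screen assumes already-normalised log2 matrices; no probe
  summarisation or between-array normalisation is performed.
* Gene identifier cross-mapping is out of scope; inputs are expected to
  carry already-mapped symbols, with an explicit alias table as the only
  translation mechanism.
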