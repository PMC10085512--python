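# Methods

## Sequence-based counting

The unit of analysis is the exact insert sequence. A library's reads are
adapter-trimmed and identical inserts are tallied per sample; the resulting
integer matrix (unique sequences × samples) is never altered by any later
annotation step. The PAC object binds this matrix to a Pheno table (one row
per sample) and an Anno table (one row per sequence, starting with its
length), with hard invariants — identical row keys and order between Counts
and Anno, identical column keys and order between Counts and Pheno, no
negative entries — checked by `pac_check` and re-established by every
operation that returns a PAC. Row order is deterministic (total count
descending, ties lexicographic) so all written outputs are byte-stable.

Evidence filtering at count-table construction defaults to ≥ 2 reads in
≥ 2 samples, a conservative noise floor for sequencing singletons; pass
`EvidenceFilter(1, 1)` to keep everything (this is also the setting under
which column sums equal trimmed read counts exactly).

## Adapter trimming

The 3′ adapter is located by leftmost prefix-overlap matching: the insert
ends at the first position `p` where `read[p:]` matches a prefix of the
adapter over `min(len(read)-p, len(adapter))` ≥ `min_overlap` compared
bases with at most `floor(max_mismatch_fraction × overlap)` mismatches.
There are no indels in the search, matching the substitution-only error
model of short-read sRNA data, and the leftmost (shortest-insert) match is
the conservative choice against adapter read-through. Defaults:
`max_mismatch_fraction = 0.1`, `min_overlap = 10`, insert size window
16–75 nt (mature small RNAs rarely exceed 75 nt), zero ambiguous bases, no
quality filter. Reads without a detectable adapter are discarded by default
because in single-end sRNA libraries the adapter certifies that the entire
small RNA was read; `policy_no_adapter="keep"` is available for other
library types. The mean-quality filter, when enabled, averages Phred scores
over the retained insert only. Each read lands in exactly one accounting
category (retained, no-adapter, size, N, quality), so the per-sample report
always partitions the input — this is asserted on every run.

## Internal k-mismatch aligner

Reannotation aligns each unique sequence end-to-end and ungapped against
every window of every reference record, on both strands, reporting all
placements with Hamming distance ≤ k (k ≤ 3; beyond that, ungapped
alignment of short sequences is dominated by chance hits). The scan is
vectorized over reference positions (one numpy comparison per query base)
and is exact at every reference size — the hit set equals brute-force
enumeration by construction, which the test suite verifies against an
independently coded scan. Minus-strand hits are found by scanning the
reverse-complemented query and reported at forward-strand, 0-based,
half-open coordinates. Hit sets are monotone in k (hits(k) ⊆ hits(k+1)),
which is the mechanism behind false-positive inflation at permissive
mismatch settings; `false_positive_curve` quantifies it by aligning
uniform-random sequences of an empirical length distribution and reporting
the hit fraction per k and its ratio to perfect matching.

Per reference set, only the *minimal* mismatch stratum (mis0…mis3) and the
number of hits at that stratum are recorded; multimapping is deliberately
not resolved to one locus. Class resolution happens at the level of a
user-declared ordered hierarchy: under `strict_hierarchy` (default) the
first class with any hit wins regardless of stratum; under
`prefer_less_mismatch_within_class` the smallest stratum wins and hierarchy
order only breaks ties. Sequences hitting nothing get `no_anno`.

## tRF classification

A fragment placed at `[start, end)` on a tRNA reference (body + CCA when
the model's `cca` flag is set; loop coordinates are given on the body and
are unaffected by the appended CCA) is labelled by two anchor tests with
`end_tolerance` nt of slack (default 0): 5′-anchored iff `start ≤ tol`,
3′-anchored iff `end ≥ len − tol`. Both anchors → whole-tRNA; 5′ only →
5p-half if the fragment's **last base** lies inside the half-open
anticodon-loop interval, else 5p-tRF; 3′ only → 3p-half if the **first
base** lies inside the loop, else 3p-tRF; neither → i-tRF. Base containment
(rather than cut-site containment) makes a fragment ending on the loop's
first base a half and keeps the six labels an exact partition of all
placements, verified by exhaustive enumeration. The loop interval is
supplied per tRNA, so any coordinate convention can be configured and no
species-specific lookup table is involved. With CCA present, a fragment
stopping at the discriminator base is *not* 3′-anchored at zero tolerance —
the documented 1–2 nt tolerance absorbs non-templated additions.

Placement uses the internal aligner, forward strand only (tRFs are sense
fragments of the mature tRNA), at ≤ `max_mismatch` (default 0). Labels are
taken from the minimal-mismatch placements; under the default `report_all`
policy a sequence with conflicting labels keeps the sorted label set joined
by `|`, under `majority_label` the most frequent label wins with
alphabetical tie-break. The summary stratifies by label × tRNA × fragment
length; other stratifications can be derived from the per-placement call
table.

## Normalization, composition, PCA

CPM is the only built-in normalization: `counts × 10⁶ / library size`,
library size being the column total of the current table, computed before
any row filtering in the same call. Group summaries offer per-group mean
CPM and log₂ fold change with a pseudocount of 1 CPM (avoiding infinities
on dropouts). Composition tables are read-weighted (class share of each
library) or unique-sequence-weighted, and always sum to 1 per sample.

PCA operates on log₂(CPM + 1) with samples as observations, per-sequence
centering and no scaling — the standard transform for count data when no
variance-stabilizing model is assumed. It is computed by SVD; variance
fractions are squared singular values over total variance and sum to 1 at
full rank (n_samples − 1 after centering). Component signs are fixed by
making each loading vector's largest-magnitude element positive, so scores
are bit-reproducible across runs and write/read round-trips.

## Yield-loss regression

The rectangular hyperbola `y = I·x/(1 + I·x/A)` is the classical model for
crop-yield loss as a function of weed density, re-used here for the effect
of a contaminant fraction `x` on a sample-level response `y`: linear damage
`I·x` at low contamination saturating at `A`. `YieldLossModel(x, y).fit()`
runs bounded trust-region least squares (A > 0, I free) from three
deterministic initializations — `I₀` from a straight-line fit to the lowest
quartile of x, `A₀ = max|y|`, plus (½I₀, 2A₀) and (2I₀, ½A₀) — keeping the
best residual sum of squares. The fit requires ≥ 3 distinct x values, is
invariant to sample order, and reports convergence and RSS in a
statsmodels-style results object. Zero-noise data recover (I, A) to 1e-6
relative; Monte-Carlo recovery at 5 % noise is median-unbiased within 5 %
(both are asserted in the tests). When the true response is nearly linear
over the observed range, A is weakly identified and drifts large while I
remains stable — this is a property of the model, not a fitting failure.

`variance_vs_contamination` orients PC1 so its correlation with the
contamination fraction is non-negative (a PC's sign is arbitrary), anchors
the response at the least-contaminated sample so the model's y(0) = 0 is
meaningful, and returns the correlation together with the fit. Constant
contamination yields an explicit degenerate result instead of an error.

## Synthetic data generator

The generator emulates a single-end sRNA library sequenced with fixed read
length (default 75 nt): each read is an insert — a uniformly placed slice
of a randomly chosen source sequence from the sample's mixture of source
pools, with i.i.d. substitution errors at `error_rate` — followed by as
much of the 3′ adapter as fits, padded with random read-through bases.
Insert lengths default to discrete-uniform 16–45 nt; qualities are constant
Phred-40 (optionally uniform-random for exercising the quality filter); a
configurable fraction of reads carries no adapter. The default read length
is chosen so that the longest default insert still leaves at least the
minimum detectable adapter overlap in the read. Output is byte-identical
for identical specs, and a ground-truth table records every read's sample,
pool, source, coordinates and pre-error insert.

What it does **not** simulate: PCR duplicates, ligation/GC bias, chemical
modifications, indels, quality decay along the read, or paired ends.
Passing tests therefore demonstrate correctness of the counting, alignment
and classification logic under a substitution-only error model — not
robustness to library-preparation artefacts of real data.

## Demonstration experiment sizes

The end-to-end contamination experiment uses 12 samples × 1200 reads with
two pools of 3 × 60 nt sources and 16–22 nt inserts. Low source diversity
is deliberate: it makes the same sequences recur across libraries, the
regime (typical of real sRNA data, where a few species dominate) in which
a contamination gradient appears as a dominant principal component. With
highly diverse sources the PC1–contamination correlation remains > 0.95
but the variance is spread across components by singleton noise. Oracle
comparisons run at 500–2000 random queries against 2 kb–100 kb references;
all are exact-equality checks, so scale affects coverage, not tolerance.

## Provenance

Every pipeline run writes `manifest.json` recording, per step, the
operation, parameters and SHA-256 digests of inputs and outputs (relative
paths). Verification recomputes digests; when a later step legitimately
rewrites a file (Anno gaining annotation columns), the last recorded digest
is authoritative. Timestamps are omitted by default so identical configs
reproduce identical bytes, including the manifest; `record_time=True`
stamps steps at the cost of manifest-level reproducibility. Gzip outputs
are written with a fixed mtime for the same reason.

## Known limitations

- Ungapped alignment only; indel-bearing variants appear as high-mismatch
  or unaligned sequences (by design — they remain in the table and can be
  reannotated later).
- No 5′-adapter/UMI handling; no adapter auto-detection; single-end only.
- CPM is the only normalization; differential-expression statistics are
  out of scope — the PAC tables export cleanly to any downstream framework.
- The aligner is built for sRNA-scale references (feature databases,
  microbial genomes, ≤ a few Mb); it is exact but not engineered for
  mammalian whole-genome scans.
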