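# pacseq — sequence-based counting for small-RNA sequencing

Small RNAs are short, ill-defined, heavily multimapping and often
post-transcriptionally modified. Feature-based RNA-seq workflows — align
reads to one genome, sum overlapping reads into genes or miRNAs, discard
whatever fails to align — lose the read sequence itself in the very first
step. After that, differential mismatches, length shifts and contaminating
species are invisible, and no number in the final tables can be traced back
to the raw FASTQ.

`pacseq` inverts the order of operations. Identical read sequences are
counted **first**; alignment happens **afterwards**, as annotation:

1. **Trim** — 3′-adapter detection (leftmost prefix-overlap match with a
   mismatch fraction) delimits the insert and certifies a complete small
   RNA; adapterless reads are discarded by default.
2. **Count** — identical inserts are tallied into a matrix of unique
   sequences × samples. Together with sample metadata (Pheno) and
   per-sequence annotations (Anno) it forms a **PAC object**, three tables
   whose keys and order are kept aligned and machine-checked.
3. **Reannotate** — each unique sequence is aligned, ungapped and
   end-to-end, against any number of reference sets with ≤ *k* mismatches
   (*k* ≤ 3). Per set, the *mismatch stratum* (mis0…mis3 or no_hit) and the
   hit count at that stratum are recorded; a user-declared hierarchy
   (e.g. rRNA ≻ miRNA ≻ tRNA) resolves one class per sequence. Multimapping
   is never collapsed to a single locus.
4. **Classify tRFs** — tRNA-placed sequences are labelled 5′/3′-half,
   5′/3′-tRF, i′-tRF or whole-tRNA purely from their position relative to
   the anticodon loop and the CCA-bearing 3′ end, in any species.
5. **Model contamination** — per-sample class compositions, PCA of
   log₂(CPM+1), and the weed-science yield-loss hyperbola

   &nbsp;&nbsp;&nbsp;&nbsp;*y = I·x / (1 + I·x/A)*

   fitted by nonlinear least squares, linking a sample's contamination
   fraction *x* to a response *y* (such as its PC1 score): *I* is the
   initial slope — the damage done by the first trace of contamination —
   and *A* the saturation asymptote.

Every pipeline run writes a `manifest.json` of SHA-256 digests for each
step's inputs and outputs, so any result can be re-verified byte-for-byte
against the raw data (`pacseq verify`). A seeded synthetic-read generator
(`pacseq.simulate`) produces adapter-bearing multi-species libraries with
full ground truth, making the whole chain testable end to end.

## Worked example

A six-sample experiment in which a "microbial" pool contaminates a "host"
pool at fractions 0 → 0.8, analysed without ever telling the analysis which
reads are which:

```python
import tempfile
import numpy as np
import pandas as pd

from pacseq import (SimSpec, SourcePool, TrimParams, EvidenceFilter, AlignSpec,
                    HierarchySpec, ReferenceSet, gen_references, simulate_fastq,
                    trim_fastq, make_counts, make_pac, reanno, simplify_reanno,
                    pca_counts, variance_vs_contamination, composition)

adapter = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
lengths = tuple(range(16, 23))
host = SourcePool("host", gen_references(1, 3, 60), length_dist=lengths)
microbe = SourcePool("microbe", gen_references(2, 3, 60), length_dist=lengths)
fractions = np.linspace(0.0, 0.8, 6)
mixture = {f"s{j}": {"host": 1 - f, "microbe": f} for j, f in enumerate(fractions)}
spec = SimSpec(pools=[host, microbe], per_sample_mixture=mixture,
               n_reads_per_sample=1000, adapter=adapter, seed=3)

with tempfile.TemporaryDirectory() as tmp:
    fastqs, truth = simulate_fastq(spec, tmp)
    per_sample = {s: trim_fastq(p, TrimParams(adapter=adapter), sample=s)[0]
                  for s, p in fastqs.items()}

counts = make_counts(per_sample, EvidenceFilter(min_count=2, min_samples=2))
pheno = pd.DataFrame({"sample_id": list(mixture), "microbe_frac": fractions})
pac = make_pac(pheno, counts)
print(pac)

refs = [ReferenceSet(p.name, {f"r{i}": s for i, s in enumerate(p.sequences)})
        for p in (host, microbe)]
table = reanno(list(pac.anno.index), refs, AlignSpec(max_mismatch=0))
hier = HierarchySpec(levels=[("host", "host"), ("microbe", "microbe")])
pac.anno = pac.anno.join(simplify_reanno(table, hier))
print(composition(pac, "resolved_class")[["host", "microbe"]].round(3))

res = pca_counts(pac)
effect = variance_vs_contamination(res, pac.pheno["microbe_frac"])
print(f"PC1 explains {res.var_explained[0]:.1%} of variance")
print(f"corr(PC1, microbial fraction) = {effect.correlation:.3f}")
```

Output:

```
PACObject(306 sequences x 6 samples, anno columns: ['length'])
resolved_class   host  microbe
sample_id
s0              1.000    0.000
s1              0.962    0.038
s2              0.868    0.132
s3              0.693    0.307
s4              0.544    0.456
s5              0.332    0.668
PC1 explains 40.2% of variance
corr(PC1, microbial fraction) = 0.976
```

The read-weighted composition recovers the simulated contamination gradient
(the small deviations are sampling noise plus the hierarchy's host-first
priority on chance ties), and the first principal component of the count
table tracks the contaminant fraction almost perfectly. `effect.fit` holds
the fitted yield-loss curve; at these settings the response is close to
linear over the sampled range, so the asymptote `A` is large and poorly
pinned while the initial slope `I` is stable — `effect.fit.summary()`
prints both with the residual sum of squares.

The same pipeline runs from the shell via a single config file:

```bash
pacseq run --config experiment.yaml --out results/
pacseq verify results/        # recompute all manifest digests
```

plus per-step commands (`pacseq simulate|trim|count|filter|norm|summary|
reanno|trf|pca|composition|yieldloss`).

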