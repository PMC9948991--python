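# Methods

## Single-insertion simulation model

Each replicate plants exactly one TE insertion. Given a breakpoint `p` and a
TSD length `t`, the duplicated bases `D` are the reference bases `[p, p+t)`
and the synthetic chromosome is

    ref[0 : p+t] + TE + ref[p : L]

with the consensus reverse-complemented for minus-strand insertions. The
inserted element is therefore flanked by a copy of `D` on each side, the
synthetic chromosome is exactly `|TE| + t` bp longer than the reference, and
excising the TE plus one TSD copy restores the reference string exactly.
Biologically, which flank "is" the duplication is not observable — the two
copies are identical — so the convention anchors the truth interval at
`[p, p+t)` in reference coordinates, which is symmetric and reproducible.
The default TSD length is 5 bp, the value shared by all yeast Ty families.

Insertion plans are drawn from a user-supplied set of permissible intervals:
the family per the family policy (uniform over the library by default;
per-family weights can be supplied as a table when a taxon-specific
insertion model is wanted), the interval with probability proportional to its
width, the breakpoint uniformly within the interval, and the strand +/− with
probability 1/2 unless fixed. Two site models ship with the fixtures: a
tRNA-promoter model (the ~1 kb immediately 5′ of each tRNA TSS, mirroring
the integration preference of yeast Ty elements) and a unique-region model
(the complement of tRNA neighbourhoods), which separates detector
performance in repeat-rich target regions from baseline performance.

## Read simulator

The bundled simulator is deliberately minimal: uniform fragment placement,
truncated-Normal fragment lengths (rejection sampling, 1,000-round cap so a
degenerate range on a tiny chromosome fails loudly instead of biasing
silently), per-base substitution errors at a uniform rate, constant base
quality (Q40). Pair count per chromosome is `round(cov·L / (2·read_len))`,
which makes mean depth equal the requested fold-coverage by construction;
single-end mode emits `round(cov·L / read_len)` reads. It models neither
indels, quality decay along the read, GC bias, nor duplicate fragments —
adequate for exercising breakpoint detectors on clean signal, not for
calibrating error-model-sensitive tools. Down-sampling keeps each read pair
independently with probability `target/current` (mates always together),
the standard behaviour of seqtk-style thinning.

## Scoring

The within-N predicate tests **both** endpoints of a call against the truth
TSD interval's endpoints (`|start−s| ≤ N` and `|end−e| ≤ N`). Testing the
two endpoints symmetrically, rather than a single breakpoint, means a call
of the wrong length can pass wide windows but never within-0. A "." strand
on a call is a strand mismatch by default, since the definition of a true
positive includes strand identity; `ignore_strand` relaxes this for
detectors that do not report strand. Reference-category calls are tallied
for the mean-count summaries but never enter TP/FP/FN. When several calls
match within-N, the one nearest the truth start is recorded as the match for
the audit trail, but only one TP is counted — the rest are FPs. Precision
with zero positive calls is reported as missing (empty CSV cell), never 0.

## Copy number

`copy_number = location(depth over consensus region) / mean(depth over
non-repetitive regions)`. The location statistic is the mean by default (a
median flag exists for spike-robust estimates); the non-repetitive interval
set is a required input rather than something inferred, because "non-
repetitive" is assembly- and annotation-dependent. Union semantics
deduplicate overlapping background intervals so each base counts once.
`edge_trim` (default 0) exists because consensus termini are systematically
under-covered in real alignments. Under the Poisson depth model the
estimator's standard error at background `b` over a consensus of length `m`
is `sqrt(c·b/m)/b`; at b = 50×, m = 5 kb this is under 0.015 even at 20
copies, hence the recovery checks use a 0.1 absolute band.

## Positional profiling

Promoter-window filtering keeps a call that overlaps, for any feature, the
window from `upstream` bp 5′ of the feature to `downstream` bp 3′ of it
(defaults 1000/500), with the flanks swapped for minus-strand features —
the stranded-window idiom of interval tools. Signed TSS distance is measured
from the call's interval midpoint (floor for even lengths; midpoint is the
symmetric choice for TSD-style intervals) and is feature-relative: upstream
of the TSS is negative regardless of which genomic direction that is. The
KDE uses a Gaussian kernel with bandwidth `0.4 × nrd0`, where nrd0 is
Silverman's rule `0.9·min(sd, IQR/1.34)·n^(−1/5)` — the narrow-kernel
setting conventional for insertion-site density plots — evaluated on 512
points spanning the data ± 3 bandwidths. Signal aggregation around TSSs
extracts `[TSS−2000, TSS+500)` per feature, reverses the vector for
minus-strand features, and averages per relative position ignoring missing
values.

## Determinism

All randomness flows from one integer seed through numpy Generators. The
benchmark derives each replicate's generator from
`SeedSequence(seed, spawn_key=(coverage_index, replicate))`, so cells are
independent and the whole grid is reproducible byte-for-byte, which the
tests assert on FASTA/FASTQ/CSV output.

## Problem sizes

The toy dataset is a 3-chromosome, 100-kb genome with three TE families
(1.5–2.5 kb, LTR-flanked with defined internal regions) and 20 tRNA genes.
Benchmarks in the tests and the acceptance script run 3 replicates per
coverage over the 3–100× grid for the perfect-detector identity, 200
replicates at 10× for the noisy-stub calibration, and 5-kb consensi at 50×
background for copy-number recovery. These sizes keep a full run in tens of
seconds while leaving the statistical checks well-powered (binomial/Poisson
standard errors an order of magnitude below the tested tolerances).

## Known limitations

One insertion per genome (multi-insertion genomes, tandem and nested
elements are out of scope); no wrappers for real detector binaries — the
pluggable detector interface takes any callable, and the bundled stubs have
known accuracy by construction; depth is consumed from text tracks, not
computed from alignments; the occupancy track in the fixtures is a
sinusoidal stand-in with nucleosome-like periodicity, not inferred from
MNase-seq. Passing tests on the toy data show the machinery is correct, not
that any particular real detector performs well.
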