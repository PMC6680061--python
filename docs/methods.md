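# Methods

## Model

Depth of coverage at reference position *j* is the number of kept reads with
an alignment block covering *j*. A read's blocks are the maximal
reference-contiguous covered intervals of its CIGAR: `M`, `=` and `X` cover;
`D` (deletion) covers under the default policy (a read spanning a deletion
still supports depth there, the semantics of `samtools depth -J`) and can be
switched off; `N` (splice skip) consumes reference but never covers, so it
always splits blocks; `I`, `S`, `H`, `P` consume no reference and never split.
Adjacent covered segments are merged, so blocks from one read are strictly
increasing and non-adjacent.

Instead of incrementing a counter at every covered base (pileup), the
algorithm records two events per block — +1 at `start`, −1 at `start+len` —
and recovers depth as the cumulative sum of the delta array. Per (partition,
contig) the array covers only `[min block start, max block end + 1]` with the
genomic offset stored alongside, so memory scales with the covered span, not
the contig; results are unchanged by this restriction.

## Partitioned execution

`partition_reads` splits the filtered, coordinate-ordered stream into ≤n
contiguous slices whose sizes differ by at most one read. Boundaries are by
read count only; a slice may span a contig boundary and two slices may cover
intersecting genomic ranges. Each slice independently yields
`partial_coverage` vectors (optionally on a process pool; the coordinator
gathers (extent, vector) pairs — the in-process equivalent of a
gather–scatter over shared state).

Merging folds left to right per contig. For consecutive holders whose extents
intersect by *l* positions, the left vector's *l*-length tail is added
elementwise onto the right vector's head and removed from the left; totals
are conserved by construction. Two deliberate extensions keep the fold exactly
equal to the n=1 computation in the corner cases a pairwise rule alone does
not cover:

* **Cascade rule.** If the left tail reaches past the right vector's end (a
  single long block spanning ≥2 downstream partitions), the right vector is
  zero-extended to the tail's end before the addition, so the surplus is
  carried into the next comparison. Verified with singleton partitions and a
  600-base block crossing six of them, and on a 10,000-read fixture whose
  800-base reads span ≥3 of 64 partition extents.
* **Re-trimming.** Cutting a tail can expose trailing zeros on the left
  vector; these are trimmed so the first/last-nonzero invariant holds and
  downstream overlap detection sees true extents.

Mis-ordered inputs fail loudly: a right vector starting before its left
neighbour, or partials out of partition order, raise rather than merge
silently.

## Output types

* **per-base** — one row per position; zero-depth positions omitted by
  default (the samtools-depth convention), emitted under `include_zeros`.
* **blocks** — maximal runs of equal depth; expanding blocks back to
  per-base reproduces it exactly (tested as an identity).
* **windows** — tiling bins anchored at position 1 of each contig (the one
  anchor needing no extra parameter); the mean always includes zero-depth
  positions, the terminal window may be short and its mean is over its actual
  length. Windows are emitted for the complete tiling of every contig in the
  header, including tails beyond the last read and contigs without reads —
  a mean over a fixed bin is only well defined on the full grid.

Σ(per-base depth) = Σ(block lengths of kept reads) and
Σ(window mean × window length) = Σ(per-base depth) hold on every input and
are asserted in the test suite.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `exclude_flags` | `0x704` | drop reads with UNMAP/SECONDARY/QCFAIL/DUP bits; the samtools-depth default, so default output is comparable to `samtools depth` |
| `min_mapq` | 0 | minimum mapping quality, inclusive |
| `count_deletions` | true | deleted reference bases count as covered (`samtools depth -J` semantics); `--no-deletions` matches plain `samtools depth` |
| `include_zeros` | false | emit zero-depth rows in per-base/blocks |
| `n_partitions` | 1 | read-stream slices; any value ≥1 gives identical output |
| `workers` | 1 | processes computing slices; never affects output |
| `window` | — | bin width in bp, required for windows output |

## Numerical choices

Depth counters are compact 16-bit unsigned integers by default, honouring the
memory rationale for parsimonious types in the original design. The cumulative
sum itself runs in 64-bit; if any depth exceeds 65,535 the stored vector is
promoted to 32-bit. Overflow therefore cannot wrap silently — exactness at
70,000× is a tested contract. A negative running sum (only possible from a
corrupted delta array) raises immediately. Window means are written with
fixed 4-decimal formatting so repeated runs are byte-identical.

Coordinates are 1-based inclusive everywhere internally and in TSV/CSV
output; BED conversion to 0-based half-open happens only in the writer.
Contig order follows the header reference dictionary, matching samtools.

## Synthetic data and what it shows

`FixtureSpec`/`generate_fixture` emulate exactly the features depth depends
on: read placement, CIGAR structure (match segments interleaved with
insertions, deletions, splice skips, soft clips at tunable rates and length
ranges), duplicate/secondary/QC-fail/unmapped flag fractions, and a MAPQ
distribution. Defaults (100-bp reads, 5% indel junction rates, 2% skips, 10%
clip probability, 5/3/2/2% flagged fractions, MAPQ uniform 0–60) are a
generic short-read resequencing profile; long-read layouts are produced by
raising `read_length` into the kilobases with wider indel/skip ranges. Base
content, qualities, sequencing error and mate-pair structure are *not*
modelled — coverage is a pure function of alignment layout, so passing tests
establish correctness of the counting, not anything about aligner behaviour
on real data.

Ground truth comes from an independent pileup oracle that walks every kept
read's CIGAR position by position with its own cursor and flag check, sharing
no code with the event path. One test additionally cross-checks the oracle
itself against `samtools depth` (with and without `-J`) on a mixed fixture.

## Test scale

The suite runs on one CPU in well under a minute: 50 oracle-equivalence
fixtures of 60–300 reads over 1–3 contigs of 2–20 kb, a 10,000-read
partition-invariance grid, and a 70,000-read deep-locus stack. These sizes
were chosen as the smallest that still exercise every code path (all CIGAR op
kinds, multi-partition block spans, counter promotion); the algorithms are
linear in read count and covered span, so nothing about the method changes at
larger scale.

## Known limitations

* CRAM input, remote/object-store access and BGZF decompression tuning are
  out of scope; input is local SAM or BAM.
* Parallelism is a single-host process pool; there is no cross-machine
  execution.
* No GC or mappability normalisation, and no median/quantile window
  statistics — windows report arithmetic means only.
* Overlapping mates of one template are counted independently (as does
  `samtools depth` without `-s`).
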