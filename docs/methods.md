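# Methods

## Model of the RRBS library

Every sequenced RRBS molecule is an MspI restriction fragment. MspI cuts
`C^CGG` on both strands, leaving 5'-CG overhangs, so in 0-based genome
coordinates a fragment is the interval `[site_i + 1, site_{i+1} + 1)`
between consecutive motif occurrences: its top strand begins `CGG` and ends
with the first C of the downstream `CCGG`. Terminal genome pieces with only
one MspI end are not fragments — they cannot be adapter-ligated on both
sides. Fragments containing N are dropped because neither conversion nor
alignment is defined over ambiguous bases.

End repair fills the recessed 3' ends using the overhang as template: the
top strand gains the downstream `CCGG`'s C and G (genomic positions `end`,
`end+1`), the bottom strand gains the complement of the upstream `CCGG`'s G
and C (positions `start+1`, `start`). Both fill-in cytosines therefore sit
on genuine genomic CpG dyads — the junction dyads at the fragment's cut
sites — but are unmethylated on the molecule regardless of the genome's
state. That is the entire artifact: junction CpGs receive a systematic,
always-unmethylated vote whenever a fragment is shorter than the read.

After the single-A spacer (A-tailing) and the adapter (default: the
Illumina TruSeq read-1 adapter prefix) are appended, the whole entry is
converted C→T. Reads are converted the same way, so the adapter's physical
methylation state is irrelevant to alignment; it matters only to the
simulator's raw-read emission, which emits adapter bases unchanged
(methylated-adapter model).

## Alignment

Directional libraries only: read 1 always begins at a fragment's 5' `CGG`,
so reads are matched forward-only, against both strand entries of every
fragment. The aligner is a seed-and-extend ungapped matcher: an exact match
of the read's first *k* converted bases (default *k* = 20) anchors
candidate offsets via a hash of all entry *k*-mers; extension counts
mismatches over the full read with an early exit past the limit (default
*M* = 2). No indels, no quality-aware scoring — mismatch counting only.
Reads shorter than *k* are unaligned. A read must fit entirely inside an
entry (entries carry the adapter tail precisely so that short-fragment
reads do fit).

Resolution: hits on more than one distinct fragment → discarded (the two
strand entries of one fragment are the same fragment); otherwise a
placement at offset 0 (the fragment start, where real RRBS reads begin)
wins; remaining ties break by fewest mismatches, smallest offset, then top
strand. Lift-over maps entry index *i* to `frag_start + i` (top) or
`frag_end + 1 − i` (bottom); fill-in bases keep their genomic coordinates
and stay inside the CIGAR match, spacer/adapter bases are soft-clipped. A
placement lying entirely in the tail (possible only for adapter-dimer-like
input) is demoted to unaligned rather than emitting a matchless SAM record.

## Methylation calling

Pileups tally the *pre-converted* read bases at the reference-cytosine
positions of each entry's repaired sequence (the only positions any
downstream consumer reads); bases other than C/T at a reference C are
counted as `other` and excluded from both numerator and denominator. With
exclusion on (default), the fill-in position of each strand entry
contributes nothing; the genuine opposite-strand cytosine of the same
junction CpG still counts, as does the neighbouring fragment's evidence for
the same dyad. Because fill-in evidence is always T, disabling exclusion
can only lower an affected CpG's ratio, never raise it.

Contexts (CpG/CHG/CHH) come from the genome, not the fragment; the default
report is CpG-only, with non-CpG contexts behind a flag. Dyad merging pools
the plus-strand C at *p* with the minus-strand C at *p+1*, reported at *p*.
Output conventions: TSV positions 1-based, bedGraph 0-based half-open.

## Simulator

Defaults are the standard study conditions: 50 bp reads, per-CpG
methylation probability 0.20, fragment pool 30–250 bp with mean 70 bp.
The methylation parameter is a **per-site binary Bernoulli state** shared
by both strands of a dyad, not a per-read coin flip — only under this
reading can a lossless pipeline recover truth exactly. Two truth modes:

- `iid` — independent Bernoulli(p) per dyad (calibration tests);
- `mosaic` — dyads grouped into blocks with exponentially distributed
  lengths (default mean 500 bp, a typical scale for regional methylation
  domains), one shared state per block. Mosaic truth makes the
  autocorrelation diagnostic meaningful: with i.i.d. truth the expected
  autocorrelation is zero, so there is nothing for the artifact to degrade.

Fragment sampling uses truncated-exponential weights `w ∝ exp(−λ·length)`
with λ solved (Brent's method) so the expected sampled length equals the
target mean — the maximum-entropy distribution given only the range and
mean; a uniform-weight flag exists. Strand is drawn uniformly; reads always
start at the fragment 5' end; molecules shorter than the read are padded by
repeating the adapter. Bisulfite conversion is complete and sequencing
error-free by default; both are configurable (`conversion_rate`,
`error_rate`) for robustness experiments. Quality strings are constant Q40.

## Evaluation definitions

- **%unique** = unique-status reads / all reads; **%correct** = unique
  reads whose lifted chromosome, leftmost position and strand equal the
  truth record / all reads (so %correct ≤ %unique by construction).
- **Recall**: covered CpG dyads / *expected* dyads, where expected means
  dyads whose cytosine lies within one read length of either fragment end
  (the only dyads a directional fragment-start read can reach). This
  denominator is a design choice; no universal definition exists.
- **Autocorrelation**: Pearson r of dyad-merged ratios over all
  same-chromosome CpG pairs at exact distance d, for d = 1..100; NA when
  fewer than 3 pairs or zero variance.
- **Fragment uniqueness**: percent of size-selected fragments whose
  top-strand sequence occurs ≥ 2 times, before and after C→T conversion.
  Every member of a duplicate group is counted by default
  (group-counting and reverse-complement canonicalisation are flags);
  conversion is many-to-one, so the converted percentage never drops below
  the raw one.

## Synthetic genomes and what the tests do and do not show

`synthetic_genome` plants `CCGG` motifs at uniform random spacings (default
20–420 bp) on an i.i.d. background (default GC 0.5); chance motifs in the
background are genuine extra cut sites. One megabase yields roughly 6,000
fragments in the 30–250 bp window and ~45,000 CpG dyads with truth states —
enough for stable percentages at the default read counts.

Passing tests on this material demonstrate the pipeline's *logic*: exact
coordinate bookkeeping, lossless round-trip recovery, correct artifact
masking, and deterministic outputs. They do not demonstrate performance on
real genomes, which have repeats and near-duplicate MspI fragments
(ambiguous reads are discarded, lowering %unique), incomplete bisulfite
conversion, sequencing errors, and non-uniform fragment sampling. The
simulator can inject conversion failures and errors, but its error model is
uniform and quality-blind.

## Numerical and degenerate-input choices

- Size selection is inclusive on both bounds, measured on the cut-to-cut
  length before end repair.
- Sampler λ is bracketed by doubling and solved to |Δλ| ≤ 1e−12; the
  two-point analytic case agrees to ~1e−9 in the achieved mean. A target
  mean outside the pool's length range is an error.
- R² and autocorrelation return NaN (never raise) for < 3 pairs or zero
  variance.
- Zero CCGG sites, zero reads, and empty call sets all produce valid empty
  outputs, not errors; an empty reference logs a warning.
- All randomness flows from explicit integer seeds through NumPy
  generators; fixed seed ⇒ byte-identical FASTQ/SAM/TSV/bedGraph.

## Known limitations

Single-end directional libraries only; MspI only (no double-digest or
isoschizomer protocols); ungapped alignment (indel-containing reads go
unaligned or mismatch out); no quality-aware scoring; no differential
methylation statistics. The scale used in the bundled accuracy checks
(~1 Mb genomes, 2×10⁵ reads) was chosen as the smallest size at which the
reported percentages are statistically stable.
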