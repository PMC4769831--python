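"""Three-letter alignment of bisulfite reads to the targeted reference.

Reads are C→T converted and matched end-to-end (ungapped) against the
converted alignable entries with a seed-and-extend strategy: the first
``k`` bases of the converted read are looked up exactly in a k-mer index of
the entries, and each candidate placement is extended over the whole read
counting mismatches (up to ``max_mismatches``, default 2).  Directional
libraries are assumed: reads are matched forward-only, but against both
strand entries of every fragment, so both original bisulfite strands are
reachable.

Multi-mapping is resolved with the targeted-reference rules: a read hitting
more than one distinct fragment is discarded outright; among placements on
a single fragment, one starting at the fragment start wins (RRBS reads
begin at the MspI cut), then fewest mismatches, smallest offset, top strand.

Unique placements are lifted back to genome coordinates.  Read bases on the
fill-in CG keep genomic coordinates (the neighbouring CCGG's CG) and stay
inside the CIGAR match; spacer/adapter bases have no genomic home and are
soft-clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .exceptions import (
    InternalConsistencyError,
    InvalidInputError,
    InvalidParameterError,
)
from .genome import GenomeSequence, revcomp
from .reference import TOP, AlignableEntry, ReferenceBundle

logger = logging.getLogger("tracerrbs")

DEFAULT_SEED_LENGTH = 20
DEFAULT_MAX_MISMATCHES = 2


class AlignmentStatus(str, Enum):
    UNIQUE = "unique"
    MULTI_FRAGMENT_DISCARDED = "multi_fragment_discarded"
    UNALIGNED = "unaligned"


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise InvalidInputError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class ConvertedRead:
    read_id: str
    conv_seq: str
    original_seq: str
    qual: str


@dataclass(frozen=True)
class CandidateHit:
    entry_id: str
    fragment_id: str
    strand: str
    offset: int
    mismatches: int

    @property
    def starts_at_fragment_start(self) -> bool:
        return self.offset == 0


@dataclass
class ReadAlignment:
    """Resolution + genome lift-over for one read."""

    read: RawRead
    status: AlignmentStatus
    entry_id: str | None = None
    fragment_id: str | None = None
    strand: str | None = None  # entry strand (top/bottom)
    offset: int | None = None
    mismatches: int | None = None
    chrom: str | None = None
    genomic_pos: int | None = None  # 0-based leftmost mapped position
    genomic_strand: str | None = None  # '+' / '-'
    cigar: str | None = None
    match_len: int | None = None
    discard_reason: str | None = None

    @property
    def read_id(self) -> str:
        return self.read.read_id

    @property
    def five_prime_pos(self) -> int | None:
        """Genomic coordinate of the read's biological 5' end."""
        if self.genomic_pos is None:
            return None
        if self.genomic_strand == "+":
            return self.genomic_pos
        return self.genomic_pos + self.match_len - 1


def read_fastq(path: str | Path) -> list[RawRead]:
    """Read a (possibly gzipped) FASTQ into RawRead records."""
    import gzip

    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    reads: list[RawRead] = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(RawRead(rec.id, str(rec.seq).upper(), qual))
    return reads


def convert_read(read: RawRead) -> ConvertedRead | None:
    """Three-letter conversion (C→T) of a read; the original is retained
    for methylation extraction.  Empty reads are skipped with a warning."""
    if not read.seq:
        logger.warning("skipping empty read %s", read.read_id)
        return None
    return ConvertedRead(read.read_id, read.seq.replace("C", "T"), read.seq, read.qual)


class SeedIndex:
    """Exact k-mer lookup over the converted entry sequences."""

    def __init__(self, bundle: ReferenceBundle, k: int = DEFAULT_SEED_LENGTH):
        if k < 8:
            raise InvalidParameterError(f"seed length {k} too short (minimum 8)")
        if not bundle.entries:
            raise InvalidInputError("cannot index an empty reference bundle")
        shortest = min(len(e.converted_seq) for e in bundle.entries)
        if k > shortest:
            raise InvalidParameterError(
                f"seed length {k} exceeds shortest entry ({shortest} bp)"
            )
        self.k = k
        self.entries: list[AlignableEntry] = list(bundle.entries)
        postings: dict[str, list[tuple[int, int]]] = {}
        for ei, entry in enumerate(self.entries):
            cs = entry.converted_seq
            for pos in range(len(cs) - k + 1):
                postings.setdefault(cs[pos : pos + k], []).append((ei, pos))
        self.postings = postings

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.postings.get(kmer, [])


def build_index(bundle: ReferenceBundle, k: int = DEFAULT_SEED_LENGTH) -> SeedIndex:
    return SeedIndex(bundle, k)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit past ``limit``; N never matches."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def align_read(
    cread: ConvertedRead,
    index: SeedIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[CandidateHit]:
    """End-to-end ungapped placements of a converted read on the entries.

    Reads shorter than the seed produce no candidates.  A placement is
    reported only when the whole read fits inside the entry.
    """
    conv = cread.conv_seq
    n = len(conv)
    if n < index.k:
        return []
    seed = conv[: index.k]
    hits: list[CandidateHit] = []
    seen: set[tuple[int, int]] = set()
    for ei, pos in index.lookup(seed):
        if (ei, pos) in seen:
            continue
        seen.add((ei, pos))
        entry = index.entries[ei]
        cs = entry.converted_seq
        if pos + n > len(cs):
            continue
        window = cs[pos : pos + n]
        if window == conv and "N" not in conv:
            mm = 0
        else:
            mm = _count_mismatches(conv, window, max_mismatches)
        if mm <= max_mismatches:
            hits.append(
                CandidateHit(
                    entry_id=entry.entry_id,
                    fragment_id=entry.fragment_id,
                    strand=entry.strand,
                    offset=pos,
                    mismatches=mm,
                )
            )
    return hits


def resolve(read: RawRead, candidates: Sequence[CandidateHit]) -> ReadAlignment:
    """Apply the multi-mapping rules to one read's candidate placements.

    Hits on more than one distinct fragment → discarded (the two strand
    entries of one fragment count as the same fragment).  On a single
    fragment, a placement at the fragment start wins; ties break by fewest
    mismatches, smallest offset, then top strand.
    """
    if not candidates:
        return ReadAlignment(read=read, status=AlignmentStatus.UNALIGNED)
    fragment_ids = {c.fragment_id for c in candidates}
    if len(fragment_ids) > 1:
        return ReadAlignment(
            read=read,
            status=AlignmentStatus.MULTI_FRAGMENT_DISCARDED,
            discard_reason=f"hits {len(fragment_ids)} fragments",
        )
    at_start = [c for c in candidates if c.starts_at_fragment_start]
    pool = at_start if at_start else list(candidates)
    best = min(pool, key=lambda c: (c.mismatches, c.offset, c.strand != TOP))
    return ReadAlignment(
        read=read,
        status=AlignmentStatus.UNIQUE,
        entry_id=best.entry_id,
        fragment_id=best.fragment_id,
        strand=best.strand,
        offset=best.offset,
        mismatches=best.mismatches,
    )


def lift_to_genome(aln: ReadAlignment, entry: AlignableEntry) -> ReadAlignment:
    """Fill in genome coordinates, strand and CIGAR for a unique placement.

    The match span covers read bases over ``repaired_seq`` (fill-in CG
    included — it has genomic coordinates on the neighbouring CCGG); the
    spacer/adapter tail is soft-clipped.  A placement lying entirely in the
    tail is demoted to unaligned.
    """
    if aln.status is not AlignmentStatus.UNIQUE:
        raise InvalidParameterError("lift_to_genome requires a unique alignment")
    if entry.entry_id != aln.entry_id or entry.adapter_start is None:
        raise InternalConsistencyError(
            f"entry metadata mismatch for read {aln.read_id}"
        )
    n = len(aln.read.seq)
    m = min(n, entry.adapter_start - aln.offset)
    if m <= 0:
        aln.status = AlignmentStatus.UNALIGNED
        aln.discard_reason = "placement entirely within spacer/adapter tail"
        return aln
    s = n - m
    aln.match_len = m
    aln.chrom = entry.chrom
    if entry.strand == TOP:
        aln.genomic_pos = entry.frag_start + aln.offset
        aln.genomic_strand = "+"
        aln.cigar = f"{m}M{s}S" if s else f"{m}M"
    else:
        # bottom index i sits at frag_end+1-i; leftmost mapped base is the
        # highest index of the match span.
        aln.genomic_pos = entry.frag_end - aln.offset - m + 2
        aln.genomic_strand = "-"
        aln.cigar = f"{s}S{m}M" if s else f"{m}M"
    return aln


def align_reads(
    reads: Iterable[RawRead],
    bundle: ReferenceBundle,
    *,
    index: SeedIndex | None = None,
    k: int = DEFAULT_SEED_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[ReadAlignment]:
    """Convert, align, resolve and lift a batch of reads."""
    if index is None:
        index = build_index(bundle, k)
    by_entry = bundle.by_entry_id
    alignments: list[ReadAlignment] = []
    for read in reads:
        cread = convert_read(read)
        if cread is None:
            alignments.append(
                ReadAlignment(
                    read=read,
                    status=AlignmentStatus.UNALIGNED,
                    discard_reason="empty read",
                )
            )
            continue
        aln = resolve(read, align_read(cread, index, max_mismatches))
        if aln.status is AlignmentStatus.UNIQUE:
            aln = lift_to_genome(aln, by_entry[aln.entry_id])
        alignments.append(aln)
    return alignments


def write_sam(
    alignments: Iterable[ReadAlignment],
    genomes: Sequence[GenomeSequence],
    path: str | Path,
) -> None:
    """Emit genome-coordinate SAM (one record per read).

    Discarded/unaligned reads are written with the unmapped flag and a
    ``ZD`` tag recording the reason; unique reads carry ``NM`` (mismatches
    in converted space) and ``ZF`` (origin fragment).
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": g.name, "LN": g.length} for g in genomes],
        }
    )
    tid = {g.name: i for i, g in enumerate(genomes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.read_id
            if aln.status is AlignmentStatus.UNIQUE:
                reverse = aln.genomic_strand == "-"
                rec.flag = 16 if reverse else 0
                rec.reference_id = tid[aln.chrom]
                rec.reference_start = aln.genomic_pos
                rec.mapping_quality = 60
                rec.cigarstring = aln.cigar
                seq = aln.read.seq
                qual = aln.read.qual
                if reverse:
                    seq = revcomp(seq)
                    qual = qual[::-1]
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                rec.set_tag("NM", aln.mismatches)
                rec.set_tag("ZF", aln.fragment_id)
            else:
                rec.flag = 4
                rec.query_sequence = aln.read.seq or None
                if aln.read.qual:
                    rec.query_qualities = pysam.qualitystring_to_array(aln.read.qual)
                reason = aln.discard_reason or aln.status.value
                rec.set_tag("ZD", f"{aln.status.value}:{reason}")
            out.write(rec)
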