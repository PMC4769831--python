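"""Methylation calling from unique alignments, with artifact exclusion.

For every cytosine of an alignable entry, the pre-converted read bases
piled up on it are tallied: C means the molecule's cytosine was protected
(methylated), T means it was converted (unmethylated), anything else is a
sequencing error and is ignored.  The fill-in cytosine created by end
repair sits at a genuine genomic CpG (the second C of the neighbouring
CCGG) but is never methylated on the molecule, so with the default
``exclude_artificial=True`` it contributes nothing; disabling the exclusion
reproduces the biased "before removal" behaviour, which can only pull
affected ratios down.  Spacer/adapter bases never reach a pileup.

Calls are reported per genomic strand with sequence context (CpG/CHG/CHH,
derived from the genome, not the fragment); the default report is CpG-only.
``merge_strands`` pools the two cytosines of a CpG dyad at the plus-strand
C coordinate.
"""

from __future__ import annotations

import csv
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .align import AlignmentStatus, ReadAlignment
from .exceptions import InternalConsistencyError, InvalidParameterError
from .genome import GenomeSequence
from .reference import TOP, AlignableEntry, ReferenceBundle


@dataclass(frozen=True)
class CytosineSite:
    chrom: str
    pos: int  # 0-based genomic coordinate of the cytosine
    strand: str  # '+' or '-'
    context: str  # CpG / CHG / CHH


@dataclass(frozen=True)
class CpGCall:
    site: CytosineSite
    count_meth: int
    count_unmeth: int

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def ratio(self) -> float:
        return self.count_meth / self.coverage


def cytosine_context(seq: str, pos: int, strand: str) -> str:
    """Sequence context of a cytosine from the reference genome."""
    if strand == "+":
        n1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        n2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
        if n1 == "G":
            return "CpG"
        return "CHG" if n2 == "G" else "CHH"
    n1 = seq[pos - 1] if pos >= 1 else "N"
    n2 = seq[pos - 2] if pos >= 2 else "N"
    if n1 == "C":
        return "CpG"
    return "CHG" if n2 == "C" else "CHH"


def pileup(
    alignments: Sequence[ReadAlignment], entry: AlignableEntry
) -> dict[int, dict[str, int]]:
    """Tally pre-converted read bases at each covered cytosine of the entry.

    Returns {repaired_seq index: {"C": n, "T": n, "other": n}} for the
    reference-cytosine positions with coverage.  Only the match span of
    each alignment contributes; spacer/adapter bases never do.
    """
    c_positions = [i for i, b in enumerate(entry.repaired_seq) if b == "C"]
    counts: dict[int, dict[str, int]] = {}
    for aln in alignments:
        if aln.status is not AlignmentStatus.UNIQUE or aln.entry_id != entry.entry_id:
            raise InvalidParameterError(
                "pileup requires unique alignments on this entry"
            )
        if aln.offset + aln.match_len > entry.adapter_start:
            raise InternalConsistencyError(
                f"alignment {aln.read_id} overruns entry {entry.entry_id}"
            )
        lo = bisect_left(c_positions, aln.offset)
        hi = bisect_right(c_positions, aln.offset + aln.match_len - 1)
        seq = aln.read.seq
        off = aln.offset
        for i in c_positions[lo:hi]:
            base = seq[i - off]
            d = counts.get(i)
            if d is None:
                d = counts[i] = {"C": 0, "T": 0, "other": 0}
            if base == "C":
                d["C"] += 1
            elif base == "T":
                d["T"] += 1
            else:
                d["other"] += 1
    return counts


def call_methylation(
    alignments: Iterable[ReadAlignment],
    bundle: ReferenceBundle,
    genomes: Sequence[GenomeSequence],
    *,
    exclude_artificial: bool = True,
    contexts: tuple[str, ...] | None = ("CpG",),
) -> list[CpGCall]:
    """Per-cytosine methylation ratios in genome coordinates.

    Evidence from the artificial fill-in cytosine of each strand entry is
    masked by default; the genuine opposite-strand cytosine of the same CpG
    still counts.  ``contexts=None`` reports all cytosine contexts.
    """
    genome_seq = {g.name: g.seq for g in genomes}
    by_entry: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        if aln.status is AlignmentStatus.UNIQUE:
            by_entry.setdefault(aln.entry_id, []).append(aln)

    agg: dict[tuple[str, int, str], list[int]] = {}
    for entry_id, alns in by_entry.items():
        entry = bundle.by_entry_id[entry_id]
        counts = pileup(alns, entry)
        for i, tally in counts.items():
            if exclude_artificial and i == entry.artificial_c_index:
                continue
            pos = entry.genomic_position(i)
            strand = "+" if entry.strand == TOP else "-"
            key = (entry.chrom, pos, strand)
            acc = agg.get(key)
            if acc is None:
                acc = agg[key] = [0, 0]
            acc[0] += tally["C"]
            acc[1] += tally["T"]

    calls: list[CpGCall] = []
    for (chrom, pos, strand), (meth, unmeth) in agg.items():
        if meth + unmeth < 1:
            continue
        ctx = cytosine_context(genome_seq[chrom], pos, strand)
        if contexts is not None and ctx not in contexts:
            continue
        calls.append(CpGCall(CytosineSite(chrom, pos, strand, ctx), meth, unmeth))
    calls.sort(key=lambda c: (c.site.chrom, c.site.pos, c.site.strand))
    return calls


def merge_strands(calls: Sequence[CpGCall]) -> list[CpGCall]:
    """Pool the two strands of each CpG dyad at the plus-strand C position.

    A minus-strand CpG cytosine at position p+1 belongs to the dyad whose
    plus-strand C is at p.  Total evidence is conserved.  Non-CpG calls are
    rejected — dyads only exist in CpG context.
    """
    agg: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        if call.site.context != "CpG":
            raise InvalidParameterError("merge_strands expects CpG-context calls")
        pos = call.site.pos if call.site.strand == "+" else call.site.pos - 1
        key = (call.site.chrom, pos)
        acc = agg.get(key)
        if acc is None:
            acc = agg[key] = [0, 0]
        acc[0] += call.count_meth
        acc[1] += call.count_unmeth
    merged = [
        CpGCall(CytosineSite(chrom, pos, "+", "CpG"), meth, unmeth)
        for (chrom, pos), (meth, unmeth) in agg.items()
    ]
    merged.sort(key=lambda c: (c.site.chrom, c.site.pos))
    return merged


def write_calls(
    calls: Sequence[CpGCall],
    tsv_path: str | Path,
    bedgraph_path: str | Path | None = None,
) -> None:
    """Write calls as a TSV (1-based positions) and optionally bedGraph
    (0-based half-open), ordered by (chrom, pos, strand)."""
    ordered = sorted(calls, key=lambda c: (c.site.chrom, c.site.pos, c.site.strand))
    with open(tsv_path, "w") as out:
        out.write("chrom\tpos\tstrand\tcontext\tcount_meth\tcount_unmeth\tratio\n")
        for c in ordered:
            out.write(
                f"{c.site.chrom}\t{c.site.pos + 1}\t{c.site.strand}\t{c.site.context}"
                f"\t{c.count_meth}\t{c.count_unmeth}\t{c.ratio:.6g}\n"
            )
    if bedgraph_path is not None:
        with open(bedgraph_path, "w") as out:
            out.write('track type=bedGraph name="methylation_ratio"\n')
            for c in ordered:
                out.write(
                    f"{c.site.chrom}\t{c.site.pos}\t{c.site.pos + 1}\t{c.ratio:.6g}\n"
                )


def read_calls(tsv_path: str | Path) -> list[CpGCall]:
    """Round-trip reader for the call TSV (counts are authoritative)."""
    calls: list[CpGCall] = []
    with open(tsv_path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            calls.append(
                CpGCall(
                    CytosineSite(
                        row["chrom"], int(row["pos"]) - 1, row["strand"], row["context"]
                    ),
                    int(row["count_meth"]),
                    int(row["count_unmeth"]),
                )
            )
    return calls
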