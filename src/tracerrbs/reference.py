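"""Targeted RRBS reference construction.

The reference an RRBS read should be aligned against is not the whole
genome: every sequenced molecule is an MspI restriction fragment that has
been end-repaired (a CG fill-in at each 3' recessed end), A-tailed, adapter
ligated and bisulfite converted.  This module reproduces that library
chemistry in silico:

1. ``digest``       — cut the genome between the two Cs of every CCGG;
2. ``size_select``  — keep fragments inside the protocol's size window;
3. ``end_repair``   — append the fill-in CG to each strand (both strands of
   a fragment become independent alignable entries because bisulfite
   conversion destroys their complementarity);
4. ``attach_and_convert`` — append the A-tail spacer plus sequencing
   adapter, then convert every C to T (three-letter space).

The artificial fill-in cytosine sits at a genuine genomic CpG (the second C
of the neighbouring CCGG) but is never methylated on the molecule, so its
position is tracked on every entry for exclusion during methylation calling.
Coordinates are 0-based half-open throughout; reports are 1-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import InvalidInputError, InvalidParameterError
from .genome import GenomeSequence, revcomp, write_fasta

logger = logging.getLogger("tracerrbs")

#: Illumina TruSeq read-1 adapter prefix; configurable everywhere it is used.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
#: Single-A spacer modelling A-tailing before adapter ligation.
DEFAULT_SPACER = "A"

_MOTIF = "CCGG"
_DNA = frozenset("ACGT")

TOP = "top"
BOTTOM = "bottom"


@dataclass(frozen=True)
class MspFragment:
    """A cut-to-cut MspI fragment on the top strand.

    ``start``/``end`` are the cut points (0-based half-open); the sequence
    always begins ``CGG`` (the remainder of the fragment's own CCGG) and
    ends with the first C of the downstream CCGG.
    """

    chrom: str
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def fragment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class AlignableEntry:
    """One strand of an end-repaired, adapter-annealed fragment.

    ``repaired_seq`` is the strand's 5'→3' sequence after the CG fill-in;
    index ``artificial_c_index`` (= len−2) is the fill-in cytosine.  After
    :func:`attach_and_convert`, ``full_seq`` carries the spacer+adapter tail
    starting at ``adapter_start`` and ``converted_seq`` is its three-letter
    (C→T) form used for alignment.
    """

    fragment_id: str
    chrom: str
    frag_start: int
    frag_end: int
    strand: str  # TOP or BOTTOM
    repaired_seq: str
    full_seq: str | None = None
    adapter_start: int | None = None
    converted_seq: str | None = None

    @property
    def artificial_c_index(self) -> int:
        return len(self.repaired_seq) - 2

    @property
    def artificial_g_index(self) -> int:
        return len(self.repaired_seq) - 1

    @property
    def entry_id(self) -> str:
        return f"{self.fragment_id}:{self.strand}"

    def genomic_position(self, index: int) -> int:
        """Map an index of ``repaired_seq`` to its genomic coordinate.

        Top-strand index i sits at ``frag_start + i``; the appended CG
        occupies the downstream CCGG's CG (positions end, end+1).  The
        bottom strand runs antiparallel: index i sits at ``frag_end+1−i``,
        with its fill-in CG landing on the upstream CCGG's CG.
        """
        if index < 0 or index >= len(self.repaired_seq):
            raise InvalidParameterError(f"index {index} outside repaired_seq")
        if self.strand == TOP:
            return self.frag_start + index
        return self.frag_end + 1 - index


@dataclass
class ReferenceBundle:
    """All alignable entries for one genome plus the build parameters."""

    entries: list[AlignableEntry]
    fragments: list[MspFragment]
    size_range: tuple[int, int]
    adapter: str
    spacer: str
    provenance: dict = field(default_factory=dict)
    _by_entry_id: dict | None = field(default=None, repr=False)
    _by_fragment_id: dict | None = field(default=None, repr=False)

    @property
    def by_entry_id(self) -> dict[str, AlignableEntry]:
        if self._by_entry_id is None:
            self._by_entry_id = {e.entry_id: e for e in self.entries}
        return self._by_entry_id

    @property
    def by_fragment_id(self) -> dict[str, MspFragment]:
        if self._by_fragment_id is None:
            self._by_fragment_id = {f.fragment_id: f for f in self.fragments}
        return self._by_fragment_id


def digest(genome: GenomeSequence) -> list[MspFragment]:
    """In-silico MspI digestion: cut between the two Cs of every CCGG.

    Returns one fragment per consecutive pair of cut sites, in genomic
    order.  Terminal pieces (with only one MspI end) are not fragments —
    they cannot be adapter-ligated on both sides in a real library.
    Fragments containing N are dropped.  Motifs containing N never match.
    """
    if not isinstance(genome, GenomeSequence):
        raise InvalidInputError("digest expects a GenomeSequence")
    # CCGG cannot overlap itself, so non-overlapping search finds all sites.
    cuts = [m.start() + 1 for m in re.finditer(_MOTIF, genome.seq)]
    fragments: list[MspFragment] = []
    for a, b in zip(cuts, cuts[1:]):
        seq = genome.seq[a:b]
        if "N" in seq:
            continue
        fragments.append(MspFragment(genome.name, a, b, seq))
    return fragments


def size_select(
    fragments: Sequence[MspFragment], s_min: int, s_max: int
) -> list[MspFragment]:
    """Keep fragments whose cut-to-cut length is within [s_min, s_max].

    Bounds are inclusive and measured before end repair, matching gel size
    selection of the digested (pre-fill-in) fragments.
    """
    if s_min <= 0 or s_min > s_max:
        raise InvalidParameterError(
            f"invalid size-selection range ({s_min}, {s_max}): need 0 < min <= max"
        )
    return [f for f in fragments if s_min <= f.length <= s_max]


def end_repair(fragment: MspFragment) -> tuple[AlignableEntry, AlignableEntry]:
    """Model the end-repair fill-in: append CG to each strand's 3' end.

    The top entry is ``fragment.seq + "CG"``; the bottom entry is its
    reverse complement (the physical bottom strand after its own fill-in).
    Both start CGG and end CCG, with the artificial C at index len−2.
    """
    top_seq = fragment.seq + "CG"
    common = dict(
        fragment_id=fragment.fragment_id,
        chrom=fragment.chrom,
        frag_start=fragment.start,
        frag_end=fragment.end,
    )
    top = AlignableEntry(strand=TOP, repaired_seq=top_seq, **common)
    bottom = AlignableEntry(strand=BOTTOM, repaired_seq=revcomp(top_seq), **common)
    return top, bottom


def attach_and_convert(
    entry: AlignableEntry,
    adapter: str = DEFAULT_ADAPTER,
    spacer: str = DEFAULT_SPACER,
) -> AlignableEntry:
    """Append the spacer+adapter tail and produce the three-letter form.

    The adapter is C→T converted along with everything else: reads are
    fully converted before matching, so the adapter's methylation state is
    irrelevant in alignment space.
    """
    if not adapter or not _DNA.issuperset(adapter):
        raise InvalidInputError("adapter must be a non-empty A/C/G/T string")
    if spacer and not _DNA.issuperset(spacer):
        raise InvalidInputError("spacer must be an A/C/G/T string")
    full_seq = entry.repaired_seq + spacer + adapter
    return replace(
        entry,
        full_seq=full_seq,
        adapter_start=len(entry.repaired_seq),
        converted_seq=full_seq.replace("C", "T"),
    )


def build_reference(
    genomes: Sequence[GenomeSequence],
    *,
    s_min: int = 40,
    s_max: int = 250,
    adapter: str = DEFAULT_ADAPTER,
    spacer: str = DEFAULT_SPACER,
) -> ReferenceBundle:
    """Run digest → size_select → end_repair → attach_and_convert.

    Every retained fragment contributes exactly two entries (top, bottom).
    """
    all_fragments: list[MspFragment] = []
    entries: list[AlignableEntry] = []
    for genome in genomes:
        kept = size_select(digest(genome), s_min, s_max)
        all_fragments.extend(kept)
        for frag in kept:
            for entry in end_repair(frag):
                entries.append(attach_and_convert(entry, adapter, spacer))
    if not entries:
        logger.warning(
            "reference is empty: no CCGG fragments within %d-%d bp", s_min, s_max
        )
    return ReferenceBundle(
        entries=entries,
        fragments=all_fragments,
        size_range=(s_min, s_max),
        adapter=adapter,
        spacer=spacer,
        provenance={
            "genomes": [g.name for g in genomes],
            "s_min": s_min,
            "s_max": s_max,
            "adapter": adapter,
            "spacer": spacer,
        },
    )


def write_reference(bundle: ReferenceBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the converted-entry FASTA and the entry metadata TSV.

    Output is byte-deterministic for a fixed input bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / "reference_converted.fa"
    tsv_path = out_dir / "reference_entries.tsv"
    write_fasta(((e.entry_id, e.converted_seq) for e in bundle.entries), fasta_path)
    with open(tsv_path, "w") as out:
        out.write(
            "entry_id\tchrom\tfrag_start\tfrag_end\tstrand\tfrag_len"
            "\tartificial_c_index\tadapter_start\n"
        )
        for e in bundle.entries:
            out.write(
                f"{e.entry_id}\t{e.chrom}\t{e.frag_start}\t{e.frag_end}\t{e.strand}"
                f"\t{e.frag_end - e.frag_start}\t{e.artificial_c_index}"
                f"\t{e.adapter_start}\n"
            )
    return {"fasta": fasta_path, "metadata": tsv_path}
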