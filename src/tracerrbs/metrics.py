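"""Evaluation of alignment and methylation-calling accuracy on simulations.

Implements the standard benchmark quantities for an RRBS pipeline run
against simulator truth: percent uniquely aligned reads, percent of reads
mapped to their exact origin, CpG recall (covered / expected), squared
Pearson correlation of called ratios with truth, methylation
autocorrelation by inter-CpG distance (the diagnostic that exposes the
end-repair artifact), and fragment-uniqueness of the digested reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentStatus, ReadAlignment
from .exceptions import InvalidInputError, InvalidParameterError
from .genome import revcomp
from .methcall import CpGCall
from .reference import TOP, MspFragment, ReferenceBundle, size_select
from .simulate import ReadOrigin


@dataclass
class EvalReport:
    pct_unique: float
    pct_correct: float
    recall_pct: float | None = None
    r_squared: float | None = None
    autocorr: pd.DataFrame | None = None
    autocorr_no_exclusion: pd.DataFrame | None = None
    uniqueness: tuple[float, float] | None = None
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "pct_unique": self.pct_unique,
            "pct_correct": self.pct_correct,
            "recall_pct": self.recall_pct,
            "r_squared": self.r_squared,
            "counts": self.counts,
        }
        if self.autocorr is not None:
            out["mean_autocorr"] = float(np.nanmean(self.autocorr["r"]))
        if self.autocorr_no_exclusion is not None:
            out["mean_autocorr_no_exclusion"] = float(
                np.nanmean(self.autocorr_no_exclusion["r"])
            )
        if self.uniqueness is not None:
            out["pct_duplicate_raw"], out["pct_duplicate_converted"] = self.uniqueness
        return out


def alignment_accuracy(
    alignments: Sequence[ReadAlignment],
    origins: Mapping[str, ReadOrigin],
) -> tuple[float, float]:
    """(%unique, %correct) against the simulator's origin records.

    A unique read is correct when its lifted chromosome, leftmost genomic
    position and strand all equal the truth record.  Both percentages are
    over all reads, so %correct <= %unique by construction.
    """
    if not alignments:
        return 0.0, 0.0
    unique = 0
    correct = 0
    for aln in alignments:
        origin = origins.get(aln.read_id)
        if origin is None:
            raise InvalidInputError(f"read {aln.read_id} missing from truth table")
        if aln.status is not AlignmentStatus.UNIQUE:
            continue
        unique += 1
        if (
            aln.chrom == origin.chrom
            and aln.genomic_pos == origin.genomic_start
            and aln.genomic_strand == origin.strand
        ):
            correct += 1
    total = len(alignments)
    return 100.0 * unique / total, 100.0 * correct / total


def expected_cpgs(bundle: ReferenceBundle, read_length: int) -> set[tuple[str, int]]:
    """CpG dyads reachable within one read length from either fragment end.

    Enumerated from the repaired strand sequences: a dyad is expected when
    its cytosine lies within the first ``read_length`` bases of the top or
    bottom strand of any size-selected fragment.  Keys are (chrom,
    plus-strand C position).
    """
    expected: set[tuple[str, int]] = set()
    for entry in bundle.entries:
        rep = entry.repaired_seq
        limit = min(read_length, len(rep) - 1)
        for i in range(limit):
            if rep[i] == "C" and rep[i + 1] == "G":
                if entry.strand == TOP:
                    expected.add((entry.chrom, entry.frag_start + i))
                else:
                    # bottom index i is the minus-strand C at frag_end+1-i;
                    # its dyad's plus-strand C is one base to the left.
                    expected.add((entry.chrom, entry.frag_end - i))
    return expected


def recall(
    calls: Sequence[CpGCall], bundle: ReferenceBundle, read_length: int
) -> float | None:
    """Percent of expected CpG dyads with >= 1x coverage.

    ``calls`` must be dyad-merged (plus-strand coordinates).  Returns None
    when no CpGs are expected.
    """
    expected = expected_cpgs(bundle, read_length)
    if not expected:
        return None
    covered = {(c.site.chrom, c.site.pos) for c in calls if c.coverage >= 1}
    return 100.0 * len(covered & expected) / len(expected)


def r_squared(estimates: Sequence[float], truth: Sequence[float]) -> float:
    """Square of the Pearson correlation between paired vectors.

    NaN (with no exception) when fewer than 3 pairs or either vector has
    zero variance.
    """
    x = np.asarray(estimates, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise InvalidParameterError("estimate and truth vectors differ in length")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def autocorrelation(
    calls: Sequence[CpGCall],
    d_max: int = 100,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Pearson correlation of methylation ratios between CpGs at each
    genomic distance d = 1..d_max.

    ``calls`` should be dyad-merged.  Rows: distance, r (NaN when fewer
    than 3 pairs or zero variance), n_pairs.
    """
    by_chrom: dict[str, dict[int, float]] = {}
    for c in calls:
        if c.coverage >= min_cov:
            by_chrom.setdefault(c.site.chrom, {})[c.site.pos] = c.ratio
    rows = []
    for d in range(1, d_max + 1):
        xs: list[float] = []
        ys: list[float] = []
        for ratios in by_chrom.values():
            for pos, val in ratios.items():
                other = ratios.get(pos + d)
                if other is not None:
                    xs.append(val)
                    ys.append(other)
        n = len(xs)
        if n < 3 or np.std(xs) == 0 or np.std(ys) == 0:
            r = float("nan")
        else:
            r = float(np.corrcoef(xs, ys)[0, 1])
        rows.append({"distance": d, "r": r, "n_pairs": n})
    return pd.DataFrame(rows)


def fragment_uniqueness(
    fragments: Sequence[MspFragment],
    s_min: int = 40,
    s_max: int = 250,
    *,
    count_groups: bool = False,
    canonical_revcomp: bool = False,
) -> tuple[float, float] | None:
    """Percent of size-selected fragments with non-unique sequence, before
    and after three-letter (C→T) conversion.

    By default every member of a duplicate group is counted (2 identical
    among 4 fragments → 50%); ``count_groups`` counts duplicate groups
    instead.  ``canonical_revcomp`` treats a fragment and its reverse
    complement as the same sequence.  Conversion is many-to-one, so the
    converted percentage is always >= the raw one.
    """
    kept = size_select(list(fragments), s_min, s_max)
    if not kept:
        return None

    def pct(seqs: list[str]) -> float:
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s] = counts.get(s, 0) + 1
        if count_groups:
            dup = sum(1 for n in counts.values() if n >= 2)
            return 100.0 * dup / len(counts)
        dup = sum(n for n in counts.values() if n >= 2)
        return 100.0 * dup / len(seqs)

    raw = [f.seq for f in kept]
    if canonical_revcomp:
        raw = [min(s, revcomp(s)) for s in raw]
    converted = [s.replace("C", "T") for s in raw]
    if canonical_revcomp:
        converted = [min(s, revcomp(s)) for s in converted]
    return pct(raw), pct(converted)


def duplicated_fragment_ids(
    bundle: ReferenceBundle, read_length: int
) -> set[str]:
    """Fragments whose converted entry prefix (one read length) collides
    with a different fragment's — reads from these are inherently ambiguous
    in three-letter space and are discarded by the multi-fragment rule."""
    prefix_owners: dict[str, set[str]] = {}
    for entry in bundle.entries:
        prefix = entry.converted_seq[:read_length]
        prefix_owners.setdefault(prefix, set()).add(entry.fragment_id)
    dup: set[str] = set()
    for owners in prefix_owners.values():
        if len(owners) > 1:
            dup.update(owners)
    return dup
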