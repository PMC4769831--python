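"""End-to-end drivers: reference → alignment → calling (→ evaluation).

These are thin orchestration helpers shared by the command-line interface,
the example scripts and the acceptance checks.  All heavy lifting lives in
the per-stage modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import (
    DEFAULT_MAX_MISMATCHES,
    DEFAULT_SEED_LENGTH,
    AlignmentStatus,
    RawRead,
    ReadAlignment,
    align_reads,
    build_index,
)
from .genome import GenomeSequence
from .methcall import CpGCall, call_methylation, merge_strands
from .metrics import (
    EvalReport,
    alignment_accuracy,
    autocorrelation,
    r_squared,
    recall,
)
from .reference import DEFAULT_ADAPTER, DEFAULT_SPACER, ReferenceBundle, build_reference
from .simulate import SimConfig, SimulationResult, TruthTable, simulate

logger = logging.getLogger("tracerrbs")


@dataclass
class PipelineResult:
    bundle: ReferenceBundle
    alignments: list[ReadAlignment]
    calls: list[CpGCall]  # per-strand CpG calls
    calls_merged: list[CpGCall]  # dyad-merged calls
    counts: dict = field(default_factory=dict)


def run_pipeline(
    genomes: Sequence[GenomeSequence],
    reads: Sequence[RawRead],
    *,
    s_min: int = 40,
    s_max: int = 250,
    adapter: str = DEFAULT_ADAPTER,
    spacer: str = DEFAULT_SPACER,
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    exclude_artificial: bool = True,
    bundle: ReferenceBundle | None = None,
) -> PipelineResult:
    """Align reads to the digested reference and call CpG methylation."""
    if bundle is None:
        bundle = build_reference(
            genomes, s_min=s_min, s_max=s_max, adapter=adapter, spacer=spacer
        )
    alignments = align_reads(
        reads, bundle, k=seed_length, max_mismatches=max_mismatches
    )
    calls = call_methylation(
        alignments, bundle, genomes, exclude_artificial=exclude_artificial
    )
    merged = merge_strands(calls)
    status_counts = {s.value: 0 for s in AlignmentStatus}
    for aln in alignments:
        status_counts[aln.status.value] += 1
    counts = {
        "reads_in": len(alignments),
        **status_counts,
        "cpg_calls": len(calls),
        "cpg_dyads_called": len(merged),
    }
    logger.info("pipeline counts: %s", counts)
    return PipelineResult(bundle, alignments, calls, merged, counts)


def evaluate_against_truth(
    result: PipelineResult,
    truth: TruthTable,
    read_length: int,
    *,
    d_max: int = 100,
    calls_no_exclusion: Sequence[CpGCall] | None = None,
) -> EvalReport:
    """Score a pipeline run against simulator truth."""
    pct_unique, pct_correct = alignment_accuracy(result.alignments, truth.origins)
    rec = recall(result.calls_merged, result.bundle, read_length)
    pairs = [
        (c.ratio, truth.cpg_states[(c.site.chrom, c.site.pos)])
        for c in result.calls_merged
        if (c.site.chrom, c.site.pos) in truth.cpg_states
    ]
    r2 = r_squared([p[0] for p in pairs], [p[1] for p in pairs]) if pairs else None
    report = EvalReport(
        pct_unique=pct_unique,
        pct_correct=pct_correct,
        recall_pct=rec,
        r_squared=r2,
        autocorr=autocorrelation(result.calls_merged, d_max=d_max),
        counts=dict(result.counts, truth_pairs=len(pairs)),
    )
    if calls_no_exclusion is not None:
        report.autocorr_no_exclusion = autocorrelation(
            list(calls_no_exclusion), d_max=d_max
        )
    return report


def simulate_and_run(
    genomes: Sequence[GenomeSequence],
    sim_config: SimConfig,
    *,
    seed_length: int = DEFAULT_SEED_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    exclude_artificial: bool = True,
) -> tuple[SimulationResult, PipelineResult]:
    """Simulate reads and run the pipeline with a matching reference.

    The reference uses the simulator's fragment size range and adapter so
    every simulated fragment is representable.
    """
    sim = simulate(genomes, sim_config)
    result = run_pipeline(
        genomes,
        sim.reads,
        s_min=sim_config.frag_min,
        s_max=sim_config.frag_max,
        adapter=sim_config.adapter,
        spacer=sim_config.spacer,
        seed_length=seed_length,
        max_mismatches=max_mismatches,
        exclude_artificial=exclude_artificial,
    )
    return sim, result
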