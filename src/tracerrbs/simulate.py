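"""Directional RRBS read simulator with per-CpG methylation truth.

The simulator emulates the library chemistry end to end.  Each CpG dyad
inside a size-eligible MspI fragment is assigned a binary methylation state
(shared by both strands of the dyad): independently Bernoulli(p) per site
("iid" mode), or in contiguous genomic blocks sharing one state ("mosaic"
mode, emulating the regional methylation structure of real genomes).
Fragments are sampled with truncated-exponential length weights calibrated
so the expected sampled fragment length hits ``frag_mean``; a uniform
fallback is available.  For each read a strand is drawn uniformly and the
molecule is built exactly as the library would be:

    repaired strand (fragment + fill-in CG, fill-in C never methylated)
    + A-tail spacer + adapter

then bisulfite transformed — a C at a methylated CpG survives, every other
fragment C (including non-CpG cytosines and the fill-in) becomes T, and
spacer/adapter bases are emitted unchanged.  The read is the first L bases
of the transformed molecule, so fragments shorter than the read length
read through into the fill-in CG and adapter, exactly the contamination
the caller's artifact exclusion is designed to remove.

Bisulfite conversion is complete and sequencing is error-free by default;
both are configurable for robustness experiments.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .align import RawRead
from .exceptions import InvalidInputError, InvalidParameterError
from .genome import GenomeSequence, revcomp
from .reference import (
    BOTTOM,
    DEFAULT_ADAPTER,
    DEFAULT_SPACER,
    TOP,
    MspFragment,
    digest,
    size_select,
)


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the standard study conditions
    (50 bp reads, 20% per-CpG methylation, 30-250 bp pool, mean 70 bp)."""

    n_reads: int = 10_000
    read_length: int = 50
    meth_prob: float = 0.20
    frag_min: int = 30
    frag_max: int = 250
    frag_mean: float = 70.0
    seed: int = 0
    adapter: str = DEFAULT_ADAPTER
    spacer: str = DEFAULT_SPACER
    quality_char: str = "I"  # constant Phred Q40
    truth_mode: str = "iid"  # "iid" or "mosaic"
    block_mean_bp: float = 500.0  # mosaic mode: mean methylation-block length
    uniform_fragment_weights: bool = False
    conversion_rate: float = 1.0  # bisulfite conversion efficiency
    error_rate: float = 0.0  # per-base substitution error
    read_id_prefix: str = "simread"

    def __post_init__(self) -> None:
        if not (0 <= self.meth_prob <= 1):
            raise InvalidParameterError("meth_prob must be in [0, 1]")
        if self.read_length < 1:
            raise InvalidParameterError("read_length must be >= 1")
        if not (0 < self.frag_min <= self.frag_mean <= self.frag_max):
            raise InvalidParameterError(
                "need 0 < frag_min <= frag_mean <= frag_max"
            )
        if self.truth_mode not in ("iid", "mosaic"):
            raise InvalidParameterError("truth_mode must be 'iid' or 'mosaic'")


@dataclass(frozen=True)
class ReadOrigin:
    """Ground-truth placement of one simulated read."""

    read_id: str
    fragment_id: str
    chrom: str
    strand: str  # '+' (top) or '-' (bottom)
    genomic_start: int  # leftmost genomic coordinate of the read's footprint
    genomic_end: int  # half-open right edge of the footprint


@dataclass
class TruthTable:
    """Per-CpG states (dyad-level, keyed by plus-strand C position) and
    per-read origin records."""

    cpg_states: dict[tuple[str, int], int]
    origins: dict[str, ReadOrigin] = field(default_factory=dict)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_states)

    @property
    def mean_state(self) -> float:
        if not self.cpg_states:
            return float("nan")
        return float(np.mean(list(self.cpg_states.values())))


def cpg_dyads(genome_seq: str, fragment: MspFragment) -> list[int]:
    """Plus-strand C positions of the CpG dyads a fragment's strands carry.

    Includes the junction dyads at both cut sites (positions ``start`` and
    ``end``), which the fill-in cytosines land on.
    """
    return [
        p
        for p in range(fragment.start, fragment.end + 1)
        if genome_seq[p : p + 2] == "CG"
    ]


def assign_truth(
    genomes: Sequence[GenomeSequence],
    fragments: Sequence[MspFragment],
    p: float,
    seed: int,
    *,
    mode: str = "iid",
    block_mean_bp: float = 500.0,
) -> dict[tuple[str, int], int]:
    """Draw one binary state per CpG dyad within the eligible fragments.

    "iid": independent Bernoulli(p) per dyad.  "mosaic": dyads are grouped
    into genomic blocks with exponentially distributed lengths (mean
    ``block_mean_bp``); each block draws one Bernoulli(p) state shared by
    all its dyads.  Deterministic given the seed.
    """
    genome_seq = {g.name: g.seq for g in genomes}
    positions: dict[str, set[int]] = {}
    for frag in fragments:
        positions.setdefault(frag.chrom, set()).update(
            cpg_dyads(genome_seq[frag.chrom], frag)
        )
    rng = np.random.default_rng(seed)
    states: dict[tuple[str, int], int] = {}
    for chrom in sorted(positions):
        ordered = sorted(positions[chrom])
        if mode == "iid":
            draws = rng.random(len(ordered)) < p
            for pos, state in zip(ordered, draws):
                states[(chrom, pos)] = int(state)
        else:
            block_end = -1.0
            state = 0
            for pos in ordered:
                if pos >= block_end:
                    state = int(rng.random() < p)
                    block_end = pos + rng.exponential(block_mean_bp)
                states[(chrom, pos)] = state
    return states


class FragmentSampler:
    """Length-weighted fragment sampler targeting a mean sampled length.

    Weights are truncated-exponential in fragment length, w_i ∝ exp(−λ·l_i),
    with λ solved so that Σ w_i l_i / Σ w_i equals the target mean — the
    maximum-entropy choice given only the range and the mean.
    """

    def __init__(
        self,
        fragments: Sequence[MspFragment],
        frag_min: int,
        frag_max: int,
        frag_mean: float,
        seed: int,
        *,
        uniform: bool = False,
    ):
        eligible = size_select(list(fragments), frag_min, frag_max)
        if not eligible:
            raise InvalidInputError(
                f"no fragments within {frag_min}-{frag_max} bp to sample from"
            )
        self.fragments = eligible
        lengths = np.array([f.length for f in eligible], dtype=float)
        self.lengths = lengths
        if uniform or len(eligible) == 1 or lengths.min() == lengths.max():
            weights = np.full(len(eligible), 1.0 / len(eligible))
        else:
            lo, hi = lengths.min(), lengths.max()
            if not (lo <= frag_mean <= hi):
                raise InvalidParameterError(
                    f"target mean {frag_mean} outside pool length range [{lo}, {hi}]"
                )
            weights = self._solve_weights(lengths, frag_mean)
        self.weights = weights
        self._rng = np.random.default_rng(seed)

    @staticmethod
    def _solve_weights(lengths: np.ndarray, target: float) -> np.ndarray:
        def weighted_mean(lam: float) -> float:
            # shift exponent for numerical stability
            z = -lam * lengths
            z -= z.max()
            w = np.exp(z)
            return float(np.sum(w * lengths) / np.sum(w))

        lo, hi = -1e-6, 1e-6
        # expand the bracket until the target mean is enclosed;
        # weighted_mean is strictly decreasing in lambda.
        for _ in range(80):
            if weighted_mean(lo) >= target:
                break
            lo *= 2
        for _ in range(80):
            if weighted_mean(hi) <= target:
                break
            hi *= 2
        lam = brentq(lambda x: weighted_mean(x) - target, lo, hi, xtol=1e-12)
        z = -lam * lengths
        z -= z.max()
        w = np.exp(z)
        return w / w.sum()

    @property
    def expected_length(self) -> float:
        return float(np.sum(self.weights * self.lengths))

    def sample(self, n: int) -> np.ndarray:
        """Draw n fragment indices (into ``self.fragments``)."""
        return self._rng.choice(len(self.fragments), size=n, p=self.weights)

    def length_cdf(self, x: float) -> float:
        """Probability that a sampled fragment is shorter than x bp."""
        return float(np.sum(self.weights[self.lengths < x]))


def sample_fragment_pool(
    fragments: Sequence[MspFragment],
    frag_min: int,
    frag_max: int,
    frag_mean: float,
    seed: int,
    *,
    uniform: bool = False,
) -> FragmentSampler:
    return FragmentSampler(
        fragments, frag_min, frag_max, frag_mean, seed, uniform=uniform
    )


def _bisulfite_molecule(
    fragment: MspFragment,
    strand: str,
    states: dict[tuple[str, int], int],
    genome_seq: str,
    config: SimConfig,
) -> str:
    """Fully converted (error-free) sequenced molecule for one strand."""
    top_repaired = fragment.seq + genome_seq[fragment.end : fragment.end + 2]
    repaired = top_repaired if strand == TOP else revcomp(top_repaired)
    out = []
    last = len(repaired) - 2  # fill-in C index
    for i, base in enumerate(repaired):
        if base != "C":
            out.append(base)
            continue
        if i == last:
            out.append("T")  # fill-in cytosine is never methylated
            continue
        if strand == TOP:
            gpos = fragment.start + i
            dyad = gpos if genome_seq[gpos + 1 : gpos + 2] == "G" else None
        else:
            gpos = fragment.end + 1 - i
            dyad = gpos - 1 if genome_seq[gpos - 1 : gpos] == "C" else None
        methylated = dyad is not None and states.get((fragment.chrom, dyad), 0) == 1
        out.append("C" if methylated else "T")
    return "".join(out) + config.spacer + config.adapter


def make_read(
    fragment: MspFragment,
    strand: str,
    states: dict[tuple[str, int], int],
    genome_seq: str,
    config: SimConfig,
    read_id: str,
    rng: np.random.Generator | None = None,
) -> tuple[RawRead, ReadOrigin]:
    """One directional read from the 5' end of the chosen strand."""
    molecule = _bisulfite_molecule(fragment, strand, states, genome_seq, config)
    L = config.read_length
    while len(molecule) < L:
        if not config.adapter:
            raise InvalidParameterError(
                "molecule shorter than read length and no adapter to pad with"
            )
        molecule += config.adapter
    seq = molecule[:L]
    if rng is not None and (config.conversion_rate < 1.0 or config.error_rate > 0.0):
        seq = _degrade(seq, fragment, strand, config, rng)
    read = RawRead(read_id, seq, config.quality_char * L)
    repaired_len = fragment.length + 2
    if strand == TOP:
        start = fragment.start
        end = fragment.start + min(L, repaired_len)
    else:
        start = fragment.end + 2 - min(L, repaired_len)
        end = fragment.end + 2
    origin = ReadOrigin(
        read_id=read_id,
        fragment_id=fragment.fragment_id,
        chrom=fragment.chrom,
        strand="+" if strand == TOP else "-",
        genomic_start=start,
        genomic_end=end,
    )
    return read, origin


def _degrade(
    seq: str,
    fragment: MspFragment,
    strand: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> str:
    """Apply incomplete conversion (T that should have stayed C reverts is
    not modelled; instead converted positions fail with the given rate) and
    uniform substitution errors."""
    bases = list(seq)
    repaired_len = fragment.length + 2
    if config.conversion_rate < 1.0:
        # conversion failures: fragment-derived T positions whose molecule
        # base was an unmethylated C remain C with prob 1 - conversion_rate
        top_repaired = fragment.seq + "CG"
        repaired = top_repaired if strand == TOP else revcomp(top_repaired)
        for i in range(min(len(bases), repaired_len)):
            if repaired[i] == "C" and bases[i] == "T":
                if rng.random() > config.conversion_rate:
                    bases[i] = "C"
    if config.error_rate > 0.0:
        for i in range(len(bases)):
            if rng.random() < config.error_rate:
                bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    return "".join(bases)


@dataclass
class SimulationResult:
    reads: list[RawRead]
    truth: TruthTable
    fragments: list[MspFragment]  # size-eligible pool
    sampler: FragmentSampler
    config: SimConfig


def simulate(genomes: Sequence[GenomeSequence], config: SimConfig) -> SimulationResult:
    """Generate reads and truth tables; fully reproducible given the seed."""
    genome_seq = {g.name: g.seq for g in genomes}
    pool: list[MspFragment] = []
    for g in genomes:
        pool.extend(size_select(digest(g), config.frag_min, config.frag_max))
    if not pool:
        raise InvalidInputError("no size-eligible fragments in the genome")

    master = np.random.default_rng(config.seed)
    truth_seed, sampler_seed = (int(x) for x in master.integers(0, 2**31, size=2))
    states = assign_truth(
        genomes,
        pool,
        config.meth_prob,
        truth_seed,
        mode=config.truth_mode,
        block_mean_bp=config.block_mean_bp,
    )
    sampler = FragmentSampler(
        pool,
        config.frag_min,
        config.frag_max,
        config.frag_mean,
        sampler_seed,
        uniform=config.uniform_fragment_weights,
    )

    frag_idx = sampler.sample(config.n_reads) if config.n_reads else np.array([], int)
    strand_draws = master.integers(0, 2, size=config.n_reads)
    clean = config.conversion_rate >= 1.0 and config.error_rate <= 0.0
    cache: dict[tuple[str, str], tuple[RawRead, ReadOrigin]] = {}
    reads: list[RawRead] = []
    origins: dict[str, ReadOrigin] = {}
    width = max(6, len(str(max(config.n_reads - 1, 0))))
    for i in range(config.n_reads):
        frag = sampler.fragments[frag_idx[i]]
        strand = TOP if strand_draws[i] == 0 else BOTTOM
        read_id = f"{config.read_id_prefix}-{i:0{width}d}"
        key = (frag.fragment_id, strand)
        if clean and key in cache:
            template_read, template_origin = cache[key]
            read = RawRead(read_id, template_read.seq, template_read.qual)
            origin = ReadOrigin(
                read_id,
                template_origin.fragment_id,
                template_origin.chrom,
                template_origin.strand,
                template_origin.genomic_start,
                template_origin.genomic_end,
            )
        else:
            read, origin = make_read(
                frag,
                strand,
                states,
                genome_seq[frag.chrom],
                config,
                read_id,
                rng=None if clean else master,
            )
            if clean:
                cache[key] = (read, origin)
        reads.append(read)
        origins[read_id] = origin
    return SimulationResult(
        reads=reads,
        truth=TruthTable(cpg_states=states, origins=origins),
        fragments=pool,
        sampler=sampler,
        config=config,
    )


def write_fastq(reads: Sequence[RawRead], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.seq}\n+\n{read.qual}\n")


def write_truth(truth: TruthTable, out_dir: str | Path) -> dict[str, Path]:
    """Write per-CpG states and per-read origins as TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cpg_path = out_dir / "truth_cpg.tsv"
    reads_path = out_dir / "truth_reads.tsv"
    with open(cpg_path, "w") as out:
        out.write("chrom\tpos\tstate\n")
        for (chrom, pos), state in sorted(truth.cpg_states.items()):
            out.write(f"{chrom}\t{pos}\t{state}\n")
    with open(reads_path, "w") as out:
        out.write("read_id\tfragment_id\tchrom\tstrand\tgenomic_start\tgenomic_end\n")
        for read_id in sorted(truth.origins):
            o = truth.origins[read_id]
            out.write(
                f"{o.read_id}\t{o.fragment_id}\t{o.chrom}\t{o.strand}"
                f"\t{o.genomic_start}\t{o.genomic_end}\n"
            )
    return {"cpg": cpg_path, "reads": reads_path}


def read_truth(out_dir: str | Path) -> TruthTable:
    out_dir = Path(out_dir)
    states: dict[tuple[str, int], int] = {}
    with open(out_dir / "truth_cpg.tsv") as handle:
        next(handle)
        for line in handle:
            chrom, pos, state = line.rstrip("\n").split("\t")
            states[(chrom, int(pos))] = int(state)
    origins: dict[str, ReadOrigin] = {}
    with open(out_dir / "truth_reads.tsv") as handle:
        next(handle)
        for line in handle:
            read_id, fragment_id, chrom, strand, start, end = line.rstrip("\n").split(
                "\t"
            )
            origins[read_id] = ReadOrigin(
                read_id, fragment_id, chrom, strand, int(start), int(end)
            )
    return TruthTable(cpg_states=states, origins=origins)
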