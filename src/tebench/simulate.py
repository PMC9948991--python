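"""Single-insertion synthetic genomes with target-site duplications, and a
built-in paired-end whole-genome-shotgun read simulator.

The generative model is the "single synthetic insertion" benchmark: one TE
consensus sequence is spiked into an otherwise-unmodified reference genome
together with its target-site duplication (TSD), and a WGS read set is
simulated from the modified genome. Detectors are then scored on whether they
recover the one planted insertion.

Construction convention: for a breakpoint p and TSD length t, the duplicated
bases D are the reference bases [p, p+t). The synthetic chromosome is

    ref[0 : p+t] + TE + ref[p : L]

so the inserted element is flanked by a copy of D on each side, and the truth
interval is [p, p+t) in *reference* coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core_io import (
    Interval,
    ReferenceGenome,
    SimConfig,
    TELibrary,
    TruthRecord,
)

__all__ = [
    "InsertionPlan",
    "FastqRead",
    "ReadSet",
    "plan_insertion",
    "build_synthetic_genome",
    "simulate_reads",
    "downsample",
    "reverse_complement",
    "write_fastq_pair",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class InsertionPlan:
    """Where and what to insert: one family at one breakpoint."""

    chrom: str
    breakpoint: int
    family: str
    strand: str
    tsd_len: int

    def __post_init__(self) -> None:
        if self.breakpoint < 0 or self.tsd_len < 0:
            raise ValueError("negative breakpoint or TSD length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"plan strand must be +/-, got {self.strand!r}")


@dataclass(frozen=True)
class FastqRead:
    id: str
    seq: str
    qual: str


@dataclass
class ReadSet:
    """Paired (or single-end) FASTQ reads with provenance metadata."""

    mate1: list[FastqRead]
    mate2: list[FastqRead] = field(default_factory=list)
    coverage: float = 0.0
    genome_id: str = ""
    seed: Optional[int] = None

    @property
    def paired(self) -> bool:
        return bool(self.mate2)

    @property
    def n_pairs(self) -> int:
        return len(self.mate1)

    def __post_init__(self) -> None:
        if self.mate2 and len(self.mate1) != len(self.mate2):
            raise ValueError("mate lists differ in length")


def plan_insertion(
    genome: ReferenceGenome,
    library: TELibrary,
    sites: Sequence[Interval],
    config: SimConfig,
    rng: np.random.Generator,
) -> InsertionPlan:
    """Draw a random insertion plan from the permissible site intervals.

    The family is drawn per ``config.family_policy`` (uniform over the library
    by default), the site interval with probability proportional to its width,
    the breakpoint uniformly within the interval, and the strand per
    ``config.strand_policy``. Deterministic given the generator state.
    """
    if not sites:
        raise ValueError("empty permissible-site list")
    widths = np.array([s.end - s.start for s in sites], dtype=float)
    if (widths < 1).any():
        raise ValueError("permissible site narrower than 1 bp")
    for s in sites:
        if s.chrom not in genome:
            raise ValueError(f"site chromosome {s.chrom!r} absent from genome")
        if s.end > len(genome[s.chrom]):
            raise ValueError(f"site {s.chrom}:{s.start}-{s.end} exceeds chromosome")

    if isinstance(config.family_policy, str):
        families = library.families
        weights = np.ones(len(families))
    else:
        families = list(config.family_policy)
        for fam in families:
            if fam not in library:
                raise ValueError(f"weighted family {fam!r} absent from library")
        weights = np.array([config.family_policy[f] for f in families], dtype=float)
    family = families[rng.choice(len(families), p=weights / weights.sum())]

    site = sites[rng.choice(len(sites), p=widths / widths.sum())]
    breakpoint = int(rng.integers(site.start, site.end))

    if config.strand_policy == "random":
        strand = "+" if rng.random() < 0.5 else "-"
    else:
        strand = config.strand_policy[-1]

    if breakpoint + config.tsd_len > len(genome[site.chrom]):
        breakpoint = len(genome[site.chrom]) - config.tsd_len
    return InsertionPlan(site.chrom, breakpoint, family, strand, config.tsd_len)


def build_synthetic_genome(
    genome: ReferenceGenome,
    library: TELibrary,
    plan: InsertionPlan,
) -> tuple[ReferenceGenome, TruthRecord]:
    """Insert one TE (with TSD) into the reference per the plan.

    Returns the synthetic genome and the truth record in reference
    coordinates. Length conservation holds exactly:
    ``len(synthetic) - len(reference) == len(consensus) + tsd_len``.
    """
    if plan.family not in library:
        raise ValueError(f"family {plan.family!r} absent from library")
    if plan.chrom not in genome:
        raise ValueError(f"chromosome {plan.chrom!r} absent from genome")
    ref = genome[plan.chrom]
    p, t = plan.breakpoint, plan.tsd_len
    if p + t > len(ref):
        raise ValueError("breakpoint + TSD length exceeds chromosome length")
    te = library.consensus[plan.family]
    if plan.strand == "-":
        te = reverse_complement(te)
    synthetic_chrom = ref[: p + t] + te + ref[p:]
    sequences = dict(genome.sequences)
    sequences[plan.chrom] = synthetic_chrom
    truth = TruthRecord(
        chrom=plan.chrom,
        tsd_start=p,
        tsd_end=p + t,
        family=plan.family,
        strand=plan.strand,
    )
    return ReferenceGenome(sequences), truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL_CHAR = "I"  # constant Phred symbol (Q40)


def _truncated_normal_lengths(
    n: int, mean: float, sd: float, lo: int, hi: int, rng: np.random.Generator
) -> np.ndarray:
    """Fragment lengths ~ Normal(mean, sd) truncated to [lo, hi] by rejection.

    A 1,000-round cap guards against a degenerate truncation range on tiny
    test chromosomes.
    """
    if sd == 0:
        val = int(round(mean))
        if not (lo <= val <= hi):
            raise ValueError("degenerate fragment length outside feasible range")
        return np.full(n, val, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        if filled >= n:
            break
        draw = np.rint(rng.normal(mean, sd, size=n - filled)).astype(np.int64)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    else:
        raise ValueError(
            "could not draw fragment lengths inside the feasible range "
            "after 1000 rejection rounds"
        )
    return out


def _apply_errors(reads: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability error_rate to a uniform other base."""
    if error_rate <= 0:
        return reads
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return reads
    reads = reads.copy()
    current = reads[mask]
    # index of the base in ACGT; non-ACGT (N) maps to a uniform ACGT draw
    idx = np.searchsorted(_BASES, current)
    known = np.isin(current, _BASES)
    shift = rng.integers(1, 4, size=n_err)
    new_idx = np.where(known, (idx + shift) % 4, rng.integers(0, 4, size=n_err))
    reads[mask] = _BASES[new_idx]
    return reads


def _revcomp_u8(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    return comp[arr][..., ::-1]


def simulate_reads(
    genome: ReferenceGenome,
    config: SimConfig,
    coverage: float,
    rng: np.random.Generator,
    genome_id: str = "genome",
) -> ReadSet:
    """Simulate a WGS read set from a genome at the given fold-coverage.

    Paired mode: per chromosome of length L, round(coverage * L / (2 *
    read_len)) fragments are placed uniformly, with lengths drawn from a
    truncated Normal(insert_mean, insert_sd). Mate 1 is the forward strand of
    the fragment's 5' end and mate 2 the reverse complement of its 3' end.
    Each base is substituted with probability ``error_rate``. Single-end mode
    emits mate-1 reads only, count = round(coverage * L / read_len).
    """
    if config.simulator != "builtin":
        raise NotImplementedError(
            f"read simulator {config.simulator!r} is not bundled; use 'builtin'"
        )
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rl = config.read_len
    if config.paired and config.insert_mean < rl:
        raise ValueError("insert_mean must be >= read_len for paired reads")

    mate1: list[FastqRead] = []
    mate2: list[FastqRead] = []
    qual = _QUAL_CHAR * rl
    serial = 0
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        if rl > L:
            raise ValueError(f"read_len {rl} exceeds length of {chrom!r}")
        seq_u8 = np.frombuffer(seq.encode(), dtype=np.uint8)
        if config.paired:
            n = int(round(coverage * L / (2 * rl)))
            if n == 0:
                continue
            frag = _truncated_normal_lengths(
                n, config.insert_mean, config.insert_sd, rl, L, rng
            )
            starts = (rng.random(n) * (L - frag + 1)).astype(np.int64)
            offs = np.arange(rl)
            r1 = seq_u8[starts[:, None] + offs]
            r2 = _revcomp_u8(seq_u8[(starts + frag - rl)[:, None] + offs])
            r1 = _apply_errors(r1, config.error_rate, rng)
            r2 = _apply_errors(r2, config.error_rate, rng)
            for i in range(n):
                rid = f"{genome_id}:{chrom}:{serial + i}"
                mate1.append(FastqRead(rid + "/1", r1[i].tobytes().decode(), qual))
                mate2.append(FastqRead(rid + "/2", r2[i].tobytes().decode(), qual))
            serial += n
        else:
            n = int(round(coverage * L / rl))
            if n == 0:
                continue
            starts = (rng.random(n) * (L - rl + 1)).astype(np.int64)
            r1 = seq_u8[starts[:, None] + np.arange(rl)]
            r1 = _apply_errors(r1, config.error_rate, rng)
            fwd = rng.random(n) < 0.5
            for i in range(n):
                read = r1[i] if fwd[i] else _revcomp_u8(r1[i])
                rid = f"{genome_id}:{chrom}:{serial + i}"
                mate1.append(FastqRead(rid, read.tobytes().decode(), qual))
            serial += n
    return ReadSet(mate1, mate2, coverage=coverage, genome_id=genome_id)


def downsample(
    readset: ReadSet,
    current_cov: float,
    target_cov: float,
    rng: np.random.Generator,
) -> ReadSet:
    """Randomly thin a read set from current to target fold-coverage.

    Each pair is kept independently with probability target/current, mates
    kept or dropped together. A target at or above the current coverage
    returns the input unchanged.
    """
    if current_cov <= 0:
        raise ValueError("current coverage must be positive")
    if target_cov <= 0:
        raise ValueError("target coverage must be positive")
    if target_cov >= current_cov:
        return readset
    keep = rng.random(readset.n_pairs) < (target_cov / current_cov)
    mate1 = [r for r, k in zip(readset.mate1, keep) if k]
    mate2 = [r for r, k in zip(readset.mate2, keep) if k] if readset.paired else []
    return ReadSet(
        mate1,
        mate2,
        coverage=target_cov,
        genome_id=readset.genome_id,
        seed=readset.seed,
    )


def write_fastq_pair(
    readset: ReadSet, prefix: Union[str, Path]
) -> tuple[Path, Optional[Path]]:
    """Write a read set as ``<prefix>_1.fastq`` (and ``_2`` when paired)."""
    prefix = Path(prefix)
    path1 = prefix.with_name(prefix.name + "_1.fastq")
    with open(path1, "w") as handle:
        for read in readset.mate1:
            handle.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
    path2 = None
    if readset.paired:
        path2 = prefix.with_name(prefix.name + "_2.fastq")
        with open(path2, "w") as handle:
            for read in readset.mate2:
                handle.write(f"@{read.id}\n{read.seq}\n+\n{read.qual}\n")
    return path1, path2
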