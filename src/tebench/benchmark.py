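"""End-to-end "simulate -> detect -> evaluate" benchmark driver.

For each (coverage, replicate) cell the driver plans one insertion, builds
the synthetic genome, simulates a read set, hands everything to a pluggable
detector, and scores the detector's predictions with the within-N scheme.
Two built-in stub detectors make the driver testable without any external
TE-detection software: ``perfect`` emits the truth, ``noisy`` misses the
truth with a set probability, jitters breakpoints, and adds spurious calls.

All randomness flows from one integer seed; a replicate's child generator is
derived from (seed, coverage index, replicate index), so re-running with the
same configuration reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Protocol, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    Interval,
    Prediction,
    ReferenceGenome,
    SimConfig,
    TELibrary,
    TruthRecord,
)
from .evaluate import ReplicateResult, precision_recall_curve, tally_replicate
from .simulate import (
    ReadSet,
    build_synthetic_genome,
    plan_insertion,
    simulate_reads,
)

__all__ = [
    "Detector",
    "PerfectDetector",
    "NoisyDetector",
    "DetectorError",
    "RunManifest",
    "run_benchmark",
    "make_detector",
]


class DetectorError(RuntimeError):
    """A detector failed on one replicate."""


class Detector(Protocol):
    """Anything that maps (reads, synthetic genome, library, truth) to calls.

    The truth record is passed so stub detectors can emulate a real detector
    of known accuracy; a wrapper around real software would ignore it.
    """

    name: str

    def __call__(
        self,
        reads: ReadSet,
        genome: ReferenceGenome,
        library: TELibrary,
        truth: TruthRecord,
        rng: np.random.Generator,
    ) -> list[Prediction]: ...


@dataclass
class PerfectDetector:
    """Emits exactly the truth record — the identity check for the scorer."""

    name: str = "perfect"

    def __call__(self, reads, genome, library, truth, rng) -> list[Prediction]:
        return [truth.as_prediction(method=self.name)]


@dataclass
class NoisyDetector:
    """Detector of known, tunable accuracy.

    Misses the planted insertion with probability ``p_miss``; otherwise
    reports it with both endpoints jittered by one rounded Normal(0,
    shift_sd) offset. Adds ``n_spurious`` false calls at random positions of
    random families. ``fail_rate`` makes the call raise, to exercise the
    driver's failure handling.
    """

    p_miss: float = 0.0
    shift_sd: float = 0.0
    n_spurious: int = 0
    fail_rate: float = 0.0
    name: str = "noisy"

    def __call__(self, reads, genome, library, truth, rng) -> list[Prediction]:
        if self.fail_rate > 0 and rng.random() < self.fail_rate:
            raise DetectorError("stub detector failure")
        calls: list[Prediction] = []
        if rng.random() >= self.p_miss:
            shift = int(round(rng.normal(0, self.shift_sd))) if self.shift_sd > 0 else 0
            start = max(truth.tsd_start + shift, 0)
            calls.append(
                Prediction(
                    chrom=truth.chrom,
                    start=start,
                    end=start + truth.tsd_len,
                    family=truth.family,
                    category="non-reference",
                    method=self.name,
                    strand=truth.strand,
                )
            )
        families = library.families
        for _ in range(self.n_spurious):
            chrom = list(genome.sequences)[rng.integers(0, len(genome.sequences))]
            pos = int(rng.integers(0, len(genome[chrom])))
            calls.append(
                Prediction(
                    chrom=chrom,
                    start=pos,
                    end=pos + truth.tsd_len,
                    family=families[rng.integers(0, len(families))],
                    category="non-reference",
                    method=self.name,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        return calls


def make_detector(spec: Union[str, dict]) -> Detector:
    """Build a stub detector from a name or a {"name": ..., params} dict."""
    if isinstance(spec, str):
        spec = {"name": spec}
    name = spec.get("name", "perfect")
    params = {k: v for k, v in spec.items() if k != "name"}
    if name == "perfect":
        return PerfectDetector()
    if name == "noisy":
        return NoisyDetector(**params)
    raise ValueError(f"unknown detector {name!r}")


@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every benchmark output."""

    config: dict
    seed: int
    version: str = __version__
    outputs: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            json.dump(self.__dict__, handle, indent=2, sort_keys=True, default=str)
            handle.write("\n")


def _child_rng(seed: int, cov_idx: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(cov_idx, rep)))


def run_benchmark(
    genome: ReferenceGenome,
    library: TELibrary,
    sites: Sequence[Interval],
    config: SimConfig,
    detector: Detector,
    out_dir: Optional[Union[str, Path]] = None,
    log: Optional[Callable[[str], None]] = None,
    max_retries: int = 1,
) -> pd.DataFrame:
    """Run the full simulate -> detect -> evaluate grid.

    Returns the long-format precision/recall table (one row per coverage x
    window). A detector failure is retried once; a replicate that fails twice
    is logged, excluded from the pooled metrics, and counted in ``n_failed``.
    When ``out_dir`` is given, the table (metrics.csv) and a RunManifest are
    written there.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    results: list[ReplicateResult] = []
    for cov_idx, coverage in enumerate(config.coverages):
        for rep in range(config.replicates):
            rng = _child_rng(config.seed, cov_idx, rep)
            t0 = time.perf_counter()
            plan = plan_insertion(genome, library, sites, config, rng)
            synthetic, truth = build_synthetic_genome(genome, library, plan)
            reads = simulate_reads(
                synthetic, config, coverage, rng, genome_id=f"rep{rep}_cov{coverage:g}"
            )
            predictions: Optional[list[Prediction]] = None
            for attempt in range(max_retries + 1):
                try:
                    predictions = detector(reads, synthetic, library, truth, rng)
                    break
                except DetectorError as exc:
                    if log:
                        log(
                            f"replicate={rep} coverage={coverage:g} stage=detect "
                            f"attempt={attempt + 1} outcome=failed ({exc})"
                        )
            if predictions is None:
                results.append(
                    ReplicateResult(
                        replicate=rep,
                        coverage=coverage,
                        truth=truth,
                        tally=tally_replicate(truth, [], config.windows),
                        failed=True,
                    )
                )
                continue
            tally = tally_replicate(truth, predictions, config.windows)
            results.append(
                ReplicateResult(replicate=rep, coverage=coverage, truth=truth, tally=tally)
            )
            if log:
                log(
                    f"replicate={rep} coverage={coverage:g} stage=evaluate "
                    f"elapsed={time.perf_counter() - t0:.2f}s outcome=ok"
                )
    table = precision_recall_curve(results)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        metrics_path = out_dir / "metrics.csv"
        # undefined precision becomes an empty cell, never 0
        table.to_csv(metrics_path, index=False, na_rep="")
        manifest = RunManifest(
            config={k: v for k, v in config.__dict__.items()},
            seed=config.seed,
            outputs={"metrics": metrics_path.name},
            started=started,
            finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        manifest.write(out_dir / "manifest.json")
    return table
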