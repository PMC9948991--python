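"""Domain types and readers/writers for the standard formats the toolkit touches.

Coordinates are BED-style 0-based half-open everywhere in memory; the VCF
writer converts to 1-based at the boundary. Strand is one of ``+``, ``-``,
``.`` and a missing strand is preserved as ``.``, never guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ReferenceGenome",
    "TELibrary",
    "TaxonomyMap",
    "Interval",
    "Prediction",
    "TruthRecord",
    "SimConfig",
    "SignalTrack",
    "MetricsRow",
    "read_fasta",
    "read_genome",
    "read_library",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_vcf",
    "read_vcf_predictions",
    "read_track",
    "write_bedgraph",
    "read_taxonomy",
    "load_config",
    "parse_prediction_name",
]

_DNA_OK = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceGenome:
    """An ordered mapping of chromosome name -> uppercase DNA sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")
            bad = set(seq) - _DNA_OK
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains non-DNA characters: {sorted(bad)!r}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]


@dataclass(frozen=True)
class TELibrary:
    """TE family consensus sequences plus optional internal coding regions.

    ``internal_region`` maps a family to the 0-based half-open sub-interval of
    its consensus that holds internal coding sequence (i.e. excludes the LTRs);
    restricting depth estimates to it counts full-length elements only, since
    solo LTRs contribute no internal-region coverage.
    """

    consensus: dict[str, str]
    internal_region: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, seq in self.consensus.items():
            if not seq:
                raise FormatError(f"empty consensus for family {fam!r}")
        for fam, (start, end) in self.internal_region.items():
            if fam not in self.consensus:
                raise FormatError(f"internal region for unknown family {fam!r}")
            if not (0 <= start < end <= len(self.consensus[fam])):
                raise FormatError(
                    f"internal region {start}-{end} outside consensus of {fam!r}"
                )

    @property
    def families(self) -> list[str]:
        return list(self.consensus)

    def __contains__(self, family: str) -> bool:
        return family in self.consensus


@dataclass(frozen=True)
class TaxonomyMap:
    """Maps reference TE copy identifiers to TE family names."""

    rows: tuple[tuple[str, str], ...]

    def family_of(self, te_copy_id: str) -> str:
        for copy_id, fam in self.rows:
            if copy_id == te_copy_id:
                return fam
        raise KeyError(te_copy_id)

    def validate_against(self, library: TELibrary) -> None:
        missing = {fam for _, fam in self.rows if fam not in library}
        if missing:
            raise FormatError(f"taxonomy families absent from library: {sorted(missing)}")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Interval midpoint, floor for even lengths."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Prediction:
    """One detector call for a TE insertion."""

    chrom: str
    start: int
    end: int
    family: str
    category: str  # "reference" | "non-reference"
    method: str = "unknown"
    sample: str = "sample"
    strand: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("empty family")
        if self.category not in ("reference", "non-reference"):
            raise ValueError(f"bad category {self.category!r}")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return f"{self.family}|{self.category}|{self.method}"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic insertion, in reference coordinates.

    The interval [tsd_start, tsd_end) is the target-site duplication: the
    reference bases duplicated on both flanks of the inserted element.
    """

    chrom: str
    tsd_start: int
    tsd_end: int
    family: str
    strand: str

    def __post_init__(self) -> None:
        if self.tsd_end < self.tsd_start:
            raise ValueError("tsd_end < tsd_start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"truth strand must be +/-, got {self.strand!r}")

    @property
    def tsd_len(self) -> int:
        return self.tsd_end - self.tsd_start

    def as_prediction(self, method: str = "truth", sample: str = "sample") -> Prediction:
        return Prediction(
            chrom=self.chrom,
            start=self.tsd_start,
            end=self.tsd_end,
            family=self.family,
            category="non-reference",
            method=method,
            sample=sample,
            strand=self.strand,
        )


DEFAULT_WINDOWS = (0, 5, 100, 300, 500)


@dataclass(frozen=True)
class SimConfig:
    """All simulation knobs for the single-insertion benchmark."""

    replicates: int = 1
    tsd_len: int = 5
    strand_policy: str = "random"  # random | fixed+ | fixed-
    family_policy: Union[str, Mapping[str, float]] = "uniform"
    read_len: int = 100
    paired: bool = True
    insert_mean: int = 300
    insert_sd: int = 30
    error_rate: float = 0.0
    coverages: tuple[float, ...] = (50.0,)
    simulator: str = "builtin"
    seed: int = 0
    windows: tuple[int, ...] = DEFAULT_WINDOWS
    genome: Optional[str] = None
    library: Optional[str] = None
    sites: Optional[str] = None

    def __post_init__(self) -> None:
        errors = []
        for key in ("replicates", "tsd_len", "read_len", "insert_mean", "insert_sd"):
            if getattr(self, key) < 0:
                errors.append(key)
        if not (0.0 <= self.error_rate <= 1.0):
            errors.append("error_rate")
        if not self.coverages or any(c <= 0 for c in self.coverages):
            errors.append("coverages")
        if self.strand_policy not in ("random", "fixed+", "fixed-"):
            errors.append("strand_policy")
        if self.simulator not in ("builtin", "art", "wgsim"):
            errors.append("simulator")
        if list(self.windows) != sorted(self.windows) or any(n < 0 for n in self.windows):
            errors.append("windows")
        if isinstance(self.family_policy, Mapping):
            if not self.family_policy or any(w < 0 for w in self.family_policy.values()):
                errors.append("family_policy")
        elif self.family_policy != "uniform":
            errors.append("family_policy")
        if errors:
            raise ValueError(f"invalid SimConfig values for: {', '.join(errors)}")


@dataclass
class SignalTrack:
    """Per-base numeric values over named sequences; NaN marks uncovered bases."""

    values: dict[str, np.ndarray] = field(default_factory=dict)

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end); positions off the track come back NaN."""
        out = np.full(end - start, np.nan)
        arr = self.values.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def chroms(self) -> list[str]:
        return list(self.values)


@dataclass(frozen=True)
class MetricsRow:
    """Summary for one window size N across replicates."""

    window: int
    tp: int
    fp: int
    fn: int
    recall: Optional[float]
    precision: Optional[float]
    mean_nonref: float
    mean_ref: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("negative count")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping.

    The name is the header token before the first whitespace. Duplicate names
    and empty sequences are format errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: line 1: not FASTA (expected '>')")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in sequences:
                raise FormatError(f"{path}: duplicate sequence name {name!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise FormatError(f"{path}: empty sequence for {name!r}")
            sequences[name] = seq
    return sequences


def read_genome(path: Union[str, Path]) -> ReferenceGenome:
    return ReferenceGenome(read_fasta(path))


def read_library(
    path: Union[str, Path],
    internal_regions: Optional[Union[str, Path]] = None,
) -> TELibrary:
    """Read a TE consensus FASTA, optionally with an internal-region BED."""
    consensus = read_fasta(path)
    internal: dict[str, tuple[int, int]] = {}
    if internal_regions is not None:
        for iv in read_bed(internal_regions):
            internal[iv.chrom] = (iv.start, iv.end)
    return TELibrary(consensus, internal)


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

_NAME_GRAMMAR = re.compile(r"^(?P<family>[^|]+)\|(?P<category>[^|]+)\|(?P<method>[^|]+)$")


def parse_prediction_name(name: str) -> tuple[str, str, str]:
    """Split a BED name field into (family, category, method).

    Primary grammar is ``FAMILY|CATEGORY|METHOD``. As a fallback,
    ``FAMILY_non-reference`` / ``FAMILY_reference`` style names are accepted
    with the method reported as ``unknown``.
    """
    m = _NAME_GRAMMAR.match(name)
    if m:
        return m.group("family"), m.group("category"), m.group("method")
    for cat in ("non-reference", "reference"):
        suffix = "_" + cat
        if name.endswith(suffix):
            return name[: -len(suffix)], cat, "unknown"
    raise FormatError(f"cannot parse prediction name {name!r}")


def read_bed(
    path: Union[str, Path],
    as_predictions: bool = False,
    sample: str = "sample",
    name_parser: Callable[[str], tuple[str, str, str]] = parse_prediction_name,
) -> list:
    """Read BED into Interval records, or Prediction records when asked.

    Requires >=3 tab-separated columns with integral coordinates; missing
    strand is recorded as ".".
    """
    path = Path(path)
    out = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            name = cols[3] if len(cols) > 3 else "."
            try:
                score = float(cols[4]) if len(cols) > 4 and cols[4] != "." else 0.0
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            strand = cols[5] if len(cols) > 5 else "."
            if as_predictions:
                family, category, method = name_parser(name)
                out.append(
                    Prediction(
                        chrom=chrom,
                        start=start,
                        end=end,
                        family=family,
                        category=category,
                        method=method,
                        sample=sample,
                        strand=strand,
                        score=score,
                    )
                )
            else:
                out.append(Interval(chrom, start, end, name, score, strand))
    return out


def write_bed(records: Iterable, path: Union[str, Path]) -> None:
    """Write Interval / Prediction / TruthRecord rows as BED6."""
    with open(path, "w") as handle:
        for rec in records:
            if isinstance(rec, TruthRecord):
                row = (rec.chrom, rec.tsd_start, rec.tsd_end, rec.family, 0, rec.strand)
            elif isinstance(rec, Prediction):
                row = (rec.chrom, rec.start, rec.end, rec.name, rec.score, rec.strand)
            else:
                row = (rec.chrom, rec.start, rec.end, rec.name, rec.score, rec.strand)
            handle.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(
    predictions: Sequence[Prediction],
    genome: ReferenceGenome,
    path: Union[str, Path],
) -> None:
    """Write non-reference insertion predictions as VCF 4.2 symbolic records.

    POS is the 1-based position of the interval start; REF is the reference
    base there and ALT a symbolic ``<INS:ME:FAMILY>`` allele.
    """
    for pred in predictions:
        if pred.category != "non-reference":
            raise ValueError(f"VCF output is for non-reference predictions: {pred}")
        if pred.chrom not in genome:
            raise ValueError(f"chromosome {pred.chrom!r} absent from genome")
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##ALT=<ID=INS:ME,Description="Mobile element insertion">\n')
        handle.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the TSD interval">\n')
        handle.write('##INFO=<ID=FAMILY,Number=1,Type=String,Description="TE family">\n')
        handle.write('##INFO=<ID=STRAND,Number=1,Type=String,Description="Insertion strand">\n')
        handle.write('##INFO=<ID=METHOD,Number=1,Type=String,Description="Detection method">\n')
        for name, length in genome.lengths.items():
            handle.write(f"##contig=<ID={name},length={length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pred in predictions:
            pos = pred.start + 1  # 1-based
            ref_base = genome[pred.chrom][pred.start]
            info = (
                f"END={pred.end};FAMILY={pred.family};"
                f"STRAND={pred.strand};METHOD={pred.method}"
            )
            handle.write(
                f"{pred.chrom}\t{pos}\t.\t{ref_base}\t<INS:ME:{pred.family}>"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf_predictions(path: Union[str, Path], sample: str = "sample") -> list[Prediction]:
    """Read insertion predictions back from a VCF written by :func:`write_vcf`."""
    preds = []
    with open(path) as handle:
        for line in handle:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            chrom, pos, _, _, alt = cols[0], int(cols[1]), cols[2], cols[3], cols[4]
            info = dict(
                kv.split("=", 1) for kv in cols[7].split(";") if "=" in kv
            )
            m = re.match(r"<INS:ME:(?P<fam>[^>]+)>", alt)
            family = m.group("fam") if m else info.get("FAMILY", ".")
            preds.append(
                Prediction(
                    chrom=chrom,
                    start=pos - 1,
                    end=int(info.get("END", pos)),
                    family=family,
                    category="non-reference",
                    method=info.get("METHOD", "unknown"),
                    sample=sample,
                    strand=info.get("STRAND", "."),
                )
            )
    return preds


# ---------------------------------------------------------------------------
# signal tracks (bedGraph / fixed-step wiggle)
# ---------------------------------------------------------------------------


def read_track(path: Union[str, Path]) -> SignalTrack:
    """Read a bedGraph or fixed-step wiggle file into a per-base SignalTrack.

    Wiggle is 1-based; bedGraph is 0-based half-open. Uncovered positions are
    NaN. Overlapping bedGraph intervals with conflicting values are an error.
    """
    path = Path(path)
    runs: dict[str, list[tuple[int, int, float]]] = {}
    mode = "bedgraph"
    chrom = None
    pos = step = span = 1
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixedstep"
                continue
            if line.startswith("variableStep"):
                raise FormatError(f"{path}:{lineno}: variableStep wiggle not supported")
            if mode == "fixedstep" and "\t" not in line and " " not in line:
                try:
                    value = float(line)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad wiggle value") from None
                runs.setdefault(chrom, []).append((pos, pos + span, value))
                pos += step
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad bedGraph record") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end")
            runs.setdefault(cols[0], []).append((start, end, value))
            mode = "bedgraph"

    track = SignalTrack()
    for name, run_list in runs.items():
        size = max(end for _, end, _ in run_list)
        arr = np.full(size, np.nan)
        for start, end, value in run_list:
            existing = arr[start:end]
            conflict = ~np.isnan(existing) & (existing != value)
            if conflict.any():
                raise FormatError(
                    f"{path}: overlapping intervals with conflicting values on {name}"
                )
            arr[start:end] = value
        track.values[name] = arr
    return track


def write_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    """Write a SignalTrack as bedGraph, merging equal-value runs."""
    with open(path, "w") as handle:
        for chrom, arr in track.values.items():
            i = 0
            n = arr.size
            while i < n:
                if np.isnan(arr[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                    j += 1
                handle.write(f"{chrom}\t{i}\t{j}\t{arr[i]:g}\n")
                i = j


# ---------------------------------------------------------------------------
# taxonomy + config
# ---------------------------------------------------------------------------


def read_taxonomy(path: Union[str, Path]) -> TaxonomyMap:
    rows = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rows.append((cols[0], cols[1]))
    return TaxonomyMap(tuple(rows))


def load_config(source: Union[str, Path, Mapping]) -> SimConfig:
    """Load a JSON run configuration, filling defaults and validating.

    Unknown keys are rejected (listed in the error) so typos never silently
    fall back to a default.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source) as handle:
            data = json.load(handle)
        if not isinstance(data, dict):
            raise FormatError(f"{source}: config must be a JSON object")
    known = {f.name for f in dc_fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("coverages", "windows"):
        if key in data:
            data[key] = tuple(data[key])
    return SimConfig(**data)
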