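"""Self-contained toy dataset generator.

Emits everything the toolkit consumes — a ~100-kb three-chromosome genome, a
three-family TE library with internal coding regions, permissible-site BEDs
for a tRNA-promoter insertion model and a unique-region insertion model, toy
tRNA features, a sinusoidal nucleosome-like occupancy track, and a taxonomy
table — so every stage can be exercised without downloading data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core_io import (
    Interval,
    ReferenceGenome,
    SignalTrack,
    TELibrary,
    write_bed,
    write_bedgraph,
    write_fasta,
)

__all__ = ["FixtureSet", "make_fixtures", "build_fixture_objects"]

_CHROM_LENGTHS = {"chrI": 40_000, "chrII": 30_000, "chrIII": 30_000}
_FAMILY_SPECS = {
    # name -> (consensus length, LTR length); internal region excludes LTRs
    "TY1": (2500, 330),
    "TY2": (2000, 330),
    "TY3": (1500, 340),
}
_N_TRNA = 20
_TRNA_LEN = 72


@dataclass
class FixtureSet:
    """In-memory handles plus the on-disk paths of a generated fixture."""

    genome: ReferenceGenome
    library: TELibrary
    trna: list[Interval]
    promoter_sites: list[Interval]
    unique_sites: list[Interval]
    occupancy: SignalTrack
    taxonomy: list[tuple[str, str]]
    paths: dict[str, Path]


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def build_fixture_objects(seed: int) -> FixtureSet:
    """Build the toy dataset in memory; deterministic given the seed."""
    rng = np.random.default_rng(seed)
    genome = ReferenceGenome(
        {name: _random_dna(length, rng) for name, length in _CHROM_LENGTHS.items()}
    )

    consensus = {}
    internal = {}
    for fam, (length, ltr) in _FAMILY_SPECS.items():
        seq = _random_dna(length, rng)
        # retrotransposon-style structure: identical LTRs flanking the body
        consensus[fam] = seq[:ltr] + seq[ltr : length - ltr] + seq[:ltr]
        internal[fam] = (ltr, len(consensus[fam]) - ltr)
    library = TELibrary(consensus, internal)

    # place tRNA genes sparsely, alternating strands, away from chromosome ends
    chroms = list(_CHROM_LENGTHS)
    trna = []
    per_chrom = _N_TRNA // len(chroms) + 1
    idx = 0
    for chrom in chroms:
        length = _CHROM_LENGTHS[chrom]
        spacing = (length - 8000) // per_chrom
        for k in range(per_chrom):
            if idx >= _N_TRNA:
                break
            start = 4000 + k * spacing + int(rng.integers(0, spacing // 4))
            strand = "+" if idx % 2 == 0 else "-"
            trna.append(
                Interval(chrom, start, start + _TRNA_LEN, f"tRNA-{idx + 1}", 0, strand)
            )
            idx += 1

    # promoter model: the ~1 kb immediately 5' of each tRNA TSS
    promoter_sites = []
    for t in trna:
        if t.strand == "+":
            promoter_sites.append(
                Interval(t.chrom, max(t.start - 1000, 0), t.start - 100, t.name + "_up")
            )
        else:
            promoter_sites.append(
                Interval(t.chrom, t.end + 100, t.end + 1000, t.name + "_up")
            )

    # unique-region model: complement of tRNA neighbourhoods (+/- 1200 bp),
    # clipped away from chromosome ends, pieces >= 400 bp
    margin = 1200
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for t in trna:
        forbidden.setdefault(t.chrom, []).append((t.start - margin, t.end + margin))
    unique_sites = []
    for chrom, length in _CHROM_LENGTHS.items():
        zones = sorted(forbidden.get(chrom, []))
        cursor = 1500
        pieces = []
        for lo, hi in zones + [(length - 1500, length)]:
            if lo - cursor >= 400:
                pieces.append((cursor, lo))
            cursor = max(cursor, hi)
        for i, (lo, hi) in enumerate(pieces):
            unique_sites.append(Interval(chrom, lo, hi, f"{chrom}_uniq_{i}"))

    # nucleosome-like occupancy: ~165-bp periodic peaks plus a smooth baseline
    occupancy = SignalTrack()
    for chrom, length in _CHROM_LENGTHS.items():
        x = np.arange(length)
        phase = rng.uniform(0, 2 * np.pi)
        vals = 1.0 + 0.8 * np.sin(2 * np.pi * x / 165.0 + phase) ** 2
        occupancy.values[chrom] = np.round(vals, 4)

    taxonomy = [
        (f"{fam}_copy{i}", fam) for fam in consensus for i in (1, 2)
    ]
    return FixtureSet(
        genome=genome,
        library=library,
        trna=trna,
        promoter_sites=promoter_sites,
        unique_sites=unique_sites,
        occupancy=occupancy,
        taxonomy=taxonomy,
        paths={},
    )


def make_fixtures(
    seed: int, out_dir: Union[str, Path], force: bool = False
) -> FixtureSet:
    """Write the toy dataset to ``out_dir``; byte-identical for equal seeds."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty (use force=True / --force)")
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture_objects(seed)

    paths = {
        "genome": out_dir / "genome.fasta",
        "library": out_dir / "te_library.fasta",
        "internal": out_dir / "internal_regions.bed",
        "trna": out_dir / "trna.bed",
        "promoter_sites": out_dir / "sites_promoter.bed",
        "unique_sites": out_dir / "sites_unique.bed",
        "occupancy": out_dir / "occupancy.bedgraph",
        "taxonomy": out_dir / "taxonomy.tsv",
        "manifest": out_dir / "fixtures.json",
    }
    write_fasta(fx.genome.sequences, paths["genome"])
    write_fasta(fx.library.consensus, paths["library"])
    write_bed(
        [
            Interval(fam, lo, hi, "internal")
            for fam, (lo, hi) in fx.library.internal_region.items()
        ],
        paths["internal"],
    )
    write_bed(fx.trna, paths["trna"])
    write_bed(fx.promoter_sites, paths["promoter_sites"])
    write_bed(fx.unique_sites, paths["unique_sites"])
    write_bedgraph(fx.occupancy, paths["occupancy"])
    with open(paths["taxonomy"], "w") as handle:
        for copy_id, fam in fx.taxonomy:
            handle.write(f"{copy_id}\t{fam}\n")
    with open(paths["manifest"], "w") as handle:
        json.dump(
            {"seed": seed, "files": {k: p.name for k, p in paths.items() if k != "manifest"}},
            handle,
            indent=2,
            sort_keys=True,
        )
        handle.write("\n")
    fx.paths = paths
    return fx
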