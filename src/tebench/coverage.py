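"""Depth-of-coverage TE copy-number estimation.

Copy number of a TE family is estimated as the mean read depth over its
consensus sequence (optionally restricted to the internal coding region, which
counts full-length elements only — solo LTRs contribute no internal coverage)
divided by the background depth, the mean per-base depth over user-supplied
non-repetitive regions of the genome. The estimator is scale-equivariant:
multiplying all depths by a constant leaves the ratio unchanged.

Depth is consumed from text tracks (bedGraph or wiggle); alignment itself is
outside this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import Interval, SignalTrack

__all__ = [
    "DepthProfile",
    "background_depth",
    "te_copy_number",
    "simulate_depth",
]


@dataclass
class DepthProfile:
    """Per-position depth along a consensus, with the normalization baked in."""

    family: str
    depth: np.ndarray
    background: float

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background depth must be positive")
        if np.nanmin(self.depth) < 0:
            raise ValueError("negative depth values")

    @property
    def normalized(self) -> np.ndarray:
        return self.depth / self.background


def background_depth(
    track: SignalTrack, nonrepetitive: Sequence[Interval]
) -> float:
    """Mean per-base depth over the union of non-repetitive intervals.

    Overlapping intervals are deduplicated so each base counts once; positions
    missing from the track are ignored with a warning.
    """
    if not nonrepetitive:
        raise ValueError("no non-repetitive intervals supplied")
    # dedupe overlaps per chromosome with a boolean mask
    by_chrom: dict[str, list[Interval]] = {}
    for iv in nonrepetitive:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    values = []
    n_missing = 0
    for chrom, ivs in by_chrom.items():
        hi = max(iv.end for iv in ivs)
        mask = np.zeros(hi, dtype=bool)
        for iv in ivs:
            mask[iv.start : iv.end] = True
        vals = track.get(chrom, 0, hi)[mask]
        n_missing += int(np.isnan(vals).sum())
        values.append(vals[~np.isnan(vals)])
    if n_missing:
        warnings.warn(
            f"{n_missing} non-repetitive positions missing from the depth track",
            stacklevel=2,
        )
    all_vals = np.concatenate(values) if values else np.array([])
    if all_vals.size == 0:
        raise ValueError("no non-repetitive position is covered by the track")
    return float(all_vals.mean())


def te_copy_number(
    te_track: SignalTrack,
    family: str,
    background: float,
    region: Optional[tuple[int, int]] = None,
    edge_trim: int = 0,
    use_median: bool = False,
) -> float:
    """Depth-normalized copy-number estimate for one TE family.

    The location statistic over the consensus region (whole consensus minus
    ``edge_trim`` bases at each end by default) divided by the background
    depth. With ``region`` set to the internal coding interval this estimates
    the number of full-length copies.
    """
    if background <= 0:
        raise ValueError("background depth must be positive")
    if family not in te_track.values:
        raise ValueError(f"family {family!r} absent from the depth track")
    arr = te_track.values[family]
    if region is None:
        lo, hi = edge_trim, arr.size - edge_trim
    else:
        lo, hi = region[0] + edge_trim, region[1] - edge_trim
    if hi - lo < 1:
        raise ValueError("region shorter than 1 bp after edge trimming")
    vals = arr[lo:hi]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no covered position in the requested region")
    stat = float(np.median(vals)) if use_median else float(vals.mean())
    return stat / background


def simulate_depth(
    copy_number: float,
    background: float,
    length: int,
    rng: np.random.Generator,
    family: str = "TE",
) -> SignalTrack:
    """Synthetic per-base depth: i.i.d. Poisson(copy_number * background).

    Test fixture for the estimator — real depth comes from an aligner.
    """
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if background <= 0:
        raise ValueError("background depth must be positive")
    if length < 1:
        raise ValueError("length must be >= 1")
    values = rng.poisson(copy_number * background, size=length).astype(float)
    return SignalTrack({family: values})
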