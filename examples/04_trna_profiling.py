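"""Profile insertion positions relative to tRNA TSSs and nucleosome occupancy.

Plants insertions clustered ~100 bp upstream of toy tRNA TSSs, filters them
with the stranded promoter window (1000 bp upstream / 500 bp downstream),
computes signed TSS distances, fits the narrow-bandwidth Gaussian KDE, and
aggregates the toy occupancy track around the same TSSs.
"""

import numpy as np

from tebench import Feature, Prediction
from tebench.annotate import (
    aggregate_signal,
    kde_profile,
    near_feature_filter,
    nearest_tss_distance,
)
from tebench.fixtures import build_fixture_objects

fx = build_fixture_objects(seed=4)
rng = np.random.default_rng(4)
feats = [Feature.from_interval(t) for t in fx.trna]

# synthetic call set: insertions ~100 bp upstream of each TSS (Gaussian spread)
preds = []
for i, f in enumerate(feats):
    for j in range(10):
        offset = int(rng.normal(-100, 40))  # upstream of the TSS
        pos = f.tss + offset if f.strand == "+" else f.tss - offset
        preds.append(Prediction(f.chrom, pos, pos + 5, "TY1", "non-reference",
                                "stub", f"s{j}", f.strand))

kept = near_feature_filter(preds, feats, upstream=1000, downstream=500)
dists = [nearest_tss_distance(p, feats) for p in kept]
curve = kde_profile(dists)  # 0.4x nrd0 bandwidth
peak = curve.positions[np.argmax(curve.values)]

occ = aggregate_signal(fx.occupancy, feats, upstream=2000, downstream=500)

print(f"{len(kept)}/{len(preds)} insertions fall in the stranded tRNA promoter window")
print(f"mean signed TSS distance: {np.mean(dists):.1f} bp (negative = upstream)")
print(f"KDE density peak at {peak:.0f} bp relative to the TSS")
print(f"occupancy metaprofile spans [{occ.positions[0]}, {occ.positions[-1]}] bp, "
      f"mean {np.nanmean(occ.values):.2f}")
print("a peak near -100 bp reproduces the planted upstream targeting bias.")
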