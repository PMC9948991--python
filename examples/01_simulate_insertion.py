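"""Build one synthetic genome carrying a single TE insertion with a 5-bp TSD.

Generates the toy dataset in memory, plans a random insertion in a tRNA
promoter region, constructs the synthetic chromosome, and prints the truth
record plus the duplicated flanks.
"""

import numpy as np

from tebench import SimConfig, build_synthetic_genome, plan_insertion
from tebench.fixtures import build_fixture_objects

fx = build_fixture_objects(seed=1)
cfg = SimConfig(tsd_len=5, seed=1)
rng = np.random.default_rng(cfg.seed)

plan = plan_insertion(fx.genome, fx.library, fx.promoter_sites, cfg, rng)
synthetic, truth = build_synthetic_genome(fx.genome, fx.library, plan)

te_len = len(fx.library.consensus[truth.family])
p = truth.tsd_start
chrom = synthetic[truth.chrom]
print(f"planted {truth.family}({truth.strand}) at {truth.chrom}:{truth.tsd_start}-{truth.tsd_end}")
print(f"reference length {len(fx.genome[truth.chrom]):,} bp -> synthetic {len(chrom):,} bp "
      f"(+{te_len} bp TE + {truth.tsd_len} bp TSD)")
print(f"5' flank {chrom[p:p + 5]}  3' flank {chrom[p + 5 + te_len:p + 10 + te_len]}")
print("the two flanks are the duplicated target site: identical by construction")
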