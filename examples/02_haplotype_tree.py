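"""Neighbor-joining tree of CGT haplotype groups with bootstrap support.

Enumerates haplotype groups on the MAF-filtered core region, builds the raw
site-difference matrix and an NJ tree, and prints newick with bootstrap
percentages on internal nodes.
"""

import io

from promoterpop import (
    SnpTriplet,
    bootstrap_support,
    enumerate_haplotypes,
    filter_by_maf,
    restrict_to_region,
)
from promoterpop.haplotypes import PromoterType
from promoterpop.synthetic_data import SimConfig, simulate_dataset

cfg = SimConfig(seed=1)
ds = simulate_dataset(cfg)
triplet = SnpTriplet(positions=cfg.promoter_positions)

core = restrict_to_region(ds.panel, cfg.core)
filtered = filter_by_maf(core, 0.005, keep_positions=triplet.positions)
groups = [
    g for g in enumerate_haplotypes(filtered, triplet)
    if g.promoter_type is PromoterType.CGT
]
print(f"{len(groups)} CGT haplotype groups "
      f"(sizes {[g.size for g in groups]})")

tree = bootstrap_support(
    [g.name for g in groups], [g.sequence for g in groups], n_reps=200, seed=1
)
buf = io.StringIO()
tree.write(buf)
print(buf.getvalue().strip())
# Internal node labels are bootstrap percentages; a deep well-supported split
# separating introgressed from African-centred groups mirrors the CGT1/CGT2
# division seen in the real data.
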