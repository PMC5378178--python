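"""Decide whether two samples carry the identical bacterial population.

Consensus ANI = 1 - (variant positions / unmasked genome length), where a
variant position has >= 80% of reads conflicting with the reference, and
scaffold ends, conserved regions and low-coverage positions are masked.
Populations above 99.9% consensus ANI are treated as identical strains.
"""

import numpy as np

from strainsites import consensus_ani, mask_genome, same_population
from strainsites.simulate import SimulationConfig, simulate_community

# same strain in two samples: only a handful of subpopulation variants
cfg = SimulationConfig(genome_length=100_000, true_ptr=1.0, mean_coverage=40.0,
                       n_samples=2,
                       haplotypes=[{}, {10_000: "G", 60_000: "T"}],
                       haplotype_frequencies=[[0.1, 0.9], [0.95, 0.05]], seed=3)
truth = simulate_community(cfg)

for sample_id in truth.pileup.sample_ids:
    pm = truth.pileup.sample(sample_id)
    masked = mask_genome([pm.length], pileup=pm, end_buffer=100, min_depth=5)
    res = consensus_ani(pm, masked)
    verdict = "identical" if same_population(res) else "different"
    print(f"{sample_id}: consensus ANI {100 * res.consensus_ani:.4f}% "
          f"({res.variant_position_count} variant sites / "
          f"{res.unmasked_length} unmasked bp) -> {verdict} population")
# Sample S0 carries the alternate haplotype at 90%: its consensus differs
# from the reference at the two planted sites, but 2 sites over ~100 kb is
# still ANI 99.998% -- far above the 99.9% identity threshold.
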