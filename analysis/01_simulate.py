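#!/usr/bin/env python
"""Generate the synthetic study set.

Writes, under results/sim/:
  * a quartet of 500-kb circular genomes (~80% coding), each carrying a
    controlled-divergence variant of the 28-bp quasi-palindromic
    recombination site at 122-142 degrees from oriC;
  * one 500-kb genome with GTTG planted at 2/kb on the leading strand vs
    0.5/kb on the lagging strand, polarity inverting at 150 degrees;
  * truth JSON per genome (planted intervals / placements / terminus).
"""

import json
from pathlib import Path

from difskew.synthetic_data import SimConfig, conserved_quartet, polarized_genome, write_simulated

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
L = 500_000
SEED = 1


def main():
    quartet_cfg = SimConfig(L=L, seed=SEED)
    genomes, truths = conserved_quartet(quartet_cfg)
    write_simulated(genomes, truths, OUT)
    print(f"quartet: {len(genomes)} genomes of {L/1e6:.1f} Mb")
    for gid, t in truths.items():
        print(f"  {gid}: site {t.sequence} planted at {t.start}")

    asps_cfg = SimConfig(L=L, seed=SEED + 1000, ter_angle=150.0)
    g, truth = polarized_genome(asps_cfg)
    write_simulated({g.id: g}, {g.id: truth}, OUT)
    print(f"polarized genome: {len(truth['fwd'])} fwd / {len(truth['rev'])} rev "
          f"placements of {truth['word']}, terminus at {truth['ter']} "
          f"({truth['ter_angle']} deg)")
    with open(OUT / "config.json", "w") as fh:
        json.dump({"L": L, "seed": SEED}, fh)


if __name__ == "__main__":
    main()
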