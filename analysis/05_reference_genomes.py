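#!/usr/bin/env python
"""Reproduction on user-supplied reference genomes (no downloads).

The package never fetches data.  To rerun the real-genome analyses,
download the RefSeq records yourself (FASTA + GenBank or GFF3), e.g.
NC_000868 (P. abyssi GE5), NC_000961 (P. horikoshii OT3), NC_003413
(P. furiosus DSM 3638), NC_006624 (T. kodakaraensis KOD1), NC_000913
(E. coli K-12 MG1655), and provide oriC positions (midpoint of the
origin interval, e.g. the cdc6-adjacent region), then:

    python analysis/05_reference_genomes.py \
        --genome PAB=pab.fasta --annotation PAB=pab.gb --oric PAB=124000 \
        --genome PH=ph.fasta  --annotation PH=ph.gb  --oric PH=1160000 ...

With at least two genomes it runs conserved-site discovery and prints
each member's angle/quarter; for every genome with an oriC it also runs
the polarized-word analysis (expect the KOPS family, GGNAGGG-like
8-mers, as top words in E. coli with a skew summit near 178 degrees, and
GTTG/GTTC 4-mers in Thermococcales).
"""

import argparse
from pathlib import Path

from difskew.genome_io import read_genome
from difskew.pipeline import PipelineConfig, run_asps_analysis, run_dif_discovery

OUT = Path(__file__).resolve().parent.parent / "results" / "reference"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genome", action="append", default=[], metavar="ID=FASTA")
    ap.add_argument("--annotation", action="append", default=[], metavar="ID=FILE")
    ap.add_argument("--oric", action="append", default=[], metavar="ID=POS")
    ap.add_argument("--threshold", type=float, default=0.80)
    args = ap.parse_args()

    fastas = dict(t.split("=", 1) for t in args.genome)
    anns = dict(t.split("=", 1) for t in args.annotation)
    orics = {k: int(v) for k, v in (t.split("=", 1) for t in args.oric)}
    if not fastas:
        ap.error("supply at least one --genome ID=FASTA")

    genomes = {gid: read_genome(fa, anns.get(gid), oric=orics.get(gid))
               for gid, fa in fastas.items()}

    if len(genomes) >= 2:
        report = run_dif_discovery(
            PipelineConfig(genomes=genomes, oric=orics,
                           conservation_threshold=args.threshold,
                           outdir=OUT / "discovery"))
        print("\n".join(report.funnel))
        if report.groups:
            print(report.site_table.to_string(index=False))

    for gid in orics:
        report = run_asps_analysis(
            PipelineConfig(genomes=genomes, oric=orics, outdir=OUT / "asps"),
            genome_id=gid)
        print(f"\n{gid}:")
        print(report.table.head(5).to_string(index=False))
        if not report.no_stable_asps:
            print(f"summit: {report.summit_position} ({report.summit_angle:.1f} deg)")


if __name__ == "__main__":
    main()
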