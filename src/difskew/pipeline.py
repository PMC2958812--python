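"""End-to-end workflows: multi-genome dif discovery and single-genome
terminus-polarized word (ASPS) analysis.

Both workflows are deterministic given their config: stable orderings
everywhere and seeded randomness only.  Each pipeline stage logs its
input/output cardinalities so the filtering funnel (all candidate
windows -> conserved groups -> single best group) is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .conservation import (
    ConservedGroup,
    Consensus,
    at_fraction,
    consensus_iupac,
    conserved_groups,
)
from .genome_io import Genome, intergenic_regions, read_genome, write_predictions
from .ir_search import IRCandidate, SearchParams, enumerate_ir_candidates
from .skew import RankedWord, RotationGrid, SkewCurve, cumulative_skew, rank_asps, summit

logger = logging.getLogger("difskew")

__all__ = [
    "PipelineConfig",
    "DifDiscoveryReport",
    "AspsReport",
    "run_dif_discovery",
    "run_asps_analysis",
]


@dataclass
class PipelineConfig:
    """Inputs and parameters for both workflows.

    ``genomes`` maps genome id to a :class:`Genome` (callers reading from
    disk use :func:`difskew.genome_io.read_genome` first).  ``oric`` maps
    genome id to the origin position (midpoint of the oriC interval).
    """

    genomes: Mapping[str, Genome]
    oric: Mapping[str, int] = field(default_factory=dict)
    search: SearchParams = field(default_factory=SearchParams)
    conservation_threshold: float = 0.80
    grid: RotationGrid = field(default_factory=RotationGrid)
    k_range: Sequence[int] = tuple(range(4, 9))
    min_intergenic_length: int = 1
    flank: int = 25  # flank width for the descriptive AT-fraction report
    bin: int = 1000  # skew curve resolution
    outdir: Optional[Path] = None
    seed: int = 0

    @classmethod
    def from_paths(cls, fasta_paths, annotation_paths=None, oric=None, **kw):
        annotation_paths = annotation_paths or {}
        genomes = {}
        for key, fp in dict(fasta_paths).items():
            ann = annotation_paths.get(key)
            if ann is None:
                logger.warning("%s: no annotation; whole genome treated as intergenic", key)
            g = read_genome(fp, ann)
            genomes[key] = g
        return cls(genomes=genomes, oric=oric or {}, **kw)


@dataclass
class DifDiscoveryReport:
    candidate_counts: dict[str, int]
    groups: list[ConservedGroup]
    consensus: Optional[Consensus]
    site_table: pd.DataFrame  # per-genome member of the top group, with angles
    funnel: list[str]


@dataclass
class AspsReport:
    ranked: list[RankedWord]
    table: pd.DataFrame
    curve: Optional[SkewCurve]
    summit_position: Optional[int]
    summit_angle: Optional[float]
    no_stable_asps: bool
    funnel: list[str]


def _log(funnel: list[str], msg: str, *args) -> None:
    funnel.append(msg % args if args else msg)
    logger.info(msg, *args)


def _candidates_for_genome(
    genome: Genome, params: SearchParams, min_len: int
) -> list[IRCandidate]:
    """Enumerate candidates over all intergenic regions in one pass.

    Region sequences are joined with N runs (never part of a window), so
    one vectorized enumeration covers the whole genome; candidate starts
    are mapped back to genome coordinates.
    """
    regions = intergenic_regions(genome, min_length=max(min_len, 2 * params.arm_min + params.spacer_min))
    if not regions:
        return []
    pad = "N" * (2 * params.arm_max + params.spacer_max)
    joined = pad.join(r.sequence for r in regions)
    # offset of each region inside the joined string
    offsets = []
    pos = 0
    for r in regions:
        offsets.append(pos)
        pos += len(r.sequence) + len(pad)
    offsets_arr = np.array(offsets)
    starts_arr = np.array([r.start for r in regions])
    raw = enumerate_ir_candidates(joined, genome_id=genome.id)
    L = genome.length
    out = []
    for c in raw:
        ridx = int(np.searchsorted(offsets_arr, c.start, side="right")) - 1
        gstart = (int(starts_arr[ridx]) + (c.start - int(offsets_arr[ridx]))) % L
        out.append(dataclasses.replace(c, start=gstart))
    out.sort(key=lambda c: (c.start, c.arm_len, c.spacer_len))
    return out


def run_dif_discovery(config: PipelineConfig) -> DifDiscoveryReport:
    """Multi-genome recombination-site discovery.

    Enumerates imperfect inverted repeats in the intergenic DNA of every
    genome, keeps cross-genome groups conserved above the similarity
    threshold, builds the IUPAC consensus of the top group, and reports
    each member's angular position relative to its genome's oriC.
    """
    if len(config.genomes) < 2:
        raise ValueError("dif discovery requires at least two genomes")
    funnel: list[str] = []
    candidates: dict[str, list[IRCandidate]] = {}
    for gid in sorted(config.genomes):
        genome = config.genomes[gid]
        if not genome.features:
            logger.warning("%s: no annotation; treating whole genome as intergenic", gid)
        cands = _candidates_for_genome(genome, config.search, config.min_intergenic_length)
        candidates[gid] = cands
        _log(funnel, "ir_search %s: %d intergenic IR candidates", gid, len(cands))

    groups = conserved_groups(candidates, threshold=config.conservation_threshold)
    _log(funnel, "conservation: %d candidate sets -> %d conserved groups (threshold %.2f)",
         sum(map(len, candidates.values())), len(groups), config.conservation_threshold)

    consensus = None
    rows = []
    if groups:
        top = groups[0]
        consensus = consensus_iupac([m.canonical_seq for m in top.members])
        _log(funnel, "consensus: top group min_similarity %.3f, IUPAC %s",
             top.min_similarity, consensus.iupac)
        for m in top.members:
            genome = config.genomes[m.genome_id]
            oric = config.oric.get(m.genome_id, genome.oric)
            angle = q = None
            if oric is not None:
                angle = geometry.angle_from_origin(m.start, oric, genome.length)
                q = geometry.quarter(angle)
            flank_l = genome.fetch((m.start - config.flank) % genome.length,
                                   (m.start - config.flank) % genome.length + config.flank)
            flank_r = genome.fetch(m.end % genome.length, m.end % genome.length + config.flank)
            rows.append(
                dict(genome_id=m.genome_id, start=m.start, end=m.end,
                     arm_len=m.arm_len, spacer_len=m.spacer_len,
                     mismatches=m.mismatches, sequence=m.sequence,
                     angle_deg=angle, quarter=q,
                     flank_at_fraction=round((at_fraction(flank_l) + at_fraction(flank_r)) / 2, 3))
            )
    site_table = pd.DataFrame(rows)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        all_members = [m for g in groups for m in g.members]
        write_predictions(all_members, outdir / "conserved_sites.gff3", "GFF3")
        write_predictions(all_members, outdir / "conserved_sites.tsv", "TSV")
        if consensus is not None:
            pd.DataFrame(
                {"position": range(len(consensus.iupac)),
                 "iupac": list(consensus.iupac),
                 "info_bits": consensus.info_content}
            ).to_csv(outdir / "consensus_info.tsv", sep="\t", index=False)
            site_table.to_csv(outdir / "top_group_sites.tsv", sep="\t", index=False)
            with open(outdir / "consensus.txt", "w") as fh:
                fh.write(f">consensus_top_group min_similarity="
                         f"{groups[0].min_similarity:.3f}\n{consensus.iupac}\n")
        with open(outdir / "funnel.log", "w") as fh:
            fh.write("\n".join(funnel) + "\n")

    return DifDiscoveryReport(
        candidate_counts={g: len(c) for g, c in candidates.items()},
        groups=groups,
        consensus=consensus,
        site_table=site_table,
        funnel=funnel,
    )


def run_asps_analysis(
    config: PipelineConfig,
    genome_id: str | None = None,
    z_threshold: float = 3.0,
) -> AspsReport:
    """Single-genome search for terminus-polarized over-represented words.

    Ranks all words of the configured lengths by the rotating-terminus
    composite score, then computes the cumulative skew curve and summit of
    the top word.  If no word reaches ``z_threshold`` (median z across
    rotations) the report is flagged ``no_stable_asps``.
    """
    if genome_id is None:
        if len(config.genomes) != 1:
            raise ValueError("specify genome_id when config holds several genomes")
        genome_id = next(iter(config.genomes))
    genome = config.genomes[genome_id]
    oric = config.oric.get(genome_id, genome.oric)
    if oric is None:
        raise ValueError(f"{genome_id}: ASPS analysis requires oriC")
    funnel: list[str] = []
    ranked = rank_asps(genome, oric=oric, k_range=config.k_range, grid=config.grid)
    _log(funnel, "rank_asps %s: %d sign-consistent polarized words (k in %s)",
         genome_id, len(ranked), list(config.k_range))
    table = pd.DataFrame(
        [dataclasses.asdict(r) for r in ranked],
        columns=["word", "k", "median_z", "median_skew", "median_skew_z", "score",
                 "fwd_count", "rev_count", "expected", "self_overlapping"],
    )
    if table.empty or ranked[0].median_z < z_threshold:
        _log(funnel, "no stable ASPS: top median z %s below %.1f",
             f"{ranked[0].median_z:.2f}" if ranked else "n/a", z_threshold)
        return AspsReport(ranked=ranked, table=table, curve=None,
                          summit_position=None, summit_angle=None,
                          no_stable_asps=True, funnel=funnel)
    top = ranked[0]
    curve = cumulative_skew(genome, top.word, oric=oric, bin=config.bin)
    pos, angle = summit(curve)
    _log(funnel, "cumulative_skew %s: top word %s, summit at %d (%.1f deg from oriC)",
         genome_id, top.word, pos, angle)
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"{genome_id}_asps_ranked.tsv", sep="\t", index=False)
        pd.DataFrame({"bin_end_offset": curve.positions, "cumulative": curve.values}).to_csv(
            outdir / f"{genome_id}_skew_{top.word}.tsv", sep="\t", index=False)
        with open(outdir / f"{genome_id}_asps_funnel.log", "w") as fh:
            fh.write("\n".join(funnel) + "\n")
    return AspsReport(ranked=ranked, table=table, curve=curve,
                      summit_position=pos, summit_angle=angle,
                      no_stable_asps=False, funnel=funnel)
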