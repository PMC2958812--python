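"""Synthetic circular genomes with the structure the pipeline assumes.

Three signals can be planted, each with an exact truth record so recovery
is assertable downstream:

* gene/intergenic architecture (genes are annotation masks, not
  codon-realistic sequence -- only the intergenic mask matters here);
* a conserved imperfect inverted-repeat site at a chosen angle from oriC,
  optionally as a set of controlled-divergence variants across several
  genomes;
* a short word with strand-polarized density whose polarity inverts at a
  chosen terminus angle (leading-strand rate on the oriC->ter replichore,
  lagging rate on the other, mirrored for the reverse complement).

Divergence between genome copies uses uniform base exchange
(Jukes-Cantor-like, no indels).  Inside protected planted-site intervals,
arm positions mutate as complementary pairs (compensatory substitutions),
the way a recombinase-bound palindrome actually diverges: the
inverted-repeat structure -- what the site search detects -- is conserved
even while the sequence drifts.  Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import geometry
from .genome_io import Feature, Genome, IntergenicRegion, intergenic_regions, write_genome
from .ir_search import decode, encode, revcomp

__all__ = [
    "SimConfig",
    "PlantedSite",
    "random_genome",
    "plant_site",
    "plant_polarized_word",
    "diverge_set",
    "conserved_quartet",
    "polarized_genome",
    "write_simulated",
]

#: the 28-bp quasi-palindromic recombination site carried by the printed
#: 43-nt oligonucleotide (two 11-bp arms, 2 mismatches, 6-bp spacer)
DEFAULT_SITE = "ATTGGATATAATCGGCCTTATATCTAAA"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genomes.

    Defaults model a small archaeal chromosome: 1 Mb, balanced GC,
    ~80% of the sequence in genes of mean length ~950 bp; the planted
    recombination site sits at 130 degrees from oriC (the real sites lie
    at 120-142 degrees); the polarized word is GTTG at 2 occurrences/kb on
    the leading strand against 0.5/kb on the lagging strand, with polarity
    inverting at 150 degrees.
    """

    L: int = 1_000_000
    gc: float = 0.5
    gene_density: float = 0.80
    gene_len_mean: int = 950
    seed: int = 0
    planted_site: str = DEFAULT_SITE
    site_arm_len: int = 11
    site_spacer_len: int = 6
    site_angle: float = 130.0
    asps_word: str = "GTTG"
    asps_rate_leading: float = 2.0  # occurrences per kb
    asps_rate_lagging: float = 0.5
    ter_angle: float = 150.0
    n_genomes: int = 4
    divergence: float = 0.3  # background substitutions per site between copies
    site_divergence: float = 0.05  # per-site rate inside protected intervals

    def __post_init__(self):
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        if self.asps_rate_leading < 0 or self.asps_rate_lagging < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")
        if 2 * self.site_arm_len + self.site_spacer_len != len(self.planted_site):
            raise ValueError("site geometry inconsistent with planted_site length")


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for a planted site: genome interval plus IR geometry."""

    start: int
    end: int
    arm_len: int
    spacer_len: int
    sequence: str


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    # inverse-CDF sampling; much faster than rng.choice for Mb-scale draws
    return np.searchsorted(np.cumsum(p), rng.random(n), side="right").astype(np.uint8)


def random_genome(config: SimConfig, genome_id: str = "sim") -> Genome:
    """I.i.d. circular genome at the configured GC with non-overlapping
    gene annotations hitting ``gene_density`` within 2%."""
    rng = np.random.default_rng(config.seed)
    L = config.L
    codes = _random_bases(rng, L, config.gc)
    features: list[Feature] = []
    if config.gene_density > 0:
        target = config.gene_density * L
        mean = config.gene_len_mean
        n_genes = int(round(target / mean))
        if n_genes < 1:
            raise ValueError("gene_density too low for one gene")
        lens = np.maximum(60, rng.gamma(shape=8.0, scale=mean / 8.0, size=n_genes)).astype(int)
        lens = np.round(lens * target / lens.sum()).astype(int)
        gap_total = L - int(lens.sum())
        if gap_total < n_genes:  # need at least 1 bp between genes
            raise ValueError(
                f"infeasible gene density {config.gene_density} with mean length {mean}"
            )
        # split intergenic bp into n_genes gaps (one of them wraps the origin)
        gaps = rng.multinomial(gap_total - n_genes, np.full(n_genes, 1 / n_genes)) + 1
        pos = int(gaps[0] // 2)  # start the first gene after part of the wrap gap
        for i in range(n_genes):
            start = pos
            end = start + int(lens[i])
            features.append(
                Feature(start=start % L, end=start % L + (end - start),
                        strand="+" if rng.random() < 0.5 else "-", kind="CDS")
            )
            pos = end + int(gaps[(i + 1) % n_genes]) if i + 1 < n_genes else end
        density = lens.sum() / L
        if abs(density - config.gene_density) > 0.02:
            raise ValueError(f"gene placement achieved density {density:.3f}")
    return Genome(id=genome_id, sequence=decode(codes), features=features, oric=0)


def plant_site(
    genome: Genome,
    site: str,
    angle: float,
    arm_len: int = 11,
    spacer_len: int = 6,
) -> tuple[Genome, PlantedSite]:
    """Overwrite the intergenic region nearest to ``angle`` with ``site``.

    The target position is the configured angle from oriC; the nearest
    intergenic region able to hold the site is chosen and the site
    centered in it.  Returns the new genome and the truth record.
    """
    site = site.upper()
    if genome.oric is None:
        raise ValueError("plant_site requires oriC")
    L = genome.length
    target = geometry.angle_to_position(angle, genome.oric, L)
    regions = [
        r for r in intergenic_regions(genome, min_length=len(site))
    ]
    if not regions:
        raise ValueError("no intergenic region can hold the site")

    def circ_dist(r: IntergenicRegion) -> int:
        mid = (r.start + r.end) // 2 % L
        d = abs(mid - target)
        return min(d, L - d)

    region = min(regions, key=circ_dist)
    start = (region.start + (region.end - region.start - len(site)) // 2) % L
    seq = list(genome.sequence)
    for i, ch in enumerate(site):
        seq[(start + i) % L] = ch
    new = Genome(id=genome.id, sequence="".join(seq), features=list(genome.features),
                 oric=genome.oric, circular=genome.circular)
    return new, PlantedSite(start=start, end=start + len(site), arm_len=arm_len,
                            spacer_len=spacer_len, sequence=site)


def plant_polarized_word(
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Genome, dict]:
    """Plant strand-polarized occurrences of ``config.asps_word``.

    Forward-strand copies are placed at ``asps_rate_leading``/kb between
    oriC and the terminus and at ``asps_rate_lagging``/kb on the other
    replichore; reverse-complement copies get the mirrored rates, so the
    word's polarity inverts exactly at the terminus.  Placements are
    Poisson; overlapping draws are dropped.  Returns the genome plus a
    truth dict with the placement positions and the terminus.
    """
    word = config.asps_word.upper()
    if word == revcomp(word):
        raise ValueError("polarized word must be non-palindromic")
    k = len(word)
    for rate in (config.asps_rate_leading, config.asps_rate_lagging):
        if rate * k / 1000.0 > 1.0:
            raise ValueError(f"rate {rate}/kb saturates the sequence for a {k}-mer")
    if genome.oric is None:
        raise ValueError("plant_polarized_word requires oriC")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    L = genome.length
    oric = genome.oric
    ter = geometry.angle_to_position(config.ter_angle, oric, L)
    len_lead = (ter - oric) % L
    len_lag = L - len_lead
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    wcodes = np.frombuffer(word.encode(), dtype=np.uint8)
    rcodes = np.frombuffer(revcomp(word).encode(), dtype=np.uint8)
    placements: dict[str, list[int]] = {"fwd": [], "rev": []}

    def place(n: int, seg_start: int, seg_len: int, codes: np.ndarray, key: str):
        if n <= 0 or seg_len < k:
            return
        offs = np.sort(rng.integers(0, seg_len - k + 1, size=n))
        keep = np.concatenate([[True], np.diff(offs) >= k])  # drop overlaps
        for off in offs[keep]:
            pos = (seg_start + int(off)) % L
            idx = (pos + np.arange(k)) % L
            seq[idx] = codes
            placements[key].append(pos)

    zero_rates = config.asps_rate_leading == 0 and config.asps_rate_lagging == 0
    if not zero_rates:
        n_ll = rng.poisson(config.asps_rate_leading * len_lead / 1000.0)
        n_lg = rng.poisson(config.asps_rate_lagging * len_lag / 1000.0)
        n_rl = rng.poisson(config.asps_rate_lagging * len_lead / 1000.0)
        n_rg = rng.poisson(config.asps_rate_leading * len_lag / 1000.0)
        place(n_ll, oric, len_lead, wcodes, "fwd")  # word fwd on leading replichore
        place(n_lg, ter, len_lag, wcodes, "fwd")  # word fwd background on other arm
        place(n_rl, oric, len_lead, rcodes, "rev")
        place(n_rg, ter, len_lag, rcodes, "rev")
    new = Genome(id=genome.id, sequence=seq.tobytes().decode(), features=list(genome.features),
                 oric=oric, circular=genome.circular)
    # a later placement can overwrite part of an earlier one; the truth
    # record keeps only positions that still carry their word
    fwd = [p for p in sorted(placements["fwd"]) if new.fetch(p, p + k) == word]
    rev = [p for p in sorted(placements["rev"]) if new.fetch(p, p + k) == revcomp(word)]
    truth = {"word": word, "ter": ter, "ter_angle": config.ter_angle,
             "fwd": fwd, "rev": rev}
    return new, truth


# ---------------------------------------------------------------------------
# divergence


def _mutate_background(codes: np.ndarray, rate: float, rng: np.random.Generator,
                       protect_mask: np.ndarray) -> None:
    """In-place uniform base exchange outside protected positions."""
    hit = (rng.random(codes.size) < rate) & ~protect_mask
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return
    shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
    codes[idx] = (codes[idx] + shift) % 4


def _mutate_site_compensatory(
    codes: np.ndarray,
    site: PlantedSite,
    rate: float,
    rng: np.random.Generator,
    L: int,
) -> None:
    """Palindrome-preserving substitutions inside a planted site.

    Arm positions mutate as complementary pairs (position j of arm1 with
    position j' = total-1-j of arm2, both replaced so the pair stays
    matched); spacer positions mutate freely.  Pairs that are mismatched
    in the planted site are left untouched, so the site's mismatch count
    is invariant.
    """
    a, s = site.arm_len, site.spacer_len
    total = 2 * a + s
    for j in range(a):
        p1 = (site.start + j) % L
        p2 = (site.start + total - 1 - j) % L
        if codes[p1] != 3 - codes[p2]:
            continue  # planted mismatch pair: keep the imperfection as is
        if rng.random() < rate:
            new = (codes[p1] + rng.integers(1, 4)) % 4
            codes[p1] = new
            codes[p2] = 3 - new
    for j in range(a, a + s):
        p = (site.start + j) % L
        if rng.random() < rate:
            codes[p] = (codes[p] + rng.integers(1, 4)) % 4


def diverge_set(
    genome: Genome,
    n: int,
    divergence: float,
    protect: Sequence[PlantedSite] = (),
    seed: int = 0,
    protected_rate: float = 0.05,
) -> list[Genome]:
    """``n`` copies of a genome under i.i.d. substitution divergence.

    Background positions mutate at ``divergence`` per site per copy;
    protected intervals mutate at the (lower) ``protected_rate`` with
    compensatory arm substitutions, so the planted inverted repeat keeps
    its structure while drifting in sequence (expected pairwise identity
    of the protected site is about ``1 - 2 * protected_rate``).
    """
    if n < 2:
        raise ValueError("diverge_set requires n >= 2")
    L = genome.length
    base = encode(genome.sequence)
    protect_mask = np.zeros(L, dtype=bool)
    for site in protect:
        idx = (site.start + np.arange(site.end - site.start)) % L
        protect_mask[idx] = True
    out = []
    rng = np.random.default_rng(seed)
    for i in range(n):
        codes = base.copy()
        _mutate_background(codes, divergence, rng, protect_mask)
        for site in protect:
            _mutate_site_compensatory(codes, site, protected_rate, rng, L)
        out.append(
            Genome(id=f"{genome.id}_copy{i}", sequence=decode(codes),
                   features=list(genome.features), oric=genome.oric,
                   circular=genome.circular)
        )
    return out


# ---------------------------------------------------------------------------
# study-condition builders


def _matched_arm_pairs(master: str, arm_len: int, spacer_len: int) -> list[int]:
    codes = encode(master)
    total = 2 * arm_len + spacer_len
    return [j for j in range(arm_len) if codes[j] == 3 - codes[total - 1 - j]]


def _site_variant(master: str, arm_len: int, spacer_len: int, pair_pos: int,
                  rng: np.random.Generator) -> str:
    """One compensatory substitution at matched arm pair ``pair_pos``."""
    codes = encode(master)
    total = 2 * arm_len + spacer_len
    new = (codes[pair_pos] + rng.integers(1, 4)) % 4
    codes[pair_pos] = new
    codes[total - 1 - pair_pos] = 3 - new
    return decode(codes)


def conserved_quartet(
    config: SimConfig,
) -> tuple[dict[str, Genome], dict[str, PlantedSite]]:
    """Independent genomes sharing a conserved planted site.

    Each of ``n_genomes`` genomes gets an independent random background
    (modelling extensively rearranged chromosomes, where decoy candidates
    across genomes are unrelated) and a controlled-divergence variant of
    the master site: genome 0 carries the master, every other genome one
    compensatory arm-pair substitution at a distinct arm position.
    Pairwise site identities are then 24/28-26/28 (0.857-0.93) for the
    default 28-bp site, and every variant keeps the master's arm-mismatch
    count, so the site survives the inverted-repeat search in all genomes.
    """
    rng = np.random.default_rng(config.seed)
    genomes: dict[str, Genome] = {}
    truths: dict[str, PlantedSite] = {}
    # distinct matched arm pairs for the variants
    matched = _matched_arm_pairs(config.planted_site.upper(), config.site_arm_len,
                                 config.site_spacer_len)
    if config.n_genomes - 1 > len(matched):
        raise ValueError("not enough matched arm pairs for distinct variants")
    pair_order = rng.permutation(len(matched))
    for i in range(config.n_genomes):
        sub = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        gid = f"sim{i}"
        g = random_genome(sub, genome_id=gid)
        site = config.planted_site.upper()
        if i > 0:
            site = _site_variant(site, config.site_arm_len, config.site_spacer_len,
                                 matched[int(pair_order[i - 1])], rng)
        angle = config.site_angle + float(rng.uniform(-8, 8))  # real sites scatter 120-142
        g, truth = plant_site(g, site, angle, config.site_arm_len, config.site_spacer_len)
        genomes[gid] = g
        truths[gid] = truth
    return genomes, truths


def polarized_genome(config: SimConfig) -> tuple[Genome, dict]:
    """One genome with the polarized-word signal planted (no site)."""
    g = random_genome(config, genome_id="sim_asps")
    return plant_polarized_word(g, config)


def write_simulated(
    genomes: dict[str, Genome],
    truths: dict,
    outdir: str | Path,
) -> None:
    """Emit FASTA + GFF3 + truth JSON per genome."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, g in genomes.items():
        write_genome(g, outdir / f"{gid}.fasta", outdir / f"{gid}.gff3")
        truth = truths.get(gid)
        if truth is not None:
            if dataclasses.is_dataclass(truth) and not isinstance(truth, type):
                truth = dataclasses.asdict(truth)
            with open(outdir / f"{gid}.truth.json", "w") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
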