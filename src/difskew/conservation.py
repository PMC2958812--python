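"""Cross-genome conservation filtering and IUPAC consensus.

Candidate recombinase sites found independently in several genomes are
matched across genomes by ungapped positional identity (best of the two
orientations of one partner, since a quasi-palindromic site may be
reported on either strand).  A conserved group holds exactly one candidate
per genome, all pairwise similarities at or above the threshold (default
0.80).  Only candidates with identical (arm_len, spacer_len) geometry are
compared, so all members share one alignment length and no gaps are ever
needed.

Grouping is greedy by descending minimum pairwise similarity with a
one-to-one constraint (each candidate joins at most one group), which
makes the output deterministic under permutation of genome and candidate
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ir_search import IRCandidate, encode, revcomp

__all__ = [
    "ConservedGroup",
    "Consensus",
    "site_similarity",
    "conserved_groups",
    "consensus_iupac",
    "at_fraction",
]

# minimal IUPAC degenerate symbol covering a set of observed bases
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def site_similarity(a: str, b: str) -> float:
    """Ungapped positional identity of two equal-length sites, maximized
    over the two orientations of ``b``; symmetric, in [0, 1]."""
    if len(a) != len(b):
        raise ValueError(f"cannot compare sites of lengths {len(a)} and {len(b)}")
    if not a:
        raise ValueError("cannot compare empty sites")
    fwd = sum(x == y for x, y in zip(a, b))
    rev = sum(x == y for x, y in zip(a, revcomp(b)))
    return max(fwd, rev) / len(a)


@dataclass(frozen=True)
class ConservedGroup:
    """One candidate per genome, all pairwise similarities >= threshold."""

    members: tuple[IRCandidate, ...]  # ordered by sorted genome id
    pairwise_similarity: tuple[tuple[float, ...], ...]
    min_similarity: float

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(m.genome_id for m in self.members)

    @property
    def geometry(self) -> tuple[int, int]:
        return (self.members[0].arm_len, self.members[0].spacer_len)


@dataclass(frozen=True)
class Consensus:
    """Per-column base counts, minimal-IUPAC string and information content."""

    columns: tuple[dict, ...]
    iupac: str
    info_content: tuple[float, ...]  # bits per column, uniform background


def consensus_iupac(aligned: Sequence[str]) -> Consensus:
    """Column-wise minimal IUPAC consensus plus Shannon information content.

    Information content per column is ``2 - H(observed base frequencies)``
    bits, the quantity plotted as letter height in a sequence logo (uniform
    background, no small-sample correction).
    """
    seqs = [s.upper() for s in aligned]
    if len(seqs) < 2:
        raise ValueError("consensus requires at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted({len(s) for s in seqs})}")
    width = len(seqs[0])
    columns, codes, info = [], [], []
    for j in range(width):
        col = [s[j] for s in seqs]
        counts = {b: col.count(b) for b in "ACGT" if col.count(b)}
        observed = frozenset(counts)
        if not observed <= set("ACGT"):
            raise ValueError(f"non-ACGT base in alignment column {j}")
        columns.append(counts)
        codes.append(_IUPAC[observed])
        freqs = np.array(list(counts.values()), dtype=float)
        freqs /= freqs.sum()
        h = float(-(freqs * np.log2(freqs)).sum())
        info.append(2.0 - h)
    return Consensus(columns=tuple(columns), iupac="".join(codes), info_content=tuple(info))


def at_fraction(seq: str) -> float:
    """A+T fraction of a sequence (descriptive flank statistic)."""
    if not seq:
        return float("nan")
    return (seq.count("A") + seq.count("T")) / len(seq)


# ---------------------------------------------------------------------------
# cross-genome grouping


def _one_hot(sites: Sequence[str]) -> np.ndarray:
    """(n, width*4) float32 one-hot; N rows contribute no matches."""
    arr = np.stack([encode(s) for s in sites])
    n, w = arr.shape
    oh = np.zeros((n, w, 4), dtype=np.float32)
    mask = arr < 4
    idx = np.nonzero(mask)
    oh[idx[0], idx[1], arr[mask]] = 1.0
    return oh.reshape(n, w * 4)


def _similarity_matrix(sites_a: Sequence[str], sites_b: Sequence[str], width: int) -> np.ndarray:
    """Pairwise orientation-maximized identity between two site lists."""
    a = _one_hot(sites_a)
    b_f = _one_hot(sites_b)
    b_r = _one_hot([revcomp(s) for s in sites_b])
    sim = np.maximum(a @ b_f.T, a @ b_r.T) / width
    return sim


def conserved_groups(
    candidates_by_genome: Mapping[str, Sequence[IRCandidate]],
    threshold: float = 0.80,
) -> list[ConservedGroup]:
    """Groups of candidates conserved across *all* genomes.

    A group is emitted when one candidate per genome exists with every
    pairwise similarity >= ``threshold``.  Candidates are consumed greedily
    by descending group ``min_similarity`` (one-to-one matching).  Returns
    groups sorted by descending ``min_similarity``.
    """
    if len(candidates_by_genome) < 2:
        raise ValueError("conservation filtering requires at least two genomes")
    genome_ids = sorted(candidates_by_genome)
    n_genomes = len(genome_ids)

    # bucket candidates by identical (arm_len, spacer_len) geometry
    geometries: set[tuple[int, int]] = set()
    by_geom: dict[tuple[int, int], dict[str, list[IRCandidate]]] = {}
    for gid in genome_ids:
        for c in candidates_by_genome[gid]:
            key = (c.arm_len, c.spacer_len)
            by_geom.setdefault(key, {g: [] for g in genome_ids})[gid].append(c)
            geometries.add(key)

    proto_groups: list[tuple[float, tuple[tuple[float, ...], ...], tuple[IRCandidate, ...]]] = []
    for key in sorted(geometries):
        bucket = by_geom[key]
        if any(not bucket[g] for g in genome_ids):
            continue
        cands = {g: sorted(bucket[g], key=lambda c: (c.start, c.arm_len, c.spacer_len)) for g in genome_ids}
        width = 2 * key[0] + key[1]
        sims: dict[tuple[str, str], np.ndarray] = {}
        for ga, gb in itertools.combinations(genome_ids, 2):
            sims[(ga, gb)] = _similarity_matrix(
                [c.canonical_seq for c in cands[ga]],
                [c.canonical_seq for c in cands[gb]],
                width,
            )
        # sparse adjacency above threshold; join genome by genome
        partial: list[tuple[int, ...]] = [(i,) for i in range(len(cands[genome_ids[0]]))]
        for gi in range(1, n_genomes):
            nxt: list[tuple[int, ...]] = []
            gb = genome_ids[gi]
            for tup in partial:
                ok = None
                for gj, idx in enumerate(tup):
                    ga = genome_ids[gj]
                    row = sims[(ga, gb)][idx] >= threshold
                    ok = row if ok is None else (ok & row)
                    if not ok.any():
                        break
                else:
                    nxt.extend(tup + (j,) for j in np.flatnonzero(ok))
            partial = nxt
            if not partial:
                break
        for tup in partial:
            members = tuple(cands[genome_ids[g]][tup[g]] for g in range(n_genomes))
            mat = [[1.0] * n_genomes for _ in range(n_genomes)]
            for (gi, gj) in itertools.combinations(range(n_genomes), 2):
                s = float(sims[(genome_ids[gi], genome_ids[gj])][tup[gi], tup[gj]])
                mat[gi][gj] = mat[gj][gi] = s
            min_sim = min(
                mat[i][j] for i, j in itertools.combinations(range(n_genomes), 2)
            )
            proto_groups.append((min_sim, tuple(tuple(r) for r in mat), members))

    # greedy one-to-one assignment, deterministic ordering
    proto_groups.sort(
        key=lambda g: (-g[0], [(m.genome_id, m.start, m.arm_len, m.spacer_len) for m in g[2]])
    )
    used: set[tuple[str, int, int, int]] = set()
    groups: list[ConservedGroup] = []
    for min_sim, mat, members in proto_groups:
        keys = [(m.genome_id, m.start, m.arm_len, m.spacer_len) for m in members]
        if any(k in used for k in keys):
            continue
        used.update(keys)
        groups.append(
            ConservedGroup(members=members, pairwise_similarity=mat, min_similarity=min_sim)
        )
    return groups
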