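"""Positional log-odds profile scanning with an empirical shuffled null.

A fixed-width, ungapped alignment of predicted sites is turned into a
position weight matrix: column probabilities are pseudocount-smoothed
observed frequencies, scores are log2 odds against a background base
composition.  Genomes are scanned on both strands over the full circle.

"Statistically significant" is defined operationally: the score threshold
is a (1 - alpha) quantile of the per-shuffle maximum score over
dinucleotide-preserving shuffles of the target genome (Altschul-Erickson
Euler-path shuffling), which preserves the AT-richness and nearest-
neighbour structure that dominate intergenic DNA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from .genome_io import Genome
from .ir_search import encode, decode

__all__ = [
    "ProfileModel",
    "ProfileHit",
    "build_profile",
    "scan_genome",
    "calibrate_threshold",
    "dinucleotide_shuffle",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class ProfileModel:
    """Log-odds (base 2) positional profile over {A, C, G, T}."""

    matrix: np.ndarray  # (width, 4) log-odds
    probs: np.ndarray  # (width, 4) column probabilities, rows sum to 1
    background: np.ndarray  # (4,) base frequencies
    pseudocount: float
    score_threshold: float = -np.inf

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def consensus(self) -> str:
        return decode(self.matrix.argmax(axis=1).astype(np.uint8))

    def score(self, seq: str) -> float:
        """Additive log-odds score of one width-length window."""
        codes = encode(seq)
        if codes.size != self.width:
            raise ValueError(f"window length {codes.size} != profile width {self.width}")
        if (codes >= 4).any():
            return -np.inf
        return float(self.matrix[np.arange(self.width), codes].sum())

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"# difskew profile width={self.width} pseudocount={self.pseudocount}\n")
        buf.write("# background " + " ".join(f"{b:.6f}" for b in self.background) + "\n")
        buf.write(f"# score_threshold {self.score_threshold:.6f}\n")
        buf.write("pos\t" + "\t".join(_BASES) + "\n")
        for i, row in enumerate(self.matrix):
            buf.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "ProfileModel":
        lines = text.strip().splitlines()
        meta = dict(width=None, pseudocount=1.0)
        background = None
        threshold = -np.inf
        rows = []
        for line in lines:
            if line.startswith("# difskew profile"):
                for tok in line.split()[3:]:
                    k, v = tok.split("=")
                    meta[k] = float(v)
            elif line.startswith("# background"):
                background = np.array([float(x) for x in line.split()[2:]])
            elif line.startswith("# score_threshold"):
                threshold = float(line.split()[2])
            elif line.startswith(("#", "pos")):
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
        matrix = np.array(rows)
        probs = background * np.power(2.0, matrix)
        probs /= probs.sum(axis=1, keepdims=True)
        return cls(matrix=matrix, probs=probs, background=background,
                   pseudocount=float(meta["pseudocount"]), score_threshold=threshold)


@dataclass(frozen=True)
class ProfileHit:
    genome_id: str
    start: int
    strand: str
    score: float
    width: int
    empirical_p: float = float("nan")

    @property
    def end(self) -> int:
        return self.start + self.width


def build_profile(
    aligned: Sequence[str],
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> ProfileModel:
    """PWM from an ungapped alignment.

    Column probabilities are ``(count + pseudocount * background) /
    (n + pseudocount)``; scores are log2(p / background).
    """
    if len(aligned) < 2:
        raise ValueError("profile requires at least two aligned sequences")
    if len({len(s) for s in aligned}) != 1:
        raise ValueError("ragged alignment")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("background frequencies must all be positive")
    arr = np.stack([encode(s.upper()) for s in aligned])
    if (arr >= 4).any():
        raise ValueError("alignment may not contain N")
    n, width = arr.shape
    counts = np.zeros((width, 4))
    for b in range(4):
        counts[:, b] = (arr == b).sum(axis=0)
    probs = (counts + pseudocount * bg) / (n + pseudocount)
    matrix = np.log2(probs / bg)
    return ProfileModel(matrix=matrix, probs=probs, background=bg, pseudocount=pseudocount)


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Scores of every window; windows containing N score -inf."""
    w = matrix.shape[0]
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    has_n = np.zeros(n, dtype=bool)
    for j in range(w):
        col = codes[j : j + n]
        ok = col < 4
        has_n |= ~ok
        scores += np.where(ok, matrix[j][np.minimum(col, 3)], 0.0)
    scores[has_n] = -np.inf
    return scores


def _rc_matrix(matrix: np.ndarray) -> np.ndarray:
    return matrix[::-1, ::-1]


def scan_genome(
    genome: Genome,
    profile: ProfileModel,
    threshold: float | None = None,
) -> list[ProfileHit]:
    """All hits with score >= threshold on both strands of the circle.

    Wraparound windows are included once; a reverse-strand hit's ``start``
    is the smallest genome coordinate of the matched window.  Hits are
    sorted by descending score (ties by start, then strand).
    """
    w = profile.width
    if w > genome.length:
        raise ValueError("profile wider than genome")
    thr = profile.score_threshold if threshold is None else threshold
    ext = genome.sequence + genome.sequence[: w - 1] if genome.circular else genome.sequence
    codes = encode(ext)
    hits: list[ProfileHit] = []
    for strand, mat in (("+", profile.matrix), ("-", _rc_matrix(profile.matrix))):
        scores = _window_scores(codes, mat)
        for i in np.flatnonzero(scores >= thr):
            hits.append(
                ProfileHit(genome_id=genome.id, start=int(i), strand=strand,
                           score=float(scores[i]), width=w)
            )
    hits.sort(key=lambda h: (-h.score, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Altschul-Erickson)


@njit(cache=False)
def _euler_walk(edge_targets, edge_offsets, first, n):  # pragma: no cover - jitted
    out = np.empty(n, dtype=np.uint8)
    out[0] = first
    ptr = edge_offsets[:4].copy()
    v = first
    for i in range(1, n):
        w = edge_targets[ptr[v]]
        ptr[v] += 1
        out[i] = w
        v = w
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Random sequence with exactly the dinucleotide (and hence mononucleotide)
    counts of ``seq``, via a uniform random Euler path on the dinucleotide
    multigraph.

    Sequences containing N are shuffled per N-free segment so that N
    positions stay fixed.
    """
    if "N" in seq:
        parts = []
        cur = []
        for ch in seq:
            if ch == "N":
                if cur:
                    parts.append(dinucleotide_shuffle("".join(cur), rng))
                    cur = []
                parts.append("N")
            else:
                cur.append(ch)
        if cur:
            parts.append(dinucleotide_shuffle("".join(cur), rng))
        return "".join(parts)
    n = len(seq)
    if n <= 2:
        return seq
    codes = encode(seq)
    first, last = int(codes[0]), int(codes[-1])
    # outgoing edge target lists per vertex
    targets = [np.flatnonzero(codes[:-1] == v) + 1 for v in range(4)]  # positions of successors
    edge_lists = [codes[t] for t in targets]
    counts = [e.size for e in edge_lists]

    present = [v for v in range(4) if counts[v] > 0 or v == last]
    # choose per-vertex last edges forming an arborescence into `last`
    for _attempt in range(1000):
        last_edge = {}
        for v in present:
            if v == last or counts[v] == 0:
                continue
            last_edge[v] = int(edge_lists[v][rng.integers(counts[v])])
        # check every vertex reaches `last` via chosen last edges
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last:
                if u in seen or u not in last_edge:
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample an Euler-path spanning tree")

    # permute each vertex's edges, forcing the chosen last edge to the end
    shuffled: list[np.ndarray] = []
    for v in range(4):
        edges = edge_lists[v].copy()
        if edges.size:
            perm = rng.permutation(edges.size)
            edges = edges[perm]
            if v in last_edge:
                pos = int(np.nonzero(edges == last_edge[v])[0][0])
                edges[pos], edges[-1] = edges[-1], edges[pos]
        shuffled.append(edges.astype(np.uint8))

    edge_targets = np.concatenate([s for s in shuffled]) if shuffled else np.empty(0, np.uint8)
    edge_offsets = np.zeros(5, dtype=np.int64)
    for v in range(4):
        edge_offsets[v + 1] = edge_offsets[v] + shuffled[v].size
    out = _euler_walk(edge_targets, edge_offsets, first, n)
    return decode(out)


def calibrate_threshold(
    profile: ProfileModel,
    genome: Genome,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical significance threshold for :func:`scan_genome`.

    The (1 - alpha) quantile of the per-shuffle maximum window score over
    ``n_shuffles`` dinucleotide-preserving shuffles of the genome (both
    strands, circular).  ``alpha = 0`` gives the most stringent threshold,
    the maximum over all shuffles.  Deterministic given ``seed``.
    """
    if n_shuffles < 100:
        raise ValueError("calibration requires n_shuffles >= 100")
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    w = profile.width
    maxima = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = dinucleotide_shuffle(genome.sequence, rng)
        ext = shuf + shuf[: w - 1] if genome.circular else shuf
        codes = encode(ext)
        best = -np.inf
        for mat in (profile.matrix, _rc_matrix(profile.matrix)):
            s = _window_scores(codes, mat)
            if s.size:
                best = max(best, float(s.max()))
        maxima[i] = best
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def with_threshold(profile: ProfileModel, threshold: float) -> ProfileModel:
    return replace(profile, score_threshold=threshold)
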