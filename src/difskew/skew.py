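"""Replication-strand word skew: over-represented polarized short sequences.

In many circular prokaryotic genomes, short motifs (the 8-bp KOPS of
*E. coli*; 4-8 nt analogues elsewhere) are over-represented on the leading
strand of replication, with their polarity inverting at the replication
terminus / dif locus.  Because the terminus is often not known precisely,
candidate termini are placed on an angular grid (default every 5 degrees
from 120 to 200 degrees from oriC) and the genome is transformed to a
"leading-strand view" for each: the terminus-to-origin replichore is
reverse complemented so both replichores read in the direction of fork
movement.

Word exceptionality on the transformed sequence uses the maximal-order
Markov model (order k-2): the expected count of word ``w`` is
``N(w[:-1]) * N(w[1:]) / N(w[1:-1])`` and the Gaussian z-score uses the
variance ``E * (1 - N(w[:-1])/N(w[1:-1])) * (1 - N(w[1:])/N(w[1:-1]))``.
Under this model the z-scores of non-exceptional words are asymptotically
standard normal.  No compound-Poisson correction for self-overlapping
words is applied; such words are flagged.

Cumulative skew curves are running sums of (+1 per forward-strand
occurrence, -1 per reverse-complement occurrence) walking the circle once
from oriC; the summit of the curve estimates the polarity inversion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import geometry
from .genome_io import Genome
from .ir_search import encode, revcomp

__all__ = [
    "RotationGrid",
    "WordStats",
    "SkewCurve",
    "leading_strand_view",
    "word_zscore",
    "rank_asps",
    "cumulative_skew",
    "summit",
]


@dataclass(frozen=True)
class RotationGrid:
    """Angular grid of artificial replication termini (degrees from oriC)."""

    start_angle: float = 120.0
    end_angle: float = 200.0
    step: float = 5.0

    def __post_init__(self):
        if not self.start_angle < self.end_angle:
            raise ValueError("need start_angle < end_angle")
        n = (self.end_angle - self.start_angle) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide end_angle - start_angle")

    @property
    def angles(self) -> np.ndarray:
        n = int(round((self.end_angle - self.start_angle) / self.step))
        return self.start_angle + self.step * np.arange(n + 1)


@dataclass(frozen=True)
class WordStats:
    """Counts and exceptionality of one word on a leading-strand view."""

    word: str
    fwd_count: int
    rev_count: int
    expected: float
    zscore: float
    self_overlapping: bool = False

    @property
    def strand_skew(self) -> float:
        tot = self.fwd_count + self.rev_count
        return (self.fwd_count - self.rev_count) / tot if tot else 0.0


@dataclass
class SkewCurve:
    """Binned cumulative occurrence-difference curve starting at oriC."""

    word: str
    positions: np.ndarray  # offsets from oriC (bp), end of each bin
    values: np.ndarray  # cumulative fwd - rev occurrences
    bin: int
    oric: int
    genome_length: int


def _circular_segment(seq: str, a: int, b: int) -> str:
    """seq[a:b] on the circle (b may be < a, meaning wrap)."""
    L = len(seq)
    a %= L
    b %= L
    if b > a:
        return seq[a:b]
    return seq[a:] + seq[:b]


def leading_strand_view(genome: Genome | str, oric: int, ter: int) -> str:
    """Genome read in the direction of replication on both replichores.

    Concatenates the oriC->ter segment as given with the reverse complement
    of the ter->oriC segment; output length equals the genome length.
    """
    seq = genome.sequence if isinstance(genome, Genome) else genome
    L = len(seq)
    if oric % L == ter % L:
        raise ValueError("oriC and terminus must differ")
    return _circular_segment(seq, oric, ter) + revcomp(_circular_segment(seq, ter, oric))


def _self_overlapping(word: str) -> bool:
    return any(word[:-p] == word[p:] for p in range(1, len(word)))


def count_word(sequence: str, word: str) -> int:
    """Overlapping occurrence count of ``word`` in ``sequence``."""
    codes = encode(sequence)
    w = encode(word)
    k = w.size
    n = codes.size - k + 1
    if n <= 0:
        return 0
    hit = np.ones(n, dtype=bool)
    for j in range(k):
        hit &= codes[j : j + n] == w[j]
    return int(hit.sum())


def word_zscore(sequence: str, word: str) -> WordStats:
    """Maximal-order Markov exceptionality of one word (overlap counting).

    ``expected`` and ``zscore`` describe the word in its given orientation
    on ``sequence``; ``rev_count`` is the count of the reverse complement
    on the same strand, so ``strand_skew`` measures strand polarization.
    """
    word = word.upper()
    k = len(word)
    if not 4 <= k <= 8:
        raise ValueError(f"word length must be 4..8, got {k}")
    if "N" in word:
        raise ValueError("word may not contain N")
    n_pre = count_word(sequence, word[:-1])
    n_suf = count_word(sequence, word[1:])
    n_mid = count_word(sequence, word[1:-1])
    if n_mid == 0:
        raise ValueError(f"middle word {word[1:-1]!r} absent from sequence")
    observed = count_word(sequence, word)
    expected = n_pre * n_suf / n_mid
    var = expected * (1.0 - n_pre / n_mid) * (1.0 - n_suf / n_mid)
    sd = np.sqrt(var) if var > 0 else np.nan
    z = (observed - expected) / sd if sd and np.isfinite(sd) else 0.0
    return WordStats(
        word=word,
        fwd_count=observed,
        rev_count=count_word(sequence, revcomp(word)),
        expected=float(expected),
        zscore=float(z),
        self_overlapping=_self_overlapping(word),
    )


# ---------------------------------------------------------------------------
# vectorized all-words machinery


def _kmer_index_arrays(codes: np.ndarray, kmax: int) -> dict[int, np.ndarray]:
    """Rolling k-mer integer indices for k = 1..kmax; N-windows get -1."""
    n = codes.size
    valid = codes < 4
    idx = {1: np.where(valid, codes.astype(np.int64), -1)}
    ok = valid.copy()
    for k in range(2, kmax + 1):
        m = n - k + 1
        prev = idx[k - 1][:m]
        ok = ok[:m] & valid[k - 1 : k - 1 + m]
        nxt = prev * 4 + codes[k - 1 : k - 1 + m]
        idx[k] = np.where(ok & (prev >= 0), nxt, -1)
    return idx


def _kmer_counts(codes: np.ndarray, kmax: int) -> dict[int, np.ndarray]:
    """Counts of every k-mer for k = 1..kmax (linear sequence, overlaps)."""
    idx = _kmer_index_arrays(codes, kmax)
    out = {}
    for k, arr in idx.items():
        good = arr[arr >= 0]
        out[k] = np.bincount(good, minlength=4**k).astype(np.int64)
    return out


def _revcomp_index(k: int) -> np.ndarray:
    """Permutation mapping each k-mer index to its reverse complement's."""
    idx = np.arange(4**k)
    rc = np.zeros_like(idx)
    x = idx.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (x % 4))
        x //= 4
    return rc


def _all_word_zscores(counts_k: np.ndarray, counts_km1: np.ndarray, counts_km2: np.ndarray, k: int):
    """Vectorized maximal-order z-scores for all 4^k words."""
    words = np.arange(4**k)
    pre = words // 4
    suf = words % (4 ** (k - 1))
    mid = suf // 4
    a = counts_km1[pre].astype(float)
    b = counts_km1[suf].astype(float)
    c = counts_km2[mid].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = a * b / c
        var = expected * (1.0 - a / c) * (1.0 - b / c)
        z = np.where(var > 0, (counts_k - expected) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    z = np.where(np.isfinite(z), z, 0.0)
    return expected, z


def _decode_word(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass(frozen=True)
class RankedWord:
    """Aggregate over terminus rotations for one word (reported orientation)."""

    word: str
    k: int
    median_z: float
    median_skew: float  # (fwd - rev) / (fwd + rev), for reporting
    median_skew_z: float  # (fwd - rev) / sqrt(fwd + rev), used in the score
    score: float
    fwd_count: int  # at the central rotation
    rev_count: int
    expected: float
    self_overlapping: bool


def default_asps_score(median_z: float, median_skew_z: float, sign_consistent: bool) -> float:
    """Composite ranking: median over-representation z times median
    standardized strand skew, zero unless the skew sign is
    rotation-consistent.

    The skew factor is the binomial standardization
    ``(fwd - rev) / sqrt(fwd + rev)`` rather than the raw skew fraction:
    a rare word seen 15 times with 80% skew is far weaker evidence of
    polarization than an abundant word seen 5000 times with 20% skew,
    and standardizing puts words of every length on one scale (raw
    counts of 4-mers and 8-mers differ by orders of magnitude).
    """
    if not sign_consistent or median_skew_z <= 0:
        return 0.0
    return median_z * median_skew_z


def rank_asps(
    genome: Genome,
    oric: int | None = None,
    k_range: Iterable[int] = range(4, 9),
    grid: RotationGrid = RotationGrid(),
    scoring: Callable[[float, float, bool], float] = default_asps_score,
) -> list[RankedWord]:
    """Rank words by over-representation and leading-strand polarization.

    For each artificial terminus on the angular grid, the genome is
    transformed to its leading-strand view and every word of every k gets
    a maximal-order Markov z-score and a strand skew.  Words are ranked by
    ``scoring(median_z, median_skew, sign_consistent)``; each
    reverse-complement pair is reported once, in its over-represented
    (positive-skew) orientation.  Palindromic words have zero skew by
    definition and are excluded.
    """
    oric = genome.oric if oric is None else oric
    if oric is None:
        raise ValueError("rank_asps requires oriC")
    L = genome.length
    ks = sorted(k_range)
    if ks[0] < 4 or ks[-1] > 8:
        raise ValueError("k_range must lie within 4..8")
    kmax = ks[-1]
    angles = grid.angles
    z_rot = {k: np.empty((angles.size, 4**k)) for k in ks}
    skew_rot = {k: np.empty((angles.size, 4**k)) for k in ks}
    skew_z_rot = {k: np.empty((angles.size, 4**k)) for k in ks}
    counts_central: dict[int, np.ndarray] = {}
    expected_central: dict[int, np.ndarray] = {}
    central = angles.size // 2
    rc_idx = {k: _revcomp_index(k) for k in ks}
    for ai, angle in enumerate(angles):
        ter = geometry.angle_to_position(float(angle), oric, L)
        view = leading_strand_view(genome, oric, ter)
        codes = encode(view)
        counts = _kmer_counts(codes, kmax)
        for k in ks:
            expected, z = _all_word_zscores(counts[k], counts[k - 1], counts[k - 2], k)
            z_rot[k][ai] = z
            fwd = counts[k].astype(float)
            rev = fwd[rc_idx[k]]
            tot = fwd + rev
            with np.errstate(invalid="ignore"):
                skew_rot[k][ai] = np.where(tot > 0, (fwd - rev) / np.maximum(tot, 1), 0.0)
                skew_z_rot[k][ai] = np.where(
                    tot > 0, (fwd - rev) / np.sqrt(np.maximum(tot, 1)), 0.0)
            if ai == central:
                counts_central[k] = counts[k]
                expected_central[k] = expected
    ranked: list[RankedWord] = []
    for k in ks:
        med_z = np.median(z_rot[k], axis=0)
        med_skew = np.median(skew_rot[k], axis=0)
        med_skew_z = np.median(skew_z_rot[k], axis=0)
        consistent = (skew_rot[k] > 0).all(axis=0) | (skew_rot[k] < 0).all(axis=0)
        rc = rc_idx[k]
        words = np.arange(4**k)
        for w in words[words < rc]:  # one per revcomp pair; palindromes (w == rc) excluded
            # report the positively skewed orientation
            cand = w if med_skew[w] >= med_skew[rc[w]] else rc[w]
            score = scoring(float(med_z[cand]), float(med_skew_z[cand]), bool(consistent[w]))
            if score <= 0:
                continue
            word = _decode_word(int(cand), k)
            ranked.append(
                RankedWord(
                    word=word,
                    k=k,
                    median_z=float(med_z[cand]),
                    median_skew=float(med_skew[cand]),
                    median_skew_z=float(med_skew_z[cand]),
                    score=score,
                    fwd_count=int(counts_central[k][cand]),
                    rev_count=int(counts_central[k][rc[cand]]),
                    expected=float(expected_central[k][cand]),
                    self_overlapping=_self_overlapping(word),
                )
            )
    ranked.sort(key=lambda r: (-r.score, r.k, r.word))
    return ranked


# ---------------------------------------------------------------------------
# cumulative skew curves


def _occurrence_positions(codes: np.ndarray, word: str) -> np.ndarray:
    w = encode(word)
    k = w.size
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    hit = np.ones(n, dtype=bool)
    for j in range(k):
        hit &= codes[j : j + n] == w[j]
    return np.flatnonzero(hit)


def cumulative_skew(
    genome: Genome,
    word: str,
    oric: int | None = None,
    bin: int = 1000,
) -> SkewCurve:
    """Cumulative (forward - reverse-complement) occurrence curve from oriC.

    Walking the circle once starting at oriC, each forward-strand
    occurrence of ``word`` contributes +1 and each occurrence of its
    reverse complement -1; the running sum is reported at ``bin``
    resolution.  The final value equals total forward minus total reverse
    counts (occurrences are assigned to the bin of their start position;
    wraparound occurrences are counted once).
    """
    word = word.upper()
    if "N" in word:
        raise ValueError("word may not contain N")
    oric = genome.oric if oric is None else oric
    if oric is None:
        raise ValueError("cumulative_skew requires oriC")
    if bin < 1:
        raise ValueError("bin must be >= 1")
    L = genome.length
    k = len(word)
    # rotate so the walk starts at oriC; extend for wraparound occurrences
    rotated = genome.fetch(oric, oric + L)
    ext = rotated + rotated[: k - 1] if genome.circular else rotated
    codes = encode(ext)
    pos_f = _occurrence_positions(codes, word)
    pos_r = _occurrence_positions(codes, revcomp(word))
    pos_f = pos_f[pos_f < L]
    pos_r = pos_r[pos_r < L]
    nbins = (L + bin - 1) // bin
    delta = np.bincount(pos_f // bin, minlength=nbins).astype(np.int64)
    delta -= np.bincount(pos_r // bin, minlength=nbins)
    values = np.cumsum(delta)
    positions = np.minimum((np.arange(nbins) + 1) * bin, L)
    return SkewCurve(word=word, positions=positions, values=values, bin=bin,
                     oric=oric, genome_length=L)


def summit(curve: SkewCurve, length: int | None = None, oric: int | None = None) -> tuple[int, float]:
    """Global maximum of the skew curve as (genome position, angle from oriC).

    On a tie, the midpoint of the first maximal plateau (maximal run of
    bins attaining the global maximum) is returned.
    """
    values = np.asarray(curve.values)
    if values.size == 0:
        raise ValueError("empty skew curve")
    L = curve.genome_length if length is None else length
    oric = curve.oric if oric is None else oric
    vmax = values.max()
    at_max = np.flatnonzero(values == vmax)
    # first contiguous run of maxima
    run_end = at_max[0]
    for i in at_max[1:]:
        if i == run_end + 1:
            run_end = i
        else:
            break
    a = int(curve.positions[at_max[0]])
    b = int(curve.positions[run_end])
    offset = (a + b) // 2
    position = (oric + offset) % L
    return position, geometry.angle_from_origin(position, oric, L)
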