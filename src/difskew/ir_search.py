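"""Imperfect inverted-repeat (quasi-palindrome) enumeration.

Site-specific tyrosine recombinases such as Xer bind quasi-palindromic
sites: two arms of 11-15 bp that are approximate reverse complements of
each other, separated by a 4-10 bp spacer.  This module enumerates every
such candidate in a DNA region, scoring each by the number of positional
mismatches between arm1 and the reverse complement of arm2.

The enumeration is exhaustive over all (start, arm_len, spacer_len)
combinations and vectorized with numpy: for a fixed geometry the mismatch
count of every window is a sum of shifted base-comparison arrays, and the
count for arm length a+1 is obtained from the count for arm length a by
adding a single outer-pair comparison (the inner a pairs of the longer
window are exactly the pairs of the shorter window one position to the
right).  Windows containing N are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .genome_io import IntergenicRegion

__all__ = [
    "SearchParams",
    "IRCandidate",
    "revcomp",
    "arm_mismatches",
    "enumerate_ir_candidates",
    "best_site",
]

_COMP = str.maketrans("ACGTN", "TGCAN")

# base encoding: A=0, C=1, G=2, T=3, N=4 (complement of b<4 is 3-b)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGTN", (0, 1, 2, 3, 4)):
    _ENCODE[_b] = _c
_N_CODE = 4


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..4."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return bytes(np.frombuffer(b"ACGTN", dtype=np.uint8)[codes]).decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMP)[::-1]


def arm_mismatches(arm1: str, arm2: str) -> int:
    """Positional mismatches between ``arm1`` and ``revcomp(arm2)``.

    This is the imperfection count of the inverted repeat (arm1, arm2): a
    perfect palindromic site scores 0.
    """
    if len(arm1) != len(arm2):
        raise ValueError(f"arm lengths differ: {len(arm1)} vs {len(arm2)}")
    rc = revcomp(arm2)
    return sum(a != b for a, b in zip(arm1, rc))


@dataclass(frozen=True)
class SearchParams:
    """Geometry and tolerance of the inverted-repeat search.

    Defaults are the recombinase-site geometry: arms of 11-15 bp separated
    by a 4-10 bp spacer, with up to 3 mismatches tolerated between an arm
    and the reverse complement of its partner (~73% arm identity at the
    minimum arm length).
    """

    arm_min: int = 11
    arm_max: int = 15
    spacer_min: int = 4
    spacer_max: int = 10
    max_arm_mismatches: int = 3

    def __post_init__(self):
        if not (0 < self.arm_min <= self.arm_max):
            raise ValueError("need 0 < arm_min <= arm_max")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if not (0 <= self.max_arm_mismatches < self.arm_min):
            raise ValueError("need 0 <= max_arm_mismatches < arm_min")


@dataclass(frozen=True)
class IRCandidate:
    """One imperfect inverted repeat: arm1 + spacer + arm2."""

    genome_id: str
    start: int
    arm_len: int
    spacer_len: int
    arm1: str
    spacer: str
    arm2: str
    mismatches: int
    canonical_seq: str

    @property
    def sequence(self) -> str:
        return self.arm1 + self.spacer + self.arm2

    @property
    def total_len(self) -> int:
        return 2 * self.arm_len + self.spacer_len

    @property
    def end(self) -> int:
        return self.start + self.total_len


def _make_candidate(genome_id: str, start: int, arm: int, spacer: int, window: str) -> IRCandidate:
    arm1 = window[:arm]
    sp = window[arm : arm + spacer]
    arm2 = window[arm + spacer :]
    site = arm1 + sp + arm2
    return IRCandidate(
        genome_id=genome_id,
        start=start,
        arm_len=arm,
        spacer_len=spacer,
        arm1=arm1,
        spacer=sp,
        arm2=arm2,
        mismatches=arm_mismatches(arm1, arm2),
        canonical_seq=min(site, revcomp(site)),
    )


def _enumerate_codes(codes: np.ndarray, params: SearchParams):
    """Yield (start, arm_len, spacer_len) for every qualifying window.

    ``codes`` is a uint8 array over 0..4 (4 = N / excluded).  Runs in
    O(sum over geometries of n) using the arm-extension recursion.
    """
    n = codes.size
    p = params
    if n < 2 * p.arm_min + p.spacer_min:
        return
    comp = np.where(codes < 4, 3 - codes, np.uint8(255)).astype(np.uint8)  # N never matches
    is_n = codes == _N_CODE
    # windows containing N: prefix-sum test
    n_cum = np.concatenate([[0], np.cumsum(is_n)])

    results = []
    for spacer in range(p.spacer_min, p.spacer_max + 1):
        mism: Optional[np.ndarray] = None
        prev_nwin = 0
        for arm in range(p.arm_min, p.arm_max + 1):
            t = 2 * arm + spacer
            nwin = n - t + 1
            if nwin <= 0:
                break
            if mism is None:
                # base case: sum the arm comparison arrays directly
                m = np.zeros(nwin, dtype=np.int16)
                for j in range(arm):
                    # pair j: position i+j vs complement at i + t - 1 - j
                    m += codes[j : j + nwin] != comp[t - 1 - j : t - 1 - j + nwin]
            else:
                # extension: window (arm, spacer) at i equals inner pairs of
                # window (arm-1, spacer) at i+1, plus the new outer pair
                m = mism[1 : 1 + nwin].astype(np.int16, copy=True)
                m += codes[:nwin] != comp[t - 1 : t - 1 + nwin]
            mism = m
            valid = (m <= p.max_arm_mismatches) & (n_cum[t:] - n_cum[:nwin] == 0)
            for start in np.flatnonzero(valid):
                results.append((int(start), arm, spacer))
    results.sort()
    yield from results


def enumerate_ir_candidates(
    region: IntergenicRegion | str,
    params: SearchParams = SearchParams(),
    genome_id: str | None = None,
) -> list[IRCandidate]:
    """All imperfect inverted repeats in a region, sorted by
    (start, arm_len, spacer_len).

    Accepts an :class:`IntergenicRegion` (candidate coordinates are then in
    genome coordinates, offset by ``region.start``) or a bare sequence
    string.  Short regions yield an empty list.
    """
    if isinstance(region, str):
        seq = region.upper()
        offset = 0
        gid = genome_id or ""
    else:
        seq = region.sequence.upper()
        offset = region.start
        gid = genome_id or region.genome_id
    codes = encode(seq)
    out = [
        _make_candidate(gid, offset + start, arm, spacer, seq[start : start + 2 * arm + spacer])
        for start, arm, spacer in _enumerate_codes(codes, params)
    ]
    return out


def best_site(candidates: Iterable[IRCandidate]) -> IRCandidate:
    """Single best candidate: minimal mismatch fraction, ties broken by
    larger arm, then larger spacer, then smaller start.

    Overlapping windows at one locus often tie on mismatch fraction (a
    shifted sub-window of a quasi-palindrome can preserve the mismatch
    count); preferring the larger spacer keeps the maximal extent of the
    locus rather than a contained sub-site.  Deterministic under input
    permutation.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("best_site requires a non-empty candidate list")
    return min(
        cands,
        key=lambda c: (c.mismatches / c.arm_len, -c.arm_len, -c.spacer_len, c.start),
    )
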