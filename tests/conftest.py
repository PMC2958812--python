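"""Shared fixtures and independent oracles.

The oracles here are deliberately naive (triple loops, boolean masks) and
never call the vectorized implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from difskew.genome_io import Feature, Genome
from difskew.ir_search import SearchParams

#: the 43-nt top-strand oligonucleotide carrying the P. abyssi dif site
PAB_DIF_OLIGO = "gttaactatATTGGATATAATCGGCCTTATATCTAAAgtgttg".upper()

#: the 28-bp site inside it: 11-bp arms, 6-bp spacer, 2 arm mismatches
PAB_DIF_SITE = "ATTGGATATAATCGGCCTTATATCTAAA"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_ir(seq: str, params: SearchParams) -> list[tuple[int, int, int, int]]:
    """Triple-loop enumeration oracle: (start, arm, spacer, mismatches)."""
    out = []
    n = len(seq)
    for start in range(n):
        for arm in range(params.arm_min, params.arm_max + 1):
            for spacer in range(params.spacer_min, params.spacer_max + 1):
                end = start + 2 * arm + spacer
                if end > n:
                    continue
                window = seq[start:end]
                if "N" in window:
                    continue
                arm1, arm2 = window[:arm], window[arm + spacer :]
                rc = naive_revcomp(arm2)
                mm = sum(a != b for a, b in zip(arm1, rc))
                if mm <= params.max_arm_mismatches:
                    out.append((start, arm, spacer, mm))
    out.sort()
    return out


def random_seq(rng: np.random.Generator, n: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=list(p))])


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_genome():
    """100-bp circle, one CDS [10, 90) -> single wraparound intergenic gap."""
    rng = np.random.default_rng(5)
    seq = random_seq(rng, 100)
    return Genome(id="tiny", sequence=seq, features=[Feature(10, 90, "+", "CDS")], oric=0)
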