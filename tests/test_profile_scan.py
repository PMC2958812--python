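import itertools

import numpy as np
import pytest

from difskew.genome_io import Genome
from difskew.ir_search import revcomp
from difskew.profile_scan import (
    ProfileModel,
    build_profile,
    calibrate_threshold,
    dinucleotide_shuffle,
    scan_genome,
    with_threshold,
)

from conftest import PAB_DIF_SITE, random_seq


class TestBuildProfile:
    def test_pseudocount_arithmetic(self):
        # single column {A, A}, pseudocount 1, uniform background
        p = build_profile(["A", "A"], pseudocount=1.0)
        assert p.probs[0, 0] == pytest.approx((2 + 0.25) / 3)

    def test_identical_alignment_limit(self):
        """With a vanishing pseudocount each matched position scores ~2 bits."""
        p = build_profile([PAB_DIF_SITE] * 5, pseudocount=1e-9)
        assert p.score(PAB_DIF_SITE) == pytest.approx(2.0 * len(PAB_DIF_SITE), abs=1e-4)

    def test_columns_are_distributions(self, rng):
        p = build_profile([random_seq(rng, 20) for _ in range(8)], pseudocount=0.5)
        assert np.allclose(p.probs.sum(axis=1), 1.0)

    def test_consensus_scores_maximal(self, rng):
        """Exhaustive check at width 5: no string outscores the consensus."""
        aligned = [random_seq(rng, 5) for _ in range(6)]
        p = build_profile(aligned)
        best = p.score(p.consensus())
        for word in itertools.product("ACGT", repeat=5):
            assert p.score("".join(word)) <= best + 1e-12

    def test_additivity(self, rng):
        """A window's score equals the sum of its column log-odds."""
        aligned = [random_seq(rng, 8) for _ in range(4)]
        p = build_profile(aligned)
        s = random_seq(rng, 8)
        direct = sum(p.matrix[i, "ACGT".index(ch)] for i, ch in enumerate(s))
        assert p.score(s) == pytest.approx(direct)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_profile(["AC", "A"])
        with pytest.raises(ValueError):
            build_profile(["AC", "AC"], pseudocount=0.0)
        with pytest.raises(ValueError):
            build_profile(["AC", "AC"], background=[0.5, 0.5, 0.0, 0.0])

    def test_text_round_trip(self, rng):
        p = build_profile([random_seq(rng, 10) for _ in range(4)],
                          background=[0.3, 0.2, 0.2, 0.3])
        q = ProfileModel.from_text(p.to_text())
        assert np.allclose(p.matrix, q.matrix, atol=1e-5)
        assert np.allclose(p.background, q.background)


class TestScan:
    def _genome_with_site(self, rng, L=5000):
        seq = list(random_seq(rng, L))
        start = 1234
        for i, ch in enumerate(PAB_DIF_SITE):
            seq[start + i] = ch
        return Genome(id="g", sequence="".join(seq)), start

    def test_planted_site_top_hit(self, rng):
        g, start = self._genome_with_site(rng)
        p = build_profile([PAB_DIF_SITE] * 3)
        hits = scan_genome(g, p, threshold=p.max_score - 1e-9)
        assert hits and hits[0].start == start and hits[0].strand == "+"

    def test_impossible_threshold_empty(self, rng):
        g, _ = self._genome_with_site(rng)
        p = build_profile([PAB_DIF_SITE] * 3)
        assert scan_genome(g, p, threshold=p.max_score + 1.0) == []

    def test_revcomp_symmetry(self, rng):
        g, _ = self._genome_with_site(rng, L=2000)
        p = build_profile([PAB_DIF_SITE, PAB_DIF_SITE[:14] + "ATCGGCCTTATATC"])
        g_rc = Genome(id="g", sequence=revcomp(g.sequence))
        fwd = scan_genome(g, p, threshold=10.0)
        rev = scan_genome(g_rc, p, threshold=10.0)
        assert sorted(round(h.score, 6) for h in fwd) == sorted(
            round(h.score, 6) for h in rev
        )
        L, w = g.length, p.width
        mirrored = sorted((L - h.end) % L for h in rev)
        assert mirrored == sorted(h.start % L for h in fwd)

    def test_wraparound_window_found(self, rng):
        seq = random_seq(rng, 1000)
        site = PAB_DIF_SITE
        # place the site across the origin: last 10 bp at the end, rest at 0
        g = Genome(id="g", sequence=site[10:] + seq[:972] + site[:10])
        p = build_profile([site] * 3)
        hits = scan_genome(g, p, threshold=p.max_score - 1e-9)
        assert any(h.start == 990 for h in hits)


class TestShuffleAndCalibration:
    def test_shuffle_preserves_dinucleotides(self, rng):
        for _ in range(10):
            seq = random_seq(rng, 500, p=(0.4, 0.1, 0.1, 0.4))
            shuf = dinucleotide_shuffle(seq, rng)
            count = lambda s: {
                d: sum(1 for i in range(len(s) - 1) if s[i : i + 2] == d)
                for d in map("".join, itertools.product("ACGT", repeat=2))
            }
            assert count(shuf) == count(seq)
            assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_shuffle_keeps_n_positions(self, rng):
        seq = random_seq(rng, 200)
        seq = seq[:50] + "N" + seq[51:]
        shuf = dinucleotide_shuffle(seq, rng)
        assert shuf[50] == "N" and len(shuf) == 200

    def test_calibration_deterministic_and_monotone(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 3000))
        p = build_profile([PAB_DIF_SITE] * 3)
        t1 = calibrate_threshold(p, g, n_shuffles=100, alpha=0.05, seed=11)
        t2 = calibrate_threshold(p, g, n_shuffles=100, alpha=0.05, seed=11)
        assert t1 == t2
        t_strict = calibrate_threshold(p, g, n_shuffles=100, alpha=0.0, seed=11)
        assert t_strict >= t1  # alpha=0 is the max over shuffles

    def test_calibration_requires_enough_shuffles(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 1000))
        p = build_profile([PAB_DIF_SITE] * 3)
        with pytest.raises(ValueError):
            calibrate_threshold(p, g, n_shuffles=50)

    def test_planted_site_passes_calibrated_threshold(self, rng):
        """Power check: a planted consensus beats the alpha=0.05 threshold."""
        hits_found = 0
        n_rep = 10
        for rep in range(n_rep):
            seq = list(random_seq(rng, 30_000, p=(0.3, 0.2, 0.2, 0.3)))
            start = int(rng.integers(0, 30_000 - 28))
            for i, ch in enumerate(PAB_DIF_SITE):
                seq[start + i] = ch
            g = Genome(id="g", sequence="".join(seq))
            p = build_profile([PAB_DIF_SITE] * 4, background=[0.3, 0.2, 0.2, 0.3])
            thr = calibrate_threshold(p, g, n_shuffles=100, alpha=0.05, seed=rep)
            hits = scan_genome(g, p, threshold=thr)
            if any(h.start == start for h in hits):
                hits_found += 1
        assert hits_found >= 9

    def test_with_threshold(self):
        p = build_profile([PAB_DIF_SITE] * 2)
        q = with_threshold(p, 12.5)
        assert q.score_threshold == 12.5 and p.score_threshold == -np.inf
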