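import numpy as np
import pytest

from difskew.genome_io import Genome
from difskew.ir_search import revcomp
from difskew.skew import (
    RotationGrid,
    count_word,
    cumulative_skew,
    leading_strand_view,
    rank_asps,
    summit,
    word_zscore,
)
from difskew.synthetic_data import SimConfig, polarized_genome, random_genome

from conftest import random_seq


class TestLeadingStrandView:
    def test_homopolymer(self):
        g = Genome(id="g", sequence="A" * 10, oric=0)
        assert leading_strand_view(g, 0, 5) == "A" * 5 + "T" * 5

    def test_identity_on_first_segment(self, rng):
        seq = random_seq(rng, 1000)
        view = leading_strand_view(seq, 100, 600)
        assert view[:500] == seq[100:600]

    def test_length_and_composition_conserved(self, rng):
        """The view is a rearrangement of the circle: same length, and the
        second segment is the reverse complement of the remaining arc."""
        seq = random_seq(rng, 997)
        oric, ter = 101, 650
        view = leading_strand_view(seq, oric, ter)
        assert len(view) == 997
        assert revcomp(view[ter - oric :]) == seq[ter:] + seq[:oric]

    def test_wrapping_terminus(self, rng):
        seq = random_seq(rng, 100)
        view = leading_strand_view(seq, 80, 30)
        assert view[:50] == seq[80:] + seq[:30]

    def test_oric_equals_ter_error(self):
        with pytest.raises(ValueError):
            leading_strand_view("ACGT" * 10, 5, 5)


class TestWordZscore:
    def test_zero_when_observed_equals_expected(self):
        # periodic sequence: every count is deterministic, obs == expected
        seq = "ACGT" * 500
        ws = word_zscore(seq, "ACGT")
        assert ws.fwd_count == pytest.approx(ws.expected, abs=1e-9)
        assert ws.zscore == pytest.approx(0.0, abs=1e-9)

    def test_planted_word_highly_significant(self, rng):
        seq = list(random_seq(rng, 1_000_000))
        word = "GTAC"
        starts = rng.choice(1_000_000 - 4, size=500, replace=False)
        for s in starts:
            for i, ch in enumerate(word):
                seq[s + i] = ch
        ws = word_zscore("".join(seq), word)
        assert ws.zscore > 3.0

    def test_overlapping_occurrences_counted(self):
        assert count_word("AAAAA", "AAAA") == 2

    def test_errors(self):
        with pytest.raises(ValueError):
            word_zscore("ACGT" * 100, "ACN T".replace(" ", ""))
        with pytest.raises(ValueError):
            word_zscore("ACGT" * 100, "ACG")  # k < 4

    def test_null_calibration(self, rng):
        """On sequences from an order-(k-2) Markov source the z-scores are
        approximately standard normal."""
        zs = []
        for _ in range(100):
            seq = random_seq(rng, 100_000, p=(0.3, 0.2, 0.2, 0.3))
            zs.append(word_zscore(seq, "GTAC").zscore)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.2
        assert abs(zs.std(ddof=1) - 1.0) < 0.2


class TestRotationGrid:
    def test_default_angles(self):
        grid = RotationGrid()
        assert grid.angles[0] == 120 and grid.angles[-1] == 200
        assert len(grid.angles) == 17

    def test_invalid(self):
        with pytest.raises(ValueError):
            RotationGrid(start_angle=200, end_angle=120)
        with pytest.raises(ValueError):
            RotationGrid(step=7)


class TestRankAsps:
    def test_planted_polarity_ranked_first(self):
        cfg = SimConfig(L=300_000, seed=3, asps_word="GTTG",
                        asps_rate_leading=2.0, asps_rate_lagging=0.5,
                        ter_angle=160.0, gene_density=0.0)
        g, truth = polarized_genome(cfg)
        ranked = rank_asps(g, k_range=[4], grid=RotationGrid())
        assert ranked[0].word == "GTTG"
        assert ranked[0].median_skew > 0

    def test_palindromes_never_reported(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 100_000), oric=0)
        ranked = rank_asps(g, k_range=[4])
        assert all(r.word != revcomp(r.word) for r in ranked)

    def test_uniform_genome_no_stable_word(self, rng):
        """Unpolarized random sequence should not produce strong stable
        skewed words (median z stays small)."""
        hits = 0
        for rep in range(10):
            g = Genome(id="g", sequence=random_seq(rng, 200_000), oric=0)
            ranked = rank_asps(g, k_range=[4])
            if ranked and ranked[0].median_z >= 3.0:
                hits += 1
        assert hits <= 1

    def test_rotation_of_genome_coordinates(self):
        """Rotating the sequence start point (oriC tracked) leaves the
        ranking unchanged."""
        cfg = SimConfig(L=150_000, seed=9, gene_density=0.0, ter_angle=150.0)
        g, _ = polarized_genome(cfg)
        shift = 40_000
        g2 = Genome(id="g2", sequence=g.sequence[shift:] + g.sequence[:shift],
                    oric=(g.oric - shift) % g.length)
        r1 = rank_asps(g, k_range=[4])
        r2 = rank_asps(g2, k_range=[4])
        assert [r.word for r in r1[:5]] == [r.word for r in r2[:5]]
        assert r1[0].score == pytest.approx(r2[0].score, rel=1e-6)

    def test_missing_oric_error(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 50_000))
        with pytest.raises(ValueError):
            rank_asps(g, k_range=[4])


class TestCumulativeSkew:
    def test_absent_word_flat_zero(self, rng):
        g = Genome(id="g", sequence="AC" * 25_000, oric=0)
        curve = cumulative_skew(g, "GTAC")
        assert (curve.values == 0).all()

    def test_final_value_is_count_difference(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 50_000), oric=1234)
        word = "GTTG"
        curve = cumulative_skew(g, word)
        ext = g.sequence + g.sequence[:3]
        assert curve.values[-1] == count_word(ext, word) - count_word(ext, revcomp(word))

    def test_antisymmetry(self, rng):
        g = Genome(id="g", sequence=random_seq(rng, 50_000), oric=0)
        c1 = cumulative_skew(g, "GTTG")
        c2 = cumulative_skew(g, revcomp("GTTG"))
        assert (c1.values == -c2.values).all()

    def test_planted_switch_point(self):
        """Forward-only occurrences before theta, reverse-only after ->
        monotone rise then fall with the summit at theta."""
        L, theta = 100_000, 60_000
        seq = np.full(L, ord("A"), dtype=np.uint8)
        rng = np.random.default_rng(0)
        word, rc = "GTTC", revcomp("GTTC")
        for pos in range(500, theta - 10, 997):
            seq[pos : pos + 4] = np.frombuffer(word.encode(), np.uint8)
        for pos in range(theta + 10, L - 10, 997):
            seq[pos : pos + 4] = np.frombuffer(rc.encode(), np.uint8)
        g = Genome(id="g", sequence=seq.tobytes().decode(), oric=0)
        curve = cumulative_skew(g, word, bin=500)
        pos, angle = summit(curve)
        assert abs(pos - theta) <= 1000
        diffs = np.diff(np.concatenate([[0], curve.values]))
        switch = np.flatnonzero(diffs < 0)[0]
        assert (diffs[:switch] >= 0).all() and (diffs[switch:] <= 0).all()


class TestSummit:
    def _curve(self, values, bin=1000, L=None):
        from difskew.skew import SkewCurve
        values = np.asarray(values)
        L = L or len(values) * bin
        positions = np.minimum((np.arange(len(values)) + 1) * bin, L)
        return SkewCurve(word="GTTG", positions=positions, values=values,
                         bin=bin, oric=0, genome_length=L)

    def test_unimodal_argmax(self):
        curve = self._curve([0, 1, 2, 5, 3, 1])
        pos, _ = summit(curve)
        assert pos == 4000

    def test_plateau_midpoint(self):
        curve = self._curve([0, 5, 5, 5, 1, 0])
        pos, _ = summit(curve)
        assert pos == 3000  # midpoint of plateau bins 1..3

    def test_empty_error(self):
        with pytest.raises(ValueError):
            summit(self._curve([]))

    def test_angle_reported(self):
        curve = self._curve([0, 0, 0, 9, 0, 0, 0, 0])  # max at bin 3 of 8
        pos, angle = summit(curve)
        assert angle == pytest.approx(180.0)


def test_summit_recovery_over_seeds():
    """Planted polarity switch recovered within a few degrees on average."""
    errs = []
    for seed in range(10):
        cfg = SimConfig(L=500_000, seed=seed, ter_angle=150.0, gene_density=0.0,
                        asps_rate_leading=2.0, asps_rate_lagging=0.5)
        g, truth = polarized_genome(cfg)
        curve = cumulative_skew(g, cfg.asps_word)
        _, angle = summit(curve)
        errs.append(abs(angle - cfg.ter_angle))
    assert np.mean(errs) <= 3.0
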