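"""Harmony scores, permutation Z-scores, relief weights, logos, volumes."""

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon
from scipy.stats import fisher_exact

from pockettree.alignments import ReducedAlignment
from pockettree.specificity import (
    ALPHABET,
    GroupProfile,
    flag_positions,
    group_frequencies,
    harmony_score,
    position_zscores,
    relief_weights,
    residue_volume,
    two_sample_logo,
)


def make_ra(rows: dict[str, str]) -> ReducedAlignment:
    width = len(next(iter(rows.values())))
    return ReducedAlignment(
        ids=list(rows), rows=list(rows.values()),
        column_sources=tuple(range(1, width + 1)),
    )


class TestGroupFrequencies:
    def test_identical_rows_point_mass(self):
        ra = make_ra({"a1": "MK", "a2": "MK", "b1": "LK", "b2": "LK"})
        pa, pb = group_frequencies(ra, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert pa.distribution(1) == {"M": 1.0}
        assert pb.distribution(1) == {"L": 1.0}
        assert pa.distribution(2) == {"K": 1.0}

    def test_hand_computed_mixed_frequencies(self):
        ra = make_ra({"a1": "M-", "a2": "L-", "b1": "MA", "b2": "MA"})
        pa, pb = group_frequencies(ra, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert pa.distribution(1) == {"M": 0.5, "L": 0.5}
        assert pa.distribution(2) == {"-": 1.0}  # gap is a symbol
        assert pb.distribution(2) == {"A": 1.0}

    def test_empty_group_rejected(self):
        ra = make_ra({"a": "M", "b": "L"})
        with pytest.raises(ValueError, match="empty"):
            group_frequencies(ra, {"A": ["a"], "B": []})

    def test_overlapping_groups_rejected(self):
        ra = make_ra({"a": "M", "b": "L"})
        with pytest.raises(ValueError, match="overlap"):
            group_frequencies(ra, {"A": ["a"], "B": ["a", "b"]})


class TestHarmonyScore:
    def test_identical_distributions_one(self):
        assert harmony_score({"M": 1.0}, {"M": 1.0}) == 1.0
        assert harmony_score({"M": 0.3, "L": 0.7}, {"M": 0.3, "L": 0.7}) == (
            pytest.approx(1.0)
        )

    def test_disjoint_supports_zero(self):
        # the all-M vs all-L split of a perfectly separating position
        assert harmony_score({"M": 1.0}, {"L": 1.0}) == pytest.approx(0.0)

    def test_two_symbol_example_against_jsd_oracle(self):
        pA = {"M": 0.5, "L": 0.5}
        pB = {"L": 1.0}
        got = harmony_score(pA, pB)
        # direct summation over {M, L}: JSD = H(m) − (H(pA)+H(pB))/2
        m = {"M": 0.25, "L": 0.75}
        h = lambda p: -sum(v * np.log2(v) for v in p.values() if v > 0)  # noqa: E731
        expected = 1.0 - (h(m) - 0.5 * (h(pA) + h(pB)))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.689, abs=5e-4)
        # scipy cross-check
        va = np.zeros(len(ALPHABET))
        vb = np.zeros(len(ALPHABET))
        va[ALPHABET.index("M")] = va[ALPHABET.index("L")] = 0.5
        vb[ALPHABET.index("L")] = 1.0
        assert got == pytest.approx(1 - jensenshannon(va, vb, base=2) ** 2)

    @pytest.mark.parametrize("trial", range(20))
    def test_symmetry_on_random_distributions(self, trial):
        rng = np.random.default_rng(trial)
        pa = rng.dirichlet(np.ones(len(ALPHABET)))
        pb = rng.dirichlet(np.ones(len(ALPHABET)))
        assert harmony_score(pa, pb) == pytest.approx(harmony_score(pb, pa))
        assert 0.0 <= harmony_score(pa, pb) <= 1.0

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            harmony_score({"M": 0.6}, {"L": 1.0})


class TestPositionZscores:
    def test_constant_column_z_zero_not_flagged(self):
        rows = {f"a{i}": "KM" for i in range(3)} | {f"b{i}": "KL" for i in range(3)}
        ra = make_ra(rows)
        rep = position_zscores(ra, [f"a{i}" for i in range(3)],
                               [f"b{i}" for i in range(3)], n_perm=200, seed=1)
        assert rep.positions[0].z == 0.0
        assert not rep.positions[0].flagged

    def test_planted_separating_position_flagged(self):
        rng = np.random.default_rng(4)
        n, width = 30, 10
        bg = "".join(rng.choice(list("ACDEFGHIK"), size=width))
        rows = {}
        for g, res in (("a", "M"), ("b", "L")):
            for i in range(n):
                row = [
                    c if rng.random() > 0.15
                    else "ACDEFGHIK"[rng.integers(9)]
                    for c in bg
                ]
                row[4] = res
                rows[f"{g}{i}"] = "".join(row)
        ra = make_ra(rows)
        rep = position_zscores(ra, [f"a{i}" for i in range(n)],
                               [f"b{i}" for i in range(n)],
                               n_perm=1000, seed=17)
        assert 5 in rep.flagged_positions()
        zmin = min(p.z for p in rep.positions)
        assert rep.positions[4].z == zmin < -3

    def test_threshold_rule_on_reported_scores(self):
        assert flag_positions([-4.02, -1.0, 0.0], threshold=-3.0) == [1]

    def test_flags_monotone_in_threshold(self):
        z = [-4.0, -2.5, -0.3, 1.2]
        assert set(flag_positions(z, -3.0)) <= set(flag_positions(z, -2.0))

    def test_reproducible_per_seed(self):
        rows = {f"a{i}": "MKWC" for i in range(3)} | {
            f"b{i}": "LKWC" for i in range(3)}
        rows["a0"] = "MKAC"
        ra = make_ra(rows)
        args = ([f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        r1 = position_zscores(ra, *args, n_perm=150, seed=11)
        r2 = position_zscores(ra, *args, n_perm=150, seed=11)
        assert [p.z for p in r1.positions] == [p.z for p in r2.positions]

    def test_small_groups_rejected(self):
        ra = make_ra({"a": "M", "b": "L", "c": "M"})
        with pytest.raises(ValueError, match="at least 2"):
            position_zscores(ra, ["a"], ["b", "c"], n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self):
        ra = make_ra({f"x{i}": "ML" for i in range(4)})
        with pytest.raises(ValueError, match="n_perm"):
            position_zscores(ra, ["x0", "x1"], ["x2", "x3"], n_perm=10, seed=0)


class TestReliefWeights:
    def test_single_differing_position(self):
        ra = make_ra({"a1": "KMC", "a2": "KMC", "b1": "KLC", "b2": "KLC"})
        w = relief_weights(ra, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(w, [0.0, 1.0, 0.0])

    def test_identical_groups_zero(self):
        # groups identical as multisets, duplicates within each group:
        # hit and miss are both exact copies, so every weight vanishes
        ra = make_ra({"a1": "KMC", "a2": "KMC", "a3": "KMA", "a4": "KMA",
                      "b1": "KMC", "b2": "KMC", "b3": "KMA", "b4": "KMA"})
        w = relief_weights(ra, ["a1", "a2", "a3", "a4"],
                           ["b1", "b2", "b3", "b4"])
        np.testing.assert_allclose(w, 0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(12)
        rows = {
            f"{g}{i}": "".join(rng.choice(list("ML-K"), size=6))
            for g in "ab" for i in range(3)
        }
        ra = make_ra(rows)
        ga, gb = [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)]
        w = relief_weights(ra, ga, gb)

        # independent exhaustive scan
        expected = np.zeros(6)
        for sid in ga + gb:
            same = [s for s in (ga if sid in ga else gb) if s != sid]
            other = gb if sid in ga else ga
            def ham(x, y):
                return sum(a != b for a, b in zip(rows[x], rows[y]))
            hit = sorted(same, key=lambda s: (ham(sid, s), s))[0]
            miss = sorted(other, key=lambda s: (ham(sid, s), s))[0]
            for k in range(6):
                expected[k] += (rows[sid][k] != rows[miss][k]) - (
                    rows[sid][k] != rows[hit][k])
        expected /= 6
        np.testing.assert_allclose(w, expected)

    def test_invariant_under_alphabet_relabeling(self):
        rows = {"a1": "KMCA", "a2": "KMCA", "b1": "KLCW", "b2": "GLCW"}
        ra1 = make_ra(rows)
        trans = str.maketrans("KMLCAWG", "RPQDEFH")
        ra2 = make_ra({k: v.translate(trans) for k, v in rows.items()})
        w1 = relief_weights(ra1, ["a1", "a2"], ["b1", "b2"])
        w2 = relief_weights(ra2, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(w1, w2)


class TestTwoSampleLogo:
    def _profiles(self, rows_a, rows_b):
        rows = {f"a{i}": r for i, r in enumerate(rows_a)}
        rows |= {f"b{i}": r for i, r in enumerate(rows_b)}
        ra = make_ra(rows)
        return group_frequencies(
            ra, {"A": [f"a{i}" for i in range(len(rows_a))],
                 "B": [f"b{i}" for i in range(len(rows_b))]}
        )

    def test_identical_profiles_empty(self):
        pa, pb = self._profiles(["MK", "LK"], ["MK", "LK"])
        assert two_sample_logo(pa, pb) == []

    def test_strong_enrichment_detected(self):
        rows_a = ["M"] * 18 + ["A"] * 2
        rows_b = ["M"] * 2 + ["A"] * 18
        pa, pb = self._profiles(rows_a, rows_b)
        enr = two_sample_logo(pa, pb, alpha=0.05)
        m_hits = [e for e in enr if e.residue == "M"]
        assert m_hits and m_hits[0].group == "A"
        assert m_hits[0].delta_f == pytest.approx(0.8)
        _, p = fisher_exact([[18, 2], [2, 18]])
        assert m_hits[0].p_value == pytest.approx(p)

    def test_single_mismatch_not_significant_at_tiny_n(self):
        pa, pb = self._profiles(["M", "M"], ["M", "L"])
        assert two_sample_logo(pa, pb, alpha=0.05) == []
        _, p = fisher_exact([[2, 0], [1, 1]])
        assert p > 0.05

    def test_gap_can_be_enriched(self):
        pa, pb = self._profiles(["-"] * 10, ["M"] * 10)
        enr = two_sample_logo(pa, pb)
        assert any(e.residue == "-" and e.group == "A" for e in enr)


class TestResidueVolume:
    def test_met_and_leu_values(self):
        assert residue_volume("M") == 166.7
        assert residue_volume("L") == 162.9

    def test_all_twenty_present_and_positive(self):
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert residue_volume(aa) > 0

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            residue_volume("X")


class TestNullCalibration:
    def test_false_flag_rate_under_null(self):
        """Both groups drawn from one distribution: few |z| > 3 positions."""
        rng = np.random.default_rng(123)
        n, width, reps = 15, 8, 5
        flagged = total = 0
        for rep in range(reps):
            rows = {
                f"s{i}": "".join(rng.choice(list("ACDEFG"), size=width))
                for i in range(2 * n)
            }
            ra = make_ra(rows)
            report = position_zscores(
                ra, [f"s{i}" for i in range(n)],
                [f"s{i}" for i in range(n, 2 * n)],
                n_perm=300, seed=1000 + rep,
            )
            flagged += sum(1 for p in report.positions if abs(p.z) > 3)
            total += width
        assert flagged / total <= 0.02
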