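"""PPV statistics against brute-force oracles."""

import numpy as np
import pytest

import contactstack as cs
from contactstack.evaluate import (
    isolated_prediction_count,
    ppv_by_separation,
    ppv_by_ss_category,
    ppv_vs_meff,
    ranked_pairs,
    top_l_ppv,
    window_contact_statistics,
)

from conftest import random_contact_map, random_prediction


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, independent of the implementation)


def oracle_ranking(scores, min_sep):
    L = scores.shape[0]
    pairs = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if j - i >= min_sep
    ]
    return sorted(pairs, key=lambda p: (-scores[p], -(p[1] - p[0]), p[0], p[1]))


def oracle_top_l_ppv(scores, truth, alpha, min_sep):
    L = scores.shape[0]
    order = oracle_ranking(scores, min_sep)
    take = order[: int(np.ceil(alpha * L))]
    return sum(truth[p] for p in take) / len(take)


def oracle_sep_ppv(scores, truth, min_sep_range):
    L = scores.shape[0]
    lo, hi = min_sep_range
    pairs = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if lo <= j - i and (hi is None or j - i <= hi)
    ]
    if not pairs:
        return None
    pairs.sort(key=lambda p: (-scores[p], -(p[1] - p[0]), p[0], p[1]))
    take = pairs[: int(np.ceil(L / 10))]
    return sum(truth[p] for p in take) / len(take)


def oracle_window_stats(maps, w):
    half = w // 2
    hist = {1: np.zeros(w * w), 0: np.zeros(w * w)}
    for m in maps:
        mat = m.matrix if hasattr(m, "matrix") else m
        L = mat.shape[0]
        for i in range(half, L - half):
            for j in range(half, L - half):
                if i == j:
                    continue
                n = 0
                for a in range(i - half, i + half + 1):
                    for b in range(j - half, j + half + 1):
                        if (a, b) != (i, j) and mat[a, b]:
                            n += 1
                hist[int(mat[i, j])][n] += 1
    for k in hist:
        if hist[k].sum():
            hist[k] /= hist[k].sum()
    return hist[1], hist[0]


# ---------------------------------------------------------------------------


class TestTopLPpv:
    def test_perfect_predictor_is_exact(self):
        rng = np.random.default_rng(0)
        cm = random_contact_map(rng, 30, density=0.2)
        ppv = top_l_ppv(cm.matrix.astype(float), cm, alpha=0.3)
        assert ppv == 1.0

    def test_empty_truth_gives_zero(self):
        rng = np.random.default_rng(1)
        pred = random_prediction(rng, 20)
        cm = cs.ContactMap(matrix=np.zeros((20, 20), bool))
        assert top_l_ppv(pred, cm) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sort_and_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 15
        pred = random_prediction(rng, L)
        cm = random_contact_map(rng, L, density=0.15)
        for alpha in (0.5, 1.0, 1.7):
            got = top_l_ppv(pred, cm, alpha=alpha)
            want = oracle_top_l_ppv(pred, cm.matrix, alpha, 5)
            assert got == pytest.approx(want)

    def test_no_eligible_pairs_raises(self):
        cm = cs.ContactMap(matrix=np.zeros((4, 4), bool))
        with pytest.raises(ValueError, match="eligible"):
            top_l_ppv(np.zeros((4, 4)), cm, min_sep=5)

    def test_masked_pairs_never_ranked(self):
        rng = np.random.default_rng(2)
        L = 16
        pred = np.zeros((L, L))
        pred[0, 8] = pred[8, 0] = 1.0  # best-scoring pair is masked
        mask = np.ones((L, L), bool)
        mask[0, 8] = mask[8, 0] = False
        cm = cs.ContactMap(matrix=np.zeros((L, L), bool), mask=mask)
        ii, jj, _ = ranked_pairs(pred, cm)
        assert (0, 8) not in set(zip(ii, jj))


class TestPpvBySeparation:
    def test_perfect_predictor_every_range(self):
        rng = np.random.default_rng(3)
        cm = random_contact_map(rng, 30, density=0.3)
        out = ppv_by_separation(cm.matrix.astype(float), cm)
        for label, val in out.items():
            assert val is None or val == 1.0

    def test_short_protein_reports_undefined_not_zero(self):
        cm = cs.ContactMap(matrix=np.zeros((10, 10), bool))
        out = ppv_by_separation(np.zeros((10, 10)), cm)
        assert out["long"] is None  # no pairs at separation >= 25

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_range_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        L = 30
        pred = random_prediction(rng, L)
        cm = random_contact_map(rng, L, density=0.15)
        got = ppv_by_separation(pred, cm)
        for label, rng_ in (("short", (6, 12)), ("medium", (13, 24)), ("long", (25, None))):
            want = oracle_sep_ppv(pred, cm.matrix, rng_)
            assert got[label] == pytest.approx(want)


class TestPpvBySsCategory:
    def test_all_helix_concentrates_in_one_category(self):
        rng = np.random.default_rng(4)
        L = 20
        cm = random_contact_map(rng, L, density=0.2)
        out = ppv_by_ss_category(random_prediction(rng, L), cm, "H" * L)
        assert out["helix-helix"]["fraction"] == 1.0
        for cat, d in out.items():
            if cat != "helix-helix":
                assert d["fraction"] == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        L = 24
        ss = "".join(rng.choice(list("HEC"), size=L))
        out = ppv_by_ss_category(
            random_prediction(rng, L), random_contact_map(rng, L), ss
        )
        total = sum(d["fraction"] for d in out.values())
        assert total == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_categorisation_oracle(self, seed):
        rng = np.random.default_rng(seed + 20)
        L = 22
        pred = random_prediction(rng, L)
        cm = random_contact_map(rng, L, density=0.2)
        ss = "".join(rng.choice(list("HEC"), size=L))
        got = ppv_by_ss_category(pred, cm, ss)
        # oracle: global ranking then categorize
        name = {"H": "helix", "E": "strand", "C": "loop"}
        order = "helix strand loop".split()
        take = oracle_ranking(pred, 5)[: int(np.ceil(L))]
        counts, hits = {}, {}
        for i, j in take:
            a, b = sorted((name[ss[i]], name[ss[j]]), key=order.index)
            cat = f"{a}-{b}"
            counts[cat] = counts.get(cat, 0) + 1
            hits[cat] = hits.get(cat, 0) + int(cm.matrix[i, j])
        for cat, d in got.items():
            if cat in counts:
                assert d["fraction"] == pytest.approx(counts[cat] / len(take))
                assert d["ppv"] == pytest.approx(hits[cat] / counts[cat])
            else:
                assert d["fraction"] == 0.0 and d["ppv"] is None

    def test_unknown_class_symbol_rejected(self):
        cm = random_contact_map(np.random.default_rng(0), 12)
        with pytest.raises(ValueError, match="class"):
            ppv_by_ss_category(np.zeros((12, 12)), cm, "HHHXHHHHHHHH")


class TestWindowContactStatistics:
    def test_empty_maps_concentrate_noncontact_at_zero(self):
        maps = [cs.ContactMap(matrix=np.zeros((12, 12), bool))]
        hist_c, hist_n = window_contact_statistics(maps)
        assert hist_n[0] == 1.0
        assert hist_c.sum() == 0.0  # no contacts observed at all

    def test_histograms_normalised(self):
        rng = np.random.default_rng(6)
        maps = [random_contact_map(rng, 20, density=0.1) for _ in range(3)]
        hist_c, hist_n = window_contact_statistics(maps)
        assert hist_c.sum() == pytest.approx(1.0)
        assert hist_n.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_window_count_oracle(self, seed):
        rng = np.random.default_rng(seed + 30)
        maps = [random_contact_map(rng, 20, density=0.12)]
        got_c, got_n = window_contact_statistics(maps)
        want_c, want_n = oracle_window_stats(maps, 3)
        assert np.allclose(got_c, want_c)
        assert np.allclose(got_n, want_n)


class TestPpvVsMeff:
    def test_constant_ppv_gives_constant_curve(self):
        res = [(10 * k, 0.4) for k in range(1, 30)]
        _, curve = ppv_vs_meff(res, frame=5)
        assert np.allclose(curve, 0.4)

    def test_frame_one_returns_sorted_points(self):
        res = [(3, 0.1), (1, 0.9), (2, 0.5)]
        meffs, curve = ppv_vs_meff(res, frame=1)
        assert np.allclose(meffs, [1, 2, 3])
        assert np.allclose(curve, [0.9, 0.5, 0.1])

    def test_frame_larger_than_n_collapses_to_global_mean(self):
        res = [(1, 0.2), (2, 0.6)]
        meffs, curve = ppv_vs_meff(res, frame=20)
        assert curve.shape == (1,)
        assert curve[0] == pytest.approx(0.4)

    def test_matches_direct_windowed_mean(self):
        rng = np.random.default_rng(7)
        res = [(rng.random() * 100, rng.random()) for _ in range(40)]
        frame = 7
        _, curve = ppv_vs_meff(res, frame=frame)
        srt = sorted(res)
        want = [
            np.mean([p for _, p in srt[k : k + frame]])
            for k in range(len(srt) - frame + 1)
        ]
        assert np.allclose(curve, want)


class TestIsolatedPredictionCount:
    def test_single_prediction_is_isolated(self):
        L = 16
        pred = np.zeros((L, L))
        pred[2, 10] = pred[10, 2] = 1.0
        cm = cs.ContactMap(matrix=np.zeros((L, L), bool))
        # alpha chosen so exactly one pair is taken
        assert isolated_prediction_count(pred, cm, alpha=1 / L) == 1

    def test_clustered_predictions_not_isolated(self):
        L = 20
        pred = np.zeros((L, L))
        for d in range(3):
            pred[3 + d, 15 - d] = pred[15 - d, 3 + d] = 1.0
        cm = cs.ContactMap(matrix=np.zeros((L, L), bool))
        assert isolated_prediction_count(pred, cm, alpha=3 / L) == 0
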