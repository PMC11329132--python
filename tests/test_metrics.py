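"""Metric correctness against brute-force oracles and library cross-checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctthinslice as ct
from ctthinslice.metrics import CaseResult, _gaussian_window


def brute_mse(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] / 4095 - b[i, j] / 4095) ** 2
    return total / a.size


def brute_ssim(a, b, win=11, sigma=1.5, k1=0.01, k2=0.03):
    """Windowed SSIM via explicit loops over valid window positions."""
    ua, ub = a / 4095.0, b / 4095.0
    w = _gaussian_window(win, sigma)
    c1, c2 = k1 ** 2, k2 ** 2
    vals = []
    for i in range(ua.shape[0] - win + 1):
        for j in range(ua.shape[1] - win + 1):
            pa = ua[i:i + win, j:j + win]
            pb = ub[i:i + win, j:j + win]
            mu_a = float((w * pa).sum())
            mu_b = float((w * pb).sum())
            va = float((w * pa * pa).sum()) - mu_a ** 2
            vb = float((w * pb * pb).sum()) - mu_b ** 2
            cov = float((w * pa * pb).sum()) - mu_a * mu_b
            vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                        / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


def random_pairs(n, shape=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        yield (rng.integers(0, 4096, shape).astype(np.uint16),
               rng.integers(0, 4096, shape).astype(np.uint16))


class TestMSE:
    def test_identical_zero_and_full_range_one(self):
        a = np.zeros((8, 8), dtype=np.uint16)
        assert ct.mse(a, a) == 0.0
        assert ct.mse(a, np.full((8, 8), 4095, dtype=np.uint16)) == 1.0

    def test_matches_brute_force(self):
        for a, b in random_pairs(5, (8, 8), seed=1):
            assert ct.mse(a, b) == pytest.approx(brute_mse(a, b), abs=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ct.mse(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPSNR:
    def test_closed_form_40db(self):
        # construct a pair with exact MSE 1e-4, peak 1
        a = np.zeros((10, 10), dtype=np.float64)
        b = a.copy()
        b[0, 0] = 4095 * 0.1  # (0.1)^2 / 100 pixels = 1e-4
        assert ct.mse(a, b) == pytest.approx(1e-4, abs=1e-18)
        assert ct.psnr(a, b) == pytest.approx(40.0, abs=1e-9)

    def test_identical_is_positive_infinity(self):
        a = np.full((4, 4), 123, dtype=np.uint16)
        assert ct.psnr(a, a) == math.inf

    def test_matches_library_cross_check(self):
        from skimage.metrics import peak_signal_noise_ratio

        for a, b in random_pairs(5, (16, 16), seed=2):
            ref = peak_signal_noise_ratio(a / 4095.0, b / 4095.0, data_range=1.0)
            assert ct.psnr(a, b) == pytest.approx(ref, abs=1e-9)


class TestSSIM:
    def test_identical_is_one(self):
        a = np.random.default_rng(0).integers(0, 4096, (16, 16)).astype(np.uint16)
        assert ct.ssim(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_checkerboard_negative(self):
        tile = np.indices((32, 32)).sum(axis=0) % 2
        a = (tile * 4095).astype(np.uint16)
        b = 4095 - a  # contrast inversion
        assert ct.ssim(a, b) < 0

    def test_matches_brute_force_loops(self):
        for a, b in random_pairs(3, (16, 16), seed=3):
            assert ct.ssim(a, b) == pytest.approx(brute_ssim(a, b), abs=1e-6)

    def test_matches_skimage_convention(self):
        from skimage.metrics import structural_similarity

        for a, b in random_pairs(3, (32, 32), seed=4):
            ref = structural_similarity(
                a / 4095.0, b / 4095.0, win_size=11, gaussian_weights=True,
                sigma=1.5, use_sample_covariance=False, data_range=1.0)
            assert ct.ssim(a, b) == pytest.approx(ref, abs=1e-6)

    def test_symmetric(self):
        a, b = next(iter(random_pairs(1, seed=5)))
        assert ct.ssim(a, b) == pytest.approx(ct.ssim(b, a), abs=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            ct.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestWinnerCounts:
    def _triples(self, mses, ssims):
        return [ct.MetricTriple(psnr=(math.inf if m == 0 else 10 * math.log10(1 / m)),
                                mse=m, ssim=s)
                for m, s in zip(mses, ssims)]

    def test_counting(self):
        t1 = self._triples([0.2, 0.2, 0.1], [0.5, 0.5, 0.5])
        t2 = self._triples([0.1, 0.1, 0.2], [0.5, 0.6, 0.4])
        counts = ct.winner_counts(t1, t2)
        assert counts["psnr_mse"] == {"method1": 1, "method2": 2, "tie": 0}
        assert counts["ssim"] == {"method1": 1, "method2": 1, "tie": 1}

    def test_all_ties(self):
        t = self._triples([0.1, 0.2], [0.7, 0.8])
        counts = ct.winner_counts(t, t)
        assert counts["psnr_mse"] == {"method1": 0, "method2": 0, "tie": 2}

    @given(st.lists(st.tuples(st.floats(1e-8, 1.0), st.floats(1e-8, 1.0)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_psnr_winner_equals_mse_winner(self, mse_pairs):
        """PSNR is strictly decreasing in MSE, so the winner sets coincide."""
        t1 = self._triples([p[0] for p in mse_pairs], [0.5] * len(mse_pairs))
        t2 = self._triples([p[1] for p in mse_pairs], [0.5] * len(mse_pairs))
        for a, b in zip(t1, t2):
            if a.mse != b.mse and abs(a.mse - b.mse) < 1e-12 * max(a.mse, b.mse):
                continue  # below float64 log10 resolution: PSNR may tie
            mse_winner = 1 if a.mse < b.mse else (2 if b.mse < a.mse else 0)
            psnr_winner = 1 if a.psnr > b.psnr else (2 if b.psnr > a.psnr else 0)
            assert mse_winner == psnr_winner

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ct.winner_counts(self._triples([0.1], [0.5]), [])


class TestDifferenceImage:
    def test_identical_all_black(self):
        a = np.full((8, 8), 100, dtype=np.uint16)
        signed, render = ct.difference_image(a, a)
        assert np.all(signed == 0) and np.all(render == 0)

    def test_uniform_positive_pure_red(self):
        a = np.full((8, 8), 300, dtype=np.uint16)
        b = np.full((8, 8), 200, dtype=np.uint16)
        signed, render = ct.difference_image(a, b)
        assert np.all(signed == 100)
        assert np.all(render[..., 0] == 255)
        assert np.all(render[..., 1] == 0) and np.all(render[..., 2] == 0)

    def test_antisymmetry_swaps_channels(self):
        rng = np.random.default_rng(6)
        a = rng.integers(0, 4096, (8, 8)).astype(np.uint16)
        b = rng.integers(0, 4096, (8, 8)).astype(np.uint16)
        s_ab, r_ab = ct.difference_image(a, b)
        s_ba, r_ba = ct.difference_image(b, a)
        np.testing.assert_array_equal(s_ab, -s_ba)
        np.testing.assert_array_equal(r_ab[..., 0], r_ba[..., 2])
        np.testing.assert_array_equal(r_ab[..., 2], r_ba[..., 0])


class TestCohenKappa:
    def test_perfect_agreement(self):
        assert ct.cohen_kappa([1, 2, 3, 4, 1], [1, 2, 3, 4, 1]) == 1.0

    def test_constructed_independence_is_zero(self):
        # p_o = 0.5 and p_e = 0.5 -> kappa = 0
        assert ct.cohen_kappa(list("AABB"), list("ABAB")) == pytest.approx(0.0)

    def test_contingency_table_longhand(self):
        # 2x2 table: both-A 20, A/B 5, B/A 10, both-B 15 (n = 50)
        r1 = ["A"] * 25 + ["B"] * 25
        r2 = ["A"] * 20 + ["B"] * 5 + ["A"] * 10 + ["B"] * 15
        n = 50
        p_o = (20 + 15) / n
        p_e = (25 / n) * (30 / n) + (25 / n) * (20 / n)
        expected = (p_o - p_e) / (1 - p_e)
        assert ct.cohen_kappa(r1, r2) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        for _ in range(5):
            r1 = rng.integers(1, 5, 40)
            r2 = rng.integers(1, 5, 40)
            assert ct.cohen_kappa(list(r1), list(r2)) == pytest.approx(
                cohen_kappa_score(r1, r2), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        r1, r2 = rng.integers(1, 5, 30), rng.integers(1, 5, 30)
        relabel = {1: "d", 2: "c", 3: "b", 4: "a"}
        k1 = ct.cohen_kappa(list(r1), list(r2))
        k2 = ct.cohen_kappa([relabel[v] for v in r1], [relabel[v] for v in r2])
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_degenerate_cases(self):
        assert ct.cohen_kappa(["A", "A"], ["A", "A"]) == 1.0
        with pytest.raises(ValueError):
            ct.cohen_kappa([], [])
        with pytest.raises(ValueError):
            ct.cohen_kappa(["A"], ["A", "B"])


class TestMetricReport:
    def _report(self):
        rng = np.random.default_rng(9)
        results = {}
        for method in (1, 2):
            crs = []
            for cid, n in (("c0", 3), ("c1", 2)):
                triples = [ct.MetricTriple(psnr=float(rng.uniform(20, 50)),
                                           mse=float(rng.uniform(1e-4, 1e-2)),
                                           ssim=float(rng.uniform(0.5, 1.0)))
                           for _ in range(n)]
                crs.append(CaseResult(case_id=cid, triples=triples))
            results[method] = crs
        return ct.metric_report(results)

    def test_single_slice_means_equal_triple(self):
        t = ct.MetricTriple(psnr=30.0, mse=1e-3, ssim=0.9)
        report = ct.metric_report({1: [CaseResult("c", [t])]})
        means = report.grand_means(1)["pooled"]
        assert (means["psnr"], means["mse"], means["ssim"]) == (30.0, 1e-3, 0.9)

    def test_pooled_vs_mean_of_case_means_both_reported(self):
        report = self._report()
        gm = report.grand_means(1)
        all_t = [t for cr in report.per_case[1] for t in cr.triples]
        assert gm["pooled"]["psnr"] == pytest.approx(
            np.mean([t.psnr for t in all_t]))
        case_means = [np.mean([t.psnr for t in cr.triples])
                      for cr in report.per_case[1]]
        assert gm["mean_of_case_means"]["psnr"] == pytest.approx(np.mean(case_means))

    def test_infinite_psnr_excluded_with_count(self):
        triples = [ct.MetricTriple(psnr=math.inf, mse=0.0, ssim=1.0),
                   ct.MetricTriple(psnr=40.0, mse=1e-4, ssim=0.9)]
        report = ct.metric_report({1: [CaseResult("c", triples)]})
        means = report.grand_means(1)["pooled"]
        assert means["psnr"] == 40.0
        assert means["psnr_inf_excluded"] == 1

    def test_json_round_trip_exact(self):
        report = self._report()
        back = ct.MetricReport.from_json(report.to_json())
        assert back.to_dict() == report.to_dict()

    def test_winner_counts_totals(self):
        report = self._report()
        total = report.total_winner_counts()
        n_slices = sum(len(cr.triples) for cr in report.per_case[1])
        for fam in ("psnr_mse", "ssim"):
            assert sum(total[fam].values()) == n_slices

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ct.metric_report({})
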