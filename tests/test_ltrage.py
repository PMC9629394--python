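"""LTR divergence counting, count models and enrichment scanning."""

import itertools
import math

import numpy as np
import pytest
from scipy import optimize, stats

from recsup import ltrage
from recsup.synth import make_ltr_element


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestAlignLtrs:
    def test_identical_fragments(self):
        rng = np.random.default_rng(0)
        s = _random_seq(rng, 150)
        assert ltrage.align_ltrs(s, s) == (0, 0, 150)

    def test_planted_substitutions_recovered(self):
        element, truth = make_ltr_element(200, 5, 0, seed=3, sub_region=(0, 150))
        l5 = element[slice(*truth["ltr5_span"])]
        l3 = element[slice(*truth["ltr3_span"])]
        k, events, _ = ltrage.align_ltrs(l5, l3)
        assert k == 5 and events == 5

    def test_gap_run_counts_one_event(self):
        rng = np.random.default_rng(7)
        a = _random_seq(rng, 160)
        b = list(a)
        for p in (20, 60, 100):  # 3 substitutions
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        del b[130:132]  # one 2-bp deletion = one event
        k, events, _ = ltrage.align_ltrs(a, "".join(b) + "AA", fragment=150)
        assert k == 3
        assert events == 4

    def test_short_ltr_raises(self):
        with pytest.raises(ValueError):
            ltrage.align_ltrs("ACGT" * 10, "ACGT" * 40)


class TestHistogram:
    def test_counts(self):
        els = [
            ltrage.LTRElement(str(i), "c", i, i + 1, (0, 1), (0, 1), k=k)
            for i, k in enumerate([0, 0, 5])
        ]
        d = ltrage.mismatch_histogram(els)
        assert d.counts == {0: 2, 5: 1}
        assert d.n_elements == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ltrage.mismatch_histogram([])

    def test_mixture_sample_mean_matches_expectation(self):
        rng = np.random.default_rng(11)
        lam, w, n = (2.0, 9.0), (0.4, 0.6), 500
        comp = rng.choice([0, 1], size=n, p=w)
        ks = rng.poisson(np.array(lam)[comp])
        els = [
            ltrage.LTRElement(str(i), "c", i, i + 1, (0, 1), (0, 1), k=int(k))
            for i, k in enumerate(ks)
        ]
        expect = sum(wi * li for wi, li in zip(w, lam))
        assert ltrage.mismatch_histogram(els).mean == pytest.approx(
            expect, rel=0.05
        )


def _hist_from_sample(sample):
    counts = {}
    for k in sample:
        counts[int(k)] = counts.get(int(k), 0) + 1
    return ltrage.MismatchDistribution(counts=dict(sorted(counts.items())))


class TestNbdFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        sample = stats.nbinom(2, 0.3).rvs(10_000, random_state=rng)
        r, p = ltrage.fit_nbd(_hist_from_sample(sample))
        assert 1.8 <= r <= 2.2

    def test_fitted_mean_equals_sample_mean(self):
        rng = np.random.default_rng(1)
        sample = stats.nbinom(3, 0.5).rvs(2_000, random_state=rng)
        d = _hist_from_sample(sample)
        r, p = ltrage.fit_nbd(d)
        assert r * (1 - p) / p == pytest.approx(d.mean, abs=1e-6)

    def test_equidispersed_fallback(self):
        r, _ = ltrage.fit_nbd(
            ltrage.MismatchDistribution(counts={2: 10})  # zero variance
        )
        assert math.isinf(r)


class TestGammaMode:
    def test_closed_form(self):
        shape, scale, mode = ltrage.gamma_mode_age(2.0, 0.25)
        assert shape == 2.0
        assert scale == pytest.approx(3.0)
        assert mode == pytest.approx(3.0)  # (shape - 1) * scale

    def test_shape_below_one_mode_zero(self):
        assert ltrage.gamma_mode_age(0.8, 0.5)[2] == 0.0

    def test_mode_matches_numeric_argmax(self):
        shape, scale = 5.0, 0.8
        p = scale / (1 + scale)  # invert scale = (1-p)/p
        _, _, mode = ltrage.gamma_mode_age(shape, 1 - p)
        res = optimize.minimize_scalar(
            lambda x: -stats.gamma(shape, scale=scale).pdf(x),
            bounds=(0.01, 50),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert mode == pytest.approx(3.2, abs=1e-9)
        assert mode == pytest.approx(res.x, abs=1e-6)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            ltrage.gamma_mode_age(-1.0, 0.5)


class TestPoissonMixture:
    def test_single_component_is_sample_mean(self):
        d = ltrage.MismatchDistribution(counts={0: 3, 2: 5, 7: 2})
        lam, w, _, _ = ltrage.fit_poisson_mixture(d, n_components=1)
        assert lam == [pytest.approx(d.mean)]
        assert w == [1.0]

    def test_two_component_recovery(self):
        rng = np.random.default_rng(5)
        comp = rng.choice([0, 1], size=5_000, p=[0.4, 0.6])
        sample = rng.poisson(np.where(comp == 0, 2.0, 9.0))
        lam, w, r2, trace = ltrage.fit_poisson_mixture(
            _hist_from_sample(sample), n_components=2, seed=5
        )
        assert lam[0] == pytest.approx(2.0, rel=0.15)
        assert lam[1] == pytest.approx(9.0, rel=0.15)
        assert w[0] == pytest.approx(0.4, abs=0.1)
        assert w[1] == pytest.approx(0.6, abs=0.1)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_perfect_histogram_gives_r2_one(self):
        lam, w = (2.0, 9.0), (0.4, 0.6)
        ks = np.arange(0, 25)
        pmf = w[0] * stats.poisson.pmf(ks, lam[0]) + w[1] * stats.poisson.pmf(
            ks, lam[1]
        )
        counts = {int(k): int(round(p * 1e6)) for k, p in zip(ks, pmf) if p * 1e6 >= 1}
        _, _, r2, _ = ltrage.fit_poisson_mixture(
            ltrage.MismatchDistribution(counts=counts), n_components=2, seed=0
        )
        assert r2 >= 0.999

    def test_bic_selection_prefers_two_for_bimodal(self):
        rng = np.random.default_rng(9)
        comp = rng.choice([0, 1], size=4_000, p=[0.4, 0.6])
        sample = rng.poisson(np.where(comp == 0, 2.0, 12.0))
        assert ltrage.select_n_components(_hist_from_sample(sample), seed=9) == 2


class TestClassifyAge:
    def _el(self, k):
        return ltrage.LTRElement("e", "c", 0, 1, (0, 1), (0, 1), k=k)

    def test_five_mismatches_is_1p28_myr(self):
        (el,) = ltrage.classify_age([self._el(5)], young_threshold=5)
        assert el.age_years == pytest.approx(1.282e6, rel=1e-3)
        assert el.age_class == "young"

    def test_zero_is_age_zero_young(self):
        (el,) = ltrage.classify_age([self._el(0)], young_threshold=5)
        assert el.age_years == 0.0 and el.age_class == "young"

    def test_six_is_old(self):
        (el,) = ltrage.classify_age([self._el(6)], young_threshold=5)
        assert el.age_class == "old"

    def test_age_scale_equivariance(self):
        (a,) = ltrage.classify_age([self._el(7)], 5, mu=1.3e-8)
        (b,) = ltrage.classify_age([self._el(7)], 5, mu=2.6e-8)
        assert a.age_years == pytest.approx(2 * b.age_years)

    def test_threshold_rounding(self):
        model = ltrage.DivergenceModel(
            nbd=(2, 0.5), gamma=(2, 1), gamma_mode=5.2,
            mixture=([2], [1.0], 1.0), young_threshold=0,
        )
        assert ltrage.threshold_from_model(model) == 5
        model.gamma_mode = 0.4
        assert ltrage.threshold_from_model(model) == 0


def _elements_with_classes(classes):
    els = []
    for i, c in enumerate(classes):
        e = ltrage.LTRElement(str(i), "c", i * 1000, i * 1000 + 800,
                              (0, 1), (0, 1))
        e.age_class = c
        els.append(e)
    return els


class TestEnrichment:
    def test_extreme_window_probability_exact(self):
        # 10 young of 30, window captures all 10: p = 1 / C(30, 10)
        els = _elements_with_classes(["young"] * 10 + ["old"] * 20)
        scan = ltrage.enrichment_scan(els, window=10)
        assert scan.windows[0]["p_over"] == pytest.approx(
            1 / math.comb(30, 10), rel=1e-9
        )

    def test_all_young_population_p_over_one(self):
        els = _elements_with_classes(["young"] * 15)
        scan = ltrage.enrichment_scan(els, window=10)
        assert all(w["p_over"] == pytest.approx(1.0) for w in scan.windows)

    def test_tail_identity(self):
        rng = np.random.default_rng(3)
        classes = ["young" if rng.random() < 0.3 else "old" for _ in range(40)]
        els = _elements_with_classes(classes)
        scan = ltrage.enrichment_scan(els, window=10)
        N, K = scan.n_total, scan.n_young
        hg = stats.hypergeom(N, K, 10)
        for w in scan.windows:
            k = w["n_young"]
            assert w["p_over"] + w["p_under"] == pytest.approx(
                1.0 + hg.pmf(k), rel=1e-9
            )

    def test_tails_match_exhaustive_enumeration(self):
        # brute force over all C(N, n) draws for a small population
        N, K, n = 11, 4, 5
        labels = [1] * K + [0] * (N - K)
        hg = stats.hypergeom(N, K, n)
        for k in range(0, n + 1):
            count_ge = count_le = 0
            total = 0
            for combo in itertools.combinations(range(N), n):
                s = sum(labels[i] for i in combo)
                total += 1
                count_ge += s >= k
                count_le += s <= k
            assert hg.sf(k - 1) == pytest.approx(count_ge / total, rel=1e-9)
            assert hg.cdf(k) == pytest.approx(count_le / total, rel=1e-9)

    def test_fewer_than_window_empty_scan(self):
        els = _elements_with_classes(["young"] * 4)
        assert ltrage.enrichment_scan(els, window=10).windows == []


class TestGff3RoundTrip:
    def test_truth_gff_parses(self, demo_pair, tmp_path):
        paths = demo_pair.write(tmp_path / "out")
        els = ltrage.read_gff3_elements(paths["elements.gff3"])
        assert len(els) == len(demo_pair.elements)
        truth = {e["id"]: e for e in demo_pair.elements}
        for el in els:
            assert el.ltr5 == truth[el.id]["ltr5_span"]
            assert el.ltr3 == truth[el.id]["ltr3_span"]
            assert el.k == truth[el.id]["k"]
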