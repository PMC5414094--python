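import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from chipwin.genome import GenomeBuild
from chipwin.peaks import (
    PoissonWindowModel,
    WindowTest,
    call_peaks,
    estimate_fdr_swap,
    poisson_upper_tail,
    window_lambda,
)
from chipwin.peaks import test_windows as poisson_test_windows
from chipwin.windows import WindowTrack


def summed_pmf_upper_tail(k, lam):
    """Independent oracle: P(X >= k) by direct pmf summation to convergence."""
    # pmf(0), then the recurrence pmf(i) = pmf(i-1) * lam / i
    term = math.exp(-lam)
    for i in range(1, k):
        term *= lam / i
    total = 0.0
    i = k
    if k > 0:
        term *= lam / k
    while True:
        total += term
        i += 1
        term *= lam / i
        if term < total * 1e-16 + 1e-320:
            break
    return total


class TestPoissonUpperTail:
    def test_k_zero_is_one(self):
        assert poisson_upper_tail(0, 0.01) == 1.0
        assert poisson_upper_tail(0, 100.0) == 1.0

    def test_k3_lambda1_matches_closed_form(self):
        # 1 - e^-1 (1 + 1 + 1/2)
        assert poisson_upper_tail(3, 1.0) == pytest.approx(0.0803014, abs=5e-8)

    def test_k10_lambda1_matches_pmf_oracle(self):
        assert poisson_upper_tail(10, 1.0) == pytest.approx(
            summed_pmf_upper_tail(10, 1.0), rel=1e-9
        )
        assert poisson_upper_tail(10, 1.0) == pytest.approx(1.11e-7, rel=5e-3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(3, 0.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 1.0)


class TestWindowLambda:
    def test_equal_libraries_pass_input_through(self):
        assert window_lambda(10, 1000, 1000, genome_background=0.5) == 10

    def test_zero_input_floored(self):
        lam = window_lambda(0, 1000, 1000, genome_background=0.1, lambda_floor=0.25)
        assert lam == 0.25 > 0

    def test_library_scaling_is_linear(self):
        assert window_lambda(5, 2000, 1000, genome_background=0.5) == 10

    def test_zero_input_library_rejected(self):
        with pytest.raises(ValueError):
            window_lambda(1, 100, 0, genome_background=0.1)


def _tracks(chip_counts, input_counts, window_size=100):
    n = len(chip_counts)
    genome = GenomeBuild((("c", n * window_size),))
    return (
        WindowTrack(genome, window_size, {"c": np.array(chip_counts)},
                    int(np.sum(chip_counts)), "chip"),
        WindowTrack(genome, window_size, {"c": np.array(input_counts)},
                    int(np.sum(input_counts)), "input"),
    )


class TestTestWindows:
    def test_zero_chip_never_significant(self):
        chip, inp = _tracks([0] * 10, [5] * 10)
        chip = WindowTrack(chip.genome, 100, chip.counts, 50, "chip")  # nonzero lib
        tests = poisson_test_windows(chip, inp)
        assert all(t.p_value == 1.0 and not t.significant for t in tests)

    def test_threshold_is_strict_inequality(self):
        chip, inp = _tracks([3] + [1] * 9, [1] * 10)
        # expectation by the documented rule: max(scaled input, background, floor)
        lam = max(1 * 12 / 10, 12 * 100 / 1000, 0.25)
        p_exact = float(stats.poisson.sf(2, lam))  # p for chip_count=3
        at = poisson_test_windows(chip, inp, alpha=p_exact)[0]
        assert at.p_value == p_exact and not at.significant
        above = poisson_test_windows(chip, inp, alpha=np.nextafter(p_exact, 1))[0]
        assert above.significant

    def test_significant_window_detected(self):
        chip, inp = _tracks([20] + [1] * 9, [1] * 10)
        tests = poisson_test_windows(chip, inp, alpha=1e-3)
        assert tests[0].significant and not any(t.significant for t in tests[1:])

    def test_mismatched_grids_rejected(self):
        chip, _ = _tracks([1] * 10, [1] * 10)
        _, inp = _tracks([1] * 5, [1] * 5)
        with pytest.raises(ValueError):
            poisson_test_windows(chip, inp)


def _fake_tests(sig_vector, chip_counts=None):
    chip_counts = chip_counts or [10] * len(sig_vector)
    return [
        WindowTest("c", w, chip_counts[w], 1, 1.0,
                   1e-5 if s else 0.5, bool(s))
        for w, s in enumerate(sig_vector)
    ]


def brute_force_runs(sig, min_run=2):
    """Oracle: enumerate maximal runs of consecutive significant windows."""
    runs, cur = [], []
    for i, s in enumerate(sig):
        if s:
            cur.append(i)
        else:
            if len(cur) >= min_run:
                runs.append((cur[0], cur[-1] + 1))
            cur = []
    if len(cur) >= min_run:
        runs.append((cur[0], cur[-1] + 1))
    return runs


class TestCallPeaks:
    GENOME = GenomeBuild((("c", 5000),))

    def _call(self, sig, **kw):
        return call_peaks(_fake_tests(sig), self.GENOME, 100, **kw)

    def test_two_runs_found(self):
        peaks = self._call([1, 0, 1, 1, 0, 1, 1, 1])
        assert [(p.start, p.end) for p in peaks] == [(200, 400), (500, 800)]
        assert [p.n_windows for p in peaks] == [2, 3]

    def test_isolated_windows_discarded(self):
        assert len(self._call([1, 0, 1, 0, 1])) == 0

    def test_all_significant_is_one_peak(self):
        peaks = self._call([1] * 8)
        assert len(peaks) == 1 and peaks.peaks[0].n_windows == 8

    def test_summit_is_max_chip_window_midpoint(self):
        tests = _fake_tests([0, 1, 1, 1, 0], chip_counts=[0, 5, 9, 5, 0])
        (peak,) = call_peaks(tests, self.GENOME, 100)
        assert peak.summit == 250 and peak.max_chip_count == 9

    def test_flanked_rule_requires_both_neighbours(self):
        peaks = self._call([1, 1, 0, 1, 1, 1], rule="flanked")
        # only window 4 has significant neighbours on both sides
        assert [(p.start, p.end) for p in peaks] == [(400, 500)]

    @given(st.lists(st.booleans(), min_size=1, max_size=50),
           st.integers(1, 4))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_brute_force_enumeration(self, sig, min_run):
        peaks = self._call_any_len(sig, min_run)
        expected = brute_force_runs(sig, min_run)
        assert [(p.start // 100, p.end // 100) for p in peaks] == expected

    def _call_any_len(self, sig, min_run):
        genome = GenomeBuild((("c", len(sig) * 100),))
        return call_peaks(_fake_tests(sig), genome, 100, min_run=min_run)


class TestFdrAndModel:
    def _spiked(self, rng):
        n = 400
        base = rng.poisson(5.0, n)
        chip = base + 0
        chip = rng.poisson(5.0, n)
        for s in (50, 150, 250):
            chip[s:s + 5] = rng.poisson(50.0, 5)
        inp = rng.poisson(5.0, n)
        return _tracks(chip.tolist(), inp.tolist())

    def test_identical_tracks_give_fdr_one(self, rng):
        counts = rng.poisson(5.0, 200)
        for s in (20, 120):
            counts[s:s + 4] = 60
        chip, _ = _tracks(counts.tolist(), counts.tolist())
        inp = WindowTrack(chip.genome, 100, {"c": counts.copy()},
                          int(counts.sum()), "input")
        est = estimate_fdr_swap(chip, inp)
        if est.n_forward:
            assert est.fdr == 1.0

    def test_spiked_chip_flat_input_gives_low_fdr(self, rng):
        chip, inp = self._spiked(rng)
        est = estimate_fdr_swap(chip, inp)
        assert est.n_forward >= 3 and est.fdr == 0.0

    def test_no_forward_peaks_flagged(self):
        chip, inp = _tracks([1] * 50, [1] * 50)
        est = estimate_fdr_swap(chip, inp)
        assert est.n_forward == 0 and est.fdr == 0.0 and est.zero_denominator

    def test_lowering_alpha_never_adds_peaks(self, rng):
        chip, inp = self._spiked(rng)
        alphas = [1e-1, 1e-2, 1e-3, 1e-5]
        counts = [
            len(PoissonWindowModel(chip, inp, alpha=a).fit(estimate_fdr=False).peaks)
            for a in alphas
        ]
        assert counts == sorted(counts, reverse=True)

    def test_raising_one_count_never_raises_its_pvalue(self):
        chip, inp = _tracks([5] * 10, [5] * 10)
        p0 = poisson_test_windows(chip, inp)[0].p_value
        bumped = chip.counts["c"].copy()
        bumped[0] += 3
        chip2 = WindowTrack(chip.genome, 100, {"c": bumped}, chip.library_size, "chip")
        assert poisson_test_windows(chip2, inp)[0].p_value <= p0

    def test_model_summary_reports_key_quantities(self, rng):
        chip, inp = self._spiked(rng)
        res = PoissonWindowModel(chip, inp).fit()
        text = res.summary()
        assert "Peaks called" in text and "Swap FDR" in text
        assert res.peaks.fdr_estimate == res.fdr.fdr

    def test_peak_bed_roundtrip(self, rng, tmp_path):
        from chipwin.peaks import PeakSet
        chip, inp = self._spiked(rng)
        res = PoissonWindowModel(chip, inp).fit(estimate_fdr=False)
        path = tmp_path / "peaks.bed"
        res.to_bed(path)
        back = PeakSet.from_bed(path)
        assert [(p.chrom, p.start, p.end) for p in back] == [
            (p.chrom, p.start, p.end) for p in res.peaks
        ]
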