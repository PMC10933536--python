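"""Call rates, silence, bout-criterion MLE, bout segmentation, exchanges."""
import numpy as np
import pytest

from callerid.vocal import (
    AnalysisPeriod,
    DegenerateMixtureError,
    InsufficientDataError,
    InvalidPeriodError,
    bout_end_criterion,
    call_rate,
    exchange_auc,
    fit_bout_model,
    ici_series,
    inter_individual_icis,
    segment_bouts,
    silence_stats,
)


def period(minutes, group="g"):
    return AnalysisPeriod(group, 0.0, minutes * 60.0)


class TestCallRate:
    @pytest.mark.parametrize(
        "n,minutes,expected",
        [(20, 88, 13.6), (46, 31, 89.0), (0, 300, 0.0)],
    )
    def test_rates(self, n, minutes, expected):
        assert call_rate(n, period(minutes)) == expected

    def test_zero_duration_period(self):
        with pytest.raises(InvalidPeriodError):
            AnalysisPeriod("g", 10.0, 10.0)


def brute_silence(spans, t0, t1, step=None):
    """Independent oracle: endpoint sweep over the union of spans."""
    events = []
    for s, e in spans:
        s, e = max(s, t0), min(e, t1)
        if e > s:
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    gaps = []
    depth = 0
    cursor = t0
    occupied = 0.0
    for t, d in events:
        if depth == 0 and t > cursor:
            gaps.append(t - cursor)
        if depth > 0:
            occupied += t - cursor
        cursor = t
        depth += d
    if cursor < t1:
        gaps.append(t1 - cursor)
    return (t1 - t0 - occupied) / (t1 - t0), (max(gaps) if gaps else 0.0)


class TestSilence:
    def test_no_detections(self):
        assert silence_stats([], period(10)) == (1.0, 600.0)

    def test_single_call(self):
        p = AnalysisPeriod("g", 0.0, 100.0)
        prop, longest = silence_stats([(10.0, 12.0)], p)
        assert prop == pytest.approx(0.98)
        assert longest == pytest.approx(88.0)

    def test_abutting_calls_merge(self):
        p = AnalysisPeriod("g", 0.0, 100.0)
        prop, longest = silence_stats([(10.0, 12.0), (12.0, 14.0)], p)
        assert prop == pytest.approx(0.96)
        assert longest == pytest.approx(86.0)

    def test_random_instances_match_oracle(self, rng):
        p = AnalysisPeriod("g", 0.0, 200.0)
        for _ in range(100):
            spans = [
                (t, t + rng.uniform(0.1, 20.0))
                for t in rng.uniform(-10, 210, rng.integers(0, 15))
            ]
            got = silence_stats(spans, p)
            exp = brute_silence(spans, 0.0, 200.0)
            assert got[0] == pytest.approx(exp[0], abs=1e-9)
            assert got[1] == pytest.approx(exp[1], abs=1e-9)


class TestICISeries:
    def test_basic(self):
        assert np.allclose(ici_series([0, 1.5, 3.0, 60]), [1.5, 1.5, 57])

    def test_single_call_empty(self):
        assert ici_series([5.0]).size == 0

    def test_duplicate_starts_dropped(self):
        assert np.allclose(ici_series([0.0, 0.0, 2.0]), [2.0])


class TestBoutModel:
    TRUE = dict(p=0.75, lf=0.5, ls=0.01)

    def _sample(self, rng, n):
        fast = rng.random(n) < self.TRUE["p"]
        return np.where(
            fast,
            rng.exponential(1 / self.TRUE["lf"], n),
            rng.exponential(1 / self.TRUE["ls"], n),
        )

    def test_parameter_recovery(self, rng):
        """BEC of the fitted mixture within 15% of the closed-form truth."""
        true_bec = bout_end_criterion(0.75, 0.5, 0.01)  # = ln(150)/0.49
        assert true_bec == pytest.approx(10.226, abs=0.01)
        m = fit_bout_model(self._sample(rng, 1000))
        assert m.bec == pytest.approx(true_bec, rel=0.15)
        assert m.lambda_fast == pytest.approx(0.5, rel=0.2)
        assert m.lambda_slow == pytest.approx(0.01, rel=0.2)

    def test_pure_exponential_degenerate(self, rng):
        with pytest.raises(DegenerateMixtureError):
            fit_bout_model(rng.exponential(5.0, 500))

    def test_order_invariance(self, rng):
        x = self._sample(rng, 500)
        m1 = fit_bout_model(x)
        m2 = fit_bout_model(np.random.default_rng(0).permutation(x))
        assert m1.bec == pytest.approx(m2.bec, rel=1e-6)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            fit_bout_model([1.0] * 10)


def brute_bouts(times, bec):
    """Independent oracle: link flags + run lengths via groupby."""
    import itertools

    times = sorted(times)
    links = [times[i] - times[i - 1] < bec for i in range(1, len(times))]
    bouts = []
    i = 0
    for flag, grp in itertools.groupby(links):
        L = len(list(grp))
        if flag:
            bouts.append(L + 1)  # L links -> L+1 calls
        i += L
    return bouts


class TestBouts:
    def test_worked_example(self):
        """BEC 2.2 s splits [0,1.5,3.0,60,61,200] into two bouts."""
        bouts, summary = segment_bouts({"w": [0, 1.5, 3.0, 60, 61, 200]}, bec=2.2)
        assert [b.n_calls for b in bouts] == [3, 2]
        row = summary.iloc[0]
        assert row["n_bouts"] == 2
        assert row["mean_calls_per_bout"] == pytest.approx(2.5)
        assert row["frac_in_bouts"] == pytest.approx(5 / 6)

    def test_bout_rate(self):
        """7 bouts in 31 minutes -> 13.5 bouts/h."""
        times = [k * 200.0 + d for k in range(7) for d in (0.0, 1.0)]
        _, summary = segment_bouts({"w": times}, bec=2.2, period=period(31))
        assert summary.iloc[0]["bout_rate"] == 13.5

    def test_no_bouts_when_all_slow(self):
        bouts, summary = segment_bouts({"w": [0, 10, 20, 30]}, bec=2.2)
        assert not bouts
        assert summary.iloc[0]["frac_in_bouts"] == 0.0

    def test_counting_conservation(self, rng):
        """Calls in bouts plus singleton calls equal total calls."""
        for _ in range(100):
            times = np.cumsum(rng.exponential(3.0, rng.integers(2, 60)))
            bouts, summary = segment_bouts({"w": times}, bec=2.2)
            in_bouts = sum(b.n_calls for b in bouts)
            assert in_bouts + (times.size - in_bouts) == summary.iloc[0]["n_calls"]
            assert [b.n_calls for b in bouts] == brute_bouts(times, 2.2)


def brute_cross_icis(times_by_whale):
    """Independent oracle: min over all later calls by other whales."""
    events = [(t, w) for w, ts in times_by_whale.items() for t in ts]
    out = []
    for t, w in events:
        later = [t2 - t for t2, w2 in events if w2 != w and t2 > t]
        if later:
            out.append(min(later))
    return sorted(out)


class TestExchanges:
    def test_alternating_example(self):
        got = inter_individual_icis({"A": [0, 100, 200], "B": [50, 150, 250]})
        assert np.allclose(sorted(got), [50] * 5)

    def test_two_calls(self):
        assert np.allclose(inter_individual_icis({"A": [0.0], "B": [30.0]}), [30.0])

    def test_one_vocal_whale_raises(self):
        with pytest.raises(InsufficientDataError):
            inter_individual_icis({"A": [1.0, 2.0], "B": []})

    def test_random_instances_match_oracle(self, rng):
        for _ in range(100):
            tbw = {
                w: sorted(rng.uniform(0, 500, rng.integers(1, 20)))
                for w in ("A", "B", "C")
            }
            got = sorted(inter_individual_icis(tbw))
            assert np.allclose(got, brute_cross_icis(tbw))

    def test_auc_constant_intervals(self):
        auc, prop = exchange_auc([50.0] * 20, horizon=100.0)
        assert prop == 1.0 and auc == 1.0
        _, prop2 = exchange_auc([150.0] * 20, horizon=100.0)
        assert prop2 == 0.0

    def test_auc_uniform_law(self, rng):
        """Uniform [0,200] intervals: about half fall within 100 s, and the
        KDE integral agrees with the empirical proportion."""
        x = rng.uniform(0, 200, 2000)
        auc, prop = exchange_auc(x, horizon=100.0)
        assert prop == pytest.approx(0.5, abs=0.03)
        assert abs(auc - prop) < 0.05

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            exchange_auc([1.0, 2.0], horizon=100.0)
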