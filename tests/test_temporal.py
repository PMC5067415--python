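"""Temporal models, instantaneous distributions, expectation profiles,
loud rests and entrainment."""

import numpy as np
import pytest

from idyot import (
    Symbol,
    TimeGrid,
    detect_loud_rests,
    entrain,
    expectation_profile,
    gen_renewal_stream,
    instantaneous_distribution,
    iso_onsets,
    observe_timing,
    profile_period,
    surprisal_trace,
    temporal_distribution,
    train_transitions,
)
from idyot.chunking import HierarchicalMemory, Level
from idyot.errors import StreamError
from idyot.temporal import ExpectationProfile, renewal_onset_mass

from conftest import syms


def timed(tokens: str, onsets, viewpoint="t"):
    return syms(tokens, viewpoint), list(onsets)


class TestObserveTiming:
    def test_degenerate_iois_give_point_mass(self):
        s, o = timed("a a a a a", range(0, 2500, 500))
        m = train_transitions([s])
        tm = observe_timing(m, [(s, o)], TimeGrid(20, 1000))
        td = temporal_distribution(tm, s[:1], s[0])
        assert td.mode_ms == 500
        assert td.density[td.mode_bin] == 1.0

    def test_two_equal_modes(self):
        onsets = [0]
        for i in range(40):
            onsets.append(onsets[-1] + (400 if i % 2 == 0 else 600))
        s = [Symbol("a", 0, "t")] * len(onsets)
        m = train_transitions([s])
        tm = observe_timing(m, [(s, onsets)], TimeGrid(20, 1000))
        td = temporal_distribution(tm, s[:1], s[0])
        assert td.density[400 // 20] == pytest.approx(0.5)
        assert td.density[600 // 20] == pytest.approx(0.5)

    def test_symmetric_data_gives_symmetric_density(self):
        centre = 500
        offs = [-60, -40, -20, 0, 20, 40, 60]
        onsets = [0]
        for i in range(140):
            onsets.append(onsets[-1] + centre + offs[i % len(offs)])
        s = [Symbol("a", 0, "t")] * len(onsets)
        m = train_transitions([s])
        tm = observe_timing(m, [(s, onsets)], TimeGrid(20, 1000))
        d = temporal_distribution(tm, s[:1], s[0]).density
        lo, hi = (centre - 60) // 20, (centre + 60) // 20
        window = d[lo : hi + 1]
        assert np.allclose(window, window[::-1], atol=1e-9)

    def test_decreasing_onsets_rejected(self):
        s, o = timed("a a", [100, 50])
        m = train_transitions([s])
        with pytest.raises(StreamError):
            observe_timing(m, [(s, o)], TimeGrid(20, 1000))

    def test_unseen_pair_uniform_or_error(self):
        s, o = timed("a a", [0, 500])
        m = train_transitions([s])
        tm = observe_timing(m, [(s, o)], TimeGrid(20, 1000))
        b = Symbol("b", 0, "t")
        with pytest.raises(KeyError):
            temporal_distribution(tm, s[:1], b)
        td = temporal_distribution(tm, s[:1], b, epsilon=1e-6)
        assert np.allclose(td.density, 1.0 / tm.grid.n_bins)


class TestInstantaneous:
    def _two_symbol_model(self):
        """alpha always arrives ~300 ms after context, beta ~700 ms."""
        a, b, x = (Symbol(i, 0, "t") for i in "abx")
        streams = []
        for sym, ioi in ((a, 300), (b, 700)):
            ss = [x, sym] * 30
            oo = [0]
            for i in range(1, len(ss)):
                oo.append(oo[-1] + (ioi if ss[i] is sym else 1000 - ioi))
            streams.append((ss, oo))
        m = train_transitions([s for s, _ in streams], smoothing_k=0)
        tm = observe_timing(m, streams, TimeGrid(20, 2000))
        return m, tm, a, b, x

    def test_disjoint_support_resolves_to_certainty(self):
        m, tm, a, b, x = self._two_symbol_model()
        d = instantaneous_distribution(tm, m, (x,), 300)
        assert d.mass(a) == pytest.approx(1.0)
        d = instantaneous_distribution(tm, m, (x,), 700)
        assert d.mass(b) == pytest.approx(1.0)

    def test_product_and_renormalize_oracle(self):
        """Three symbols with hand-set timing; probe times checked against
        an independently computed product-then-renormalize."""
        x = Symbol("x", 0, "t")
        alphas = {"al": 200, "be": 400, "ga": 600}
        streams = []
        weights = {"al": 3, "be": 2, "ga": 1}
        for name, ioi in alphas.items():
            s = Symbol(name, 0, "t")
            for _ in range(weights[name]):
                ss = [x, s] * 10
                oo = [0]
                for i in range(1, len(ss)):
                    oo.append(oo[-1] + (ioi if ss[i] is s else 1000 - ioi))
                streams.append((ss, oo))
        m = train_transitions([s for s, _ in streams], smoothing_k=0)
        tm = observe_timing(m, streams, TimeGrid(20, 2000))
        eps = 1e-6
        n = tm.grid.n_bins
        for probe in (200, 400, 600):
            d = instantaneous_distribution(tm, m, (x,), probe, epsilon=eps)
            # oracle: P(s|x) is weight-proportional; density is a point mass
            # smoothed with the same epsilon floor
            raw = {}
            for name, ioi in alphas.items():
                p = weights[name] / sum(weights.values())
                dens = (1.0 if ioi == probe else 0.0)
                dens = (dens + eps) / (1 + eps * n)
                raw[name] = p * dens
            z = sum(raw.values())
            for name in alphas:
                assert d.mass(Symbol(name, 0, "t")) == pytest.approx(
                    raw[name] / z, rel=1e-9
                )

    def test_incremental_lexical_disambiguation(self):
        """With two continuations whose /k/ differs only in timing, the
        posterior flips toward the word whose /k/ onset matches: the /k/
        closing 'bank' is expected earlier than the /k/ opening 'catching'."""
        ctx = Symbol("ban", 0, "ph")
        k = Symbol("k", 0, "ph")
        streams = []
        # 'bank': /k/ closes the syllable ~80 ms after /ban/
        for _ in range(10):
            streams.append(([ctx, k], [0, 80]))
        # 'bang catching': /k/ starts the next word ~400 ms later
        for _ in range(10):
            streams.append(([ctx, k], [0, 400]))
        m = train_transitions([s for s, _ in streams], smoothing_k=0)
        tm = observe_timing(m, streams, TimeGrid(20, 1000))
        td = temporal_distribution(tm, (ctx,), k)
        early, late = td.density[80 // 20], td.density[400 // 20]
        assert early == pytest.approx(0.5) and late == pytest.approx(0.5)
        # the early bin supports the 'bank' reading, the late bin 'catching'
        assert td.density[80 // 20] > td.density[200 // 20]

    def test_negative_probe_rejected(self):
        m, tm, a, b, x = self._two_symbol_model()
        with pytest.raises(ValueError):
            instantaneous_distribution(tm, m, (x,), -1)


def periodic_memory(periods_ms, n=60, quantum=20):
    """A hand-built memory whose level k emits one symbol every periods[k] ms."""
    mem = HierarchicalMemory(max_depth=len(periods_ms) - 1, max_alphabet=16)
    for k, period in enumerate(periods_ms):
        s = Symbol(f"L{k}", k, "t")
        stream = [s] * n
        onsets = [i * period for i in range(n)]
        model = train_transitions([stream], smoothing_k=0)
        mem.levels.append(Level(streams=[stream], model=model, onsets=[onsets]))
    return mem


class TestExpectationProfile:
    def test_single_level_equals_combined(self):
        mem = periodic_memory([500])
        tms = {
            0: observe_timing(
                mem.levels[0].model,
                [(mem.levels[0].streams[0], mem.levels[0].onsets[0])],
                TimeGrid(20, 2000),
            )
        }
        prof = expectation_profile(mem, tms, 2000, anchor_ms=5000)
        assert np.array_equal(prof.combined, prof.per_level[0])

    def test_two_periodic_levels_superpose_additively(self):
        """Periods of 2 and 4 quanta with unit mass per expected onset:
        strength 2 at multiples of 4, 1 at other even bins, 0 at odd."""
        mem = periodic_memory([40, 80])
        grid = TimeGrid(20, 2000)
        tms = {
            k: observe_timing(
                mem.levels[k].model,
                [(mem.levels[k].streams[0], mem.levels[k].onsets[0])],
                grid,
            )
            for k in (0, 1)
        }
        prof = expectation_profile(mem, tms, 400, anchor_ms=1600)
        c = prof.combined
        for b in range(1, 20):
            if b % 4 == 0:
                assert c[b] == pytest.approx(2.0)
            elif b % 2 == 0:
                assert c[b] == pytest.approx(1.0)
            else:
                assert c[b] == pytest.approx(0.0)

    def test_combined_is_exact_per_level_sum(self):
        mem = periodic_memory([40, 80, 160])
        grid = TimeGrid(20, 2000)
        tms = {
            k: observe_timing(
                mem.levels[k].model,
                [(mem.levels[k].streams[0], mem.levels[k].onsets[0])],
                grid,
            )
            for k in range(3)
        }
        prof = expectation_profile(mem, tms, 800, anchor_ms=2000)
        total = sum(prof.per_level.values())
        assert np.array_equal(prof.combined, total)

    def test_missing_temporal_model_skips_level(self, caplog):
        mem = periodic_memory([40, 80])
        grid = TimeGrid(20, 2000)
        tms = {
            0: observe_timing(
                mem.levels[0].model,
                [(mem.levels[0].streams[0], mem.levels[0].onsets[0])],
                grid,
            )
        }
        prof = expectation_profile(mem, tms, 400, anchor_ms=1600)
        assert set(prof.per_level) == {0}

    def test_renewal_mass_of_deterministic_period(self):
        s = Symbol("a", 0, "t")
        stream, onsets = [s] * 50, [i * 100 for i in range(50)]
        m = train_transitions([stream], smoothing_k=0)
        tm = observe_timing(m, [(stream, onsets)], TimeGrid(20, 1000))
        mass = renewal_onset_mass(m, tm, (s,), 26)
        for b in range(1, 26):
            assert mass[b] == pytest.approx(1.0 if b % 5 == 0 else 0.0)


class TestRenewalRecovery:
    def test_mode_and_tv_against_generator(self):
        syms_, onsets, truth = gen_renewal_stream(500, seed=3)
        m = train_transitions([syms_], smoothing_k=0)
        tm = observe_timing(m, [(syms_, onsets)], TimeGrid(20, 1000))
        tvs, ws = [], []
        for (a, b), pmf in truth["iois"].items():
            td = temporal_distribution(tm, (a,), b)
            true = np.zeros(tm.grid.n_bins)
            for t, p in pmf.items():
                true[t // 20] += p
            assert abs(td.mode_bin - int(np.argmax(true))) <= 1
            tvs.append(0.5 * np.abs(td.density - true).sum())
            ws.append(tm.lookup((a,), b).sum())
        assert np.average(tvs, weights=ws) <= 0.1


class TestLoudRests:
    def _uniform_profile(self, strengths):
        grid = TimeGrid(20, 20 * len(strengths))
        return ExpectationProfile(
            grid=grid, per_level={0: np.asarray(strengths, dtype=float)}
        )

    def test_fully_realized_stream_unflagged(self):
        prof = self._uniform_profile([0, 1, 1, 1, 1, 1])
        onsets = [20 * b for b in range(6)]
        assert detect_loud_rests(prof, onsets, strength_threshold=0.5) == []

    def test_single_omission_flagged_exactly(self):
        prof = self._uniform_profile([0, 1, 1, 1, 1, 1, 1, 1])
        onsets = [20 * b for b in range(8) if b != 4]
        assert detect_loud_rests(prof, onsets, strength_threshold=0.5) == [4]

    def test_translation_invariance(self):
        prof = self._uniform_profile([0, 1, 1, 1, 1, 1, 1, 1])
        base = [20 * b for b in range(8) if b != 5]
        shifted = [o + 40_000 for o in base]
        assert detect_loud_rests(prof, base) == detect_loud_rests(
            prof, shifted, anchor_ms=40_000
        )

    def test_nonpositive_threshold_rejected(self):
        prof = self._uniform_profile([0, 1, 1])
        with pytest.raises(ValueError):
            detect_loud_rests(prof, [0, 20], strength_threshold=0.0)


class TestEntrainment:
    def test_phase_error_contracts_by_one_minus_gain(self):
        onsets = iso_onsets(500, 12)
        for gain in (0.3, 0.5, 1.0):
            rec = entrain(None, onsets, gain, initial_phase_ms=100.0)
            closed = [100.0 * (1 - gain) ** k for k in range(len(rec.phase_errors_ms))]
            assert np.allclose(rec.phase_errors_ms, closed)

    def test_converges_within_eight_events_at_half_gain(self):
        rec = entrain(None, iso_onsets(500, 12), 0.5, initial_phase_ms=100.0)
        assert all(abs(e) < 20 for e in rec.phase_errors_ms[7:])
        assert any(abs(e) < 20 for e in rec.phase_errors_ms[:8])

    def test_zero_gain_tracks_drift_uncorrected(self):
        drift = [int(500 * i + 0.5 * i * i) for i in range(12)]
        rec = entrain(500.0, drift, gain=0.0)
        errs = np.abs(rec.phase_errors_ms)
        assert errs[-1] > errs[0]  # no convergence under drift

    def test_gain_bounds_enforced(self):
        with pytest.raises(ValueError):
            entrain(None, iso_onsets(500, 5), 1.5)
        with pytest.raises(ValueError):
            entrain(None, iso_onsets(500, 5), -0.1)

    def test_needs_two_onsets_before_first_tap(self):
        with pytest.raises(ValueError):
            entrain(None, [0, 500], 0.5)

    def test_period_from_profile(self):
        strengths = np.zeros(100)
        strengths[25] = strengths[50] = strengths[75] = 1.0
        prof = ExpectationProfile(
            grid=TimeGrid(20, 2000), per_level={0: strengths}
        )
        assert profile_period(prof) == 500


class TestSurprisalTrace:
    def test_spikes_at_unseen_timing(self):
        a = Symbol("a", 0, "t")
        stream, onsets = [a] * 40, [i * 500 for i in range(40)]
        m = train_transitions([stream], smoothing_k=1.0)
        tm = observe_timing(m, [(stream, onsets)], TimeGrid(20, 2000))
        odd = list(onsets)
        odd[20:] = [o - 300 for o in odd[20:]]  # one shortened cycle
        trace = surprisal_trace(m, tm, stream, odd)
        assert int(np.argmax(trace)) == 20
        assert trace[20] > trace[1:20].mean() + 6
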