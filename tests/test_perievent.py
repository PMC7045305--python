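"""Trial selection, peri-event tensors, and responder classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vppipe import perievent, synth
from vppipe.types import BehaviorSession, KernelParams, PeriEventTensor, TraceSet


def _session(session_type, pokes, cued=None):
    cued = [False] * len(pokes) if cued is None else cued
    df = pd.DataFrame(
        {"time_s": list(pokes), "event": ["active_poke"] * len(pokes), "cued": cued}
    )
    return BehaviorSession(events=df, session_type=session_type, duration_s=7200.0)


def _tensor(avg_traces, fs=15.0, window=(-10.0, 20.0)):
    """Tensor with one trial per cell equal to the given average trace."""
    values = np.asarray(avg_traces, dtype=float)[:, None, :]
    nb = values.shape[2]
    return PeriEventTensor(
        values=values,
        bin_times=window[0] + np.arange(nb) / fs,
        trial_times=np.array([0.0]),
        session_type="Ext1",
    )


class TestSelectTrials:
    def test_extinction_separation_rule(self):
        session = _session("Ext1", [0.0, 10.0, 40.0])
        assert perievent.select_trials(session).tolist() == [40.0]

    def test_reinstatement_keeps_only_cued_pokes(self):
        session = _session("Reinst", [100.0, 105.0], cued=[True, False])
        assert perievent.select_trials(session).tolist() == [100.0]

    def test_single_poke_survives(self):
        assert perievent.select_trials(_session("Ext10", [500.0])).tolist() == [500.0]

    def test_trials_limited_to_first_hour(self):
        session = _session("Ext1", [100.0, 3700.0])
        assert perievent.select_trials(session).tolist() == [100.0]

    @given(st.permutations(list(range(6))))
    def test_row_order_invariance(self, order):
        pokes = [0.0, 10.0, 40.0, 100.0, 115.0, 200.0]
        df = pd.DataFrame(
            {
                "time_s": [pokes[i] for i in order],
                "event": ["active_poke"] * 6,
                "cued": [False] * 6,
            }
        )
        shuffled = BehaviorSession(events=df, session_type="Ext1", duration_s=7200.0)
        baseline = perievent.select_trials(_session("Ext1", pokes))
        assert perievent.select_trials(shuffled).tolist() == baseline.tolist()

    def test_brute_force_equivalence_on_random_sessions(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pokes = np.sort(rng.uniform(0, 4000, size=rng.integers(1, 40)))
            selected = perievent.select_trials(_session("Ext1", pokes))
            brute = [
                t
                for i, t in enumerate(pokes)
                if t < 3600.0
                and all(abs(t - u) >= 20.0 for j, u in enumerate(pokes) if j != i)
            ]
            assert selected.tolist() == brute


class TestBuildPerievent:
    def test_windowed_segments_are_z_normalized(self):
        traces, _ = synth.gen_traces(3, 300.0, 2.0, KernelParams(), snr=8, seed=5)
        tensor = perievent.build_perievent(traces, np.array([50.0, 100.0, 200.0]))
        for ci in range(3):
            for ti in range(3):
                seg = tensor.values[ci, ti]
                assert abs(seg.mean()) < 1e-9
                assert seg.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_trace_dropped_with_warning(self):
        traces = TraceSet(np.ones((1, 4500)), 15.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            tensor = perievent.build_perievent(traces, np.array([100.0]))
        assert np.isnan(tensor.values).all()

    def test_partial_windows_dropped(self):
        traces = TraceSet(np.random.default_rng(0).normal(size=(1, 1500)), 15.0)
        with pytest.warns(UserWarning, match="full peri-event window"):
            tensor = perievent.build_perievent(traces, np.array([5.0, 50.0]))
        assert tensor.n_trials == 1

    def test_planted_response_peaks_at_half_second(self):
        fs = 15.0
        kernel = KernelParams()
        n = int(600 * fs)
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.02, size=n)
        trials = np.array([60.0, 120.0, 180.0, 240.0, 300.0])
        t_grid = np.arange(n) / fs
        for trial in trials:
            x += 0.5 * kernel.evaluate(t_grid - (trial + 0.5))
        tensor = perievent.build_perievent(TraceSet(x[None, :], fs), trials)
        avg = tensor.trial_average()[0]
        peak_time = tensor.bin_times[np.argmax(avg)]
        assert 0.3 < peak_time < 1.2  # transient peaks shortly after +0.5 s


class TestPopulationResponse:
    def test_step_response_post_minus_pre_is_one(self):
        fs = 15.0
        nb = int(30 * fs)
        bins = -10.0 + np.arange(nb) / fs
        trace = np.where((bins > 0) & (bins <= 2.0), 1.0, 0.0)
        resp = perievent.population_response(_tensor([trace]))
        row = resp.per_cell.iloc[0]
        assert row["post"] - row["pre"] == pytest.approx(1.0, abs=0.05)

    def test_absolute_value_treats_inhibition_as_magnitude(self):
        fs = 15.0
        nb = int(30 * fs)
        bins = -10.0 + np.arange(nb) / fs
        up = np.where((bins > 0) & (bins <= 2.0), 1.0, 0.0)
        resp = perievent.population_response(_tensor([up, -up]))
        assert resp.per_cell["abs_post"].iloc[0] == pytest.approx(
            resp.per_cell["abs_post"].iloc[1]
        )

    def test_fractions_partition_to_one(self):
        traces, _ = synth.gen_traces(10, 600.0, 1.0, KernelParams(), snr=8, seed=2)
        tensor = perievent.build_perievent(traces, np.array([100.0, 200.0, 400.0]))
        resp = perievent.population_response(tensor)
        total = resp.group_fractions[["increased", "decreased", "unchanged"]].sum(axis=1)
        assert np.allclose(total, 1.0)

    def test_empty_tensor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            perievent.population_response(
                PeriEventTensor(
                    np.empty((0, 0, 450)),
                    -10.0 + np.arange(450) / 15.0,
                    np.empty(0),
                    "Ext1",
                )
            )


class TestClassification:
    def test_strong_planted_response_is_increased(self):
        fs = 15.0
        nb = int(30 * fs)
        bins = -10.0 + np.arange(nb) / fs
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.3, size=nb)
        trace = base + np.where((bins > 0) & (bins <= 2.0), 5.0 * 0.3, 0.0)
        cls = perievent.classify_cells(_tensor([trace]))
        assert cls["cls"].iloc[0] == "increased"

    def test_zero_baseline_sd_flagged_unchanged(self):
        nb = int(30 * 15.0)
        bins = -10.0 + np.arange(nb) / 15.0
        trace = np.where(bins > 0, 1.0, 0.0)  # exactly constant baseline
        cls = perievent.classify_cells(_tensor([trace]))
        assert cls["cls"].iloc[0] == "unchanged" and cls["flagged_zero_sd"].iloc[0]

    def test_classification_invariant_to_affine_rescaling(self):
        traces, _ = synth.gen_traces(8, 600.0, 1.5, KernelParams(), snr=8, seed=4)
        trials = np.array([100.0, 250.0, 400.0])
        cls_a = perievent.classify_cells(perievent.build_perievent(traces, trials))
        rescaled = TraceSet(3.7 * traces.data + 11.0, traces.frame_rate_hz)
        cls_b = perievent.classify_cells(perievent.build_perievent(rescaled, trials))
        assert cls_a["cls"].tolist() == cls_b["cls"].tolist()

    def test_null_rate_matches_monte_carlo_oracle(self):
        # the rule's false-positive rate differs from the nominal 2-SD tail
        # because smoothing and averaging correlate bins; estimate it by
        # Monte-Carlo on one noise cohort, then check an independent cohort
        def modulated_fraction(seed_base, n_cells):
            traces, _ = synth.gen_traces(
                n_cells, 900.0, 0.0, KernelParams(), snr=8, seed=seed_base
            )
            rng = np.random.default_rng(seed_base)
            trials = np.sort(rng.uniform(15.0, 900.0 - 25.0, size=10))
            tensor = perievent.build_perievent(traces, trials)
            cls = perievent.classify_cells(tensor)
            return (cls["cls"] != "unchanged").to_numpy()

        oracle = np.concatenate([modulated_fraction(100 + r, 150) for r in range(4)])
        cohort = np.concatenate([modulated_fraction(200 + r, 150) for r in range(2)])
        p0 = oracle.mean()
        half_ci = 1.96 * np.sqrt(p0 * (1 - p0) / len(cohort))
        assert abs(cohort.mean() - p0) < half_ci + 0.02

    def test_planted_responder_fraction_recovered(self):
        # cells responding at +4 SD should be classified increased on top of
        # the simulated null rate
        fs = 15.0
        nb = int(30 * fs)
        bins = -10.0 + np.arange(nb) / fs
        rng = np.random.default_rng(5)
        n_cells, f = 200, 0.3
        responder = np.arange(n_cells) < f * n_cells
        traces = []
        for i in range(n_cells):
            base = rng.normal(0, 0.3, size=nb)
            bump = 4.0 * 0.3 if responder[i] else 0.0
            traces.append(base + np.where((bins > 0) & (bins <= 2.0), bump, 0.0))
        cls = perievent.classify_cells(_tensor(traces))
        increased = (cls["cls"] == "increased").mean()
        null_rate = (cls["cls"][~responder] == "increased").mean()
        expect = f + (1 - f) * null_rate
        half_ci = 1.96 * np.sqrt(expect * (1 - expect) / n_cells)
        assert abs(increased - expect) < half_ci + 0.03


class TestHeatmapOrdering:
    def test_class_blocks_then_magnitude(self):
        per_cell = pd.DataFrame(
            {
                "cell": [0, 1, 2, 3],
                "cls": ["decreased", "increased", "unchanged", "increased"],
                "pre": [0.0, 0.0, 0.0, 0.0],
                "post": [-1.0, 0.5, 0.1, 2.0],
            }
        )
        assert perievent.order_heatmap(per_cell).tolist() == [3, 1, 2, 0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        per_cell = pd.DataFrame(
            {
                "cell": np.arange(20),
                "cls": rng.choice(["increased", "decreased", "unchanged"], 20),
                "pre": rng.normal(size=20),
                "post": rng.normal(size=20),
            }
        )
        base = perievent.order_heatmap(per_cell).tolist()
        shuffled = per_cell.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert perievent.order_heatmap(shuffled).tolist() == base
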