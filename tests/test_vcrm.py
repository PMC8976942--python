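"""Cycle classification, NF labelling and within-individual permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermoresp import (
    CallEvent,
    SyncMap,
    call_duration_correlation,
    classify_cycles,
    delta_mean,
    label_nf_phases,
    permutation_test,
)
from thermoresp.segmentation import RespirationCycle, RespirationPhase

SYNC = SyncMap(offset_s=0.0, fps=30.0)


def make_cycles(n, frames_per_cycle=45):
    cycles = []
    for i in range(n):
        s = i * frames_per_cycle
        phases = [
            RespirationPhase("inspiration", s, s + 10, 10 / 30, 0.9, 2.7),
            RespirationPhase("expiration", s + 10, s + 20, 10 / 30, 0.8, 2.4),
            RespirationPhase("expiratory_pause", s + 20, s + 45, 25 / 30, 0.15, 0.18),
        ]
        cycles.append(RespirationCycle(i, phases))
    return cycles


def call_at_frame(f, dur_s=0.05):
    return CallEvent(f / 30.0, f / 30.0 + dur_s, "focal")


class TestClassifyCycles:
    def test_no_calls_all_quiet(self):
        cycles = make_cycles(6)
        assert classify_cycles(cycles, [], SYNC) == ["Quiet"] * 6

    def test_single_call_labels_neighbours(self):
        cycles = make_cycles(6)
        labels = classify_cycles(cycles, [call_at_frame(3 * 45 + 12)], SYNC)
        assert labels == ["Quiet", "Quiet", "Pre-call", "Call", "Post-call",
                          "Quiet"]
        assert cycles[3].cycle_type == "Call"

    def test_call_between_two_call_cycles_precedence(self):
        # cycle between two Call cycles qualifies as both Post- and
        # Pre-call; Post-call wins by default precedence
        cycles = make_cycles(5)
        labels = classify_cycles(
            cycles, [call_at_frame(1 * 45 + 5), call_at_frame(3 * 45 + 5)],
            SYNC)
        assert labels == ["Pre-call", "Call", "Post-call", "Call", "Post-call"]

    def test_call_spanning_boundary_belongs_to_onset_cycle(self):
        cycles = make_cycles(4)
        labels = classify_cycles(cycles, [call_at_frame(44, dur_s=0.5)], SYNC)
        assert labels[0] == "Call" and labels[1] == "Post-call"

    def test_edge_windows_mark_first_and_last_cycles(self):
        cycles = make_cycles(4)  # frames 0..180
        labels = classify_cycles(
            cycles,
            [CallEvent(-0.5, -0.45, "focal"),        # 0.5 s before segment
             CallEvent(180 / 30 + 1.0, 180 / 30 + 1.05, "focal")],  # 1 s after
            SYNC)
        assert labels[0] == "Post-call"
        assert labels[-1] == "Pre-call"

    def test_call_beyond_edge_window_ignored(self):
        cycles = make_cycles(4)
        labels = classify_cycles(
            cycles, [CallEvent(180 / 30 + 3.0, 180 / 30 + 3.05, "focal")],
            SYNC)
        assert labels == ["Quiet"] * 4

    def test_matches_brute_force_interval_membership(self, rng):
        for _ in range(20):
            cycles = make_cycles(12)
            onsets = rng.uniform(0, 12 * 45 / 30, size=3)
            calls = [CallEvent(float(o), float(o) + 0.05, "focal")
                     for o in sorted(onsets)]
            labels = classify_cycles(cycles, calls, SYNC)
            call_idx = set()
            for e in calls:
                f = round(e.onset_s * 30)
                for i, c in enumerate(cycles):
                    if c.start_frame <= f < c.end_frame:
                        call_idx.add(i)
            for i, lab in enumerate(labels):
                if i in call_idx:
                    assert lab == "Call"
                elif i + 1 in call_idx and i - 1 in call_idx:
                    assert lab == "Post-call"
                elif i - 1 in call_idx:
                    assert lab == "Post-call"
                elif i + 1 in call_idx:
                    assert lab == "Pre-call"
                else:
                    assert lab == "Quiet"

    def test_unsorted_cycles_raise(self):
        cycles = make_cycles(3)[::-1]
        with pytest.raises(ValueError, match="sorted"):
            classify_cycles(cycles, [], SYNC)


class TestLabelNfPhases:
    def _phases(self, n=9, frames_per_phase=15):
        rows = [(i * frames_per_phase, (i + 1) * frames_per_phase)
                for i in range(n)]
        return pd.DataFrame(rows, columns=["start_frame", "end_frame"])

    def test_no_nf_calls(self):
        labels = label_nf_phases(self._phases(), [], SYNC)
        assert (labels == "No calls").all()

    def test_onset_marks_phase_and_preceding(self):
        phases = self._phases()
        nf = [CallEvent(4 * 15 / 30 + 0.1, 4 * 15 / 30 + 0.15, "nonfocal")]
        labels = label_nf_phases(phases, nf, SYNC)
        assert list(labels == "NF heard") == [False] * 3 + [True, True] + [False] * 4

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            phases = self._phases(n=12)
            onsets = sorted(rng.uniform(0, 12 * 15 / 30, size=3))
            nf = [CallEvent(float(o), float(o) + 0.05, "nonfocal")
                  for o in onsets]
            labels = label_nf_phases(phases, nf, SYNC)
            heard = set()
            for e in nf:
                f = round(e.onset_s * 30)
                for j in range(len(phases)):
                    if phases.start_frame[j] <= f < phases.end_frame[j]:
                        heard.add(j)
                        if j > 0:
                            heard.add(j - 1)
            assert set(np.nonzero((labels == "NF heard").to_numpy())[0]) == heard


class TestDeltaMean:
    def test_identical_groups_zero(self):
        assert delta_mean([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_simple_arithmetic(self):
        assert delta_mean([2.0, 4.0], [1.0, 1.0]) == 2.0

    def test_matches_brute_force(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=15)
        assert delta_mean(a, b) == pytest.approx(sum(a) / 20 - sum(b) / 15)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            delta_mean([], [1.0])


def records_frame(values_by_ind, labels_by_ind, phase="expiration",
                  parameter="amplitude_C"):
    rows = []
    for ind, (vals, labs) in enumerate(zip(values_by_ind, labels_by_ind)):
        for v, l in zip(vals, labs):
            rows.append({"individual_id": f"ind{ind}", "phase": phase,
                         "cycle_type": l, parameter: v})
    return pd.DataFrame(rows)


def exhaustive_pseudo_p(values_by_ind, labels_by_ind):
    """Enumerate every within-individual label arrangement."""
    obs_a = [v for vals, labs in zip(values_by_ind, labels_by_ind)
             for v, l in zip(vals, labs) if l == "Call"]
    obs_b = [v for vals, labs in zip(values_by_ind, labels_by_ind)
             for v, l in zip(vals, labs) if l == "Quiet"]
    observed = np.mean(obs_a) - np.mean(obs_b)
    per_ind = []
    for vals, labs in zip(values_by_ind, labels_by_ind):
        k = sum(1 for l in labs if l == "Call")
        per_ind.append([(sum(vals[i] for i in c), sum(vals))
                        for c in itertools.combinations(range(len(vals)), k)])
    n_a, n_b = len(obs_a), len(obs_b)
    deltas = []
    for combo in itertools.product(*per_ind):
        sa = sum(x[0] for x in combo)
        st = sum(x[1] for x in combo)
        deltas.append(sa / n_a - (st - sa) / n_b)
    deltas = np.array(deltas)
    return float(np.mean(np.abs(deltas) >= abs(observed) - 1e-12)), observed


class TestPermutationTest:
    def test_all_values_equal_gives_p_one(self):
        rec = records_frame([[1.0] * 6], [["Call"] * 3 + ["Quiet"] * 3])
        res = permutation_test(rec, "amplitude_C", "expiration",
                               ("Call", "Quiet"), n_permutations=500, seed=0)
        assert res.delta_mean_observed == 0.0
        assert res.pseudo_p == 1.0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        rec = records_frame([rng.normal(size=10), rng.normal(size=8)],
                            [["Call"] * 4 + ["Quiet"] * 6,
                             ["Call"] * 3 + ["Quiet"] * 5])
        r1 = permutation_test(rec, "amplitude_C", "expiration",
                              ("Call", "Quiet"), n_permutations=1000, seed=42)
        r2 = permutation_test(rec, "amplitude_C", "expiration",
                              ("Call", "Quiet"), n_permutations=1000, seed=42)
        assert r1.pseudo_p == r2.pseudo_p
        assert np.array_equal(r1.null_deltas, r2.null_deltas)
        assert len(r1.null_deltas) == 1000
        assert r1.pseudo_p > 0.0

    @pytest.mark.parametrize("split", [(6, 3), (5, 2)])
    def test_monte_carlo_matches_exhaustive_single_individual(self, split, rng):
        n, k = split
        vals = list(rng.normal(size=n))
        labs = ["Call"] * k + ["Quiet"] * (n - k)
        p_exact, _ = exhaustive_pseudo_p([vals], [labs])
        rec = records_frame([vals], [labs])
        n_perm = 4000
        res = permutation_test(rec, "amplitude_C", "expiration",
                               ("Call", "Quiet"), n_permutations=n_perm, seed=1)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm)
        assert abs(res.pseudo_p - p_exact) <= 3 * se + 2 / n_perm

    def test_monte_carlo_matches_exhaustive_two_individuals(self, rng):
        vals1, vals2 = list(rng.normal(size=5)), list(rng.normal(size=5))
        labs1 = ["Call", "Call", "Quiet", "Quiet", "Quiet"]
        labs2 = ["Call", "Quiet", "Quiet", "Quiet", "Quiet"]
        p_exact, _ = exhaustive_pseudo_p([vals1, vals2], [labs1, labs2])
        rec = records_frame([vals1, vals2], [labs1, labs2])
        n_perm = 4000
        res = permutation_test(rec, "amplitude_C", "expiration",
                               ("Call", "Quiet"), n_permutations=n_perm, seed=2)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm)
        assert abs(res.pseudo_p - p_exact) <= 3 * se + 2 / n_perm

    def test_label_counts_preserved_within_individual(self, rng):
        # the null statistic never leaves the range attainable when each
        # individual keeps its own label counts
        vals = [10.0, 10.0, 10.0, 0.0, 0.0, 0.0]
        labs = ["Call", "Call", "Call", "Quiet", "Quiet", "Quiet"]
        rec = records_frame([vals, [v + 100 for v in vals]], [labs, labs])
        res = permutation_test(rec, "amplitude_C", "expiration",
                               ("Call", "Quiet"), n_permutations=2000, seed=0)
        # if labels leaked across individuals, group A could average near
        # 105 or 5; within-individual shuffles keep it at 50 +- 10
        means_a = res.null_deltas / 2 + (np.sum(vals) + np.sum(vals) + 600) / 12
        assert np.all(means_a > 35) and np.all(means_a < 65)

    def test_absent_label_raises(self):
        rec = records_frame([[1.0, 2.0]], [["Quiet", "Quiet"]])
        with pytest.raises(ValueError):
            permutation_test(rec, "amplitude_C", "expiration",
                             ("Call", "Quiet"), n_permutations=10, seed=0)

    def test_power_on_reported_amplitude_effect(self, rng):
        # Call vs Quiet expiration amplitude medians 1.14 vs 0.78 degC:
        # with >= 30 Call phases the test should reject at alpha = 0.05 in
        # the large majority of replicates
        sd_call = np.arcsinh(0.73 / 2.28) / 0.6745
        sd_quiet = np.arcsinh(0.40 / 1.56) / 0.6745
        rejections = 0
        n_rep = 25
        for rep in range(n_rep):
            vals, labs = [], []
            for ind in range(5):
                call = rng.lognormal(np.log(1.14), sd_call, size=6)
                quiet = rng.lognormal(np.log(0.78), sd_quiet, size=20)
                vals.append(list(call) + list(quiet))
                labs.append(["Call"] * 6 + ["Quiet"] * 20)
            rec = records_frame(vals, labs)
            res = permutation_test(rec, "amplitude_C", "expiration",
                                   ("Call", "Quiet"), n_permutations=800,
                                   seed=rep)
            rejections += res.pseudo_p < 0.05
        assert rejections / n_rep > 0.8


class TestCallDurationCorrelation:
    def _records(self, durations, diffs, phase="expiration"):
        call = pd.DataFrame({
            "phase": phase, "amplitude_C": np.asarray(diffs) + 1.0,
            "call_duration_s": durations,
        })
        quiet = pd.DataFrame({"phase": phase,
                              "amplitude_C": np.ones(50)})
        return call, quiet

    def test_perfectly_monotone_rho_one(self):
        call, quiet = self._records([0.02, 0.04, 0.06, 0.08],
                                    [0.1, 0.2, 0.3, 0.4])
        out = call_duration_correlation(call, quiet,
                                        parameters=("amplitude_C",))
        assert out.rho.iloc[0] == pytest.approx(1.0)

    def test_constant_differences_degenerate(self):
        call, quiet = self._records([0.02, 0.04, 0.06], [0.2, 0.2, 0.2])
        out = call_duration_correlation(call, quiet,
                                        parameters=("amplitude_C",))
        assert out.degenerate.iloc[0]
        assert np.isnan(out.rho.iloc[0])

    def test_matches_independent_rank_computation(self, rng):
        durations = rng.uniform(0.02, 0.2, size=12)
        diffs = rng.normal(size=12)
        call, quiet = self._records(durations, diffs)
        out = call_duration_correlation(call, quiet,
                                        parameters=("amplitude_C",))
        # independent oracle: Pearson correlation of ranks
        qmed = float(quiet.amplitude_C.median())
        d = (call.amplitude_C - qmed).to_numpy()
        rx = np.argsort(np.argsort(durations))
        ry = np.argsort(np.argsort(d))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert out.rho.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_raise(self):
        call, quiet = self._records([0.02, 0.04], [0.1, 0.2])
        with pytest.raises(ValueError, match=">= 3"):
            call_duration_correlation(call, quiet,
                                      parameters=("amplitude_C",))
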