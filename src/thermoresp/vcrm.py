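"""Vocalization-correlated respiratory movement (VCRM) analysis.

Respiration cycles are classified relative to the focal animal's calls
(Call, Pre-call, Post-call, Quiet), phases of Quiet cycles are labelled by
conspecific non-focal (NF) calls (NF heard vs No calls), and group
differences in phase metrics are tested with a within-individual
permutation procedure: the group labels are reshuffled against the
measured values independently within each individual, preserving each
individual's label counts, and the observed difference in group means
(the delta-mean statistic) is compared with its permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

from .segmentation import RespirationCycle
from .sync import CallEvent, SyncMap, audio_time_to_frame

__all__ = [
    "CYCLE_TYPES",
    "PermutationResult",
    "classify_cycles",
    "label_nf_phases",
    "delta_mean",
    "permutation_test",
    "call_duration_correlation",
]

CYCLE_TYPES = ("Call", "Pre-call", "Post-call", "Quiet")
DEFAULT_EDGE_WINDOW_S = 2.0
DEFAULT_N_PERMUTATIONS = 10_000


def classify_cycles(
    cycles: Sequence[RespirationCycle],
    focal_calls: Sequence[CallEvent],
    sync: SyncMap,
    frame_offset: int = 0,
    edge_window_s: float = DEFAULT_EDGE_WINDOW_S,
    precedence: Sequence[str] = ("Call", "Post-call", "Pre-call"),
) -> list[str]:
    """Assign a cycle type to every cycle; sets ``cycle_type`` in place.

    A cycle is *Call* when a focal call onset falls within it (a call
    spanning a boundary belongs to its onset cycle); the cycle immediately
    before a Call cycle is *Pre-call*, the one immediately after is
    *Post-call*; all others are *Quiet*.  Cycles qualifying for several
    labels resolve by ``precedence`` (default Call > Post-call > Pre-call).

    Edge rule: the audio track is also examined ``edge_window_s`` beyond
    the analysable video segment — a focal call onset within that window
    after the segment's last cycle makes the last cycle Pre-call; within
    the window before the first cycle makes the first cycle Post-call.

    ``frame_offset`` translates cycle-internal frame indices (0-based
    within the trace) to absolute video frames for comparison with the
    sync map.
    """
    starts = [c.start_frame for c in cycles]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("cycles must be sorted by start frame")
    n = len(cycles)
    if n == 0:
        return []
    onset_frames = np.array(
        [audio_time_to_frame(e.onset_s, sync) for e in focal_calls], dtype=int
    ) - frame_offset

    rank = {label: i for i, label in enumerate(precedence)}
    labels = ["Quiet"] * n

    def propose(i: int, label: str) -> None:
        if not (0 <= i < n):
            return
        cur = labels[i]
        if cur == "Quiet" or rank.get(label, 99) < rank.get(cur, 99):
            labels[i] = label

    call_idx = []
    for f in onset_frames:
        for i, c in enumerate(cycles):
            if c.start_frame <= f < c.end_frame:
                call_idx.append(i)
                break
    for i in sorted(set(call_idx)):
        labels[i] = "Call"
    for i in sorted(set(call_idx)):
        propose(i - 1, "Pre-call")
        propose(i + 1, "Post-call")

    # calls just beyond the segment edges
    fps = sync.fps
    edge_frames = edge_window_s * fps
    seg_start, seg_end = cycles[0].start_frame, cycles[-1].end_frame
    for f in onset_frames:
        if seg_end <= f <= seg_end + edge_frames:
            propose(n - 1, "Pre-call")
        if seg_start - edge_frames <= f < seg_start:
            propose(0, "Post-call")

    for c, label in zip(cycles, labels):
        c.cycle_type = label
    return labels


def label_nf_phases(
    phases: pd.DataFrame,
    nonfocal_calls: Sequence[CallEvent],
    sync: SyncMap,
    frame_offset: int = 0,
    window_s: float | None = None,
) -> pd.Series:
    """Label phases of Quiet cycles as 'NF heard' or 'No calls'.

    ``phases`` is a tidy per-phase table (columns ``start_frame``,
    ``end_frame``, ordered in trace order) restricted to Quiet cycles — an
    individual's own calling would mask the subtler effects of hearing a
    neighbour.  A phase is *NF heard* when a non-focal call onset falls
    within it or within the immediately following phase (the phase just
    before a heard call captures any anticipatory change).  With
    ``window_s`` set, the 'immediately preceding' rule instead uses a time
    window of that many seconds before the onset.
    """
    onset_frames = np.array(
        [audio_time_to_frame(e.onset_s, sync) for e in nonfocal_calls], dtype=int
    ) - frame_offset
    starts = phases["start_frame"].to_numpy()
    ends = phases["end_frame"].to_numpy()
    heard = np.zeros(len(phases), dtype=bool)
    for f in onset_frames:
        inside = (starts <= f) & (f < ends)
        heard |= inside
        if window_s is not None:
            pre = (ends <= f) & (f - window_s * sync.fps < ends)
            heard |= pre
        else:
            idx = np.nonzero(inside)[0]
            for j in idx:
                if j > 0:
                    heard[j - 1] = True
    return pd.Series(np.where(heard, "NF heard", "No calls"),
                     index=phases.index, name="nf_label")


def delta_mean(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Difference in group means, mean(A) - mean(B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("delta_mean requires two non-empty groups")
    return float(a.mean() - b.mean())


@dataclass
class PermutationResult:
    """Outcome of a within-individual permutation test."""

    parameter: str
    phase: str
    groups: tuple[str, str]
    n_a: int
    n_b: int
    delta_mean_observed: float
    null_deltas: np.ndarray
    n_permutations: int
    pseudo_p: float
    seed: int

    def __post_init__(self) -> None:
        assert 0.0 < self.pseudo_p <= 1.0
        assert len(self.null_deltas) == self.n_permutations


def permutation_test(
    records: pd.DataFrame,
    parameter: str,
    phase: str,
    groups: tuple[str, str],
    group_column: str = "cycle_type",
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Within-individual permutation test of a phase metric between groups.

    Rows of ``records`` carry ``individual_id``, ``phase``, the grouping
    column and the metric column ``parameter``.  The observed statistic is
    delta-mean = mean(group A) - mean(group B) over the pooled data.  Each
    permutation independently reshuffles the group labels against the
    values within every individual block, preserving each individual's
    label counts, which controls for between-individual differences in
    breathing and call rates.  The two-tailed pseudo P-value uses the
    add-one estimator

        p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_permutations + 1)

    so it is never exactly zero and equals 1 when all values tie.
    """
    sub = records[(records["phase"] == phase)
                  & (records[group_column].isin(groups))]
    if sub.empty:
        raise ValueError(f"no records for phase {phase!r} and groups {groups}")
    values = sub[parameter].to_numpy(dtype=float)
    is_a = (sub[group_column] == groups[0]).to_numpy()
    individuals = sub["individual_id"].to_numpy()
    n_a, n_b = int(is_a.sum()), int((~is_a).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"group {groups[0 if n_a == 0 else 1]!r} absent from every individual"
        )
    observed = delta_mean(values[is_a], values[~is_a])

    if rng is None:
        rng = np.random.default_rng(seed)
    total = values.sum()
    sum_a = np.zeros(n_permutations)
    for ind in np.unique(individuals):
        mask = individuals == ind
        v = values[mask]
        k = int(is_a[mask].sum())
        if k == 0:
            continue
        if k == v.size:
            sum_a += v.sum()
            continue
        # vectorised within-block reshuffle: random order, first k rows -> A
        order = np.argsort(rng.random((n_permutations, v.size)), axis=1)
        sum_a += v[order[:, :k]].sum(axis=1)
    null = sum_a / n_a - (total - sum_a) / n_b
    pseudo_p = (1.0 + np.count_nonzero(np.abs(null) >= np.abs(observed) - 1e-12)) \
        / (n_permutations + 1.0)
    return PermutationResult(
        parameter=parameter, phase=phase, groups=tuple(groups),
        n_a=n_a, n_b=n_b, delta_mean_observed=observed,
        null_deltas=null, n_permutations=n_permutations,
        pseudo_p=float(pseudo_p), seed=seed,
    )


def call_duration_correlation(
    call_records: pd.DataFrame,
    quiet_records: pd.DataFrame,
    parameters: Sequence[str] = ("amplitude_C", "duration_s", "slope"),
) -> pd.DataFrame:
    """Spearman correlation of call duration with respiratory change.

    For each (phase, parameter) cell the Call-cycle value minus the
    corresponding Quiet-cycle median quantifies the vocalization-driven
    deviation; its rank correlation with the produced call's duration
    (column ``call_duration_s`` of ``call_records``) asks whether longer
    calls demand larger respiratory adjustments.  Cells with fewer than 3
    pairs raise; degenerate (constant-rank) cells report NaN with a
    warning column set.
    """
    rows = []
    for phase in sorted(call_records["phase"].unique()):
        cr = call_records[call_records["phase"] == phase]
        qr = quiet_records[quiet_records["phase"] == phase]
        for param in parameters:
            if len(cr) < 3:
                raise ValueError(
                    f"phase {phase!r}: need >= 3 Call cycles with call "
                    f"durations, got {len(cr)}"
                )
            diff = cr[param].to_numpy(dtype=float) - float(qr[param].median())
            dur = cr["call_duration_s"].to_numpy(dtype=float)
            if np.all(diff == diff[0]) or np.all(dur == dur[0]):
                rows.append({"phase": phase, "parameter": param,
                             "rho": np.nan, "p_value": np.nan, "n": len(cr),
                             "degenerate": True})
                continue
            rho, p = ss.spearmanr(dur, diff)
            rows.append({"phase": phase, "parameter": param,
                         "rho": float(rho), "p_value": float(p), "n": len(cr),
                         "degenerate": False})
    return pd.DataFrame(rows)
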