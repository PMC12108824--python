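"""Minimal sensor-subset search against the full-array PELT reference.

Fewer sensors mean a cheaper pillow. A subset of 3-6 sensors is considered
adequate when the whole detection pipeline (flux -> PELT -> events), rerun
on only those sensors with the *same* penalty, reproduces the full
7-sensor segmentation: the same number of change points, with every
reference change point matched one-to-one within the tolerance window.
Reusing the penalty isolates the effect of the sensor choice from tuning;
``regrid=True`` re-runs the per-subset penalty search instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .changepoint import (
    EvaluationReport,
    PeltDetector,
    PenaltyGrid,
    PenaltyGridSearch,
    Segmentation,
    evaluate_changepoints,
    posture_change_times,
)
from .flux import windowed_std_flux
from .simulate import SleepSession

__all__ = ["SubsetResult", "enumerate_subsets", "subset_match_search"]


@dataclass
class SubsetResult:
    sensors: tuple[int, ...]
    segmentation: Segmentation
    change_times: np.ndarray
    matches_reference: bool
    match_report: EvaluationReport


def enumerate_subsets(n_sensors: int, k_range: tuple[int, int] = (3, 6)):
    """All sensor index subsets of sizes k_range[0]..k_range[1], in
    deterministic lexicographic order (1-based indices)."""
    lo, hi = k_range
    if not 1 <= lo <= hi <= n_sensors:
        raise ValueError("k_range must satisfy 1 <= lo <= hi <= n_sensors")
    out = []
    for k in range(lo, hi + 1):
        out.extend(combinations(range(1, n_sensors + 1), k))
    return out


def subset_match_search(
    session: SleepSession,
    k_range: tuple[int, int] = (3, 6),
    penalty: float | None = None,
    grid: PenaltyGrid = PenaltyGrid(),
    tolerance_s: float = 10.0,
    window_s: float = 60.0,
    min_points: int = 6,
    min_seg_len: int = 2,
    min_rise: float = 0.1,
    merge_gap_s: float = 60.0,
    lag_correction_samples: float = 1.0,
    regrid: bool = False,
) -> tuple[SubsetResult, list[SubsetResult]]:
    """Run the pipeline on every sensor subset and compare to the reference.

    The 7-sensor (full-array) segmentation is the reference. If ``penalty``
    is None it is grid-searched against the session's ground truth (when
    available) for the reference, then reused for every subset unless
    ``regrid`` is set. Returns ``(reference_result, subset_results)`` with
    subsets in deterministic lexicographic order, sizes ascending.
    """
    n = session.humidity.shape[1]
    dt = session.sampling_period_s

    def detect(sensors, pen):
        fx = windowed_std_flux(
            session, sensors=sensors, window_s=window_s, min_points=min_points
        )
        det = PeltDetector(penalty=pen, min_seg_len=min_seg_len).fit(fx.values)
        times = posture_change_times(
            fx.values,
            det.segmentation_,
            dt,
            min_rise,
            merge_gap_s,
            lag_correction_samples,
        )
        return det.segmentation_, times

    full = tuple(range(1, n + 1))
    if penalty is None:
        if session.truth is None:
            raise ValueError("penalty=None requires a session with ground truth")
        fx = windowed_std_flux(session, window_s=window_s, min_points=min_points)
        gs = PenaltyGridSearch(
            grid=grid,
            tolerance_s=tolerance_s,
            min_seg_len=min_seg_len,
            sampling_period_s=dt,
            min_rise=min_rise,
            merge_gap_s=merge_gap_s,
            lag_correction_samples=lag_correction_samples,
        ).fit(fx.values, session.truth.transition_times)
        penalty = gs.best_penalty_

    ref_seg, ref_times = detect(full, penalty)
    ref_report = evaluate_changepoints(ref_times, ref_times, tolerance_s)
    reference = SubsetResult(full, ref_seg, ref_times, True, ref_report)

    results = []
    for sensors in enumerate_subsets(n, k_range):
        pen = penalty
        if regrid:
            if session.truth is None:
                raise ValueError("regrid requires a session with ground truth")
            fx = windowed_std_flux(
                session, sensors=sensors, window_s=window_s, min_points=min_points
            )
            gs = PenaltyGridSearch(
                grid=grid,
                tolerance_s=tolerance_s,
                min_seg_len=min_seg_len,
                sampling_period_s=dt,
                min_rise=min_rise,
                merge_gap_s=merge_gap_s,
                lag_correction_samples=lag_correction_samples,
            ).fit(fx.values, session.truth.transition_times)
            pen = gs.best_penalty_
        seg, times = detect(sensors, pen)
        report = evaluate_changepoints(times, ref_times, tolerance_s)
        matches = (
            len(times) == len(ref_times) and report.n_matched == len(ref_times)
        )
        results.append(SubsetResult(tuple(sensors), seg, times, matches, report))
    return reference, results


def match_table(results: list[SubsetResult]):
    """Group matching subsets by size: {k: [sensor tuples]}."""
    table: dict[int, list[tuple[int, ...]]] = {}
    for r in results:
        if r.matches_reference:
            table.setdefault(len(r.sensors), []).append(r.sensors)
    return table
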