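"""Reference experiments on seeded synthetic sessions.

These are the package's standard evaluation runs: a change-point benchmark
(pooled precision/recall/F1 of PELT and Binary Segmentation over a suite
of simulated nights) and a classifier benchmark (the supine-dominated
438/66/24 image mix, trained and validated over several seeds). Both are
driven entirely by a single integer seed and are what the test suite and
the reproduction script execute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .changepoint import PenaltyGrid, PenaltyGridSearch, evaluate_changepoints
from .classify import ClassificationReport, ClassifierSpec, build_dataset, train_and_evaluate
from .flux import windowed_std_flux
from .simulate import PostureSchedule, SensorArrayConfig, SleepSession, random_schedule, simulate_session

__all__ = [
    "ChangepointBenchmarkResult",
    "changepoint_benchmark",
    "make_imbalanced_sessions",
    "ClassifierBenchmarkResult",
    "classifier_benchmark",
]


@dataclass
class ChangepointBenchmarkResult:
    algorithm: str
    pooled_precision: float
    pooled_recall: float
    pooled_f1: float
    per_session_f1: list[float]
    best_penalties: list[float]
    n_sessions: int
    n_truth_total: int


def _pooled(matched: int, detected: int, truth: int):
    p = matched / detected if detected else 0.0
    r = matched / truth if truth else 1.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def changepoint_benchmark(
    n_sessions: int = 20,
    seed: int = 1,
    duration_s: float = 4 * 3600.0,
    n_transitions: tuple[int, int] = (6, 20),
    min_gap_s: float = 600.0,
    noise_sd_rh: float = 0.5,
    window_s: float = 60.0,
    min_points: int = 6,
    grid: PenaltyGrid = PenaltyGrid(),
    tolerance_s: float = 10.0,
    algorithms: tuple[str, ...] = ("pelt", "binseg"),
) -> dict[str, ChangepointBenchmarkResult]:
    """Grid-searched detection on a suite of simulated nights.

    Each session gets its own schedule (6-20 transitions, 10-min minimum
    dwell) and sensor noise; the std-sum flux is segmented with the penalty
    grid-searched per session against ground truth, and matches within the
    ±10 s tolerance are pooled across sessions.
    """
    master = np.random.default_rng(seed)
    config = SensorArrayConfig(noise_sd_rh=noise_sd_rh)
    tallies = {a: [0, 0, 0] for a in algorithms}  # matched, detected, truth
    per_f1 = {a: [] for a in algorithms}
    pens = {a: [] for a in algorithms}
    for _ in range(n_sessions):
        schedule = random_schedule(
            duration_s,
            n_transitions,
            min_gap_s,
            config.sampling_period_s,
            master,
        )
        sim_seed = int(master.integers(0, 2**31 - 1))
        session = simulate_session(config, schedule, sim_seed)
        fx = windowed_std_flux(session, window_s=window_s, min_points=min_points)
        truth = schedule.transition_times
        for algo in algorithms:
            gs = PenaltyGridSearch(
                grid=grid,
                tolerance_s=tolerance_s,
                sampling_period_s=config.sampling_period_s,
                algorithm=algo,
            ).fit(fx.values, truth)
            rep = evaluate_changepoints(gs.change_times_, truth, tolerance_s)
            tallies[algo][0] += rep.n_matched
            tallies[algo][1] += rep.n_detected
            tallies[algo][2] += rep.n_truth
            per_f1[algo].append(rep.f1)
            pens[algo].append(gs.best_penalty_)
    out = {}
    for algo in algorithms:
        m, d, t = tallies[algo]
        p, r, f1 = _pooled(m, d, t)
        out[algo] = ChangepointBenchmarkResult(
            algorithm=algo,
            pooled_precision=p,
            pooled_recall=r,
            pooled_f1=f1,
            per_session_f1=per_f1[algo],
            best_penalties=pens[algo],
            n_sessions=n_sessions,
            n_truth_total=t,
        )
    return out


def make_imbalanced_sessions(
    counts: dict[str, int] = {"supine": 438, "left": 66, "right": 24},
    window_s: float = 600.0,
    windows_per_session: int = 44,
    noise_sd_rh: float = 0.5,
    seed: int = 0,
) -> list[SleepSession]:
    """Sessions whose 10-min windows realize an exact posture-label mix.

    The full label multiset is shuffled, chunked into sessions, and each
    chunk's run-length encoding becomes the session's posture schedule with
    segment boundaries aligned to window boundaries, so window majority
    labels reproduce ``counts`` exactly.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate([[lab] * n for lab, n in counts.items()])
    labels = labels[rng.permutation(len(labels))]
    config = SensorArrayConfig(noise_sd_rh=noise_sd_rh)
    sessions = []
    for lo in range(0, len(labels), windows_per_session):
        chunk = labels[lo : lo + windows_per_session]
        segments = [(0.0, chunk[0])]
        for i in range(1, len(chunk)):
            if chunk[i] != chunk[i - 1]:
                segments.append((i * window_s, chunk[i]))
        schedule = PostureSchedule(segments, len(chunk) * window_s)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        sessions.append(simulate_session(config, schedule, sim_seed))
    return sessions


@dataclass
class ClassifierBenchmarkResult:
    accuracies: list[float]
    mean_accuracy_pct: float
    reports: list[ClassificationReport]
    binary_confusion_pooled: np.ndarray
    binary_accuracy: float
    binary_f1: float
    class_counts: dict = field(default_factory=dict)


def classifier_benchmark(
    seeds: tuple[int, ...] = (1, 2, 3),
    counts: dict[str, int] = {"supine": 438, "left": 66, "right": 24},
    window_s: float = 600.0,
    render_size: int = 224,
    spec: ClassifierSpec | None = None,
) -> ClassifierBenchmarkResult:
    """Posture CNN on the imbalanced image mix, averaged over seeds.

    Per seed: fresh sessions, 528 rendered windows, stratified 80/20
    split, class-weighted training; reports mean validation accuracy (%)
    and the binary change/no-change metrics pooled over seeds.
    """
    accs, reports = [], []
    pooled = np.zeros((2, 2), dtype=int)
    for s in seeds:
        sessions = make_imbalanced_sessions(counts, window_s=window_s, seed=s)
        dataset = build_dataset(sessions, window_s=window_s, size=render_size)
        run_spec = spec if spec is not None else ClassifierSpec()
        run_spec = ClassifierSpec(**{**run_spec.__dict__, "seed": s})
        report = train_and_evaluate(dataset, run_spec)
        accs.append(report.accuracy)
        reports.append(report)
        pooled += report.binary_confusion
    tn, fp, fn, tp = pooled.ravel()
    bacc = (tp + tn) / pooled.sum() if pooled.sum() else 1.0
    bprec = tp / (tp + fp) if tp + fp else 0.0
    brec = tp / (tp + fn) if tp + fn else 0.0
    bf1 = 2 * bprec * brec / (bprec + brec) if bprec + brec else 0.0
    return ClassifierBenchmarkResult(
        accuracies=accs,
        mean_accuracy_pct=float(np.mean(accs) * 100.0),
        reports=reports,
        binary_confusion_pooled=pooled,
        binary_accuracy=float(bacc),
        binary_f1=float(bf1),
        class_counts=dict(counts),
    )
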