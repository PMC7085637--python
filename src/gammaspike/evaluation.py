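"""Event matching and performance measures.

Sensitivity = 100 TP/(TP+FN), selectivity = 100 TP/(TP+FP); overall
performance is their unweighted mean.  Detections are matched to
annotations event-to-event within a time tolerance (default ±20 ms, one
maximal spike duration); the precision-recall curve is traced by sweeping
the moving threshold λ2, and true positives are binned over the 6 h latent
phase in 30-min epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import AnnotationSet, DetectionResult


@dataclass(frozen=True)
class MatchConfig:
    """Event-matching policy.

    ``greedy_nearest`` pairs the closest detection/annotation first;
    ``optimal`` maximizes the number of pairs via assignment.  The two agree
    whenever no detection lies within tolerance of two annotations.
    """

    tolerance_ms: float = 20.0
    policy: str = "greedy_nearest"

    def __post_init__(self) -> None:
        if self.tolerance_ms <= 0:
            raise ValueError("tolerance_ms must be > 0")
        if self.policy not in ("greedy_nearest", "optimal"):
            raise ValueError(f"unknown policy {self.policy!r}")


@dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    pairs: tuple[tuple[int, int], ...]  # (detection index, annotation index)


def _event_centers(obj) -> np.ndarray:
    if isinstance(obj, (AnnotationSet, DetectionResult)):
        return obj.centers()
    return np.asarray([int(e) for e in obj], dtype=int)


def match_events(
    detections,
    annotations,
    config: MatchConfig | None = None,
    fs: float = 1024.0,
) -> MatchResult:
    """Match detections to annotations within ±tolerance.

    Each annotation matches at most one detection; unmatched detections are
    false positives, unmatched annotations false negatives.
    """
    config = config or MatchConfig()
    det = _event_centers(detections)
    ann = _event_centers(annotations)
    tol = config.tolerance_ms * fs / 1000.0

    if det.size == 0 or ann.size == 0:
        return MatchResult(0, det.size, ann.size, ())

    if config.policy == "greedy_nearest":
        pairs = _greedy_pairs(det, ann, tol)
    else:
        pairs = _optimal_pairs(det, ann, tol)
    tp = len(pairs)
    return MatchResult(tp, det.size - tp, ann.size - tp, tuple(pairs))


def _greedy_pairs(det: np.ndarray, ann: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Smallest time difference first; ties broken toward the earlier
    detection, then the earlier annotation."""
    cands = []
    for i, d in enumerate(det):
        for j, a in enumerate(ann):
            dt = abs(int(d) - int(a))
            if dt <= tol:
                cands.append((dt, d, a, i, j))
    cands.sort(key=lambda c: (c[0], c[1], c[2]))
    used_d: set[int] = set()
    used_a: set[int] = set()
    pairs = []
    for _, _, _, i, j in cands:
        if i in used_d or j in used_a:
            continue
        used_d.add(i)
        used_a.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def _optimal_pairs(det: np.ndarray, ann: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Maximum-cardinality assignment (min total |Δt| among feasible pairs)."""
    from scipy.optimize import linear_sum_assignment

    dt = np.abs(det[:, None].astype(float) - ann[None, :].astype(float))
    feasible = dt <= tol
    # infeasible pairs get a cost larger than any feasible total
    big = tol * (det.size + ann.size + 1) + 1.0
    cost = np.where(feasible, dt, big)
    rows, cols = linear_sum_assignment(cost)
    return sorted(
        (int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]
    )


@dataclass(frozen=True)
class PerformanceRecord:
    """TP/FP/FN counts and the derived percentages at one threshold.

    A degenerate denominator (no annotated events, or no detections) is
    reported as 100% with the corresponding flag set rather than an error,
    matching how all-correct subjects are conventionally scored.
    """

    tp: int
    fp: int
    fn: int
    sensitivity: float
    selectivity: float
    overall: float
    lambda2: float | None = None
    degenerate_sensitivity: bool = False
    degenerate_selectivity: bool = False

    def as_dict(self) -> dict:
        d = {
            "lambda2": self.lambda2,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "selectivity": self.selectivity,
            "overall": self.overall,
        }
        if self.degenerate_sensitivity or self.degenerate_selectivity:
            d["degenerate"] = True
        return d


def performance(tp: int, fp: int, fn: int, lambda2: float | None = None) -> PerformanceRecord:
    """Compute sensitivity, selectivity and overall performance (%)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    deg_sens = tp + fn == 0
    deg_sel = tp + fp == 0
    sens = 100.0 if deg_sens else 100.0 * tp / (tp + fn)
    sel = 100.0 if deg_sel else 100.0 * tp / (tp + fp)
    return PerformanceRecord(
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sens,
        selectivity=sel,
        overall=(sens + sel) / 2.0,
        lambda2=lambda2,
        degenerate_sensitivity=deg_sens,
        degenerate_selectivity=deg_sel,
    )


def prc_curve(records: Sequence[PerformanceRecord]) -> list[tuple[float, float]]:
    """(recall %, precision %) points ordered by λ2.

    Recall is sensitivity, precision selectivity; sweeping λ2 upward traces
    the curve.
    """
    if not records:
        raise ValueError("need at least one performance record")
    ordered = sorted(
        records, key=lambda r: r.lambda2 if r.lambda2 is not None else 0.0
    )
    return [(r.sensitivity, r.selectivity) for r in ordered]


#: 30-min bin edges over the 6 h latent phase, minutes post-insult.
LATENT_PHASE_EDGES_MIN = tuple(range(0, 361, 30))


@dataclass(frozen=True)
class BinSummary:
    """Per-bin event counts over the latent phase.

    Bins are half-open [edge_{k-1}, edge_k) in minutes post-insult; events
    outside the edges land in ``overflow`` and set the flag.
    """

    bin_edges_min: tuple[float, ...]
    counts: tuple[int, ...]
    overflow: int = 0

    @property
    def flagged(self) -> bool:
        return self.overflow > 0

    @property
    def total(self) -> int:
        return int(sum(self.counts)) + self.overflow


def bin_counts(
    event_samples: Iterable[int],
    fs: float = 1024.0,
    t0_offset_min: float = 0.0,
    edges_min: Sequence[float] = LATENT_PHASE_EDGES_MIN,
) -> BinSummary:
    """Histogram events (sample indices) into latent-phase bins.

    ``t0_offset_min`` places the first sample of the record relative to the
    end of the insult.
    """
    edges = np.asarray(edges_min, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be increasing with at least two values")
    samples = np.asarray(list(event_samples), dtype=float)
    minutes = t0_offset_min + samples / fs / 60.0
    inside = (minutes >= edges[0]) & (minutes < edges[-1])
    hist, _ = np.histogram(minutes[inside], bins=edges)
    return BinSummary(
        bin_edges_min=tuple(edges.tolist()),
        counts=tuple(int(c) for c in hist),
        overflow=int(np.sum(~inside)),
    )


def cohort_bin_stats(summaries: Sequence[BinSummary]) -> dict[str, np.ndarray]:
    """Cohort mean and quartiles per latent-phase bin across subjects."""
    if not summaries:
        raise ValueError("need at least one subject")
    edges = summaries[0].bin_edges_min
    if any(s.bin_edges_min != edges for s in summaries):
        raise ValueError("all subjects must share bin edges")
    counts = np.array([s.counts for s in summaries], dtype=float)
    return {
        "bin_edges_min": np.asarray(edges),
        "mean": counts.mean(axis=0),
        "q1": np.percentile(counts, 25, axis=0),
        "median": np.percentile(counts, 50, axis=0),
        "q3": np.percentile(counts, 75, axis=0),
    }


def cohort_summary(overall_values: Sequence[float]) -> tuple[float, float]:
    """Cohort mean and sample (n-1) standard deviation of per-subject best
    overall performance, in percent.

    With fewer than two subjects the SD is undefined and returned as NaN.
    """
    vals = np.asarray(list(overall_values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one subject")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    return mean, sd
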