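"""Sample-wise comparison of detected artifacts against expert labels.

Exact artifact borders are ambiguous even for experts, so the comparison is
lenient near expert borders: a run of disagreeing samples touching an
expert artifact border (a "residual segment") is forgiven — counted as if
both raters agreed — when it lasts at least 10% of the adjacent artifact's
duration and no more than 1.5 s.  A forgiven detector-only overshoot counts
as TP; a forgiven expert-only undershoot counts as TN.  From the resulting
confusion counts the module computes Cohen's kappa K, percentage of
agreement S, sensitivity Se and false discovery rate FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import ArtifactSegment

__all__ = [
    "ConfusionCounts",
    "EvaluationResult",
    "rasterize",
    "fuzzy_confusion",
    "kappa_from_counts",
    "evaluate_detection",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationResult:
    kappa: float
    agreement: float
    sensitivity: float  # NaN when no expert-positive samples
    fdr: float  # NaN when nothing was detected
    artifact_rate_detected: float
    counts: ConfusionCounts


def rasterize(segments: list[ArtifactSegment], n_samples: int, fs: float) -> np.ndarray:
    """Per-sample boolean mask from half-open [start_s, end_s) intervals.

    Sample i covers [i/fs, (i+1)/fs).  Segments must be disjoint and sorted.
    """
    mask = np.zeros(n_samples, dtype=bool)
    prev_end = -math.inf
    for seg in segments:
        if seg.end_s <= seg.start_s:
            raise ValueError(f"empty or inverted segment [{seg.start_s}, {seg.end_s})")
        if seg.start_s < prev_end:
            raise ValueError("segments overlap or are unsorted")
        prev_end = seg.end_s
        a = int(round(seg.start_s * fs))
        b = int(round(seg.end_s * fs))
        mask[max(a, 0) : min(b, n_samples)] = True
    return mask


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, stop) pairs of contiguous True runs, half-open in samples."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return edges.reshape(-1, 2)


def _adjacent_expert_duration(start: int, stop: int, expert_runs: np.ndarray) -> int | None:
    """Length (samples) of the expert artifact whose border this run
    touches, or None.  A run touching two artifacts uses the longer one."""
    best = None
    for a, b in expert_runs:
        # a run covering the whole artifact is a complete miss, not a
        # border residual, and is never forgiven
        inside_border = a <= start and stop <= b and (start == a) != (stop == b)
        touches = stop == a or start == b or inside_border
        if touches:
            dur = b - a
            if best is None or dur > best:
                best = int(dur)
    return best


def fuzzy_confusion(
    detected: list[ArtifactSegment],
    expert: list[ArtifactSegment],
    rec_duration_s: float,
    fs: float,
    min_fraction: float = 0.10,
    max_lenient_s: float = 1.5,
    lenient_rule: str = "and",
) -> ConfusionCounts:
    """Sample-wise confusion counts with fuzzy expert borders.

    Both labelings are rasterized; agreeing samples are TP/TN.  A
    disagreeing run adjacent to an expert artifact border is forgiven
    (detector-only run -> TP, expert-only run -> TN) when its duration is
    at least ``min_fraction`` of the adjacent artifact's duration AND at
    most ``max_lenient_s`` — the literal rule, which penalises very small
    overshoots.  ``lenient_rule="or"`` selects the alternative reading
    (forgiven when <= max(min_fraction * duration, max_lenient_s)).
    Disagreeing runs not touching any expert border are plain FP/FN.
    """
    n_samples = int(round(rec_duration_s * fs))
    det_mask = rasterize(detected, n_samples, fs)
    exp_mask = rasterize(expert, n_samples, fs)
    expert_runs = _runs(exp_mask)

    tp = int(np.sum(det_mask & exp_mask))
    tn = int(np.sum(~det_mask & ~exp_mask))
    fp = fn = 0

    for kind, disagree in (("fp", det_mask & ~exp_mask), ("fn", ~det_mask & exp_mask)):
        for start, stop in _runs(disagree):
            dur = stop - start
            adj = _adjacent_expert_duration(start, stop, expert_runs)
            lenient = False
            if adj is not None:
                if lenient_rule == "and":
                    lenient = dur >= min_fraction * adj and dur <= max_lenient_s * fs
                elif lenient_rule == "or":
                    lenient = dur <= max(min_fraction * adj, max_lenient_s * fs)
                else:
                    raise ValueError(f"unknown lenient_rule {lenient_rule!r}")
            if kind == "fp":
                if lenient:
                    tp += dur
                else:
                    fp += dur
            else:
                if lenient:
                    tn += dur
                else:
                    fn += dur

    return ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def kappa_from_counts(c: ConfusionCounts) -> EvaluationResult:
    """Cohen's kappa, agreement, sensitivity and FDR from sample counts.

    K = (Po - Pr) / (1 - Pr) with observed agreement
    Po = (TP + TN) / N and chance agreement
    Pr = [(TP+FN)(TP+FP) + (FN+TN)(FP+TN)] / N^2.
    Se = TP/(TP+FN) (NaN when the expert marked nothing);
    FDR = FP/(TP+FP) (NaN when nothing was detected).
    """
    N = c.total
    if N == 0:
        raise ValueError("empty confusion counts")
    po = (c.tp + c.tn) / N
    pr = ((c.tp + c.fn) * (c.tp + c.fp) + (c.fn + c.tn) * (c.fp + c.tn)) / N**2
    kappa = 1.0 if pr == 1.0 else (po - pr) / (1.0 - pr)
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    fdr = c.fp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else float("nan")
    return EvaluationResult(
        kappa=kappa,
        agreement=po,
        sensitivity=se,
        fdr=fdr,
        artifact_rate_detected=(c.tp + c.fp) / N,
        counts=c,
    )


def evaluate_detection(
    detected: list[ArtifactSegment],
    expert: list[ArtifactSegment],
    rec_duration_s: float,
    fs: float,
    min_fraction: float = 0.10,
    max_lenient_s: float = 1.5,
    lenient_rule: str = "and",
) -> EvaluationResult:
    """Fuzzy confusion counting followed by the agreement metrics."""
    counts = fuzzy_confusion(
        detected, expert, rec_duration_s, fs, min_fraction, max_lenient_s, lenient_rule
    )
    return kappa_from_counts(counts)
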