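"""Rule-based Roar/Sigh/Intermediate pulse classification from F0 contours.

The revised scheme reduces the six historical pulse types to three
reproducible classes defined by the shape and height of the
fundamental-frequency contour:

- **Roar** — F0 ascends and reaches its maximum (> 350 Hz) at or near the
  pulse midpoint before descending.
- **Sigh** — F0 reaches its maximum at the start of the pulse and
  descends, with no later ascending portion.
- **Intermediate** — either (a) the maximum occurs at the start but an
  ascending portion appears later in the pulse, or (b) F0 ascends to a
  mid-pulse maximum below 350 Hz.

An optional four-class mode additionally recognizes huitus pulses by the
unvoiced gap between their ascending and descending parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .supervised import ConfusionResult, _confusion, _confusion_to_result
from .types import F0Contour

UNCLASSIFIABLE = "Unclassifiable"


@dataclass
class RuleConfig:
    f0_threshold: float = 350.0        # Hz; strict '>' for the Roar rule
    midpoint_window: float = 0.4       # central fraction of voiced duration
    min_ascent: float = 21.5           # Hz; ~2 bins at 10.8 Hz resolution
    start_frac: float = 0.1            # 'start of the pulse' region
    four_class: bool = False           # recognize huitus via unvoiced gap
    min_gap_s: float = 0.03

    def __post_init__(self) -> None:
        if self.f0_threshold <= 0:
            raise ValueError(f"f0_threshold must be positive (got {self.f0_threshold})")
        if not 0.0 < self.midpoint_window <= 1.0:
            raise ValueError(
                f"midpoint_window must be in (0, 1] (got {self.midpoint_window})")


@dataclass
class RuleTrace:
    label: str
    max_hz: float
    max_rel_pos: float
    ascent_to_max: float
    later_ascent: float
    has_gap: bool


def _max_run_ascent(f: np.ndarray) -> float:
    """Largest cumulative rise over consecutive increasing frames."""
    best = cur = 0.0
    for d in np.diff(f):
        cur = cur + d if d > 0 else 0.0
        best = max(best, cur)
    return best


def classify_contour(
    contour: F0Contour,
    config: RuleConfig | None = None,
    return_trace: bool = False,
):
    """Assign exactly one of Roar / Sigh / Intermediate to an F0 contour.

    Contours with fewer than 3 voiced frames are unclassifiable and get
    the sentinel label ``"Unclassifiable"``. An "ascending portion" is a
    consecutive voiced run with cumulative rise >= ``config.min_ascent``,
    which suppresses bin-quantization jitter. The Roar frequency test is a
    strict inequality: a 350.0 Hz maximum is not a Roar.
    """
    config = config or RuleConfig()
    voiced = contour.voiced
    t = contour.frame_times[voiced]
    f = contour.f0_hz[voiced]
    if len(f) < 3:
        trace = RuleTrace(UNCLASSIFIABLE, float("nan"), float("nan"),
                          0.0, 0.0, False)
        return trace if return_trace else trace.label

    span = t[-1] - t[0]
    i_max = int(np.argmax(f))
    rel = (t[i_max] - t[0]) / span if span > 0 else 0.0
    f_max = float(f[i_max])
    ascent_to_max = _max_run_ascent(f[: i_max + 1])
    later_ascent = _max_run_ascent(f[i_max:]) if i_max < len(f) - 1 else 0.0
    # an ascending portion after the initial start region (the Sigh rule
    # forbids any later ascent, wherever the maximum sits)
    start_cut = max(int(np.ceil(config.start_frac * len(f))), 1)
    ascent_after_start = _max_run_ascent(f[start_cut - 1:]) if len(f) > start_cut else 0.0

    has_gap = False
    if config.four_class:
        vidx = np.where(voiced)[0]
        if len(vidx) >= 2:
            times = contour.frame_times
            gaps = np.where(np.diff(vidx) > 1)[0]
            for g in gaps:
                dur = times[vidx[g + 1]] - times[vidx[g]]
                if dur >= config.min_gap_s:
                    has_gap = True
                    break

    half = config.midpoint_window / 2.0
    in_mid = abs(rel - 0.5) <= half
    at_start = rel <= config.start_frac

    if config.four_class and has_gap:
        label = "Huitus"
    elif in_mid and ascent_to_max >= config.min_ascent:
        label = "Roar" if f_max > config.f0_threshold else "Intermediate"
    elif at_start:
        label = "Intermediate" if ascent_after_start >= config.min_ascent else "Sigh"
    else:
        # maximum neither at start nor near the midpoint: graded shape
        label = ("Sigh" if ascent_after_start < config.min_ascent
                 and ascent_to_max < config.min_ascent else "Intermediate")

    trace = RuleTrace(label, f_max, float(rel), float(ascent_to_max),
                      float(later_ascent), has_gap)
    return trace if return_trace else trace.label


def classify_contours(
    contours,
    config: RuleConfig | None = None,
) -> pd.DataFrame:
    """Classify a sequence of contours, returning labels with rule traces."""
    rows = []
    for i, c in enumerate(contours):
        tr = classify_contour(c, config, return_trace=True)
        rows.append({"index": i, "label": tr.label, "max_hz": tr.max_hz,
                     "max_rel_pos": tr.max_rel_pos,
                     "ascent_to_max": tr.ascent_to_max,
                     "later_ascent": tr.later_ascent, "has_gap": tr.has_gap})
    return pd.DataFrame(rows)


def evaluate_rules(
    contours,
    truth_labels,
    config: RuleConfig | None = None,
) -> ConfusionResult:
    """Confusion of rule labels against ground-truth labels.

    Unclassifiable contours are dropped from the confusion (reported via
    the matrix row sums). Raises when the predicted and truth label sets
    are disjoint.
    """
    truth = list(truth_labels)
    if len(truth) != len(contours):
        raise ValueError("contours and truth_labels must align")
    pred = [classify_contour(c, config) for c in contours]
    keep = [i for i, p in enumerate(pred) if p != UNCLASSIFIABLE]
    pred_k = [pred[i] for i in keep]
    truth_k = [truth[i] for i in keep]
    if not set(pred_k) & set(truth_k):
        raise ValueError(
            f"rule labels {sorted(set(pred_k))} share no classes with truth "
            f"labels {sorted(set(truth_k))}")
    labels = sorted(set(pred_k) | set(truth_k))
    return _confusion_to_result(_confusion(truth_k, pred_k, labels))
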