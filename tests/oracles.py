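"""Independent brute-force reference implementations used only by tests.

These deliberately use naive scalar loops rather than the vectorized code
paths in the package, so that agreement between the two is informative.
"""

from __future__ import annotations

import math

import numpy as np


def windowed_rms(x: np.ndarray, win: int, step: int) -> list[float]:
    """Naive per-window RMS."""
    out = []
    start = 0
    while start + win <= len(x):
        seg = x[start : start + win]
        out.append(math.sqrt(sum(float(v) ** 2 for v in seg) / win))
        start += step
    return out


def threshold_run_events(
    values,
    mean: float,
    sd: float,
    core_k: float = 3.0,
    boundary_k: float = 2.0,
    min_consecutive: int = 3,
    amplitude_floor: float = 0.0,
) -> list[tuple[int, int]]:
    """Enumerate threshold runs: inclusive (start, end) window-index spans.

    Cores are maximal runs of >= min_consecutive values strictly above
    mean + core_k * sd (and above the floor); each core is walked outward
    through values >= mean + boundary_k * sd; spans that touch or overlap
    are merged.
    """
    values = list(values)
    n = len(values)
    core_thr = mean + core_k * sd
    b_thr = mean + boundary_k * sd

    spans = []
    i = 0
    while i < n:
        if values[i] > core_thr and values[i] > amplitude_floor:
            j = i
            while j + 1 < n and values[j + 1] > core_thr and values[j + 1] > amplitude_floor:
                j += 1
            if j - i + 1 >= min_consecutive:
                lo, hi = i, j
                while lo > 0 and values[lo - 1] >= b_thr:
                    lo -= 1
                while hi < n - 1 and values[hi + 1] >= b_thr:
                    hi += 1
                spans.append([lo, hi])
            i = j + 1
        else:
            i += 1

    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(a, b) for a, b in merged]


def events_to_spans(table, step_s: float, window_s: float) -> list[tuple[int, int]]:
    """Convert detected event times back to inclusive window-index spans."""
    spans = []
    for e in table.events:
        lo = int(round(e.onset_s / step_s))
        hi = int(round((e.offset_s - window_s) / step_s))
        spans.append((lo, hi))
    return spans


def closed_loop_trigger_oracle(
    y: np.ndarray,
    fs: float,
    k: float,
    window_s: float,
    max_stim_s: float,
    release_hold_s: float,
    refractory_s: float = 0.0,
) -> tuple[list[int], list[tuple[int, int]]]:
    """Scalar re-derivation of trigger samples and gates from the filtered stream.

    Recomputes the adaptive statistics (cumulative average during warm-up,
    then exponential forgetting), freezes them during gates, and applies the
    release-hold / maximum-duration closing rules.
    """
    alpha = 1.0 / (window_s * fs)
    warmup = int(round(window_s * fs))
    max_gate = max(1, int(round(max_stim_s * fs)))
    hold = max(1, int(round(release_hold_s * fs)))
    refr_n = int(round(refractory_s * fs))

    m = d = 0.0
    count = 0
    triggers: list[int] = []
    gates: list[tuple[int, int]] = []
    gated = False
    frozen = math.inf
    start = 0
    below = 0
    refr = 0
    for t in range(len(y)):
        a = abs(float(y[t]))
        if not gated:
            count += 1
            w = max(1.0 / count, alpha)
            m += w * (a - m)
            d += w * (abs(a - m) - d)
            thr = math.inf if count < warmup else m + k * d
            if refr > 0:
                refr -= 1
            elif a > thr:
                gated = True
                start = t
                frozen = thr
                below = 0
                triggers.append(t)
        if gated:
            below = below + 1 if a < frozen else 0
            if below >= hold or t - start + 1 >= max_gate:
                gates.append((start, t))
                gated = False
                refr = refr_n
    if gated:
        gates.append((start, len(y) - 1))
    return triggers, gates
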