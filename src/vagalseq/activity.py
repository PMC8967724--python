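"""Calcium-trace analysis for in vivo vagal ganglion imaging.

Raw GCaMP fluorescence is converted to dF/F against a 10-frame pre-stimulus
baseline (frames onset-20 .. onset-11; the half-open window [-20, -10) keeps
exactly ten frames).  A cell is responsive to a stimulus when its maximum
dF/F within the stimulus window is strictly greater than 1.0 (more than 100%
above baseline).  Activation kinetics use 10%-of-peak first-crossing
semantics on the discrete frame sequence, without interpolation.

Marker-rule classification assigns each imaged cell to a transcriptomic
subpopulation (A-L) from its in situ hybridisation positivity calls; the
first matching rule wins and unmatched cells are labelled "X".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FRAME_INTERVAL_S = 1.72
BASELINE_WINDOW = (-20, -10)  # half-open, relative to stimulus onset
RESPONSE_THRESHOLD = 1.0
KINETICS_LEVEL = 0.1

#: Post-onset window lengths (frames) for the two timed stimulus kinds.
INTESTINE_STRETCH_FRAMES = 40  # 68.8 s at 1.72 s/frame
INFUSION_FRAMES = 90           # 154.8 s

__all__ = [
    "StimulusWindow",
    "ResponseResult",
    "MarkerRule",
    "DEFAULT_MARKER_RULES",
    "delta_f_over_f",
    "is_responsive",
    "activation_metrics",
    "align_at_activation",
    "classify_subpopulation",
    "classify_archetype",
    "stretch_window",
    "intestine_stretch_window",
    "infusion_window",
]


@dataclass(frozen=True)
class StimulusWindow:
    """A named stimulus with onset frame and response window [start, stop)."""

    name: str
    onset: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty stimulus window")


def stretch_window(name: str, onset: int, offset: int) -> StimulusWindow:
    """Lung/stomach stretch: window runs from stretch on to stretch off."""
    return StimulusWindow(name, onset, onset, offset + 1)


def intestine_stretch_window(name: str, onset: int) -> StimulusWindow:
    return StimulusWindow(name, onset, onset, onset + INTESTINE_STRETCH_FRAMES)


def infusion_window(name: str, onset: int) -> StimulusWindow:
    return StimulusWindow(name, onset, onset, onset + INFUSION_FRAMES)


@dataclass(frozen=True)
class ResponseResult:
    responsive: bool
    peak: float
    peak_frame: int
    activation_frame: int
    activation_duration: int
    censored: bool = False


def delta_f_over_f(trace: Sequence[float], onset: int) -> np.ndarray:
    """Per-frame (F_t - F0)/F0 with F0 the 10-frame pre-stimulus baseline."""
    trace = np.asarray(trace, dtype=float)
    lo, hi = onset + BASELINE_WINDOW[0], onset + BASELINE_WINDOW[1]
    if lo < 0:
        raise ValueError("baseline frames before trace start; onset too early")
    f0 = trace[lo:hi].mean()
    if f0 <= 0:
        raise ValueError("nonpositive baseline fluorescence")
    return (trace - f0) / f0


def is_responsive(
    dff: np.ndarray, window: StimulusWindow, threshold: float = RESPONSE_THRESHOLD
) -> bool:
    """True iff max dF/F within the stimulus window strictly exceeds threshold."""
    seg = np.asarray(dff)[window.start:window.stop]
    if seg.size == 0:
        raise ValueError("stimulus window outside trace extent")
    return bool(seg.max() > threshold)


def activation_metrics(
    dff: np.ndarray,
    window: StimulusWindow,
    level: float = KINETICS_LEVEL,
    threshold: float = RESPONSE_THRESHOLD,
) -> ResponseResult:
    """Peak response and 10%-of-peak activation kinetics.

    The peak is the maximum dF/F within the stimulus window.  The activation
    frame is the first frame of the contiguous run of frames >= level*peak
    that contains the peak; the activation duration counts frames from that
    crossing to the last frame >= level*peak after the peak, inclusive.
    If the trace never falls back below the level after the peak the
    duration is censored at the trace end.
    """
    dff = np.asarray(dff, dtype=float)
    seg = dff[window.start:window.stop]
    if seg.size == 0:
        raise ValueError("stimulus window outside trace extent")
    responsive = bool(seg.max() > threshold)
    peak_frame = window.start + int(np.argmax(seg))
    peak = float(dff[peak_frame])
    cut = level * peak
    below_before = np.nonzero(dff[: peak_frame + 1] < cut)[0]
    activation = int(below_before[-1]) + 1 if below_before.size else 0
    below_after = np.nonzero(dff[peak_frame:] < cut)[0]
    if below_after.size:
        post = peak_frame + int(below_after[0]) - 1
        censored = False
    else:
        post = len(dff) - 1
        censored = True
    return ResponseResult(
        responsive=responsive,
        peak=peak,
        peak_frame=peak_frame,
        activation_frame=activation,
        activation_duration=post - activation + 1,
        censored=censored,
    )


def align_at_activation(
    dffs: Sequence[np.ndarray],
    window: StimulusWindow,
    n_pre: int = 0,
    n_post: int | None = None,
) -> np.ndarray:
    """Shift traces so each cell's activation frame maps to column ``n_pre``.

    Returns a matrix whose columns are frames relative to activation
    (-n_pre .. n_post - 1); frames outside a trace are NaN.  All cells must
    be responsive to the stimulus.
    """
    dffs = [np.asarray(d, dtype=float) for d in dffs]
    acts = []
    for d in dffs:
        r = activation_metrics(d, window)
        if not r.responsive:
            raise ValueError("align_at_activation requires responsive cells")
        acts.append(r.activation_frame)
    if n_post is None:
        n_post = max(len(d) - a for d, a in zip(dffs, acts))
    out = np.full((len(dffs), n_pre + n_post), np.nan)
    for i, (d, a) in enumerate(zip(dffs, acts)):
        for j in range(-n_pre, n_post):
            src = a + j
            if 0 <= src < len(d):
                out[i, n_pre + j] = d[src]
    return out


# ---------------------------------------------------------------------------
# Marker-rule subpopulation classification


@dataclass(frozen=True)
class MarkerRule:
    """One subpopulation rule over marker positivity calls.

    A cell matches when all of ``all_pos`` are positive, all of ``all_neg``
    are negative, at least one of ``any_pos`` is positive (if declared) and
    at least two of ``multi_pos`` are positive (if declared).
    """

    name: str
    all_pos: tuple[str, ...] = ()
    all_neg: tuple[str, ...] = ()
    any_groups: tuple[tuple[str, ...], ...] = ()  # match if any group all-positive
    multi_pos: tuple[str, ...] = ()

    def genes(self) -> tuple[str, ...]:
        return (
            self.all_pos
            + self.all_neg
            + tuple(g for grp in self.any_groups for g in grp)
            + self.multi_pos
        )

    def matches(self, positivity: Mapping[str, bool]) -> bool:
        for g in self.genes():
            if g not in positivity:
                raise KeyError(f"rule {self.name!r} references unmeasured gene {g!r}")
        if any(not positivity[g] for g in self.all_pos):
            return False
        if any(positivity[g] for g in self.all_neg):
            return False
        if self.any_groups and not any(
            all(positivity[g] for g in grp) for grp in self.any_groups
        ):
            return False
        if self.multi_pos and sum(positivity[g] for g in self.multi_pos) < 2:
            return False
        return True


#: Subpopulation rules in evaluation order A -> L ("multiple hits" = >= 2
#: of the listed markers).  E (damaged neurons) is absent by construction.
DEFAULT_MARKER_RULES: tuple[MarkerRule, ...] = (
    MarkerRule("A", any_groups=(("Runx3",), ("Piezo2", "P2ry1")), all_neg=("Tmc3",)),
    MarkerRule("B", all_pos=("Gabra1",)),
    MarkerRule("C", multi_pos=("Slit2", "Piezo2", "Ddc", "Tmc3"), all_neg=("Trpv1", "P2ry1")),
    MarkerRule("D", all_pos=("Tmc3",), all_neg=("Trpv1",)),
    MarkerRule("F", all_pos=("Gpr65",)),
    MarkerRule("G", all_pos=("Trpv1",), multi_pos=("Uts2b", "Vip", "Glp1r", "Cckar")),
    MarkerRule("H", all_pos=("Trpv1", "Trpa1"), all_neg=("Tmc3",)),
    MarkerRule("I", multi_pos=("Tmc3", "Car8", "Cckar"), all_neg=("Piezo2",)),
    MarkerRule("J", all_pos=("Trpv1", "Calca"), all_neg=("Piezo2",)),
    MarkerRule("K", all_pos=("Trpa1", "Kcng1", "Trpv1", "Calca")),
    MarkerRule("L", all_pos=("P2ry1",), all_neg=("Trpv1",)),
)


def classify_subpopulation(
    positivity: Mapping[str, bool],
    rules: Sequence[MarkerRule] = DEFAULT_MARKER_RULES,
) -> str:
    """First matching rule wins; cells matching none are labelled 'X'."""
    for rule in rules:
        if rule.matches(positivity):
            return rule.name
    return "X"


def classify_archetype(
    trace: Sequence[float],
    windows: Sequence[StimulusWindow],
    sustained_min_duration: int = 15,
    threshold: float = RESPONSE_THRESHOLD,
) -> str:
    """Classify one raw trace into a response archetype.

    Non-responder: responsive to no stimulus.  Polymodal: responsive to two
    or more stimuli.  Otherwise sustained vs transient by the activation
    duration of the single responded-to stimulus (sustained when duration
    >= ``sustained_min_duration`` frames or censored).
    """
    results = []
    for w in windows:
        dff = delta_f_over_f(trace, w.onset)
        results.append(activation_metrics(dff, w, threshold=threshold))
    responded = [r for r in results if r.responsive]
    if not responded:
        return "non_responder"
    if len(responded) >= 2:
        return "polymodal"
    r = responded[0]
    if r.censored or r.activation_duration >= sustained_min_duration:
        return "sustained"
    return "transient"
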