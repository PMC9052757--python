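"""Rule-based conformational-state and binding-phase classification.

The oxyanion strand (h49-PGVG) is classified into three states from the
backbone φ dihedrals of hV51 and hG50:

* ``inactive-OxH`` — strand blocked, ϕ-hV51 in [-180°, -100°]; the
  substrate can only bind in this state;
* ``unblocked-OxH`` — partial rotation of ϕ-hG50 with ϕ-hV51 still in the
  inactive band;
* ``active-OxH`` — complete rotation of ϕ-hV51 (around +60°), the oxyanion
  hole formed and catalytically competent.

Only the inactive ϕ-hV51 interval and the "ca. 60°" active position are
published; the default boxes below (in particular the unblocked ϕ-hG50
band (0°, 120°]) are explicit, config-overridable defaults chosen to match
the basin topology of the landscape, not published numbers.

Substrate-binding phases follow fixed d_nuc thresholds: unbound above the
12 Å recognition distance, captured below 6 Å, and catalytic only when
d_nuc <= 3.5 Å while the strand is in the active-OxH state.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import wrap_angle

__all__ = [
    "PeriodicInterval",
    "StateDefinition",
    "StateTrajectory",
    "BindingPhaseDefinition",
    "default_state_definitions",
    "classify_states",
    "classify_binding_phase",
    "dwell_segments",
    "landscape_histogram",
    "UNASSIGNED",
    "PRODUCTIVE_CLOSURE_THETA",
]

UNASSIGNED = "unassigned"

#: Interface-angle threshold (degrees) below which the HisF:HisH interface
#: counts as productively closed.
PRODUCTIVE_CLOSURE_THETA = 13.0


@dataclass(frozen=True)
class PeriodicInterval:
    """An angular interval on the (-180, 180] circle.

    ``lo``/``hi`` are degrees; closure of each edge is explicit.  Intervals
    may wrap through ±180 (lo > hi).  Membership is evaluated after
    wrapping the query into (-180, 180], so -180 and +180 are the same
    point on the circle.
    """

    lo: float
    hi: float
    closed_lo: bool = True
    closed_hi: bool = True

    def contains(self, x) -> np.ndarray:
        x = np.atleast_1d(wrap_angle(x))
        lo = wrap_angle(self.lo)
        hi = wrap_angle(self.hi)
        width = (hi - lo) % 360.0
        if width == 0.0 and self.lo != self.hi:
            width = 360.0  # full circle expressed as e.g. (-180, 180]
        d = (x - lo) % 360.0
        inside = (d > 0) & (d < width)
        at_lo = d == 0
        at_hi = d == width
        out = inside | (at_lo & self.closed_lo) | (at_hi & self.closed_hi)
        out[~np.isfinite(x)] = False
        return out


_ANY = PeriodicInterval(-180.0, 180.0, closed_lo=True, closed_hi=True)


@dataclass(frozen=True)
class StateDefinition:
    """A named state as a box of per-CV periodic intervals."""

    name: str
    phi_v51: PeriodicInterval = _ANY
    phi_g50: PeriodicInterval = _ANY

    def matches(self, v51, g50) -> np.ndarray:
        return self.phi_v51.contains(v51) & self.phi_g50.contains(g50)


def default_state_definitions() -> list[StateDefinition]:
    """Default oxyanion-strand state boxes, in priority order."""
    return [
        StateDefinition(
            "inactive-OxH",
            phi_v51=PeriodicInterval(-180.0, -100.0),
            phi_g50=PeriodicInterval(-180.0, 0.0),
        ),
        StateDefinition(
            "unblocked-OxH",
            phi_v51=PeriodicInterval(-180.0, -100.0),
            phi_g50=PeriodicInterval(0.0, 120.0, closed_lo=False),
        ),
        StateDefinition(
            "active-OxH",
            phi_v51=PeriodicInterval(20.0, 100.0),
        ),
    ]


@dataclass
class StateTrajectory:
    """Per-frame labels plus dwell segments and a transition count matrix."""

    labels: np.ndarray                      # (n,) str
    times: np.ndarray | None = None         # ns
    segments: list[tuple[str, int, int, float]] = field(default_factory=list)
    transitions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    def populations(self) -> pd.Series:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return pd.Series(counts / len(self.labels), index=vals)


def classify_states(
    phi_v51,
    phi_g50,
    defs: list[StateDefinition] | None = None,
    times=None,
) -> StateTrajectory:
    """Label each frame by the first matching state definition.

    ``phi_v51``/``phi_g50`` may be arrays or ObservableSeries.  Frames that
    match no definition (or have undefined dihedrals) are ``unassigned``.
    Classification is deterministic: identical inputs give identical labels.
    """
    v51 = np.asarray(getattr(phi_v51, "values", phi_v51), dtype=float)
    g50 = np.asarray(getattr(phi_g50, "values", phi_g50), dtype=float)
    if v51.shape != g50.shape:
        raise ValueError(
            f"series length mismatch: {v51.shape} vs {g50.shape}")
    if times is None:
        times = getattr(phi_v51, "times", None)
    defs = default_state_definitions() if defs is None else defs
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise ValueError("state names must be unique")
    labels = np.full(v51.shape, UNASSIGNED, dtype=object)
    unset = np.ones(v51.shape, dtype=bool)
    for d in defs:
        hit = d.matches(v51, g50) & unset
        labels[hit] = d.name
        unset &= ~hit
    return StateTrajectory(labels=labels, times=times)


@dataclass(frozen=True)
class BindingPhaseDefinition:
    """d_nuc thresholds (Å) and the conformational gate for catalysis."""

    recognition: float = 12.0
    capture: float = 6.0
    catalytic: float = 3.5
    required_state: str = "active-OxH"

    def __post_init__(self) -> None:
        if not (self.catalytic < self.capture < self.recognition):
            raise ValueError(
                "thresholds must satisfy catalytic < capture < recognition")


PHASES = ("unbound", "recognition", "captured", "catalytic")


def classify_binding_phase(
    d_nuc,
    state_labels,
    defs: BindingPhaseDefinition | None = None,
) -> np.ndarray:
    """Per-frame binding phase from d_nuc and the oxyanion-strand state.

    unbound: d > recognition; recognition: capture < d <= recognition;
    captured: catalytic < d <= capture, or d <= catalytic while the strand
    is not in the required state; catalytic: d <= catalytic AND the
    required (active-OxH) state.
    """
    defs = defs or BindingPhaseDefinition()
    d = np.asarray(getattr(d_nuc, "values", d_nuc), dtype=float)
    labels = np.asarray(
        getattr(state_labels, "labels", state_labels), dtype=object)
    if d.shape != labels.shape:
        raise ValueError(
            f"series length mismatch: {d.shape} vs {labels.shape}")
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("negative d_nuc distances")
    phases = np.full(d.shape, "unbound", dtype=object)
    phases[(d <= defs.recognition) & (d > defs.capture)] = "recognition"
    phases[(d <= defs.capture)] = "captured"
    catalytic = (d <= defs.catalytic) & (labels == defs.required_state)
    phases[catalytic] = "catalytic"
    return phases


def _runs(labels: np.ndarray) -> list[list]:
    """Run-length encode labels into mutable [label, start, end] triples."""
    runs: list[list] = []
    for i, lab in enumerate(labels):
        if runs and runs[-1][0] == lab:
            runs[-1][2] = i
        else:
            runs.append([lab, i, i])
    return runs


def dwell_segments(
    labels,
    min_dwell_frames: int = 1,
    times=None,
) -> StateTrajectory:
    """Extract dwell segments and transition counts from a label series.

    Runs shorter than ``min_dwell_frames`` are absorbed into a flanking
    segment: the shorter neighbour absorbs nothing — the blip takes the
    label of the longer flanking run (ties go to the preceding run).  The
    transition matrix counts label changes at the filtered segment
    boundaries.
    """
    if min_dwell_frames < 1:
        raise ValueError("min_dwell_frames must be >= 1")
    labels = np.asarray(getattr(labels, "labels", labels), dtype=object)
    if times is None and hasattr(labels, "times"):
        times = labels.times
    runs = _runs(labels)

    def run_len(r):
        return r[2] - r[1] + 1

    while len(runs) > 1:
        short = [i for i, r in enumerate(runs) if run_len(r) < min_dwell_frames]
        if not short:
            break
        # handle the shortest run first (first on ties) for determinism
        i = min(short, key=lambda k: (run_len(runs[k]), k))
        prev_r = runs[i - 1] if i > 0 else None
        next_r = runs[i + 1] if i + 1 < len(runs) else None
        if prev_r is None:
            absorber = next_r
        elif next_r is None:
            absorber = prev_r
        else:
            absorber = prev_r if run_len(prev_r) >= run_len(next_r) else next_r
        runs[i][0] = absorber[0]
        # merge adjacent equal-label runs back together
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged

    filtered = np.concatenate(
        [np.full(run_len(r), r[0], dtype=object) for r in runs]
    ) if runs else np.empty(0, dtype=object)

    if times is not None:
        times = np.asarray(times, dtype=float)
        dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    else:
        dt = 0.0
    segments = [
        (r[0], r[1], r[2], run_len(r) * dt) for r in runs
    ]

    names = sorted({str(r[0]) for r in runs})
    trans = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for a, b in zip(runs[:-1], runs[1:]):
        trans.loc[str(a[0]), str(b[0])] += 1
    return StateTrajectory(labels=filtered, times=times, segments=segments,
                           transitions=trans)


def landscape_histogram(phi_v51, phi_g50, bins: int = 72):
    """Periodic 2D population histogram over (-180°, 180°]².

    Returns ``(counts, xedges, yedges)``.  Values are wrapped into
    (-180, 180]; a value at exactly 180° lands in the last bin and -180°
    wraps into the same bin.  Undefined (NaN) frames are excluded.
    """
    if bins < 4:
        raise ValueError("need at least 4 bins per axis")
    v51 = wrap_angle(np.asarray(getattr(phi_v51, "values", phi_v51), float))
    g50 = wrap_angle(np.asarray(getattr(phi_g50, "values", phi_g50), float))
    ok = np.isfinite(v51) & np.isfinite(g50)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    counts, xe, ye = np.histogram2d(v51[ok], g50[ok], bins=[edges, edges])
    return counts, xe, ye
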