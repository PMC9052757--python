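"""Detection of spontaneous substrate-binding events.

A binding event is one excursion of the substrate from solvent into the
active site, read off the per-frame binding-phase labels (from
:func:`allostate.states.classify_binding_phase`).  An event opens at the
first frame that leaves ``unbound`` and closes when the phase returns to
``unbound`` (hysteresis: closure requires d_nuc back above the recognition
threshold, not merely above the capture threshold, so threshold chatter
does not fragment one excursion into many events) or when the trajectory
ends.  Events whose captured + catalytic dwell is below a minimum frame
count are discarded as grazing contacts.  An event is *productive* when at
least one frame reached the catalytic phase (d_nuc <= 3.5 Å in the
active-OxH state).

The anchoring hydrogen bond between the substrate and the hG52 backbone is
reported per event (its occupancy within the event span) but never used as
a gate: empirically no unbinding is seen while that bond holds, but there
is no rule to enforce.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BindingEvent", "detect_binding_events"]


@dataclass
class BindingEvent:
    """One contiguous excursion below the recognition threshold."""

    start: int                       # first non-unbound frame
    end: int                         # last non-unbound frame (inclusive)
    phase_sequence: list[tuple[str, float]] = field(default_factory=list)
    # ordered (phase, dwell_ns) with consecutive repeats merged
    anchor_occupancy: float = float("nan")
    productive: bool = False

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


def detect_binding_events(
    d_nuc,
    phase_labels,
    anchor_occupancy_series=None,
    min_capture_frames: int = 10,
    times=None,
) -> list[BindingEvent]:
    """Extract binding events from aligned d_nuc and phase-label series.

    Returns events in chronological order with disjoint frame spans.
    Raising ``min_capture_frames`` can only remove events, never add them.
    """
    if min_capture_frames < 1:
        raise ValueError("min_capture_frames must be >= 1")
    d = np.asarray(getattr(d_nuc, "values", d_nuc), dtype=float)
    phases = np.asarray(phase_labels, dtype=object)
    if d.shape != phases.shape:
        raise ValueError(
            f"misaligned series: d_nuc has {d.shape}, phases {phases.shape}")
    anchor = None
    if anchor_occupancy_series is not None:
        anchor = np.asarray(
            getattr(anchor_occupancy_series, "values",
                    anchor_occupancy_series), dtype=float)
        if anchor.shape != d.shape:
            raise ValueError("misaligned anchor occupancy series")
    if times is None:
        times = getattr(d_nuc, "times", None)
    if times is not None and len(times) > 1:
        dt = float(np.median(np.diff(np.asarray(times, dtype=float))))
    else:
        dt = 0.0

    events: list[BindingEvent] = []
    open_start: int | None = None
    for i in range(len(phases) + 1):
        in_bound = i < len(phases) and phases[i] != "unbound"
        if in_bound and open_start is None:
            open_start = i
        elif not in_bound and open_start is not None:
            events.append(_make_event(open_start, i - 1, phases, anchor, dt))
            open_start = None

    kept = []
    for ev in events:
        depth = sum(1 for p in phases[ev.start:ev.end + 1]
                    if p in ("captured", "catalytic"))
        if depth >= min_capture_frames:
            kept.append(ev)
    return kept


def _make_event(start: int, end: int, phases: np.ndarray,
                anchor: np.ndarray | None, dt: float) -> BindingEvent:
    seq: list[tuple[str, float]] = []
    count = 0
    current = None
    for p in phases[start:end + 1]:
        if p == current:
            count += 1
        else:
            if current is not None:
                seq.append((current, count * dt))
            current, count = p, 1
    if current is not None:
        seq.append((current, count * dt))
    occupancy = float("nan")
    if anchor is not None:
        occupancy = float(np.nanmean(anchor[start:end + 1]))
    return BindingEvent(
        start=start,
        end=end,
        phase_sequence=seq,
        anchor_occupancy=occupancy,
        productive=bool(np.any(phases[start:end + 1] == "catalytic")),
    )
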