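"""Experimental protocol timeline for the six-phase VR/platform paradigm.

The protocol alternates visual and motion stimulation: a quiet-stance
baseline with a static scene (BL), a visual onset with the sea scene but a
still platform (PRE), three platform-motion phases at 25/50/75 % of maximum
amplitude (P25, P50, P75), and a final phase where motion stops abruptly
while the scene continues (POST).
"""

from __future__ import annotations

from dataclasses import dataclass, field

PHASE_LABELS = ("BL", "PRE", "P25", "P50", "P75", "POST")

#: Platform motion amplitude as a fraction of maximum, per phase.
#: POST has the platform switched off; the perturbation there is the
#: after-effect of motion, not motion itself.
PLATFORM_INTENSITY = {
    "BL": 0.0,
    "PRE": 0.0,
    "P25": 0.25,
    "P50": 0.50,
    "P75": 0.75,
    "POST": 0.0,
}

DEFAULT_DURATIONS = {
    "BL": 120.0,
    "PRE": 40.0,
    "P25": 40.0,
    "P50": 40.0,
    "P75": 40.0,
    "POST": 40.0,
}


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered sequence of (phase label, duration in seconds).

    Labels must be unique and drawn from :data:`PHASE_LABELS`; durations
    strictly positive.
    """

    phases: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: tuple(DEFAULT_DURATIONS.items())
    )

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.phases]
        if len(labels) != len(set(labels)):
            raise ValueError("phase labels must be unique")
        for lab, dur in self.phases:
            if lab not in PHASE_LABELS:
                raise ValueError(f"unknown phase label {lab!r}")
            if not dur > 0:
                raise ValueError(f"duration of phase {lab!r} must be > 0, got {dur}")

    @classmethod
    def default(cls) -> "ProtocolTimeline":
        return cls()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.phases)

    def duration(self, label: str) -> float:
        for lab, dur in self.phases:
            if lab == label:
                return dur
        raise KeyError(f"phase {label!r} not in timeline")

    def onset(self, label: str) -> float:
        """Start time of *label* in seconds from the beginning of the recording."""
        t = 0.0
        for lab, dur in self.phases:
            if lab == label:
                return t
            t += dur
        raise KeyError(f"phase {label!r} not in timeline")

    @property
    def total_duration(self) -> float:
        return sum(dur for _, dur in self.phases)

    def to_dict(self) -> dict:
        return {"phases": [[lab, dur] for lab, dur in self.phases]}

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolTimeline":
        return cls(tuple((str(lab), float(dur)) for lab, dur in d["phases"]))
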