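"""Stimulus protocol: the temporal contract obeyed by all response detection.

Frames are 0-based; times are ``frame * frame_interval_s``; windows are
half-open ``[start, end)`` unless a criterion states an inclusive bound
(the 60-s latency limit is inclusive: a crossing at exactly 60 s counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml


@dataclass(frozen=True)
class Application:
    """One application of one stimulus."""

    stimulus: str
    onset_frame: int
    duration_s: float = 30.0


@dataclass
class StimulusProtocol:
    """Frame timing and stimulus application schedule of one recording.

    Defaults mirror the en face imaging configuration: one frame every
    1.5 s, a 50-frame baseline preceding the first stimulus, 30-s
    applications delivered at least twice per stimulus with >= 4 min
    between onsets, and a 60-s post-onset latency window for responses.
    """

    frame_interval_s: float = 1.5
    baseline_window: tuple[int, int] = (0, 50)  # half-open frame range
    applications: list[Application] = field(default_factory=list)
    latency_window_s: float = 60.0
    min_applications_per_stimulus: int = 2
    min_interstimulus_s: float = 240.0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        b0, b1 = self.baseline_window
        if not (0 <= b0 < b1):
            raise ValueError("baseline_window must be a non-empty [start, end) range")
        self.applications = [
            a if isinstance(a, Application) else Application(*a) for a in self.applications
        ]
        onsets = [a.onset_frame for a in self.applications]
        if onsets != sorted(onsets):
            raise ValueError("applications must be sorted by onset frame")
        if self.applications and onsets[0] < b1:
            raise ValueError("baseline_window must precede the first application onset")
        for prev, nxt in zip(self.applications, self.applications[1:]):
            gap_s = (nxt.onset_frame - prev.onset_frame) * self.frame_interval_s
            if gap_s < self.min_interstimulus_s:
                warnings.warn(
                    f"inter-onset gap {gap_s:.1f} s between {prev.stimulus!r} and "
                    f"{nxt.stimulus!r} is below {self.min_interstimulus_s:.0f} s",
                    stacklevel=2,
                )
        for label in self.stimuli:
            n = len(self.applications_of(label))
            if n < self.min_applications_per_stimulus:
                raise ValueError(
                    f"stimulus {label!r} has {n} applications; "
                    f"{self.min_applications_per_stimulus} required"
                )

    # -- derived quantities -------------------------------------------------

    @property
    def stimuli(self) -> list[str]:
        """Unique stimulus labels in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.applications:
            seen.setdefault(a.stimulus, None)
        return list(seen)

    def applications_of(self, stimulus: str) -> list[Application]:
        return [a for a in self.applications if a.stimulus == stimulus]

    @property
    def latency_window_frames(self) -> int:
        """Number of frames from onset to the last frame inside the latency
        window (inclusive of a crossing at exactly ``latency_window_s``)."""
        return int(self.latency_window_s / self.frame_interval_s + 1e-9)

    @property
    def n_frames_required(self) -> int:
        """Minimum trace length covering baseline and every search window."""
        n = self.baseline_window[1]
        for a in self.applications:
            n = max(n, a.onset_frame + self.latency_window_frames + 1)
        return n

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame_interval_s": self.frame_interval_s,
            "baseline_window": list(self.baseline_window),
            "applications": [
                {"stimulus": a.stimulus, "onset_frame": a.onset_frame, "duration_s": a.duration_s}
                for a in self.applications
            ],
            "latency_window_s": self.latency_window_s,
            "min_applications_per_stimulus": self.min_applications_per_stimulus,
            "min_interstimulus_s": self.min_interstimulus_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        apps = [
            Application(a["stimulus"], int(a["onset_frame"]), float(a.get("duration_s", 30.0)))
            for a in d.get("applications", [])
        ]
        kwargs = {k: d[k] for k in (
            "frame_interval_s", "latency_window_s",
            "min_applications_per_stimulus", "min_interstimulus_s",
        ) if k in d}
        bw = tuple(d.get("baseline_window", (0, 50)))
        return cls(applications=apps, baseline_window=bw, **kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def two_stimulus_protocol(
    labels: tuple[str, str] = ("A", "B"),
    n_repeats: int = 2,
    first_onset_frame: int = 60,
    gap_frames: int = 160,
    frame_interval_s: float = 1.5,
) -> StimulusProtocol:
    """Alternating two-stimulus schedule A, B, A, B, ... with equal gaps.

    The default 160-frame gap at 1.5 s/frame is the 4-min inter-stimulus
    interval of the recordings.
    """
    apps = []
    onset = first_onset_frame
    for _ in range(n_repeats):
        for lab in labels:
            apps.append(Application(lab, onset))
            onset += gap_frames
    return StimulusProtocol(frame_interval_s=frame_interval_s, applications=apps)
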