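"""Synthetic-data generator for every input kind the pipeline consumes.

The generator emulates the structure of the study's recordings with known
ground truth so that every downstream stage is testable without real data:

* knob fields on a jittered hexagonal lattice at 8.32 knobs/100 um^2
  (knobs are physical structures and cannot overlap, hence not Poisson);
* per-knob raw fluorescence traces — a baseline with optional linear
  bleaching and iid Gaussian noise, plus double-exponential Ca2+ transients
  planted on the applications of each responder's stimulus class.  Class
  fractions default to the selectivity pattern of the urine recordings
  (both 1.6%, A-only 0.5%, B-only 0.1% of all knobs);
* rendered image stacks (Gaussian spots) for the knob detector;
* behavioral cohorts with a planted log2 investigation-time preference;
* region count tables with binomial positive-cell counts.

All randomness flows from a single explicit seed; outputs are reproducible
bit-for-bit for a fixed seed and library version.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from ._util import DataError
from .behavior import BehaviorSession, Bout
from .counts import CountRegion
from .protocol import StimulusProtocol
from .traces import KnobTrace

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "TraceDataset",
    "generate_knob_field",
    "generate_trace_dataset",
    "render_frame",
    "render_stack",
    "write_stack",
    "generate_behavior_cohort",
    "generate_count_regions",
    "transient_kernel",
]

#: Default class fractions (of ALL knobs) for the two-stimulus selectivity
#: pattern seen with urine stimuli: 1.6% respond to both, 0.5% only to the
#: healthy-condition stimulus, 0.1% only to the sick-condition stimulus.
DEFAULT_CLASS_FRACTIONS = {"A_only": 0.005, "B_only": 0.001, "both": 0.016}


@dataclass
class SynthConfig:
    """Parameters of the synthetic recordings.

    Amplitudes are drawn per transient from ``amp_range`` in multiples of
    ``amp_ref_sd`` (defaulting to ``noise_sd``), expressed on the normalized
    dF/F0 scale; the lower end must exceed the 2-SD detection threshold or
    planted responders would be sub-threshold by construction.
    """

    seed: int = 0
    field_area_um: tuple[float, float] = (100.0, 100.0)
    knob_density_per_100um2: float = 8.32
    class_fractions: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    noise_sd: float = 0.02  # fraction of F0, per frame
    bleach_slope: float = 0.0  # fraction of F0 lost per frame
    amp_range: tuple[float, float] = (5.0, 8.0)  # multiples of amp_ref_sd
    amp_ref_sd: Optional[float] = None  # reference sigma; defaults to noise_sd
    rise_tau_s: float = 3.0
    decay_tau_s: float = 15.0
    latency_range_s: tuple[float, float] = (1.5, 9.0)
    respond_prob: float = 1.0
    f0_range: tuple[float, float] = (200.0, 600.0)  # raw fluorescence units

    def __post_init__(self) -> None:
        fr = self.class_fractions
        if any(v < 0 for v in fr.values()) or sum(fr.values()) > 1 + 1e-12:
            raise ValueError("class fractions must be >= 0 and sum to <= 1")
        if self.knob_density_per_100um2 < 0:
            raise ValueError("knob density must be non-negative")
        if not (0 < self.respond_prob <= 1):
            raise ValueError("respond_prob must be in (0, 1]")
        if self.noise_sd < 0 or self.bleach_slope < 0:
            raise ValueError("noise_sd and bleach_slope must be non-negative")
        ref = self.amp_ref_sd if self.amp_ref_sd is not None else self.noise_sd
        if ref > 0 and self.amp_range[0] <= 2:
            raise ValueError(
                "amp_range minimum must exceed 2 (the detection threshold in SD units)"
            )

    @property
    def effective_amp_ref_sd(self) -> float:
        return self.amp_ref_sd if self.amp_ref_sd is not None else self.noise_sd


@dataclass
class GroundTruth:
    """True class per knob and true per-application fire events."""

    classes: pd.DataFrame  # columns knob_id, true_class
    fire_events: pd.DataFrame  # columns knob_id, application_index, stimulus, fired

    def class_counts(self) -> dict[str, int]:
        return self.classes["true_class"].value_counts().to_dict()


@dataclass
class TraceDataset:
    """A set of per-knob raw traces from one synthetic recording site."""

    site_id: str
    traces: list[KnobTrace]
    protocol: StimulusProtocol

    def __len__(self) -> int:
        return len(self.traces)

    def to_table(self) -> pd.DataFrame:
        """Long format: site_id, knob_id, frame, fluorescence."""
        n_frames = len(self.traces[0].raw) if self.traces else 0
        return pd.DataFrame(
            {
                "site_id": np.repeat([t.site_id for t in self.traces], n_frames),
                "knob_id": np.repeat([t.knob_id for t in self.traces], n_frames),
                "frame": np.tile(np.arange(n_frames), len(self.traces)),
                "fluorescence": np.concatenate([t.raw for t in self.traces])
                if self.traces else np.array([]),
            }
        )

    def write(self, path, float_format: Optional[str] = None) -> None:
        """Write the long-format table; ``float_format`` (e.g. ``"%.2f"``)
        trades file size for precision."""
        self.to_table().to_csv(path, index=False, float_format=float_format)


# -- knob fields ------------------------------------------------------------

MIN_KNOB_SPACING_UM = 2.0


def generate_knob_field(config: SynthConfig) -> np.ndarray:
    """Knob positions (n, 2) in um on a jittered hexagonal lattice.

    The lattice pitch is set so the point density matches the configured
    knob density; jitter is bounded so no two knobs come closer than 2 um.
    """
    w, h = config.field_area_um
    if w <= 0 or h <= 0:
        raise ValueError("field area dimensions must be positive")
    rho = config.knob_density_per_100um2 / 100.0  # knobs per um^2
    if rho == 0:
        return np.empty((0, 2))
    rng = np.random.default_rng(config.seed)
    pitch = float(np.sqrt(2.0 / (np.sqrt(3.0) * rho)))
    row_dy = pitch * np.sqrt(3.0) / 2.0
    # per-axis jitter bound keeping displacement norm <= (pitch - 2) / 2
    jit = max(0.0, (pitch - MIN_KNOB_SPACING_UM) / 2.0) / np.sqrt(2.0)
    pts = []
    y = row_dy / 2.0
    row = 0
    while y < h:
        x0 = pitch / 2.0 + (pitch / 2.0 if row % 2 else 0.0)
        xs = np.arange(x0, w, pitch)
        for x in xs:
            dx, dy = rng.uniform(-jit, jit, size=2)
            px, py = x + dx, y + dy
            if 0 <= px < w and 0 <= py < h:
                pts.append((px, py))
        y += row_dy
        row += 1
    return np.asarray(pts, dtype=float).reshape(-1, 2)


# -- trace datasets ---------------------------------------------------------

#: Kernel values below this fraction of the peak are clamped to zero, giving
#: transients finite support (~9 decay time constants) so a response cannot
#: bleed an infinitesimal tail into the next stimulus window.
KERNEL_CUTOFF = 1e-4


def transient_kernel(
    t_s: np.ndarray, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Unit-peak double-exponential Ca2+ transient, zero for t < 0.

    The exponential tail is truncated at ``KERNEL_CUTOFF`` of the peak.
    """
    t = np.asarray(t_s, dtype=float)
    g = np.where(t >= 0, (1.0 - np.exp(-t / rise_tau_s)) * np.exp(-t / decay_tau_s), 0.0)
    t_peak = rise_tau_s * np.log1p(decay_tau_s / rise_tau_s)
    g_peak = (1.0 - np.exp(-t_peak / rise_tau_s)) * np.exp(-t_peak / decay_tau_s)
    g = g / g_peak
    return np.where(g >= KERNEL_CUTOFF, g, 0.0)


CLASS_ORDER = ("A_only", "B_only", "both", "none")


def _class_stimuli(cls: str, stimuli: Sequence[str]) -> tuple[str, ...]:
    if cls == "none":
        return ()
    if len(stimuli) < 2 and cls in ("B_only", "both"):
        raise DataError(f"class {cls} requires a two-stimulus protocol")
    if cls == "A_only":
        return (stimuli[0],)
    if cls == "B_only":
        return (stimuli[1],)
    return (stimuli[0], stimuli[1])


def generate_trace_dataset(
    field: np.ndarray,
    protocol: StimulusProtocol,
    config: SynthConfig,
    site_id: str = "site0",
    n_frames: Optional[int] = None,
) -> tuple[TraceDataset, GroundTruth]:
    """Raw traces for every knob in the field plus the planted ground truth.

    Each knob's raw trace is ``F0_true * (1 - bleach_slope * frame)`` plus
    iid Gaussian noise of SD ``noise_sd * F0_true``.  Knob classes are drawn
    multinomially from the class fractions; on each application of a
    stimulus in its class a responder fires with probability
    ``respond_prob``, adding a double-exponential transient that starts a
    random latency after onset.
    """
    field = np.asarray(field, dtype=float).reshape(-1, 2)
    n = field.shape[0]
    required = protocol.n_frames_required
    if n_frames is None:
        n_frames = required
    if n_frames < required:
        raise DataError(
            f"trace length {n_frames} does not cover the protocol ({required} frames)"
        )
    rng = np.random.default_rng(config.seed)
    stimuli = protocol.stimuli

    # multinomial class assignment: counts sum to n exactly
    fracs = [config.class_fractions.get(c, 0.0) for c in CLASS_ORDER[:3]]
    fracs.append(1.0 - sum(fracs))
    counts = rng.multinomial(n, fracs)
    classes = np.repeat(np.arange(4), counts)
    rng.shuffle(classes)

    f0 = rng.uniform(*config.f0_range, size=n)
    t_frames = np.arange(n_frames, dtype=float)
    raw = f0[:, None] * (1.0 - config.bleach_slope * t_frames)[None, :]
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, 1.0, size=(n, n_frames)) * (config.noise_sd * f0)[:, None]

    amp_ref = config.effective_amp_ref_sd
    fire_rows = []
    for i in np.flatnonzero(classes != 3):
        cls = CLASS_ORDER[classes[i]]
        mine = _class_stimuli(cls, stimuli)
        for app_idx, app in enumerate(protocol.applications):
            if app.stimulus not in mine:
                continue
            fired = bool(rng.random() < config.respond_prob)
            fire_rows.append(
                {"knob_id": f"k{i:05d}", "application_index": app_idx,
                 "stimulus": app.stimulus, "fired": fired}
            )
            if not fired:
                continue
            amp = rng.uniform(*config.amp_range) * amp_ref * f0[i]
            latency = rng.uniform(*config.latency_range_s)
            t_rel = (t_frames - app.onset_frame) * protocol.frame_interval_s - latency
            raw[i] += amp * transient_kernel(t_rel, config.rise_tau_s, config.decay_tau_s)

    traces = [
        KnobTrace(site_id, f"k{i:05d}", raw[i], position_um=tuple(field[i]))
        for i in range(n)
    ]
    truth = GroundTruth(
        classes=pd.DataFrame(
            {"knob_id": [f"k{i:05d}" for i in range(n)],
             "true_class": [CLASS_ORDER[c] for c in classes]}
        ),
        fire_events=pd.DataFrame(
            fire_rows, columns=["knob_id", "application_index", "stimulus", "fired"]
        ),
    )
    return TraceDataset(site_id, traces, protocol), truth


# -- image rendering --------------------------------------------------------

def render_frame(
    field: np.ndarray,
    values: np.ndarray,
    field_area_um: tuple[float, float],
    psf_sigma_um: float = 0.6,
    pixel_um: float = 0.25,
) -> np.ndarray:
    """Render one frame: each knob a Gaussian spot scaled by its value."""
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    w, h = field_area_um
    shape = (int(np.ceil(h / pixel_um)), int(np.ceil(w / pixel_um)))
    img = np.zeros(shape, dtype=np.float32)
    field = np.asarray(field, dtype=float).reshape(-1, 2)
    if field.shape[0] == 0:
        return img
    sig_px = psf_sigma_um / pixel_um
    r = int(np.ceil(4 * sig_px))
    for (x_um, y_um), v in zip(field, np.asarray(values, dtype=float)):
        cx, cy = x_um / pixel_um, y_um / pixel_um
        x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        patch = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sig_px**2))
        img[y0:y1, x0:x1] += (v * patch).astype(np.float32)
    return img


def render_stack(
    field: np.ndarray,
    dataset: TraceDataset,
    psf_sigma_um: float = 0.6,
    pixel_um: float = 0.25,
    frames: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Render a (frames, H, W) stack from a trace dataset."""
    field = np.asarray(field, dtype=float).reshape(-1, 2)
    if field.shape[0] != len(dataset.traces) and field.shape[0] > 0:
        raise ValueError("field and dataset disagree on knob count")
    n_frames = len(dataset.traces[0].raw) if dataset.traces else 0
    idx = list(range(n_frames)) if frames is None else list(frames)
    w = max((t.position_um[0] for t in dataset.traces), default=0.0)
    h = max((t.position_um[1] for t in dataset.traces), default=0.0)
    area = (w + 4 * psf_sigma_um, h + 4 * psf_sigma_um)
    vals = np.array([t.raw for t in dataset.traces]) if dataset.traces else np.empty((0, 0))
    stack = [
        render_frame(field, vals[:, f] if vals.size else vals, area, psf_sigma_um, pixel_um)
        for f in idx
    ]
    return np.stack(stack) if stack else np.zeros((0, 1, 1), dtype=np.float32)


def write_stack(path, stack: np.ndarray) -> None:
    """Write a multi-page grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


# -- behavior ---------------------------------------------------------------

def generate_behavior_cohort(
    n_mice: int,
    planted_mu: float = 0.81,
    bout_rate: float = 12.0,
    bout_mean_s: float = 2.5,
    seed: int = 0,
    session_length_s: float = 600.0,
    gamma_shape: float = 2.0,
) -> list[BehaviorSession]:
    """Cohort of sessions with a planted log2 investigation-time preference.

    Per mouse and side, the bout count is Poisson(``bout_rate``) and bout
    durations are Gamma with mean ``bout_mean_s`` (side A scaled by
    ``2**planted_mu``), so the expected log2 IT ratio equals ``planted_mu``
    (the lognormal-style bias of log-of-sums cancels between sides).  Bouts
    are placed non-overlapping with Dirichlet-distributed gaps.  A side's
    Poisson zero (probability ~e^-rate) is redrawn so investigation times
    stay positive.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    rng = np.random.default_rng(seed)
    sessions = []
    for m in range(n_mice):
        bouts: list[tuple[str, float]] = []
        for label, scale_mult in (("A", 2.0**planted_mu), ("B", 1.0)):
            n_b = 0
            while n_b == 0:
                n_b = int(rng.poisson(bout_rate))
            durs = rng.gamma(gamma_shape, bout_mean_s * scale_mult / gamma_shape, size=n_b)
            bouts.extend((label, float(d)) for d in durs)
        order = rng.permutation(len(bouts))
        bouts = [bouts[i] for i in order]
        total = sum(d for _, d in bouts)
        if total >= session_length_s:
            raise DataError(
                f"mouse {m}: bout durations ({total:.0f} s) exceed the session"
            )
        gaps = rng.dirichlet(np.ones(len(bouts) + 1)) * (session_length_s - total)
        t = 0.0
        placed = []
        for (label, dur), gap in zip(bouts, gaps[:-1]):
            t += gap
            placed.append(Bout(label, t, t + dur))
            t += dur
        sessions.append(BehaviorSession(f"m{m:03d}", placed, session_length_s))
    return sessions


# -- count tables -----------------------------------------------------------

def generate_count_regions(
    n_regions: int,
    dapi_rate_per_um2: float = 0.05,
    p_positive: float = 0.0219,
    seed: int = 0,
    area_um2: float = 20000.0,
    subject_id: str = "s000",
    region_label: str = "VNO",
) -> list[CountRegion]:
    """Binomial positive-cell counts over Poisson DAPI totals per region."""
    if not (0 <= p_positive <= 1):
        raise ValueError("p_positive must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_regions):
        dapi = int(rng.poisson(dapi_rate_per_um2 * area_um2))
        pos = int(rng.binomial(dapi, p_positive)) if dapi > 0 else 0
        out.append(
            CountRegion(subject_id, f"{region_label}_{i:03d}", area_um2, pos, dapi)
        )
    return out
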