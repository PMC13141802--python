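"""Synthetic data generators for the event-segmentation pipeline.

Real recordings for this paradigm (button presses while watching a silent
30-minute film, plus 60-channel EEG) are not shareable, so every downstream
stage is exercised on simulated data that carries the statistical structure
the stages assume:

* a per-2-s-bin coding of nine types of situational change (Bernoulli flags),
* button-press streams generated from a random-intercept logistic model whose
  slope on the change count may differ between groups,
* voxel-grid log-power datasets with a planted boundary-vs-no-boundary effect,
* band-limited sensor segments mixed through a leadfield, for the beamformer.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The nine situational change types coded per 2-s movie bin.
CHANGE_TYPES = (
    "character",
    "character_character",
    "character_object",
    "temporal",
    "large_space",
    "small_space",
    "cause",
    "goal",
    "scene",
)

#: Default clip layout: three 10-minute clips.
DEFAULT_CLIP_BOUNDARIES = (0.0, 600.0, 1200.0, 1800.0)


@dataclass
class SimConfig:
    """Parameters of the behavioral simulation.

    The logistic model generating responses is, per subject ``s`` and bin ``b``::

        logit P(response) = beta0 + u_s + (beta_count + group_s * beta_group_interaction) * n_changes_b

    with ``u_s ~ Normal(0, random_intercept_sd)`` and ``group`` coded 0/1
    (neurotypical / ASD).  Default coefficients follow the fitted behavioral
    model: intercept -3.26, count slope 0.30, group-by-count interaction -0.09.
    """

    seed: int = 0
    n_subjects_per_group: int = 30
    n_bins: int = 900
    bin_width: float = 2.0
    clip_boundaries: tuple = DEFAULT_CLIP_BOUNDARIES
    change_probs: tuple = (0.1,) * 9
    beta0: float = -3.26
    beta_count: float = 0.30
    beta_group_interaction: float = -0.09
    random_intercept_sd: float = 0.5

    def __post_init__(self) -> None:
        probs = np.asarray(self.change_probs, dtype=float)
        if probs.shape != (len(CHANGE_TYPES),):
            raise ValueError(f"change_probs must have {len(CHANGE_TYPES)} entries")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("change probabilities must lie in [0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be non-negative")
        duration = self.n_bins * self.bin_width
        if abs(self.clip_boundaries[-1] - duration) > 1e-9:
            raise ValueError(
                f"clip boundaries end at {self.clip_boundaries[-1]} s but "
                f"n_bins * bin_width = {duration} s"
            )

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width


@dataclass
class ResponseStream:
    """One subject's button-press times (seconds, strictly increasing)."""

    subject_id: str
    group: int  # 0 = NT, 1 = ASD
    response_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.response_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("response times must be strictly increasing")
        self.response_times = t


def simulate_change_table(config: SimConfig) -> pd.DataFrame:
    """Draw the situational-change coding: i.i.d. Bernoulli flags per bin.

    Returns a frame with ``bin_index``, one 0/1 column per change type and the
    derived ``n_changes`` count.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.change_probs, dtype=float)
    flags = (rng.random((config.n_bins, len(CHANGE_TYPES))) < probs).astype(np.int64)
    table = pd.DataFrame(flags, columns=list(CHANGE_TYPES))
    table.insert(0, "bin_index", np.arange(config.n_bins))
    table["n_changes"] = flags.sum(axis=1)
    return table


def simulate_responses(table: pd.DataFrame, config: SimConfig) -> list[ResponseStream]:
    """Generate button-press streams from the random-intercept logistic model.

    A response, when drawn for a bin, is placed at a uniform offset inside that
    bin (the model does not resolve within-bin timing).  Subjects are returned
    NT group first, then ASD, with ids ``nt00``…, ``asd00``….
    """
    if len(table) != config.n_bins:
        raise ValueError("change table does not match config.n_bins")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_changes = table["n_changes"].to_numpy(dtype=float)
    streams: list[ResponseStream] = []
    for group, prefix in ((0, "nt"), (1, "asd")):
        slope = config.beta_count + group * config.beta_group_interaction
        for s in range(config.n_subjects_per_group):
            u = rng.normal(0.0, config.random_intercept_sd)
            eta = config.beta0 + u + slope * n_changes
            p = 1.0 / (1.0 + np.exp(-eta))
            hits = rng.random(config.n_bins) < p
            offsets = rng.uniform(0.0, config.bin_width, size=config.n_bins)
            times = (np.flatnonzero(hits) * config.bin_width) + offsets[hits]
            streams.append(ResponseStream(f"{prefix}{s:02d}", group, np.sort(times)))
    return streams


# ---------------------------------------------------------------------------
# Source-space power datasets
# ---------------------------------------------------------------------------

@dataclass
class SourceSimSpec:
    """Voxel-grid power simulation with a planted condition effect.

    ``effect_delta`` is the log-power shift added to planted voxels in the
    boundary (BI) condition; ``group_scale`` multiplies the planted *extent*
    for the second group (its first ``round(scale * k)`` voxels, in sorted
    order, stay planted), leaving the per-voxel shift unchanged.
    """

    grid_shape: tuple = (10, 10, 10)
    grid_spacing: float = 0.5  # cm
    planted_voxels: tuple = ()
    effect_delta: float = 0.0
    group_scale: float = 1.0
    noise_sd: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        n = int(np.prod(self.grid_shape))
        if n == 0:
            raise ValueError("grid is empty")
        planted = np.asarray(sorted(self.planted_voxels), dtype=np.int64)
        if planted.size and (planted.min() < 0 or planted.max() >= n):
            raise ValueError("planted_voxels outside the grid")
        self.planted_voxels = tuple(planted.tolist())

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class PowerDataset:
    """Per-subject, per-condition, per-voxel source power for one group.

    ``power`` has shape (n_subjects, 2, n_voxels) with condition axis ordered
    (BI, NBI).  Conditions are paired within subject.
    """

    power: np.ndarray
    grid_shape: tuple
    grid_spacing: float
    group: int = 0

    CONDITIONS = ("BI", "NBI")

    @property
    def bi(self) -> np.ndarray:
        return self.power[:, 0, :]

    @property
    def nbi(self) -> np.ndarray:
        return self.power[:, 1, :]

    @property
    def n_subjects(self) -> int:
        return self.power.shape[0]


def grid_coordinates(grid_shape, grid_spacing: float) -> np.ndarray:
    """(n_voxels, 3) cm coordinates of a regular lattice, C-order voxel ids."""
    idx = np.indices(grid_shape).reshape(3, -1).T
    return idx * float(grid_spacing)


def planted_voxels_for_group(spec: SourceSimSpec, group: int) -> np.ndarray:
    """The planted voxel set for a group; group 2's extent is scaled."""
    planted = np.asarray(spec.planted_voxels, dtype=np.int64)
    if group == 0 or spec.group_scale == 1.0 or planted.size == 0:
        return planted
    k = int(round(spec.group_scale * planted.size))
    return planted[:k]


def simulate_power_dataset(
    spec: SourceSimSpec, n_per_group: int, seed: int
) -> tuple[PowerDataset, PowerDataset]:
    """Simulate paired BI/NBI log-power for two groups on the same grid.

    log-power = baseline + delta * 1[voxel planted, condition BI] + N(0, noise_sd),
    independently per subject, condition and voxel.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n_vox = spec.n_voxels
    out = []
    for group in (0, 1):
        power = spec.baseline + rng.normal(
            0.0, spec.noise_sd, size=(n_per_group, 2, n_vox)
        )
        planted = planted_voxels_for_group(spec, group)
        power[:, 0, planted] += spec.effect_delta
        out.append(PowerDataset(power, tuple(spec.grid_shape), spec.grid_spacing, group))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Sensor-level segments for the beamformer
# ---------------------------------------------------------------------------

@dataclass
class SensorSimSpec:
    """A single oscillatory source mixed through a leadfield, plus white noise.

    ``leadfield`` has shape (n_sensors, n_voxels, 3): the gain of a unit dipole
    at each voxel, one column per orientation.  The active voxel emits one
    band-limited oscillation per orientation with phases redrawn every segment.
    """

    leadfield: np.ndarray
    active_voxel: int = 0
    source_band: tuple = (8.0, 12.0)
    amplitude: float = 1.0
    noise_sd: float = 1.0
    n_segments: int = 50
    sampling_rate: float = 300.0
    segment_seconds: float = 2.0

    def __post_init__(self) -> None:
        lf = np.asarray(self.leadfield, dtype=float)
        if lf.ndim != 3 or lf.shape[2] != 3:
            raise ValueError("leadfield must have shape (n_sensors, n_voxels, 3)")
        if not np.all(np.isfinite(lf)):
            raise ValueError("leadfield must be finite")
        lo, hi = self.source_band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError("source band must lie within (0, Nyquist)")
        if not (0 <= self.active_voxel < lf.shape[1]):
            raise ValueError("active_voxel outside the leadfield grid")
        self.leadfield = lf


def simulate_leadfield(
    n_sensors: int, n_voxels: int, seed: int, smooth: float = 0.0, coords=None
) -> np.ndarray:
    """Random free-orientation leadfield, optionally smoothed over the grid.

    With ``smooth > 0`` and voxel coordinates given, gains are convolved with a
    Gaussian kernel of that length scale (cm), mimicking the spatial coherence
    of volume conduction; otherwise entries are i.i.d. standard normal.
    """
    rng = np.random.default_rng(seed)
    lf = rng.standard_normal((n_sensors, n_voxels, 3))
    if smooth > 0:
        if coords is None:
            raise ValueError("smoothing requires voxel coordinates")
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        kernel = np.exp(-d2 / (2 * smooth**2))
        kernel /= kernel.sum(axis=1, keepdims=True)
        lf = np.einsum("vw,swo->svo", kernel, lf)
    return lf


def simulate_sensor_segments(spec: SensorSimSpec, seed: int) -> np.ndarray:
    """Segments of shape (n_segments, n_sensors, n_samples).

    Each segment is ``L @ s(t) + noise`` where ``L`` is the active voxel's
    (n_sensors, 3) leadfield and each orientation of ``s`` is a sum of cosines
    at the FFT frequencies inside the source band, with independent random
    phases per segment and orientation (so the band CSD has rank <= 3).
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(spec.segment_seconds * spec.sampling_rate))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / spec.sampling_rate)
    lo, hi = spec.source_band
    in_band = freqs[(freqs >= lo) & (freqs <= hi)]
    if in_band.size == 0:
        raise ValueError("no FFT frequency falls inside the source band")
    t = np.arange(n_samples) / spec.sampling_rate
    L = spec.leadfield[:, spec.active_voxel, :]  # (n_sensors, 3)
    n_sensors = spec.leadfield.shape[0]
    segments = np.empty((spec.n_segments, n_sensors, n_samples))
    scale = spec.amplitude / np.sqrt(in_band.size)
    for k in range(spec.n_segments):
        phases = rng.uniform(0, 2 * np.pi, size=(3, in_band.size))
        source = scale * np.cos(
            2 * np.pi * in_band[None, :, None] * t[None, None, :] + phases[:, :, None]
        ).sum(axis=1)  # (3, n_samples)
        segments[k] = L @ source + rng.normal(0, spec.noise_sd, (n_sensors, n_samples))
    return segments


def replace(obj, **changes):
    """``dataclasses.replace`` re-export for convenient spec tweaking."""
    return dataclasses.replace(obj, **changes)
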