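"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* time in milliseconds, sampling rates in kHz (samples per ms)
* currents in pA, voltages in mV, charge in fC (1 pA * 1 ms = 1 fC)
* inward (excitatory) currents are negative-going in raw traces;
  magnitudes are reported positive by the analysis layers
* image dimensions in pixels with an explicit pixel size in um/px
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np


class DegenerateSweepError(ValueError):
    """Raised when a sweep lacks the structure an analysis requires."""


class ParameterError(ValueError):
    """Raised for physically impossible or inconsistent configuration."""


@dataclass
class Sweep:
    """A single sampled trace (current- or voltage-clamp).

    Parameters
    ----------
    values : np.ndarray
        Sampled signal, pA (voltage clamp) or mV (current clamp).
    sampling_rate : float
        Sampling rate in kHz (samples per millisecond).
    units : str
        ``"pA"`` or ``"mV"``.
    epochs : dict
        Named intervals ``{name: (t0_ms, t1_ms)}``, e.g. baseline/step/post.
    holding_potential : float, optional
        Command potential in mV for voltage-clamp sweeps.
    meta : dict
        Free-form metadata (injected current, stimulus strength, ...).
    """

    values: np.ndarray
    sampling_rate: float
    units: str = "pA"
    epochs: dict = field(default_factory=dict)
    holding_potential: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        for name, (t0, t1) in self.epochs.items():
            if not (0 <= t0 <= t1 <= self.duration + 1e-9):
                raise ParameterError(f"epoch {name!r} outside sweep duration")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms (0-based, sample-aligned)."""
        return np.arange(self.n_samples) / self.sampling_rate

    def idx(self, t_ms: float) -> int:
        """Nearest sample index for a time in ms (clipped to range)."""
        return int(np.clip(round(t_ms * self.sampling_rate), 0, self.n_samples - 1))

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples in the half-open window [t0, t1) ms."""
        return self.values[self.idx(t0):max(self.idx(t0), int(round(t1 * self.sampling_rate)))]

    def epoch_values(self, name: str) -> np.ndarray:
        t0, t1 = self.epochs[name]
        return self.slice(t0, t1)


def save_sweep(sweep: Sweep, path: str | Path) -> None:
    """Write a sweep as a binary array plus JSON sidecar (``.npy`` + ``.json``)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), sweep.values)
    sidecar = {
        "sampling_rate_khz": sweep.sampling_rate,
        "units": sweep.units,
        "epochs": {k: list(v) for k, v in sweep.epochs.items()},
        "holding_potential_mV": sweep.holding_potential,
        "meta": sweep.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_sweep(path: str | Path) -> Sweep:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    side = json.loads(path.with_suffix(".json").read_text())
    return Sweep(
        values=values,
        sampling_rate=side["sampling_rate_khz"],
        units=side["units"],
        epochs={k: tuple(v) for k, v in side.get("epochs", {}).items()},
        holding_potential=side.get("holding_potential_mV"),
        meta=side.get("meta", {}),
    )


@dataclass
class ImageStack:
    """Multi-channel 3D voxel grid (z, y, x) with physical pixel sizes."""

    channels: dict  # name -> np.ndarray (z, y, x)
    pixel_size_xy: float  # um / px
    z_step: float = 0.25  # um
    bit_depth: int = 12

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ParameterError("all channels must share one shape")
        if self.pixel_size_xy <= 0 or self.z_step <= 0:
            raise ParameterError("pixel sizes must be positive")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"unknown channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in um^2."""
        return self.pixel_size_xy ** 2

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return self.pixel_size_xy ** 2 * self.z_step


def save_stack_tiff(stack: ImageStack, path: str | Path) -> None:
    """Write channels as a multi-series TIFF plus a JSON pixel-size sidecar."""
    import tifffile

    path = Path(path)
    arr = np.stack([stack.channels[k] for k in sorted(stack.channels)])
    tifffile.imwrite(path.with_suffix(".tif"), arr.astype(np.float32),
                     photometric="minisblack")
    side = {
        "channel_names": sorted(stack.channels),
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "bit_depth": stack.bit_depth,
    }
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def load_stack_tiff(path: str | Path) -> ImageStack:
    import tifffile

    path = Path(path)
    arr = tifffile.imread(path.with_suffix(".tif"))
    side = json.loads(path.with_suffix(".json").read_text())
    names = side["channel_names"]
    return ImageStack(
        channels={n: arr[i] for i, n in enumerate(names)},
        pixel_size_xy=side["pixel_size_xy_um"],
        z_step=side["z_step_um"],
        bit_depth=side.get("bit_depth", 12),
    )


@dataclass
class GroundTruth:
    """Planted ground truth recorded alongside every synthetic object."""

    event_times: Optional[list] = None      # ms
    event_k: Optional[list] = None          # release-site multiplicity per event
    event_edge_flag: Optional[list] = None  # True if event lies within one kernel length of the end
    true_peak_amps: Optional[list] = None   # pA magnitude per event
    true_charges: Optional[dict] = None     # fC per component
    spike_times: Optional[dict] = None      # per-step spike times, ms
    planted_puncta: Optional[list] = None   # dicts: center, area_um2, colocalized, oversize
    tree_total_length: Optional[float] = None  # um
    tree_crossings: Optional[dict] = None   # radius -> count
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(asdict(self), indent=1, default=_default))
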