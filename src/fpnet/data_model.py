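"""Domain types and I/O for collections of multi-node timeseries responses.

A *response matrix* is one trial's nonnegative nodes x time firing-rate
matrix (a PSTH) recorded while a stimulus is applied to a fixed-point
network.  A *response collection* gathers, per stimulus, the trials of such
matrices together with class labels (behavioral / non-behavioral / control).
Raw spike times can be converted to PSTHs with :func:`spikes_to_psth`.

The native on-disk layout is plain text: a ``collection.json`` descriptor
plus one numeric CSV per (stimulus, trial) under ``responses/``, so that a
saved collection round-trips bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ResponseMatrix",
    "ResponseCollection",
    "SpikeTrains",
    "spikes_to_psth",
    "save_collection",
    "load_collection",
    "CollectionFormatError",
]

CLASS_LABELS = ("behavioral", "non-behavioral", "control")


class CollectionFormatError(ValueError):
    """Raised when an on-disk collection is malformed or inconsistent."""


@dataclass
class ResponseMatrix:
    """One trial's nodes x time nonnegative firing-rate matrix.

    Parameters
    ----------
    stimulus_label : str
        Label of the stimulus applied during the recording.
    trial_index : int
        Zero-based trial number.
    rates : ndarray of shape (n_nodes, n_samples)
        Nonnegative instantaneous firing rates.
    dt : float
        Sampling interval in seconds.
    on_window : tuple of float
        Half-open interval ``[t_on, t_off)`` in seconds during which the
        stimulus is ON.
    """

    stimulus_label: str
    trial_index: int
    rates: np.ndarray
    dt: float
    on_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 2 or min(self.rates.shape) < 1:
            raise ValueError("rates must be a 2-D nodes x time matrix")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")
        if np.any(self.rates < 0):
            raise ValueError("firing rates must be nonnegative")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        t_on, t_off = self.on_window
        if not (0.0 <= t_on < t_off <= self.duration + 1e-12):
            raise ValueError(
                f"on_window {self.on_window} must lie inside [0, {self.duration})"
            )

    @property
    def n_nodes(self) -> int:
        return self.rates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rates.shape[1]

    @property
    def duration(self) -> float:
        return self.rates.shape[1] * self.dt

    def on_sample_indices(self) -> np.ndarray:
        """Indices of the time samples whose bin start falls in the ON window."""
        t = np.arange(self.n_samples) * self.dt
        t_on, t_off = self.on_window
        return np.flatnonzero((t >= t_on) & (t < t_off))


@dataclass
class ResponseCollection:
    """Supervised collection of per-stimulus, per-trial response matrices.

    All member matrices must agree in node count, sample count, sampling
    interval and ON window; trials are kept separate and never pooled
    implicitly.
    """

    stimuli: list[str]
    trials: dict[str, list[ResponseMatrix]]
    class_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stimuli:
            raise ValueError("collection must contain at least one stimulus")
        ref = None
        for stim in self.stimuli:
            if stim not in self.trials or not self.trials[stim]:
                raise ValueError(f"stimulus {stim!r} has no trials")
            for rm in self.trials[stim]:
                key = (rm.n_nodes, rm.n_samples, rm.dt, tuple(rm.on_window))
                if ref is None:
                    ref = key
                elif key != ref:
                    raise ValueError(
                        f"trial {rm.trial_index} of {stim!r} has inconsistent "
                        f"geometry {key} != {ref}"
                    )
        for stim, cls in self.class_labels.items():
            if cls not in CLASS_LABELS:
                raise ValueError(f"unknown class label {cls!r} for {stim!r}")

    @property
    def n_nodes(self) -> int:
        return self.trials[self.stimuli[0]][0].n_nodes

    @property
    def n_samples(self) -> int:
        return self.trials[self.stimuli[0]][0].n_samples

    @property
    def dt(self) -> float:
        return self.trials[self.stimuli[0]][0].dt

    @property
    def on_window(self) -> tuple[float, float]:
        return self.trials[self.stimuli[0]][0].on_window

    def n_trials(self, stimulus: str) -> int:
        return len(self.trials[stimulus])

    def get(self, stimulus: str, trial: int) -> ResponseMatrix:
        if stimulus not in self.trials:
            raise KeyError(f"unknown stimulus {stimulus!r}")
        return self.trials[stimulus][trial]

    def trial_average(self, stimulus: str) -> np.ndarray:
        """Mean rate matrix over the trials of one stimulus."""
        if stimulus not in self.trials:
            raise KeyError(f"unknown stimulus {stimulus!r}")
        return np.mean([rm.rates for rm in self.trials[stimulus]], axis=0)


@dataclass
class SpikeTrains:
    """Per-node spike times (seconds) over a recording of fixed duration."""

    spikes: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        cleaned = []
        for i, s in enumerate(self.spikes):
            s = np.asarray(s, dtype=float)
            if s.size and (np.any(s < 0) or np.any(s >= self.duration)):
                raise ValueError(f"node {i}: spike times must lie in [0, duration)")
            if s.size and np.any(np.diff(s) < 0):
                raise ValueError(f"node {i}: spike times must be nondecreasing")
            cleaned.append(s)
        self.spikes = cleaned

    @property
    def n_nodes(self) -> int:
        return len(self.spikes)


def spikes_to_psth(
    spikes: SpikeTrains,
    dt: float = 0.01,
    kernel_width: float = 0.05,
    stimulus_label: str = "",
    trial_index: int = 0,
    on_window: tuple[float, float] | None = None,
) -> ResponseMatrix:
    """Convert spike trains to a peri-stimulus time histogram.

    Each spike contributes a unit mass of rate x time.  With
    ``kernel_width > 0`` the mass is spread by a Gaussian kernel (standard
    deviation ``kernel_width``) evaluated at bin centers, truncated at the
    recording boundaries and renormalized per spike so that the
    time-integrated rate of every node equals its spike count.  With
    ``kernel_width == 0`` the PSTH is a pure binned histogram (counts / dt).

    Parameters
    ----------
    dt : float
        Bin width in seconds (default 10 ms).
    kernel_width : float
        Gaussian smoothing standard deviation in seconds (default 50 ms);
        0 disables smoothing.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kernel_width < 0:
        raise ValueError("kernel_width must be >= 0")
    n_bins = math.ceil(spikes.duration / dt - 1e-12)
    rates = np.zeros((spikes.n_nodes, n_bins))
    centers = (np.arange(n_bins) + 0.5) * dt
    for i, times in enumerate(spikes.spikes):
        if times.size == 0:
            continue
        if kernel_width == 0.0:
            counts, _ = np.histogram(times, bins=n_bins, range=(0.0, n_bins * dt))
            rates[i] = counts / dt
        else:
            # one truncated-renormalized Gaussian bump per spike
            z = (centers[None, :] - times[:, None]) / kernel_width
            bumps = np.exp(-0.5 * z**2)
            mass = bumps.sum(axis=1) * dt
            mass[mass == 0] = 1.0
            rates[i] = (bumps / mass[:, None]).sum(axis=0)
    if on_window is None:
        on_window = (0.0, n_bins * dt)
    return ResponseMatrix(
        stimulus_label=stimulus_label,
        trial_index=trial_index,
        rates=rates,
        dt=dt,
        on_window=on_window,
    )


# ---------------------------------------------------------------------------
# native directory layout: collection.json + responses/<stimulus>_<trial>.csv

def save_collection(collection: ResponseCollection, path: str | Path) -> Path:
    """Write a collection to a directory in the native plain-text layout."""
    path = Path(path)
    (path / "responses").mkdir(parents=True, exist_ok=True)
    meta = {
        "stimuli": collection.stimuli,
        "class_labels": collection.class_labels,
        "dt": collection.dt,
        "on_window": list(collection.on_window),
        "n_nodes": collection.n_nodes,
        "n_samples": collection.n_samples,
        "n_trials": {s: collection.n_trials(s) for s in collection.stimuli},
    }
    (path / "collection.json").write_text(json.dumps(meta, indent=2))
    for stim in collection.stimuli:
        for rm in collection.trials[stim]:
            fname = path / "responses" / f"{stim}_{rm.trial_index}.csv"
            # %.17g preserves float64 exactly across the round trip
            np.savetxt(fname, rm.rates, delimiter=",", fmt="%.17g")
    return path


def load_collection(path: str | Path) -> ResponseCollection:
    """Load a collection previously written by :func:`save_collection`."""
    path = Path(path)
    meta_file = path / "collection.json"
    if not meta_file.exists():
        raise CollectionFormatError(f"missing metadata descriptor {meta_file}")
    meta = json.loads(meta_file.read_text())
    for key in ("stimuli", "dt", "on_window", "n_trials"):
        if key not in meta:
            raise CollectionFormatError(f"metadata missing required field {key!r}")
    on_window = tuple(meta["on_window"])
    trials: dict[str, list[ResponseMatrix]] = {}
    shape = None
    for stim in meta["stimuli"]:
        trials[stim] = []
        for k in range(meta["n_trials"][stim]):
            fname = path / "responses" / f"{stim}_{k}.csv"
            if not fname.exists():
                raise CollectionFormatError(f"missing trial file {fname}")
            rates = np.loadtxt(fname, delimiter=",", ndmin=2)
            if shape is None:
                shape = rates.shape
            elif rates.shape != shape:
                raise CollectionFormatError(
                    f"{fname} has shape {rates.shape}, expected {shape}"
                )
            trials[stim].append(
                ResponseMatrix(
                    stimulus_label=stim,
                    trial_index=k,
                    rates=rates,
                    dt=meta["dt"],
                    on_window=on_window,
                )
            )
    return ResponseCollection(
        stimuli=list(meta["stimuli"]),
        trials=trials,
        class_labels=dict(meta.get("class_labels", {})),
    )
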