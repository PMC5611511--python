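"""Synthetic fixed-point-network response generator.

Emulates the statistical structure of multi-unit olfactory recordings: a
population of N nodes (default 106) responds to m mono-molecular stimuli
(default 8) over several trials (default 5) of 1 s at dt = 10 ms, with the
stimulus ON during the first 500 ms.  Each stimulus excites a ground-truth
nonnegative spatial pattern; the noiseless response rises toward that fixed
point with a saturating envelope, decays after stimulus OFF, and is
corrupted by i.i.d. Gaussian noise (clipped at zero) at a configurable
signal-to-noise ratio.  Mixtures are superpositions of their constituents'
patterns; a control stimulus is pure noise.

Rates are produced in normalized units with ON-plateau amplitude 1 and
unit-norm patterns, so projected trajectories live on the scale where the
classification space's fixed points are unit vectors (the scale on which
hyperellipse radii such as 0.65 are expressed).

The default mixture roster mirrors a 17-stimulus behavioral benchmark:
three behavioral mixtures sharing the constituents of the first three
odorants at behaviorally effective ratios, five non-behavioral mixtures
(dropping or substituting a constituent, or combining unrelated odorants),
and one blank control.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import ResponseCollection, ResponseMatrix

__all__ = [
    "MixtureSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_patterns",
    "generate_response",
    "generate_benchmark_like",
    "default_mixtures",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A labeled superposition of mono-stimulus patterns."""

    label: str
    weights: tuple[float, ...]  # one nonnegative weight per mono stimulus
    class_label: str  # behavioral / non-behavioral / control


def default_mixtures(n_stimuli: int = 8) -> list[MixtureSpec]:
    """Benchmark-like roster: B1-B3 behavioral, E1-E5 non-behavioral, E6 control.

    B1 is the equal-weight blend of the first three odorants; B2 and B3
    perturb its ratios (behavioral mixtures share constituents at effective
    ratios).  E1 drops the third constituent, E2 substitutes it with a
    fourth odorant — both of which abolish the behavioral response — and
    E3-E5 combine unrelated odorants.  E6 is a blank (noise-only) control.
    """
    if n_stimuli < 8:
        raise ValueError("default mixture roster needs at least 8 mono stimuli")

    def w(d: dict[int, float]) -> tuple[float, ...]:
        v = [0.0] * n_stimuli
        for i, x in d.items():
            v[i] = x
        return tuple(v)

    return [
        MixtureSpec("B1", w({0: 1.0, 1: 1.0, 2: 1.0}), "behavioral"),
        MixtureSpec("B2", w({0: 1.0, 1: 1.0, 2: 0.8}), "behavioral"),
        MixtureSpec("B3", w({0: 0.9, 1: 1.1, 2: 1.0}), "behavioral"),
        MixtureSpec("E1", w({0: 1.0, 1: 1.0}), "non-behavioral"),
        MixtureSpec("E2", w({0: 1.0, 1: 1.0, 3: 1.0}), "non-behavioral"),
        MixtureSpec("E3", w({3: 1.0, 4: 1.0}), "non-behavioral"),
        MixtureSpec("E4", w({5: 1.0, 6: 1.0}), "non-behavioral"),
        MixtureSpec("E5", w({1: 1.0, 7: 1.0}), "non-behavioral"),
        MixtureSpec("E6", w({}), "control"),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    snr is the ratio of time-averaged signal power to noise variance over
    the ON window, per node, averaged over signal-carrying nodes (default 3,
    the noisy regime typical of multi-unit recordings).  support_overlap is
    the fraction of nodes responsive to more than one stimulus (0 =
    perfectly selective population, 1 = fully shared support).
    """

    n_nodes: int = 106
    n_stimuli: int = 8
    n_trials: int = 5
    n_samples: int = 100
    dt: float = 0.01
    on_window: tuple[float, float] = (0.0, 0.5)
    snr: float = 3.0
    support_overlap: float = 0.3
    tau_rise: float = 0.1
    tau_decay: float = 0.15
    mixtures: tuple[MixtureSpec, ...] | None = None
    # sublinear mixture suppression exponent: the combined pattern is scaled
    # by (sum of weights)^(-mixture_suppression); 0 = purely linear blending
    mixture_suppression: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mixtures is None:
            roster = default_mixtures(self.n_stimuli) if self.n_stimuli >= 8 else []
            object.__setattr__(self, "mixtures", tuple(roster))
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0.0 <= self.support_overlap <= 1.0:
            raise ValueError("support_overlap must lie in [0, 1]")
        for mix in self.mixtures:
            if len(mix.weights) != self.n_stimuli:
                raise ValueError(f"mixture {mix.label}: needs {self.n_stimuli} weights")
            if any(w < 0 for w in mix.weights):
                raise ValueError(f"mixture {mix.label}: weights must be >= 0")

    def mono_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_stimuli)]


@dataclass
class GroundTruth:
    """Latent truth behind a synthetic collection (for recovery tests)."""

    patterns: np.ndarray  # N x m, nonnegative, unit-norm columns
    assignment: np.ndarray  # primary stimulus index per node
    shared_nodes: np.ndarray  # bool, True where support spans > 1 stimulus
    noise_sigma: float
    config: SyntheticConfig


def generate_patterns(config: SyntheticConfig) -> GroundTruth:
    """Draw ground-truth spatial patterns with controlled support overlap.

    Every node has a primary stimulus (balanced assignment) with a dominant
    weight; a ``support_overlap`` fraction of nodes additionally carries
    smaller weights for all other stimuli.  Columns are normalized to unit
    norm so that responses plateau on the unit fixed-point scale.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_nodes, config.n_stimuli
    primary = np.arange(n) % m
    rng.shuffle(primary)
    n_shared = int(round(config.support_overlap * n))
    shared = np.zeros(n, dtype=bool)
    shared[rng.choice(n, size=n_shared, replace=False)] = True

    G = np.zeros((n, m))
    G[np.arange(n), primary] = rng.uniform(0.5, 1.0, size=n)
    # shared nodes respond (more weakly) to every stimulus
    secondary = rng.uniform(0.05, 0.45, size=(n, m))
    G[shared] = np.where(
        np.arange(m)[None, :] == primary[shared, None],
        G[shared],
        secondary[shared],
    )
    norms = np.linalg.norm(G, axis=0)
    if np.any(norms == 0):
        raise ValueError("degenerate pattern column; increase n_nodes")
    G = G / norms

    truth = GroundTruth(
        patterns=G,
        assignment=primary,
        shared_nodes=shared,
        noise_sigma=0.0,
        config=config,
    )
    truth.noise_sigma = _reference_sigma(truth)
    return truth


def _envelope(config: SyntheticConfig) -> np.ndarray:
    """Saturating rise toward the fixed point during ON, decay after OFF."""
    t = np.arange(config.n_samples) * config.dt
    t_on, t_off = config.on_window
    env = np.zeros_like(t)
    on = (t >= t_on) & (t < t_off)
    env[on] = 1.0 - np.exp(-(t[on] - t_on) / config.tau_rise)
    after = t >= t_off
    level = 1.0 - np.exp(-(t_off - t_on) / config.tau_rise)
    env[after] = level * np.exp(-(t[after] - t_off) / config.tau_decay)
    return env


def _signal(truth: GroundTruth, weights: np.ndarray) -> np.ndarray:
    pattern = truth.patterns @ weights
    s = truth.config.mixture_suppression
    total = float(np.sum(weights))
    if s > 0 and total > 1.0:
        pattern = pattern * total ** (-s)
    return pattern[:, None] * _envelope(truth.config)[None, :]


def _reference_sigma(truth: GroundTruth) -> float:
    """Noise std from the configured SNR, referenced to mono-stimulus power.

    Signal power is averaged over ON-window samples and over the nodes in
    each mono stimulus's support, then over stimuli; sigma^2 = power / snr.
    The same sigma applies to every stimulus, mixtures and control included
    (noise is a property of the recording, not of the stimulus).
    """
    config = truth.config
    t = np.arange(config.n_samples) * config.dt
    on = (t >= config.on_window[0]) & (t < config.on_window[1])
    powers = []
    for j in range(config.n_stimuli):
        w = np.zeros(config.n_stimuli)
        w[j] = 1.0
        sig = _signal(truth, w)
        support = truth.patterns[:, j] > 0
        powers.append(np.mean(sig[np.ix_(support, on)] ** 2))
    return float(np.sqrt(np.mean(powers) / config.snr))


def _mixture_weights(
    truth: GroundTruth, stimulus: str
) -> np.ndarray:
    config = truth.config
    monos = config.mono_labels()
    if stimulus in monos:
        w = np.zeros(config.n_stimuli)
        w[monos.index(stimulus)] = 1.0
        return w
    for mix in config.mixtures:
        if mix.label == stimulus:
            return np.asarray(mix.weights, dtype=float)
    raise KeyError(f"unknown stimulus {stimulus!r}")


def generate_response(
    truth: GroundTruth,
    stimulus: str,
    trial: int,
    noiseless: bool = False,
) -> ResponseMatrix:
    """One trial's response to a mono stimulus or mixture.

    The signal component is deterministic given the ground truth; noise is
    drawn from a stream derived from (config seed, stimulus, trial), so the
    same trial is bit-reproducible and distinct trials differ only in noise.
    """
    config = truth.config
    weights = _mixture_weights(truth, stimulus)
    sig = _signal(truth, weights)
    if noiseless:
        rates = sig.copy()
    else:
        stim_key = zlib.crc32(stimulus.encode()) % (2**31)
        child = np.random.default_rng([config.seed, stim_key, trial])
        rates = sig + child.normal(0.0, truth.noise_sigma, size=sig.shape)
        np.clip(rates, 0.0, None, out=rates)
    return ResponseMatrix(
        stimulus_label=stimulus,
        trial_index=trial,
        rates=rates,
        dt=config.dt,
        on_window=config.on_window,
    )


def generate_poisson_response(
    truth: GroundTruth,
    stimulus: str,
    trial: int,
    peak_rate: float = 50.0,
    kernel_width: float = 0.05,
) -> ResponseMatrix:
    """Alternative noise path: inhomogeneous Poisson spiking plus PSTH.

    Node n fires with instantaneous rate ``peak_rate * signal_n(t)`` (Hz);
    spikes are drawn by thinning and converted back to a smoothed PSTH with
    :func:`fpnet.data_model.spikes_to_psth`, exercising the full
    spikes-to-rates conversion instead of additive Gaussian noise.
    """
    from .data_model import SpikeTrains, spikes_to_psth

    config = truth.config
    sig = _signal(truth, _mixture_weights(truth, stimulus)) * peak_rate
    duration = config.n_samples * config.dt
    stim_key = zlib.crc32(stimulus.encode()) % (2**31)
    rng = np.random.default_rng([config.seed, stim_key, trial, 977])
    spikes = []
    lam_max = max(sig.max(), 1e-9)
    for n in range(config.n_nodes):
        n_cand = rng.poisson(lam_max * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        bins = np.minimum((t_cand / config.dt).astype(int), config.n_samples - 1)
        keep = rng.uniform(size=n_cand) < sig[n, bins] / lam_max
        spikes.append(t_cand[keep])
    trains = SpikeTrains(spikes=spikes, duration=duration)
    return spikes_to_psth(
        trains,
        dt=config.dt,
        kernel_width=kernel_width,
        stimulus_label=stimulus,
        trial_index=trial,
        on_window=config.on_window,
    )


def generate_benchmark_like(
    config: SyntheticConfig | None = None,
    noiseless: bool = False,
    include_mixtures: bool = True,
) -> tuple[ResponseCollection, GroundTruth]:
    """Full benchmark-like collection: monos + mixtures + control.

    With the defaults this yields 17 stimuli x 5 trials = 85 response
    matrices over 106 nodes.
    """
    if config is None:
        config = SyntheticConfig()
    truth = generate_patterns(config)
    labels = config.mono_labels()
    class_labels = {s: "non-behavioral" for s in labels}
    if include_mixtures:
        for mix in config.mixtures:
            labels.append(mix.label)
            class_labels[mix.label] = mix.class_label
    trials = {
        s: [
            generate_response(truth, s, k, noiseless=noiseless)
            for k in range(config.n_trials)
        ]
        for s in labels
    }
    collection = ResponseCollection(
        stimuli=labels, trials=trials, class_labels=class_labels
    )
    return collection, truth


def disjoint_config(**kwargs) -> SyntheticConfig:
    """Convenience config with perfectly selective nodes (zero overlap)."""
    kwargs.setdefault("support_overlap", 0.0)
    return SyntheticConfig(**kwargs)
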