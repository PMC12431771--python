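"""Synthetic spike-train sessions with SF-tuned, latency-graded neurons.

No generative model of IT dynamics is published for this paradigm, so the
simulator is an explicit stand-in: inhomogeneous-Poisson neurons whose rate
is a baseline plus a stimulus-driven transient.  The transient's amplitude
depends on the stimulus band through a per-neuron tuning profile (LP, HP,
U, IU, or flat), on category through a face gain (unscrambled stimuli
only), and its latency grows with band index so low spatial frequencies
drive responses earlier.  An optional late response lobe, weighted toward
high bands, produces the late shift of preference toward high SF.

Everything is deterministic given the supplied ``numpy`` Generator and
neurons are conditionally independent given the stimulus, which makes the
conditional-mutual-information null exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stimgen import BAND_LABELS, StimulusRecord

__all__ = [
    "PROFILE_TEMPLATES",
    "DEFAULT_PROFILE_MIX",
    "DEFAULT_LATENCIES_MS",
    "LSF_BAND_BIAS",
    "TuningProfileSpec",
    "KernelSpec",
    "NeuronSpec",
    "SessionSpec",
    "SpikeSession",
    "make_population",
    "rate_function",
    "make_trial_schedule",
    "make_stimulus_manifest",
    "simulate_session",
    "write_session_hdf5",
    "read_session_hdf5",
]

#: Band-gain templates per tuning profile, R1..R5 (dimensionless).
#: Max/min contrast is >= 2:1 in every non-flat profile.
PROFILE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "LP": (1.0, 0.78, 0.60, 0.45, 0.33),
    "HP": (0.33, 0.45, 0.60, 0.78, 1.0),
    "U": (1.0, 0.62, 0.42, 0.62, 1.0),
    "IU": (0.42, 0.66, 1.0, 0.66, 0.42),
    "flat": (0.7, 0.7, 0.7, 0.7, 0.7),
}

#: Default profile composition: U-shaped largest, HP smallest (~6%).
DEFAULT_PROFILE_MIX: dict[str, float] = {
    "LP": 0.25,
    "HP": 0.06,
    "U": 0.34,
    "IU": 0.16,
    "flat": 0.19,
}

#: Response latency per band (ms); graded so low SF drives spikes earlier.
DEFAULT_LATENCIES_MS: tuple[float, ...] = (70.0, 76.0, 82.0, 88.0, 98.0)

#: Population-level multiplicative bias favouring low-SF drive.  Applied to
#: non-flat profiles only (a biased flat neuron would no longer be flat).
LSF_BAND_BIAS: tuple[float, ...] = (1.30, 1.12, 1.0, 0.92, 0.85)


@dataclass(frozen=True)
class TuningProfileSpec:
    """Generative SF tuning of one neuron: shape label, gains, latencies."""

    label: str
    band_gains: tuple[float, ...]
    latency_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        g = np.asarray(self.band_gains, dtype=float)
        lat = np.asarray(self.latency_ms, dtype=float)
        if g.shape != (5,) or lat.shape != (5,):
            raise ValueError("band_gains and latency_ms must have 5 entries")
        if np.any(g <= 0):
            raise ValueError("band gains must be positive")
        if np.any(lat < 0):
            raise ValueError("latencies must be non-negative")
        diffs = np.diff(g)
        ok = {
            "LP": bool(np.all(diffs < 0)),
            "HP": bool(np.all(diffs > 0)),
            "U": bool(1 <= int(np.argmin(g)) <= 3),
            "IU": bool(1 <= int(np.argmax(g)) <= 3),
            "flat": bool(np.allclose(g, g[0])),
        }.get(self.label)
        if ok is None:
            raise ValueError(f"unknown profile label {self.label!r}")
        if not ok:
            raise ValueError(f"band gains violate the {self.label} shape")


@dataclass(frozen=True)
class KernelSpec:
    """Difference-of-exponentials temporal response kernel (peak one).

    A second lobe, delayed by ``late_delay_ms`` and weighted linearly from
    zero at R1 to ``late_weight`` at R5, models the late drive by high SF.
    """

    rise_ms: float = 10.0
    decay_ms: float = 60.0
    late_weight: float = 0.0
    late_delay_ms: float = 130.0

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Kernel value at times after response onset (0 for t < 0)."""
        t = np.asarray(t_ms, dtype=float)
        tp = self.decay_ms * self.rise_ms / (self.decay_ms - self.rise_ms) * np.log(
            self.decay_ms / self.rise_ms
        )
        peak = np.exp(-tp / self.decay_ms) - np.exp(-tp / self.rise_ms)
        out = np.where(
            t > 0,
            (np.exp(-t / self.decay_ms) - np.exp(-t / self.rise_ms)) / peak,
            0.0,
        )
        return out


@dataclass(frozen=True)
class NeuronSpec:
    """Generative parameters for one simulated neuron."""

    neuron_id: int
    baseline_rate: float
    response_gain: float
    category_gain: float
    profile: TuningProfileSpec
    kernel: KernelSpec = KernelSpec()

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.response_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.category_gain <= 0:
            raise ValueError("category gain must be positive")


@dataclass(frozen=True)
class SessionSpec:
    """Timing and size of one recording session (main-phase defaults)."""

    n_blocks: int = 15
    stimulus_duration_ms: float = 33.0
    blank_ms: float = 465.0
    epoch_ms: tuple[float, float] = (-200.0, 500.0)
    dt_ms: float = 1.0


@dataclass
class SpikeSession:
    """Spike events of one simulated session in long format.

    ``spike_times`` holds every spike (ms from stimulus onset) with parallel
    ``trial_index`` / ``neuron_index`` arrays; ``manifest`` has one row per
    trial with the presented stimulus' keys (trial, block, stim_id, base_id,
    category, band, scrambled).
    """

    spike_times: np.ndarray
    trial_index: np.ndarray
    neuron_index: np.ndarray
    manifest: pd.DataFrame
    n_neurons: int
    epoch_ms: tuple[float, float]

    @property
    def n_trials(self) -> int:
        return len(self.manifest)


def _profile_gains(
    label: str, band_bias: Sequence[float] | None
) -> np.ndarray:
    g = np.asarray(PROFILE_TEMPLATES[label], dtype=float)
    if band_bias is not None and label != "flat":
        g = g * np.asarray(band_bias, dtype=float)
    return g


def make_population(
    n_neurons: int,
    profile_mix: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
    baseline_rate: float = 20.0,
    response_gain: float = 30.0,
    gain_jitter: float = 0.15,
    latency_jitter_ms: float = 3.0,
    band_bias: Sequence[float] | None = LSF_BAND_BIAS,
    category_gain_sd: float = 0.3,
    late_weight: float = 0.5,
    latencies_ms: Sequence[float] = DEFAULT_LATENCIES_MS,
) -> list[NeuronSpec]:
    """Draw a population of neurons with the requested profile mixture.

    Per-neuron variability is a common multiplicative jitter on band gains
    (shape-preserving), jittered latencies (common shift, preserving the SF
    gradient), and a lognormal face gain whose median is shifted upward for
    HP and LP profiles (face-selective bias of the high/low-preferring
    groups).  HP and U neurons get the late high-SF kernel lobe by default.
    """
    if profile_mix is None:
        profile_mix = DEFAULT_PROFILE_MIX
    labels = list(profile_mix)
    probs = np.asarray([profile_mix[k] for k in labels], dtype=float)
    if np.any(probs < 0):
        raise ValueError("profile proportions must be non-negative")
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("profile proportions must sum to 1")
    if rng is None:
        rng = np.random.default_rng()

    drawn = rng.choice(len(labels), size=n_neurons, p=probs)
    cat_shift = {"HP": 0.25, "LP": 0.15, "IU": -0.15, "U": 0.0, "flat": 0.0}
    neurons: list[NeuronSpec] = []
    for i in range(n_neurons):
        label = labels[int(drawn[i])]
        gains = _profile_gains(label, band_bias)
        gains = tuple(gains * np.exp(rng.normal(0.0, gain_jitter)))
        shift = rng.normal(0.0, latency_jitter_ms)
        lat = tuple(float(v + shift) for v in latencies_ms)
        profile = TuningProfileSpec(label, gains, lat)
        lw = late_weight if label in ("HP", "U") else 0.0
        kernel = KernelSpec(late_weight=lw)
        cg = float(
            np.exp(rng.normal(cat_shift[label], category_gain_sd))
        )
        neurons.append(
            NeuronSpec(
                neuron_id=i,
                baseline_rate=float(baseline_rate * np.exp(rng.normal(0, 0.2))),
                response_gain=float(response_gain * np.exp(rng.normal(0, 0.2))),
                category_gain=cg,
                profile=profile,
                kernel=kernel,
            )
        )
    return neurons


def _stimulus_drive(
    neuron: NeuronSpec, band: str, category: str, scrambled: bool
) -> tuple[float, float, float]:
    """(amplitude Hz, latency ms, late-lobe amplitude Hz) for one stimulus."""
    gains = np.asarray(neuron.profile.band_gains)
    lats = np.asarray(neuron.profile.latency_ms)
    if band == "intact":
        k = int(np.argmax(gains))
        band_gain, latency = float(gains[k]), float(lats[k])
        band_frac = k / 4.0
    else:
        k = BAND_LABELS.index(band)
        band_gain, latency = float(gains[k]), float(lats[k])
        band_frac = k / 4.0
    cat_gain = neuron.category_gain if (category == "face" and not scrambled) else 1.0
    amp = neuron.response_gain * band_gain * cat_gain
    late_amp = neuron.response_gain * neuron.kernel.late_weight * band_frac * band_gain
    return amp, latency, late_amp


def rate_function(
    neuron: NeuronSpec, stimulus: "StimulusRecord | pd.Series", t_ms: np.ndarray
) -> np.ndarray:
    """Instantaneous firing rate (Hz) of a neuron for one stimulus.

    ``rate(t) = baseline + A * k(t - latency) + A_late * k(t - latency - d)``
    where ``A`` folds band gain and (for unscrambled faces) the category
    gain, and the late lobe amplitude grows with band index.  Intact
    stimuli drive the neuron at its best band.
    """
    if isinstance(stimulus, StimulusRecord):
        band, category, scrambled = stimulus.band, stimulus.category, stimulus.scrambled
    else:
        band = stimulus["band"]
        category = stimulus["category"]
        scrambled = bool(stimulus["scrambled"])
    amp, latency, late_amp = _stimulus_drive(neuron, band, category, scrambled)
    t = np.asarray(t_ms, dtype=float)
    rate = neuron.baseline_rate + amp * neuron.kernel.evaluate(t - latency)
    if late_amp > 0:
        rate = rate + late_amp * neuron.kernel.evaluate(
            t - latency - neuron.kernel.late_delay_ms
        )
    return rate


def make_stimulus_manifest(
    n_base: int = 15,
    n_face: int | None = None,
    n_nonface: int | None = None,
    include_intact: bool = True,
    include_unscrambled: bool = True,
    include_scrambled: bool = True,
) -> pd.DataFrame:
    """Stimulus-level manifest (one row per unique stimulus, no pixels).

    The simulator's rates depend only on (band, category, scrambled), so a
    manifest is sufficient input for simulation when pixel grids are not
    needed.  Defaults reproduce the main-phase set: ``n_base`` bases x
    {intact, R1..R5} x {unscrambled, scrambled}.
    """
    from .stimgen import category_split

    n_face, n_nonface = category_split(n_base, n_face, n_nonface)
    bands = (["intact"] if include_intact else []) + list(BAND_LABELS)
    scr_flags = ([False] if include_unscrambled else []) + (
        [True] if include_scrambled else []
    )
    if not bands or not scr_flags:
        raise ValueError("empty stimulus manifest requested")
    rows = []
    for i in range(n_base):
        if i < n_face:
            category = "face"
        elif i < n_face + n_nonface:
            category = "nonface"
        else:
            category = "selective"
        for scrambled in scr_flags:
            for band in bands:
                tag = "scr" if scrambled else "uns"
                rows.append(
                    {
                        "stim_id": f"base{i:02d}:{band}:{tag}",
                        "base_id": f"base{i:02d}",
                        "category": category,
                        "band": band,
                        "scrambled": scrambled,
                    }
                )
    return pd.DataFrame(rows)


def make_trial_schedule(
    stim_ids: Sequence[str], n_blocks: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Blocked schedule: every stimulus once per block, order randomized."""
    rows = []
    trial = 0
    for block in range(n_blocks):
        order = rng.permutation(len(stim_ids))
        for j in order:
            rows.append({"trial": trial, "block": block, "stim_id": stim_ids[int(j)]})
            trial += 1
    return pd.DataFrame(rows)


def simulate_session(
    population: Sequence[NeuronSpec],
    stimuli: pd.DataFrame | Sequence[StimulusRecord],
    session: SessionSpec = SessionSpec(),
    rng: np.random.Generator | None = None,
    trial_gain_sd: float = 0.2,
) -> SpikeSession:
    """Simulate spikes for every neuron on every trial of a blocked session.

    Spikes are drawn by fine-bin (``dt_ms``) Poisson sampling of each
    neuron's rate function, with an independent lognormal trial gain (mean
    one, ``sigma = trial_gain_sd``) per neuron-trial modelling excitability
    fluctuations.  Trial count per neuron is ``n_blocks x n_stimuli``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not isinstance(stimuli, pd.DataFrame):
        stimuli = pd.DataFrame(
            [
                {
                    "stim_id": r.stim_id,
                    "base_id": r.base_id,
                    "category": r.category,
                    "band": r.band,
                    "scrambled": r.scrambled,
                }
                for r in stimuli
            ]
        )
    if len(stimuli) == 0:
        raise ValueError("empty stimulus set")
    n_neurons = len(population)
    t0, t1 = session.epoch_ms
    dt = session.dt_ms
    n_bins = int(round((t1 - t0) / dt))
    t_centers = t0 + (np.arange(n_bins) + 0.5) * dt

    # rate per (stimulus, neuron, time bin), in expected spikes per bin
    stim_rows = stimuli.reset_index(drop=True)
    lam = np.empty((len(stim_rows), n_neurons, n_bins), dtype=np.float32)
    for s, row in stim_rows.iterrows():
        for i, nrn in enumerate(population):
            lam[s, i] = rate_function(nrn, row, t_centers) * (dt / 1000.0)

    schedule = make_trial_schedule(list(stim_rows["stim_id"]), session.n_blocks, rng)
    stim_lookup = {sid: k for k, sid in enumerate(stim_rows["stim_id"])}

    times_parts: list[np.ndarray] = []
    trial_parts: list[np.ndarray] = []
    neuron_parts: list[np.ndarray] = []
    log_adj = -0.5 * trial_gain_sd**2  # lognormal mean-one correction
    for _, tr in schedule.iterrows():
        s = stim_lookup[tr["stim_id"]]
        gains = np.exp(rng.normal(log_adj, trial_gain_sd, size=n_neurons))
        counts = rng.poisson(lam[s] * gains[:, None])
        nz_n, nz_b = np.nonzero(counts)
        reps = counts[nz_n, nz_b]
        bin_idx = np.repeat(nz_b, reps)
        nrn_idx = np.repeat(nz_n, reps)
        times = t0 + (bin_idx + rng.random(bin_idx.size)) * dt
        order = np.lexsort((times, nrn_idx))
        times_parts.append(times[order].astype(np.float32))
        neuron_parts.append(nrn_idx[order].astype(np.int32))
        trial_parts.append(
            np.full(bin_idx.size, tr["trial"], dtype=np.int32)
        )

    manifest = schedule.merge(stim_rows, on="stim_id", how="left")
    return SpikeSession(
        spike_times=np.concatenate(times_parts) if times_parts else np.empty(0),
        trial_index=np.concatenate(trial_parts) if trial_parts else np.empty(0, int),
        neuron_index=np.concatenate(neuron_parts) if neuron_parts else np.empty(0, int),
        manifest=manifest,
        n_neurons=n_neurons,
        epoch_ms=session.epoch_ms,
    )


def write_session_hdf5(session: SpikeSession, path: str | Path) -> None:
    """Persist a session (events + manifest) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("spike_times", data=session.spike_times)
        f.create_dataset("trial_index", data=session.trial_index)
        f.create_dataset("neuron_index", data=session.neuron_index)
        f.attrs["n_neurons"] = session.n_neurons
        f.attrs["epoch_ms"] = session.epoch_ms
        man = f.create_group("manifest")
        for col in session.manifest.columns:
            data = session.manifest[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            man.create_dataset(col, data=data)


def read_session_hdf5(path: str | Path) -> SpikeSession:
    """Load a session previously written by :func:`write_session_hdf5`."""
    import h5py

    with h5py.File(path, "r") as f:
        cols = {}
        for col in f["manifest"]:
            data = f["manifest"][col][...]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        return SpikeSession(
            spike_times=f["spike_times"][...],
            trial_index=f["trial_index"][...],
            neuron_index=f["neuron_index"][...],
            manifest=pd.DataFrame(cols),
            n_neurons=int(f.attrs["n_neurons"]),
            epoch_ms=tuple(f.attrs["epoch_ms"]),
        )
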