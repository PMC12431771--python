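"""Spike times to response representations.

Sliding-window rate tensors (50-ms window, 5-ms step), PSTHs, baseline
statistics, z-scoring, the responsiveness screen, and split-half band
ranking.  The windowed rate tensor — neurons x trials x time with its trial
manifest — is the common currency consumed by the decoding and metrics
modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d

from .simdata import SpikeSession
from .stimgen import BAND_LABELS

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseTensor",
    "BaselineStats",
    "bin_rates",
    "psth",
    "baseline_stats",
    "zscore",
    "responsiveness_screen",
    "split_half_band_ranking",
    "trial_mask",
]


@dataclass
class ResponseTensor:
    """Windowed firing rates: ``rates[neuron, trial, time]`` in Hz.

    ``times`` holds the window centers (ms from stimulus onset); each
    window covers the half-open interval ``[t - w/2, t + w/2)``.
    """

    rates: np.ndarray
    times: np.ndarray
    manifest: pd.DataFrame
    window_ms: float = 50.0
    step_ms: float = 5.0
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rates.ndim != 3:
            raise ValueError("rates must be neurons x trials x time")
        if self.rates.shape[2] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.rates.shape[1] != len(self.manifest):
            raise ValueError("trial axis does not match manifest length")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.rates.shape[0])

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def time_index(self, t: float) -> int:
        """Index of the window center closest to ``t`` ms."""
        return int(np.argmin(np.abs(self.times - t)))

    def at_time(self, t: float) -> np.ndarray:
        """Trials x neurons feature matrix at one window center."""
        return self.rates[:, :, self.time_index(t)].T

    def window_mean(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Trials x neurons matrix of mean rate over centers in [t_lo, t_hi]."""
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        if not mask.any():
            raise ValueError(f"no window centers in [{t_lo}, {t_hi}] ms")
        return self.rates[:, :, mask].mean(axis=2).T

    def select_trials(self, mask: np.ndarray) -> "ResponseTensor":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask
        return replace(
            self,
            rates=self.rates[:, idx, :],
            manifest=self.manifest.iloc[idx].reset_index(drop=True),
        )

    def select_neurons(self, mask: np.ndarray) -> "ResponseTensor":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return replace(
            self,
            rates=self.rates[idx],
            neuron_ids=np.asarray(self.neuron_ids)[idx],
        )


@dataclass(frozen=True)
class BaselineStats:
    """Per-neuron mean and SD of baseline-epoch rates (across trials)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd < 0):
            raise ValueError("baseline SD cannot be negative")


def trial_mask(
    manifest: pd.DataFrame,
    bands: list[str] | None = None,
    scrambled: bool | None = None,
    categories: list[str] | None = None,
) -> np.ndarray:
    """Boolean trial selector over a manifest by band/scrambling/category."""
    mask = np.ones(len(manifest), dtype=bool)
    if bands is not None:
        mask &= manifest["band"].isin(bands).to_numpy()
    if scrambled is not None:
        mask &= (manifest["scrambled"].to_numpy() == scrambled)
    if categories is not None:
        mask &= manifest["category"].isin(categories).to_numpy()
    return mask


def _counts_1ms(
    session: SpikeSession, trial_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-ms spike counts, shape (trials, neurons, ms bins).

    ``trial_range=(lo, hi)`` restricts to trials ``lo..hi-1`` (contiguous
    chunking keeps the peak allocation bounded for large sessions).
    """
    t0, t1 = session.epoch_ms
    n_ms = int(round(t1 - t0))
    lo, hi = trial_range if trial_range is not None else (0, session.n_trials)
    n_trials = hi - lo
    n_neurons = session.n_neurons
    bins = np.floor(session.spike_times - t0).astype(np.int64)
    valid = (bins >= 0) & (bins < n_ms)
    valid &= (session.trial_index >= lo) & (session.trial_index < hi)
    flat = (
        (session.trial_index[valid].astype(np.int64) - lo) * n_neurons
        + session.neuron_index[valid]
    ) * n_ms + bins[valid]
    counts = np.bincount(flat, minlength=n_trials * n_neurons * n_ms)
    return counts.reshape(n_trials, n_neurons, n_ms)


def bin_rates(
    session: SpikeSession, window_ms: float = 50.0, step_ms: float = 5.0
) -> ResponseTensor:
    """Sliding-window firing rates from spike times.

    Rate at center ``t`` is the spike count in ``[t - w/2, t + w/2)``
    divided by the window length.  Window centers run over every multiple
    of ``step_ms`` for which the full window fits inside the epoch.
    """
    t0, t1 = session.epoch_ms
    if window_ms > (t1 - t0):
        raise ValueError("window larger than recorded epoch")
    half = window_ms / 2.0
    first = step_ms * np.ceil((t0 + half) / step_ms)
    centers = np.arange(first, t1 - half + 1e-9, step_ms)
    lo = np.round(centers - half - t0).astype(int)
    hi = np.round(centers + half - t0).astype(int)
    n_trials = session.n_trials
    win = np.empty(
        (n_trials, session.n_neurons, len(centers)), dtype=np.float32
    )
    chunk = 256
    for start in range(0, n_trials, chunk):
        stop = min(start + chunk, n_trials)
        counts = _counts_1ms(session, (start, stop))
        cs = np.concatenate(
            [
                np.zeros(counts.shape[:2] + (1,), dtype=np.int64),
                np.cumsum(counts, axis=2),
            ],
            axis=2,
        )
        win[start:stop] = (cs[:, :, hi] - cs[:, :, lo]).astype(np.float32) / (
            window_ms / 1000.0
        )
    return ResponseTensor(
        rates=np.transpose(win, (1, 0, 2)),
        times=centers,
        manifest=session.manifest.copy(),
        window_ms=window_ms,
        step_ms=step_ms,
    )


def psth(
    session: SpikeSession,
    trial_sel: np.ndarray | None = None,
    neuron: int | None = None,
    smoothing_sd_ms: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged smoothed firing rate (Hz) at 1-ms resolution.

    Gaussian smoothing with the kernel mass renormalized at the epoch edges
    so a flat rate stays flat and the time-integral is preserved away from
    the boundaries.  Returns ``(times, rate)``; ``rate`` is per neuron if
    ``neuron`` is None, averaged across the population otherwise selected.
    """
    counts = _counts_1ms(session)
    if trial_sel is not None:
        counts = counts[np.asarray(trial_sel)]
    if counts.shape[0] == 0:
        raise ValueError("no trials selected")
    rate = counts.mean(axis=0) * 1000.0  # Hz per neuron x ms
    if neuron is not None:
        rate = rate[neuron : neuron + 1]
    if smoothing_sd_ms > 0:
        sm = gaussian_filter1d(rate, smoothing_sd_ms, axis=1, mode="constant")
        norm = gaussian_filter1d(
            np.ones(rate.shape[1]), smoothing_sd_ms, mode="constant"
        )
        rate = sm / norm[None, :]
    t0, t1 = session.epoch_ms
    times = t0 + np.arange(rate.shape[1]) + 0.5
    return times, (rate[0] if neuron is not None else rate)


def baseline_stats(
    tensor: ResponseTensor, baseline: tuple[float, float] = (-50.0, 50.0)
) -> BaselineStats:
    """Mean/SD across trials of each neuron's baseline-epoch mean rate."""
    base = tensor.window_mean(*baseline)  # trials x neurons
    return BaselineStats(mean=base.mean(axis=0), sd=base.std(axis=0))


def zscore(
    tensor: ResponseTensor,
    stats: BaselineStats | None = None,
    min_sd: float = 1e-9,
) -> tuple[ResponseTensor, np.ndarray]:
    """Z-score rates per neuron using baseline statistics.

    Neurons with zero baseline SD are excluded (their z-score is undefined)
    and logged; the returned array holds the excluded neuron ids.
    """
    if stats is None:
        stats = baseline_stats(tensor)
    bad = stats.sd <= min_sd
    if bad.any():
        logger.warning(
            "excluding %d neuron(s) with zero baseline SD: %s",
            int(bad.sum()),
            np.asarray(tensor.neuron_ids)[bad].tolist(),
        )
    keep = ~bad
    z = (tensor.rates[keep] - stats.mean[keep, None, None]) / stats.sd[
        keep, None, None
    ]
    out = replace(
        tensor, rates=z.astype(np.float32), neuron_ids=np.asarray(tensor.neuron_ids)[keep]
    )
    return out, np.asarray(tensor.neuron_ids)[bad]


def responsiveness_screen(
    tensor: ResponseTensor,
    evoked: tuple[float, float] = (70.0, 170.0),
    baseline: tuple[float, float] = (-50.0, 50.0),
    alpha: float = 0.05,
) -> np.ndarray:
    """Per-neuron flag: significant rate increase in the evoked epoch.

    One-sided Wilcoxon signed-rank test across trials of the evoked-window
    mean against the baseline-window mean, at level ``alpha``.  Neurons
    whose paired differences are all ties are flagged False with a warning.
    """
    ev = tensor.window_mean(*evoked)  # trials x neurons
    ba = tensor.window_mean(*baseline)
    flags = np.zeros(tensor.n_neurons, dtype=bool)
    for i in range(tensor.n_neurons):
        diffs = ev[:, i] - ba[:, i]
        if np.all(diffs == 0):
            warnings.warn(
                f"neuron {tensor.neuron_ids[i]}: all-tied evoked/baseline pairs",
                stacklevel=2,
            )
            continue
        res = sps.wilcoxon(diffs, alternative="greater", zero_method="wilcox")
        flags[i] = res.pvalue < alpha
    return flags


def split_half_band_ranking(
    tensor: ResponseTensor,
    rng: np.random.Generator,
    window: tuple[float, float] = (70.0, 170.0),
) -> pd.DataFrame:
    """Rank-consistency of band preference across random trial halves.

    For each neuron the five scrambled bands are ranked by mean response on
    a random half of trials; the held-out half's mean responses are then
    averaged by rank across neurons.  A flat population yields a flat curve
    over ranks; genuine tuning yields a decreasing one.
    """
    sel = trial_mask(tensor.manifest, bands=list(BAND_LABELS), scrambled=True)
    sub = tensor.select_trials(sel)
    resp = sub.window_mean(*window)  # trials x neurons
    band_of = sub.manifest["band"].to_numpy()
    curves = np.zeros((sub.n_neurons, 5))
    for i in range(sub.n_neurons):
        half_a = np.zeros(5)
        half_b = np.zeros(5)
        for k, band in enumerate(BAND_LABELS):
            idx = np.nonzero(band_of == band)[0]
            idx = rng.permutation(idx)
            cut = len(idx) // 2
            half_a[k] = resp[idx[:cut], i].mean()
            half_b[k] = resp[idx[cut:], i].mean()
        order = np.argsort(-half_a)  # rank 0 = preferred band on half A
        curves[i] = half_b[order]
    return pd.DataFrame(
        {
            "rank": np.arange(1, 6),
            "held_out_mean": curves.mean(axis=0),
            "held_out_sem": curves.std(axis=0, ddof=1) / np.sqrt(len(curves)),
        }
    )
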