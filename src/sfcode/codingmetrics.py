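"""Population-coding structure statistics.

Four complementary views of how a neural population carries task
information:

* **Separability index (SI)** — the Frobenius-norm ratio of the
  between-class to the within-class scatter matrix of population response
  vectors; a classifier-free measure of class separation.
* **Single-neuron contribution (SNC)** — the drop in cross-validated
  decoding accuracy when one neuron is removed, with splits shared across
  leave-outs for variance reduction.
* **Conditional mutual information (CMI)** — plug-in estimate, in bits, of
  the mutual information between two neurons' 10-level-binned responses
  given the class label; a redundancy measure, shuffle-corrected against
  the within-class independence null.
* **Weight sparseness** — ``S = 1 - E(|w|)^2 / E(w^2)`` over the decoder's
  per-neuron weights: 0 when all neurons contribute equally, ``1 - 1/N``
  when a single neuron carries the discriminant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decoding import decode_cv, fit_linear_decoder, make_splits
from .responses import ResponseTensor

__all__ = [
    "SIResult",
    "SNCResult",
    "CMIMatrix",
    "SparsenessValue",
    "separability_index",
    "snc",
    "cmi_pairs",
    "weight_sparseness",
    "sparseness_timecourse",
]


@dataclass
class SIResult:
    """Scatter matrices and their norm ratio."""

    si: float
    s_within: np.ndarray
    s_between: np.ndarray
    centroids: np.ndarray  # (n_classes, n_features)
    total_mean: np.ndarray
    class_sizes: np.ndarray
    infinite_separation: bool = False


@dataclass
class SNCResult:
    """Accuracy drop (percentage points) from removing each neuron."""

    drops_pp: np.ndarray
    reference_accuracy: float
    loo_accuracies: np.ndarray


@dataclass
class CMIMatrix:
    """Pairwise conditional mutual information (bits)."""

    raw: np.ndarray
    corrected: np.ndarray
    n_bins: int
    n_shuffles: int

    def mean_offdiag(self, corrected: bool = True) -> float:
        m = self.corrected if corrected else self.raw
        iu = np.triu_indices_from(m, k=1)
        return float(m[iu].mean())


@dataclass(frozen=True)
class SparsenessValue:
    s: float
    n: int


def separability_index(
    X: np.ndarray, labels: np.ndarray, norm: str = "fro"
) -> SIResult:
    """Between- to within-class scatter ratio of population responses.

    ``S_W = sum_c sum_{r in c} (r - mu_c)(r - mu_c)^T`` and
    ``S_B = sum_c n_c (mu_c - m)(mu_c - m)^T``; ``SI = ||S_B|| / ||S_W||``
    (Frobenius norm by default, spectral via ``norm="spec"``).  SI is zero
    iff all class centroids coincide and is invariant to translating the
    whole data set.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    m = X.mean(axis=0)
    p = X.shape[1]
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    mus = []
    for c, n_c in zip(classes, counts):
        Xc = X[labels == c]
        mu = Xc.mean(axis=0)
        mus.append(mu)
        d = Xc - mu
        s_w += d.T @ d
        dm = (mu - m)[:, None]
        s_b += n_c * (dm @ dm.T)
    ord_ = "fro" if norm == "fro" else 2
    nw = float(np.linalg.norm(s_w, ord_))
    nb = float(np.linalg.norm(s_b, ord_))
    if nw == 0.0:
        return SIResult(
            si=np.inf, s_within=s_w, s_between=s_b,
            centroids=np.asarray(mus), total_mean=m,
            class_sizes=counts, infinite_separation=True,
        )
    return SIResult(
        si=nb / nw, s_within=s_w, s_between=s_b,
        centroids=np.asarray(mus), total_mean=m, class_sizes=counts,
    )


def snc(
    X: np.ndarray,
    y: np.ndarray,
    runs: int = 100,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.3,
    balance: bool = False,
    shrinkage: str | float | None = "auto",
) -> SNCResult:
    """Single-neuron contribution to population decoding.

    For each neuron the decoder is refit without that neuron's column, on
    exactly the same train/test splits as the full population (shared
    splits make the leave-out comparison deterministic given the seed and
    lower-variance).  Drops are in percentage points and may be negative
    for redundant or noisy neurons.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("population of one neuron has no leave-out")
    splits = list(make_splits(y, test_fraction, runs, rng, balance=balance))

    def _acc(cols: np.ndarray) -> float:
        accs = []
        for train, test in splits:
            model = fit_linear_decoder(X[np.ix_(train, cols)], y[train], shrinkage)
            pred = model.predict(X[np.ix_(test, cols)])
            accs.append(float((pred == y[test]).mean()))
        return float(np.mean(accs))

    all_cols = np.arange(X.shape[1])
    full = _acc(all_cols)
    loo = np.array([_acc(np.delete(all_cols, j)) for j in all_cols])
    return SNCResult(
        drops_pp=(full - loo) * 100.0, reference_accuracy=full, loo_accuracies=loo
    )


def _digitize_uniform(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-neuron uniform binning over each neuron's observed range.

    Constant neurons fall back to a single bin (code 0 everywhere).
    """
    codes = np.zeros(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        lo, hi = X[:, j].min(), X[:, j].max()
        if hi <= lo:
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        codes[:, j] = np.clip(np.searchsorted(edges, X[:, j], "right") - 1, 0,
                              n_bins - 1)
    return codes


def _cmi_from_codes(
    di: np.ndarray, dj: np.ndarray, c: np.ndarray, n_bins: int, n_c: int
) -> float:
    """Plug-in conditional mutual information (bits) of two binned neurons."""
    flat = (di * n_bins + dj) * n_c + c
    joint = np.bincount(flat, minlength=n_bins * n_bins * n_c).astype(float)
    joint = joint.reshape(n_bins, n_bins, n_c) / len(c)
    p_c = joint.sum(axis=(0, 1))
    p_ic = joint.sum(axis=1)  # (n_bins, n_c)
    p_jc = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_term = np.log2(
            joint * p_c[None, None, :]
        ) - np.log2(p_ic[:, None, :] * p_jc[None, :, :])
    mask = joint > 0
    return float(np.sum(joint[mask] * log_term[mask]))


def cmi_pairs(
    X: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    n_shuffles: int = 20,
    rng: np.random.Generator | None = None,
) -> CMIMatrix:
    """Pairwise conditional mutual information between neurons given labels.

    Responses are discretized into ``n_bins`` uniformly spaced bins per
    neuron (spanning that neuron's observed range).  The shuffle correction
    subtracts, for each pair, the mean CMI after permuting the second
    neuron's responses within each label stratum — which preserves both
    marginals and label dependence while destroying noise correlation, the
    exact null under conditional independence.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two label values")
    n_samples, n_neurons = X.shape
    if n_samples < 10 * n_bins:
        warnings.warn(
            "fewer than 10 samples per bin on average; CMI estimates will "
            "be biased upward", stacklevel=2,
        )
    c = np.searchsorted(classes, labels)
    codes = _digitize_uniform(X, n_bins)

    strata = [np.nonzero(c == k)[0] for k in range(len(classes))]
    shuffled = []
    for _ in range(n_shuffles):
        perm = np.arange(n_samples)
        for ix in strata:
            perm[ix] = ix[rng.permutation(len(ix))]
        shuffled.append(codes[perm])

    raw = np.zeros((n_neurons, n_neurons))
    corrected = np.zeros((n_neurons, n_neurons))
    for i in range(n_neurons):
        for j in range(i + 1, n_neurons):
            v = _cmi_from_codes(codes[:, i], codes[:, j], c, n_bins, len(classes))
            null = np.mean(
                [
                    _cmi_from_codes(codes[:, i], s[:, j], c, n_bins, len(classes))
                    for s in shuffled
                ]
            ) if n_shuffles else 0.0
            raw[i, j] = raw[j, i] = v
            corrected[i, j] = corrected[j, i] = v - null
    return CMIMatrix(raw=raw, corrected=corrected, n_bins=n_bins,
                     n_shuffles=n_shuffles)


def weight_sparseness(weights: np.ndarray) -> SparsenessValue:
    """Sparseness of a decoder weight vector.

    ``S = 1 - E(|w|)^2 / E(w^2)``: zero when all weights share one
    magnitude, ``1 - 1/N`` when exactly one weight is nonzero.  Invariant
    to rescaling the weights.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size == 0 or np.all(w == 0) or np.mean(w**2) == 0:
        raise ValueError("sparseness undefined for all-zero weights")
    s = 1.0 - np.mean(np.abs(w)) ** 2 / np.mean(w**2)
    return SparsenessValue(s=float(s), n=w.size)


def sparseness_timecourse(
    tensor: ResponseTensor,
    y: np.ndarray,
    runs: int = 50,
    rng: np.random.Generator | None = None,
    test_fraction: float = 0.3,
    balance: bool = False,
    shrinkage: str | float | None = "auto",
    time_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Time course of decoder-weight sparseness for a binary task.

    At every window center a binary decoder is fitted on each resampled
    training set (z-scored input expected) and the sparseness of its
    per-neuron weights recorded; the mean and SD over runs are returned.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y)
    times = tensor.times
    mask = np.ones(len(times), dtype=bool)
    if time_range is not None:
        mask = (times >= time_range[0]) & (times <= time_range[1])
    rows = []
    for ti in np.nonzero(mask)[0]:
        X = tensor.rates[:, :, ti].T
        svals = []
        for train, _ in make_splits(y, test_fraction, runs, rng, balance=balance):
            model = fit_linear_decoder(X[train], y[train], shrinkage)
            svals.append(weight_sparseness(model.weights).s)
        svals = np.asarray(svals)
        rows.append(
            {
                "time": times[ti],
                "sparseness_mean": float(svals.mean()),
                "sparseness_sd": float(svals.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)
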