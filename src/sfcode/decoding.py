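"""Linear-discriminant decoding with leave-p-out resampling.

Population and single-neuron decoding of spatial-frequency band and
category, per-class recall, decoding time courses, onset detection, and
the sorted sub-population analysis.  The classifier is linear discriminant
analysis with a shared within-class covariance; because the number of
neurons can approach the number of trials, Ledoit–Wolf shrinkage of the
covariance is on by default.

Resampling follows the leave-p-out scheme: in each run a stratified random
30% of trials is held out for testing, optionally after downsampling every
class to the minority count (class balancing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .responses import ResponseTensor

__all__ = [
    "DecoderModel",
    "CVResult",
    "OnsetResult",
    "TimecourseResult",
    "SingularCovarianceError",
    "fit_linear_decoder",
    "make_splits",
    "decode_cv",
    "sf_decoding_timecourse",
    "onset_time",
    "single_neuron_timecourse",
    "sorted_subpopulation_analysis",
]


class SingularCovarianceError(np.linalg.LinAlgError):
    """Within-class covariance is singular and no shrinkage was requested."""


@dataclass
class DecoderModel:
    """Fitted linear discriminant: per-class weights over neurons."""

    coef: np.ndarray  # (n_classes or 1, n_features)
    intercept: np.ndarray
    classes: np.ndarray
    estimator: object | None = None

    @property
    def weights(self) -> np.ndarray:
        """Per-neuron weight vector (binary: the single discriminant)."""
        return self.coef[0] if self.coef.shape[0] == 1 else self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self.coef.T + self.intercept
        if self.coef.shape[0] == 1:
            return self.classes[(scores[:, 0] > 0).astype(int)]
        return self.classes[np.argmax(scores, axis=1)]


@dataclass
class CVResult:
    """Accuracy and per-class recall distributions over resampling runs."""

    accuracies: np.ndarray  # (runs,)
    recalls: np.ndarray  # (runs, n_classes)
    classes: np.ndarray
    confusion: np.ndarray  # (n_classes, n_classes), summed over runs
    chance: float

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_recalls(self) -> np.ndarray:
        return self.recalls.mean(axis=0)


@dataclass
class OnsetResult:
    """Decoding onset: first sustained, significant rise above baseline."""

    onset_ms: float | None
    threshold: float
    n_consecutive: int


@dataclass
class TimecourseResult:
    """Run-resolved decoding time course."""

    times: np.ndarray
    accuracies: np.ndarray  # (n_time, runs)
    recalls: np.ndarray  # (n_time, runs, n_classes)
    classes: np.ndarray
    chance: float

    def summary(self) -> pd.DataFrame:
        rows = {
            "time": self.times,
            "accuracy_mean": self.accuracies.mean(axis=1),
            "accuracy_sd": self.accuracies.std(axis=1, ddof=1),
        }
        for k, cls in enumerate(self.classes):
            rows[f"recall_{cls}"] = self.recalls[:, :, k].mean(axis=1)
        return pd.DataFrame(rows)


def fit_linear_decoder(
    X: np.ndarray, y: np.ndarray, shrinkage: str | float | None = "auto"
) -> DecoderModel:
    """Fit an LDA decoder with shared within-class covariance.

    ``shrinkage="auto"`` uses Ledoit–Wolf covariance shrinkage (needed when
    neurons rival trials in number); ``None`` or ``0`` uses the plain
    empirical covariance and raises :class:`SingularCovarianceError` when
    that covariance is rank-deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    if shrinkage in (None, 0, 0.0):
        centered = X - np.stack([X[y == c].mean(axis=0) for c in classes])[
            np.searchsorted(classes, y)
        ]
        if np.linalg.matrix_rank(centered) < X.shape[1]:
            raise SingularCovarianceError(
                "within-class covariance is singular; enable shrinkage "
                "(shrinkage='auto') to regularize"
            )
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    else:
        lda = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=shrinkage if shrinkage != "auto" else "auto"
        )
    lda.fit(X, y)
    return DecoderModel(
        coef=np.atleast_2d(lda.coef_),
        intercept=np.atleast_1d(lda.intercept_),
        classes=lda.classes_,
        estimator=lda,
    )


def make_splits(
    y: np.ndarray,
    test_fraction: float,
    runs: int,
    rng: np.random.Generator,
    balance: bool = False,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stratified random train/test splits, optionally class-balanced.

    With ``balance=True`` every class is first downsampled to the minority
    class count (fresh subsample each run) before the stratified split.
    Guarantees at least one test and two training samples per class.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    class_idx = [np.nonzero(y == c)[0] for c in classes]
    min_count = min(len(ix) for ix in class_idx)
    for _ in range(runs):
        train_parts, test_parts = [], []
        for ix in class_idx:
            ix = rng.permutation(ix)
            if balance:
                ix = ix[:min_count]
            n_test = max(1, int(round(test_fraction * len(ix))))
            n_test = min(n_test, len(ix) - 2)
            if n_test < 1:
                raise ValueError("class too small for the requested split")
            test_parts.append(ix[:n_test])
            train_parts.append(ix[n_test:])
        yield np.concatenate(train_parts), np.concatenate(test_parts)


def _decode_1d_run(
    x: np.ndarray, y_codes: np.ndarray, n_classes: int,
    train: np.ndarray, test: np.ndarray,
) -> np.ndarray:
    """Exact 1-D LDA: shared variance, class means, empirical log-priors.

    With one feature the LDA decision reduces to comparing
    ``x*mu_c/s2 - mu_c^2/(2 s2) + log pi_c`` across classes, which this
    fast path evaluates directly (identical decision rule to the matrix
    solver, without estimator overhead).
    """
    xt = x[train]
    yt = y_codes[train]
    means = np.array([xt[yt == c].mean() for c in range(n_classes)])
    # pooled within-class variance
    ss = 0.0
    for c in range(n_classes):
        d = xt[yt == c] - means[c]
        ss += float(d @ d)
    var = ss / max(len(xt) - n_classes, 1)
    var = max(var, 1e-12)
    priors = np.array([(yt == c).mean() for c in range(n_classes)])
    scores = (
        x[test, None] * means[None, :] / var
        - means[None, :] ** 2 / (2 * var)
        + np.log(np.maximum(priors, 1e-300))[None, :]
    )
    return np.argmax(scores, axis=1)


def decode_cv(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.3,
    runs: int = 1000,
    balance: bool = False,
    shrinkage: str | float | None = "auto",
    rng: np.random.Generator | None = None,
    collect_weights: bool = False,
) -> CVResult | tuple[CVResult, np.ndarray]:
    """Leave-p-out cross-validated decoding.

    Each run holds out a stratified ``test_fraction`` of trials, fits the
    decoder on the remainder, and records test accuracy and per-class
    recall.  With ``collect_weights`` the per-run weight vectors (binary
    tasks: the discriminant over neurons) are returned as well.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n_classes = len(classes)
    y_codes = np.searchsorted(classes, y)
    acc = np.empty(runs)
    rec = np.empty((runs, n_classes))
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    weights = [] if collect_weights else None
    one_d = X.shape[1] == 1 and not collect_weights

    for r, (train, test) in enumerate(
        make_splits(y, test_fraction, runs, rng, balance=balance)
    ):
        if one_d:
            pred = _decode_1d_run(X[:, 0], y_codes, n_classes, train, test)
        else:
            model = fit_linear_decoder(X[train], y[train], shrinkage=shrinkage)
            pred = np.searchsorted(classes, model.predict(X[test]))
            if collect_weights:
                weights.append(model.weights.copy())
        truth = y_codes[test]
        acc[r] = float((pred == truth).mean())
        np.add.at(confusion, (truth, pred), 1)
        for k in range(n_classes):
            m = truth == k
            rec[r, k] = float((pred[m] == k).mean()) if m.any() else np.nan
    result = CVResult(
        accuracies=acc,
        recalls=rec,
        classes=classes,
        confusion=confusion,
        chance=1.0 / n_classes,
    )
    if collect_weights:
        return result, np.asarray(weights)
    return result


def sf_decoding_timecourse(
    tensor: ResponseTensor,
    runs: int = 200,
    rng: np.random.Generator | None = None,
    time_range: tuple[float, float] | None = None,
    shrinkage: str | float | None = "auto",
    test_fraction: float = 0.3,
) -> TimecourseResult:
    """Five-way band decoding at every window center.

    The tensor must already be restricted to scrambled band trials (use
    :func:`sfcode.responses.trial_mask`); labels are the manifest bands.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = tensor.manifest["band"].to_numpy()
    times = tensor.times
    mask = np.ones(len(times), dtype=bool)
    if time_range is not None:
        mask = (times >= time_range[0]) & (times <= time_range[1])
    sel_times = times[mask]
    classes = np.unique(y)
    accs = np.empty((len(sel_times), runs))
    recs = np.empty((len(sel_times), runs, len(classes)))
    for k, ti in enumerate(np.nonzero(mask)[0]):
        X = tensor.rates[:, :, ti].T
        res = decode_cv(
            X, y, test_fraction=test_fraction, runs=runs,
            shrinkage=shrinkage, rng=rng,
        )
        accs[k] = res.accuracies
        recs[k] = res.recalls
    return TimecourseResult(
        times=sel_times, accuracies=accs, recalls=recs,
        classes=classes, chance=1.0 / len(classes),
    )


def onset_time(
    times: np.ndarray,
    run_matrix: np.ndarray,
    baseline: tuple[float, float] = (-50.0, 50.0),
    n_consecutive: int = 5,
    alpha: float = 0.05,
) -> OnsetResult:
    """Detect the onset of above-baseline decoding.

    The threshold is the mean of the average trace over the baseline
    interval plus one SD of that interval.  A window is significant when
    the empirical run distribution exceeds the threshold with p < alpha
    (fewer than ``alpha`` of runs at or below it); the onset is the first
    window starting ``n_consecutive`` consecutive significant windows.
    """
    times = np.asarray(times)
    run_matrix = np.asarray(run_matrix)
    base = (times >= baseline[0]) & (times <= baseline[1])
    if not base.any():
        raise ValueError("trace does not cover the baseline interval")
    mean_trace = run_matrix.mean(axis=1)
    thr = float(mean_trace[base].mean() + mean_trace[base].std(ddof=1))
    p_at = (run_matrix <= thr).mean(axis=1)
    sig = p_at < alpha
    count = 0
    for i, s in enumerate(sig):
        count = count + 1 if s else 0
        if count >= n_consecutive:
            return OnsetResult(
                onset_ms=float(times[i - n_consecutive + 1]),
                threshold=thr,
                n_consecutive=n_consecutive,
            )
    return OnsetResult(onset_ms=None, threshold=thr, n_consecutive=n_consecutive)


def single_neuron_timecourse(
    tensor: ResponseTensor,
    y: np.ndarray,
    runs: int = 50,
    rng: np.random.Generator | None = None,
    n_consecutive: int = 3,
    alpha: float = 0.05,
    test_fraction: float = 0.3,
    balance: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron decoding accuracy over time, plus the inclusion mask.

    Each neuron is decoded alone (one feature).  A neuron is included when
    its run distribution beats chance (empirical p < alpha) in at least
    ``n_consecutive`` consecutive windows.  Returns ``(acc, mask)`` with
    ``acc`` of shape (neurons, time).
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y)
    chance = 1.0 / len(np.unique(y))
    acc = np.empty((tensor.n_neurons, len(tensor.times)))
    mask = np.zeros(tensor.n_neurons, dtype=bool)
    for i in range(tensor.n_neurons):
        sig = np.zeros(len(tensor.times), dtype=bool)
        for t in range(len(tensor.times)):
            res = decode_cv(
                tensor.rates[i, :, t][:, None], y,
                test_fraction=test_fraction, runs=runs, rng=rng, balance=balance,
            )
            acc[i, t] = res.mean_accuracy
            sig[t] = (res.accuracies <= chance).mean() < alpha
        run = 0
        for s in sig:
            run = run + 1 if s else 0
            if run >= n_consecutive:
                mask[i] = True
                break
    return acc, mask


@dataclass
class SubpopulationResult:
    """Sorted sub-population scatter: mean single skill vs population skill."""

    table: pd.DataFrame
    corr_sf: float
    corr_category: float
    p_sf: float
    p_category: float


def sorted_subpopulation_analysis(
    single_scores: np.ndarray,
    X_sf: np.ndarray,
    y_sf: np.ndarray,
    X_cat: np.ndarray,
    y_cat: np.ndarray,
    window: int = 20,
    runs: int = 50,
    rng: np.random.Generator | None = None,
    shrinkage: str | float | None = "auto",
    balance_category: bool = True,
) -> SubpopulationResult:
    """Decode with sliding sub-populations of ``window`` adjacent neurons.

    Neurons are sorted by ``single_scores`` (their single-neuron accuracy
    on the sort task); every window of ``window`` adjacent neurons in the
    sorted order is decoded as a population for both the SF and the
    category task.  Returns the scatter pairs (mean single score vs
    population accuracy) and Pearson correlations.  The number of windows
    is ``N - window + 1``.
    """
    if rng is None:
        rng = np.random.default_rng()
    single_scores = np.asarray(single_scores, dtype=float)
    n = len(single_scores)
    if n < window:
        raise ValueError("fewer neurons than the sub-population window")
    order = np.argsort(single_scores)
    rows = []
    for start in range(n - window + 1):
        sel = order[start : start + window]
        acc_sf = decode_cv(
            X_sf[:, sel], y_sf, runs=runs, rng=rng, shrinkage=shrinkage
        ).mean_accuracy
        acc_cat = decode_cv(
            X_cat[:, sel], y_cat, runs=runs, rng=rng,
            shrinkage=shrinkage, balance=balance_category,
        ).mean_accuracy
        rows.append(
            {
                "window_start": start,
                "mean_single_score": float(single_scores[sel].mean()),
                "population_sf_accuracy": acc_sf,
                "population_category_accuracy": acc_cat,
            }
        )
    table = pd.DataFrame(rows)
    r_sf, p_sf = sps.pearsonr(
        table["mean_single_score"], table["population_sf_accuracy"]
    )
    r_cat, p_cat = sps.pearsonr(
        table["mean_single_score"], table["population_category_accuracy"]
    )
    return SubpopulationResult(
        table=table, corr_sf=float(r_sf), corr_category=float(r_cat),
        p_sf=float(p_sf), p_category=float(p_cat),
    )
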