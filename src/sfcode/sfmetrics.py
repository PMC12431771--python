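"""SF-tuning statistics: preferred SF, dominant band, and SF profiles.

The preferred SF of a neuron is the rate-weighted mean of band
coefficients ``c = (-2, -1, 0, 1, 2)`` for R1..R5::

    PSF = sum_i f_Ri * c_Ri / sum_i f_Ri

positive when the neuron leans toward high spatial frequencies.  The
dominant band is the band with the highest mean rate, reported only when a
one-way ANOVA across bands is significant.  The SF profile classifies the
shape of the band tuning curve — LP (low-preferring), HP (high-
preferring), U (middle suppressed), IU (middle enhanced), or flat — from a
quadratic fit over band index followed by rank tests on per-block means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .responses import ResponseTensor, trial_mask
from .stimgen import BAND_LABELS

__all__ = [
    "PSF_COEFFICIENTS",
    "PSFResult",
    "QuadraticFit",
    "ProfileResult",
    "preferred_sf",
    "preferred_sf_timecourse",
    "dominant_band",
    "classify_sf_profile",
    "classify_population_profiles",
    "split_half_profile_consistency",
]

#: Band coefficients for the preferred-SF statistic (R1..R5).
PSF_COEFFICIENTS: tuple[int, ...] = (-2, -1, 0, 1, 2)

PROFILE_LABELS = ("LP", "HP", "U", "IU", "flat")


@dataclass(frozen=True)
class PSFResult:
    """Preferred-SF statistic with its inputs."""

    psf: float
    band_rates: tuple[float, ...]
    coefficients: tuple[int, ...] = PSF_COEFFICIENTS


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic fit of response against band index 1..5."""

    a: float
    b: float
    c: float

    @property
    def vertex(self) -> float | None:
        return -self.b / (2 * self.a) if self.a != 0 else None

    @property
    def vertex_type(self) -> str | None:
        if self.a == 0:
            return None
        return "min" if self.a > 0 else "max"


@dataclass
class ProfileResult:
    """SF-profile label plus the fit and test p-values behind it."""

    label: str
    fit: QuadraticFit
    pvalues: dict[str, float]


def preferred_sf(band_rates) -> PSFResult:
    """Rate-weighted mean of band coefficients (the preferred-SF statistic).

    ``band_rates`` are the five mean firing rates for R1..R5.  Scaling all
    rates by a positive constant leaves the statistic unchanged; it is
    bounded by the extreme coefficients [-2, 2] for non-negative rates.
    """
    rates = np.asarray(band_rates, dtype=float)
    if rates.shape != (5,):
        raise ValueError("need exactly five band rates")
    total = rates.sum()
    if total <= 0:
        raise ValueError("preferred SF undefined: band rates sum to zero")
    psf = float(np.dot(rates, PSF_COEFFICIENTS) / total)
    return PSFResult(psf=psf, band_rates=tuple(rates))


def preferred_sf_timecourse(
    tensor: ResponseTensor,
) -> pd.DataFrame:
    """Mean preferred SF across neurons at every window center.

    The tensor should hold raw (non-negative, non-z-scored) rates and be
    restricted to scrambled band trials.  Neurons whose band rates sum to
    zero in a window are dropped from that window's average.
    """
    band_of = tensor.manifest["band"].to_numpy()
    band_means = np.stack(
        [tensor.rates[:, band_of == b, :].mean(axis=1) for b in BAND_LABELS],
        axis=0,
    )  # bands x neurons x time
    coeffs = np.asarray(PSF_COEFFICIENTS, dtype=float)
    totals = band_means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        psf = np.tensordot(coeffs, band_means, axes=(0, 0)) / totals
    psf = np.where(totals > 0, psf, np.nan)
    mean = np.nanmean(psf, axis=0)
    n_valid = np.sum(~np.isnan(psf), axis=0)
    se = np.nanstd(psf, axis=0, ddof=1) / np.sqrt(np.maximum(n_valid, 1))
    return pd.DataFrame({"time": tensor.times, "psf_mean": mean, "psf_se": se})


def dominant_band(
    band_responses: list[np.ndarray], alpha: float = 0.05
) -> str | None:
    """Band with the significantly highest mean rate, or None.

    A one-way ANOVA across the five bands' trial responses gates the call;
    below ``alpha`` the band with the highest mean is returned, ties broken
    toward the lower band with a warning.
    """
    if len(band_responses) != 5:
        raise ValueError("need responses for exactly five bands")
    stat, p = sps.f_oneway(*band_responses)
    if not (p < alpha):
        return None
    means = np.array([np.mean(r) for r in band_responses])
    best = int(np.argmax(means))
    if np.sum(means == means[best]) > 1:
        warnings.warn("tied winning band means; reporting the lower band",
                      stacklevel=2)
    return BAND_LABELS[best]


def _block_band_means(
    responses: np.ndarray, band_idx: np.ndarray, blocks: np.ndarray,
    members: list[int],
) -> np.ndarray:
    """Per-block mean response pooled over the given band indices (1..5)."""
    out = []
    for blk in np.unique(blocks):
        m = (blocks == blk) & np.isin(band_idx, members)
        if m.any():
            out.append(responses[m].mean())
        else:
            out.append(np.nan)
    return np.asarray(out)


def _signed_rank_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """One-sided Wilcoxon signed-rank p on paired per-block means."""
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    if len(d) == 0 or np.all(d == 0):
        return 1.0
    return float(sps.wilcoxon(d, alternative=alternative, zero_method="wilcox").pvalue)


def classify_sf_profile(
    responses: np.ndarray,
    band_idx: np.ndarray,
    blocks: np.ndarray,
    alpha: float = 0.05,
    curvature_tol: float = 1e-8,
) -> ProfileResult:
    """Classify one neuron's SF tuning shape from per-trial band responses.

    A quadratic is least-squares fitted to (band index 1..5, response) over
    all trials.  If the vertex lies in [2, 4] with non-negligible curvature
    the neuron is routed to the interior group: the band nearest the vertex
    is compared against R1 and R5 by one-sided signed-rank tests on
    per-block means — significantly below both gives U, above both IU.
    Otherwise the monotone group applies: pooled {R1, R2} vs {R4, R5}
    per-block means — significantly greater gives LP, smaller HP.  Anything
    that fails its tests is flat.
    """
    responses = np.asarray(responses, dtype=float)
    band_idx = np.asarray(band_idx)
    blocks = np.asarray(blocks)
    if responses.shape != band_idx.shape or responses.shape != blocks.shape:
        raise ValueError("responses, band_idx, blocks must be parallel arrays")
    for k in range(1, 6):
        if np.sum(band_idx == k) < 2:
            raise ValueError(f"need at least two trials in band R{k}")

    a, b, c = np.polyfit(band_idx.astype(float), responses, 2)
    fit = QuadraticFit(float(a), float(b), float(c))
    scale = max(np.abs(responses).max(), 1.0)
    degenerate = abs(a) < curvature_tol * scale
    vertex = fit.vertex if not degenerate else None
    interior = vertex is not None and 2.0 <= vertex <= 4.0

    pvals: dict[str, float] = {}
    if interior:
        mid = int(np.clip(round(vertex), 2, 4))
        mid_means = _block_band_means(responses, band_idx, blocks, [mid])
        r1_means = _block_band_means(responses, band_idx, blocks, [1])
        r5_means = _block_band_means(responses, band_idx, blocks, [5])
        pvals["mid_below_r1"] = _signed_rank_p(mid_means, r1_means, "less")
        pvals["mid_below_r5"] = _signed_rank_p(mid_means, r5_means, "less")
        pvals["mid_above_r1"] = _signed_rank_p(mid_means, r1_means, "greater")
        pvals["mid_above_r5"] = _signed_rank_p(mid_means, r5_means, "greater")
        if pvals["mid_below_r1"] < alpha and pvals["mid_below_r5"] < alpha:
            return ProfileResult("U", fit, pvals)
        if pvals["mid_above_r1"] < alpha and pvals["mid_above_r5"] < alpha:
            return ProfileResult("IU", fit, pvals)
        return ProfileResult("flat", fit, pvals)

    low_means = _block_band_means(responses, band_idx, blocks, [1, 2])
    high_means = _block_band_means(responses, band_idx, blocks, [4, 5])
    pvals["low_gt_high"] = _signed_rank_p(low_means, high_means, "greater")
    pvals["low_lt_high"] = _signed_rank_p(low_means, high_means, "less")
    if pvals["low_gt_high"] < alpha:
        return ProfileResult("LP", fit, pvals)
    if pvals["low_lt_high"] < alpha:
        return ProfileResult("HP", fit, pvals)
    return ProfileResult("flat", fit, pvals)


def classify_population_profiles(
    tensor: ResponseTensor,
    window: tuple[float, float] = (70.0, 170.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Profile label per neuron from scrambled band trials in a window.

    Returns a table with neuron id, label, fit coefficients, vertex, and
    test p-values.  The tensor may be raw or baseline-standardized; the
    classification uses within-neuron comparisons only.
    """
    sel = trial_mask(tensor.manifest, bands=list(BAND_LABELS), scrambled=True)
    sub = tensor.select_trials(sel)
    resp = sub.window_mean(*window)  # trials x neurons
    band_idx = np.array(
        [BAND_LABELS.index(b) + 1 for b in sub.manifest["band"]]
    )
    blocks = sub.manifest["block"].to_numpy()
    rows = []
    for i in range(sub.n_neurons):
        res = classify_sf_profile(resp[:, i], band_idx, blocks, alpha=alpha)
        rows.append(
            {
                "neuron_id": sub.neuron_ids[i],
                "label": res.label,
                "a": res.fit.a,
                "b": res.fit.b,
                "c": res.fit.c,
                "vertex": res.fit.vertex,
                **{f"p_{k}": v for k, v in res.pvalues.items()},
            }
        )
    return pd.DataFrame(rows)


def split_half_profile_consistency(
    tensor: ResponseTensor,
    rng: np.random.Generator,
    window: tuple[float, float] = (70.0, 170.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Held-out band tuning per profile group from split halves.

    Profiles are classified on a random half of trials (within band and
    block); the other half's mean band responses are then averaged within
    each assigned profile group.  Tuned populations reproduce their shapes
    on held-out data; flat ones stay flat.
    """
    sel = trial_mask(tensor.manifest, bands=list(BAND_LABELS), scrambled=True)
    sub = tensor.select_trials(sel)
    resp = sub.window_mean(*window)
    band_idx = np.array([BAND_LABELS.index(b) + 1 for b in sub.manifest["band"]])
    blocks = sub.manifest["block"].to_numpy()

    half_a = np.zeros(len(resp), dtype=bool)
    for k in range(1, 6):
        for blk in np.unique(blocks):
            idx = np.nonzero((band_idx == k) & (blocks == blk))[0]
            idx = rng.permutation(idx)
            half_a[idx[: len(idx) // 2 + len(idx) % 2]] = True

    curves: dict[str, list[np.ndarray]] = {lbl: [] for lbl in PROFILE_LABELS}
    for i in range(sub.n_neurons):
        res = classify_sf_profile(
            resp[half_a, i], band_idx[half_a], blocks[half_a], alpha=alpha
        )
        held = np.array(
            [resp[~half_a & (band_idx == k), i].mean() for k in range(1, 6)]
        )
        curves[res.label].append(held)
    rows = []
    for lbl, lst in curves.items():
        if not lst:
            continue
        arr = np.asarray(lst)
        for k in range(5):
            rows.append(
                {
                    "label": lbl,
                    "band": BAND_LABELS[k],
                    "held_out_mean": float(arr[:, k].mean()),
                    "held_out_sem": float(
                        arr[:, k].std(ddof=1) / np.sqrt(len(arr))
                    ) if len(arr) > 1 else np.nan,
                    "n_neurons": len(arr),
                }
            )
    return pd.DataFrame(rows)
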