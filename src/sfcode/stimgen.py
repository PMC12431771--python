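"""Spatial-frequency-controlled stimulus construction.

Builds the band-pass filtered, phase-scrambled, statistics-equalized
stimulus sets used throughout the package.  Every base image yields twelve
variants: an intact version, five isotropic Butterworth band-pass versions
(R1..R5, low to high spatial frequency), and a phase-scrambled counterpart
of each.  After filtering, every variant is brought to a common mean
luminance ``L`` and pixel contrast (standard deviation) ``C`` by a linear
transform, so luminance and contrast are equal across conditions by
construction.

Conventions
-----------
* Images are square 2-D float arrays with luminance nominally in [0, 1].
* Radial frequency is measured in cycles per image: the Euclidean distance
  of an FFT coefficient from DC, in FFT index units.
* Filtering is isotropic (no orientation dependence); DC is removed by the
  high-pass factor, so band-passed images are zero-mean before
  re-normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "BandSpec",
    "NormTargets",
    "StimulusRecord",
    "DEFAULT_BAND_EDGES",
    "DEFAULT_ORDER",
    "INTACT",
    "default_bands",
    "butterworth_bandpass_gain",
    "radial_frequency_grid",
    "apply_sf_filter",
    "phase_scramble",
    "normalize_luminance_contrast",
    "sf_power",
    "build_stimulus_set",
    "records_manifest",
    "make_texture_bases",
    "load_grayscale_png",
    "save_grayscale_png",
    "save_stimulus_archive",
]

#: Pass-band edges in cycles per image for the five bands, low to high SF.
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "R1": (1.0, 5.0),
    "R2": (5.0, 10.0),
    "R3": (10.0, 18.0),
    "R4": (18.0, 45.0),
    "R5": (45.0, 75.0),
}

#: Default Butterworth order; steep enough to keep the five bands
#: near-disjoint at the standard edges without ringing artifacts.
DEFAULT_ORDER: int = 4

BAND_LABELS: tuple[str, ...] = ("R1", "R2", "R3", "R4", "R5")


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on a constant image."""


@dataclass(frozen=True)
class BandSpec:
    """One spatial-frequency pass-band.

    Parameters
    ----------
    label : str
        ``"intact"`` or one of ``"R1"``..``"R5"``.
    f_lo, f_hi : float or None
        Lower / upper pass-band edges in cycles per image; ``None`` for the
        intact (unfiltered) condition.
    order : int
        Butterworth order ``n`` shared by the low- and high-pass factors.
    """

    label: str
    f_lo: float | None
    f_hi: float | None
    order: int = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if self.label == "intact":
            if self.f_lo is not None or self.f_hi is not None:
                raise ValueError("intact band has no cutoff frequencies")
            return
        if self.f_lo is None or self.f_hi is None:
            raise ValueError(f"band {self.label!r} requires both cutoffs")
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )
        if self.order < 1:
            raise ValueError("Butterworth order must be >= 1")

    @property
    def is_intact(self) -> bool:
        return self.label == "intact"


INTACT = BandSpec("intact", None, None)


def default_bands(order: int = DEFAULT_ORDER) -> list[BandSpec]:
    """The five standard pass-bands R1..R5 at the given Butterworth order."""
    return [
        BandSpec(lbl, lo, hi, order) for lbl, (lo, hi) in DEFAULT_BAND_EDGES.items()
    ]


@dataclass(frozen=True)
class NormTargets:
    """Target moments for the luminance/contrast equalization step.

    Defaults are mean 0.5 (128/255) and standard deviation 0.0314 (8/255).
    """

    L: float = 0.5
    C: float = 0.0314

    def __post_init__(self) -> None:
        if not (0 < self.L < 1):
            raise ValueError("target mean L must lie in (0, 1)")
        if self.C <= 0:
            raise ValueError("target contrast C must be positive")


@dataclass
class StimulusRecord:
    """One stimulus variant: a base image in one band/scrambling condition."""

    base_id: str
    category: str  # face | nonface | selective
    band: str  # intact | R1..R5
    scrambled: bool
    image: np.ndarray
    seed: int | None = None

    @property
    def stim_id(self) -> str:
        tag = "scr" if self.scrambled else "uns"
        return f"{self.base_id}:{self.band}:{tag}"


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"image must be square 2-D, got shape {arr.shape}")
    if arr.shape[0] < 8:
        raise ValueError("image side must be at least 8 pixels")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def butterworth_bandpass_gain(
    r: float | np.ndarray, band: BandSpec
) -> float | np.ndarray:
    """Band-pass gain at radial frequency ``r`` (cycles per image).

    The gain is the product of a low-pass Butterworth factor with cutoff at
    the upper band edge and a high-pass factor with cutoff at the lower
    edge::

        B(r) = 1 / (1 + (r / f_hi)^(2n)) * 1 / (1 + (f_lo / r)^(2n))

    The high-pass factor vanishes at ``r = 0``, so DC is always removed.
    Gains lie in [0, 1], rising then falling around the pass-band.
    """
    if band.is_intact:
        raise ValueError("gain is undefined for the intact (unfiltered) band")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("radial frequency must be non-negative")
    two_n = 2 * band.order
    lp = 1.0 / (1.0 + (r_arr / band.f_hi) ** two_n)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(r_arr > 0, band.f_lo / np.where(r_arr > 0, r_arr, 1.0), np.inf)
        hp = np.where(np.isinf(ratio), 0.0, 1.0 / (1.0 + ratio**two_n))
    gain = lp * hp
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(gain)
    return gain


def radial_frequency_grid(side: int) -> np.ndarray:
    """Radial frequency (cycles per image) of each unshifted FFT coefficient."""
    f = np.fft.fftfreq(side) * side
    return np.hypot(f[:, None], f[None, :])


def apply_sf_filter(image: np.ndarray, band: BandSpec) -> np.ndarray:
    """Band-pass filter an image in the Fourier domain.

    The 2-D FFT is multiplied coefficient-wise by the Butterworth band-pass
    gain at each coefficient's radial frequency and inverted; the real part
    is returned.  Output is zero-mean for R1..R5 because DC is suppressed.
    """
    arr = _validate_image(image)
    if band.is_intact:
        return arr.copy()
    r = radial_frequency_grid(arr.shape[0])
    gain = butterworth_bandpass_gain(r, band)
    return np.real(np.fft.ifft2(np.fft.fft2(arr) * gain))


def phase_scramble(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomize Fourier phases while preserving the amplitude spectrum.

    The replacement phases are the phases of the FFT of a white-noise field,
    which are conjugate-symmetric by construction, so the inverse transform
    is real up to float error; the real part is extracted regardless.  The
    DC phase is kept so the image mean is unchanged.
    """
    arr = _validate_image(image)
    spectrum = np.fft.fft2(arr)
    noise_phase = np.angle(np.fft.fft2(rng.standard_normal(arr.shape)))
    noise_phase[0, 0] = np.angle(spectrum[0, 0])
    return np.real(np.fft.ifft2(np.abs(spectrum) * np.exp(1j * noise_phase)))


def normalize_luminance_contrast(
    image: np.ndarray, targets: NormTargets = NormTargets()
) -> np.ndarray:
    """Linearly map an image to target mean ``L`` and standard deviation ``C``.

    ``I_norm = C * (I - mu) / sigma + L``.  Output moments hit the targets
    to float precision; pixels may leave [0, 1] (no clipping, which would
    distort the moments).

    Raises
    ------
    DegenerateImageError
        If the image is constant (zero standard deviation).
    """
    arr = _validate_image(image)
    sigma = float(arr.std())
    if sigma < 1e-12:
        raise DegenerateImageError("constant image: contrast normalization undefined")
    return targets.C * (arr - arr.mean()) / sigma + targets.L


def sf_power(image: np.ndarray) -> float:
    """Total spectral power: the sum of squared FFT coefficient magnitudes.

    By Parseval's theorem this equals ``side**2`` times the spatial-domain
    sum of squared pixel values.
    """
    arr = _validate_image(image)
    return float(np.sum(np.abs(np.fft.fft2(arr)) ** 2))


def _ac_power(image: np.ndarray) -> float:
    """Spectral power excluding DC (power of the mean-removed image)."""
    return sf_power(image - image.mean())


def build_stimulus_set(
    base_images: Sequence[tuple[str, str, np.ndarray]],
    bands: Sequence[BandSpec] | None = None,
    targets: NormTargets = NormTargets(),
    rng: np.random.Generator | None = None,
    equalize_band_power: bool = False,
) -> list[StimulusRecord]:
    """Construct the full stimulus set from base images.

    For each ``(base_id, category, image)`` the set contains the intact
    image, its five band-pass versions, and the phase-scrambled counterpart
    of all six — twelve records per base image.  The scrambled variants are
    obtained by phase-scrambling the base image once and passing the result
    through the same filters, so each scrambled variant shares the band's
    amplitude statistics with its unscrambled sibling.  The luminance/
    contrast normalization is applied last, so all records share the target
    mean and contrast exactly.

    Parameters
    ----------
    equalize_band_power : bool
        If True, rescale each filtered variant's AC (non-DC) power to that
        of its intact sibling before the final normalization.  The final
        normalization fixes spatial variance — hence total AC power — in any
        case; the flag only matters for diagnostic band-power bookkeeping.
    """
    if len(base_images) == 0:
        raise ValueError("need at least one base image")
    ids = [bid for bid, _, _ in base_images]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate base ids in base_images")
    if bands is None:
        bands = default_bands()
    if rng is None:
        rng = np.random.default_rng()

    records: list[StimulusRecord] = []
    for base_id, category, img in base_images:
        img = _validate_image(img)
        seed = int(rng.integers(2**31))
        scram = phase_scramble(img, np.random.default_rng(seed))
        for scrambled, source in ((False, img), (True, scram)):
            for band in [INTACT, *bands]:
                filtered = apply_sf_filter(source, band)
                if equalize_band_power and not band.is_intact:
                    p_ref = _ac_power(source)
                    p = _ac_power(filtered)
                    if p > 0:
                        filtered = filtered * np.sqrt(p_ref / p)
                records.append(
                    StimulusRecord(
                        base_id=base_id,
                        category=category,
                        band=band.label,
                        scrambled=scrambled,
                        image=normalize_luminance_contrast(filtered, targets),
                        seed=seed,
                    )
                )
    return records


def records_manifest(records: Iterable[StimulusRecord]) -> pd.DataFrame:
    """Tidy manifest of a stimulus set (one row per record)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "stim_id": rec.stim_id,
                "base_id": rec.base_id,
                "category": rec.category,
                "band": rec.band,
                "scrambled": rec.scrambled,
                "seed": rec.seed,
                "mean": float(rec.image.mean()),
                "std": float(rec.image.std()),
                "band_power": _ac_power(rec.image),
            }
        )
    return pd.DataFrame(rows)


def category_split(n_base: int, n_face: int | None, n_nonface: int | None
                   ) -> tuple[int, int]:
    """Default face/nonface counts, scaled from the standard 6/3-of-15 mix."""
    if n_face is None:
        n_face = max(1, round(n_base * 6 / 15))
    if n_nonface is None:
        n_nonface = max(1, round(n_base * 3 / 15))
    if n_face + n_nonface > n_base:
        raise ValueError("category counts exceed n_base")
    return n_face, n_nonface


def make_texture_bases(
    n_base: int = 15,
    side: int = 128,
    rng: np.random.Generator | None = None,
    n_face: int | None = None,
    n_nonface: int | None = None,
) -> list[tuple[str, str, np.ndarray]]:
    """Generate synthetic grayscale base images with broadband structure.

    Stand-ins for photographic stimuli: smoothed-noise textures with energy
    across all five bands (1/f-like spectrum).  The first ``n_face`` are
    labelled ``face``, the next ``n_nonface`` ``nonface``, the remainder
    ``selective`` (the screening-phase picks), mirroring the standard
    6/3/6 composition when ``n_base = 15``.
    """
    n_face, n_nonface = category_split(n_base, n_face, n_nonface)
    if rng is None:
        rng = np.random.default_rng()
    freqs = radial_frequency_grid(side)
    # 1/f amplitude profile gives natural-image-like broadband content
    amp = 1.0 / np.maximum(freqs, 1.0)
    bases = []
    for i in range(n_base):
        phase = np.angle(np.fft.fft2(rng.standard_normal((side, side))))
        img = np.real(np.fft.ifft2(amp * np.exp(1j * phase)))
        img = (img - img.min()) / (img.max() - img.min())
        if i < n_face:
            category = "face"
        elif i < n_face + n_nonface:
            category = "nonface"
        else:
            category = "selective"
        bases.append((f"base{i:02d}", category, img))
    return bases


def load_grayscale_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG as a float image in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return _validate_image(arr)


def save_grayscale_png(image: np.ndarray, path: str | Path) -> None:
    """Write a float image as 8-bit grayscale PNG (clipped to [0, 1])."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    out = np.round(arr * 255.0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(path)


def save_stimulus_archive(
    records: Sequence[StimulusRecord], path: str | Path
) -> None:
    """Save float stimulus grids losslessly to HDF5 alongside their keys."""
    import h5py

    with h5py.File(path, "w") as f:
        for rec in records:
            grp = f.create_group(rec.stim_id.replace(":", "/"))
            grp.create_dataset("image", data=rec.image, compression="gzip")
            grp.attrs["base_id"] = rec.base_id
            grp.attrs["category"] = rec.category
            grp.attrs["band"] = rec.band
            grp.attrs["scrambled"] = rec.scrambled
            if rec.seed is not None:
                grp.attrs["seed"] = rec.seed
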