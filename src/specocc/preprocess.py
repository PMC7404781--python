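"""Row-wise spectral pretreatments.

All transforms are pure functions ``SpectrumSet -> SpectrumSet`` that
preserve the matrix shape and the sample/metadata pairing.  Five standard
pretreatments are provided: normalization (max or area), smoothing and
derivatives via Savitzky-Golay local polynomial filtering, multiplicative
scatter correction (MSC) and the standard normal variate (SNV).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Optional

import numpy as np
from scipy.signal import savgol_coeffs

from .dataset import SpectrumSet

_METHODS = {"none", "normalize", "smooth", "msc", "snv", "savgol"}


class PreprocessError(ValueError):
    """A pretreatment could not be applied to one or more samples."""


@dataclass
class PreprocessConfig:
    """Serializable pretreatment choice.

    ``smooth`` is Savitzky-Golay with ``deriv_order = 0``; ``savgol`` uses
    the configured derivative order.  ``msc_reference`` is either
    ``train_mean`` (mean spectrum of the calibration set) or an explicit
    spectrum supplied at apply time.
    """

    method: str = "snv"
    normalize_mode: str = "max"
    window: int = 11
    polyorder: int = 2
    deriv_order: int = 0
    msc_reference: str = "train_mean"

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.normalize_mode not in {"max", "area"}:
            raise ValueError(f"unknown normalize_mode {self.normalize_mode!r}")
        if self.method in {"smooth", "savgol"}:
            if self.window < 3 or self.window % 2 == 0:
                raise ValueError("window must be an odd integer >= 3")
            if self.window <= self.polyorder:
                raise ValueError("window must exceed polyorder")
            if not 0 <= self.deriv_order <= 2:
                raise ValueError("deriv_order must be 0, 1 or 2")
            if self.deriv_order > self.polyorder:
                raise ValueError("deriv_order must not exceed polyorder")


def snv(data: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: center and unit-scale each spectrum.

    Output rows have mean 0 and sample standard deviation (n-1 denominator)
    1; removes per-sample additive offsets and multiplicative scatter.
    """
    X = data.intensities
    if X.shape[1] < 2:
        raise PreprocessError("SNV requires at least 2 points per spectrum")
    sd = X.std(axis=1, ddof=1)
    bad = ~(sd > 0)
    if bad.any():
        ids = [data.sample_ids[i] for i in np.where(bad)[0]]
        raise PreprocessError(f"zero-variance spectra cannot be SNV-scaled: {ids}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return data.with_intensities(out)


def msc(data: SpectrumSet, reference: Optional[np.ndarray] = None) -> SpectrumSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as ``x ~ a + b * ref`` by ordinary least
    squares and corrected to ``(x - a) / b``.  With ``reference=None`` the
    mean spectrum of ``data`` is used (the usual calibration-set choice).
    """
    X = data.intensities
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, float).ravel()
    if ref.size != X.shape[1]:
        raise PreprocessError(
            f"reference length {ref.size} != axis length {X.shape[1]}"
        )
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom <= 0:
        raise PreprocessError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    small = np.abs(b) < 1e-12
    if small.any():
        ids = [data.sample_ids[i] for i in np.where(small)[0]]
        raise PreprocessError(f"MSC slope below 1e-12 for samples: {ids}")
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return data.with_intensities(out)


def normalize(data: SpectrumSet, mode: str = "max") -> SpectrumSet:
    """Scale each spectrum by its maximum (``max``) or total |area| (``area``)."""
    X = data.intensities
    if mode == "max":
        scale = X.max(axis=1)
    elif mode == "area":
        scale = np.abs(X).sum(axis=1)
    else:
        raise ValueError(f"unknown normalize mode {mode!r}")
    bad = ~(np.abs(scale) > 0)
    if bad.any():
        ids = [data.sample_ids[i] for i in np.where(bad)[0]]
        raise PreprocessError(f"cannot normalize all-zero spectra: {ids}")
    return data.with_intensities(X / scale[:, None])


def _uniform_step(wavenumbers: np.ndarray) -> float:
    d = np.diff(wavenumbers)
    step = d[0]
    if np.max(np.abs(d - step)) > 1e-9 * abs(step):
        raise PreprocessError(
            "Savitzky-Golay requires a uniform wavenumber grid; resample first"
        )
    return step


def savgol(
    data: SpectrumSet, window: int, polyorder: int, deriv_order: int = 0
) -> SpectrumSet:
    """Savitzky-Golay smoothing / derivative filter.

    Each point is replaced by the ``deriv_order``-th derivative of the local
    least-squares polynomial of degree ``polyorder`` over the centered
    ``window``; derivatives are scaled by the physical axis step so order-1
    output is in units per cm^-1 and the sign follows the axis direction.
    Near the edges the polynomial is fitted on the one-sided truncated
    window (minimally widened inward when fewer than ``polyorder + 1``
    points remain, so the fit stays determined).
    """
    PreprocessConfig(
        method="savgol", window=window, polyorder=polyorder, deriv_order=deriv_order
    )
    X = data.intensities
    n_pts = X.shape[1]
    if window > n_pts:
        raise PreprocessError(f"window {window} exceeds axis length {n_pts}")
    step = _uniform_step(data.wavenumbers)
    kernel = savgol_coeffs(
        window, polyorder, deriv=deriv_order, delta=abs(step), use="dot"
    )
    half = window // 2
    out = np.empty_like(X)
    for j in range(half, n_pts - half):
        out[:, j] = X[:, j - half : j + half + 1] @ kernel
    sign = 1.0 if step > 0 else (-1.0) ** deriv_order
    out[:, half : n_pts - half] *= sign
    # one-sided truncated-window polynomial fits at the edges, in physical
    # axis units (handles step scaling and direction automatically)
    edge_idx = list(range(half)) + list(range(n_pts - half, n_pts))
    fact = float(factorial(deriv_order))
    for j in edge_idx:
        lo, hi = max(0, j - half), min(n_pts, j + half + 1)
        if hi - lo < polyorder + 1:  # widen inward to keep the fit determined
            if lo == 0:
                hi = polyorder + 1
            else:
                lo = n_pts - (polyorder + 1)
        x = data.wavenumbers[lo:hi] - data.wavenumbers[j]
        V = np.vander(x, N=polyorder + 1, increasing=True)
        sol, *_ = np.linalg.lstsq(V, X[:, lo:hi].T, rcond=None)
        out[:, j] = fact * sol[deriv_order]
    return data.with_intensities(out)


def apply_preprocess(
    config: PreprocessConfig,
    data: SpectrumSet,
    msc_reference: Optional[np.ndarray] = None,
) -> SpectrumSet:
    """Dispatch a configured pretreatment."""
    if config.method == "none":
        return data
    if config.method == "snv":
        return snv(data)
    if config.method == "msc":
        return msc(data, reference=msc_reference)
    if config.method == "normalize":
        return normalize(data, mode=config.normalize_mode)
    if config.method == "smooth":
        return savgol(data, config.window, config.polyorder, 0)
    if config.method == "savgol":
        return savgol(data, config.window, config.polyorder, config.deriv_order)
    raise ValueError(f"unknown preprocessing method {config.method!r}")
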