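"""Spectral preprocessing operators and the method-tag dispatcher.

Implements the five operators used throughout the comparison workflow —
Savitzky-Golay smoothing (SG), standard normal variate (SNV),
multiplicative scatter correction (MSC), peak-area normalization (PAN),
and the continuous wavelet transform (CWT, gaus1 mother wavelet at
dyadic scales 2^1..2^10) — plus :func:`preprocess`, which maps method
tags (``R``, ``SG``, ``SG-SNV``, ``SG-MSC``, ``SG-PAN``,
``CWT-1``..``CWT-10``) to operator chains. All tags except ``R`` apply
SG smoothing first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import convolve1d
from scipy.signal import fftconvolve, savgol_filter

from .io import SpectraMatrix

CWT_SCALES = tuple(2 ** k for k in range(1, 11))

VALID_TAGS = ("R", "SG", "SG-SNV", "SG-MSC", "SG-PAN") + tuple(
    f"CWT-{k}" for k in range(1, 11))


@dataclass
class SGConfig:
    """Savitzky-Golay settings: polynomial degree and half-width.

    A half-width of ``w`` gives a symmetric (2w + 1)-point window; the
    defaults (degree 4, half-width 6, i.e. a 13-point window) are the
    settings the smoothing was tuned to.
    """
    degree: int = 4
    half_width: int = 6

    def __post_init__(self):
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if 2 * self.half_width + 1 <= self.degree:
            raise ValueError("window (2*half_width+1) must exceed degree")

    @property
    def window(self) -> int:
        return 2 * self.half_width + 1


@dataclass
class MSCFit:
    """Per-sample multiplicative scatter correction fit: slope ``alpha``
    and offset ``beta`` of the sample's regression on the reference."""
    alpha: np.ndarray
    beta: np.ndarray
    reference: np.ndarray


def _as2d(x):
    x = np.asarray(x, dtype=float)
    return np.atleast_2d(x), x.ndim == 1


# ---------------------------------------------------------------------------
# Savitzky-Golay

def _edge_rows(cfg: SGConfig, n_avail: int, center: int) -> np.ndarray:
    """Row of the least-squares projection matrix for a truncated window
    of length ``n_avail``, evaluated at position ``center``."""
    t = np.arange(n_avail, dtype=float)
    A = np.vander(t, cfg.degree + 1, increasing=True)
    # P = A (A^T A)^-1 A^T ; we need row `center`
    coef, *_ = np.linalg.lstsq(A, np.eye(n_avail), rcond=None)
    return A[center] @ coef


def sg_smooth(spectrum, cfg: SGConfig = SGConfig()):
    """Savitzky-Golay smoothing with truncate-and-refit boundaries.

    Interior points are the local least-squares polynomial fit value
    (degree-``cfg.degree`` polynomials pass through unchanged). Near the
    ends the window is truncated to the available points and the
    polynomial refitted, which degrades gracefully instead of padding.
    Accepts a single spectrum or a (n_samples, n_bands) matrix.
    """
    X, was1d = _as2d(spectrum)
    p = X.shape[1]
    if p <= cfg.window:
        raise ValueError(f"spectrum length {p} must exceed window {cfg.window}")
    out = savgol_filter(X, cfg.window, cfg.degree, axis=1, mode="interp")
    w = cfg.half_width
    for i in range(w):
        # left edge: points 0..i+w available
        row = _edge_rows(cfg, i + w + 1, i)
        out[:, i] = X[:, :i + w + 1] @ row
        # right edge: points p-1-i-w..p-1 available, target at offset w
        row = _edge_rows(cfg, i + w + 1, w)
        out[:, p - 1 - i] = X[:, p - 1 - i - w:] @ row
    return out[0] if was1d else out


# ---------------------------------------------------------------------------
# SNV

def snv(spectrum):
    """Standard normal variate: per-spectrum centering and scaling to
    unit sample standard deviation (N-1 denominator)."""
    X, was1d = _as2d(spectrum)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        raise ValueError("zero variance: SNV undefined for a constant spectrum")
    out = (X - mean) / sd
    return out[0] if was1d else out


# ---------------------------------------------------------------------------
# MSC

def msc_fit(calibration) -> np.ndarray:
    """Mean calibration spectrum, the MSC reference."""
    X = calibration.values if isinstance(calibration, SpectraMatrix) else np.asarray(calibration, float)
    X = np.atleast_2d(X)
    if X.shape[0] < 2:
        raise ValueError("MSC reference requires at least 2 calibration samples")
    return X.mean(axis=0)


def msc_apply(spectrum, reference):
    """Correct spectra against a reference: regress each sample on the
    reference by ordinary least squares and return (x - beta) / alpha.

    Returns ``(corrected, MSCFit)``.
    """
    ref = np.asarray(reference, dtype=float)
    X, was1d = _as2d(spectrum)
    if X.shape[1] != ref.size:
        raise ValueError(f"reference length {ref.size} != spectrum length {X.shape[1]}")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    alpha = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(alpha == 0):
        raise ValueError("zero regression slope: MSC undefined")
    beta = X.mean(axis=1) - alpha * ref.mean()
    corrected = (X - beta[:, None]) / alpha[:, None]
    fit = MSCFit(alpha=alpha, beta=beta, reference=ref)
    return (corrected[0] if was1d else corrected), fit


# ---------------------------------------------------------------------------
# PAN

def pan(spectrum, wavelengths):
    """Peak-area normalization: divide by the trapezoidal area under the
    spectral curve, so the output integrates to 1 over wavelength."""
    w = np.asarray(wavelengths, dtype=float)
    X, was1d = _as2d(spectrum)
    area = np.trapezoid(X, w, axis=1)
    if np.any(area <= 0):
        raise ValueError("non-positive spectral area: PAN undefined")
    out = X / area[:, None]
    return out[0] if was1d else out


# ---------------------------------------------------------------------------
# CWT

def _gaus1_kernel(scale: int) -> np.ndarray:
    """Sampled gaus1 wavelet (first derivative of a Gaussian) at the
    given scale, L2-normalized by 1/sqrt(scale), exactly zero-mean."""
    wav = pywt.ContinuousWavelet("gaus1")
    psi, x = wav.wavefun(length=1024)
    lo, hi = wav.lower_bound, wav.upper_bound
    half = int(np.ceil(hi * scale))
    k = np.arange(-half, half + 1, dtype=float)
    kernel = np.interp(k / scale, x, psi, left=0.0, right=0.0) / np.sqrt(scale)
    kernel -= kernel.mean()  # exact zero response to constants
    return kernel


def cwt_scale(spectrum, scale: int):
    """Wavelet coefficients at one dyadic scale.

    Correlates the spectrum with the scaled gaus1 wavelet using
    symmetric (mirror) boundary padding; one coefficient per band.
    """
    if scale not in CWT_SCALES:
        raise ValueError(f"unsupported scale {scale}; valid: {CWT_SCALES}")
    X, was1d = _as2d(spectrum)
    kernel = _gaus1_kernel(scale)
    # Correlate with the wavelet under mirror (symmetric) padding.
    # ndimage 'reflect' is that padding; convolve1d applies the reversed
    # kernel, so flip it. Large kernels go through FFT convolution on an
    # explicitly mirror-padded signal (identical result, much faster).
    if kernel.size <= 301:
        out = convolve1d(X, kernel[::-1], axis=1, mode="reflect")
    else:
        half = kernel.size // 2
        Xp = np.pad(X, ((0, 0), (half, half)), mode="symmetric")
        out = fftconvolve(Xp, kernel[::-1][None, :], mode="valid", axes=1)
    return out[0] if was1d else out


@dataclass
class CWTStack:
    """sample x scale x band wavelet coefficients at scales 2^1..2^10."""
    coefficients: np.ndarray
    scales: tuple = CWT_SCALES


def cwt_all(spectrum) -> CWTStack:
    """All ten dyadic scale planes of a spectrum or matrix."""
    X, was1d = _as2d(spectrum)
    coeff = np.stack([cwt_scale(X, a) for a in CWT_SCALES], axis=1)
    return CWTStack(coefficients=coeff[0] if was1d else coeff)


# ---------------------------------------------------------------------------
# dispatcher

def preprocess(matrix: SpectraMatrix, tag: str,
               calibration_ids=None, sg: SGConfig = SGConfig()) -> SpectraMatrix:
    """Apply a named preprocessing chain to a spectra matrix.

    ``R`` is the identity; every other tag applies SG smoothing first,
    then the named operator. ``CWT-k`` returns the scale-2^k coefficient
    plane. ``SG-MSC`` fits its reference on ``calibration_ids`` only (a
    leakage guard: validation samples never contribute to the
    reference); the reference provenance is recorded in the result's
    ``meta``.
    """
    if tag not in VALID_TAGS:
        raise ValueError(f"unknown preprocessing tag {tag!r}; valid tags: "
                         + ", ".join(VALID_TAGS))
    meta = dict(matrix.meta)
    meta["tag"] = tag
    if tag == "R":
        return SpectraMatrix(list(matrix.sample_ids), matrix.wavelengths.copy(),
                             matrix.values.copy(), meta)
    smoothed = sg_smooth(matrix.values, sg)
    if tag == "SG":
        out = smoothed
    elif tag == "SG-SNV":
        out = snv(smoothed)
    elif tag == "SG-MSC":
        if calibration_ids is None:
            raise ValueError("SG-MSC requires calibration_ids for the reference")
        cal_pos = [matrix.sample_ids.index(s) for s in calibration_ids]
        reference = msc_fit(smoothed[cal_pos])
        out, _ = msc_apply(smoothed, reference)
        meta["msc_reference_ids"] = list(calibration_ids)
    elif tag == "SG-PAN":
        out = pan(smoothed, matrix.wavelengths)
    else:  # CWT-k
        k = int(tag.split("-")[1])
        out = cwt_scale(smoothed, 2 ** k)
    return SpectraMatrix(list(matrix.sample_ids), matrix.wavelengths.copy(),
                         out, meta)
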