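"""Successive projections algorithm (SPA) for spectral band selection.

SPA builds, from each candidate start band, a greedy chain of bands: at
every step the band whose (calibration-centered) column has the largest
norm after orthogonal projection onto the complement of the span of the
already-selected columns is appended. Candidate subsets — every chain
prefix of length 5..30 from every start band — are scored by an ordinary
least-squares fit on the calibration set and root-mean-square error on
the validation set; the subset with the smallest validation RMSE wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class FeatureSet:
    """An SPA-selected band subset for one (parameter, stress, tag) cell."""

    indices: list                      # band indices, in selection order
    wavelengths: list                  # nm, aligned with indices
    parameter: str = ""
    stress: str = ""
    tag: str = ""
    validation_rmse: float = float("nan")
    start_band: int = -1
    scores: dict = field(default_factory=dict, repr=False)

    @property
    def n_bands(self) -> int:
        return len(self.indices)

    def __post_init__(self):
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("feature set band indices must be unique")


def spa_chain(X_cal: np.ndarray, start_band: int, n: int) -> list:
    """Greedy SPA chain of ``n`` band indices starting at ``start_band``.

    ``X_cal`` must have centered columns. Deterministic; ties in the
    projected norm break toward the smallest band index. Columns that
    fall inside the span of the selection (projected norm ~ 0) are only
    picked once no independent candidate remains.
    """
    X = np.array(X_cal, dtype=float)
    n_samples, n_bands = X.shape
    if not (1 <= n <= min(n_samples - 1, n_bands)):
        raise ValueError(
            f"n={n} outside achievable range [1, {min(n_samples - 1, n_bands)}]")
    if not (0 <= start_band < n_bands):
        raise ValueError(f"start_band {start_band} out of range")
    P = X.copy()
    selected = [start_band]
    for _ in range(n - 1):
        u = P[:, selected[-1]]
        nu = np.linalg.norm(u)
        if nu > _EPS:
            u = u / nu
            P -= np.outer(u, u @ P)
        norms = np.linalg.norm(P, axis=0)
        norms[selected] = -1.0  # exclude already-selected bands
        selected.append(int(np.argmax(norms)))  # argmax ties -> smallest index
    return selected


def _ols_val_rmse(X_cal, y_cal, X_val, y_val, cols) -> float:
    A = np.column_stack([np.ones(X_cal.shape[0]), X_cal[:, cols]])
    coef, *_ = np.linalg.lstsq(A, y_cal, rcond=None)
    pred = np.column_stack([np.ones(X_val.shape[0]), X_val[:, cols]]) @ coef
    return float(np.sqrt(np.mean((y_val - pred) ** 2)))


def spa_select(X_cal, y_cal, X_val, y_val, n_min: int = 5, n_max: int = 30,
               wavelengths=None, start_bands=None, start_stride: int = 1,
               parameter: str = "", stress: str = "", tag: str = "") -> FeatureSet:
    """Select the band subset with minimum validation RMSE.

    Chains are grown from every start band in ``start_bands`` (default:
    all bands, optionally thinned by ``start_stride`` for quick runs)
    and every prefix of length ``n_min``..``n_max`` is scored by an
    ordinary-least-squares fit on the calibration set. Ties break toward
    fewer bands, then the lexicographically smallest sorted index list.
    Columns are centered with calibration means before projection;
    scoring uses the raw (uncentered) values with an intercept.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n_samples, n_bands = X_cal.shape
    if n_min > n_max:
        raise ValueError(f"n_min={n_min} > n_max={n_max}")
    if n_samples < n_max + 1:
        raise ValueError(
            f"need at least n_max+1={n_max + 1} calibration samples, have {n_samples}")
    n_max = min(n_max, n_bands)
    n_min = min(n_min, n_max)
    Xc = X_cal - X_cal.mean(axis=0)
    if start_bands is None:
        start_bands = range(0, n_bands, max(1, int(start_stride)))
    best = None  # (rmse, n_bands, sorted_indices, chain_prefix, start)
    scores = {}
    for start in start_bands:
        chain = spa_chain(Xc, int(start), n_max)
        for n in range(n_min, n_max + 1):
            cols = chain[:n]
            rmse = _ols_val_rmse(X_cal, y_cal, X_val, y_val, cols)
            key = (rmse, n, tuple(sorted(cols)))
            scores[(int(start), n)] = rmse
            if best is None or key < best[:3]:
                best = (rmse, n, tuple(sorted(cols)), list(cols), int(start))
    rmse, _, _, cols, start = best
    if wavelengths is None:
        wl = list(cols)
    else:
        wl = [float(np.asarray(wavelengths)[i]) for i in cols]
    return FeatureSet(indices=list(cols), wavelengths=wl, parameter=parameter,
                      stress=stress, tag=tag, validation_rmse=rmse,
                      start_band=start, scores=scores)
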