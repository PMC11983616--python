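"""Sample partitioning, accuracy metrics, and the model-comparison grid.

The partition scheme mirrors the study protocol: samples are ranked by
the target value, cut into three equal-count ranges, cleaned of gross
outliers within each range, and split 2:1 into calibration and
validation sets range by range, so both sets span the full value range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocessing, regression, spa

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """A calibration/validation split with removal provenance."""
    calibration_ids: list
    validation_ids: list
    removed_ids: list = field(default_factory=list)  # (sample_id, reason)
    ratio: tuple = (2, 1)
    n_ranges: int = 3

    def __post_init__(self):
        cal, val = set(self.calibration_ids), set(self.validation_ids)
        if cal & val:
            raise ValueError("calibration and validation sets overlap")


def partition(y: pd.Series, seed: int, ratio=(2, 1), n_ranges: int = 3,
              mad_factor: float = 3.0) -> Partition:
    """Rank-based calibration/validation split.

    Sort values descending, cut into ``n_ranges`` equal-count ranges,
    remove within-range outliers (|y - range median| > ``mad_factor`` x
    range MAD), then randomly split each range ``ratio`` (default 2:1)
    with the given seed. Calibration quotas are assigned by largest
    remainder so the global ratio is exact and each range is within one
    sample of it.
    """
    y = pd.Series(y).astype(float)
    if len(y) < n_ranges * 3:
        raise ValueError(f"need at least {n_ranges * 3} samples, have {len(y)}")
    order = y.sort_values(ascending=False, kind="stable")
    ranges = np.array_split(np.arange(len(order)), n_ranges)
    removed = []
    kept_ranges = []
    for r_idx, rr in enumerate(ranges):
        vals = order.iloc[rr]
        med = vals.median()
        mad = (vals - med).abs().median()
        if mad > 0:
            bad = (vals - med).abs() > mad_factor * mad
        else:
            bad = pd.Series(False, index=vals.index)
        for sid in vals.index[bad]:
            removed.append((sid, f"range {r_idx}: |y - median| > "
                                 f"{mad_factor} x MAD"))
            log.info("partition: removed %s (%s)", sid, removed[-1][1])
        kept = vals.index[~bad].tolist()
        if not kept:
            raise ValueError(f"range {r_idx} emptied by outlier removal")
        kept_ranges.append(kept)
    # largest-remainder calibration quotas for an exact global ratio
    frac = ratio[0] / (ratio[0] + ratio[1])
    sizes = [len(k) for k in kept_ranges]
    total_cal = round(sum(sizes) * frac)
    base = [int(np.floor(s * frac)) for s in sizes]
    rema = [s * frac - b for s, b in zip(sizes, base)]
    for i in sorted(range(len(sizes)), key=lambda i: (-rema[i], i)):
        if sum(base) >= total_cal:
            break
        base[i] += 1
    rng = np.random.default_rng(int(seed))
    cal_ids, val_ids = [], []
    for kept, n_cal in zip(kept_ranges, base):
        perm = rng.permutation(len(kept))
        cal_ids += [kept[i] for i in sorted(perm[:n_cal])]
        val_ids += [kept[i] for i in sorted(perm[n_cal:])]
    return Partition(cal_ids, val_ids, removed, tuple(ratio), n_ranges)


# ---------------------------------------------------------------------------
# metrics

def r2(y, y_hat) -> float:
    """Coefficient of determination, 1 - SSE/TSS with the mean taken
    from the scored set itself. Can be negative on validation data."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 2:
        raise ValueError("r2 requires equal-length inputs of size >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / tss


def rmse(y, y_hat) -> float:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size == 0:
        raise ValueError("rmse requires equal-length non-empty inputs")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


@dataclass
class FitReport:
    """Calibration/validation accuracy of one (parameter, stress, model,
    preprocessing) cell."""
    parameter: str
    stress: str
    model: str
    tag: str
    r2_cal: float
    rmse_cal: float
    r2_val: float
    rmse_val: float
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"parameter": self.parameter, "stress": self.stress,
               "model": self.model, "tag": self.tag,
               "r2_cal": self.r2_cal, "rmse_cal": self.rmse_cal,
               "r2_val": self.r2_val, "rmse_val": self.rmse_val}
        row.update(self.extra)
        return row


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


# ---------------------------------------------------------------------------
# comparison workflow

def _score(model_predict, X_cal, y_cal, X_val, y_val):
    p_cal = model_predict(X_cal)
    p_val = model_predict(X_val)
    return (r2(y_cal, p_cal), rmse(y_cal, p_cal),
            r2(y_val, p_val), rmse(y_val, p_val))


def _fit_one(model_name, X_cal, y_cal, X_val, y_val, seed,
             max_r=15, rf_cfg=None, bpnn_cfg=None):
    if model_name == "PLSR":
        m = regression.fit_plsr(X_cal, y_cal, max_r=max_r)
        return m, m.predict
    if model_name == "RF":
        cfg = rf_cfg or regression.RFConfig(seed=seed)
        m = regression.fit_rf(X_cal, y_cal, cfg)
        return m, m.predict
    if model_name == "BPNN":
        cfg = bpnn_cfg or regression.BPNNConfig(seed=seed)
        # the stop set is the validation split, per the training protocol
        m = regression.fit_bpnn(X_cal, y_cal, cfg, X_val, y_val)
        return m, m.predict
    raise ValueError(f"unknown model {model_name!r}")


def run_comparison(spectra, physio: pd.DataFrame, design: pd.DataFrame,
                   parameters, stresses, tags, models, seed: int = 0,
                   spa_bounds=(5, 30), spa_stride: int = 1, max_r: int = 15,
                   rf_cfg=None, bpnn_cfg=None):
    """The two-stage comparison grid.

    Stage 1 (preprocessing comparison): for every (parameter, stress)
    cell — one partition, reused everywhere in the cell — fit a
    full-band PLSR under each preprocessing tag. Stage 2 (model
    comparison): on the best tag (highest validation R^2), select bands
    with SPA and fit every requested model on the selected bands.

    Returns ``(stage1_reports, stage2_reports, feature_sets)``.
    """
    if not (list(parameters) and list(stresses) and list(tags) and list(models)):
        raise ValueError("empty comparison grid")
    stage1, stage2, feature_sets = [], [], {}
    for parameter in parameters:
        for stress in stresses:
            ids = design.loc[design["group"] == stress, "sample_id"].tolist()
            part = partition(physio.loc[ids, parameter], seed=seed)
            planes = {}
            for tag in tags:
                plane = preprocessing.preprocess(
                    spectra.subset(ids), tag,
                    calibration_ids=part.calibration_ids)
                planes[tag] = plane
                X_cal = plane.subset(part.calibration_ids).values
                X_val = plane.subset(part.validation_ids).values
                y_cal = physio.loc[part.calibration_ids, parameter].to_numpy()
                y_val = physio.loc[part.validation_ids, parameter].to_numpy()
                m = regression.fit_plsr(X_cal, y_cal, max_r=max_r)
                stage1.append(FitReport(
                    parameter, stress, "PLSR", tag,
                    *_score(m.predict, X_cal, y_cal, X_val, y_val),
                    extra={"stage": 1, "n_lv": m.n_components}))
            cell = [r for r in stage1
                    if r.parameter == parameter and r.stress == stress]
            best_tag = max(cell, key=lambda r: r.r2_val).tag
            plane = planes[best_tag]
            X_cal = plane.subset(part.calibration_ids).values
            X_val = plane.subset(part.validation_ids).values
            y_cal = physio.loc[part.calibration_ids, parameter].to_numpy()
            y_val = physio.loc[part.validation_ids, parameter].to_numpy()
            fs = spa.spa_select(
                X_cal, y_cal, X_val, y_val, *spa_bounds,
                wavelengths=plane.wavelengths, start_stride=spa_stride,
                parameter=parameter, stress=stress, tag=best_tag)
            feature_sets[(parameter, stress)] = fs
            for model_name in models:
                m, pred = _fit_one(model_name, X_cal[:, fs.indices], y_cal,
                                   X_val[:, fs.indices], y_val, seed,
                                   max_r=max_r, rf_cfg=rf_cfg, bpnn_cfg=bpnn_cfg)
                stage2.append(FitReport(
                    parameter, stress, model_name, best_tag,
                    *_score(pred, X_cal[:, fs.indices], y_cal,
                            X_val[:, fs.indices], y_val),
                    extra={"stage": 2, "n_bands": fs.n_bands,
                           "cal_ids_hash": hash(tuple(part.calibration_ids))}))
    return stage1, stage2, feature_sets
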