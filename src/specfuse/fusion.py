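"""Nitrogen-salt feature fusion for combined-stress estimation.

A single model per parameter is trained on *both* single-stress groups:
the target is the mean of the z-scored NS and SS values of paired
samples (pairs share a (year, day, replicate) design cell), and the
predictors are the series concatenation of the NS-selected and
SS-selected spectral features, each extracted under its own
preprocessing tag. Any group's samples — including the combined-stress
group — can then be scored by extracting both feature blocks from that
group's own spectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocessing, regression
from .evaluation import FitReport, partition, r2, rmse
from .spa import FeatureSet

log = logging.getLogger(__name__)


def zscore(values, mean: float, sd: float):
    """(v - mean)/sd with an N-1-denominator calibration sd."""
    if sd <= 0:
        raise ValueError("zscore requires sd > 0")
    return (np.asarray(values, dtype=float) - mean) / sd


def inverse_zscore(values, mean: float, sd: float):
    return np.asarray(values, dtype=float) * sd + mean


@dataclass
class GroupStats:
    """Calibration mean and sample SD (N-1) of one group's target."""
    mean: float
    sd: float

    @classmethod
    def from_values(cls, values) -> "GroupStats":
        v = np.asarray(values, dtype=float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)))


def pair_samples(meta_ns: pd.DataFrame, meta_ss: pd.DataFrame) -> list:
    """Pair NS and SS samples by shared (year, day, replicate) cell.

    Returns ``[(ns_id, ss_id), ...]``; unpaired remainders are dropped
    with a logged count. Raises if the two groups share no design cell.
    """
    key = ["year", "day", "replicate"]
    ns = meta_ns[["sample_id", *key]].rename(columns={"sample_id": "ns_id"})
    ss = meta_ss[["sample_id", *key]].rename(columns={"sample_id": "ss_id"})
    merged = ns.merge(ss, on=key, how="inner")
    if merged.empty:
        raise ValueError("NS and SS share no (year, day, replicate) design cell")
    dropped = (len(ns) - len(merged)) + (len(ss) - len(merged))
    if dropped:
        log.info("pair_samples: dropped %d unpaired sample(s)", dropped)
    pairs = list(zip(merged["ns_id"], merged["ss_id"]))
    assert len(set(p[0] for p in pairs)) == len(pairs)
    assert len(set(p[1] for p in pairs)) == len(pairs)
    return pairs


def fuse_targets(y_ns: pd.Series, y_ss: pd.Series, pairs,
                 stats_ns: GroupStats, stats_ss: GroupStats) -> pd.Series:
    """Fused target per pair: mean of the two z-scores.

    ``stats_*`` must come from calibration pairs only; over calibration
    pairs the fused targets average to ~0 by construction.
    """
    try:
        z_ns = zscore(y_ns.loc[[p[0] for p in pairs]].to_numpy(),
                      stats_ns.mean, stats_ns.sd)
        z_ss = zscore(y_ss.loc[[p[1] for p in pairs]].to_numpy(),
                      stats_ss.mean, stats_ss.sd)
    except KeyError as exc:
        raise ValueError(f"missing pair member: {exc}") from exc
    fused = 0.5 * (z_ns + z_ss)
    return pd.Series(fused, index=pd.Index([f"{a}|{b}" for a, b in pairs],
                                           name="pair_id"))


def _extract_block(spectra, fs: FeatureSet, sample_ids, calibration_ids):
    """Feature block as deviations from the source group's calibration
    feature means.

    Stress groups differ in their mean spectra, and that group signature
    leaks into every derived feature; centering each block on its own
    group's calibration cohort (never on validation samples) aligns the
    blocks on a common scale so the fused model transfers across groups.
    """
    plane = preprocessing.preprocess(spectra, fs.tag,
                                     calibration_ids=calibration_ids)
    block = plane.subset(list(sample_ids)).values[:, fs.indices]
    if calibration_ids is not None:
        center = plane.subset(list(calibration_ids)).values[:, fs.indices].mean(axis=0)
        block = block - center
    return block


def build_fused_X(spectra_by_group: dict, fs_ns: FeatureSet, fs_ss: FeatureSet,
                  pairs=None, group: str | None = None,
                  calibration_ids_by_group: dict | None = None) -> np.ndarray:
    """Series-concatenated feature rows, NS block first.

    Training mode (``pairs``): row i = [NS-sample i values at the
    NS-selected bands under the NS tag | SS-sample i values at the
    SS-selected bands under the SS tag].

    Prediction mode (``group``): both blocks are extracted from the same
    sample of that group, each block under its own preprocessing tag.
    """
    if (pairs is None) == (group is None):
        raise ValueError("exactly one of pairs/group must be given")
    cal = calibration_ids_by_group or {}
    if pairs is not None:
        ns_ids = [p[0] for p in pairs]
        ss_ids = [p[1] for p in pairs]
        left = _extract_block(spectra_by_group["NS"], fs_ns, ns_ids,
                              cal.get("NS"))
        right = _extract_block(spectra_by_group["SS"], fs_ss, ss_ids,
                               cal.get("SS"))
    else:
        sm = spectra_by_group[group]
        left = _extract_block(sm, fs_ns, sm.sample_ids, cal.get(group))
        right = _extract_block(sm, fs_ss, sm.sample_ids, cal.get(group))
    return np.hstack([left, right])


def train_and_validate_fusion(design: pd.DataFrame, physio: pd.DataFrame,
                              spectra, parameter: str, fs_ns: FeatureSet,
                              fs_ss: FeatureSet,
                              rf_cfg: regression.RFConfig | None = None,
                              seed: int = 0, partitions: dict | None = None):
    """Train the fused RF and validate it on NS, SS, and NS*SS.

    Each group gets its own range-based 2:1 partition of the target (or
    reuse ``partitions``); fused training uses only pairs whose both
    members are calibration samples. Group validation targets are
    z-scored with that group's calibration statistics, on which fused
    predictions live; RMSE is also reported back on the group's native
    scale. Returns ``(reports, model, stats_by_group)``.
    """
    rf_cfg = rf_cfg or regression.RFConfig(seed=seed)
    groups = ("NS", "SS", "NS*SS")
    parts, stats = {}, {}
    for g in groups:
        ids = design.loc[design["group"] == g, "sample_id"].tolist()
        parts[g] = (partitions or {}).get(g) or partition(
            physio.loc[ids, parameter], seed=seed)
        stats[g] = GroupStats.from_values(
            physio.loc[parts[g].calibration_ids, parameter])

    cal_ns = set(parts["NS"].calibration_ids)
    cal_ss = set(parts["SS"].calibration_ids)
    meta_ns = design[design["sample_id"].isin(cal_ns)]
    meta_ss = design[design["sample_id"].isin(cal_ss)]
    pairs = pair_samples(meta_ns, meta_ss)

    y = physio[parameter]
    fused_y = fuse_targets(y, y, pairs, stats["NS"], stats["SS"])
    spectra_by_group = {
        g: spectra.subset(design.loc[design["group"] == g, "sample_id"].tolist())
        for g in groups
    }
    cal_ids = {g: parts[g].calibration_ids for g in groups}
    X_train = build_fused_X(spectra_by_group, fs_ns, fs_ss, pairs=pairs,
                            calibration_ids_by_group=cal_ids)
    model = regression.fit_rf(X_train, fused_y.to_numpy(), rf_cfg)

    reports = []
    for g in groups:
        plane_rows = build_fused_X(spectra_by_group, fs_ns, fs_ss, group=g,
                                   calibration_ids_by_group=cal_ids)
        row_ids = spectra_by_group[g].sample_ids
        pos = {s: i for i, s in enumerate(row_ids)}
        for split, id_list in (("cal", parts[g].calibration_ids),
                               ("val", parts[g].validation_ids)):
            overlap = set(id_list) & {p for pr in pairs for p in pr} \
                if split == "val" else set()
            if overlap and g in ("NS", "SS"):
                raise ValueError(
                    f"leakage: validation sample(s) {sorted(overlap)[:3]} "
                    f"appear in fused training pairs")
        X_cal = plane_rows[[pos[s] for s in parts[g].calibration_ids]]
        X_val = plane_rows[[pos[s] for s in parts[g].validation_ids]]
        z_cal = zscore(y.loc[parts[g].calibration_ids].to_numpy(),
                       stats[g].mean, stats[g].sd)
        z_val = zscore(y.loc[parts[g].validation_ids].to_numpy(),
                       stats[g].mean, stats[g].sd)
        p_cal, p_val = model.predict(X_cal), model.predict(X_val)
        raw_rmse = rmse(y.loc[parts[g].validation_ids].to_numpy(),
                        inverse_zscore(p_val, stats[g].mean, stats[g].sd))
        reports.append(FitReport(
            parameter, g, "RF-fusion", f"{fs_ns.tag}|{fs_ss.tag}",
            r2_cal=r2(z_cal, p_cal), rmse_cal=rmse(z_cal, p_cal),
            r2_val=r2(z_val, p_val), rmse_val=rmse(z_val, p_val),
            extra={"rmse_val_raw": raw_rmse,
                   "n_train_pairs": len(pairs)}))
    return reports, model, stats


def fusion_vs_direct(design, physio, spectra, parameter: str, tag_ns: str,
                     tag_ss: str, tag_xx: str, seed: int = 0,
                     spa_stride: int = 25, spa_bounds=(5, 30)):
    """Head-to-head: fused RF vs a directly NS*SS-trained RF.

    Selects per-group SPA features under the given tags, trains both
    models with the same partitions, and returns ``(r2_fused,
    r2_direct)`` — the combined-stress validation R^2 of each.
    """
    from . import spa as spa_mod

    parts, planes, features = {}, {}, {}
    for g, tag in (("NS", tag_ns), ("SS", tag_ss), ("NS*SS", tag_xx)):
        ids = design.loc[design["group"] == g, "sample_id"].tolist()
        parts[g] = partition(physio.loc[ids, parameter], seed=seed)
        plane = preprocessing.preprocess(spectra.subset(ids), tag,
                                         calibration_ids=parts[g].calibration_ids)
        planes[g] = plane
        features[g] = spa_mod.spa_select(
            plane.subset(parts[g].calibration_ids).values,
            physio.loc[parts[g].calibration_ids, parameter].to_numpy(),
            plane.subset(parts[g].validation_ids).values,
            physio.loc[parts[g].validation_ids, parameter].to_numpy(),
            *spa_bounds, wavelengths=plane.wavelengths,
            start_stride=spa_stride, parameter=parameter, stress=g, tag=tag)

    reports, _, _ = train_and_validate_fusion(
        design, physio, spectra, parameter, features["NS"], features["SS"],
        seed=seed, partitions=parts)
    r2_fused = next(r.r2_val for r in reports if r.stress == "NS*SS")

    g = "NS*SS"
    fs = features[g]
    X_cal = planes[g].subset(parts[g].calibration_ids).values[:, fs.indices]
    X_val = planes[g].subset(parts[g].validation_ids).values[:, fs.indices]
    y_cal = physio.loc[parts[g].calibration_ids, parameter].to_numpy()
    y_val = physio.loc[parts[g].validation_ids, parameter].to_numpy()
    rf = regression.fit_rf(X_cal, y_cal, regression.RFConfig(seed=seed))
    r2_direct = r2(y_val, rf.predict(X_val))
    return r2_fused, r2_direct
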