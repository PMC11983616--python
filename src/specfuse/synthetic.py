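"""Synthetic leaf spectra, physiology, and metadata for stress experiments.

Emulates a pot experiment on forage rape (*Brassica napus*) measured over
three seasons: four treatment groups — unstressed control (CK), nitrogen
stress (NS), salt stress (SS), and combined stress (NS*SS) — sampled on
days 10/20/30/40 after sowing. Each sample carries ten leaf gas-exchange
and chlorophyll-fluorescence parameters (Pn, Ci, gs, Tr, PhiPSII, Fv/Fm,
Fv/F0, qP, NPQ, ETR) and a 2151-band reflectance spectrum on the
canonical 350-2500 nm grid.

The generator is calibrated so that, at the default cohort size of 240
samples per group, group-mean contrasts reproduce the measured stress
responses: a green-peak (558 nm) reflectance depression of 15.48 / 21.79
/ 25.76 % and a short-wave-infrared (1626 nm) elevation of 3.46 / 5.83 /
16.26 % for NS / SS / NS*SS relative to CK, and day-10 physiological
shifts such as a 38.9 % drop of net photosynthesis and an 85.4 % rise of
NPQ under combined stress.

Physiology couples to reflectance through band-localized channels: a
nitrogen channel in the visible region and a salt channel at the
short-wave-infrared water-absorption bands. NS activates the nitrogen
channel, SS the salt channel, and NS*SS both (additively, plus a small
interaction and per-sample heterogeneity that makes direct combined-
stress modelling hard — the situation feature fusion addresses).

Measurement-session artifacts (multiplicative scatter gain, additive
offset, band noise) and a block component of physiological noise are
drawn per (day, year, replicate) cell and shared across the four groups,
as for treatments measured in the same session; this keeps cohort-mean
contrasts tightly calibrated while leaving realistic within-group
variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CANONICAL_GRID, SpectraMatrix

PARAMETERS = ("Pn", "Ci", "gs", "Tr", "PhiPSII", "FvFm", "FvF0", "qP", "NPQ", "ETR")
GROUPS = ("CK", "NS", "SS", "NS*SS")
STRESS_GROUPS = ("NS", "SS", "NS*SS")

#: Day-10 group-mean multipliers relative to CK (measured stress responses).
DAY10_MULTIPLIERS = {
    "Pn":      {"NS": 0.854, "SS": 0.784, "NS*SS": 0.611},
    "Tr":      {"NS": 0.743, "SS": 0.677, "NS*SS": 0.463},
    "gs":      {"NS": 0.842, "SS": 0.772, "NS*SS": 0.586},
    "Ci":      {"NS": 1.433, "SS": 1.498, "NS*SS": 1.678},
    "FvF0":    {"NS": 0.766, "SS": 0.713, "NS*SS": 0.608},
    "FvFm":    {"NS": 0.761, "SS": 0.727, "NS*SS": 0.689},
    "qP":      {"NS": 0.912, "SS": 0.835, "NS*SS": 0.814},
    "PhiPSII": {"NS": 0.803, "SS": 0.607, "NS*SS": 0.528},
    "ETR":     {"NS": 0.729, "SS": 0.605, "NS*SS": 0.522},
    "NPQ":     {"NS": 1.271, "SS": 1.722, "NS*SS": 1.854},
}

#: Reflectance group effects at the anchor bands: (558 nm depression,
#: 1626 nm elevation), as fractions of the CK mean.
SPECTRAL_EFFECTS = {
    "CK":    (0.0, 0.0),
    "NS":    (0.1548, 0.0346),
    "SS":    (0.2179, 0.0583),
    "NS*SS": (0.2576, 0.1626),
}

#: CK day-10 parameter means (units: Pn umol CO2 m-2 s-1, Ci umol mol-1,
#: gs mol m-2 s-1, Tr mmol m-2 s-1, ETR umol e- m-2 s-1; others unitless).
CK_BASELINES = {
    "Pn": 20.0, "Ci": 260.0, "gs": 0.32, "Tr": 6.0, "PhiPSII": 0.62,
    "FvFm": 0.80, "FvF0": 4.0, "qP": 0.78, "NPQ": 0.85, "ETR": 130.0,
}

#: CK mean trajectory across days 10/20/30/40, relative to day 10
#: (rise-then-fall for rates, gradual rise for Ci, mild arcs for ratios).
CK_TRAJECTORIES = {
    "Pn":      (1.00, 1.08, 1.15, 0.95),
    "Tr":      (1.00, 1.08, 1.15, 0.95),
    "gs":      (1.00, 1.08, 1.15, 0.95),
    "Ci":      (1.00, 1.04, 1.09, 1.14),
    "PhiPSII": (1.00, 1.08, 1.12, 1.00),
    "FvFm":    (1.00, 1.02, 1.03, 1.00),
    "FvF0":    (1.00, 1.10, 1.18, 1.05),
    "qP":      (1.00, 1.05, 1.08, 1.00),
    "NPQ":     (1.00, 1.05, 1.12, 1.08),
    "ETR":     (1.00, 1.10, 1.18, 1.05),
}

#: Weight of the day-10 stress deviation on later days (largest shift on
#: day 10, decaying as plants acclimate).
DAY_WEIGHTS = (1.00, 0.75, 0.55, 0.45)

#: Parameters bounded in (0, 1).
_UNIT_INTERVAL = ("PhiPSII", "FvFm", "qP")


def _default_coupling_map() -> dict:
    """Physiology-to-reflectance coupling channels.

    Each parameter maps to nitrogen-channel windows (visible region) and
    salt-channel windows (short-wave-infrared water bands), with a peak
    modulation amplitude per unit relative physiological deviation. The
    windows deliberately avoid the 558 and 1626 nm anchor bands so the
    group-level calibration stays exact.
    """
    return {
        "Ci":      {"N": [(405, 465), (620, 700)], "S": [(1420, 1500), (2220, 2300)],
                    "amp_N": 0.20, "amp_S": 0.20},
        "FvFm":    {"N": [(395, 435), (690, 760)], "S": [(1540, 1600), (2230, 2290)],
                    "amp_N": 0.18, "amp_S": 0.18},
        "NPQ":     {"N": [(950, 1030)], "S": [(1480, 1560), (1720, 1800)],
                    "amp_N": 0.15, "amp_S": 0.18},
        "ETR":     {"N": [(490, 540), (730, 790), (850, 910)],
                    "S": [(1660, 1720), (2030, 2090)],
                    "amp_N": 0.18, "amp_S": 0.18},
        "Pn":      {"N": [(660, 710)], "S": [(1920, 1970)], "amp_N": 0.06, "amp_S": 0.06},
        "gs":      {"N": [(470, 510)], "S": [(1890, 1930)], "amp_N": 0.05, "amp_S": 0.05},
        "Tr":      {"N": [(940, 990)], "S": [(1390, 1430)], "amp_N": 0.05, "amp_S": 0.06},
        "PhiPSII": {"N": [(680, 720)], "S": [(1650, 1690)], "amp_N": 0.06, "amp_S": 0.05},
        "FvF0":    {"N": [(420, 460)], "S": [(2140, 2190)], "amp_N": 0.05, "amp_S": 0.05},
        "qP":      {"N": [(525, 550)], "S": [(1330, 1370)], "amp_N": 0.04, "amp_S": 0.04},
    }


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Study-design and calibration constants of the synthetic world."""

    n_per_group: int = 240
    groups: tuple = GROUPS
    days: tuple = (10, 20, 30, 40)
    years: tuple = (1, 2, 3)
    stress_effect_table: dict = field(default_factory=lambda: {
        p: dict(DAY10_MULTIPLIERS[p]) for p in PARAMETERS})
    day_weights: tuple = DAY_WEIGHTS
    trajectories: dict = field(default_factory=lambda: dict(CK_TRAJECTORIES))
    baselines: dict = field(default_factory=lambda: dict(CK_BASELINES))
    spectral_effect_table: dict = field(default_factory=lambda: dict(SPECTRAL_EFFECTS))
    coupling_map: dict = field(default_factory=_default_coupling_map)
    interaction: float = 0.10            # extra coupling gain under NS*SS
    coupling_jitter_nsss: float = 0.15   # per-sample coupling heterogeneity, NS*SS only
    drift_bumps_nsss: int = 14           # structured spectral artifacts, NS*SS only
    drift_amp_nsss: float = 0.03         # bump amplitude sd (reflectance units)
    scatter_gain_sd: float = 0.05        # lognormal sigma of per-sample gain
    scatter_offset_sd: float = 0.01      # sd of per-sample additive offset
    noise_sd: float = 0.002              # additive per-band reflectance noise
    physio_block_cv: float = 0.20        # session/block noise shared across groups
    physio_group_cv: float = 0.01        # group-specific replicate noise
    seed: int = 0

    def __post_init__(self):
        for p, chan in self.coupling_map.items():
            if p not in PARAMETERS:
                raise ConfigurationError(f"unknown parameter in coupling_map: {p!r}")
            for key in ("N", "S"):
                for lo, hi in chan.get(key, []):
                    if not (350 <= lo < hi <= 2500):
                        raise ConfigurationError(
                            f"coupling window ({lo}, {hi}) for {p} outside 350-2500 nm")
        for p, row in self.stress_effect_table.items():
            for g, m in row.items():
                if m <= 0:
                    raise ConfigurationError(
                        f"non-positive effect multiplier {m} for {p}/{g}")

    @property
    def n_cells(self) -> int:
        return len(self.days) * len(self.years)

    @property
    def replicates(self) -> int:
        n_cells = self.n_cells
        if self.n_per_group % n_cells:
            raise ConfigurationError(
                f"n_per_group={self.n_per_group} does not divide evenly over "
                f"{len(self.days)} days x {len(self.years)} years "
                f"({n_cells} cells)")
        return self.n_per_group // n_cells

    def noiseless(self) -> "SimConfig":
        """Copy with every stochastic component switched off."""
        return replace(self, scatter_gain_sd=0.0, scatter_offset_sd=0.0,
                       noise_sd=0.0, physio_block_cv=0.0, physio_group_cv=0.0,
                       coupling_jitter_nsss=0.0, drift_amp_nsss=0.0)


# ---------------------------------------------------------------------------
# design

def generate_design(config: SimConfig) -> pd.DataFrame:
    """Deterministic sample metadata: one row per (group, day, year, replicate).

    Returns a DataFrame with columns sample_id, group, day, year,
    replicate; ``n_per_group`` rows per group.
    """
    reps = config.replicates  # validates divisibility
    rows = []
    for group in config.groups:
        for day in config.days:
            for year in config.years:
                for r in range(1, reps + 1):
                    rows.append({
                        "sample_id": f"{group}-y{year}-d{day}-r{r:02d}",
                        "group": group, "day": day, "year": year, "replicate": r,
                    })
    df = pd.DataFrame(rows)
    assert not df.duplicated(["group", "day", "year", "replicate"]).any()
    return df


def _cell_index(design: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Index of each sample's (day, year, replicate) measurement cell,
    identical across groups (the common-random-numbers key)."""
    day_pos = {d: i for i, d in enumerate(config.days)}
    year_pos = {y: i for i, y in enumerate(config.years)}
    reps = config.replicates
    return ((design["day"].map(day_pos).to_numpy() * len(config.years)
             + design["year"].map(year_pos).to_numpy()) * reps
            + design["replicate"].to_numpy() - 1)


# ---------------------------------------------------------------------------
# physiology

def group_day_mean(config: SimConfig, parameter: str, group: str, day: int) -> float:
    """The configured population mean of ``parameter`` for a group/day."""
    if parameter not in PARAMETERS:
        raise ConfigurationError(f"unknown parameter {parameter!r}")
    if group not in config.groups:
        raise ConfigurationError(f"unknown group label {group!r}")
    di = list(config.days).index(day)
    base = config.baselines[parameter] * config.trajectories[parameter][di]
    if group == "CK":
        return base
    k10 = config.stress_effect_table[parameter][group]
    k = 1.0 + (k10 - 1.0) * config.day_weights[di]
    return base * k


def generate_physio(design: pd.DataFrame, config: SimConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Simulate the ten-parameter physiology table for a design.

    Group/day means follow the calibrated stress multipliers; replicate
    noise has a session (block) component shared across groups and a
    smaller independent group-specific component. Fully deterministic
    for a given (config, seed).
    """
    if design.empty:
        raise ConfigurationError("empty design")
    unknown = set(design["group"]) - set(config.groups)
    if unknown:
        raise ConfigurationError(f"unknown group label(s) {sorted(unknown)!r}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 11])
    n_cells = config.n_cells * config.replicates
    n_par = len(PARAMETERS)
    block = np.exp(rng.normal(0.0, config.physio_block_cv, (n_cells, n_par)))
    group_noise = {
        g: np.exp(rng.normal(0.0, config.physio_group_cv, (n_cells, n_par)))
        for g in config.groups
    }
    cells = _cell_index(design, config)
    out = np.empty((len(design), n_par))
    for j, p in enumerate(PARAMETERS):
        means = np.array([
            group_day_mean(config, p, g, d)
            for g, d in zip(design["group"], design["day"])
        ])
        noise = np.array([
            block[c, j] * group_noise[g][c, j]
            for g, c in zip(design["group"], cells)
        ])
        out[:, j] = means * noise
    df = pd.DataFrame(out, columns=list(PARAMETERS),
                      index=pd.Index(design["sample_id"], name="sample_id"))
    for p in _UNIT_INTERVAL:
        df[p] = df[p].clip(1e-3, 0.999)
    return df


# ---------------------------------------------------------------------------
# spectra

def _gaussian(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def base_reflectance(grid: np.ndarray = CANONICAL_GRID) -> np.ndarray:
    """Smooth unstressed leaf reflectance on the given grid.

    Built from a logistic red edge, a green peak at 558 nm, a slowly
    decaying near/short-wave-infrared plateau, and Gaussian water
    absorption troughs near 1450, 1940, and 2250 nm, leaving a local
    short-wave-infrared maximum near 1626 nm. Values stay within
    (0.02, 0.65).
    """
    lam = np.asarray(grid, dtype=float)
    plateau_decay = np.exp(-0.5 * (np.maximum(lam - 1080.0, 0.0) / 800.0) ** 2)
    r = (0.035
         + 0.115 * _gaussian(lam, 558.0, 40.0)
         + 0.46 * _sigmoid((lam - 718.0) / 13.0) * plateau_decay
         - 0.16 * _gaussian(lam, 1450.0, 45.0)
         - 0.19 * _gaussian(lam, 1940.0, 70.0)
         - 0.05 * _gaussian(lam, 2250.0, 45.0))
    return r


def _vis_shape(lam: np.ndarray) -> np.ndarray:
    """Visible-region depression profile, exactly 1 at 558 nm."""
    return _gaussian(lam, 558.0, 70.0)


def _swir_shape(lam: np.ndarray) -> np.ndarray:
    """Short-wave-infrared elevation profile, exactly 1 at 1626 nm."""
    s = _gaussian(lam, 1626.0, 330.0) * _sigmoid((lam - 1050.0) / 80.0)
    at_anchor = 1.0 / (1.0 + math.exp(-(1626.0 - 1050.0) / 80.0))
    return s / at_anchor


def group_modulation(config: SimConfig, group: str,
                     grid: np.ndarray = CANONICAL_GRID) -> np.ndarray:
    """Multiplicative group reflectance modulation profile."""
    if group not in config.spectral_effect_table:
        raise ConfigurationError(f"unknown group label {group!r}")
    depress, elevate = config.spectral_effect_table[group]
    lam = np.asarray(grid, dtype=float)
    return 1.0 - depress * _vis_shape(lam) + elevate * _swir_shape(lam)


def _window_profile(windows, grid: np.ndarray) -> np.ndarray:
    prof = np.zeros_like(grid, dtype=float)
    for lo, hi in windows:
        center = 0.5 * (lo + hi)
        sigma = max((hi - lo) / 4.0, 1.0)
        prof += _gaussian(grid, center, sigma)
    return prof


def _channel_profiles(config: SimConfig, grid: np.ndarray):
    """Per-parameter coupling profiles (amplitude included) for the
    nitrogen and salt channels, as (n_params, n_bands) arrays."""
    n_par = len(PARAMETERS)
    C_N = np.zeros((n_par, grid.size))
    C_S = np.zeros((n_par, grid.size))
    for j, p in enumerate(PARAMETERS):
        chan = config.coupling_map.get(p)
        if chan is None:
            continue
        C_N[j] = chan.get("amp_N", 0.0) * _window_profile(chan.get("N", []), grid)
        C_S[j] = chan.get("amp_S", 0.0) * _window_profile(chan.get("S", []), grid)
    return C_N, C_S


#: Coupling gain per group: (nitrogen channel, salt channel). Both
#: channels exist in every leaf — pigment and water features always
#: respond to physiological state — but each stress amplifies the
#: dynamic range of its own channel, which is where that stress's
#: dominant spectral features sit.
_CHANNEL_GATE = {"CK": (0.6, 0.6), "NS": (1.0, 0.35), "SS": (0.35, 1.0)}


def generate_spectra(physio: pd.DataFrame, design: pd.DataFrame,
                     config: SimConfig, seed: int | None = None) -> SpectraMatrix:
    """Simulate reflectance spectra consistent with a physiology table.

    The noise-free signal of a sample is
    ``base(lam) * M_group(lam) * (1 + coupling(lam))`` where the coupling
    term sums band-localized modulations proportional to the sample's
    relative physiological deviations. Per-sample multiplicative gain,
    additive offset, and band noise are applied after signal
    construction, so scatter-correcting preprocessing has real work to
    do. Deterministic for a given (config, seed).
    """
    if list(physio.index) != list(design["sample_id"]):
        raise ConfigurationError("physio and design are not aligned by sample_id")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), 23])
    grid = CANONICAL_GRID
    n_cells = config.n_cells * config.replicates

    gains = np.exp(rng.normal(0.0, config.scatter_gain_sd, n_cells)) \
        if config.scatter_gain_sd > 0 else np.ones(n_cells)
    offsets = rng.normal(0.0, config.scatter_offset_sd, n_cells) \
        if config.scatter_offset_sd > 0 else np.zeros(n_cells)
    band_noise = rng.normal(0.0, config.noise_sd, (n_cells, grid.size)) \
        if config.noise_sd > 0 else np.zeros((n_cells, grid.size))
    # combined-stress heterogeneity: independent per-sample jitter on the
    # nitrogen and salt coupling channels
    jitter_n = rng.normal(0.0, config.coupling_jitter_nsss, n_cells) \
        if config.coupling_jitter_nsss > 0 else np.zeros(n_cells)
    jitter_s = rng.normal(0.0, config.coupling_jitter_nsss, n_cells) \
        if config.coupling_jitter_nsss > 0 else np.zeros(n_cells)

    base = base_reflectance(grid)
    C_N, C_S = _channel_profiles(config, grid)
    refs = np.array([config.baselines[p] for p in PARAMETERS])
    cells = _cell_index(design, config)

    values = np.empty((len(design), grid.size))
    for group in config.groups:
        mask = (design["group"] == group).to_numpy()
        if not mask.any():
            continue
        delta = physio.to_numpy()[mask] / refs - 1.0
        if group == "NS*SS":
            scale = 1.0 + config.interaction
            jn = (1.0 + jitter_n[cells[mask]])[:, None]
            js = (1.0 + jitter_s[cells[mask]])[:, None]
            coup = scale * (jn * (delta @ C_N) + js * (delta @ C_S))
        else:
            a_n, a_s = _CHANNEL_GATE[group]
            coup = delta @ (a_n * C_N + a_s * C_S)
        signal = base * group_modulation(config, group, grid) * (1.0 + coup)
        if group == "NS*SS" and config.drift_amp_nsss > 0 and config.drift_bumps_nsss > 0:
            # combined-stress spectral drift: per-sample random mid-width
            # bumps, centered across the cohort so group means are
            # untouched; they corrupt within-group feature extraction
            n_g = int(mask.sum())
            k = config.drift_bumps_nsss
            centers = rng.uniform(grid[0], grid[-1], (n_g, k))
            widths = rng.uniform(8.0, 25.0, (n_g, k))
            amps = rng.normal(0.0, config.drift_amp_nsss, (n_g, k))
            drift = np.zeros((n_g, grid.size))
            for j in range(k):
                drift += amps[:, j, None] * np.exp(
                    -0.5 * ((grid[None, :] - centers[:, j, None])
                            / widths[:, j, None]) ** 2)
            drift -= drift.mean(axis=0)
            signal = signal + drift
        c = cells[mask]
        values[mask] = (gains[c, None] * signal
                        + offsets[c, None] + band_noise[c])
    np.clip(values, 1e-4, 1.2, out=values)
    return SpectraMatrix(list(design["sample_id"]), grid.copy(), values,
                         meta={"tag": "R", "seed": int(seed)})


def ground_truth_bands(config: SimConfig, parameter: str,
                       stress: str = "NS") -> list:
    """The exact coupling windows used by :func:`generate_spectra` for a
    parameter under a given stress group (for selector-recovery tests)."""
    if parameter not in PARAMETERS:
        raise ConfigurationError(f"unknown parameter {parameter!r}")
    if stress not in GROUPS:
        raise ConfigurationError(f"unknown group label {stress!r}")
    chan = config.coupling_map.get(parameter)
    if chan is None:
        return []
    # the channels a stress amplifies, i.e. where its dominant spectral
    # features of the parameter sit
    dominant = {"NS": ("N",), "SS": ("S",),
                "NS*SS": ("N", "S"), "CK": ("N", "S")}[stress]
    windows = []
    for key in dominant:
        if chan.get(f"amp_{key}", 0.0):
            windows += [tuple(w) for w in chan.get(key, [])]
    return windows


def simulate(config: SimConfig, seed: int | None = None):
    """Generate (design, physio, spectra) in one call."""
    if seed is None:
        seed = config.seed
    design = generate_design(config)
    physio = generate_physio(design, config, seed)
    spectra = generate_spectra(physio, design, config, seed)
    return design, physio, spectra
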