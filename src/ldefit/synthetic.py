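"""Synthetic damped-linear-oscillator panels.

Generates multivariate, multi-person daily-diary-style panels from a damped
linear oscillator (DLO)

    f''(t) = eta * f(t) + zeta * f'(t)

with person-specific equilibria and per-series measurement noise, so that the
whole embedding -> FIML -> selection pipeline can be exercised without any
external data.  The latent trajectory is the exact closed-form homogeneous
solution; an optional Euler-Maruyama process-noise variant is provided for
robustness experiments only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DLOParams",
    "SimConfig",
    "LongPanel",
    "NonOscillatingError",
    "dlo_trajectory",
    "simulate_panel",
    "add_missingness",
]


class NonOscillatingError(ValueError):
    """Raised when (eta, zeta) do not describe an underdamped oscillator."""


@dataclass(frozen=True)
class DLOParams:
    """Frequency and damping parameters of a damped linear oscillator.

    Parameters
    ----------
    eta : float
        Frequency parameter (1/time^2).  Negative for oscillation.
    zeta : float
        Damping parameter (1/time).  Negative values damp the amplitude.
    """

    eta: float
    zeta: float

    @property
    def discriminant(self) -> float:
        """-eta - zeta^2/4; positive iff the system is underdamped."""
        return -self.eta - self.zeta**2 / 4.0

    @property
    def is_underdamped(self) -> bool:
        return self.discriminant > 0.0

    def require_underdamped(self) -> None:
        if not self.is_underdamped:
            raise NonOscillatingError(
                f"parameters eta={self.eta}, zeta={self.zeta} are not "
                f"underdamped: discriminant -eta - zeta^2/4 = "
                f"{self.discriminant:.6g} <= 0"
            )


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated multi-person, multi-series diary panel.

    Defaults emulate a 56-day daily diary of perceived stress in N=41
    older adults: a slow oscillation (wavelength 65 days), mild damping,
    three indicator series of one latent process, person-varying
    equilibria on a stress-composite scale, and ~90% within-person
    indicator reliability.
    """

    params: DLOParams = DLOParams(eta=-0.00997, zeta=-0.05)
    n_persons: int = 41
    n_occasions: int = 56
    n_series: int = 3
    series_loadings: tuple[float, ...] = (1.0, 0.9, 1.1)
    equilibrium_mean: float = 15.0
    equilibrium_sd: float = 5.0
    init_pos_sd: float = 3.0
    init_vel_sd: float = 0.3
    noise_sd: tuple[float, ...] = (1.0, 1.0, 1.0)
    missing_rate: float = 0.05
    seed: int = 0
    delta_t: float = 1.0
    process_noise_sd: float = 0.0  # robustness experiments only
    allow_non_oscillating: bool = False

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_occasions < 1 or self.n_series < 1:
            raise ValueError("n_persons, n_occasions, n_series must be >= 1")
        if len(self.series_loadings) != self.n_series:
            raise ValueError("series_loadings length must equal n_series")
        if len(self.noise_sd) != self.n_series:
            raise ValueError("noise_sd length must equal n_series")
        if self.series_loadings[0] != 1.0:
            raise ValueError("first series loading is fixed to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not self.allow_non_oscillating:
            self.params.require_underdamped()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["params"] = DLOParams(**d["params"])
        d["series_loadings"] = tuple(d["series_loadings"])
        d["noise_sd"] = tuple(d["noise_sd"])
        return cls(**d)


class LongPanel:
    """Long-format person-by-occasion observations of P indicator series.

    Backed by a DataFrame with columns ``person_id``, ``occasion`` and one
    column per series.  Missing values are NaN, never a sentinel number.
    Occasion indices are unique and sorted within each person.
    """

    def __init__(self, data: pd.DataFrame, series_names: Sequence[str]):
        required = ["person_id", "occasion"] + list(series_names)
        missing = [c for c in required if c not in data.columns]
        if missing:
            raise ValueError(f"panel is missing columns {missing}")
        df = data.loc[:, required].copy()
        df["occasion"] = df["occasion"].astype(int)
        df = df.sort_values(["person_id", "occasion"], kind="mergesort")
        dup = df.duplicated(["person_id", "occasion"])
        if dup.any():
            raise ValueError("duplicate (person, occasion) records in panel")
        self.data = df.reset_index(drop=True)
        self.series_names = list(series_names)

    @property
    def persons(self) -> list:
        return list(pd.unique(self.data["person_id"]))

    @property
    def n_series(self) -> int:
        return len(self.series_names)

    def values_for(self, person) -> pd.DataFrame:
        sub = self.data[self.data["person_id"] == person]
        if sub.empty:
            raise KeyError(f"unknown person {person!r}")
        return sub

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LongPanel":
        df = pd.read_csv(path)
        series = [c for c in df.columns if c not in ("person_id", "occasion")]
        if not series:
            raise ValueError("panel CSV has no series columns")
        return cls(df, series)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LongPanel)
            and self.series_names == other.series_names
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:
        return (
            f"LongPanel({len(self.persons)} persons, "
            f"{len(self.data)} records, series={self.series_names})"
        )


def dlo_trajectory(
    params: DLOParams,
    x0: float,
    v0: float,
    times: Sequence[float],
) -> np.ndarray:
    """Exact homogeneous solution of the damped linear oscillator.

    x(t) = exp((zeta/2) t) [A cos(omega t) + B sin(omega t)] with
    omega = sqrt(-eta - zeta^2/4), A = x0, B = (v0 - (zeta/2) x0) / omega.
    """
    params.require_underdamped()
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    omega = np.sqrt(params.discriminant)
    a = x0
    b = (v0 - params.zeta / 2.0 * x0) / omega
    return np.exp(params.zeta / 2.0 * t) * (a * np.cos(omega * t) + b * np.sin(omega * t))


def _dlo_em_path(
    params: DLOParams, x0: float, v0: float, t_grid: np.ndarray,
    sigma: float, rng: np.random.Generator, substeps: int = 100,
) -> np.ndarray:
    """Euler-Maruyama path of the DLO with process noise on the acceleration."""
    out = np.empty(t_grid.size)
    x, v = x0, v0
    out[0] = x
    for k in range(1, t_grid.size):
        h = (t_grid[k] - t_grid[k - 1]) / substeps
        for _ in range(substeps):
            a = params.eta * x + params.zeta * v
            x = x + v * h
            v = v + a * h + sigma * np.sqrt(h) * rng.standard_normal()
        out[k] = x
    return out


def simulate_panel(config: SimConfig) -> LongPanel:
    """Draw a LongPanel from the damped-oscillator measurement model.

    For each person j: equilibrium m_j ~ N(equilibrium_mean, equilibrium_sd^2),
    initial position/velocity ~ N(0, init_*_sd^2), latent f_j(t) from the
    closed-form trajectory at t = 0..T-1 (times delta_t); observed series s is
    loadings[s] * (m_j + f_j(t)) + N(0, noise_sd[s]^2).  Cells are then
    deleted completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    t_grid = np.arange(config.n_occasions, dtype=float) * config.delta_t
    loadings = np.asarray(config.series_loadings, dtype=float)
    noise_sd = np.asarray(config.noise_sd, dtype=float)

    frames = []
    for j in range(config.n_persons):
        m_j = config.equilibrium_mean + config.equilibrium_sd * rng.standard_normal()
        x0 = config.init_pos_sd * rng.standard_normal()
        v0 = config.init_vel_sd * rng.standard_normal()
        if config.process_noise_sd > 0:
            f = _dlo_em_path(config.params, x0, v0, t_grid,
                             config.process_noise_sd, rng)
        else:
            f = dlo_trajectory(config.params, x0, v0, t_grid)
        latent = m_j + f  # (T,)
        obs = latent[:, None] * loadings[None, :]
        obs = obs + noise_sd[None, :] * rng.standard_normal(obs.shape)
        frame = pd.DataFrame(obs, columns=_series_names(config.n_series))
        frame.insert(0, "occasion", np.arange(config.n_occasions))
        frame.insert(0, "person_id", j + 1)
        frames.append(frame)

    panel = LongPanel(pd.concat(frames, ignore_index=True),
                      _series_names(config.n_series))
    if config.missing_rate > 0:
        # deterministic sub-seed so the whole panel is a pure function of seed
        panel = add_missingness(panel, config.missing_rate,
                                seed=(config.seed * 7919 + 13) % (2**31))
    return panel


def add_missingness(panel: LongPanel, rate: float, seed: int) -> LongPanel:
    """Delete each observed cell independently with probability ``rate``.

    The person/occasion skeleton is left untouched; only series cells become
    NaN.  MCAR by construction, which is sufficient for testing estimation
    under the missing-at-random assumption.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must be in [0, 1), got {rate}")
    df = panel.data.copy()
    if rate > 0:
        rng = np.random.default_rng(seed)
        vals = df[panel.series_names].to_numpy(dtype=float)
        mask = rng.random(vals.shape) < rate
        vals[mask] = np.nan
        df[panel.series_names] = vals
    return LongPanel(df, panel.series_names)


def _series_names(p: int) -> list[str]:
    return [f"series_{s + 1}" for s in range(p)]
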