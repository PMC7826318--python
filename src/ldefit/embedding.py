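"""Time-delay embedding of multi-person, multi-series panels.

Each person's series is cut into overlapping length-D windows (lag tau
between adjacent window columns) and the windows are row-bound; the per-series
embedded matrices are then column-bound into one wide matrix with D*P columns
(series-major blocks).  Windows never span two persons.  Missing cells are
kept as NaN for full-information likelihood downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .synthetic import LongPanel

__all__ = ["TDEMatrix", "embed_series", "embed_panel", "nyquist_check", "NyquistResult"]

logger = logging.getLogger(__name__)


@dataclass
class TDEMatrix:
    """Row-bound time-delay-embedded data matrix.

    ``values`` has one row per window and D*P columns ordered series-major:
    all D lags of the first series, then of the second, and so on.
    ``row_person[i]`` is the person whose series produced row i.
    """

    values: np.ndarray
    row_person: np.ndarray
    D: int
    tau: int
    delta_t: float
    series_names: list[str]

    @property
    def n_series(self) -> int:
        return len(self.series_names)

    @property
    def column_names(self) -> list[str]:
        return [f"{s}_lag{i}" for s in self.series_names for i in range(self.D)]

    @property
    def persons(self) -> list:
        return list(pd.unique(self.row_person))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        df.insert(0, "person_id", self.row_person)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, tau: int = 1, delta_t: float = 1.0) -> "TDEMatrix":
        df = pd.read_csv(path)
        lag_cols = [c for c in df.columns if "_lag" in c]
        series, seen = [], set()
        d = 0
        for c in lag_cols:
            name, lag = c.rsplit("_lag", 1)
            d = max(d, int(lag) + 1)
            if name not in seen:
                seen.add(name)
                series.append(name)
        return cls(
            values=df[lag_cols].to_numpy(dtype=float),
            row_person=df["person_id"].to_numpy(),
            D=d, tau=tau, delta_t=delta_t, series_names=series,
        )


def embed_series(x: Sequence[float], D: int, tau: int = 1) -> np.ndarray:
    """Overlapping windows of ``x``: row i = (x_i, x_{i+tau}, ..., x_{i+(D-1)tau}).

    Rows containing NaN are retained.  A series shorter than (D-1)*tau + 1
    yields zero rows (logged, not an error).
    """
    if D < 1 or tau < 1:
        raise ValueError("D and tau must be >= 1")
    x = np.asarray(x, dtype=float)
    n_rows = x.size - (D - 1) * tau
    if n_rows <= 0:
        logger.warning(
            "series of length %d too short for D=%d, tau=%d: zero rows",
            x.size, D, tau,
        )
        return np.empty((0, D))
    idx = np.arange(n_rows)[:, None] + tau * np.arange(D)[None, :]
    return x[idx]


def embed_panel(panel: LongPanel, D: int, tau: int = 1,
                delta_t: float = 1.0) -> TDEMatrix:
    """Embed every person's series and bind them into one TDEMatrix.

    Windows are formed on each person's occasion grid (min..max occasion);
    skipped occasions enter as missing cells rather than silently compressing
    time.  Per person the row count is max(0, span - (D-1)*tau) where span is
    the person's contiguous occasion span.
    """
    blocks, owners = [], []
    for person in panel.persons:
        sub = panel.values_for(person)
        occ = sub["occasion"].to_numpy()
        span = int(occ.max() - occ.min() + 1)
        # place observed occasions on the full grid, NaN where skipped
        grid = np.full((span, panel.n_series), np.nan)
        grid[occ - occ.min(), :] = sub[panel.series_names].to_numpy(dtype=float)
        per_series = [embed_series(grid[:, s], D, tau)
                      for s in range(panel.n_series)]
        block = np.hstack(per_series)
        if block.shape[0]:
            blocks.append(block)
            owners.extend([person] * block.shape[0])
    if blocks:
        values = np.vstack(blocks)
    else:
        values = np.empty((0, D * panel.n_series))
    return TDEMatrix(
        values=values,
        row_person=np.asarray(owners),
        D=D, tau=tau, delta_t=delta_t,
        series_names=list(panel.series_names),
    )


class NyquistResult(NamedTuple):
    passed: bool
    ratio: float  # elapsed window span / wavelength


def nyquist_check(D: int, tau: int, delta_t: float,
                  wavelength: float) -> NyquistResult:
    """Check that the window's elapsed time stays below the wavelength.

    The time elapsed between the first and last window columns,
    (D-1)*tau*delta_t, must be strictly less than the oscillation wavelength
    for the dynamics to be identifiable.  Returns the span/wavelength ratio;
    failure is a warning condition, not an exception, since the wavelength is
    usually known only after fitting.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    span = (D - 1) * tau * delta_t
    ratio = span / wavelength
    passed = span < wavelength
    if not passed:
        logger.warning(
            "embedding window spans %.3g time units >= wavelength %.3g",
            span, wavelength,
        )
    return NyquistResult(passed=passed, ratio=ratio)
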