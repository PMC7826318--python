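"""Embedding-dimension selection and wavelength computation.

The embedding dimension D controls how much of the oscillation each window
sees; the frequency parameter eta is typically unstable at small D and
settles ("stabilizes") once D is large enough.  ``scan_embedding`` refits
the model independently at each D, and ``detect_elbow`` turns the visual
stabilization heuristic into an explicit rule.  ``wavelength`` converts
(eta, zeta) into the oscillation period — the substantively meaningful
quantity, and one that is very sensitive to small changes in either
parameter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .embedding import embed_panel, nyquist_check
from .model import FitOptions, LDEModel
from .synthetic import LongPanel, NonOscillatingError

__all__ = ["ScanResult", "scan_embedding", "detect_elbow", "wavelength"]

logger = logging.getLogger(__name__)


def wavelength(eta: float, zeta: float, delta_t: float = 1.0) -> float:
    """Oscillation wavelength 2*pi*delta_t / sqrt(-eta - zeta^2/4).

    The period of the damped linear oscillator f'' = eta f + zeta f'; defined
    only in the underdamped region -eta - zeta^2/4 > 0.
    """
    disc = -eta - zeta**2 / 4.0
    if disc <= 0:
        raise NonOscillatingError(
            f"wavelength undefined: -eta - zeta^2/4 = {disc:.6g} <= 0 "
            f"(eta={eta}, zeta={zeta})"
        )
    return 2.0 * math.pi * delta_t / math.sqrt(disc)


def detect_elbow(eta_by_d: Sequence[tuple[int, float]],
                 rule: str = "relative-change",
                 threshold: float = 0.10):
    """Pick the D at which the eta-by-D curve stabilizes (the 'elbow').

    relative-change (default): the smallest D whose eta all subsequent D'
    reproduce within ``threshold`` relative, i.e. |eta(D') - eta(D)| /
    |eta(D)| < threshold for every larger D' in range.  Requires the
    stabilization to persist, guarding against transient plateaus.

    max-curvature: the D maximizing the discrete second difference of eta.

    Both are algorithmic interpretations of a heuristic that is applied
    visually in practice.  Returns None when no D qualifies.
    """
    pairs = sorted(eta_by_d)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (D, eta) pairs")
    ds = [d for d, _ in pairs]
    etas = np.array([e for _, e in pairs], dtype=float)
    if rule == "relative-change":
        for i, d in enumerate(ds):
            ref = etas[i]
            if ref == 0:
                continue
            later = etas[i + 1:]
            if later.size == 0:
                return None  # stabilization cannot be confirmed at the last D
            if np.all(np.abs(later - ref) / abs(ref) < threshold):
                return d
        return None
    if rule == "max-curvature":
        curv = np.abs(np.diff(etas, 2))
        if curv.size == 0 or not np.isfinite(curv).any():
            return None
        return ds[int(np.nanargmax(curv)) + 1]
    raise ValueError(f"unknown elbow rule {rule!r}")


@dataclass
class ScanResult:
    """Per-dimension fit summaries plus the selected elbow dimension."""

    rows: list[dict] = field(default_factory=list)
    elbow_D: int | None = None
    rule: str = "relative-change"
    threshold: float = 0.10
    order: int = 2

    def to_frame(self) -> pd.DataFrame:
        cols = ["D", "eta", "eta_se", "zeta", "zeta_se", "wavelength",
                "minus2ll", "converged", "nyquist_ok", "nyquist_ratio"]
        return pd.DataFrame(self.rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None):
        """Three panels by embedding dimension: eta +/- SE, zeta, wavelength."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.to_frame()
        fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
        axes[0].errorbar(df["D"], df["eta"], yerr=df["eta_se"], marker="o")
        axes[0].set_ylabel(r"$\eta$ (frequency)")
        axes[1].errorbar(df["D"], df["zeta"], yerr=df["zeta_se"], marker="o")
        axes[1].set_ylabel(r"$\zeta$ (damping)")
        axes[2].plot(df["D"], df["wavelength"], marker="o")
        axes[2].set_ylabel("wavelength (time units)")
        for ax in axes:
            ax.set_xlabel("embedding dimension D")
        if self.elbow_D is not None:
            for ax in axes:
                ax.axvline(self.elbow_D, color="grey", ls="--", lw=1)
            axes[0].annotate(f"elbow D={self.elbow_D}",
                             xy=(self.elbow_D, df["eta"].iloc[-1]),
                             fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig


def scan_embedding(panel: LongPanel, order: int,
                   d_range: Iterable[int],
                   tau: int = 1, delta_t: float = 1.0,
                   options: FitOptions | None = None,
                   rule: str = "relative-change",
                   threshold: float = 0.10,
                   warm_start: bool = False) -> ScanResult:
    """Fit the model independently at each embedding dimension in d_range.

    By default estimates are never reused across dimensions; each D gets its
    own data-driven start (``warm_start=True`` seeds each fit with the
    previous dimension's estimates instead).  Dimensions below the
    identification limit D >= q are skipped with a logged reason.  The elbow
    rule runs on the converged eta sequence when at least three dimensions
    are available.
    """
    options = options or FitOptions()
    result = ScanResult(rule=rule, threshold=threshold, order=order)
    q = order + 1
    prev_params = None
    for d in sorted(set(int(d) for d in d_range)):
        if d < q:
            logger.warning("skipping D=%d: below identification limit q=%d",
                           d, q)
            continue
        tde = embed_panel(panel, d, tau=tau, delta_t=delta_t)
        model = LDEModel(tde, order=order)
        start = None
        if warm_start and prev_params is not None:
            # parameter layout is D-independent, so estimates carry over
            start = model._as_paramvector(prev_params.values)
        res = model.fit(options, start=start)
        if warm_start and res.converged:
            prev_params = res.params
        try:
            lam = res.wavelength()
        except NonOscillatingError:
            lam = float("nan")
        tbl = res.param_table
        if np.isfinite(lam):
            nyq = nyquist_check(d, tau, delta_t, lam)
            nyq_ok, nyq_ratio = nyq.passed, nyq.ratio
        else:
            nyq_ok, nyq_ratio = None, float("nan")
        result.rows.append({
            "D": d,
            "eta": res.eta, "eta_se": tbl.loc["eta", "se"],
            "zeta": res.zeta, "zeta_se": tbl.loc["zeta", "se"],
            "wavelength": lam,
            "minus2ll": res.minus2ll,
            "converged": res.converged,
            "nyquist_ok": nyq_ok, "nyquist_ratio": nyq_ratio,
        })
    usable = [(r["D"], r["eta"]) for r in result.rows if r["converged"]]
    if len(usable) >= 3:
        result.elbow_D = detect_elbow(usable, rule=rule, threshold=threshold)
    return result
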