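"""Factor scores for the latent derivatives and phase-plane vector fields.

After the model parameters are estimated, per-row scores for (f, f', f''
[, f''', f'''']) can be computed by the regression method (weights by the
latent covariance, hence shrunken but minimum-MSE) or the Bartlett method
(weights by the unique variances only, conditionally unbiased: B L = I).
Binning the (f, f') scores and averaging (f', f'') within bins yields an
empirical phase-plane vector field of the estimated dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .embedding import TDEMatrix
from .structure import LDESpec, ParamVector, build_loading_matrix, latent_covariance

__all__ = ["ScoreMatrix", "VectorField", "factor_scores", "vector_field",
           "plot_vector_field"]

logger = logging.getLogger(__name__)

_DERIV_NAMES = ["f", "df", "d2f", "d3f", "d4f"]


@dataclass
class ScoreMatrix:
    """Per-row latent derivative scores with the method that produced them."""

    scores: pd.DataFrame  # columns: person_id, f, df, d2f[, d3f, d4f]
    method: str
    skipped_rows: int = 0

    def to_csv(self, path) -> None:
        self.scores.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.scores)


def factor_scores(fit, spec: LDESpec, data: TDEMatrix,
                  method: str = "regression") -> ScoreMatrix:
    """Score every embedded row for the latent derivatives.

    regression: F = Psi L' Sigma^-1 (w - mu_j); bartlett:
    F = (L' Theta^-1 L)^-1 L' Theta^-1 (w - mu_j).  Rows with missing cells
    are scored from the observed sub-pattern; rows with fewer observed cells
    than latent factors are skipped (logged).  Centering uses the fitted
    person equilibria, not person sample means.
    """
    if method not in ("regression", "bartlett"):
        raise ValueError(f"unknown scoring method {method!r}")
    theta = fit.params if hasattr(fit, "params") else fit
    if not isinstance(theta, ParamVector):
        raise TypeError("fit must be an LDEResults or a ParamVector")
    if hasattr(fit, "converged") and not fit.converged:
        raise ValueError("factor scores require a converged fit")

    q = spec.q
    loading = build_loading_matrix(spec.D, spec.order, spec.delta_t,
                                   theta.series_loadings)
    l0 = loading[:, 0]
    psi = latent_covariance(spec, theta)
    theta_diag = np.repeat(theta.unique_variances, spec.D)

    vals = data.values
    mask = np.isfinite(vals)
    means = np.array([theta.mean_for(p) for p in data.row_person])

    # one weight matrix per missingness pattern
    weights: dict[bytes, np.ndarray | None] = {}
    rows_out, persons_out, skipped = [], [], 0
    for i in range(vals.shape[0]):
        key = mask[i].tobytes()
        if key not in weights:
            cols = np.flatnonzero(mask[i])
            if cols.size < q:
                weights[key] = None
            else:
                lsub = loading[cols]
                try:
                    if method == "regression":
                        sigma_sub = (lsub @ psi @ lsub.T
                                     + np.diag(theta_diag[cols]))
                        weights[key] = psi @ lsub.T @ linalg.inv(sigma_sub)
                    else:
                        li = lsub / theta_diag[cols][:, None]
                        weights[key] = linalg.solve(lsub.T @ li, li.T)
                except linalg.LinAlgError as err:
                    raise linalg.LinAlgError(
                        f"singular weighting matrix for missingness pattern "
                        f"with observed columns {cols.tolist()}: {err}"
                    ) from err
        w_mat = weights[key]
        if w_mat is None:
            skipped += 1
            continue
        cols = np.flatnonzero(mask[i])
        centered = vals[i, cols] - means[i] * l0[cols]
        rows_out.append(w_mat @ centered)
        persons_out.append(data.row_person[i])
    if skipped:
        logger.info("skipped %d rows with fewer than %d observed cells",
                    skipped, q)
    frame = pd.DataFrame(rows_out, columns=_DERIV_NAMES[:q])
    frame.insert(0, "person_id", persons_out)
    return ScoreMatrix(scores=frame, method=method, skipped_rows=skipped)


@dataclass
class VectorField:
    """Binned phase-plane flow: mean (f', f'') arrow per occupied (f, f') bin."""

    f_centers: np.ndarray
    df_centers: np.ndarray
    arrows: np.ndarray      # (nf, ndf, 2): mean (df, d2f); NaN when sparse
    counts: np.ndarray      # (nf, ndf)
    min_count: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for i, fc in enumerate(self.f_centers):
            for j, dc in enumerate(self.df_centers):
                if self.counts[i, j] >= self.min_count:
                    recs.append({
                        "f": fc, "df": dc,
                        "arrow_df": self.arrows[i, j, 0],
                        "arrow_d2f": self.arrows[i, j, 1],
                        "count": int(self.counts[i, j]),
                    })
        return pd.DataFrame(recs,
                            columns=["f", "df", "arrow_df", "arrow_d2f",
                                     "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def vector_field(scores: ScoreMatrix, n_bins: int = 10,
                 min_count: int = 5,
                 coverage: float = 0.95) -> VectorField:
    """Bin the (f, f') scores and average (f', f'') within each bin.

    The grid spans the central ``coverage`` quantile range of each axis.
    Arrows are reported only for bins holding at least ``min_count`` rows.
    An empty score matrix yields an empty field.
    """
    df = scores.scores
    if df.empty:
        return VectorField(np.array([]), np.array([]),
                           np.empty((0, 0, 2)), np.empty((0, 0), dtype=int),
                           min_count)
    for col in ("f", "df", "d2f"):
        if col not in df.columns:
            raise ValueError(f"scores lack required column {col!r}")
    lo = (1.0 - coverage) / 2.0
    f_edges = np.linspace(df["f"].quantile(lo), df["f"].quantile(1 - lo),
                          n_bins + 1)
    d_edges = np.linspace(df["df"].quantile(lo), df["df"].quantile(1 - lo),
                          n_bins + 1)
    fi = np.clip(np.searchsorted(f_edges, df["f"], side="right") - 1,
                 0, n_bins - 1)
    di = np.clip(np.searchsorted(d_edges, df["df"], side="right") - 1,
                 0, n_bins - 1)
    inside = ((df["f"] >= f_edges[0]) & (df["f"] <= f_edges[-1])
              & (df["df"] >= d_edges[0]) & (df["df"] <= d_edges[-1])).to_numpy()
    counts = np.zeros((n_bins, n_bins), dtype=int)
    sums = np.zeros((n_bins, n_bins, 2))
    np.add.at(counts, (fi[inside], di[inside]), 1)
    np.add.at(sums, (fi[inside], di[inside]),
              df.loc[inside, ["df", "d2f"]].to_numpy())
    arrows = np.full((n_bins, n_bins, 2), np.nan)
    occ = counts >= min_count
    arrows[occ] = sums[occ] / counts[occ][:, None]
    centers = lambda e: (e[:-1] + e[1:]) / 2.0  # noqa: E731
    return VectorField(centers(f_edges), centers(d_edges), arrows, counts,
                       min_count)


def plot_vector_field(fields, labels=None, path=None):
    """Quiver plot(s) of one or more vector fields in the (f, f') plane."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(fields, VectorField):
        fields = [fields]
    labels = labels or [f"field {i + 1}" for i in range(len(fields))]
    fig, axes = plt.subplots(1, len(fields),
                             figsize=(4.2 * len(fields), 3.8), squeeze=False)
    for ax, fld, lab in zip(axes[0], fields, labels):
        tab = fld.to_frame()
        if not tab.empty:
            ax.quiver(tab["f"], tab["df"], tab["arrow_df"], tab["arrow_d2f"],
                      angles="xy")
        ax.set_xlabel("f (displacement from equilibrium)")
        ax.set_ylabel("f' (velocity)")
        ax.set_title(lab)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
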