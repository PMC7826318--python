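"""Model structure for second- and constrained fourth-order latent ODE models.

A latent differential equation (LDE) model treats a variable and its time
derivatives as latent factors whose loadings on a time-delay-embedded data
matrix are a fixed Taylor basis.  The second-order model (SOLDE) carries
latents (f, f', f''); the constrained fourth-order model (FOLDE) adds f''' and
f'''' and regresses each higher derivative on the two below it with the same
coefficients eta (frequency) and zeta (damping), giving three structurally
tied copies of the damped-oscillator equation

    f'' = eta f + zeta f'.

This module builds the loading matrix, the structural regression matrix, the
model-implied covariance Sigma = L Psi L' + Theta and per-person mean vectors,
and defines the free-parameter layout with its unconstrained transform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDESpec",
    "ParamVector",
    "build_loading_matrix",
    "build_structural",
    "implied_covariance",
    "implied_row_mean",
    "count_free_parameters",
]


def lag_offsets(D: int, delta_t: float) -> np.ndarray:
    """Centered time offsets (i - (D-1)/2) * delta_t for lags i = 0..D-1.

    For odd D these are integer multiples of delta_t (e.g. -2..2 at D=5);
    even D extends the same pattern symmetrically to half-integer offsets,
    keeping the zeroth-derivative reference at the window midpoint.
    """
    return (np.arange(D) - (D - 1) / 2.0) * delta_t


def build_loading_matrix(D: int, order: int, delta_t: float,
                         series_loadings) -> np.ndarray:
    """Fixed Taylor-basis loading matrix, (D*P) x (order+1).

    Entry for series s, lag i, derivative k is l_s * o_i^k / k! with centered
    offset o_i.  At D=5, delta_t=1 this reproduces the familiar
    (1, -2, 2 | ...) SOLDE block and its quartic FOLDE extension.
    """
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    q = order + 1
    if D < q:
        raise ValueError(
            f"embedding dimension D={D} < number of latent derivatives q={q}: "
            "model not identified"
        )
    loadings = np.asarray(series_loadings, dtype=float)
    if loadings[0] != 1.0:
        raise ValueError("first series loading must be fixed to 1")
    offsets = lag_offsets(D, delta_t)
    basis = np.column_stack(
        [offsets**k / math.factorial(k) for k in range(q)]
    )  # D x q
    return np.vstack([l * basis for l in loadings])  # (D*P) x q


def build_structural(order: int, eta: float, zeta: float) -> np.ndarray:
    """Latent regression matrix A (q x q), strictly lower triangular.

    Second derivative on (f, f'); for order 4 also third on (f', f'') and
    fourth on (f'', f'''), every pair constrained to (eta, zeta).
    """
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    q = order + 1
    a = np.zeros((q, q))
    for k in range(2, q):
        a[k, k - 2] = eta
        a[k, k - 1] = zeta
    return a


@dataclass(frozen=True)
class LDESpec:
    """Structure of one SOLDE (order 2) or FOLDE (order 4) model.

    Fixes the embedding dimension D, series count P, occasion spacing
    delta_t and the person roster; induces the free-parameter layout:

    eta, zeta, l_2..l_P, {V(f), V(f'), Cov(f, f')}, structural residual
    variance(s), unique variances u_1..u_P, person equilibria m_j.
    """

    order: int
    D: int
    P: int
    delta_t: float
    person_ids: tuple
    series_names: tuple = ()

    def __post_init__(self):
        if self.order not in (2, 4):
            raise ValueError("order must be 2 or 4")
        if self.D < self.q:
            raise ValueError(
                f"D={self.D} < q={self.q}: model not identified"
            )
        if self.P < 1 or len(self.person_ids) < 1:
            raise ValueError("need at least one series and one person")
        if not self.series_names:
            object.__setattr__(
                self, "series_names",
                tuple(f"series_{s+1}" for s in range(self.P)),
            )
        if len(self.series_names) != self.P:
            raise ValueError("series_names length must equal P")

    @property
    def q(self) -> int:
        """Number of latent derivative factors (order + 1)."""
        return self.order + 1

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def n_resid(self) -> int:
        """Structural residual variances: 1 (SOLDE) or 3 (FOLDE)."""
        return 1 if self.order == 2 else 3

    @property
    def n_structural(self) -> int:
        """Free parameters excluding the person equilibrium means."""
        return 2 + (self.P - 1) + 3 + self.n_resid + self.P

    @property
    def param_names(self) -> list[str]:
        names = ["eta", "zeta"]
        names += [f"l_{s+1}" for s in range(1, self.P)]
        names += ["V_f", "V_df", "C_f_df"]
        names += [f"V_e_d{k}" for k in range(2, self.order + 1)]
        names += [f"u_{s}" for s in self.series_names]
        names += [f"m_{p}" for p in self.person_ids]
        return names

    def to_json(self) -> str:
        return json.dumps({
            "order": self.order, "D": self.D, "P": self.P,
            "delta_t": self.delta_t,
            "person_ids": list(self.person_ids),
            "series_names": list(self.series_names),
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LDESpec":
        d = json.loads(text)
        return cls(order=d["order"], D=d["D"], P=d["P"],
                   delta_t=d["delta_t"],
                   person_ids=tuple(d["person_ids"]),
                   series_names=tuple(d["series_names"]))


def count_free_parameters(spec: LDESpec) -> int:
    """2 (eta, zeta) + (P-1) loadings + 3 exogenous (co)variances +
    1 or 3 structural residual variances + P unique variances + N means."""
    return spec.n_structural + spec.n_persons


class ParamVector:
    """Named flat parameter vector in the LDESpec layout, natural scale.

    Provides lossless round-trips to the unconstrained optimization scale:
    variances are log-transformed and the exogenous 2x2 block {V(f), V(f'),
    Cov} goes through a log-Cholesky map so it stays positive definite.
    """

    def __init__(self, spec: LDESpec, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.size != count_free_parameters(spec):
            raise ValueError(
                f"expected {count_free_parameters(spec)} parameters, "
                f"got {values.size}"
            )
        self.spec = spec
        self.values = values
        self._index = {n: i for i, n in enumerate(spec.param_names)}

    def __getitem__(self, name: str) -> float:
        return self.values[self._index[name]]

    @property
    def eta(self) -> float:
        return self.values[0]

    @property
    def zeta(self) -> float:
        return self.values[1]

    @property
    def series_loadings(self) -> np.ndarray:
        """(1, l_2, ..., l_P)."""
        return np.concatenate([[1.0], self.values[2:2 + self.spec.P - 1]])

    @property
    def phi(self) -> np.ndarray:
        """Exogenous covariance of (f, f')."""
        i = 2 + self.spec.P - 1
        vf, vdf, c = self.values[i:i + 3]
        return np.array([[vf, c], [c, vdf]])

    @property
    def resid_variances(self) -> np.ndarray:
        i = 2 + self.spec.P - 1 + 3
        return self.values[i:i + self.spec.n_resid]

    @property
    def unique_variances(self) -> np.ndarray:
        i = 2 + self.spec.P - 1 + 3 + self.spec.n_resid
        return self.values[i:i + self.spec.P]

    @property
    def person_means(self) -> np.ndarray:
        return self.values[self.spec.n_structural:]

    def mean_for(self, person) -> float:
        try:
            j = self.spec.person_ids.index(person)
        except ValueError:
            raise KeyError(f"unknown person {person!r}") from None
        return self.person_means[j]

    # --- unconstrained transform (structural block only; means are linear) ---

    def to_transformed(self) -> np.ndarray:
        s = self.spec
        x = self.values[:s.n_structural].copy()
        i = 2 + s.P - 1
        vf, vdf, c = x[i], x[i + 1], x[i + 2]
        c11 = math.sqrt(vf)
        c21 = c / c11
        c22sq = vdf - c21**2
        if c22sq <= 0:
            raise ValueError("exogenous covariance block not positive definite")
        x[i], x[i + 1], x[i + 2] = math.log(c11), c21, math.log(math.sqrt(c22sq))
        j = i + 3
        x[j:] = np.log(x[j:])
        return np.concatenate([x, self.person_means])

    @classmethod
    def from_transformed(cls, spec: LDESpec, x: np.ndarray) -> "ParamVector":
        x = np.asarray(x, dtype=float)
        v = x.copy()
        i = 2 + spec.P - 1
        c11, c21, c22 = math.exp(x[i]), x[i + 1], math.exp(x[i + 2])
        v[i] = c11**2
        v[i + 1] = c21**2 + c22**2
        v[i + 2] = c11 * c21
        j = i + 3
        v[j:spec.n_structural] = np.exp(x[j:spec.n_structural])
        return cls(spec, v)

    def to_series(self):
        import pandas as pd
        return pd.Series(self.values, index=self.spec.param_names)


def _phi_star(spec: LDESpec, theta: ParamVector) -> np.ndarray:
    """Exogenous covariance on (f, f') plus residual variances on the
    regressed derivatives, assembled into the q x q latent input covariance."""
    q = spec.q
    phi = theta.phi
    if np.linalg.eigvalsh(phi).min() < -1e-10 * max(1.0, abs(phi).max()):
        raise ValueError("exogenous (f, f') covariance is not PSD")
    full = np.zeros((q, q))
    full[:2, :2] = phi
    full[range(2, q), range(2, q)] = theta.resid_variances
    return full


def implied_covariance(spec: LDESpec, theta: ParamVector) -> np.ndarray:
    """Model-implied covariance Sigma = L Psi L' + Theta of one embedded row.

    Psi = (I - A)^-1 Phi* (I - A)^-T with A the structural regressions;
    Theta is diagonal with each series' unique variance repeated over its
    D embedded columns (equal within a series, free across series).
    """
    loading = build_loading_matrix(spec.D, spec.order, spec.delta_t,
                                   theta.series_loadings)
    a = build_structural(spec.order, theta.eta, theta.zeta)
    ia = np.linalg.inv(np.eye(spec.q) - a)
    psi = ia @ _phi_star(spec, theta) @ ia.T
    theta_diag = np.repeat(theta.unique_variances, spec.D)
    sigma = loading @ psi @ loading.T + np.diag(theta_diag)
    return (sigma + sigma.T) / 2.0


def latent_covariance(spec: LDESpec, theta: ParamVector) -> np.ndarray:
    """Psi, the implied covariance of the latent derivative factors."""
    a = build_structural(spec.order, theta.eta, theta.zeta)
    ia = np.linalg.inv(np.eye(spec.q) - a)
    return ia @ _phi_star(spec, theta) @ ia.T


def implied_row_mean(spec: LDESpec, theta: ParamVector, person) -> np.ndarray:
    """mu_j = m_j * (first loading column): the person equilibrium, scaled by
    the series loading and replicated across the D lags of each series."""
    m_j = theta.mean_for(person)
    loading = build_loading_matrix(spec.D, spec.order, spec.delta_t,
                                   theta.series_loadings)
    return m_j * loading[:, 0]
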