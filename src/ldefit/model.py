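"""Full-information maximum-likelihood estimation of latent ODE models.

``LDEModel`` wraps a time-delay-embedded data matrix together with an
``LDESpec`` and exposes the FIML log-likelihood; ``fit`` maximizes it by
quasi-Newton iteration with uniformly perturbed restarts and returns an
``LDEResults`` object carrying estimates, naive standard errors, fit
statistics and diagnostics.

Each embedded row contributes the multivariate-normal log-density of its
*observed* cells only (missing-at-random), with the row's person-specific
mean and the pattern's marginal covariance.  Rows of the embedded matrix are
treated as independent even though adjacent windows overlap — the standard
estimation convention for this model family.  The likelihood is therefore a
pseudo-likelihood in the rows and the reported standard errors are naive;
point estimates are unaffected, but uncertainty is understated.

Person equilibrium means enter the likelihood linearly, so they are profiled
out of the numerical optimization (exact per-person generalized-least-squares
updates at each candidate covariance); the maximized likelihood is identical
to joint optimization and the means are reported as ordinary free parameters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .embedding import TDEMatrix
from .structure import (
    LDESpec,
    ParamVector,
    build_loading_matrix,
    count_free_parameters,
    implied_covariance,
)

__all__ = [
    "LDEModel",
    "LDEResults",
    "FitOptions",
    "LRTResult",
    "total_loglik",
    "likelihood_ratio_test",
]

logger = logging.getLogger(__name__)

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12  # objective value for rejected (non-PD) points


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration.

    Restarts re-launch the quasi-Newton search from the best solution so
    far, perturbed per parameter by Uniform(-h, h) scaled to the
    parameter's magnitude on the transformed scale (h =
    ``perturb_half_width``).  At least one restart always runs, to confirm
    that the incumbent optimum cannot be improved; up to
    ``max_extra_attempts`` run in total when attempts fail or keep
    improving.
    """

    max_extra_attempts: int = 30
    perturb_half_width: float = 1.0
    gtol: float = 1e-8
    maxiter: int = 2000
    seed: int = 0
    compute_se: bool = True


class _Pattern:
    """One missingness pattern: observed columns and member rows."""

    __slots__ = ("cols", "w", "person_idx", "sinv", "logdet")

    def __init__(self, cols, w, person_idx):
        self.cols = cols          # observed column indices
        self.w = w                # (n_rows, k) observed values
        self.person_idx = person_idx  # (n_rows,) integer person index
        self.sinv = None          # marginal precision at the current Sigma
        self.logdet = 0.0


class LDEModel:
    """Latent differential equation model on a time-delay-embedded matrix.

    Parameters
    ----------
    data : TDEMatrix
        Embedded data; missing cells NaN.
    order : int
        2 for the second-order model (SOLDE), 4 for the constrained
        fourth-order model (FOLDE).
    spec : LDESpec, optional
        Full structure; built from the data when omitted.
    """

    def __init__(self, data: TDEMatrix, order: int = 2,
                 spec: LDESpec | None = None):
        if spec is None:
            spec = LDESpec(
                order=order, D=data.D, P=data.n_series,
                delta_t=data.delta_t,
                person_ids=tuple(data.persons),
                series_names=tuple(data.series_names),
            )
        if data.values.shape[1] != spec.D * spec.P:
            raise ValueError(
                f"data has {data.values.shape[1]} columns, spec implies "
                f"{spec.D * spec.P}"
            )
        known = set(spec.person_ids)
        if not set(data.persons) <= known:
            raise ValueError("data contains persons missing from the spec")
        self.data = data
        self.spec = spec
        self._person_index = {p: i for i, p in enumerate(spec.person_ids)}
        self._build_patterns()

    # ------------------------------------------------------------------ #
    # FIML machinery

    def _build_patterns(self) -> None:
        vals = self.data.values
        mask = np.isfinite(vals)
        person_idx = np.array(
            [self._person_index[p] for p in self.data.row_person], dtype=int
        )
        self.n_rows_used = int((mask.any(axis=1)).sum())
        self.n_rows_empty = vals.shape[0] - self.n_rows_used
        groups: dict[bytes, list[int]] = {}
        for i in range(vals.shape[0]):
            if not mask[i].any():
                continue  # fully missing rows contribute nothing
            groups.setdefault(mask[i].tobytes(), []).append(i)
        self.patterns: list[_Pattern] = []
        for key, rows in groups.items():
            cols = np.flatnonzero(np.frombuffer(key, dtype=bool))
            rows = np.asarray(rows)
            self.patterns.append(
                _Pattern(cols, vals[np.ix_(rows, cols)], person_idx[rows])
            )
        self.n_obs_cells = int(mask.sum())
        # patterns grouped by observed-cell count for batched linear algebra
        by_k: dict[int, list[int]] = {}
        for i, pat in enumerate(self.patterns):
            by_k.setdefault(pat.cols.size, []).append(i)
        self._k_groups = [
            (np.asarray(idxs), np.vstack([self.patterns[i].cols
                                          for i in idxs]))
            for idxs in by_k.values()
        ]

    def _update_pattern_precisions(self, sigma: np.ndarray) -> bool:
        """Marginal precision and log-determinant per missingness pattern.

        Batched over patterns with the same observed-cell count; returns
        False when any marginal covariance is not positive definite.
        """
        for idxs, cols in self._k_groups:
            sub = sigma[cols[:, :, None], cols[:, None, :]]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return False
            diags = np.einsum("gii->gi", chol)
            if np.any(diags <= 0) or not np.all(np.isfinite(diags)):
                return False
            logdets = 2.0 * np.sum(np.log(diags), axis=1)
            sinvs = np.linalg.inv(sub)
            for j, i in enumerate(idxs):
                self.patterns[i].sinv = sinvs[j]
                self.patterns[i].logdet = logdets[j]
        return True

    def _profiled_means(self, l0: np.ndarray) -> np.ndarray:
        """Per-person GLS equilibrium means at the current precisions."""
        n = self.spec.n_persons
        numer = np.zeros(n)
        denom = np.zeros(n)
        for pat in self.patterns:
            a = pat.sinv @ l0[pat.cols]
            d = float(l0[pat.cols] @ a)
            numer += np.bincount(pat.person_idx, weights=pat.w @ a,
                                 minlength=n)
            denom += d * np.bincount(pat.person_idx, minlength=n)
        means = np.zeros(n)
        ok = denom > 0
        means[ok] = numer[ok] / denom[ok]
        self._last_mean_denom = denom
        return means

    def _loglik_at(self, l0, means) -> float:
        total = 0.0
        for pat in self.patterns:
            k = pat.cols.size
            centered = pat.w - np.outer(means[pat.person_idx], l0[pat.cols])
            quad = np.einsum("ij,jk,ik->i", centered, pat.sinv, centered)
            total += -0.5 * (k * _LOG2PI + pat.logdet) * pat.w.shape[0] \
                     - 0.5 * quad.sum()
        return float(total)

    def loglike(self, params) -> float:
        """FIML log-likelihood at a full (natural-scale) parameter vector."""
        theta = self._as_paramvector(params)
        sigma = implied_covariance(self.spec, theta)
        if not self._update_pattern_precisions(sigma):
            logger.debug("implied covariance not positive definite; "
                         "point rejected")
            return -np.inf
        l0 = build_loading_matrix(self.spec.D, self.spec.order,
                                  self.spec.delta_t,
                                  theta.series_loadings)[:, 0]
        return self._loglik_at(l0, theta.person_means)

    def _as_paramvector(self, params) -> ParamVector:
        if isinstance(params, ParamVector):
            if params.spec != self.spec:
                raise ValueError("parameter vector built for a different spec")
            return params
        return ParamVector(self.spec, np.asarray(params, dtype=float))

    def _profiled_negloglik(self, x_struct: np.ndarray,
                            return_means: bool = False):
        """-loglik with person means profiled out; x_struct transformed."""
        theta = self._theta_from_struct(x_struct)
        try:
            sigma = implied_covariance(self.spec, theta)
        except (ValueError, FloatingPointError):
            return (_BIG, None) if return_means else _BIG
        if not np.all(np.isfinite(sigma)):
            return (_BIG, None) if return_means else _BIG
        if not self._update_pattern_precisions(sigma):
            return (_BIG, None) if return_means else _BIG
        l0 = build_loading_matrix(self.spec.D, self.spec.order,
                                  self.spec.delta_t,
                                  theta.series_loadings)[:, 0]
        means = self._profiled_means(l0)
        nll = -self._loglik_at(l0, means)
        if not np.isfinite(nll):
            return (_BIG, None) if return_means else _BIG
        return (nll, means) if return_means else nll

    def _theta_from_struct(self, x_struct: np.ndarray) -> ParamVector:
        full = np.concatenate([x_struct, np.zeros(self.spec.n_persons)])
        return ParamVector.from_transformed(self.spec, full)

    def _profiled_nll_grad(self, x_struct: np.ndarray):
        """Profiled negative log-likelihood and its exact gradient.

        The gradient is analytic: the derivative of the implied covariance
        with respect to each structural parameter contracts against the
        score matrix d(ll)/d(Sigma), and the dependence of the profiled
        person means on the structural parameters drops out by the envelope
        theorem.  Returned on the transformed (optimization) scale.
        """
        from .structure import build_structural, _phi_star

        s = self.spec
        n_struct = s.n_structural
        bad = (_BIG, np.zeros(n_struct))
        theta = self._theta_from_struct(x_struct)
        try:
            loading = build_loading_matrix(s.D, s.order, s.delta_t,
                                           theta.series_loadings)
            a = build_structural(s.order, theta.eta, theta.zeta)
            ia = np.linalg.inv(np.eye(s.q) - a)
            phistar = _phi_star(s, theta)
        except (ValueError, FloatingPointError):
            return bad
        psi = ia @ phistar @ ia.T
        theta_diag = np.repeat(theta.unique_variances, s.D)
        sigma = loading @ psi @ loading.T + np.diag(theta_diag)
        sigma = (sigma + sigma.T) / 2.0
        if not np.all(np.isfinite(sigma)):
            return bad
        if not self._update_pattern_precisions(sigma):
            return bad
        l0 = loading[:, 0]
        means = self._profiled_means(l0)

        dp = s.D * s.P
        ll = 0.0
        score = np.zeros((dp, dp))   # d(ll)/d(Sigma)
        vmean = np.zeros(dp)         # sum over rows of m_j * Sigma^-1 resid
        for pat in self.patterns:
            k = pat.cols.size
            n_r = pat.w.shape[0]
            centered = pat.w - np.outer(means[pat.person_idx], l0[pat.cols])
            sinv_r = centered @ pat.sinv
            quad = np.einsum("ij,ij->i", centered, sinv_r)
            ll += -0.5 * (k * _LOG2PI + pat.logdet) * n_r - 0.5 * quad.sum()
            g_p = 0.5 * (sinv_r.T @ sinv_r - n_r * pat.sinv)
            score[np.ix_(pat.cols, pat.cols)] += g_p
            vmean[pat.cols] += sinv_r.T @ means[pat.person_idx]
        if not np.isfinite(ll):
            return bad

        m_mat = loading @ ia                       # Sigma = M Phi* M' + Theta
        h_mat = m_mat.T @ score @ m_mat            # d(ll)/d(Phi*)
        q_mat = psi @ loading.T @ score @ m_mat    # for eta, zeta via dA

        g = np.zeros(n_struct)
        g[0] = 2.0 * sum(q_mat[k - 2, k] for k in range(2, s.q))  # eta
        g[1] = 2.0 * sum(q_mat[k - 1, k] for k in range(2, s.q))  # zeta
        basis = loading[:s.D]                      # unit-loading block
        x_blk = basis @ psi @ loading.T            # dL Psi L' rows, any block
        for j in range(1, s.P):
            blk = slice(j * s.D, (j + 1) * s.D)
            g[2 + j - 1] = 2.0 * np.sum(score[blk, :] * x_blk) \
                + vmean[blk].sum()
        i = 2 + s.P - 1
        g[i] = h_mat[0, 0]
        g[i + 1] = h_mat[1, 1]
        g[i + 2] = h_mat[0, 1] + h_mat[1, 0]
        for j in range(s.n_resid):
            g[i + 3 + j] = h_mat[2 + j, 2 + j]
        diag_score = np.diag(score)
        for j in range(s.P):
            g[i + 3 + s.n_resid + j] = \
                diag_score[j * s.D:(j + 1) * s.D].sum()

        # chain rule onto the transformed scale
        gx = g.copy()
        c11, c21, c22 = (math.exp(x_struct[i]), x_struct[i + 1],
                         math.exp(x_struct[i + 2]))
        gx[i] = g[i] * 2.0 * c11**2 + g[i + 2] * c11 * c21
        gx[i + 1] = g[i + 1] * 2.0 * c21 + g[i + 2] * c11
        gx[i + 2] = g[i + 1] * 2.0 * c22**2
        gx[i + 3:] = g[i + 3:] * theta.values[i + 3:n_struct]
        return -ll, -gx

    # ------------------------------------------------------------------ #
    # starting values

    def start_params(self) -> np.ndarray:
        """Data-driven starting values, transformed structural scale."""
        s = self.spec
        # typical person series length back from the row counts
        counts = pd.Series(self.data.row_person).value_counts()
        t_typ = float(counts.mean()) + (s.D - 1) * self.data.tau
        eta0 = -(2.0 * math.pi / (t_typ / 2.0)) ** 2
        # within-person variance per series block
        per_series_var = np.empty(s.P)
        vals = self.data.values
        for p in range(s.P):
            block = vals[:, p * s.D:(p + 1) * s.D]
            col = block.ravel()
            owner = np.repeat(self.data.row_person, s.D)
            df = pd.DataFrame({"person": owner, "v": col}).dropna()
            centered = df["v"] - df.groupby("person")["v"].transform("mean")
            per_series_var[p] = max(float(centered.var()), 1e-6)
        v_f = 0.5 * per_series_var[0]
        natural = np.concatenate([
            [eta0, 0.0],
            np.ones(s.P - 1),
            [v_f, abs(eta0) * v_f, 0.0],
            np.full(s.n_resid, 0.1 * eta0**2 * v_f),
            0.5 * per_series_var,
            np.zeros(s.n_persons),
        ])
        return ParamVector(s, natural).to_transformed()[:s.n_structural]

    # ------------------------------------------------------------------ #
    # fitting

    def fit(self, options: FitOptions | None = None, start=None,
            **kwargs) -> "LDEResults":
        """Maximize the FIML likelihood with perturbed restarts.

        ``start`` overrides the data-driven starting values with a natural-
        scale ParamVector (or array).  Never raises on non-convergence: the
        best point found is returned with ``converged=False``.
        """
        if options is None:
            options = FitOptions(**kwargs)
        elif kwargs:
            raise TypeError("pass either options or keyword overrides")
        s = self.spec
        if self.n_rows_used < s.q + 1:
            raise ValueError(
                f"need at least {s.q + 1} informative rows, have "
                f"{self.n_rows_used}"
            )
        rng = np.random.default_rng(options.seed)
        n_struct = s.n_structural
        # box bounds keep log-variances finite at boundary solutions
        i_var = 2 + (s.P - 1)
        bounds = [(None, None)] * n_struct
        bounds[i_var] = (-30.0, 30.0)          # log chol_11
        bounds[i_var + 2] = (-30.0, 30.0)      # log chol_22
        for j in range(i_var + 3, n_struct):
            bounds[j] = (-30.0, 30.0)          # log variances

        if start is None:
            x0 = self.start_params()
        else:
            x0 = self._as_paramvector(start).to_transformed()[:n_struct]

        # per-row scaling keeps finite-difference gradients accurate on
        # large panels, where the raw log-likelihood is O(10^5)
        scale = 1.0 / max(self.n_rows_used, 1)

        def objective(x):
            f, g = self._profiled_nll_grad(x)
            return f * scale, g * scale

        def perturb(x):
            # magnitude-scaled uniform perturbation: an absolute draw would
            # throw the small frequency/damping coordinates far outside the
            # admissible region
            mag = np.minimum(np.maximum(0.25 * np.abs(x), 0.05), 1.0)
            return x + rng.uniform(-options.perturb_half_width,
                                   options.perturb_half_width,
                                   size=x.size) * mag

        history = []
        best = None  # (scaled nll, x)
        confirmed = False
        for attempt in range(options.max_extra_attempts + 1):
            x_start = x0 if attempt == 0 else perturb(best[1] if best
                                                      else x0)
            res = optimize.minimize(
                objective, x_start, jac=True, method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.maxiter, "gtol": options.gtol,
                         "ftol": 1e-13},
            )
            # status 2 is L-BFGS-B's line-search failure, which at a sharp
            # optimum just means no representable step improves the fit
            ok = (np.isfinite(res.fun) and res.fun < _BIG * scale / 2
                  and (bool(res.success) or res.status == 2))
            history.append({"attempt": attempt,
                            "neg_loglik": float(res.fun / scale),
                            "converged": ok, "n_iter": int(res.nit)})
            improved = best is None or \
                res.fun < best[0] - 1e-8 * max(1.0, abs(best[0]))
            if ok and improved:
                best = (float(res.fun), res.x.copy())
            elif ok and best is not None and attempt >= 1:
                confirmed = True
                break

        if best is None:
            # nothing converged: report the last point, flagged
            logger.warning("no fit attempt converged after %d tries",
                           len(history))
            best = (float(res.fun), res.x.copy())
            converged = False
        else:
            converged = True
        x_best = best[1]

        nll_check, means = self._profiled_negloglik(x_best, return_means=True)
        theta_struct = self._theta_from_struct(x_best)
        values = theta_struct.values.copy()
        values[s.n_structural:] = means
        theta = ParamVector(s, values)
        llf = -nll_check
        grad = self._profiled_nll_grad(x_best)[1] * scale
        bse = self._standard_errors(theta, x_best) if options.compute_se \
            else np.full(count_free_parameters(s), np.nan)
        return LDEResults(
            model=self, params=theta, llf=llf, converged=converged,
            n_attempts=len(history), grad_norm=float(np.linalg.norm(grad)),
            attempt_history=history, bse=bse, options=options,
        )

    def _standard_errors(self, theta: ParamVector,
                         x_best: np.ndarray) -> np.ndarray:
        """Naive SEs: structural from the profile-likelihood observed
        information (computed on the smooth transformed scale, mapped to
        the natural scale by the delta method); means from their GLS
        weights.  Variance parameters resting on the boundary of the
        admissible region get NaN — their curvature is uninformative."""
        from statsmodels.tools.numdiff import approx_hess

        s = self.spec
        n_struct = s.n_structural
        bse = np.full(count_free_parameters(s), np.nan)
        i = 2 + s.P - 1  # first index of the (f, f') covariance block
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                hess = approx_hess(x_best, self._profiled_negloglik)
                cov_x = np.linalg.pinv((hess + hess.T) / 2.0)
                # Jacobian of natural = T(transformed) at x_best
                jac = np.eye(n_struct)
                c11, c21, c22 = (math.exp(x_best[i]), x_best[i + 1],
                                 math.exp(x_best[i + 2]))
                jac[i:i + 3, i:i + 3] = [
                    [2 * c11**2, 0.0, 0.0],          # V_f
                    [0.0, 2 * c21, 2 * c22**2],      # V_df
                    [c11 * c21, c11, 0.0],           # C_f_df
                ]
                for j in range(i + 3, n_struct):
                    jac[j, j] = theta.values[j]      # d exp(x) / dx
                d = np.diag(jac @ cov_x @ jac.T)
                bse[:n_struct] = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
                at_bound = np.zeros(n_struct, dtype=bool)
                at_bound[i:i + 3] = np.abs(x_best[i:i + 3]) > 29.0
                at_bound[i + 1] = False
                at_bound[i + 3:] = np.abs(x_best[i + 3:]) > 29.0
                bse[:n_struct][at_bound] = np.nan
            except Exception:  # singular information at degenerate fits
                logger.warning("structural standard errors unavailable")
        # means: conditional GLS variance 1 / sum of weights
        self._profiled_negloglik(x_best, return_means=True)
        denom = self._last_mean_denom
        with np.errstate(divide="ignore"):
            bse[s.n_structural:] = np.where(denom > 0,
                                            1.0 / np.sqrt(denom), np.nan)
        return bse


def total_loglik(spec: LDESpec, theta: ParamVector,
                 data: TDEMatrix) -> float:
    """FIML log-likelihood of ``data`` under ``spec`` at ``theta``.

    Convenience wrapper equivalent to ``LDEModel(data, spec=spec)
    .loglike(theta)``.
    """
    return LDEModel(data, order=spec.order, spec=spec).loglike(theta)


@dataclass
class LDEResults:
    """Fitted latent differential equation model.

    Attributes
    ----------
    params : ParamVector
        Estimates on the natural scale (named access via ``param_table``).
    bse : ndarray
        Naive standard errors aligned with ``params`` (see module notes).
    llf : float
        Maximized log-likelihood; ``minus2ll`` is -2 llf.
    """

    model: LDEModel
    params: ParamVector
    llf: float
    converged: bool
    n_attempts: int
    grad_norm: float
    attempt_history: list = field(default_factory=list)
    bse: np.ndarray = None
    options: FitOptions = None

    @property
    def spec(self) -> LDESpec:
        return self.model.spec

    @property
    def minus2ll(self) -> float:
        return -2.0 * self.llf

    @property
    def eta(self) -> float:
        return self.params.eta

    @property
    def zeta(self) -> float:
        return self.params.zeta

    @property
    def k_free(self) -> int:
        return count_free_parameters(self.spec)

    def wavelength(self) -> float:
        """Oscillation wavelength implied by (eta, zeta), in time units."""
        from .selection import wavelength
        return wavelength(self.eta, self.zeta, self.spec.delta_t)

    def wavelength_or_nan(self) -> float:
        from .synthetic import NonOscillatingError
        try:
            return self.wavelength()
        except NonOscillatingError:
            return float("nan")

    @property
    def param_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params.values,
            "se": self.bse,
        }, index=self.spec.param_names)

    def factor_scores(self, method: str = "regression"):
        from .scores import factor_scores
        return factor_scores(self, self.model.spec, self.model.data, method)

    def lrt(self, other: "LDEResults") -> "LRTResult":
        nested, full = ((self, other) if self.k_free < other.k_free
                        else (other, self))
        return likelihood_ratio_test(nested, full)

    def summary(self) -> str:
        s = self.spec
        name = "SOLDE" if s.order == 2 else "FOLDE"
        lines = [
            f"{name} latent differential equation model "
            f"(order {s.order}, D={s.D}, P={s.P})",
            "=" * 68,
            f"persons: {s.n_persons:>5}    embedded rows: "
            f"{self.model.n_rows_used:>6}    free parameters: {self.k_free}",
            f"log-likelihood: {self.llf:.4f}    -2lnL: {self.minus2ll:.4f}",
            f"converged: {self.converged}    attempts: {self.n_attempts}    "
            f"|grad|: {self.grad_norm:.3g}",
            "-" * 68,
            f"{'parameter':<12}{'estimate':>14}{'std err':>14}",
        ]
        for nm, est, se in zip(s.param_names[:s.n_structural],
                               self.params.values, self.bse):
            se_s = f"{se:>14.6g}" if np.isfinite(se) else f"{'--':>14}"
            lines.append(f"{nm:<12}{est:>14.6g}{se_s}")
        lam = self.wavelength_or_nan()
        lines.append("-" * 68)
        if np.isfinite(lam):
            lines.append(f"wavelength: {lam:.3f} time units "
                         f"(2*pi / sqrt(-eta - zeta^2/4))")
        else:
            lines.append("wavelength: undefined (estimates not underdamped)")
        lines.append(f"person equilibria: {s.n_persons} fixed-effect means "
                     f"(range {self.params.person_means.min():.3g} .. "
                     f"{self.params.person_means.max():.3g})")
        lines.append("note: SEs are naive — embedded rows treated as "
                     "independent despite window overlap.")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "order": self.spec.order, "D": self.spec.D, "P": self.spec.P,
            "estimates": dict(zip(self.spec.param_names,
                                  map(float, self.params.values))),
            "se": {n: (float(v) if np.isfinite(v) else None)
                   for n, v in zip(self.spec.param_names, self.bse)},
            "loglik": float(self.llf),
            "minus2ll": float(self.minus2ll),
            "converged": bool(self.converged),
            "n_attempts": int(self.n_attempts),
            "grad_norm": float(self.grad_norm),
            "wavelength": (float(self.wavelength_or_nan())
                           if np.isfinite(self.wavelength_or_nan()) else None),
            "attempt_history": self.attempt_history,
        }

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class LRTResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def likelihood_ratio_test(nested: LDEResults, full: LDEResults) -> LRTResult:
    """Chi-square difference test of a nested model pair (SOLDE vs FOLDE).

    The statistic is -2lnL(nested) - (-2lnL(full)), clipped at zero (with a
    warning) when optimizer noise makes it slightly negative; df is the
    free-parameter difference (2 for SOLDE-in-FOLDE at equal D, P, N).
    """
    sn, sf = nested.spec, full.spec
    if not (sn.D == sf.D and sn.P == sf.P
            and sn.n_persons == sf.n_persons
            and sn.order < sf.order):
        raise ValueError("models are not nested: need identical D, P and "
                         "persons with a lower-order model first")
    df = full.k_free - nested.k_free
    stat = nested.minus2ll - full.minus2ll
    if stat < 0:
        warnings.warn(
            f"negative LRT statistic {stat:.3g} clipped to 0 "
            "(optimizer noise)", RuntimeWarning)
        stat = 0.0
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=float(stat), df=int(df), pvalue=p)
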