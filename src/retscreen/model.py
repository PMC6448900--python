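"""Maximum-likelihood fitting of the progression model.

Follows the statsmodels convention: :class:`RetinopathyMarkovModel` is built
from a panel dataset and a choice of active covariates; its :meth:`fit`
returns a :class:`RetinopathyMarkovResults` carrying estimates, standard
errors from the inverse observed information, diagnostics and a
``summary()`` table.  Estimates from several multiply-imputed datasets can
be pooled with :func:`pool_results` (Rubin's rules).

The likelihood gradient is analytic: each interval's transition-probability
matrix is diagonalised and the directional derivative of the matrix
exponential is contracted against the single observed entry, giving exact
scores for all intercepts, covariate coefficients and the Weibull shape at
roughly the cost of one likelihood evaluation.  Covariates are standardised
internally for optimiser conditioning; all reported parameters are on the
raw per-unit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .markov import (
    INTENSITY_FLOOR,
    IntervalTable,
    TransitionModel,
    build_interval_table,
    expm_batch,
    intensity_matrix_from_rates,
)
from .states import COVARIATES, TRANSITIONS, transition_label

#: Log-intensity assigned to transitions with no usable exposure.
PINNED_INTERCEPT = -20.0

#: Cap on log-intensities during evaluation; e^8 per year is far beyond
#: screening resolution and keeps line-search excursions finite.
_ETA_CAP = 8.0

_INTERCEPT_BOUNDS = (-20.0, 6.0)
_COEF_BOUNDS = (-5.0, 5.0)  # per-SD log hazard ratio, internal scale
_LOG_ALPHA_BOUNDS = (np.log(0.05), np.log(2.0))

#: Cap on expm batch size (matrices) to bound peak memory.
_EXPM_CHUNK = 250_000

_IDX = tuple((i - 1, j - 1) for i, j in TRANSITIONS)


class ConvergenceError(RuntimeError):
    """Optimiser failed; carries best-so-far parameters and gradient norm."""

    def __init__(self, message, params=None, grad_norm=None):
        super().__init__(message)
        self.params = params
        self.grad_norm = grad_norm


class RetinopathyMarkovModel:
    """Four-state Weibull operational-time Markov model for screening panels.

    Parameters
    ----------
    panel : PanelData
        Complete (imputed) panel dataset.
    covariates
        Active covariate names; each gets one coefficient per permitted
        transition.  Default: every covariate column present in the panel.
    fix_alpha
        Fix the Weibull shape at this value instead of estimating it.
    center
        Covariate centering constants; default is the cohort mean at first
        screening, stored with the fitted model for reproducible prediction.
    duration_fixed_at_baseline
        Carry disease duration at its baseline value through follow-up
        (default), rather than updating it at each episode.
    """

    def __init__(
        self,
        panel,
        covariates: Sequence[str] | None = None,
        fix_alpha: float | None = None,
        center: Mapping[str, float] | None = None,
        duration_fixed_at_baseline: bool = True,
    ):
        if covariates is None:
            covariates = panel.covariate_columns
        unknown = [c for c in covariates if c not in COVARIATES]
        if unknown:
            raise ValueError(f"unknown covariates: {unknown}")
        self.panel = panel
        self.covariates = tuple(c for c in COVARIATES if c in covariates)
        self.fix_alpha = fix_alpha
        self.duration_fixed_at_baseline = duration_fixed_at_baseline
        self.table: IntervalTable = build_interval_table(
            panel, self.covariates, duration_fixed_at_baseline
        )
        if center is None:
            base = panel.baseline()
            center = {c: float(base[c].mean()) for c in self.covariates}
        self.center = {c: float(center.get(c, 0.0)) for c in self.covariates}
        C = len(self.covariates)
        M = self.table.n_intervals
        self._Xc = (
            self.table.X
            - np.array([self.center[c] for c in self.covariates]).reshape(1, -1)
            if C
            else np.zeros((M, 0))
        )
        sd = self._Xc.std(axis=0) if C else np.empty(0)
        self._xsd = np.where(sd > 0, sd, 1.0)
        self._Xs = self._Xc / self._xsd if C else self._Xc
        # transitions with no exposure from their source state are unidentified
        self._identified = np.array(
            [np.any(self.table.s1 == i) for i, _ in TRANSITIONS]
        )
        self.n_subjects = panel.n_subjects
        # cached pieces for the likelihood
        self._rows = np.arange(M)
        with np.errstate(divide="ignore"):
            self._logt1 = np.where(self.table.t1 > 0, np.log(self.table.t1), 0.0)
            self._logt2 = np.where(self.table.t2 > 0, np.log(self.table.t2), 0.0)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "RetinopathyMarkovModel":
        from .panel import PanelData

        return cls(PanelData(frame), **kwargs)

    # -- parameter vector layout ----------------------------------------

    @property
    def estimate_alpha(self) -> bool:
        return self.fix_alpha is None

    @property
    def k_params(self) -> int:
        """Length of the parameter vector (including pinned intercepts)."""
        return 6 + 6 * len(self.covariates) + (1 if self.estimate_alpha else 0)

    @property
    def n_free_params(self) -> int:
        return int(self._identified.sum()) + 6 * len(self.covariates) + (
            1 if self.estimate_alpha else 0
        )

    def param_names(self) -> list[str]:
        names = [f"intercept[{transition_label(i, j)}]" for i, j in TRANSITIONS]
        for cov in self.covariates:
            names += [f"{cov}[{transition_label(i, j)}]" for i, j in TRANSITIONS]
        if self.estimate_alpha:
            names.append("log_alpha")
        return names

    def pack(self, model: TransitionModel) -> np.ndarray:
        """Parameter vector corresponding to a TransitionModel (centres must match)."""
        theta = [np.asarray(model.intercepts, float)]
        for cov in self.covariates:
            theta.append(model.coefficients.get(cov, np.zeros(6)))
        if self.estimate_alpha:
            theta.append([np.log(model.alpha)])
        return np.concatenate(theta)

    def _scale_vector(self) -> np.ndarray:
        """Elementwise factor mapping internal (per-SD) to raw parameters."""
        C = len(self.covariates)
        scale = np.ones(self.k_params)
        if C:
            scale[6 : 6 + 6 * C] = np.repeat(1.0 / self._xsd, 6)
        return scale

    # -- likelihood and analytic score -----------------------------------

    def _components(self, theta: np.ndarray, internal: bool):
        C = len(self.covariates)
        beta0 = theta[:6]
        coefs = theta[6 : 6 + 6 * C].reshape(C, 6)
        alpha = np.exp(theta[-1]) if self.estimate_alpha else float(self.fix_alpha)
        X = self._Xs if internal else self._Xc
        eta = beta0[None, :] + X @ coefs
        capped = eta >= _ETA_CAP
        lam = np.exp(np.minimum(eta, _ETA_CAP))
        np.maximum(lam, INTENSITY_FLOOR, out=lam)
        du = self.table.t2**alpha - self.table.t1**alpha
        A = intensity_matrix_from_rates(lam) * du[:, None, None]
        return lam, capped, alpha, du, A, X

    def _eval(self, theta: np.ndarray, need_grad: bool, internal: bool = True):
        """Log-likelihood and (optionally) its exact gradient.

        ``internal`` selects the standardised coefficient scale used by the
        optimiser; the public :meth:`loglike`/:meth:`score` use raw scale.
        """
        lam, capped, alpha, du, A, X = self._components(theta, internal)
        M = self.table.n_intervals
        s1 = self.table.s1 - 1
        s2 = self.table.s2 - 1
        P = expm_batch(A)
        p_obs = np.clip(P[self._rows, s1, s2], 1e-300, None)
        ll = float(np.log(p_obs).sum())
        if not need_grad:
            return ll, None
        # directional derivatives of expm via diagonalisation: for direction
        # E, dP = V (F o (V^-1 E V)) V^-1 with F the divided-difference matrix
        with np.errstate(all="ignore"):
            w, V = np.linalg.eig(A)
            try:
                Vinv = np.linalg.inv(V)
            except np.linalg.LinAlgError:
                Vinv = np.linalg.pinv(V)
            expw = np.exp(w)
            dwa = w[:, :, None] - w[:, None, :]
            near = np.abs(dwa) < 1e-7
            F = np.where(
                near,
                np.exp(0.5 * (w[:, :, None] + w[:, None, :])),
                (expw[:, :, None] - expw[:, None, :]) / np.where(near, 1.0, dwa),
            )
            L = V[self._rows, s1, :]        # (M, 4)
            R = Vinv[self._rows, :, s2]     # (M, 4)
            inv_p = 1.0 / p_obs
            # per-interval score wrt each transition's log-intensity, and wrt
            # a multiplicative rescaling of the whole interval matrix
            dk = np.empty((M, 6))
            for k, (r, c) in enumerate(_IDX):
                w1 = L * Vinv[:, :, r]
                z = (V[:, c, :] - V[:, r, :]) * R
                val = np.einsum("ma,mab,mb->m", w1, F, z).real
                dk[:, k] = lam[:, k] * du * val * inv_p
            # dA in direction A (scale derivative) collapses to diag(w e^w)
            dscale = np.einsum("ma,ma,ma->m", L, w * expw, R).real * inv_p
            # near-defective interval matrices make the eigen route unreliable;
            # recompute those intervals by central differences on Pade expm
            p_eig = np.einsum("ma,ma,ma->m", L, expw, R).real
        bad = (
            ~np.isfinite(dk).all(axis=1)
            | ~np.isfinite(dscale)
            | (np.abs(p_eig - p_obs) > 1e-9 * np.maximum(p_obs, 1e-6))
        )
        if bad.any():
            self._fd_interval_scores(np.flatnonzero(bad), lam, du, s1, s2, dk, dscale)
        dk[capped] = 0.0  # capped intensities do not respond to parameters
        grad = np.empty_like(theta)
        grad[:6] = dk.sum(axis=0)
        C = len(self.covariates)
        if C:
            grad[6 : 6 + 6 * C] = np.einsum("mk,mc->ck", dk, X).reshape(-1)
        if self.estimate_alpha:
            # dA/dalpha = A * (du'/du)
            dup = self.table.t2**alpha * self._logt2 - self.table.t1**alpha * self._logt1
            safe_du = np.where(np.abs(du) > 0, du, 1.0)
            grad[-1] = float(np.sum(dscale * dup / safe_du) * alpha)
        return ll, grad

    def _fd_interval_scores(self, bidx, lam, du, s1, s2, dk, dscale) -> None:
        """Per-interval scores by central differences (robust fallback)."""
        h = 1e-6
        mats = []
        for m in bidx:
            for k in range(6):
                for sgn in (1.0, -1.0):
                    lam_p = lam[m].copy()
                    lam_p[k] *= np.exp(sgn * h)
                    mats.append(intensity_matrix_from_rates(lam_p) * du[m])
            base = intensity_matrix_from_rates(lam[m]) * du[m]
            mats.append(base * (1 + h))
            mats.append(base * (1 - h))
        P = expm_batch(np.asarray(mats))
        p = P[np.arange(len(mats)), np.repeat(s1[bidx], 14), np.repeat(s2[bidx], 14)]
        logp = np.log(np.clip(p, 1e-300, None)).reshape(len(bidx), 14)
        for pos, m in enumerate(bidx):
            row = logp[pos]
            for k in range(6):
                dk[m, k] = (row[2 * k] - row[2 * k + 1]) / (2 * h)
            dscale[m] = (row[12] - row[13]) / (2 * h)

    def loglike(self, params: np.ndarray) -> float:
        """Panel log-likelihood at a raw-scale parameter vector."""
        return self._eval(np.asarray(params, float), need_grad=False, internal=False)[0]

    def score(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the log-likelihood (raw scale)."""
        return self._eval(np.asarray(params, float), need_grad=True, internal=False)[1]

    def loglike_many(self, theta: np.ndarray) -> np.ndarray:
        """Panel log-likelihood for a (B, k) batch of raw parameter vectors."""
        theta = np.atleast_2d(np.asarray(theta, float))
        B = theta.shape[0]
        C = len(self.covariates)
        M = self.table.n_intervals
        beta0 = theta[:, :6]
        coefs = theta[:, 6 : 6 + 6 * C].reshape(B, C, 6)
        alpha = (
            np.exp(theta[:, -1]) if self.estimate_alpha else np.full(B, float(self.fix_alpha))
        )
        eta = beta0[:, None, :] + np.einsum("mc,bcs->bms", self._Xc, coefs)
        lam = np.exp(np.minimum(eta, _ETA_CAP))
        np.maximum(lam, INTENSITY_FLOOR, out=lam)
        du = self.table.t2[None, :] ** alpha[:, None] - self.table.t1[None, :] ** alpha[:, None]
        A = (intensity_matrix_from_rates(lam) * du[..., None, None]).reshape(B * M, 4, 4)
        P = np.empty_like(A)
        for lo in range(0, B * M, _EXPM_CHUNK):
            hi = min(lo + _EXPM_CHUNK, B * M)
            P[lo:hi] = expm_batch(A[lo:hi])
        P = P.reshape(B, M, 4, 4)
        p_obs = P[:, self._rows, self.table.s1 - 1, self.table.s2 - 1]
        return np.log(np.clip(p_obs, 1e-300, None)).sum(axis=1)

    # -- fitting ---------------------------------------------------------

    def start_params(self) -> np.ndarray:
        """Crude occurrence/exposure starting values (coefficients zero)."""
        alpha0 = self.fix_alpha if self.fix_alpha is not None else 1.0
        du = self.table.t2**alpha0 - self.table.t1**alpha0
        beta0 = np.full(6, PINNED_INTERCEPT)
        for k, (i, j) in enumerate(TRANSITIONS):
            at_risk = self.table.s1 == i
            exposure = float(du[at_risk].sum())
            if exposure <= 0:
                continue
            count = float(np.sum(at_risk & (self.table.s2 == j)))
            beta0[k] = np.log(max(count, 0.5) / exposure)
        theta = [beta0, np.zeros(6 * len(self.covariates))]
        if self.estimate_alpha:
            theta.append([0.0])
        return np.concatenate(theta)

    def _bounds(self) -> list[tuple[float, float]]:
        bounds: list[tuple[float, float]] = []
        for k in range(6):
            if self._identified[k]:
                bounds.append(_INTERCEPT_BOUNDS)
            else:
                bounds.append((PINNED_INTERCEPT, PINNED_INTERCEPT))
        bounds += [_COEF_BOUNDS] * (6 * len(self.covariates))
        if self.estimate_alpha:
            bounds.append(_LOG_ALPHA_BOUNDS)
        return bounds

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 500,
        compute_cov: bool = True,
        raise_on_fail: bool = True,
    ) -> "RetinopathyMarkovResults":
        """Maximise the panel likelihood (L-BFGS-B, analytic gradients)."""
        theta0 = np.asarray(
            self.start_params() if start_params is None else start_params, float
        )
        if theta0.shape != (self.k_params,):
            raise ValueError(f"start_params must have length {self.k_params}")
        scale = self._scale_vector()
        theta0_int = theta0 / scale
        bounds = self._bounds()
        theta0_int = np.clip(theta0_int, [b[0] for b in bounds], [b[1] for b in bounds])

        def negloglike(th):
            ll, g = self._eval(th, need_grad=True, internal=True)
            return -ll, -g

        res = optimize.minimize(
            negloglike,
            theta0_int,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6, "maxcor": 30},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success) or grad_norm < 1e-3
        params = res.x * scale
        if not converged and raise_on_fail:
            raise ConvergenceError(
                f"optimiser did not converge after {res.nit} iterations "
                f"(projected gradient max-norm {grad_norm:.3g}): {res.message}",
                params=params,
                grad_norm=grad_norm,
            )
        cov = None
        cov_flags: list[str] = []
        if compute_cov:
            cov, cov_flags = self._covariance(res.x, scale)
        return RetinopathyMarkovResults(
            model=self,
            params=params,
            llf=float(-res.fun),
            cov_params_arr=cov,
            cov_flags=cov_flags,
            converged=converged,
            niter=int(res.nit),
            grad_norm=grad_norm,
        )

    # -- covariance ------------------------------------------------------

    def _covariance(self, theta_int: np.ndarray, scale: np.ndarray):
        """Inverse observed information via central differences of the score."""
        free = np.array([lo < hi for lo, hi in self._bounds()])
        idx = np.flatnonzero(free)
        p = len(idx)
        h = 1e-5 * (1.0 + np.abs(theta_int[idx]))
        H = np.zeros((p, p))
        for a in range(p):
            tp = theta_int.copy()
            tp[idx[a]] += h[a]
            tm = theta_int.copy()
            tm[idx[a]] -= h[a]
            gp = self._eval(tp, need_grad=True, internal=True)[1]
            gm = self._eval(tm, need_grad=True, internal=True)[1]
            H[a] = (gp[idx] - gm[idx]) / (2.0 * h[a])
        info = -0.5 * (H + H.T)
        flags: list[str] = []
        try:
            cov_free = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(info)
            flags.append("singular_information")
        if np.any(np.diag(cov_free) < 0):
            flags.append("negative_variance")
        cov_int = np.full((self.k_params, self.k_params), np.nan)
        cov_int[np.ix_(idx, idx)] = cov_free
        cov = cov_int * np.outer(scale, scale)
        if flags:
            warnings.warn(
                f"observed information is ill-conditioned ({flags}); "
                "standard errors may be unavailable"
            )
        return cov, flags


class RetinopathyMarkovResults:
    """Fitted progression model: estimates, uncertainty and diagnostics."""

    def __init__(self, model, params, llf, cov_params_arr, cov_flags, converged, niter, grad_norm):
        self.model = model
        self.params = np.asarray(params, float)
        self.llf = llf
        self._cov = cov_params_arr
        self.cov_flags = list(cov_flags)
        self.converged = converged
        self.niter = niter
        self.grad_norm = grad_norm
        self.n_subjects = model.n_subjects
        self.n_parameters = model.n_free_params

    # -- parameter views -------------------------------------------------

    @property
    def alpha(self) -> float:
        if self.model.estimate_alpha:
            return float(np.exp(self.params[-1]))
        return float(self.model.fix_alpha)

    @property
    def intercepts(self) -> np.ndarray:
        return self.params[:6].copy()

    def coefficient_matrix(self) -> dict[str, np.ndarray]:
        C = len(self.model.covariates)
        block = self.params[6 : 6 + 6 * C].reshape(C, 6)
        return {cov: block[k].copy() for k, cov in enumerate(self.model.covariates)}

    def cov_params(self) -> np.ndarray:
        if self._cov is None:
            raise ValueError("fit was run with compute_cov=False")
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params()))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def hazard_ratios(self) -> pd.DataFrame:
        return self.transition_model().hazard_ratios()

    def transition_model(self) -> TransitionModel:
        """Export the estimates as a self-contained :class:`TransitionModel`."""
        base = self.model.panel.baseline()
        worst_case = {}
        for cov in self.model.covariates:
            vals = base[cov].dropna().to_numpy()
            if len(vals):
                worst_case[cov] = float(np.percentile(vals, 75))
        return TransitionModel(
            intercepts=self.intercepts,
            coefficients=self.coefficient_matrix(),
            alpha=self.alpha,
            centering=dict(self.model.center),
            worst_case=worst_case,
            metadata={
                "llf": self.llf,
                "n_subjects": self.n_subjects,
                "n_parameters": self.n_parameters,
                "converged": self.converged,
            },
        )

    # -- inference -------------------------------------------------------

    def wald_test_covariate(self, covariate: str):
        """Joint Wald chi-square for a covariate's six transition coefficients.

        Returns ``(statistic, df, pvalue)`` for H0: all six per-transition
        coefficients of ``covariate`` are zero.
        """
        if covariate not in self.model.covariates:
            raise ValueError(f"covariate {covariate!r} is not active in this fit")
        k = self.model.covariates.index(covariate)
        sl = slice(6 + 6 * k, 12 + 6 * k)
        beta = self.params[sl]
        V = self.cov_params()[sl, sl]
        stat = float(beta @ np.linalg.solve(V, beta))
        df = 6
        return stat, df, float(stats.chi2.sf(stat, df))

    @property
    def aicc(self) -> float:
        return aicc(self)

    def summary(self) -> str:
        """Human-readable fit summary (hazard ratios with 95% CIs)."""
        lines = []
        lines.append("Retinopathy progression model (Weibull operational-time Markov)")
        lines.append("=" * 72)
        lines.append(
            f"subjects: {self.n_subjects}   episodes: "
            f"{self.model.panel.n_episodes}   intervals: {self.model.table.n_intervals}"
        )
        lines.append(
            f"log-likelihood: {self.llf:.3f}   AICc: {self.aicc:.3f}   "
            f"free parameters: {self.n_parameters}"
        )
        status = "yes" if self.converged else "NO"
        lines.append(
            f"converged: {status} ({self.niter} iterations, "
            f"|grad|_max {self.grad_norm:.2e})"
        )
        if self.model.estimate_alpha:
            se_la = self.bse[-1]
            lo, hi = np.exp(self.params[-1] - 1.96 * se_la), np.exp(self.params[-1] + 1.96 * se_la)
            lines.append(f"Weibull shape alpha: {self.alpha:.4f} (95% CI {lo:.4f}, {hi:.4f})")
        else:
            lines.append(f"Weibull shape alpha: {self.alpha:.4f} (fixed)")
        lines.append("")
        lines.append("Baseline 1-year transition intensities exp(beta0):")
        for k, (i, j) in enumerate(TRANSITIONS):
            pin = "" if self.model._identified[k] else "  [pinned: no exposure]"
            lines.append(f"  {transition_label(i, j)}: {np.exp(self.params[k]):.5f}{pin}")
        if self.model.covariates:
            lines.append("")
            lines.append("Per-unit hazard ratios exp(beta) (95% CI):")
            ci = self.conf_int()
            for k, cov in enumerate(self.model.covariates):
                lines.append(f"  {cov}:")
                for m, (i, j) in enumerate(TRANSITIONS):
                    p = 6 + 6 * k + m
                    lines.append(
                        f"    {transition_label(i, j)}: {np.exp(self.params[p]):.4f} "
                        f"({np.exp(ci[p, 0]):.4f}, {np.exp(ci[p, 1]):.4f})"
                    )
        return "\n".join(lines)


def aicc(fit: RetinopathyMarkovResults) -> float:
    """Corrected Akaike information criterion of a fit.

    AICc = -2 llf + 2k + 2k(k+1)/(n - k - 1), with k the number of free
    parameters and n the number of subjects (the independent units).
    """
    k = fit.n_parameters
    n = fit.n_subjects
    if n <= k + 1:
        raise ValueError(f"AICc undefined: n_subjects={n} <= k+1={k + 1}")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_mle(
    panel,
    covariates: Sequence[str] | None = None,
    fix_alpha: float | None = None,
    **fit_kwargs,
) -> RetinopathyMarkovResults:
    """Convenience wrapper: build the model and fit by maximum likelihood."""
    return RetinopathyMarkovModel(panel, covariates=covariates, fix_alpha=fix_alpha).fit(
        **fit_kwargs
    )


@dataclass
class PooledResults:
    """Rubin's-rules pooling of fits across multiply-imputed datasets."""

    params: np.ndarray
    bse: np.ndarray
    within_var: np.ndarray
    between_var: np.ndarray
    m: int
    param_names: list[str]

    def hazard_ratio_frame(self, covariates: Sequence[str]) -> pd.DataFrame:
        C = len(covariates)
        block = self.params[6 : 6 + 6 * C].reshape(C, 6)
        idx = [transition_label(i, j) for i, j in TRANSITIONS]
        return pd.DataFrame({c: np.exp(block[k]) for k, c in enumerate(covariates)}, index=idx)


def pool_results(fits: Sequence[RetinopathyMarkovResults]) -> PooledResults:
    """Pool coefficient estimates across imputed-dataset fits (Rubin's rules)."""
    if len(fits) < 2:
        raise ValueError("pooling needs at least two fits")
    P = np.vstack([f.params for f in fits])
    V = np.vstack([np.diag(f.cov_params()) for f in fits])
    m = len(fits)
    qbar = P.mean(axis=0)
    within = V.mean(axis=0)
    between = P.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    return PooledResults(
        params=qbar,
        bse=np.sqrt(total),
        within_var=within,
        between_var=between,
        m=m,
        param_names=fits[0].model.param_names(),
    )
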