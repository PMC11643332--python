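"""Per-taxon Gompertz state-space denoising (stage 1 of the two-stage fit).

Each taxon's log abundance is modelled as a latent Gompertz (univariate
AR(1)) process observed with sampling error:

    X_t     = a + c X_{t-1} + e_t,    e_t ~ N(0, tau2)      (process)
    Y_{t,r} = X_t + f_{t,r},          f_{t,r} ~ N(0, obs_var)  (observation)

with r = 1..m exchangeable replicate measurements per day and missing
days allowed.  The exact likelihood is computed with a Kalman filter in
which each replicate enters as a conditionally independent scalar update
(so the filter likelihood equals the joint normal density of all observed
replicates); missing observations simply skip the update.  Smoothed
(Rauch-Tung-Striebel) state means and variances provide the denoised
series and per-cell uncertainties used downstream by the MAR fit and its
parametric bootstrap.

The initial state prior is the stationary distribution of the latent
process when |c| < 1 and tau2 > 0, otherwise a diffuse prior with
variance 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import CommunityTimeSeries, check_design
from .exceptions import ConvergenceError, DesignError, ValidationError

__all__ = [
    "GompertzStateSpaceModel",
    "StateSpaceFit",
    "fit_state_space",
    "denoise_community",
]

_DIFFUSE_VAR = 1e6
_LOGVAR_BOUNDS = (-25.0, 8.0)


def _kalman(y, a, c, tau2, obs_var, smooth=False):
    """Filter (and optionally smooth) one univariate series.

    Parameters
    ----------
    y : (n, m) array with NaN for missing cells.

    Returns
    -------
    loglik  -- exact joint log density of all non-missing entries
    (sm_mean, sm_var) when ``smooth`` -- RTS-smoothed state moments.
    """
    n, m = y.shape
    if abs(c) < 1.0 and tau2 > 0:
        mu = a / (1.0 - c)
        P = tau2 / (1.0 - c * c)
    elif abs(c) < 1.0:
        mu, P = a / (1.0 - c), 0.0
    else:
        mu, P = 0.0, _DIFFUSE_VAR
    loglik = 0.0
    filt_mean = np.empty(n)
    filt_var = np.empty(n)
    log2pi = np.log(2.0 * np.pi)
    for t in range(n):
        if t > 0:
            mu = a + c * mu
            P = c * c * P + tau2
        for r in range(m):
            obs = y[t, r]
            if np.isnan(obs):
                continue
            S = P + obs_var
            if S <= 0.0:
                # degenerate: state known exactly and no measurement noise
                if abs(obs - mu) > 1e-10:
                    return (-np.inf, None, None) if smooth else -np.inf
                continue
            resid = obs - mu
            loglik += -0.5 * (log2pi + np.log(S) + resid * resid / S)
            K = P / S
            mu = mu + K * resid
            P = P * (1.0 - K)
        filt_mean[t] = mu
        filt_var[t] = P
    if not smooth:
        return loglik
    sm_mean = np.empty(n)
    sm_var = np.empty(n)
    sm_mean[-1] = filt_mean[-1]
    sm_var[-1] = filt_var[-1]
    for t in range(n - 2, -1, -1):
        P_pred = c * c * filt_var[t] + tau2
        if P_pred > 0.0:
            J = filt_var[t] * c / P_pred
        else:
            J = 0.0
        sm_mean[t] = filt_mean[t] + J * (sm_mean[t + 1] - (a + c * filt_mean[t]))
        sm_var[t] = filt_var[t] + J * J * (sm_var[t + 1] - P_pred)
        if sm_var[t] < 0.0:
            sm_var[t] = 0.0
    return loglik, sm_mean, sm_var


@dataclass(frozen=True)
class StateSpaceFit:
    """Maximum-likelihood fit of the univariate Gompertz state-space model.

    Attributes
    ----------
    a, c : float
        Growth rate and density-dependence coefficient of the latent
        process (c near 1 = weak density dependence).
    tau2, obs_var : float
        Process and observation-error variances.
    smoothed_mean, smoothed_var : (n,) arrays
        Denoised state estimates and their variances at every day,
        including days with missing observations.
    loglik : float
        Maximised log-likelihood.
    """

    a: float
    c: float
    tau2: float
    obs_var: float
    smoothed_mean: np.ndarray
    smoothed_var: np.ndarray
    loglik: float
    converged: bool = True
    taxon: str = None
    n_obs: int = field(default=0, repr=False)

    def summary(self) -> str:
        lines = [
            "Gompertz state-space fit"
            + (f" ({self.taxon})" if self.taxon else ""),
            "-" * 40,
            f"{'growth rate a':<28}{self.a: .6g}",
            f"{'density dependence c':<28}{self.c: .6g}",
            f"{'process variance tau2':<28}{self.tau2: .6g}",
            f"{'observation variance':<28}{self.obs_var: .6g}",
            f"{'log-likelihood':<28}{self.loglik: .6g}",
            f"{'observations':<28}{self.n_obs:d}",
        ]
        return "\n".join(lines)


class GompertzStateSpaceModel:
    """Univariate Gompertz state-space model for one taxon's log abundances.

    Parameters
    ----------
    endog : (n,) or (n, m) array_like
        Log abundances, NaN marking missing cells (m replicate columns).
    taxon : str, optional
        Name carried through to the results.
    """

    def __init__(self, endog, taxon: str | None = None):
        y = np.asarray(endog, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if y.ndim != 2:
            raise ValidationError("endog must be 1-D or 2-D (time x replicate)")
        obs_per_day = np.sum(~np.isnan(y), axis=1)
        present = np.nonzero(obs_per_day > 0)[0]
        if present.size == 0:
            raise ValidationError("series has no observations")
        # trim fully-missing prefix/suffix before the feasibility check
        lo, hi = present[0], present[-1] + 1
        n_eff, m = hi - lo, y.shape[1]
        info = check_design(1, max(n_eff, 2), m)
        if n_eff < 2 or not info.feasible:
            raise DesignError(
                f"series too short for a state-space fit: {n_eff} usable days "
                f"with m={m}, need at least {info.min_length}"
            )
        self.endog = y
        self.taxon = taxon
        self.nobs = int(obs_per_day.sum())

    # -- likelihood ----------------------------------------------------
    def loglike(self, a, c, tau2, obs_var) -> float:
        """Exact log-likelihood at the given parameter values."""
        if tau2 < 0 or obs_var < 0:
            raise ValidationError("variances must be nonnegative")
        return _kalman(self.endog, a, c, tau2, obs_var, smooth=False)

    def smooth(self, a, c, tau2, obs_var) -> tuple[np.ndarray, np.ndarray]:
        """Smoothed state means and variances at given parameters."""
        _, sm_mean, sm_var = _kalman(
            self.endog, a, c, tau2, obs_var, smooth=True
        )
        return sm_mean, sm_var

    # -- starting values -----------------------------------------------
    def _start_points(self, fix_obs_var):
        ybar = np.nanmean(self.endog, axis=1)
        filled = ybar.copy()
        idx = np.nonzero(~np.isnan(filled))[0]
        filled = np.interp(np.arange(filled.size), idx, filled[idx])
        x0, x1 = filled[:-1], filled[1:]
        vx = np.var(x0)
        if vx > 0:
            c0 = float(np.cov(x0, x1)[0, 1] / vx)
            c0 = float(np.clip(c0, -0.98, 0.98))
        else:
            c0 = 0.5
        a0 = float(np.mean(x1) - c0 * np.mean(x0))
        v = float(np.var(x1 - (a0 + c0 * x0)))
        v = max(v, 1e-4)
        # within-day replicate scatter is a direct read on obs_var
        if self.endog.shape[1] > 1:
            counts = np.sum(~np.isnan(self.endog), axis=1)
            rows = self.endog[counts > 1]
            rep_var = (float(np.nanmean(np.nanvar(rows, axis=1, ddof=1)))
                       if rows.size else np.nan)
            rep_var = rep_var if np.isfinite(rep_var) else 0.5 * v
            rep_var = max(rep_var, 1e-6)
        else:
            rep_var = 0.5 * v
        mean_level = float(np.mean(filled))
        splits = [
            (a0, c0, 0.5 * v, rep_var),
            (a0, c0, 0.9 * v, 0.1 * v),
            (a0, c0, 0.1 * v, 0.9 * v),
            (a0, c0, max(v - rep_var, 0.1 * v), rep_var),
            (0.5 * mean_level, 0.5, v, 0.5 * v),
        ]
        pts = []
        for a, c, t2, ov in splits:
            if fix_obs_var is None:
                pts.append([a, c, np.log(t2), np.log(ov)])
            else:
                pts.append([a, c, np.log(t2)])
        return pts

    # -- fitting -------------------------------------------------------
    def fit(
        self,
        fix_obs_var: float | None = None,
        n_starts: int = 5,
        gtol: float = 1e-8,
    ) -> StateSpaceFit:
        """Maximise the Kalman likelihood over (a, c, tau2, obs_var).

        Quasi-Newton (L-BFGS-B) on transformed parameters (variances on
        the log scale, c unconstrained) with multiple starting points;
        the likelihood surface is ridge-prone when tau2 and obs_var trade
        off, so the best of all starts is kept.

        Parameters
        ----------
        fix_obs_var : float, optional
            Hold the observation variance fixed (e.g. 0 for noise-free
            measurements) and optimise the remaining parameters.
        """
        y = self.endog

        def unpack(theta):
            if fix_obs_var is None:
                a, c, lt, lo = theta
                return a, c, np.exp(lt), np.exp(lo)
            a, c, lt = theta
            return a, c, np.exp(lt), float(fix_obs_var)

        def negll(theta):
            ll = _kalman(y, *unpack(theta), smooth=False)
            return 1e12 if not np.isfinite(ll) else -ll

        lb, ub = _LOGVAR_BOUNDS
        k = 3 if fix_obs_var is not None else 4
        bounds = [(None, None), (-3.0, 3.0)] + [(lb, ub)] * (k - 2)
        best = None
        diagnostics = []
        for theta0 in self._start_points(fix_obs_var)[:n_starts]:
            res = optimize.minimize(
                negll, np.asarray(theta0, dtype=float), method="L-BFGS-B",
                bounds=bounds, options={"ftol": gtol, "gtol": 1e-7,
                                        "maxiter": 500},
            )
            diagnostics.append({"start": theta0, "fun": float(res.fun),
                                "success": bool(res.success),
                                "message": str(res.message)})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
            raise ConvergenceError(
                "state-space likelihood optimisation failed"
                + (f" for taxon {self.taxon}" if self.taxon else ""),
                best_params=None if best is None else unpack(best.x),
                diagnostics={"starts": diagnostics},
            )
        a, c, tau2, obs_var = unpack(best.x)
        loglik = -float(best.fun)
        _, sm_mean, sm_var = _kalman(y, a, c, tau2, obs_var, smooth=True)
        return StateSpaceFit(
            a=float(a), c=float(c), tau2=float(tau2), obs_var=float(obs_var),
            smoothed_mean=sm_mean, smoothed_var=sm_var, loglik=loglik,
            converged=bool(best.success), taxon=self.taxon, n_obs=self.nobs,
        )


def fit_state_space(
    y,
    taxon: str | None = None,
    fix_obs_var: float | None = None,
    n_starts: int = 5,
) -> StateSpaceFit:
    """Fit the univariate Gompertz state-space model to one series.

    Thin functional wrapper around :class:`GompertzStateSpaceModel`.
    """
    return GompertzStateSpaceModel(y, taxon=taxon).fit(
        fix_obs_var=fix_obs_var, n_starts=n_starts
    )


def denoise_community(
    series: CommunityTimeSeries,
    fix_obs_var: float | None = None,
    n_starts: int = 5,
) -> tuple[CommunityTimeSeries, list[StateSpaceFit]]:
    """Denoise every taxon of a community series by state-space smoothing.

    Observations are replaced by smoothed state means (imputing missing
    days), replicate layers collapse to a single layer, and the smoothed
    state variances are kept on the result (``state_variance``) so the
    MAR-stage parametric bootstrap can propagate stage-1 uncertainty.

    Returns
    -------
    (denoised_series, fits)
        ``denoised_series`` has ``m = 1`` and no missing cells.
    """
    fits: list[StateSpaceFit] = []
    errors: list[str] = []
    sm = np.empty((series.p, series.n))
    sv = np.empty((series.p, series.n))
    for i, taxon in enumerate(series.taxa):
        try:
            fit = fit_state_space(
                series.log_abundance[i],  # (n, m)
                taxon=taxon, fix_obs_var=fix_obs_var, n_starts=n_starts,
            )
        except (ValidationError, ConvergenceError) as exc:
            errors.append(f"{taxon}: {exc}")
            continue
        fits.append(fit)
        sm[i] = fit.smoothed_mean
        sv[i] = fit.smoothed_var
    if errors:
        raise ValidationError(
            "denoising failed for taxa: " + "; ".join(errors)
        )
    denoised = CommunityTimeSeries(
        subject_id=series.subject_id, taxa=series.taxa, times=series.times,
        log_abundance=sm[:, :, None], pseudocount=series.pseudocount,
        state_variance=sv,
    )
    return denoised, fits
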