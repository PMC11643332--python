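"""Conditional least-squares estimation of the MAR(1) community model.

Because the process is Markovian with Gaussian shocks, the conditional
likelihood factorises over the observed one-day transitions, and its
maximiser is the conditional least-squares (CLS) estimator: each taxon's
log abundance at time t is regressed on an intercept and all taxa's log
abundances at time t-1, giving one row of the interaction matrix ``B``
and one entry of the growth-rate vector ``A``; the environmental
covariance ``Sigma`` is the residual cross-covariance with divisor
``n - 1`` (conditional ML).

Stage-1 (observation error) uncertainty is propagated by a parametric
bootstrap: each replicate re-simulates the full generative chain (MAR
process noise, then per-taxon observation noise from the state-space
fits), re-runs the denoise + CLS pipeline, and percentile intervals are
taken over the re-estimated parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .data import CommunityTimeSeries, DesignInfo, check_design
from .exceptions import DesignError, NumericalError, ValidationError
from .process import MARParameters, simulate_mar

__all__ = ["MARModel", "MARResults", "BootstrapResult", "ParameterBounds",
           "fit_mar_cls", "bootstrap_mar"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterBounds:
    """Entrywise confidence bounds on (A, B, Sigma).

    Not a valid parameter set itself (entrywise bounds on a covariance
    need not be PSD) — just a container of per-entry interval endpoints.
    """

    A: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    taxa: tuple = None

    @property
    def p(self):
        return len(self.A)


@dataclass(frozen=True)
class BootstrapResult:
    """Parametric-bootstrap replicates and 95% confidence intervals."""

    replicates: tuple            # tuple of MARParameters
    ci_lower: ParameterBounds
    ci_upper: ParameterBounds
    n_requested: int
    n_failed: int
    ci_method: str = "basic"
    seed: int = None

    @property
    def n_ok(self) -> int:
        return len(self.replicates)

    def ci_table(self) -> pd.DataFrame:
        """Long-format table of 95% percentile intervals per parameter."""
        rows = []
        lo, hi = self.ci_lower, self.ci_upper
        p = lo.p
        names = lo.taxa or tuple(f"taxon{i+1}" for i in range(p))
        for i in range(p):
            rows.append(("A", names[i], "", lo.A[i], hi.A[i]))
        for i in range(p):
            for j in range(p):
                rows.append(("B", names[i], names[j], lo.B[i, j], hi.B[i, j]))
        for i in range(p):
            for j in range(i, p):
                rows.append(("Sigma", names[i], names[j],
                             lo.Sigma[i, j], hi.Sigma[i, j]))
        return pd.DataFrame(
            rows, columns=["parameter", "taxon_i", "taxon_j",
                           "ci_2.5%", "ci_97.5%"]
        )


class MARModel:
    """MAR(1) Gompertz community model built from a log-abundance matrix.

    Parameters
    ----------
    endog : (p, n) array_like or CommunityTimeSeries
        Complete (no missing cells, single replicate layer) natural-log
        abundances; typically the output of
        :func:`marstab.statespace.denoise_community`.
    taxa : sequence of str, optional

    Examples
    --------
    >>> model = MARModel(log_abundance, taxa=["Lactobacillus", "other"])
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, endog, taxa: Sequence[str] | None = None):
        if isinstance(endog, CommunityTimeSeries):
            if endog.m != 1 or endog.missing_mask.any():
                raise ValidationError(
                    "CommunityTimeSeries input must be denoised "
                    "(single replicate layer, no missing cells)"
                )
            taxa = taxa or endog.taxa
            X = endog.log_abundance[:, :, 0]
        else:
            X = np.asarray(endog, dtype=float)
        if X.ndim != 2:
            raise ValidationError("endog must be a 2-D taxa x time matrix")
        if np.any(~np.isfinite(X)):
            raise ValidationError("endog must be complete and finite")
        p, n = X.shape
        info = check_design(p, n, 1)
        if not info.feasible:
            raise DesignError(
                f"series of length {n} cannot support a {p}-taxon MAR fit: "
                f"need at least {info.min_length} days "
                f"({info.n_params} parameters vs {info.n_datapoints} points)"
            )
        self.endog = X
        self.taxa = tuple(taxa) if taxa is not None else None
        self.design_info = info

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "MARModel":
        """Build from a wide frame with taxa as index and days as columns."""
        return cls(frame.to_numpy(dtype=float), taxa=list(frame.index))

    def fit(self, sigma_divisor: str = "n-1") -> "MARResults":
        """Estimate (A, B, Sigma) by conditional least squares.

        Parameters
        ----------
        sigma_divisor : {"n-1", "n-p-2"}
            Divisor of the residual cross-products: the number of
            transitions (conditional ML, default) or a degrees-of-freedom
            corrected value.
        """
        X = self.endog
        p, n = X.shape
        Z = np.column_stack([np.ones(n - 1), X[:, :-1].T])   # (n-1, p+1)
        Y = X[:, 1:].T                                       # (n-1, p)
        rank = np.linalg.matrix_rank(Z)
        if rank < p + 1:
            offenders = _collinear_taxa(Z, self.taxa)
            raise NumericalError(
                "lagged predictors are collinear (rank "
                f"{rank} < {p + 1}); offending taxa: {offenders}"
            )
        coef, *_ = np.linalg.lstsq(Z, Y, rcond=None)         # (p+1, p)
        A = coef[0]
        B = coef[1:].T
        resid = (Y - Z @ coef).T                             # (p, n-1)
        if sigma_divisor == "n-1":
            div = n - 1
        elif sigma_divisor == "n-p-2":
            div = n - p - 2
        else:
            raise ValidationError(f"unknown sigma_divisor {sigma_divisor!r}")
        Sigma = resid @ resid.T / div
        Sigma = (Sigma + Sigma.T) / 2.0
        params = MARParameters(A=A, B=B, Sigma=Sigma, taxa=self.taxa)
        llf = conditional_loglik(X, params)
        return MARResults(model=self, params=params, resid=resid, llf=llf)


def _collinear_taxa(Z, taxa):
    """Names of lagged-predictor columns involved in a rank deficiency."""
    _, _, piv = linalg.qr(Z, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(Z)
    cols = [c - 1 for c in piv[rank:] if c > 0]   # column 0 is the intercept
    if taxa:
        return [taxa[c] for c in cols]
    return [f"taxon{c + 1}" for c in cols]


def conditional_loglik(X: np.ndarray, params: MARParameters) -> float:
    """Gaussian log-likelihood of the transitions, conditional on X_1.

    Returns NaN when Sigma is singular (e.g. a perfect noiseless fit).
    """
    X = np.asarray(X, dtype=float)
    E = X[:, 1:] - (params.A[:, None] + params.B @ X[:, :-1])
    sign, logdet = np.linalg.slogdet(params.Sigma)
    if sign <= 0:
        return float("nan")
    p, k = E.shape
    quad = np.sum(E * linalg.solve(params.Sigma, E, assume_a="pos"))
    return -0.5 * (k * (p * np.log(2.0 * np.pi) + logdet) + quad)


@dataclass(frozen=True)
class MARResults:
    """CLS estimates of a MAR(1) model, with optional bootstrap intervals."""

    model: MARModel
    params: MARParameters
    resid: np.ndarray
    llf: float
    bootstrap_result: BootstrapResult = field(default=None)

    @property
    def design(self) -> DesignInfo:
        return self.model.design_info

    # -- downstream analyses -------------------------------------------
    def stability(self, **kwargs):
        """Stochastic-stability metrics of the fitted community."""
        from .stability import stability_metrics
        return stability_metrics(self.params, **kwargs)

    def simulate(self, n_steps, n_reps=1, seed=None, x0=None):
        """Simulate forward from the fitted parameters."""
        if x0 is None:
            x0 = self.model.endog[:, -1]
        return simulate_mar(self.params, x0, n_steps, n_reps, seed)

    def rpm_curve(self, spec=None, seed=None):
        """Prospective persistence (RPM) curve under the fitted parameters."""
        from .persistence import PersistenceSpec, rpm_curve
        return rpm_curve(self.params, spec or PersistenceSpec(), seed=seed)

    # -- bootstrap ------------------------------------------------------
    def bootstrap(self, n_boot: int = 500, seed: int | None = None,
                  denoise_fits=None, m: int = 1,
                  ci_method: str = "basic",
                  max_fail_frac: float = 0.2) -> "MARResults":
        """Parametric bootstrap; returns a copy carrying the intervals."""
        boot = bootstrap_mar(
            self, denoise_fits=denoise_fits, n_boot=n_boot, seed=seed,
            m=m, ci_method=ci_method, max_fail_frac=max_fail_frac,
        )
        return MARResults(model=self.model, params=self.params,
                          resid=self.resid, llf=self.llf,
                          bootstrap_result=boot)

    # -- reporting ------------------------------------------------------
    def coef_frame(self) -> pd.DataFrame:
        names = self.params.taxa or tuple(
            f"taxon{i+1}" for i in range(self.params.p)
        )
        df = pd.DataFrame(self.params.B, index=names,
                          columns=[f"lag({t})" for t in names])
        df.insert(0, "A", self.params.A)
        return df

    def summary(self) -> str:
        p = self.params.p
        names = self.params.taxa or tuple(f"taxon{i+1}" for i in range(p))
        d = self.design
        out = [
            "MAR(1) Gompertz community model — conditional least squares",
            "=" * 64,
            f"taxa: {p}   days: {d.n}   transitions: {d.n - 1}",
            f"parameters: {d.n_params}   data points: {d.n_datapoints}"
            f"   feasible: {d.feasible}",
            f"conditional log-likelihood: {self.llf:.4f}",
            "",
            "growth rates A and interaction matrix B (rows: response taxon)",
        ]
        head = f"{'':<16}{'A':>10}" + "".join(f"{t[:10]:>12}" for t in names)
        out.append(head)
        for i, t in enumerate(names):
            row = f"{t[:15]:<16}{self.params.A[i]:>10.4f}" + "".join(
                f"{self.params.B[i, j]:>12.4f}" for j in range(p)
            )
            out.append(row)
        out.append("")
        out.append("environmental covariance Sigma")
        for i, t in enumerate(names):
            out.append(f"{t[:15]:<16}" + "".join(
                f"{self.params.Sigma[i, j]:>12.5f}" for j in range(p)
            ))
        if self.bootstrap_result is not None:
            br = self.bootstrap_result
            out += ["", f"bootstrap: {br.n_ok}/{br.n_requested} replicates "
                        f"(95% percentile intervals available via "
                        f".bootstrap_result.ci_table())"]
        return "\n".join(out)


def fit_mar_cls(log_abundance, taxa=None) -> MARResults:
    """Fit a MAR(1) model by conditional least squares (thin wrapper)."""
    return MARModel(log_abundance, taxa=taxa).fit()


def bootstrap_mar(
    fit: MARResults,
    denoise_fits=None,
    n_boot: int = 500,
    seed: int | None = None,
    m: int = 1,
    ci_method: str = "basic",
    max_fail_frac: float = 0.2,
) -> BootstrapResult:
    """Parametric bootstrap of a CLS fit, optionally through the obs stage.

    Each replicate simulates a synthetic dataset from the fitted
    generative chain: MAR process noise from ``fit.params`` (started at
    the observed first state), then — when ``denoise_fits`` (the stage-1
    :class:`~marstab.statespace.StateSpaceFit` list) is given — per-taxon
    Gaussian observation noise with ``m`` replicate layers, followed by
    re-denoising.  The CLS fit is re-run on each replicate and 95%
    intervals are formed from the 2.5/97.5 replicate percentiles —
    reflected about the estimate by default (``ci_method="basic"``),
    or used directly (``ci_method="percentile"``).  Replicate-level
    failures are logged and skipped, with an error if more than
    ``max_fail_frac`` fail.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    X = fit.model.endog
    p, n = X.shape
    params = fit.params
    rng = np.random.default_rng(seed)
    obs_vars = None
    if denoise_fits is not None:
        if len(denoise_fits) != p:
            raise ValidationError("need one StateSpaceFit per taxon")
        obs_vars = np.array([f.obs_var for f in denoise_fits])
    reps: list[MARParameters] = []
    n_failed = 0
    for b in range(n_boot):
        states = np.empty((p, n))
        states[:, 0] = X[:, 0]
        states[:, 1:] = simulate_mar(params, X[:, 0], n - 1, 1, rng)[0]
        try:
            if obs_vars is None:
                refit = fit_mar_cls(states, taxa=fit.params.taxa)
            else:
                noise = rng.standard_normal((p, n, m)) * \
                    np.sqrt(obs_vars)[:, None, None]
                obs = states[:, :, None] + noise
                from .statespace import denoise_community
                series = CommunityTimeSeries(
                    subject_id="bootstrap", taxa=fit.params.taxa or
                    tuple(f"taxon{i+1}" for i in range(p)),
                    times=np.arange(n), log_abundance=obs,
                )
                denoised, _ = denoise_community(series)
                refit = fit_mar_cls(denoised.log_abundance[:, :, 0],
                                    taxa=fit.params.taxa)
        except (ValidationError, NumericalError) as exc:
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            continue
        reps.append(refit.params)
    if n_failed > max_fail_frac * n_boot:
        raise NumericalError(
            f"{n_failed}/{n_boot} bootstrap replicates failed "
            f"(> {max_fail_frac:.0%})"
        )
    As = np.stack([r.A for r in reps])
    Bs = np.stack([r.B for r in reps])
    Ss = np.stack([r.Sigma for r in reps])
    bounds = {}
    for name, draws, est in (("A", As, params.A), ("B", Bs, params.B),
                             ("Sigma", Ss, params.Sigma)):
        qlo, qhi = np.percentile(draws, [2.5, 97.5], axis=0)
        if ci_method == "percentile":
            bounds[name] = (qlo, qhi)
        elif ci_method == "basic":
            # reflected interval 2*est - q: corrects the small-sample
            # downward bias of autoregressive CLS estimates
            bounds[name] = (2.0 * est - qhi, 2.0 * est - qlo)
        else:
            raise ValidationError(f"unknown ci_method {ci_method!r}")
    lo = ParameterBounds(bounds["A"][0], bounds["B"][0], bounds["Sigma"][0],
                         params.taxa)
    hi = ParameterBounds(bounds["A"][1], bounds["B"][1], bounds["Sigma"][1],
                         params.taxa)
    return BootstrapResult(
        replicates=tuple(reps), ci_lower=lo, ci_upper=hi,
        n_requested=n_boot, n_failed=n_failed, ci_method=ci_method,
        seed=seed,
    )
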