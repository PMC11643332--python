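"""Monte-Carlo persistence probabilities (RPM and VPM) and counterfactuals.

The prospective Risk Prediction Monitoring (RPM) tool asks: starting a
two-group community (a focal group such as pooled *Lactobacillus* versus
everything else) from a common state, what is the probability on each
forecast day that the focal group's relative abundance stays above a
threshold?  Trajectories are simulated from fitted MAR(1) parameters and
the per-day fraction above threshold is reported, either as a marginal
probability ("above the threshold on day t") or as a first-passage
probability ("above the threshold on every day up to t").

The retrospective Viability/Population Monitoring (VPM) procedure refits
the model on a growing data prefix and, after each new day, projects a
fixed window ahead and records the within-window probability that the
focal proportion crashes below the threshold.

Two counterfactual experiments probe which coefficients drive a
persistence trend: flipping the signs of a pair of interspecific
interaction coefficients, and boosting a group's intrinsic growth rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import CommunityTimeSeries, check_design
from .exceptions import NonStationaryError, ValidationError
from .process import (MARParameters, is_stationary, simulate_mar,
                      stationary_mean)

__all__ = ["PersistenceSpec", "PersistenceCurve", "rpm_curve", "vpm_series",
           "flip_interactions", "boost_growth"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PersistenceSpec:
    """Settings for a persistence computation.

    Defaults follow the prospective RPM convention: a 0.45 relative-
    abundance threshold watched over 20 forecast days with 50,000
    trajectories, both groups started at the focal group's stationary-
    mean abundance (so the starting proportion is 50%).  The
    retrospective VPM convention uses threshold 0.50 over a 10-day
    window.
    """

    focal_group: str | int = 0
    threshold: float = 0.45
    horizon: int = 20
    n_traj: int = 50_000
    mode: str = "marginal"            # "marginal" | "first_passage"
    start_rule: str = "stationary_equal"  # or "observed"

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must be in (0, 1)")
        if self.horizon < 1 or self.n_traj < 1:
            raise ValidationError("horizon and n_traj must be >= 1")
        if self.mode not in ("marginal", "first_passage"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.start_rule not in ("stationary_equal", "observed"):
            raise ValidationError(f"unknown start_rule {self.start_rule!r}")

    @classmethod
    def vpm_defaults(cls, **kwargs) -> "PersistenceSpec":
        base = dict(threshold=0.50, horizon=10, mode="first_passage",
                    start_rule="observed")
        base.update(kwargs)
        return cls(**base)


@dataclass(frozen=True)
class PersistenceCurve:
    """Per-forecast-day persistence probabilities for the focal group."""

    probabilities: np.ndarray
    spec: PersistenceSpec
    params: MARParameters
    seed: int = None

    @property
    def days(self) -> np.ndarray:
        return np.arange(1, len(self.probabilities) + 1)

    def minimum(self) -> float:
        return float(np.min(self.probabilities))


def _focal_index(params: MARParameters, focal) -> int:
    if isinstance(focal, (int, np.integer)):
        if not 0 <= focal < params.p:
            raise ValidationError(f"focal index {focal} out of range")
        return int(focal)
    if params.taxa is None or focal not in params.taxa:
        raise ValidationError(f"unknown focal group {focal!r}")
    return params.taxa.index(focal)


def _focal_proportions(traj: np.ndarray, focal: int) -> np.ndarray:
    """(n_reps, n_steps) focal-group proportions on the natural scale."""
    # subtract the running max log abundance before exponentiating so a
    # transiently explosive counterfactual cannot overflow
    shifted = traj - traj.max(axis=1, keepdims=True)
    nat = np.exp(shifted)
    return nat[:, focal, :] / nat.sum(axis=1)


def rpm_curve(
    params: MARParameters,
    spec: PersistenceSpec | None = None,
    seed: int | None = None,
    x0=None,
) -> PersistenceCurve:
    """Prospective persistence curve for a two-group community.

    Under the default ``stationary_equal`` start rule both groups begin
    at the focal group's stationary-mean log abundance (a 50% starting
    proportion); ``observed`` requires an explicit ``x0``.  An explicit
    ``x0`` always takes precedence — counterfactual experiments (sign
    flips, growth boosts) restart the modified model from the *baseline*
    model's stationary start so curves are comparable.  Ties at exactly
    the threshold count as persisting.

    Returns
    -------
    PersistenceCurve
        ``probabilities[t-1]`` = P(focal proportion >= threshold on day t)
        (marginal mode) or P(on every day up to t) (first-passage mode).
    """
    spec = spec or PersistenceSpec()
    if params.p != 2:
        raise ValidationError(
            "RPM requires a 2-group model (focal vs pooled rest); "
            f"got p={params.p}"
        )
    focal = _focal_index(params, spec.focal_group)
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
    elif spec.start_rule == "stationary_equal":
        ok, rho = is_stationary(params)
        if not ok:
            raise NonStationaryError(rho)
        mu = stationary_mean(params)
        x0 = np.full(2, mu[focal])
    else:
        raise ValidationError("start_rule 'observed' requires x0")
    traj = simulate_mar(params, x0, spec.horizon, spec.n_traj, seed)
    prop = _focal_proportions(traj, focal)
    above = prop >= spec.threshold
    if spec.mode == "first_passage":
        above = np.logical_and.accumulate(above, axis=1)
    probs = above.mean(axis=0)
    return PersistenceCurve(probabilities=probs, spec=spec, params=params,
                            seed=seed)


def vpm_series(
    observed: CommunityTimeSeries | np.ndarray,
    spec: PersistenceSpec | None = None,
    fit_start: int = 30,
    seed: int | None = None,
    taxa=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective rolling crash-risk series (the VPM procedure).

    For each day ``d`` from ``fit_start`` to the end of the series, the
    MAR model is refitted on the data up to ``d``, ``spec.horizon`` days
    are projected from the state observed at ``d``, and the within-window
    probability that the focal proportion drops below ``spec.threshold``
    (the complement of first-passage persistence) is recorded.

    Parameters
    ----------
    observed : CommunityTimeSeries (complete, m=1) or (2, n) array
        Denoised two-group log abundances.
    fit_start : int
        First evaluation day (1-based position in the series).

    Returns
    -------
    (days, risks)
        Evaluation-day indices and the matching crash probabilities.
        Infeasible prefixes are skipped with a warning.
    """
    spec = spec or PersistenceSpec.vpm_defaults()
    if isinstance(observed, CommunityTimeSeries):
        if observed.m != 1 or observed.missing_mask.any():
            raise ValidationError("vpm_series needs a denoised series")
        X = observed.log_abundance[:, :, 0]
        taxa = taxa or observed.taxa
    else:
        X = np.asarray(observed, dtype=float)
    p, n = X.shape
    if p != 2:
        raise ValidationError(f"VPM requires a 2-group model, got p={p}")
    focal = 0 if taxa is None else _focal_index(
        MARParameters(np.zeros(2), np.zeros((2, 2)), np.zeros((2, 2)),
                      taxa=taxa),
        spec.focal_group,
    )
    from .model import fit_mar_cls

    rng = np.random.default_rng(seed)
    days, risks = [], []
    for d in range(fit_start, n + 1):
        if not check_design(p, d, 1).feasible:
            logger.warning("day %d: prefix infeasible for a %d-taxon fit",
                           d, p)
            continue
        res = fit_mar_cls(X[:, :d], taxa=taxa)
        traj = simulate_mar(res.params, X[:, d - 1], spec.horizon,
                            spec.n_traj, rng)
        prop = _focal_proportions(traj, focal)
        crashed = np.any(prop < spec.threshold, axis=1)
        days.append(d)
        risks.append(float(crashed.mean()))
    if not days:
        raise ValidationError(
            "no evaluation day had a feasible fitting prefix"
        )
    return np.asarray(days), np.asarray(risks)


def flip_interactions(params: MARParameters, i: int, j: int) -> MARParameters:
    """Switch the signs of the reciprocal interaction pair (b_ij, b_ji).

    Growth rates, diagonals and Sigma are untouched.  Applying the
    operation twice restores the original parameters.
    """
    if i == j:
        raise ValidationError("flip_interactions needs two distinct taxa")
    for idx in (i, j):
        if not 0 <= idx < params.p:
            raise ValidationError(f"taxon index {idx} out of range")
    B = params.B.copy()
    B[i, j] = -B[i, j]
    B[j, i] = -B[j, i]
    return MARParameters(A=params.A, B=B, Sigma=params.Sigma,
                         taxa=params.taxa)


def boost_growth(params: MARParameters, taxon: int, factor: float
                 ) -> MARParameters:
    """Scale one taxon's intrinsic growth rate by ``factor`` (> 0)."""
    if factor <= 0:
        raise ValidationError("factor must be positive")
    if not 0 <= taxon < params.p:
        raise ValidationError(f"taxon index {taxon} out of range")
    A = params.A.copy()
    A[taxon] = A[taxon] * factor
    return MARParameters(A=A, B=params.B, Sigma=params.Sigma,
                         taxa=params.taxa)
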