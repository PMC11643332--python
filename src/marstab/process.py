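"""The MAR(1) stochastic Gompertz community process.

The model for the vector of log abundances ``X_t`` of ``p`` interacting
taxa is the linear first-order Markov recursion

    X_t = A + B X_{t-1} + E_t,      E_t ~ i.i.d. N(0, Sigma)

where ``A`` holds per-taxon intrinsic growth rates (natural-log units per
day), ``B`` is the interaction matrix whose entry ``b_ij`` is the effect
of taxon *j*'s log abundance on the growth of taxon *i* (diagonals measure
density dependence; values near 1 mean weak density dependence), and
``Sigma`` is the covariance of shared environmental growth-rate shocks.

When the spectral radius of ``B`` is below one the process is stationary
with mean ``(I - B)^{-1} A`` and covariance solving the discrete Lyapunov
equation ``V = B V B' + Sigma``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg

from .exceptions import NonStationaryError, ValidationError

__all__ = [
    "MARParameters",
    "StationaryMoments",
    "is_stationary",
    "stationary_mean",
    "stationary_covariance",
    "stationary_moments",
    "simulate_mar",
]

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class MARParameters:
    """Parameters (A, B, Sigma) of a MAR(1) Gompertz process.

    Parameters
    ----------
    A : (p,) array_like
        Intrinsic growth rates, log-abundance units per day.
    B : (p, p) array_like
        Interaction matrix; ``B[i, j]`` is the effect of taxon ``j`` on
        the growth rate of taxon ``i``.
    Sigma : (p, p) array_like
        Symmetric positive-semidefinite environmental covariance.
    taxa : sequence of str, optional
        Taxon (or group) names, length ``p``.
    """

    A: np.ndarray
    B: np.ndarray
    Sigma: np.ndarray
    taxa: tuple = field(default=None)

    def __post_init__(self):
        A = np.atleast_1d(np.asarray(self.A, dtype=float))
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        p = A.shape[0]
        if A.ndim != 1:
            raise ValidationError("A must be a 1-D vector")
        if B.shape != (p, p):
            raise ValidationError(f"B must be {p}x{p}, got {B.shape}")
        if Sigma.shape != (p, p):
            raise ValidationError(f"Sigma must be {p}x{p}, got {Sigma.shape}")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))
                and np.all(np.isfinite(Sigma))):
            raise ValidationError("A, B and Sigma must be finite")
        if not np.allclose(Sigma, Sigma.T, atol=_SYM_TOL):
            raise ValidationError("Sigma must be symmetric (tol 1e-10)")
        Sigma = (Sigma + Sigma.T) / 2.0
        if np.min(linalg.eigvalsh(Sigma)) < -_SYM_TOL:
            raise ValidationError("Sigma must be positive semidefinite")
        taxa = self.taxa
        if taxa is not None:
            taxa = tuple(str(t) for t in taxa)
            if len(taxa) != p:
                raise ValidationError("taxa must have length p")
        for name, val in (("A", A), ("B", B), ("Sigma", Sigma), ("taxa", taxa)):
            object.__setattr__(self, name, val)
        A.flags.writeable = False
        B.flags.writeable = False
        Sigma.flags.writeable = False

    @property
    def p(self) -> int:
        """Number of taxa."""
        return self.A.shape[0]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "Sigma": self.Sigma.tolist(),
            "taxa": list(self.taxa) if self.taxa is not None else None,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "MARParameters":
        return cls(A=d["A"], B=d["B"], Sigma=d["Sigma"], taxa=d.get("taxa"))

    @classmethod
    def from_json(cls, source: str) -> "MARParameters":
        try:
            d = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class StationaryMoments:
    """Long-run mean and covariance of a stationary MAR(1) process."""

    mean: np.ndarray
    covariance: np.ndarray


def is_stationary(params: MARParameters) -> tuple[bool, float]:
    """Whether the process is stationary, plus the spectral radius of B.

    Returns
    -------
    (bool, float)
        ``True`` iff ``max_i |lambda_i(B)| < 1``, and that maximum modulus.
    """
    rho = float(np.max(np.abs(np.linalg.eigvals(params.B))))
    return rho < 1.0, rho


def _require_stationary(params: MARParameters) -> None:
    ok, rho = is_stationary(params)
    if not ok:
        raise NonStationaryError(rho)


def stationary_mean(params: MARParameters) -> np.ndarray:
    """Stationary mean ``mu = (I - B)^{-1} A`` of the log abundances."""
    _require_stationary(params)
    p = params.p
    return linalg.solve(np.eye(p) - params.B, params.A)


def stationary_covariance(params: MARParameters) -> np.ndarray:
    """Stationary covariance ``V`` solving ``V = B V B' + Sigma``.

    Equivalent to ``vec(V) = (I - B (x) B)^{-1} vec(Sigma)``; in one
    dimension this is the familiar ``sigma^2 / (1 - b^2)``.
    """
    _require_stationary(params)
    V = linalg.solve_discrete_lyapunov(params.B, params.Sigma)
    return (V + V.T) / 2.0


def stationary_moments(params: MARParameters) -> StationaryMoments:
    """Stationary mean and covariance in one call."""
    return StationaryMoments(
        mean=stationary_mean(params), covariance=stationary_covariance(params)
    )


def _psd_factor(Sigma: np.ndarray) -> np.ndarray:
    """A matrix L with L L' = Sigma, valid for singular Sigma too."""
    try:
        return np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        w, Q = linalg.eigh(Sigma)
        w = np.clip(w, 0.0, None)
        return Q * np.sqrt(w)


def simulate_mar(
    params: MARParameters,
    x0: Sequence[float],
    n_steps: int,
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate MAR(1) trajectories by direct recursion.

    Parameters
    ----------
    params : MARParameters
    x0 : (p,) array_like
        Initial log abundances (time 0; not included in the output).
    n_steps : int
        Number of forward steps.
    n_reps : int
        Number of independent trajectories.
    seed : int, Generator or None
        Seed for reproducibility; a single integer fully determines the
        output.

    Returns
    -------
    ndarray, shape (n_reps, p, n_steps)
        Simulated log abundances for steps 1..n_steps.

    Notes
    -----
    Nonstationary ``B`` is allowed: finite-horizon projections (e.g. the
    interaction sign-flip experiment) do not require stationarity.
    """
    if n_steps < 1 or n_reps < 1:
        raise ValidationError("n_steps and n_reps must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    p = params.p
    if x0.shape != (p,):
        raise ValidationError(f"x0 must have shape ({p},), got {x0.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _psd_factor(params.Sigma)
    out = np.empty((n_reps, p, n_steps))
    x = np.broadcast_to(x0, (n_reps, p)).copy()
    A, B = params.A, params.B
    for t in range(n_steps):
        shocks = rng.standard_normal((n_reps, p)) @ L.T
        x = A + x @ B.T + shocks
        out[:, :, t] = x
    return out
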