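"""Stochastic-stability metrics and community classification.

For a stationary MAR(1) process with interaction matrix ``B`` and
environmental covariance ``Sigma`` (stationary covariance ``V``), four
standardised metrics describe how the community filters environmental
variance; for every one of them lower values mean higher stochastic
stability:

variance proportion
    ``VP = det(B)^(2/p)``, the geometric-mean squared eigenvalue of B:
    how much species interactions amplify environmental variance into
    long-run population variance.
mean / variance return rates
    ``MR = max |lambda(B)|`` and ``VR = max |lambda(B (x) B)| = MR^2``:
    spectral rates at which the mean and variance of the transition
    distribution converge to stationarity (return *times* are
    ``-1 / log(rate)``).
reactivity
    how strongly the system moves away from equilibrium right after a
    perturbation; worst-case ``lambda_max(B'B) - 1`` over perturbation
    directions, or expected over the stationary distribution,
    ``-tr(Sigma) / tr(V)``.

Communities are classified by z-scoring the four metrics, projecting by
PCA and k-means clustering the scores into ordered categories from
"highly stable" to "highly unstable".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .exceptions import NonStationaryError, ValidationError
from .process import MARParameters, is_stationary, stationary_covariance

__all__ = ["StabilityMetrics", "stability_metrics", "classify_communities",
           "STABILITY_LABELS"]

STABILITY_LABELS = ("highly stable", "stable", "unstable", "highly unstable")


@dataclass(frozen=True)
class StabilityMetrics:
    """The four stochastic-stability metrics of one fitted community.

    ``reactivity_expected`` is None when Sigma = 0 (undefined).
    """

    variance_proportion: float
    mean_return_rate: float
    variance_return_rate: float
    reactivity_worst: float
    reactivity_expected: float | None

    @property
    def mean_return_time(self) -> float:
        """-1/log(MR); time for the transition mean to contract by e."""
        return -1.0 / np.log(self.mean_return_rate)

    @property
    def variance_return_time(self) -> float:
        return -1.0 / np.log(self.variance_return_rate)

    def to_dict(self) -> dict:
        return {
            "variance_proportion": self.variance_proportion,
            "mean_return_rate": self.mean_return_rate,
            "variance_return_rate": self.variance_return_rate,
            "reactivity_worst": self.reactivity_worst,
            "reactivity_expected": self.reactivity_expected,
        }


def stability_metrics(params: MARParameters) -> StabilityMetrics:
    """Compute the stochastic-stability metrics of a stationary community.

    Raises
    ------
    NonStationaryError
        If the spectral radius of B is >= 1 (metrics are defined at
        stationarity).
    """
    ok, rho = is_stationary(params)
    if not ok:
        raise NonStationaryError(rho)
    B, Sigma = params.B, params.Sigma
    p = params.p
    vp = float(np.linalg.det(B) ** 2) ** (1.0 / p)
    mr = rho
    # max |lambda(B (x) B)| = (max |lambda(B)|)^2; no need to form the product
    vr = rho * rho
    worst = float(linalg.eigvalsh(B.T @ B)[-1]) - 1.0
    tr_sigma = float(np.trace(Sigma))
    if tr_sigma > 0:
        V = stationary_covariance(params)
        expected = -tr_sigma / float(np.trace(V))
    else:
        expected = None
    return StabilityMetrics(
        variance_proportion=vp,
        mean_return_rate=mr,
        variance_return_rate=vr,
        reactivity_worst=worst,
        reactivity_expected=expected,
    )


def classify_communities(
    metrics_table: pd.DataFrame,
    k: int = 4,
    seed: int | None = None,
    n_init: int = 50,
) -> tuple[pd.Series, dict]:
    """Classify communities into stability categories via PCA + k-means.

    Parameters
    ----------
    metrics_table : DataFrame
        One row per community; columns are stability metrics (typically
        VP, MR, VR and one reactivity variant).  The index identifies
        communities.
    k : int
        Number of clusters (default 4: highly stable ... highly unstable).
    seed : int
        Controls the k-means restarts.

    Returns
    -------
    (labels, pca_summary)
        ``labels`` is a Series of category names aligned with the input
        index; clusters are ordered by ascending mean of the z-scored
        metrics (lower = more stable), ties broken by cluster size.
        ``pca_summary`` holds loadings, explained variance ratios and the
        score matrix.
    """
    df = pd.DataFrame(metrics_table).astype(float)
    if df.shape[0] < k:
        raise ValidationError(
            f"need at least k={k} communities, got {df.shape[0]}"
        )
    if df.isna().any().any():
        raise ValidationError("metrics table contains missing values")
    std = df.std(axis=0, ddof=1)
    dead = std[std == 0].index.tolist()
    if dead:
        raise ValidationError(f"zero-variance metric column(s): {dead}")
    Z = (df - df.mean(axis=0)) / std
    pca = PCA()
    scores = pca.fit_transform(Z.to_numpy())
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=None if seed is None else int(seed))
    raw = km.fit_predict(scores)
    # order clusters: ascending mean z-scored metric = most to least stable
    zmean = np.array([Z.to_numpy()[raw == c].mean() for c in range(k)])
    sizes = np.array([(raw == c).sum() for c in range(k)])
    order = sorted(range(k), key=lambda c: (zmean[c], -sizes[c]))
    if k == len(STABILITY_LABELS):
        names = STABILITY_LABELS
    else:
        names = tuple(f"stability class {i+1}" for i in range(k))
    relabel = {c: names[rank] for rank, c in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=df.index,
                       name="stability_class")
    pca_summary = {
        "loadings": pd.DataFrame(
            pca.components_.T, index=df.columns,
            columns=[f"PC{i+1}" for i in range(pca.components_.shape[0])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "scores": pd.DataFrame(
            scores, index=df.index,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        "inertia": float(km.inertia_),
    }
    return labels, pca_summary
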