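"""Data model and I/O for longitudinal community abundance tables.

The central container is :class:`CommunityTimeSeries`: a taxa x time x
replicate array of natural-log absolute abundances (16S rRNA gene copies)
with an explicit missing-value mask.  Relative abundances from amplicon
profiling are "anchored" to absolute scale by multiplying by per-day total
16S copy counts from qPCR (:func:`anchor_to_absolute`) before logging,
because interaction estimates fitted to compositional data are biased.

Design feasibility: a ``p``-taxon MAR(1) fit estimates ``2 p^2 + p`` free
parameters (growth rates, interactions, environmental covariances) from
``(n - 1) m p`` observed one-day transitions, so :func:`check_design`
reports whether a series of length ``n`` with ``m`` replicates is long
enough, and the minimal feasible length (``2 (p + 1)`` when ``m = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "CommunityTimeSeries",
    "DesignInfo",
    "check_design",
    "anchor_to_absolute",
    "to_log_abundance",
    "pool_taxa",
    "read_tidy_csv",
    "read_wide_csv",
]

DEFAULT_PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# design feasibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignInfo:
    """Feasibility diagnostics for fitting a MAR(1) model.

    ``n_params = 2 p^2 + p`` (A, B and Sigma), ``n_datapoints = (n-1) m p``
    (one-day transitions), ``min_length`` the smallest feasible series
    length and ``feasible`` whether ``n >= min_length``.
    """

    p: int
    n: int
    m: int
    n_params: int
    n_datapoints: int
    min_length: int
    feasible: bool

    def to_dict(self) -> dict:
        return {
            "p": self.p, "n": self.n, "m": self.m,
            "n_params": self.n_params, "n_datapoints": self.n_datapoints,
            "min_length": self.min_length, "feasible": self.feasible,
        }


def check_design(p: int, n: int, m: int = 1) -> DesignInfo:
    """Check whether a (p, n, m) design can support a MAR(1) fit.

    Parameters
    ----------
    p : int
        Number of taxa (or pooled groups).
    n : int
        Series length in days.
    m : int
        Replicate samples per taxon per day.

    Returns
    -------
    DesignInfo

    Examples
    --------
    >>> check_design(13, 70).n_params
    351
    >>> check_design(13, 70).min_length
    28
    """
    for name, v in (("p", p), ("n", n), ("m", m)):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise ValidationError(f"{name} must be an integer, got {v!r}")
    if p < 1 or m < 1:
        raise ValidationError("p and m must be >= 1")
    if n < 2:
        raise ValidationError("n must be >= 2")
    p, n, m = int(p), int(n), int(m)
    n_params = 2 * p * p + p
    n_datapoints = (n - 1) * m * p
    # smallest n with (n-1) m p >= 2 p^2 + p, i.e. n >= (2p+1)/m + 1;
    # equals 2 (p + 1) when m = 1
    min_length = math.ceil((2 * p + 1) / m) + 1
    return DesignInfo(
        p=p, n=n, m=m, n_params=n_params, n_datapoints=n_datapoints,
        min_length=min_length, feasible=n >= min_length,
    )


# ---------------------------------------------------------------------------
# scale conversions
# ---------------------------------------------------------------------------

def anchor_to_absolute(
    relative_abundances: np.ndarray,
    totals: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Convert relative abundances to absolute 16S-copy abundances.

    Entry ``(i, t)`` of the result is ``proportion(i, t) * total(t)``.
    NaN cells are treated as missing and propagate.

    Parameters
    ----------
    relative_abundances : (p, n) array_like
        Per-day proportions; every column with data must sum to 1 within
        ``tol`` (fully-missing columns are exempt).
    totals : (n,) array_like
        Per-day total 16S rRNA gene copy counts, nonnegative.
    """
    rel = np.asarray(relative_abundances, dtype=float)
    tot = np.asarray(totals, dtype=float)
    if rel.ndim != 2:
        raise ValidationError("relative_abundances must be a 2-D taxa x time matrix")
    if tot.shape != (rel.shape[1],):
        raise ValidationError(
            f"totals must have length {rel.shape[1]}, got {tot.shape}"
        )
    if np.any(tot[np.isfinite(tot)] < 0):
        raise ValidationError("totals must be nonnegative")
    col_ok = ~np.all(np.isnan(rel), axis=0)
    sums = np.nansum(rel, axis=0)
    bad = col_ok & (np.abs(sums - 1.0) > tol)
    if np.any(bad):
        day = int(np.nonzero(bad)[0][0])
        raise ValidationError(
            f"relative abundances at day index {day} sum to {sums[day]:.8g}, "
            f"not 1 within {tol}"
        )
    return rel * tot


def to_log_abundance(
    absolute: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of absolute abundances, with a missing mask.

    Exact zeros (sequencing below-detection) are replaced by
    ``pseudocount`` before logging; NaN cells are flagged missing and left
    NaN.  Negative abundances are invalid.

    Returns
    -------
    (log_matrix, missing_mask)
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    x = np.asarray(absolute, dtype=float)
    mask = np.isnan(x)
    if np.any(x[~mask] < 0):
        raise ValidationError("absolute abundances must be nonnegative")
    filled = np.where(mask, np.nan, np.where(x == 0, pseudocount, x))
    with np.errstate(invalid="ignore"):
        logx = np.log(filled)
    return logx, mask


# ---------------------------------------------------------------------------
# the container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityTimeSeries:
    """Longitudinal log-abundance data for one subject's community.

    Parameters
    ----------
    subject_id : str
    taxa : sequence of str, length p
    times : (n,) int array, strictly increasing day indices
    log_abundance : (p, n, m) float array
        Natural-log 16S-copy abundances; replicate layers along the last
        axis.  NaN wherever ``missing_mask`` is true.
    missing_mask : (p, n, m) bool array
    pseudocount : float
        Value substituted for exact zeros before logging.
    """

    subject_id: str
    taxa: tuple
    times: np.ndarray
    log_abundance: np.ndarray
    missing_mask: np.ndarray = None
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    state_variance: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        taxa = tuple(str(t) for t in self.taxa)
        times = np.asarray(self.times, dtype=int)
        X = np.asarray(self.log_abundance, dtype=float)
        if X.ndim == 2:
            X = X[:, :, None]
        p, n, m = X.shape
        if len(taxa) != p:
            raise ValidationError(f"taxa has length {len(taxa)}, expected {p}")
        if len(set(taxa)) != p:
            raise ValidationError("taxon names must be unique")
        if p < 1 or n < 2 or m < 1:
            raise ValidationError("need p >= 1, n >= 2, m >= 1")
        if times.shape != (n,) or np.any(np.diff(times) <= 0):
            raise ValidationError("times must be strictly increasing, length n")
        mask = self.missing_mask
        mask = np.isnan(X) if mask is None else np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[:, :, None]
        if mask.shape != X.shape:
            raise ValidationError("missing_mask shape must match log_abundance")
        mask = mask | np.isnan(X)
        if not np.all(np.isfinite(X[~mask])):
            raise ValidationError("non-missing log abundances must be finite")
        X = np.where(mask, np.nan, X)
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        sv = self.state_variance
        if sv is not None:
            sv = np.asarray(sv, dtype=float)
            if sv.shape != (p, n):
                raise ValidationError("state_variance must be (p, n)")
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "log_abundance", X)
        object.__setattr__(self, "missing_mask", mask)
        object.__setattr__(self, "state_variance", sv)

    # -- basic shape ---------------------------------------------------
    @property
    def p(self) -> int:
        return self.log_abundance.shape[0]

    @property
    def n(self) -> int:
        return self.log_abundance.shape[1]

    @property
    def m(self) -> int:
        return self.log_abundance.shape[2]

    def design(self) -> DesignInfo:
        return check_design(self.p, self.n, self.m)

    # -- constructors --------------------------------------------------
    @classmethod
    def from_absolute(
        cls,
        absolute: np.ndarray,
        taxa: Sequence[str],
        times: Sequence[int] | None = None,
        subject_id: str = "subject",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "CommunityTimeSeries":
        """Build from a (p, n) or (p, n, m) matrix of absolute abundances."""
        absolute = np.asarray(absolute, dtype=float)
        logx, mask = to_log_abundance(absolute, pseudocount)
        if times is None:
            times = np.arange(absolute.shape[1])
        return cls(
            subject_id=subject_id, taxa=tuple(taxa), times=times,
            log_abundance=logx, missing_mask=mask, pseudocount=pseudocount,
        )

    @classmethod
    def from_relative(
        cls,
        relative: np.ndarray,
        totals: np.ndarray,
        taxa: Sequence[str],
        times: Sequence[int] | None = None,
        subject_id: str = "subject",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ) -> "CommunityTimeSeries":
        """Build from proportions + per-day totals ((p, n) or (p, n, m))."""
        relative = np.asarray(relative, dtype=float)
        if relative.ndim == 3:
            totals = np.asarray(totals, dtype=float)
            if totals.ndim == 1:
                totals = np.broadcast_to(totals[:, None], relative.shape[1:])
            absolute = np.stack(
                [anchor_to_absolute(relative[:, :, r], totals[:, r])
                 for r in range(relative.shape[2])],
                axis=2,
            )
        else:
            absolute = anchor_to_absolute(relative, np.asarray(totals, float))
        return cls.from_absolute(
            absolute, taxa, times=times, subject_id=subject_id,
            pseudocount=pseudocount,
        )

    # -- views ---------------------------------------------------------
    def replicate_mean(self) -> np.ndarray:
        """(p, n) mean of non-missing replicate layers (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.log_abundance, axis=2)

    def natural(self) -> np.ndarray:
        """Abundances back on the natural (copy-count) scale."""
        return np.exp(self.log_abundance)

    # -- I/O -----------------------------------------------------------
    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format frame: subject, day, taxon, replicate, log_abundance."""
        p, n, m = self.log_abundance.shape
        idx = pd.MultiIndex.from_product(
            [self.taxa, self.times, range(1, m + 1)],
            names=["taxon", "day", "replicate"],
        )
        df = pd.DataFrame(
            {"log_abundance": self.log_abundance.reshape(-1)}, index=idx
        ).reset_index()
        df.insert(0, "subject", self.subject_id)
        return df

    def to_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def pool_taxa(
    series: CommunityTimeSeries,
    grouping: Mapping[str, str],
) -> CommunityTimeSeries:
    """Pool taxa into ecological groups by summing natural-scale abundances.

    Every taxon must map to exactly one group label; the pooled
    log abundance of a group is ``log(sum_i exp(x_i))`` over its members,
    and a pooled cell is missing iff any member cell is missing.  Supports
    e.g. the 2-group *Lactobacillus* vs rest and the 3-group
    *Lactobacillus* / *G. vaginalis* / rest model variants.

    Group order follows first appearance in ``series.taxa``.
    """
    missing = [t for t in series.taxa if t not in grouping]
    if missing:
        raise ValidationError(f"taxa not assigned to any group: {missing}")
    groups: list[str] = []
    for t in series.taxa:
        g = grouping[t]
        if g not in groups:
            groups.append(g)
    X = series.natural()          # NaN propagates through the sums
    pooled = np.empty((len(groups), series.n, series.m))
    for gi, g in enumerate(groups):
        members = [i for i, t in enumerate(series.taxa) if grouping[t] == g]
        pooled[gi] = X[members].sum(axis=0)
    with np.errstate(invalid="ignore"):
        logp = np.log(pooled)
    return CommunityTimeSeries(
        subject_id=series.subject_id, taxa=tuple(groups), times=series.times,
        log_abundance=logp, pseudocount=series.pseudocount,
    )


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_tidy_csv(
    path,
    subject: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CommunityTimeSeries:
    """Read a tidy long-format abundance table.

    Expected columns: ``subject, day, taxon, relative_abundance,
    replicate, total_16S_copies``.  Missing cells may be absent rows or
    empty/NA values.  Days with gaps become explicit missing columns so
    the one-day Markov transition structure is preserved.
    """
    df = pd.read_csv(path)
    required = {"subject", "day", "taxon", "relative_abundance",
                "replicate", "total_16S_copies"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"tidy table must have columns {sorted(required)}"
        )
    if subject is not None:
        df = df[df["subject"].astype(str) == str(subject)]
    subjects = df["subject"].unique()
    if len(subjects) != 1:
        raise ValidationError(
            f"expected one subject, found {len(subjects)}; pass subject="
        )
    taxa = list(pd.unique(df["taxon"]))
    days = np.arange(int(df["day"].min()), int(df["day"].max()) + 1)
    reps = sorted(df["replicate"].unique())
    p, n, m = len(taxa), len(days), len(reps)
    rel = np.full((p, n, m), np.nan)
    tot = np.full((n, m), np.nan)
    ti = {t: i for i, t in enumerate(taxa)}
    di = {d: i for i, d in enumerate(days)}
    ri = {r: i for i, r in enumerate(reps)}
    for row in df.itertuples(index=False):
        i, j, r = ti[row.taxon], di[int(row.day)], ri[row.replicate]
        rel[i, j, r] = row.relative_abundance
        tot[j, r] = row.total_16S_copies
    return CommunityTimeSeries.from_relative(
        rel, tot, taxa, times=days, subject_id=str(subjects[0]),
        pseudocount=pseudocount,
    )


def read_wide_csv(
    matrix_path,
    totals_path,
    subject_id: str = "subject",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CommunityTimeSeries:
    """Read a wide taxa x day proportions matrix plus a per-day totals table.

    The matrix CSV has taxa as the index column and day indices as column
    headers; the totals CSV has columns ``day, total_16S_copies``.
    """
    mat = pd.read_csv(matrix_path, index_col=0)
    totals = pd.read_csv(totals_path)
    days = np.asarray([int(c) for c in mat.columns])
    tot = (
        totals.set_index("day")["total_16S_copies"]
        .reindex(days).to_numpy(dtype=float)
    )
    return CommunityTimeSeries.from_relative(
        mat.to_numpy(dtype=float), tot, list(mat.index), times=days,
        subject_id=subject_id, pseudocount=pseudocount,
    )
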