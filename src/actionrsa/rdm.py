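"""Representational dissimilarity matrices (RDMs) and rank statistics.

An RDM stores the pairwise dissimilarities between ``n_items`` stimuli as a
condensed vector over the upper triangle (row-major, the scipy ``pdist``
convention) together with a per-pair *evidence* vector: a nonnegative count or
weight recording how many (or how strongly) independent estimates back each
pair.  Evidence is what lets partial designs — where each participant only
arranged a subset of the stimuli — be averaged without bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau as _kendalltau

__all__ = [
    "RDM",
    "RankCorrelation",
    "make_rdm",
    "condensed_index",
    "condensed_pair",
    "n_pairs",
    "euclidean_rdm",
    "categorical_rdm",
    "kendall_tau_a",
    "kendall_tau",
    "average_rdms",
    "variance_inflation_factors",
    "read_rdm_csv",
    "write_rdm_csv",
]

METRIC_TAGS = ("euclidean", "categorical", "accuracy", "arrangement", "other")


def n_pairs(n_items: int) -> int:
    """Number of unordered item pairs, ``n(n-1)/2``."""
    return n_items * (n_items - 1) // 2


@dataclass
class RDM:
    """Condensed dissimilarity vector with per-pair evidence.

    Attributes
    ----------
    values : (n_pairs,) float array of dissimilarities.
    n_items : number of stimuli.
    evidence : (n_pairs,) nonnegative weights; zero marks an unmeasured pair.
    metric_tag : one of ``euclidean|categorical|accuracy|arrangement|other``.
    """

    values: np.ndarray
    n_items: int
    evidence: np.ndarray = None  # type: ignore[assignment]
    metric_tag: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        m = n_pairs(self.n_items)
        if self.values.shape[0] != m:
            raise ValueError(
                f"expected {m} pairs for n_items={self.n_items}, "
                f"got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("RDM values must be finite")
        if self.evidence is None:
            self.evidence = np.ones(m)
        else:
            self.evidence = np.asarray(self.evidence, dtype=float).ravel()
            if self.evidence.shape[0] != m:
                raise ValueError("evidence length does not match pair count")
            if np.any(self.evidence < 0):
                raise ValueError("evidence must be nonnegative")
        if self.metric_tag not in METRIC_TAGS:
            raise ValueError(f"unknown metric_tag {self.metric_tag!r}")
        if self.metric_tag == "categorical" and not np.all(
            np.isin(self.values, (0.0, 1.0))
        ):
            raise ValueError("categorical RDM values must be 0 or 1")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def square(self) -> np.ndarray:
        """Full symmetric matrix form (zero diagonal)."""
        return squareform(self.values)

    def covered(self) -> np.ndarray:
        """Boolean mask of pairs with positive evidence."""
        return self.evidence > 0

    def copy(self) -> "RDM":
        return replace(self, values=self.values.copy(), evidence=self.evidence.copy())


@dataclass
class RankCorrelation:
    """Kendall τA and the pair count it was computed over."""

    tau_a: float
    n_pairs_compared: int

    def __post_init__(self) -> None:
        if abs(self.tau_a) > 1 + 1e-12:
            raise ValueError("|tau_a| must be <= 1")

    def __float__(self) -> float:
        return float(self.tau_a)


def make_rdm(
    values: Iterable[float],
    n_items: int,
    evidence: Iterable[float] | None = None,
    metric_tag: str = "other",
) -> RDM:
    """Validate and wrap a condensed dissimilarity vector as an :class:`RDM`."""
    ev = None if evidence is None else np.asarray(evidence, dtype=float)
    return RDM(np.asarray(values, dtype=float), n_items, ev, metric_tag)


def condensed_index(i: int, j: int, n_items: int) -> int:
    """Condensed (upper-triangle, row-major) index of pair ``(i, j)``, 0-based."""
    if i == j:
        raise ValueError("diagonal entries have no condensed index")
    if i > j:
        i, j = j, i
    if i < 0 or j >= n_items:
        raise IndexError(f"pair ({i},{j}) out of range for n_items={n_items}")
    return i * (2 * n_items - i - 1) // 2 + (j - i - 1)


def condensed_pair(k: int, n_items: int) -> tuple[int, int]:
    """Inverse of :func:`condensed_index`."""
    if not 0 <= k < n_pairs(n_items):
        raise IndexError(f"condensed index {k} out of range")
    i = int(n_items - 2 - math.floor(
        (math.sqrt(4 * n_items * (n_items - 1) - 8 * k - 7) - 1) / 2
    ))
    j = k - i * (2 * n_items - i - 1) // 2 + i + 1
    return i, j


def pair_indices(n_items: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays ``(i, j)`` of the items of every condensed pair, in order."""
    i, j = np.triu_indices(n_items, k=1)
    return i, j


def euclidean_rdm(feature_matrix: np.ndarray, evidence=None) -> RDM:
    """Pairwise L2 distances between item rows of an ``items x dims`` matrix."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("feature matrix must be items x dims with dims >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing or non-finite values")
    return RDM(pdist(X, metric="euclidean"), X.shape[0], evidence, "euclidean")


def categorical_rdm(labels: Sequence) -> RDM:
    """Binary RDM: 0 for same-label pairs, 1 otherwise."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    codes = pd.factorize(labels)[0].astype(float)[:, None]
    vals = (pdist(codes, metric="hamming") > 0).astype(float)
    return RDM(vals, labels.size, None, "categorical")


def _tie_term(x: np.ndarray) -> int:
    _, counts = np.unique(x, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def kendall_tau_a(x, y) -> RankCorrelation:
    """Kendall's τA: (concordant − discordant) / (m(m−1)/2).

    Ties count as neither concordant nor discordant but remain in the
    denominator — unlike τB, which rescales by the tie-corrected pair counts.
    The integer concordance difference S is recovered exactly from scipy's τB.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    m = x.size
    if m < 2:
        raise ValueError("need at least two entries")
    n0 = m * (m - 1) // 2
    n1, n2 = _tie_term(x), _tie_term(y)
    if n0 == n1 or n0 == n2:  # a constant vector: S = 0 by definition
        return RankCorrelation(0.0, n0)
    tb = _kendalltau(x, y).statistic
    s = round(tb * math.sqrt((n0 - n1) * (n0 - n2)))
    return RankCorrelation(s / n0, n0)


def kendall_tau(x, y, variant: str = "a") -> RankCorrelation:
    """τA by default; τB available but never used by the pipeline defaults."""
    if variant == "a":
        return kendall_tau_a(x, y)
    if variant == "b":
        x = np.asarray(x, float).ravel()
        m = x.size
        tb = _kendalltau(x, y).statistic
        return RankCorrelation(0.0 if np.isnan(tb) else float(tb), m * (m - 1) // 2)
    raise ValueError("variant must be 'a' or 'b'")


def average_rdms(rdms: Sequence[RDM], allow_missing: bool = False) -> RDM:
    """Evidence-weighted mean of RDMs over a common item set.

    Pairs never measured by any input (total evidence 0) raise unless
    ``allow_missing``; then their value is 0 with evidence 0.
    """
    rdms = list(rdms)
    if not rdms:
        raise ValueError("no RDMs to average")
    n = rdms[0].n_items
    if any(r.n_items != n for r in rdms):
        raise ValueError("all RDMs must share n_items")
    w = np.stack([r.evidence for r in rdms])
    v = np.stack([r.values for r in rdms])
    tot = w.sum(axis=0)
    missing = tot == 0
    if missing.any() and not allow_missing:
        idx = np.flatnonzero(missing)
        raise ValueError(
            f"{idx.size} pairs have zero total evidence (first: {idx[:5].tolist()})"
        )
    denom = np.where(missing, 1.0, tot)
    mean = (w * v).sum(axis=0) / denom
    mean[missing] = 0.0
    tag = rdms[0].metric_tag if len({r.metric_tag for r in rdms}) == 1 else "other"
    if tag == "categorical":
        tag = "other"  # averages of binary RDMs are generally non-binary
    return RDM(mean, n, tot, tag)


def variance_inflation_factors(predictors: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 − R²_j) from regressing column j on the others.

    Perfectly collinear columns are reported as ``inf`` with a warning.
    """
    import statsmodels.api as sm

    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a pairs x p matrix with p >= 2")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("predictor columns must be non-constant")
    p = X.shape[1]
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        if r2 >= 1 - 1e-12:
            warnings.warn(f"predictor column {j} is perfectly collinear", stacklevel=2)
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# RDM CSV format: header `n_items,metric_tag`, then rows `i,j,value,evidence`
# with 1-based i<j.  Square-matrix CSV import/export also supported.
# ---------------------------------------------------------------------------

def write_rdm_csv(rdm: RDM, path) -> None:
    i, j = pair_indices(rdm.n_items)
    with open(path, "w") as fh:
        fh.write("n_items,metric_tag\n")
        fh.write(f"{rdm.n_items},{rdm.metric_tag}\n")
        fh.write("i,j,value,evidence\n")
        for a, b, v, e in zip(i + 1, j + 1, rdm.values, rdm.evidence):
            fh.write(f"{a},{b},{float(v)!r},{float(e)!r}\n")


def read_rdm_csv(path) -> RDM:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != ["n_items", "metric_tag"]:
            raise ValueError(f"{path}: line 1: expected header 'n_items,metric_tag'")
        meta = fh.readline().strip().split(",")
        n_items, tag = int(meta[0]), meta[1]
        cols = fh.readline().strip().split(",")
        if cols != ["i", "j", "value", "evidence"]:
            raise ValueError(f"{path}: line 3: expected columns 'i,j,value,evidence'")
        vals = np.zeros(n_pairs(n_items))
        ev = np.zeros(n_pairs(n_items))
        seen = np.zeros(n_pairs(n_items), dtype=bool)
        for ln, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {ln}: expected 4 fields")
            a, b = int(parts[0]) - 1, int(parts[1]) - 1
            k = condensed_index(a, b, n_items)
            vals[k], ev[k], seen[k] = float(parts[2]), float(parts[3]), True
    if not seen.all():
        raise ValueError(f"{path}: {int((~seen).sum())} pairs missing")
    return RDM(vals, n_items, ev, tag)


def write_square_csv(rdm: RDM, path) -> None:
    pd.DataFrame(rdm.square()).to_csv(path, index=False, header=False)


def read_square_csv(path, metric_tag: str = "other", tol: float = 1e-9) -> RDM:
    M = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError("square RDM file is not square")
    if np.max(np.abs(M - M.T)) > tol:
        raise ValueError(f"matrix is not symmetric to {tol}")
    M = (M + M.T) / 2
    np.fill_diagonal(M, 0.0)
    return RDM(squareform(M, checks=False), M.shape[0], None, metric_tag)
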