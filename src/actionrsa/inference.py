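"""Group inference for RSA scores: sign-permutation tests with omnibus and
cluster-sum corrections, noise ceilings, bootstrap effect onsets and paired
comparisons.

The group statistic is the mean subject-level τA (or τA² component).  The
null is built by randomly flipping the sign of each subject's whole series —
exchangeable under the null of symmetrically distributed scores around zero.
Cluster correction thresholds per-window permutation p-values at
``cluster_alpha``, scores contiguous clusters by the sum of the group
statistic, and compares them to the permutation distribution of the maximum
cluster sum.  The identity sign pattern is always part of the null set, which
makes every permutation p-value an exact randomization p (level ≤ α) and
never zero; when 2**n_subjects ≤ n_perm the sign patterns are enumerated
exhaustively instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, wilcoxon

from .rdm import RDM, average_rdms, kendall_tau_a

__all__ = [
    "InferenceConfig",
    "SubjectScoreSeries",
    "PermutationResult",
    "rsa_correlate",
    "sign_permutation_test",
    "noise_ceiling",
    "bootstrap_onsets",
    "OnsetResult",
    "paired_comparison",
]


@dataclass
class InferenceConfig:
    """Inference defaults: 5000 one-sided sign permutations at alpha 0.05,
    cluster-forming alpha 0.05, 1000 bootstrap resamples, 90% CIs."""

    n_perm: int = 5000
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    n_boot: int = 1000
    ci: float = 90.0
    tail: str = "right"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 1000:
            raise ValueError("n_perm must be >= 1000")
        if self.tail != "right":
            raise ValueError("only the one-sided right tail is supported")


@dataclass
class SubjectScoreSeries:
    """Subjects x series array of τA values; series are time windows or models."""

    values: np.ndarray
    times: np.ndarray | None = None
    model_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.nanmax(np.abs(self.values)) > 1 + 1e-9:
            raise ValueError("|tau| must be <= 1")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_series(self) -> int:
        return self.values.shape[1]


def rsa_correlate(data_rdms, model_rdm: RDM,
                  min_pairs: int = 3) -> SubjectScoreSeries:
    """Kendall τA between each subject's (time-resolved) RDM and a model RDM.

    Subjects with partial coverage are restricted to their covered pairs;
    a subject covering fewer than ``min_pairs`` pairs gets NaN with a warning.
    """
    from .decoding import TimeResolvedRDM

    rows, times = [], None
    for s, d in enumerate(data_rdms):
        if isinstance(d, TimeResolvedRDM):
            if d.n_items != model_rdm.n_items:
                raise ValueError("n_items mismatch between data and model")
            rows.append([
                kendall_tau_a(d.values[w], model_rdm.values).tau_a
                for w in range(d.n_windows)
            ])
            times = d.times
        else:
            if d.n_items != model_rdm.n_items:
                raise ValueError("n_items mismatch between data and model")
            mask = d.covered()
            if mask.sum() < min_pairs:
                warnings.warn(f"subject {s}: fewer than {min_pairs} covered "
                              "pairs; score set missing", stacklevel=2)
                rows.append([np.nan])
            else:
                rows.append([kendall_tau_a(d.values[mask],
                                           model_rdm.values[mask]).tau_a])
    return SubjectScoreSeries(np.asarray(rows, dtype=float), times)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _sign_matrix(n_subjects: int, n_perm: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Sign-flip patterns, always containing the identity pattern so that
    p = #{null >= observed}/P is an exact randomization p-value (and never
    zero).  All 2^n patterns are enumerated when that is cheaper."""
    if 2**n_subjects <= n_perm:
        warnings.warn("n_perm exceeds 2^n_subjects; enumerating all sign "
                      "patterns exhaustively", stacklevel=3)
        bits = ((np.arange(2**n_subjects)[:, None] >> np.arange(n_subjects))
                & 1)
        return bits * 2.0 - 1.0
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    signs[0] = 1.0
    return signs


def _max_cluster_sums(stat: np.ndarray, supra: np.ndarray) -> np.ndarray:
    """Row-wise maximum sum over contiguous suprathreshold runs (vectorised)."""
    R, W = stat.shape
    X = np.where(supra, stat, 0.0)
    c = np.concatenate([np.zeros((R, 1)), np.cumsum(X, axis=1)], axis=1)
    idx = np.arange(W)
    reset = np.where(~supra, idx + 1, 0)
    last_reset = np.maximum.accumulate(reset, axis=1)
    sums = c[:, 1:] - np.take_along_axis(c, last_reset, axis=1)
    sums = np.where(supra, sums, -np.inf)
    out = sums.max(axis=1)
    out[~supra.any(axis=1)] = 0.0
    return out


def _clusters_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) with stop exclusive."""
    out = []
    w = 0
    while w < mask.size:
        if mask[w]:
            start = w
            while w < mask.size and mask[w]:
                w += 1
            out.append((start, w))
        else:
            w += 1
    return out


@dataclass
class PermutationResult:
    stat: np.ndarray                 # group mean per series
    p_uncorrected: np.ndarray
    p_corrected: np.ndarray
    significant: np.ndarray          # boolean per series at config.alpha
    correction: str
    clusters: list[dict] = field(default_factory=list)
    cluster_threshold: np.ndarray | None = None  # per-window stat threshold


def sign_permutation_test(
    scores: SubjectScoreSeries | np.ndarray,
    config: InferenceConfig | None = None,
    correction: str = "none",
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """One-tailed (right) sign-permutation test of mean scores against zero.

    correction: ``none`` | ``omnibus_max`` (max statistic across series) |
    ``cluster_sum`` (contiguous clusters over series scored by summed mean).
    """
    config = config or InferenceConfig()
    if isinstance(scores, SubjectScoreSeries):
        S = scores.values
    else:
        S = np.atleast_2d(np.asarray(scores, dtype=float))
    S = S[~np.isnan(S).any(axis=1)]
    n, W = S.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    signs = _sign_matrix(n, config.n_perm, rng)
    P = signs.shape[0]
    obs = S.mean(axis=0)
    null = signs @ S / n                               # P x W
    p_unc = (null >= obs[None, :] - 1e-15).sum(axis=0) / P

    if correction == "none":
        p_corr = p_unc
        result = PermutationResult(obs, p_unc, p_corr,
                                   p_corr <= config.alpha, correction)
    elif correction == "omnibus_max":
        null_max = null.max(axis=1)
        p_corr = (null_max[:, None] >= obs[None, :] - 1e-15).sum(axis=0) / P
        result = PermutationResult(obs, p_unc, p_corr,
                                   p_corr <= config.alpha, correction)
    elif correction == "cluster_sum":
        # per-permutation per-window p by rank within the null column
        p_perm = rankdata(-null, axis=0, method="max") / P
        supra_obs = p_unc <= config.cluster_alpha
        supra_null = p_perm <= config.cluster_alpha
        null_max = _max_cluster_sums(null, supra_null)
        clusters = []
        p_corr = np.ones(W)
        for start, stop in _clusters_of(supra_obs):
            csum = obs[start:stop].sum()
            p = (null_max >= csum - 1e-15).sum() / P
            clusters.append({"start": start, "stop": stop, "sum": csum, "p": p})
            p_corr[start:stop] = p
        thr = np.quantile(null, 1 - config.cluster_alpha, axis=0)
        result = PermutationResult(obs, p_unc, p_corr,
                                   p_corr <= config.alpha, correction,
                                   clusters, thr)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return result


def noise_ceiling(subject_rdms: list[RDM]) -> dict:
    """Upper bound: τA(subject, grand average); lower bound: τA(subject,
    average excluding that subject); both restricted to the subject's
    covered pairs.  Group ceilings are the means across subjects."""
    if len(subject_rdms) < 3:
        raise ValueError("need at least 3 subjects")
    grand = average_rdms(subject_rdms, allow_missing=True)
    upper, lower = [], []
    for s, rdm in enumerate(subject_rdms):
        rest = average_rdms([r for t, r in enumerate(subject_rdms) if t != s],
                            allow_missing=True)
        mask = rdm.covered() & grand.covered()
        upper.append(kendall_tau_a(rdm.values[mask], grand.values[mask]).tau_a)
        mask = rdm.covered() & rest.covered()
        lower.append(kendall_tau_a(rdm.values[mask], rest.values[mask]).tau_a)
    upper, lower = np.asarray(upper), np.asarray(lower)
    return {
        "upper": upper,
        "lower": lower,
        "upper_mean": float(upper.mean()),
        "lower_mean": float(lower.mean()),
    }


@dataclass
class OnsetResult:
    onsets: np.ndarray              # per replicate; NaN where no cluster
    mean: float
    sd: float
    ci: tuple[float, float]
    prop_missing: float
    unreliable: bool


def bootstrap_onsets(
    scores: SubjectScoreSeries,
    config: InferenceConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> OnsetResult:
    """Bootstrap the onset of the first significant cluster.

    Subjects are resampled with replacement ``n_boot`` times; each replicate
    is run through the cluster-corrected sign-permutation test and the start
    time of its first significant cluster recorded.  Replicates with no
    significant cluster are excluded from the CI (and counted).
    """
    config = config or InferenceConfig()
    rng = np.random.default_rng(seed)
    S = scores.values
    times = scores.times if scores.times is not None else np.arange(S.shape[1])
    onsets = np.full(config.n_boot, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # exhaustive-enumeration notices
        for b in range(config.n_boot):
            idx = rng.integers(0, S.shape[0], S.shape[0])
            res = sign_permutation_test(S[idx], config, "cluster_sum", rng)
            sig = [c for c in res.clusters if c["p"] <= config.alpha]
            if sig:
                onsets[b] = times[sig[0]["start"]]
    good = onsets[~np.isnan(onsets)]
    prop_missing = 1 - good.size / config.n_boot
    if good.size == 0:
        return OnsetResult(onsets, np.nan, np.nan, (np.nan, np.nan), 1.0, True)
    lo, hi = np.percentile(good, [(100 - config.ci) / 2,
                                  100 - (100 - config.ci) / 2])
    return OnsetResult(onsets, float(good.mean()), float(good.std(ddof=1))
                       if good.size > 1 else 0.0,
                       (float(lo), float(hi)), prop_missing,
                       prop_missing > 0.5)


def paired_comparison(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired samples (exact for
    n ≤ 25, normal approximation otherwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 6:
        raise ValueError("need paired samples of equal length >= 6")
    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    method = "exact" if a.size <= 25 and np.all(d != 0) else "approx"
    return float(wilcoxon(a, b, method=method).pvalue)
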