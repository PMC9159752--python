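"""Cross-validated variance partitioning (commonality analysis) of RDMs.

Seven regressions — every non-empty subset of the visual (V), action (A) and
social-affective (S) predictor groups — are fit on an average training RDM
and evaluated as the squared Kendall τA between the predicted and the average
test RDM.  Inclusion–exclusion over the seven R values yields three unique,
three pairwise-shared and one triple-shared component that sum exactly to the
full-model τA².  Components can be negative (a known property of commonality
analysis); squared τ of an anti-predictive model still enters positively and
such iterations are logged.

Cross-validation schemes:

* ``split_estimates`` — each pair's individual similarity estimates are split
  in half (the partial design where participants saw different item subsets);
* ``split_subjects`` — participants are split in half;
* ``split_half_neural`` — participants' time-resolved RDMs are split in half
  and the partition is computed per time window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .inference import InferenceConfig, paired_comparison, sign_permutation_test
from .rdm import RDM, kendall_tau_a

__all__ = [
    "PredictorGroups",
    "COMPONENTS",
    "fit_predict_tausq",
    "commonality_partition",
    "VariancePartitioner",
    "crossval_varpart",
    "onset_distribution_compare",
]

GROUP_KEYS = ("V", "A", "S")
SUBSETS = ("V", "A", "S", "VA", "VS", "AS", "VAS")
COMPONENTS = ("uniq_V", "uniq_A", "uniq_S", "shared_VA", "shared_VS",
              "shared_AS", "shared_VAS")


@dataclass
class PredictorGroups:
    """Named predictor groups: visual / action / social-affective RDMs."""

    visual: list[RDM]
    action: list[RDM]
    social_affective: list[RDM]

    def __post_init__(self) -> None:
        n = {r.n_items for rdms in self._lists() for r in rdms}
        if len(n) > 1:
            raise ValueError("all predictor RDMs must share n_items")

    def _lists(self) -> list[list[RDM]]:
        return [self.visual, self.action, self.social_affective]

    @property
    def n_items(self) -> int:
        return self.visual[0].n_items

    def design(self, subset: str) -> np.ndarray:
        """Column-stacked, z-scored condensed predictors for a group subset."""
        cols = []
        for key, rdms in zip(GROUP_KEYS, self._lists()):
            if key in subset:
                cols.extend(r.values for r in rdms)
        X = np.column_stack(cols)
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd

    @classmethod
    def from_rdms(cls, rdms: Mapping[str, RDM],
                  groups: Mapping[str, str]) -> "PredictorGroups":
        """Build from a name→RDM mapping and a name→group assignment, so
        regrouping control analyses are pure configuration changes."""
        by = {"visual": [], "action": [], "social-affective": []}
        for name, grp in groups.items():
            by[grp].append(rdms[name])
        return cls(by["visual"], by["action"], by["social-affective"])


def _ols_predict(X_train, y_train, X_test) -> np.ndarray:
    """Least-squares fit with intercept; least-norm under collinearity."""
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, _, rank, _ = np.linalg.lstsq(A, y_train, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("collinear predictor set; least-norm solution used",
                      stacklevel=3)
    return np.column_stack([np.ones(len(X_test)), X_test]) @ coef


def fit_predict_tausq(
    train_rdm: RDM, test_rdm: RDM, predictors: np.ndarray | Sequence[RDM],
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """OLS of the train vector on predictor vectors; returns ``(tau, tau**2)``
    of the prediction against the test vector."""
    X = (np.column_stack([r.values for r in predictors])
         if not isinstance(predictors, np.ndarray) else predictors)
    return _tausq(X, train_rdm.values, test_rdm.values, mask)


def _tausq(X: np.ndarray, y_tr: np.ndarray, y_te: np.ndarray,
           mask: np.ndarray | None) -> tuple[float, float]:
    if mask is not None:
        X, y_tr, y_te = X[mask], y_tr[mask], y_te[mask]
    pred = _ols_predict(X, y_tr, X)
    tau = kendall_tau_a(pred, y_te).tau_a
    return tau, tau**2


def commonality_partition(tausq: Mapping[str, float]) -> dict[str, float]:
    """Three-set commonality decomposition of the seven subset R values.

    The components sum to ``R_VAS`` exactly (an algebraic identity).
    """
    missing = [s for s in SUBSETS if s not in tausq]
    if missing:
        raise ValueError(f"missing subset values: {missing}")
    R = {k: float(tausq[k]) for k in SUBSETS}
    out = {
        "uniq_V": R["VAS"] - R["AS"],
        "uniq_A": R["VAS"] - R["VS"],
        "uniq_S": R["VAS"] - R["VA"],
        "shared_VA": R["VS"] + R["AS"] - R["S"] - R["VAS"],
        "shared_VS": R["VA"] + R["AS"] - R["A"] - R["VAS"],
        "shared_AS": R["VA"] + R["VS"] - R["V"] - R["VAS"],
        "shared_VAS": (R["V"] + R["A"] + R["S"] - R["VA"] - R["VS"] - R["AS"]
                       + R["VAS"]),
    }
    out["total"] = R["VAS"]
    return out


class VariancePartitioner(BaseEstimator):
    """Cross-validated commonality analysis of a target RDM dataset.

    Parameters
    ----------
    scheme : split_estimates | split_subjects | split_half_neural
    n_iter : cross-validation iterations (study default 100).
    zero_negative_tau : score anti-predictive models (τ < 0) as 0 instead of
        entering the positive square.
    random_state : seed for the split draws.

    After ``fit(targets, groups)``:

    partition_ : long-format frame (iteration[, window], component, value).
    components_ : mean value per component (per window for the neural scheme).
    n_negative_tau_ : count of negative-τ subset evaluations.
    """

    def __init__(self, scheme: str = "split_subjects", n_iter: int = 100,
                 zero_negative_tau: bool = False, random_state: int = 0):
        self.scheme = scheme
        self.n_iter = n_iter
        self.zero_negative_tau = zero_negative_tau
        self.random_state = random_state

    # -- scheme-specific train/test average construction ------------------

    def _split_subjects(self, targets: list[RDM], rng) -> tuple:
        from .rdm import average_rdms

        perm = rng.permutation(len(targets))
        half = len(targets) // 2
        tr = average_rdms([targets[i] for i in perm[:half]], allow_missing=True)
        te = average_rdms([targets[i] for i in perm[half:]], allow_missing=True)
        return tr, te, tr.covered() & te.covered()

    def _split_estimates(self, targets: list[RDM], rng) -> tuple:
        V = np.stack([t.values for t in targets])      # subjects x pairs
        E = np.stack([t.evidence for t in targets])
        cover = E > 0
        # independent per-pair random halving of the available estimates
        u = rng.random(V.shape)
        u[~cover] = np.nan
        ranks = np.argsort(np.argsort(np.where(cover, u, np.inf), axis=0),
                           axis=0).astype(float)
        counts = cover.sum(axis=0)
        to_train = cover & (ranks < np.ceil(counts / 2)[None, :])
        to_test = cover & ~to_train
        wtr = np.where(to_train, E, 0.0)
        wte = np.where(to_test, E, 0.0)
        tr_e, te_e = wtr.sum(axis=0), wte.sum(axis=0)
        tr = np.where(tr_e > 0, (wtr * V).sum(axis=0) / np.where(tr_e > 0, tr_e, 1), 0)
        te = np.where(te_e > 0, (wte * V).sum(axis=0) / np.where(te_e > 0, te_e, 1), 0)
        n = targets[0].n_items
        return (RDM(tr, n, tr_e), RDM(te, n, te_e), (tr_e > 0) & (te_e > 0))

    def fit(self, targets, groups: PredictorGroups) -> "VariancePartitioner":
        rng = np.random.default_rng(self.random_state)
        rows = []
        self.n_negative_tau_ = 0
        self.masked_pair_counts_ = []
        designs = {s: groups.design(s) for s in SUBSETS}
        if self.scheme in ("split_subjects", "split_estimates"):
            splitter = (self._split_subjects if self.scheme == "split_subjects"
                        else self._split_estimates)
            for it in range(self.n_iter):
                tr, te, mask = splitter(list(targets), rng)
                self.masked_pair_counts_.append(int((~mask).sum()))
                rows.extend(self._one_partition(tr.values, te.values, mask,
                                                designs, it, None))
        elif self.scheme == "split_half_neural":
            movies = list(targets)                 # per-subject TimeResolvedRDM
            n_sub = len(movies)
            n_win = movies[0].n_windows
            stack = np.stack([m.values for m in movies])  # sub x win x pairs
            for it in range(self.n_iter):
                perm = rng.permutation(n_sub)
                half = n_sub // 2
                tr_all = stack[perm[:half]].mean(axis=0)
                te_all = stack[perm[half:]].mean(axis=0)
                for w in range(n_win):
                    rows.extend(self._one_partition(tr_all[w], te_all[w], None,
                                                    designs, it, w))
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.partition_ = pd.DataFrame(
            rows, columns=["iteration", "window", "component", "value"])
        keys = ["component"] if self.scheme != "split_half_neural" else [
            "window", "component"]
        self.components_ = (self.partition_.groupby(keys)["value"].mean())
        if self.scheme == "split_half_neural":
            self.times_ = movies[0].times
        return self

    def _one_partition(self, y_tr, y_te, mask, designs, it, window):
        tausq = {}
        for subset in SUBSETS:
            tau, t2 = _tausq(designs[subset], y_tr, y_te, mask)
            if tau < 0:
                self.n_negative_tau_ += 1
                if self.zero_negative_tau:
                    t2 = 0.0
            tausq[subset] = t2
        parts = commonality_partition(tausq)
        return [(it, window, comp, parts[comp])
                for comp in (*COMPONENTS, "total")]

    # -- significance ------------------------------------------------------

    def significance(self, config: InferenceConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
        """One-tailed sign permutation over iterations for each component
        (cluster-corrected over windows for the neural scheme)."""
        config = config or InferenceConfig()
        out = []
        neural = self.scheme == "split_half_neural"
        for comp in COMPONENTS:
            sub = self.partition_[self.partition_["component"] == comp]
            if neural:
                M = sub.pivot(index="iteration", columns="window",
                              values="value").to_numpy()
                res = sign_permutation_test(M, config, "cluster_sum", seed)
                for w in range(M.shape[1]):
                    out.append((comp, w, res.stat[w], res.p_uncorrected[w],
                                res.p_corrected[w]))
            else:
                M = sub["value"].to_numpy()[:, None]
                res = sign_permutation_test(M, config, "none", seed)
                out.append((comp, None, res.stat[0], res.p_uncorrected[0],
                            res.p_corrected[0]))
        return pd.DataFrame(out, columns=["component", "window", "value",
                                          "p_uncorrected", "p_corrected"])

    def compare_unique(self) -> pd.DataFrame:
        """Pairwise Wilcoxon tests between the unique components."""
        uniq = {c: self.partition_[self.partition_["component"] == c]
                .groupby("iteration")["value"].mean().to_numpy()
                for c in ("uniq_V", "uniq_A", "uniq_S")}
        rows = []
        names = list(uniq)
        for a in range(3):
            for b in range(a + 1, 3):
                rows.append((names[a], names[b],
                             paired_comparison(uniq[names[a]], uniq[names[b]])))
        return pd.DataFrame(rows, columns=["a", "b", "p"])


def crossval_varpart(targets, groups: PredictorGroups,
                     scheme: str = "split_subjects", n_iter: int = 100,
                     seed: int = 0, **kwargs) -> VariancePartitioner:
    """Functional wrapper over :class:`VariancePartitioner`."""
    return VariancePartitioner(scheme=scheme, n_iter=n_iter,
                               random_state=seed, **kwargs).fit(targets, groups)


# ---------------------------------------------------------------------------
# onsets over split iterations
# ---------------------------------------------------------------------------

def _iteration_onsets(M: np.ndarray, times: np.ndarray,
                      cluster_alpha: float = 0.05,
                      seed: int | np.random.Generator = 0,
                      config: InferenceConfig | None = None,
                      min_time: float = 0.0) -> np.ndarray:
    """Per-iteration onset of the first significant effect.

    Significance is established once at the group level: a one-tailed
    sign-permutation test over iterations, cluster-corrected over windows.
    Each iteration's onset is then the first window inside the earliest
    significant cluster where that iteration's own value is positive;
    iterations never positive inside any significant cluster are missing.
    Windows before ``min_time`` (stimulus onset by default) are never
    eligible — no effect can causally precede the stimulus, and split
    iterations share data, which makes the over-iterations permutation
    anticonservative for baseline windows.
    """
    config = config or InferenceConfig(cluster_alpha=cluster_alpha)
    res = sign_permutation_test(M, config, "cluster_sum", seed)
    eligible = times >= min_time
    sig = []
    for c in (c for c in res.clusters if c["p"] <= config.alpha):
        wins = np.arange(c["start"], c["stop"])[eligible[c["start"]:c["stop"]]]
        if wins.size:
            sig.append(wins)
    n_iter = M.shape[0]
    onsets = np.full(n_iter, np.nan)
    for i in range(n_iter):
        for wins in sig:
            pos = np.flatnonzero(M[i, wins] > 0)
            if pos.size:
                onsets[i] = times[wins[pos[0]]]
                break
    return onsets


def onset_distribution_compare(vp: VariancePartitioner,
                               cluster_alpha: float = 0.05,
                               seed: int = 0,
                               min_time: float = 0.0) -> pd.DataFrame:
    """Per-component onset distributions across split iterations, with mean,
    SD, 90% CI and pairwise Wilcoxon comparisons between unique components."""
    if vp.scheme != "split_half_neural":
        raise ValueError("onset analysis requires the split_half_neural scheme")
    times = vp.times_
    rows = []
    onset_store = {}
    for comp in ("uniq_V", "uniq_A", "uniq_S"):
        sub = vp.partition_[vp.partition_["component"] == comp]
        M = sub.pivot(index="iteration", columns="window",
                      values="value").to_numpy()
        onsets = _iteration_onsets(M, times, cluster_alpha, seed,
                                   min_time=min_time)
        onset_store[comp] = onsets
        good = onsets[~np.isnan(onsets)]
        if good.size:
            lo, hi = np.percentile(good, [5, 95])
            rows.append((comp, good.mean(), good.std(ddof=1) if good.size > 1
                         else 0.0, lo, hi, 1 - good.size / onsets.size))
        else:
            rows.append((comp, np.nan, np.nan, np.nan, np.nan, 1.0))
    summary = pd.DataFrame(rows, columns=["component", "mean", "sd",
                                          "ci_lo", "ci_hi", "prop_missing"])
    tests = []
    comps = list(onset_store)
    for a in range(3):
        for b in range(a + 1, 3):
            x, y = onset_store[comps[a]], onset_store[comps[b]]
            ok = ~np.isnan(x) & ~np.isnan(y)
            p = paired_comparison(x[ok], y[ok]) if ok.sum() >= 6 else np.nan
            tests.append((comps[a], comps[b], p))
    summary.attrs["pairwise"] = pd.DataFrame(tests, columns=["a", "b", "p"])
    summary.attrs["onsets"] = onset_store
    return summary
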