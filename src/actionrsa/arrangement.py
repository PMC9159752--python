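"""Multiple-arrangement sessions and inverse-MDS reconstruction.

In a multiple-arrangement task the participant drags a subset of 3–8 stimuli
inside a circular arena so that on-screen distances express dissimilarity.
An adaptive "lift-the-weakest" scheduler re-presents the pairs with the least
accumulated distance evidence until every pair reaches an evidence criterion
(0.5 by default) or a trial budget runs out.  Inverse MDS then reconstructs a
full RDM from the partial, per-trial-scaled arrangements.

Evidence model (the platform's exact formula is unpublished): a trial
contributes ``w = (d / diameter)**2`` to each of its pairs — distant pairs
carry more signal relative to motor noise — and evidence accumulates as
``1 - prod(1 - w_t)`` across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .rdm import RDM, kendall_tau_a, n_pairs, average_rdms

__all__ = [
    "ArrangementTrial",
    "ArrangementSession",
    "simulate_arranger",
    "lift_the_weakest",
    "update_evidence",
    "InverseMDS",
    "inverse_mds_estimate",
    "run_session",
    "loo_reliability",
    "exclude_arrangers",
    "SessionComplete",
    "read_session",
    "write_session",
]

DISK_DIAMETER = 2.0  # unit-disk arena


class SessionComplete(Exception):
    """Raised when a subset is requested from a session already at criterion."""


@dataclass
class ArrangementTrial:
    """One arena arrangement: item ids and their 2-D disk coordinates."""

    items: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.items.size, 2):
            raise ValueError("coords must be (len(items), 2)")
        if self.items.size < 3:
            warnings.warn("degenerate trial with fewer than 3 items", stacklevel=2)
        r = np.hypot(*self.coords.T)
        if np.any(r > 1 + 1e-9):
            raise ValueError("coordinates must lie inside the unit disk")


@dataclass
class ArrangementSession:
    """Ordered trials plus per-pair accumulated evidence."""

    n_items: int
    trials: list[ArrangementTrial] = field(default_factory=list)
    evidence: np.ndarray = None  # type: ignore[assignment]
    evidence_criterion: float = 0.5
    max_trial_size: int = 8
    max_trials: int = 500

    def __post_init__(self) -> None:
        if self.evidence is None:
            self.evidence = np.zeros(n_pairs(self.n_items))

    @property
    def complete(self) -> bool:
        return bool(
            self.evidence.min() >= self.evidence_criterion
            or len(self.trials) >= self.max_trials
        )


def simulate_arranger(
    true_rdm: RDM,
    subset: np.ndarray,
    placement_noise: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> ArrangementTrial:
    """Synthetic participant: classical 2-D MDS of the subset's sub-RDM,
    rescaled into the unit disk, plus Gaussian placement jitter."""
    rng = np.random.default_rng(seed)
    subset = np.asarray(subset, dtype=int)
    if placement_noise < 0:
        raise ValueError("placement noise must be >= 0")
    k = subset.size
    D = true_rdm.square()[np.ix_(subset, subset)]
    if np.allclose(D, 0):
        warnings.warn("degenerate all-zero sub-RDM; items placed at center",
                      stacklevel=2)
        coords = np.zeros((k, 2))
    else:
        # Torgerson double centering; top-2 eigenvectors
        J = np.eye(k) - np.ones((k, k)) / k
        B = -0.5 * J @ (D**2) @ J
        w, V = np.linalg.eigh(B)
        idx = np.argsort(w)[::-1][:2]
        coords = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))
    coords = coords + rng.normal(0, placement_noise, coords.shape)
    rmax = np.hypot(*coords.T).max()
    if rmax > 0:
        coords = coords / rmax  # isotropic rescale to fill the arena
    return ArrangementTrial(subset, coords)


def update_evidence(trial: ArrangementTrial, session: ArrangementSession
                    ) -> ArrangementSession:
    """Accumulate per-pair evidence from a completed trial (in place)."""
    session.trials.append(trial)
    idx, _, w = _trial_pairs(trial, session.n_items)
    session.evidence[idx] = 1.0 - (1.0 - session.evidence[idx]) * (1.0 - w)
    return session


def _trial_pairs(trial: ArrangementTrial, n_items: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Condensed pair indices, on-screen distances and evidence weights."""
    from scipy.spatial.distance import pdist

    a, b = np.triu_indices(trial.items.size, k=1)
    i = np.minimum(trial.items[a], trial.items[b])
    j = np.maximum(trial.items[a], trial.items[b])
    idx = i * (2 * n_items - i - 1) // 2 + (j - i - 1)
    d = pdist(trial.coords)
    w = np.minimum((d / DISK_DIAMETER) ** 2, 1.0)
    return idx, d, w


def lift_the_weakest(
    session: ArrangementSession,
    seed: int | np.random.Generator = 0,
    subset_size: int | None = None,
) -> np.ndarray:
    """Next item subset: seed with the minimum-evidence pair, then grow with
    the items whose pairs with the current subset carry the least evidence
    (ties broken toward under-sampled items, then randomly)."""
    rng = np.random.default_rng(seed)
    if session.complete:
        raise SessionComplete("session already at criterion or budget")
    size = min(subset_size or session.max_trial_size, session.n_items)
    ev = session.evidence
    sq = _evidence_square(session)
    if np.ptp(ev) == 0 and not session.trials:
        return rng.choice(session.n_items, size=size, replace=False)
    ties = np.flatnonzero(ev == ev.min())
    item_tot0 = sq.sum(axis=1)
    # among minimum-evidence pairs prefer under-sampled items (keeps early
    # trials covering the whole item set before any repeats)
    n = session.n_items
    ti = (n - 2 - np.floor(
        (np.sqrt(4 * n * (n - 1) - 8 * ties - 7) - 1) / 2)).astype(int)
    tj = ties - ti * (2 * n - ti - 1) // 2 + ti + 1
    pair_load = item_tot0[ti] + item_tot0[tj]
    k = int(ties[np.lexsort((rng.random(ties.size), pair_load))[0]])
    i, j = _pair_of(k, session.n_items)
    in_subset = np.zeros(session.n_items, dtype=bool)
    in_subset[[i, j]] = True
    item_tot = sq.sum(axis=1)
    for _ in range(size - 2):
        rest = np.flatnonzero(~in_subset)
        score = sq[rest][:, in_subset].mean(axis=1)
        # prefer under-sampled items on ties, then random
        order = np.lexsort((rng.random(rest.size), item_tot[rest], score))
        in_subset[rest[order[0]]] = True
    return np.flatnonzero(in_subset)


def _pair_of(k: int, n: int) -> tuple[int, int]:
    from .rdm import condensed_pair

    return condensed_pair(k, n)


def _evidence_square(session: ArrangementSession) -> np.ndarray:
    from scipy.spatial.distance import squareform

    return squareform(session.evidence)


def run_session(
    true_rdm: RDM,
    placement_noise: float = 0.05,
    evidence_criterion: float = 0.5,
    max_trial_size: int = 8,
    max_trials: int = 500,
    items: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> ArrangementSession:
    """Simulate a complete adaptive session against a ground-truth RDM.

    ``items`` restricts the session to a subset of the truth's items (the
    partial design where each participant arranges 30 of 152 videos); item
    ids in the returned session index that subset.
    """
    rng = np.random.default_rng(seed)
    if items is not None:
        sub = np.asarray(items, dtype=int)
        sq = true_rdm.square()[np.ix_(sub, sub)]
        from scipy.spatial.distance import squareform

        true_rdm = RDM(squareform(sq, checks=False), sub.size, None,
                       true_rdm.metric_tag)
    sess = ArrangementSession(
        true_rdm.n_items,
        evidence_criterion=evidence_criterion,
        max_trial_size=max_trial_size,
        max_trials=max_trials,
    )
    while not sess.complete:
        subset = lift_the_weakest(sess, seed=rng)
        trial = simulate_arranger(true_rdm, subset, placement_noise, seed=rng)
        update_evidence(trial, sess)
    return sess


class InverseMDS(BaseEstimator):
    """Reconstruct a full RDM from partial disk arrangements.

    Iterative estimate: initialise each pair's dissimilarity as the
    evidence-weighted mean of its on-screen distances; then alternate between
    (a) fitting one positive least-squares scale per trial aligning that
    trial's distances to the global estimate and (b) re-averaging the scaled
    distances with evidence weights, until the estimate moves by less than
    ``tol`` (relative) or ``max_iter`` passes.  The result is normalised to a
    unit root-mean-square condensed vector, making sessions comparable across
    participants.

    Attributes (after :meth:`fit`)
    ------------------------------
    rdm_ : RDM with metric_tag ``arrangement`` and the session evidence.
    n_iter_ : iterations run.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-6,
                 normalize: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.normalize = normalize

    def fit(self, session: ArrangementSession) -> "InverseMDS":
        m = n_pairs(session.n_items)
        pair_idx, trial_idx, dists, weights = [], [], [], []
        for t, trial in enumerate(session.trials):
            idx, d, w = _trial_pairs(trial, session.n_items)
            pair_idx.append(idx)
            trial_idx.append(np.full(idx.size, t))
            dists.append(d)
            weights.append(w)
        pair_idx = np.concatenate(pair_idx)
        trial_idx = np.concatenate(trial_idx)
        dists = np.concatenate(dists)
        weights = np.concatenate(weights)
        covered = np.zeros(m, dtype=bool)
        covered[pair_idx] = True
        if not covered.all():
            missing = np.flatnonzero(~covered)
            raise ValueError(
                f"{missing.size} pairs never co-presented "
                f"(first condensed indices: {missing[:5].tolist()})"
            )
        n_trials = len(session.trials)

        def weighted_mean(vals: np.ndarray, w: np.ndarray) -> np.ndarray:
            num = np.bincount(pair_idx, vals * w, minlength=m)
            den = np.bincount(pair_idx, w, minlength=m)
            # pairs whose every estimate has zero weight (coincident points):
            # fall back to the plain mean of their on-screen distances
            zero = den == 0
            if zero.any():
                num2 = np.bincount(pair_idx, vals, minlength=m)
                den2 = np.bincount(pair_idx, np.ones_like(vals), minlength=m)
                num[zero], den[zero] = num2[zero], den2[zero]
            return num / den

        est = weighted_mean(dists, weights)
        self.n_iter_ = 0
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            target = est[pair_idx]
            num = np.bincount(trial_idx, weights * dists * target,
                              minlength=n_trials)
            den = np.bincount(trial_idx, weights * dists * dists,
                              minlength=n_trials)
            scale = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
            scale = np.clip(scale, 1e-12, None)
            new = weighted_mean(scale[trial_idx] * dists, weights)
            delta = np.linalg.norm(new - est)
            norm = np.linalg.norm(est)
            est = new
            if norm > 0 and delta / norm < self.tol:
                break
        if self.normalize:
            rms = np.sqrt(np.mean(est**2))
            if rms > 0:
                est = est / rms
        self.rdm_ = RDM(est, session.n_items, session.evidence.copy(),
                        "arrangement")
        return self

    def fit_transform(self, session: ArrangementSession) -> RDM:
        return self.fit(session).rdm_


def inverse_mds_estimate(session: ArrangementSession, **kwargs) -> RDM:
    """Functional wrapper over :class:`InverseMDS`."""
    return InverseMDS(**kwargs).fit_transform(session)


def loo_reliability(subject_rdms: list[RDM]) -> np.ndarray:
    """Leave-one-subject-out τA for each subject's RDM against the
    evidence-weighted average of the others, restricted to the held-out
    subject's covered pairs.  Subjects with no overlap are NaN with warning."""
    if len(subject_rdms) < 3:
        raise ValueError("need at least 3 subjects")
    out = np.full(len(subject_rdms), np.nan)
    for s, rdm in enumerate(subject_rdms):
        others = average_rdms(
            [r for t, r in enumerate(subject_rdms) if t != s], allow_missing=True
        )
        mask = rdm.covered() & others.covered()
        if mask.sum() < 3:
            warnings.warn(f"subject {s} has no overlapping pairs; excluded",
                          stacklevel=2)
            continue
        out[s] = kendall_tau_a(rdm.values[mask], others.values[mask]).tau_a
    return out


def exclude_arrangers(
    training_rdms: list[RDM],
    catch_pass: np.ndarray | None = None,
    sd_factor: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Post-hoc participant filter: drop subjects whose training-trial RDM
    correlates with the average of the others more than ``sd_factor`` SDs
    below the mean correlation, or who failed the catch trial.

    Returns ``(keep_mask, correlations)``.
    """
    corr = loo_reliability(training_rdms)
    mu, sd = np.nanmean(corr), np.nanstd(corr)
    keep = corr >= mu - sd_factor * sd
    if catch_pass is not None:
        keep &= np.asarray(catch_pass, dtype=bool)
    return keep, corr


# ---------------------------------------------------------------------------
# Session files: '# key: value' metadata block, then CSV rows trial,item,x,y
# ---------------------------------------------------------------------------

def write_session(session: ArrangementSession, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_items: {session.n_items}\n")
        fh.write(f"# evidence_criterion: {session.evidence_criterion!r}\n")
        fh.write(f"# max_trial_size: {session.max_trial_size}\n")
        fh.write(f"# max_trials: {session.max_trials}\n")
        fh.write("trial,item,x,y\n")
        for t, trial in enumerate(session.trials):
            for item, (x, y) in zip(trial.items, trial.coords):
                fh.write(f"{t},{item},{float(x)!r},{float(y)!r}\n")


def read_session(path) -> ArrangementSession:
    meta: dict[str, str] = {}
    rows: list[tuple[int, int, float, float]] = []
    with open(Path(path)) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line == "trial,item,x,y":
                continue
            else:
                parts = line.split(",")
                if len(parts) != 4:
                    raise ValueError(f"{path}: line {ln}: expected 4 fields")
                rows.append((int(parts[0]), int(parts[1]),
                             float(parts[2]), float(parts[3])))
    try:
        n_items = int(meta["n_items"])
    except KeyError as e:
        raise ValueError(f"{path}: missing metadata field {e}") from None
    sess = ArrangementSession(
        n_items,
        evidence_criterion=float(meta.get("evidence_criterion", 0.5)),
        max_trial_size=int(meta.get("max_trial_size", 8)),
        max_trials=int(meta.get("max_trials", 500)),
    )
    if rows:
        arr = np.asarray(rows)
        for t in np.unique(arr[:, 0]).astype(int):
            sel = arr[arr[:, 0] == t]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tolerate 2-item trials
                trial = ArrangementTrial(sel[:, 1].astype(int), sel[:, 2:4])
            update_evidence(trial, sess)
    return sess
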