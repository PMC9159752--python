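"""Synthetic study generator with known ground truth.

Emulates the study's structure end to end: a stimulus set of everyday-action
videos (18 activity categories x 8 videos + 8 agent-free control videos = 152
items, or the 65-item replication set), per-rater five-point feature ratings
with rater noise and plantable bad raters, experimenter annotations, random
embedding features, multiple-arrangement sessions driven by a ground-truth
RDM, epoched multichannel recordings in which each feature's RDM structure
modulates channel patterns at a group-specific latency, and the recording
session's trial design.

The behavioral ground truth is a weighted combination of group composites
plus a shared unmodelled component.  Target unique variances are specified on
the τA² scale and mapped to Pearson weights through Greiner's relation
(ρ = sin(π·τ/2)); the mapping is approximate for sums of features, so planted
values steer the ordering and rough magnitude rather than exact components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arrangement import ArrangementSession, InverseMDS, run_session
from .decoding import EpochSet
from .features import (AnnotationSet, Feature, FeatureSet, RatingTable,
                       aggregate_ratings, build_feature_rdms, exclude_raters,
                       feature_groups)
from .rdm import RDM, euclidean_rdm, n_pairs

__all__ = [
    "GroundTruth",
    "SyntheticStudy",
    "SessionDesign",
    "gen_feature_set",
    "make_study",
    "behavior_truth_rdm",
    "gen_behavior_subjects",
    "sessions_to_rdms",
    "gen_epochs",
    "gen_session_design",
]

RATING_FEATURES = {
    "sociality": "social-affective",
    "valence": "social-affective",
    "arousal": "social-affective",
    "activity": "action",
    "transitivity": "action",
}
EMBEDDING_FEATURES = {"gist": 16, "conv1": 32, "fc8": 16}
IMAGE_STATS = ("pixel_value", "hue", "saturation", "optic_flow")


@dataclass
class GroundTruth:
    """Generator configuration; defaults mirror the 152-item study design."""

    n_categories: int = 18
    items_per_category: tuple[int, ...] | int = 8
    n_control: int = 8
    within_group_corr: float = 0.3
    rating_noise_sd: float = 1.0
    n_raters: int = 18
    n_bad_raters: int = 0
    n_catch_fail_raters: int = 0
    unique_tausq: tuple[float, float, float] = (0.02, 0.02, 0.06)
    placement_sd: float = 0.05
    channel_noise_corr: float = 0.3
    channel_noise_sd: float = 1.0
    # per-group (onset s, duration s, amplitude)
    latencies: dict = field(default_factory=lambda: {
        "visual": (0.07, 0.20, 1.0),
        "action": (0.25, 0.25, 1.0),
        "social-affective": (0.42, 0.30, 1.0),
    })

    @classmethod
    def experiment2(cls, **kw) -> "GroundTruth":
        """The 65-item replication set: 3–4 videos per activity, no controls."""
        per = tuple([4] * 11 + [3] * 7)
        return cls(items_per_category=per, n_control=0, **kw)

    @property
    def n_items(self) -> int:
        per = self.items_per_category
        total = (self.n_categories * per if isinstance(per, int) else sum(per))
        return total + self.n_control

    def categories(self) -> np.ndarray:
        per = self.items_per_category
        if isinstance(per, int):
            per = (per,) * self.n_categories
        labels = [f"activity_{c:02d}" for c, k in enumerate(per)
                  for _ in range(k)]
        labels += ["control"] * self.n_control
        return np.asarray(labels)


@dataclass
class SyntheticStudy:
    """Generated inputs plus the latent quantities recovery tests need."""

    config: GroundTruth
    features: FeatureSet
    ratings: RatingTable
    annotations: AnnotationSet
    feature_rdms: dict[str, RDM]
    groups: dict[str, str]
    latents: dict[str, np.ndarray]


def _group_latents(cfg: GroundTruth, names_by_group: dict[str, list[str]],
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One latent item vector per feature; features within a group share a
    common factor with loading sqrt(within_group_corr)."""
    n = cfg.n_items
    c = cfg.within_group_corr
    out = {}
    for group, names in names_by_group.items():
        G = rng.standard_normal(n)
        for name in names:
            out[name] = np.sqrt(c) * G + np.sqrt(1 - c) * rng.standard_normal(n)
    return out


def gen_feature_set(cfg: GroundTruth | None = None,
                    seed: int | np.random.Generator = 0) -> SyntheticStudy:
    """Draw the full 17-feature battery with rating tables and annotations."""
    cfg = cfg or GroundTruth()
    rng = np.random.default_rng(seed)
    n = cfg.n_items
    cats = cfg.categories()

    by_group = {
        "visual": ["pixel_value", "hue", "saturation", "optic_flow",
                   "gist", "conv1", "fc8", "environment", "watermark"],
        "action": ["transitivity", "activity", "category", "effectors"],
        "social-affective": ["sociality", "valence", "arousal", "n_agents"],
    }
    lat = _group_latents(cfg, by_group, rng)

    # annotations -----------------------------------------------------------
    environment = np.where(lat["environment"] > 0, "indoors", "outdoors")
    watermark = (lat["watermark"] > 0.5).astype(int)
    eff_lat = lat["effectors"][:, None] * 0.8 + rng.standard_normal((n, 5))
    effectors = (eff_lat > 0).astype(int)
    agent_lat = lat["n_agents"]
    n_agents = np.digitize(agent_lat, np.quantile(agent_lat, [0.3, 0.6, 0.85]))
    n_agents[cats == "control"] = 0
    ann = AnnotationSet(cats, environment, watermark, effectors, n_agents)

    # rating tables ---------------------------------------------------------
    rows = []
    catch = {}
    rid = 0
    for feat in RATING_FEATURES:
        z = (lat[feat] - lat[feat].mean()) / lat[feat].std()
        for _ in range(cfg.n_raters):
            noisy = 3 + 1.1 * z + rng.normal(0, cfg.rating_noise_sd, n)
            vals = np.clip(np.round(noisy), 1, 5).astype(int)
            rows.extend((f"r{rid}", i, feat, int(v)) for i, v in enumerate(vals))
            catch[f"r{rid}"] = True
            rid += 1
        for _ in range(cfg.n_bad_raters):  # only two unique values used
            vals = rng.choice([3, 4], size=n)
            rows.extend((f"r{rid}", i, feat, int(v)) for i, v in enumerate(vals))
            catch[f"r{rid}"] = True
            rid += 1
        for _ in range(cfg.n_catch_fail_raters):
            noisy = 3 + 1.1 * z + rng.normal(0, cfg.rating_noise_sd, n)
            vals = np.clip(np.round(noisy), 1, 5).astype(int)
            rows.extend((f"r{rid}", i, feat, int(v)) for i, v in enumerate(vals))
            catch[f"r{rid}"] = False
            rid += 1
    table = RatingTable(
        pd.DataFrame(rows, columns=["rater", "item", "feature", "rating"]),
        pd.Series(catch),
    )

    # assemble the feature set ---------------------------------------------
    fs = FeatureSet(item_ids=np.arange(n))
    clean, _ = exclude_raters(table)
    means, _ = aggregate_ratings(clean, zscore=True)
    for feat, group in RATING_FEATURES.items():
        fs.add(Feature(feat, means[feat].to_numpy(), group, "rating"))
    for stat in IMAGE_STATS:
        fs.add(Feature(stat, lat[stat], "visual", "image-statistic"))
    for name, dims in EMBEDDING_FEATURES.items():
        u = rng.standard_normal(dims)
        X = lat[name][:, None] * u[None, :] + 0.6 * rng.standard_normal((n, dims))
        fs.add(Feature(name, X, "visual", "embedding"))
    fs.add(Feature("environment", (environment == "indoors").astype(float),
                   "visual", "annotation"))
    fs.add(Feature("watermark", watermark.astype(float), "visual", "annotation"))
    fs.add(Feature("category", cats, "action", "annotation", kind="categorical"))
    fs.add(Feature("effectors", effectors.astype(float), "action", "annotation"))
    fs.add(Feature("n_agents", n_agents.astype(float), "social-affective",
                   "annotation"))

    rdms = build_feature_rdms(fs)
    return SyntheticStudy(cfg, fs, table, ann, rdms, feature_groups(fs), lat)


def make_study(cfg: GroundTruth | None = None,
               seed: int | np.random.Generator = 0) -> SyntheticStudy:
    return gen_feature_set(cfg, seed)


def _z(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def behavior_truth_rdm(study: SyntheticStudy,
                       seed: int | np.random.Generator = 0,
                       predictor_names: dict[str, list[str]] | None = None
                       ) -> RDM:
    """Ground-truth behavioral RDM: weighted group composites plus a shared
    unmodelled component, shifted to a nonnegative dissimilarity scale."""
    rng = np.random.default_rng(seed)
    cfg = study.config
    names = predictor_names or {
        "visual": ["environment", "fc8"],
        "action": ["category", "effectors", "transitivity", "activity"],
        "social-affective": ["sociality", "valence", "arousal", "n_agents"],
    }
    rho = {g: np.sin(np.pi * np.sqrt(u) / 2)
           for g, u in zip(("visual", "action", "social-affective"),
                           cfg.unique_tausq)}
    v = np.zeros(n_pairs(cfg.n_items))
    for g, members in names.items():
        comp = _z(np.mean([_z(study.feature_rdms[m].values) for m in members],
                          axis=0))
        v = v + rho[g] * comp
    resid_sd = np.sqrt(max(1 - sum(r**2 for r in rho.values()), 0.0))
    unmodelled = _z(euclidean_rdm(rng.standard_normal((cfg.n_items, 5))).values)
    v = v + resid_sd * unmodelled
    v = v - v.min() + 0.1 * v.std()
    return RDM(v, cfg.n_items, None, "other")


def _balanced_subsets(n_items: int, subset_size: int, n_subjects: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Per-subject item subsets balanced over PAIRS.

    Greedy: seed each subset with a least-covered pair, then repeatedly add
    the item with the least total pair coverage against the current subset
    (random tie-breaks).  Item-uniform random subsets would leave ~10% of
    pairs uncovered at 60 subjects of 30/152 items; pair-greedy coverage is
    what an adaptive sampler balancing evidence across participants gives.
    """
    C = np.zeros((n_items, n_items))
    np.fill_diagonal(C, np.inf)
    subsets = []
    for _ in range(n_subjects):
        flat = np.argmin(C + rng.random(C.shape))
        i, j = divmod(int(flat), n_items)
        chosen = np.zeros(n_items, dtype=bool)
        chosen[[i, j]] = True
        for _ in range(subset_size - 2):
            rest = np.flatnonzero(~chosen)
            sub = C[rest][:, chosen]
            uncov = (sub == 0).sum(axis=1)        # new pairs this item adds
            load = np.where(np.isfinite(sub), sub, 0).sum(axis=1)
            order = np.lexsort((rng.random(rest.size), load, -uncov))
            chosen[rest[order[0]]] = True
        pick = np.flatnonzero(chosen)
        C[np.ix_(pick, pick)] += 1
        np.fill_diagonal(C, np.inf)
        subsets.append(pick)
    return subsets


def gen_behavior_subjects(
    study: SyntheticStudy,
    n_subjects: int,
    design: str = "full_65",
    seed: int | np.random.Generator = 0,
    truth_rdm: RDM | None = None,
    max_trials: int | None = None,
) -> tuple[list[ArrangementSession], list[np.ndarray], RDM]:
    """Simulate complete adaptive arrangement sessions for many subjects.

    design ``subsets_30_of_152``: each subject arranges a balanced random
    30-item subset with trials of at most 7 videos; ``full_65``: every
    subject arranges the full item set with trials of at most 8.

    Returns (sessions, per-subject item subsets, truth RDM).
    """
    rng = np.random.default_rng(seed)
    truth = truth_rdm if truth_rdm is not None else behavior_truth_rdm(study, rng)
    n = truth.n_items
    if design == "subsets_30_of_152":
        subsets = _balanced_subsets(n, 30, n_subjects, rng)
        cap, budget = 7, max_trials or 400
    elif design == "full_65":
        subsets = [np.arange(n) for _ in range(n_subjects)]
        cap, budget = 8, max_trials or 600
    else:
        raise ValueError(f"unknown design {design!r}")
    sessions = []
    for s in range(n_subjects):
        sessions.append(run_session(
            truth, placement_noise=study.config.placement_sd,
            max_trial_size=cap, max_trials=budget,
            items=None if subsets[s].size == n else subsets[s], seed=rng,
        ))
    return sessions, subsets, truth


def sessions_to_rdms(sessions: list[ArrangementSession],
                     subsets: list[np.ndarray], n_total: int) -> list[RDM]:
    """Inverse-MDS reconstruction per subject, embedded into the full item
    set with zero evidence on unseen pairs."""
    from .rdm import condensed_index

    out = []
    for sess, items in zip(sessions, subsets):
        est = InverseMDS().fit_transform(sess)
        if items.size == n_total:
            out.append(est)
            continue
        vals = np.zeros(n_pairs(n_total))
        ev = np.zeros(n_pairs(n_total))
        k = 0
        for a in range(items.size):
            for b in range(a + 1, items.size):
                g = condensed_index(items[a], items[b], n_total)
                vals[g], ev[g] = est.values[k], est.evidence[k]
                k += 1
        out.append(RDM(vals, n_total, ev, "arrangement"))
    return out


def gen_epochs(
    study: SyntheticStudy,
    n_subjects: int = 10,
    n_channels: int = 32,
    fs: float = 500.0,
    seed: int | np.random.Generator = 0,
    items: np.ndarray | None = None,
    n_trials_per_condition: int = 10,
    tmin: float = -0.2,
    tmax: float = 1.0,
    amplitude: float = 1.0,
) -> list[EpochSet]:
    """Epoched recordings in which each feature's RDM structure drives
    condition-specific channel patterns over its group's latency window.

    Channel patterns are random per subject (idiosyncratic topographies);
    additive Gaussian noise is spatially correlated across channels
    (``channel_noise_corr``) and white in time.
    """
    rng = np.random.default_rng(seed)
    cfg = study.config
    items = np.arange(cfg.n_items) if items is None else np.asarray(items)
    n_cond = items.size
    times = np.arange(tmin, tmax, 1.0 / fs)
    n_t = times.size
    rho, sd = cfg.channel_noise_corr, cfg.channel_noise_sd
    cov = sd**2 * ((1 - rho) * np.eye(n_channels) + rho)
    L = np.linalg.cholesky(cov)
    feats = {n: f for n, f in study.features.features.items()
             if f.kind == "numeric"}
    subjects = []
    for _ in range(n_subjects):
        signal = np.zeros((n_cond, n_channels, n_t))
        for name, f in feats.items():
            onset, dur, amp = cfg.latencies[f.group]
            env = _raised_cosine(times, onset, dur)
            if not env.any():
                raise ValueError(f"latency of {name!r} lies outside the epoch")
            X = f.values[items]
            X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1,
                                                X.std(axis=0))
            B = rng.standard_normal((X.shape[1], n_channels))
            B /= np.linalg.norm(B, axis=1, keepdims=True) * np.sqrt(X.shape[1])
            patt = X @ B                                   # cond x channels
            signal += amp * amplitude * patt[:, :, None] * env[None, None, :]
        if not np.all(np.isfinite(signal)):
            raise ValueError("non-finite signal amplitudes")
        labels = np.repeat(items, n_trials_per_condition)
        noise = rng.standard_normal((labels.size, n_channels, n_t))
        data = signal[np.repeat(np.arange(n_cond), n_trials_per_condition)] \
            + np.einsum("ck,nkt->nct", L, noise)
        subjects.append(EpochSet(data, labels, fs, tmin))
    return subjects


def _raised_cosine(times: np.ndarray, onset: float, dur: float) -> np.ndarray:
    env = np.zeros_like(times)
    m = (times >= onset) & (times < onset + dur)
    env[m] = 0.5 * (1 - np.cos(2 * np.pi * (times[m] - onset) / dur))
    return env


@dataclass
class SessionDesign:
    """Recording-session trial order with catch-pair insertions."""

    trials: pd.DataFrame      # columns: trial, video, is_catch, block

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_experimental(self) -> int:
        return int((~self.trials["is_catch"]).sum())

    @property
    def n_catch(self) -> int:
        return int(self.trials["is_catch"].sum())


def gen_session_design(
    n_videos: int = 152,
    n_blocks: int = 10,
    n_catch_pairs: int = 25,
    catch_reps: int = 4,
    seed: int | np.random.Generator = 0,
    max_retries: int = 100,
) -> SessionDesign:
    """Pseudorandom block design: every video once per block with no
    consecutive repetition anywhere, catch pairs inserted at random positions
    as two consecutive trials, half of each pair's repetitions in each order.
    """
    if min(n_videos, n_blocks, n_catch_pairs, catch_reps) <= 0:
        raise ValueError("all design parameters must be positive")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        stream = []
        ok = True
        for b in range(n_blocks):
            # a block is a permutation of distinct videos, so only the
            # block boundary can violate the no-repetition constraint
            for _ in range(max_retries):
                block = rng.permutation(n_videos)
                if not stream or stream[-1][0] != block[0]:
                    stream.extend((int(v), b) for v in block)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        # catch insertions: ids live above the experimental range
        inserts = []
        for p in range(n_catch_pairs):
            v1, v2 = n_videos + 2 * p, n_videos + 2 * p + 1
            orders = [(v1, v2)] * (catch_reps // 2) + \
                     [(v2, v1)] * (catch_reps - catch_reps // 2)
            inserts.extend(orders)
        rng.shuffle(inserts)
        positions = np.sort(rng.choice(len(stream) + 1, size=len(inserts)))
        rows = []
        ins_at = {}
        for pos, pair in zip(positions, inserts):
            ins_at.setdefault(int(pos), []).append(pair)
        trial = 0
        for idx in range(len(stream) + 1):
            for a, b in ins_at.get(idx, []):
                rows.append((trial, a, True, None)); trial += 1
                rows.append((trial, b, True, None)); trial += 1
            if idx < len(stream):
                v, blk = stream[idx]
                rows.append((trial, v, False, blk)); trial += 1
        df = pd.DataFrame(rows, columns=["trial", "video", "is_catch", "block"])
        if np.all(np.diff(df["video"].to_numpy()) != 0):
            return SessionDesign(df)
    raise RuntimeError("could not satisfy the no-repetition constraint")
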