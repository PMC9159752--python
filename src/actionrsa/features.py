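"""Feature battery: ratings, annotations, embeddings and image statistics.

The study-style battery comprises 17 features in three groups:

* visual — pixel value (luminance), hue, saturation, optic flow, a scene
  descriptor and two network-layer embeddings (consumed as precomputed
  vectors), scene setting (indoors/outdoors) and watermark presence;
* action — transitivity and activity ratings, activity category, effectors;
* social-affective — sociality, valence, arousal ratings and number of agents.

Each feature becomes an RDM: Euclidean distances over its (vectorised) item
values, except the activity category which is a binary same/different RDM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .rdm import RDM, categorical_rdm, euclidean_rdm, kendall_tau_a

__all__ = [
    "RatingTable",
    "AnnotationSet",
    "Feature",
    "FeatureSet",
    "exclude_raters",
    "aggregate_ratings",
    "rating_reliability",
    "mean_frame_stats",
    "horn_schunck_flow",
    "attach_embeddings",
    "build_feature_rdms",
    "feature_intercorrelations",
]

GROUPS = ("visual", "action", "social-affective")
PROVENANCES = ("rating", "annotation", "embedding", "image-statistic")
EFFECTOR_NAMES = ("face_head", "hands", "arms", "legs", "torso")


@dataclass
class RatingTable:
    """Long-format 1–5 ratings plus per-rater catch-trial outcomes.

    ``ratings`` columns: rater, item, feature, rating (integer 1..5).
    ``catch_pass``: Series indexed by rater id, True if all catches passed.
    """

    ratings: pd.DataFrame
    catch_pass: pd.Series

    def __post_init__(self) -> None:
        req = {"rater", "item", "feature", "rating"}
        if not req.issubset(self.ratings.columns):
            raise ValueError(f"ratings table needs columns {sorted(req)}")
        r = self.ratings["rating"]
        if not np.all((r >= 1) & (r <= 5) & (r == r.astype(int))):
            raise ValueError("ratings must be integers in [1, 5]")
        if self.ratings.duplicated(["rater", "item", "feature"]).any():
            raise ValueError("duplicate (rater, item, feature) entries")

    @property
    def raters(self) -> np.ndarray:
        return self.ratings["rater"].unique()

    def to_csv(self, path) -> None:
        df = self.ratings.copy()
        df["catch_pass"] = df["rater"].map(self.catch_pass).astype(int)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        df = pd.read_csv(path)
        catch = df.groupby("rater")["catch_pass"].first().astype(bool)
        return cls(df.drop(columns=["catch_pass"]), catch)


@dataclass
class AnnotationSet:
    """Experimenter-assigned labels per item."""

    category: np.ndarray       # activity label (18 activities + control)
    environment: np.ndarray    # {"indoors", "outdoors"}
    watermark: np.ndarray      # {0, 1}
    effectors: np.ndarray      # items x 5 binary (face/head, hands, arms, legs, torso)
    n_agents: np.ndarray       # ordinal {0, 1, 2, 3}

    def __post_init__(self) -> None:
        self.effectors = np.asarray(self.effectors)
        if self.effectors.ndim != 2 or self.effectors.shape[1] != 5:
            raise ValueError("effectors must be an items x 5 binary matrix")
        self.n_agents = np.asarray(self.n_agents)
        if not np.all(np.isin(self.n_agents, [0, 1, 2, 3])):
            raise ValueError("n_agents must be in {0, 1, 2, 3}")

    @property
    def n_items(self) -> int:
        return len(self.category)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "category": self.category,
                "environment": self.environment,
                "watermark": self.watermark,
                "n_agents": self.n_agents,
            }
        )
        for k, name in enumerate(EFFECTOR_NAMES):
            df[f"effector_{name}"] = self.effectors[:, k]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationSet":
        eff = df[[f"effector_{n}" for n in EFFECTOR_NAMES]].to_numpy()
        return cls(
            df["category"].to_numpy(),
            df["environment"].to_numpy(),
            df["watermark"].to_numpy(),
            eff,
            df["n_agents"].to_numpy(),
        )


@dataclass
class Feature:
    name: str
    values: np.ndarray          # items x dims
    group: str                  # visual | action | social-affective
    provenance: str             # rating | annotation | embedding | image-statistic
    kind: str = "numeric"       # numeric -> euclidean RDM; categorical -> binary RDM

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"feature {self.name!r}: unknown group {self.group!r}")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"feature {self.name!r}: unknown provenance")
        if self.kind == "numeric":
            self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
            if self.values.shape[0] == 1 and self.values.shape[1] > 1:
                self.values = self.values.T


@dataclass
class FeatureSet:
    """Named features over a common item set."""

    features: dict[str, Feature] = field(default_factory=dict)
    item_ids: np.ndarray | None = None

    def add(self, feature: Feature) -> None:
        n = len(feature.values)
        if self.item_ids is not None and n != len(self.item_ids):
            raise ValueError(
                f"feature {feature.name!r} covers {n} items, expected "
                f"{len(self.item_ids)}"
            )
        self.features[feature.name] = feature

    def __len__(self) -> int:
        return len(self.features)

    def names(self, group: str | None = None) -> list[str]:
        return [
            n for n, f in self.features.items() if group is None or f.group == group
        ]


def exclude_raters(
    table: RatingTable, min_unique: int = 3
) -> tuple[RatingTable, pd.DataFrame]:
    """Drop raters who failed a catch trial or used fewer than ``min_unique``
    distinct rating values across their whole session.

    Returns the filtered table and an exclusion log (rater, reason).
    """
    if table.ratings.empty:
        raise ValueError("rating table is empty")
    log = []
    keep = []
    nun = table.ratings.groupby("rater")["rating"].nunique()
    for rater in table.raters:
        if not bool(table.catch_pass.get(rater, True)):
            log.append((rater, "catch_fail"))
        elif nun[rater] <= min_unique - 1:
            log.append((rater, "repetitive_ratings"))
        else:
            keep.append(rater)
    if not keep:
        raise ValueError("all raters excluded")
    out = RatingTable(
        table.ratings[table.ratings["rater"].isin(keep)].reset_index(drop=True),
        table.catch_pass.loc[keep],
    )
    return out, pd.DataFrame(log, columns=["rater", "reason"])


def aggregate_ratings(
    table: RatingTable, zscore: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item feature means across raters (after optional per-rater z-scoring).

    Z-scoring is applied per (rater, feature) across all items that rater
    rated, removing rater-specific location and scale use.  Returns
    ``(means, counts)`` as items x features frames.
    """
    df = table.ratings.copy()
    df["value"] = df["rating"].astype(float)
    if zscore:
        def _z(s: pd.Series) -> pd.Series:
            sd = s.std(ddof=0)
            return (s - s.mean()) / sd if sd > 0 else s - s.mean()

        df["value"] = df.groupby(["rater", "feature"])["value"].transform(_z)
    means = df.pivot_table(index="item", columns="feature", values="value",
                           aggfunc="mean")
    counts = df.pivot_table(index="item", columns="feature", values="value",
                            aggfunc="count")
    if means.isna().any().any():
        missing = means.index[means.isna().any(axis=1)].tolist()
        raise ValueError(f"items with no ratings for some feature: {missing[:5]}")
    return means, counts


def rating_reliability(
    table: RatingTable,
    n_splits: int = 100,
    seed: int | np.random.Generator = 0,
    zscore: bool = True,
) -> pd.DataFrame:
    """Split-half reliability per feature.

    Raters are randomly split in half ``n_splits`` times; the Spearman
    correlation between the two halves' item-mean vectors is recorded.
    Features with a single rater anywhere are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    df = table.ratings.copy()
    df["value"] = df["rating"].astype(float)
    if zscore:
        df["value"] = df.groupby(["rater", "feature"])["value"].transform(
            lambda s: (s - s.mean()) / s.std(ddof=0) if s.std(ddof=0) > 0
            else s - s.mean()
        )
    rows = []
    for feat, sub in df.groupby("feature"):
        raters = sub["rater"].unique()
        per_item = sub.groupby("item")["rater"].nunique()
        if per_item.min() < 2:
            warnings.warn(f"feature {feat!r} has items with < 2 raters; skipped",
                          stacklevel=2)
            continue
        for s in range(n_splits):
            half = rng.permutation(raters)
            a, b = half[: len(raters) // 2], half[len(raters) // 2:]
            ma = sub[sub["rater"].isin(a)].groupby("item")["value"].mean()
            mb = sub[sub["rater"].isin(b)].groupby("item")["value"].mean()
            common = ma.index.intersection(mb.index)
            rho = spearmanr(ma[common], mb[common]).statistic
            rows.append((feat, s, rho))
    return pd.DataFrame(rows, columns=["feature", "split", "reliability"])


def mean_frame_stats(frames: np.ndarray) -> tuple[float, float, float]:
    """Mean (luminance, hue°, saturation) over a stack of frames in [0, 1].

    Hue is averaged circularly (per frame over pixels, then over frames) to
    avoid the 0°/360° wrap artifact.  Grayscale stacks get hue 0, saturation 0.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3 and frames.shape[-1] == 3:
        frames = frames[None]
    elif frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("empty frame stack")
    if frames.min() < 0 or frames.max() > 1:
        raise ValueError("frame values must lie in [0, 1]")
    from skimage.color import rgb2hsv

    lums, hues, sats = [], [], []
    for fr in frames:
        if fr.ndim == 2:  # grayscale
            lums.append(fr.mean()); hues.append(0.0); sats.append(0.0)
            continue
        hsv = rgb2hsv(fr)
        lums.append(fr.mean())
        sat = hsv[..., 1]
        ang = hsv[..., 0] * 2 * np.pi
        # saturation-weighted circular mean; fully desaturated frames -> hue 0
        c = (sat * np.cos(ang)).sum()
        s = (sat * np.sin(ang)).sum()
        hues.append(np.degrees(np.arctan2(s, c)) % 360 if sat.sum() > 0 else 0.0)
        sats.append(sat.mean())
    return float(np.mean(lums)), float(_circmean_deg(hues)), float(np.mean(sats))


def _circmean_deg(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360)


def horn_schunck_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    alpha: float = 1.0,
    n_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Dense optic flow between two grayscale frames (Horn–Schunck).

    Minimises the brightness-constancy residual plus an ``alpha**2``-weighted
    smoothness penalty by Jacobi-style iterations on the local flow averages.
    Returns ``(flow, mean_magnitude)`` where ``flow`` is H x W x 2 (u, v) in
    pixels/frame.
    """
    from scipy.ndimage import convolve

    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be two grayscale images of equal shape")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    # Horn & Schunck derivative estimates over the 2x2x2 cube
    kx = np.array([[-1, 1], [-1, 1]]) * 0.25
    ky = np.array([[-1, -1], [1, 1]]) * 0.25
    kt = np.ones((2, 2)) * 0.25
    ex = convolve(a, kx) + convolve(b, kx)
    ey = convolve(a, ky) + convolve(b, ky)
    et = convolve(b, kt) - convolve(a, kt)
    avg = np.array([[1, 2, 1], [2, 0, 2], [1, 2, 1]]) / 12.0
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = alpha**2 + ex**2 + ey**2
    for _ in range(n_iter):
        ubar = convolve(u, avg)
        vbar = convolve(v, avg)
        d = (ex * ubar + ey * vbar + et) / denom
        u = ubar - ex * d
        v = vbar - ey * d
    flow = np.stack([u, v], axis=-1)
    return flow, float(np.hypot(u, v).mean())


def attach_embeddings(
    features: FeatureSet,
    embeddings: Mapping[str, np.ndarray],
    group: str = "visual",
) -> FeatureSet:
    """Register precomputed item x dim embedding matrices as features."""
    for name, mat in embeddings.items():
        mat = np.asarray(mat, dtype=float)
        if features.item_ids is not None and mat.shape[0] != len(features.item_ids):
            raise ValueError(
                f"embedding {name!r} has {mat.shape[0]} rows, expected "
                f"{len(features.item_ids)}"
            )
        features.add(Feature(name, mat, group, "embedding"))
    return features


def build_feature_rdms(features: FeatureSet) -> dict[str, RDM]:
    """One RDM per feature: Euclidean on (vectorised) values, binary for
    categorical features.  Group tags travel with the RDM via this mapping's
    companion, :func:`feature_groups`."""
    if not features.features:
        raise ValueError("feature set is empty")
    out: dict[str, RDM] = {}
    n = None
    for name, f in features.features.items():
        if f.kind == "categorical":
            r = categorical_rdm(f.values)
        else:
            r = euclidean_rdm(f.values)
        if n is None:
            n = r.n_items
        elif r.n_items != n:
            raise ValueError("features cover different item sets")
        out[name] = r
    return out


def feature_groups(features: FeatureSet) -> dict[str, str]:
    return {n: f.group for n, f in features.features.items()}


def feature_intercorrelations(rdms: Mapping[str, RDM]) -> pd.DataFrame:
    """Symmetric matrix of pairwise Kendall τA between feature RDMs."""
    names = list(rdms)
    if len(names) < 2:
        raise ValueError("need at least two RDMs")
    n_items = {rdms[n].n_items for n in names}
    if len(n_items) != 1:
        raise ValueError("RDMs cover different item sets")
    M = np.eye(len(names))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            t = kendall_tau_a(rdms[names[a]].values, rdms[names[b]].values).tau_a
            M[a, b] = M[b, a] = t
    return pd.DataFrame(M, index=names, columns=names)
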