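"""Rating pipeline, image statistics, optic flow and the feature-RDM battery."""

import numpy as np
import pandas as pd
import pytest

from actionrsa import (
    Feature,
    FeatureSet,
    RatingTable,
    aggregate_ratings,
    attach_embeddings,
    build_feature_rdms,
    euclidean_rdm,
    exclude_raters,
    feature_intercorrelations,
    horn_schunck_flow,
    kendall_tau_a,
    mean_frame_stats,
    rating_reliability,
)


class TestExcludeRaters:
    def test_repetitive_rater_excluded(self, small_rating_table):
        out, log = exclude_raters(small_rating_table)
        assert "flat" not in out.raters
        assert log.set_index("rater").loc["flat", "reason"] == "repetitive_ratings"

    def test_three_unique_values_retained(self):
        rows = [("r", i, "f", v) for i, v in enumerate([1, 2, 3, 1, 2, 3])]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({"r": True}))
        out, log = exclude_raters(t)
        assert "r" in out.raters and log.empty

    def test_catch_failure_excluded(self, small_rating_table):
        small_rating_table.catch_pass["good1"] = False
        out, log = exclude_raters(small_rating_table)
        assert "good1" not in out.raters
        assert "catch_fail" in log["reason"].tolist()

    def test_all_excluded_raises(self):
        rows = [("r", i, "f", 3) for i in range(5)]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({"r": True}))
        with pytest.raises(ValueError, match="all raters"):
            exclude_raters(t)

    def test_survivors_match_independent_scan(self, rng):
        rows, catch = [], {}
        for r in range(20):
            vals = rng.integers(1, 6, 10) if r % 3 else rng.choice([2, 4], 10)
            rows += [(f"r{r}", i, "f", int(v)) for i, v in enumerate(vals)]
            catch[f"r{r}"] = bool(r % 5)
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series(catch))
        out, _ = exclude_raters(t)
        expected = {f"r{r}" for r in range(20)
                    if catch[f"r{r}"]
                    and len(set(t.ratings[t.ratings.rater == f"r{r}"].rating)) >= 3}
        assert set(out.raters) == expected

    def test_pipeline_idempotent(self, small_rating_table):
        once, _ = exclude_raters(small_rating_table)
        twice, log = exclude_raters(once)
        assert log.empty
        pd.testing.assert_frame_equal(once.ratings, twice.ratings)


class TestAggregateRatings:
    def test_single_rater_means_are_raw(self):
        rows = [("r", i, "f", v) for i, v in enumerate([1, 5, 3])]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({"r": True}))
        means, counts = aggregate_ratings(t, zscore=False)
        assert means["f"].tolist() == [1, 5, 3]
        assert counts["f"].tolist() == [1, 1, 1]

    def test_zscore_removes_rater_offsets(self):
        base = [1, 2, 3, 4]
        rows = [("a", i, "f", v) for i, v in enumerate(base)]
        rows += [("b", i, "f", v + 1) for i, v in enumerate(base)]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({"a": True, "b": True}))
        means, _ = aggregate_ratings(t, zscore=True)
        per_rater = t.ratings.pivot(index="item", columns="rater",
                                    values="rating").astype(float)
        za = (per_rater["a"] - per_rater["a"].mean()) / per_rater["a"].std(ddof=0)
        assert np.allclose(means["f"], za, atol=1e-12)

    def test_matches_direct_groupby(self, rng):
        rows = [(f"r{r}", i, "f", int(rng.integers(1, 6)))
                for r in range(6) for i in range(8)]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({f"r{r}": True for r in range(6)}))
        means, _ = aggregate_ratings(t, zscore=False)
        direct = t.ratings.groupby("item")["rating"].mean()
        assert np.allclose(means["f"], direct, atol=1e-12)


class TestRatingReliability:
    def _table(self, item_values, n_raters, noise_sd, rng):
        rows = []
        for r in range(n_raters):
            noisy = 3 + item_values + rng.normal(0, noise_sd, len(item_values))
            vals = np.clip(np.round(noisy), 1, 5).astype(int)
            rows += [(f"r{r}", i, "f", int(v)) for i, v in enumerate(vals)]
        return RatingTable(
            pd.DataFrame(rows, columns=["rater", "item", "feature", "rating"]),
            pd.Series({f"r{r}": True for r in range(n_raters)}))

    def test_consistent_raters_near_one(self, rng):
        t = self._table(np.linspace(-1.5, 1.5, 10), 8, 0.01, rng)
        rel = rating_reliability(t, n_splits=20, seed=0)
        assert rel["reliability"].mean() > 0.95

    def test_pure_noise_near_zero(self, rng):
        rows = [(f"r{r}", i, "f", int(rng.integers(1, 6)))
                for r in range(20) for i in range(20)]
        t = RatingTable(pd.DataFrame(rows, columns=["rater", "item", "feature",
                                                    "rating"]),
                        pd.Series({f"r{r}": True for r in range(20)}))
        rel = rating_reliability(t, n_splits=50, seed=0)
        assert abs(rel["reliability"].mean()) < 0.15

    def test_more_raters_more_reliable(self, rng):
        sig = rng.normal(0, 0.8, 15)
        small = rating_reliability(self._table(sig, 5, 1.5, rng),
                                   n_splits=40, seed=1)
        large = rating_reliability(self._table(sig, 20, 1.5, rng),
                                   n_splits=40, seed=1)
        assert large["reliability"].mean() > small["reliability"].mean()


class TestFrameStats:
    def test_gray_frames(self):
        lum, hue, sat = mean_frame_stats(np.full((2, 8, 8), 0.5))
        assert lum == pytest.approx(0.5)
        assert sat == 0.0

    def test_pure_red(self):
        frame = np.zeros((4, 4, 3))
        frame[..., 0] = 1.0
        lum, hue, sat = mean_frame_stats(frame)
        assert hue == pytest.approx(0.0)
        assert sat == pytest.approx(1.0)

    def test_two_frames_average(self, rng):
        f1 = np.full((5, 5), 0.2)
        f2 = np.full((5, 5), 0.8)
        lum, _, _ = mean_frame_stats(np.stack([f1, f2]))
        assert lum == pytest.approx(0.5)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            mean_frame_stats(np.empty((0, 4, 4)))


def gaussian_blob(shift=0.0, size=48):
    y, x = np.mgrid[:size, :size].astype(float)
    return np.exp(-(((x - size / 2 - shift) ** 2) + (y - size / 2) ** 2) / 40.0)


def block_matching_shift(a, b, radius=3):
    """Oracle: integer displacement minimizing SSD over a central window."""
    best, arg = np.inf, 0
    c = slice(10, -10)
    for dx in range(-radius, radius + 1):
        diff = a[c, c] - np.roll(b, -dx, axis=1)[c, c]
        err = (diff**2).sum()
        if err < best:
            best, arg = err, dx
    return arg


class TestHornSchunck:
    def test_identical_frames_zero_flow(self):
        a = gaussian_blob()
        flow, mag = horn_schunck_flow(a, a)
        assert mag == pytest.approx(0.0, abs=1e-12)

    def test_one_pixel_shift_magnitude(self):
        a, b = gaussian_blob(0), gaussian_blob(1)
        assert abs(block_matching_shift(a, b)) == 1  # oracle sees the 1 px shift
        # low smoothness weight + long iteration so the small blob support
        # converges; the default alpha=1 oversmooths toward the static border
        flow, _ = horn_schunck_flow(a, b, alpha=0.3, n_iter=1000)
        support = a > 0.1 * a.max()
        mag = np.hypot(flow[..., 0], flow[..., 1])[support].mean()
        assert mag == pytest.approx(1.0, rel=0.2)

    def test_large_alpha_flattens_field(self):
        a, b = gaussian_blob(0), gaussian_blob(1)
        variances = []
        for alpha in (0.5, 5.0, 50.0):
            flow, _ = horn_schunck_flow(a, b, alpha=alpha, n_iter=150)
            variances.append(np.hypot(flow[..., 0], flow[..., 1]).var())
        assert variances[0] > variances[1] > variances[2]

    def test_magnitude_linear_in_displacement(self):
        shifts = [0.25, 0.5, 1.0, 1.5, 2.0]
        mags = []
        for s in shifts:
            flow, _ = horn_schunck_flow(gaussian_blob(0), gaussian_blob(s),
                                        n_iter=200)
            a = gaussian_blob(0)
            support = a > 0.1 * a.max()
            mags.append(np.hypot(flow[..., 0], flow[..., 1])[support].mean())
        r = np.corrcoef(shifts, mags)[0, 1]
        assert r**2 > 0.95

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            horn_schunck_flow(np.zeros((4, 4)), np.zeros((5, 5)))


class TestEmbeddingsAndBattery:
    def test_rotation_invariant_rdm(self, rng):
        X = rng.normal(size=(10, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        fs = FeatureSet(item_ids=np.arange(10))
        attach_embeddings(fs, {"a": X, "b": X @ q})
        rdms = build_feature_rdms(fs)
        assert np.allclose(rdms["a"].values, rdms["b"].values, atol=1e-9)

    def test_one_hot_embedding_constant_distances(self):
        fs = FeatureSet(item_ids=np.arange(6))
        attach_embeddings(fs, {"onehot": np.eye(6)})
        vals = build_feature_rdms(fs)["onehot"].values
        assert np.allclose(vals, np.sqrt(2))

    def test_row_mismatch_rejected(self, rng):
        fs = FeatureSet(item_ids=np.arange(5))
        with pytest.raises(ValueError, match="rows"):
            attach_embeddings(fs, {"bad": rng.normal(size=(4, 2))})

    def test_default_battery_has_17_rdms(self, study65):
        assert len(study65.feature_rdms) == 17
        groups = set(study65.groups.values())
        assert groups == {"visual", "action", "social-affective"}

    def test_agents_encoding(self):
        fs = FeatureSet(item_ids=np.arange(3))
        fs.add(Feature("n_agents", np.array([0.0, 1.0, 3.0]),
                       "social-affective", "annotation"))
        assert build_feature_rdms(fs)["n_agents"].values.tolist() == [1, 3, 2]

    def test_effectors_distance(self):
        fs = FeatureSet(item_ids=np.arange(2))
        fs.add(Feature("effectors",
                       np.array([[1, 1, 0, 0, 0], [1, 0, 0, 0, 1]], float),
                       "action", "annotation"))
        assert build_feature_rdms(fs)["effectors"].values[0] == pytest.approx(
            np.sqrt(2))


class TestIntercorrelations:
    def test_self_correlation_and_symmetry(self, rng):
        rdms = {n: euclidean_rdm(rng.normal(size=(12, 3))) for n in "abc"}
        M = feature_intercorrelations(rdms)
        assert np.allclose(np.diag(M), 1.0)
        assert np.allclose(M.to_numpy(), M.to_numpy().T, atol=1e-12)

    def test_independent_rdms_near_zero(self, rng):
        rdms = {n: euclidean_rdm(rng.normal(size=(100, 3))) for n in "ab"}
        assert abs(feature_intercorrelations(rdms).loc["a", "b"]) < 0.05

    def test_planted_correlation_ordering(self, rng):
        """Generative feature correlation must map to inter-RDM tau ordering."""
        base = rng.normal(size=60)
        levels = [0.0, 0.25, 0.5, 0.75, 0.95]
        taus = []
        ref = euclidean_rdm(base)
        for rho in levels:
            other = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=60)
            taus.append(kendall_tau_a(ref.values,
                                      euclidean_rdm(other).values).tau_a)
        assert np.all(np.diff(taus) > 0)
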