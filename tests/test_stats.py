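"""Dissimilarity assembly, PERMANOVA (with independent oracles), NMDS, LDA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from eggmatch.stats import (build_dissimilarity_matrix, clutch_summary,
                            lda_classify, nmds, permanova)


def toy_vectors(values):
    """Vectors with the covariate schema from a list of 5-tuples."""
    rows = []
    for i, (l, w, p, nf, s) in enumerate(values):
        rows.append({"egg_id": f"e{i}", "length_mm": l, "width_mm": w,
                     "percent_black": p, "n_features": nf,
                     "largest_scale_mm": s, "dominant_orientation_deg": 10.0 * i})
    return pd.DataFrame(rows)


class TestDissimilarityMatrix:
    def test_matches_hand_computed_oracle(self):
        df = toy_vectors([(40, 30, 10, 5, 1), (41, 31, 20, 7, 2),
                          (42, 29, 15, 6, 3), (39, 32, 5, 4, 1.5),
                          (40, 30, 12, 5, 2.5)])
        D = build_dissimilarity_matrix(df)
        # independent computation: z-score then euclidean
        X = df.drop(columns=["egg_id", "dominant_orientation_deg"]).astype(float)
        theta = np.radians(df.dominant_orientation_deg)
        X["s"], X["c"] = np.sin(theta), np.cos(theta)
        Z = (X - X.mean()) / X.std(ddof=0)
        expect = squareform(pdist(Z.to_numpy()))
        assert np.allclose(np.sort(D.to_numpy(), axis=None),
                           np.sort(expect, axis=None))

    def test_identical_vectors_distance_zero(self):
        df = toy_vectors([(40, 30, 10, 5, 1)] * 2 + [(45, 33, 30, 9, 3)])
        df.loc[1, "dominant_orientation_deg"] = df.loc[0, "dominant_orientation_deg"]
        D = build_dissimilarity_matrix(df)
        assert D.iloc[0, 1] == pytest.approx(0.0)
        assert np.allclose(D.to_numpy(), D.to_numpy().T)
        assert np.allclose(np.diag(D.to_numpy()), 0.0)

    def test_constant_column_named_in_error(self):
        df = toy_vectors([(40, 30, 10, 5, 1), (41, 30, 20, 7, 2), (42, 30, 15, 6, 3)])
        with pytest.raises(ValueError, match="width_mm"):
            build_dissimilarity_matrix(df)


def permanova_oracle_exact(D, groups):
    """Exhaustive p-value by direct enumeration, written independently."""
    D = np.asarray(D, float)
    groups = np.asarray(groups)
    n = len(groups)

    def f_stat(g):
        labels = np.unique(g)
        d2 = D**2
        ss_t = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for lab in labels:
            idx = np.flatnonzero(g == lab)
            sub = d2[np.ix_(idx, idx)]
            ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_a = ss_t - ss_w
        return (ss_a / (len(labels) - 1)) / (ss_w / (n - len(labels)))

    f_obs = f_stat(groups)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        count += f_stat(groups[list(perm)]) >= f_obs - 1e-12
        total += 1
    return count / total


class TestPermanova:
    @staticmethod
    def two_cluster_D(n_per=10, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 0.1, (n_per, 3)),
                         rng.normal(sep, 0.1, (n_per, 3))])
        return squareform(pdist(pts)), ["a"] * n_per + ["b"] * n_per

    def test_perfect_separation(self):
        D, groups = self.two_cluster_D()
        res = permanova(D, groups, n_perm=199, seed=1)
        assert res.R_squared > 0.95
        assert res.p_value == pytest.approx(1 / 200)

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        D = squareform(pdist(pts))
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(D, groups, permutations="exhaustive")
        assert res.p_value == pytest.approx(permanova_oracle_exact(D, groups))

    def test_matches_scikit_bio_cross_check(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova
        D, groups = self.two_cluster_D(n_per=6, sep=2.0, seed=4)
        ours = permanova(D, groups, n_perm=999, seed=0)
        theirs = skbio_permanova(skbio.DistanceMatrix(D), grouping=list(groups),
                                 permutations=999)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)
        assert abs(ours.p_value - theirs["p-value"]) < 0.05

    def test_single_group_rejected(self):
        D, _ = self.two_cluster_D(n_per=3)
        with pytest.raises(ValueError):
            permanova(D, ["a"] * 6, n_perm=9, seed=0)

    def test_pvalues_reproducible_under_fixed_seed(self):
        D, groups = self.two_cluster_D(n_per=5, sep=0.3, seed=7)
        a = permanova(D, groups, n_perm=499, seed=42)
        b = permanova(D, groups, n_perm=499, seed=42)
        assert a.p_value == b.p_value

    def test_r_squared_invariant_to_consistent_relabeling(self):
        D, groups = self.two_cluster_D(n_per=5, sep=1.0, seed=9)
        perm = np.random.default_rng(1).permutation(len(groups))
        D2 = D[np.ix_(perm, perm)]
        g2 = list(np.asarray(groups)[perm])
        a = permanova(D, groups, n_perm=9, seed=0)
        b = permanova(D2, g2, n_perm=9, seed=0)
        assert a.R_squared == pytest.approx(b.R_squared)
        assert a.pseudo_F == pytest.approx(b.pseudo_F)


class TestPermanovaProperties:
    @given(st.integers(min_value=0, max_value=10_000),
           st.integers(min_value=2, max_value=4))
    @settings(max_examples=25, deadline=None)
    def test_result_bounds_on_random_matrices(self, seed, n_per_group):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        pts = rng.normal(size=(n, 3))
        D = squareform(pdist(pts))
        groups = ["a"] * n_per_group + ["b"] * n_per_group
        res = permanova(D, groups, n_perm=49, seed=seed)
        assert 0.0 <= res.R_squared <= 1.0
        assert 1 / 50 <= res.p_value <= 1.0


class TestNmds:
    def test_three_equidistant_points_embed_exactly(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = nmds(D, n_dims=2, seed=0)
        assert res.stress < 1e-3

    def test_planar_configuration_reconstructed(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        D = squareform(pdist(pts))
        res = nmds(D, n_dims=2, seed=0)
        assert res.stress < 0.01

    def test_same_seed_reproduces_coordinates(self):
        rng = np.random.default_rng(5)
        D = squareform(pdist(rng.normal(size=(8, 3))))
        a = nmds(D, seed=11)
        b = nmds(D, seed=11)
        assert np.allclose(a.coordinates, b.coordinates)
        assert a.stress == b.stress


class TestLda:
    @staticmethod
    def separable(n_per=10, gap=10.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, offset in (("a", 0.0), ("b", gap)):
            for i in range(n_per):
                rows.append({"egg_id": f"{g}{i}",
                             "length_mm": offset + rng.normal(40, 0.5),
                             "width_mm": offset + rng.normal(30, 0.5),
                             "percent_black": offset + rng.normal(20, 1),
                             "n_features": offset + rng.normal(50, 3),
                             "largest_scale_mm": rng.normal(2, 0.2),
                             "dominant_orientation_deg": rng.uniform(0, 360)})
        df = pd.DataFrame(rows)
        return df, df.egg_id.str[0]

    def test_well_separated_groups_fully_classified(self):
        df, groups = self.separable()
        res = lda_classify(df, groups)
        assert res.mean_correct_loo == 100.0
        assert res.mean_correct_resub == 100.0

    def test_shuffled_labels_near_chance(self):
        df, groups = self.separable(n_per=40, gap=0.0, seed=3)
        rng = np.random.default_rng(0)
        accs = [lda_classify(df, rng.permutation(groups)).mean_correct_loo
                for _ in range(5)]
        assert abs(np.mean(accs) - 50.0) < 15.0  # chance for 2 equal groups

    def test_constant_covariate_dropped_with_warning(self):
        df, groups = self.separable()
        df["percent_black"] = 7.0
        with pytest.warns(UserWarning, match="percent_black"):
            res = lda_classify(df, groups)
        assert "percent_black" in res.dropped_covariates

    def test_tiny_groups_rejected(self):
        df, groups = self.separable(n_per=1)
        with pytest.raises(ValueError):
            lda_classify(df, groups)


class TestSignatureOrdering:
    def test_clutch_explains_more_variance_than_year(self, population,
                                                     population_features):
        """On strong-signature data the grouping hierarchy is clutch > year."""
        from eggmatch.imageprep import segment_egg
        from eggmatch.pigment import RoiError, pigment_score
        from eggmatch.stats import assemble_feature_vectors

        manifest = pd.DataFrame(
            [{"egg_id": e.egg_id, "clutch_id": e.clutch_id,
              "length_mm": e.length_mm, "width_mm": e.width_mm}
             for e in population.eggs])
        pig_rows = []
        for e in population.eggs:
            try:
                res = pigment_score(e.image.pixels, segment_egg(e.image),
                                    e.image.mm_per_px, e.egg_id)
                pig_rows.append({"egg_id": e.egg_id,
                                 "percent_black": res.percent_black})
            except RoiError:
                pig_rows.append({"egg_id": e.egg_id, "percent_black": np.nan})
        feats = pd.DataFrame(
            [{"egg_id": f.egg_id, "n_features": f.n_features,
              "largest_scale_mm": f.largest_scale_mm,
              "dominant_orientation_deg": f.dominant_orientation_deg}
             for f in population_features])
        vectors, _ = assemble_feature_vectors(manifest, pd.DataFrame(pig_rows),
                                              feats)
        nests = {n.nest_id: n for n in population.nests}
        vectors["year"] = [nests[c].year for c in vectors.clutch_id.astype(str)]
        D = build_dissimilarity_matrix(vectors)
        r2_clutch = permanova(D, vectors.clutch_id.astype(str), n_perm=99,
                              seed=0).R_squared
        r2_year = permanova(D, vectors.year.astype(str), n_perm=99,
                            seed=0).R_squared
        assert r2_clutch >= r2_year


class TestClutchSummary:
    def test_counts_and_mean(self):
        manifest = pd.DataFrame({"egg_id": list("abcdef"),
                                 "clutch_id": ["c1"] * 4 + ["c2"] * 2})
        s = clutch_summary(manifest)
        assert s == {"n_eggs": 6, "n_clutches": 2, "mean_clutch_size": 3.0}
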