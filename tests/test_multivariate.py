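"""log10 transform, Pearson/Ward clustering and redundancy analysis."""

import numpy as np
import pandas as pd
import pytest

from mtxprof.multivariate import (
    default_pseudocount,
    log10_transform,
    pearson_ward_cluster,
    rda_fit,
    rda_permutation_test,
    species_axis_filter,
)


def ward_greedy_oracle(dist: np.ndarray):
    """Greedy Ward clustering by explicit objective recomputation.

    At each step the closest pair of clusters merges at its current Ward
    distance; distances to the new cluster follow the minimum-variance
    update on squared dissimilarities (the ward.D2-style convention).
    Returns the merge sequence as (leafset_a, leafset_b, height).
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {frozenset((i, j)): dist[i, j] ** 2 for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        pair = min(d2, key=lambda k: (d2[k], sorted(k)))
        i, j = sorted(pair)
        height = np.sqrt(d2[pair])
        merges.append((clusters[i], clusters[j], height))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[frozenset((i, k))]
            djk = d2[frozenset((j, k))]
            dij = d2[pair]
            d2[frozenset((new, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        for k in list(d2):
            if i in k or j in k:
                del d2[k]
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        del clusters[i], clusters[j], sizes[i], sizes[j]
    return merges


def scipy_merge_leafsets(tree):
    """LinkageTree merges as (leafset_a, leafset_b, height)."""
    n = len(tree.labels)
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, h, _size) in enumerate(tree.merges):
        fa, fb = members[int(a)], members[int(b)]
        out.append((fa, fb, h))
        members[n + row_idx] = fa | fb
    return out


class TestLog10:
    def test_unit_value_zero_pseudocount(self):
        df = pd.DataFrame({"s": [1.0, 10.0]})
        out = log10_transform(df, pseudocount=0)
        assert out["s"].tolist() == [0.0, 1.0]

    def test_zero_with_unit_pseudocount(self):
        df = pd.DataFrame({"s": [0.0]})
        assert log10_transform(df, pseudocount=1)["s"].iloc[0] == 0.0

    def test_zero_with_zero_pseudocount_raises(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log10_transform(pd.DataFrame({"s": [0.0, 1.0]}), pseudocount=0)

    def test_default_pseudocount_half_min_nonzero(self):
        df = pd.DataFrame({"s": [0.0, 0.02, 1.0]})
        assert default_pseudocount(df) == pytest.approx(0.01)

    def test_monotonicity_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((40, 3)))
        out = log10_transform(df, pseudocount=0.5)
        for c in df.columns:
            order = np.argsort(df[c].to_numpy())
            assert (np.diff(out[c].to_numpy()[order]) >= 0).all()


class TestClustering:
    def test_identical_samples_merge_at_height_zero(self):
        rng = np.random.default_rng(1)
        base = rng.random(20)
        df = pd.DataFrame({"a": base, "b": base, "c": rng.random(20)})
        tree = pearson_ward_cluster(df)
        first = tree.merges[0]
        assert first[2] == pytest.approx(0.0, abs=1e-7)
        assert {tree.labels[int(first[0])], tree.labels[int(first[1])]} == {"a", "b"}

    def test_correlated_pair_merges_before_anticorrelated_sample(self):
        x = np.linspace(0, 1, 15)
        noise = 0.01 * np.sin(np.arange(15))
        df = pd.DataFrame({"up1": x, "up2": 2 * x + noise, "down": -x})
        tree = pearson_ward_cluster(df)
        first = tree.merges[0]
        assert {tree.labels[int(first[0])], tree.labels[int(first[1])]} == {"up1", "up2"}

    def test_constant_sample_rejected_by_name(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pearson_ward_cluster(df)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_merge_sequence_matches_greedy_oracle_on_six_samples(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.random((25, 6)), columns=[f"s{i}" for i in range(6)]
        )
        tree = pearson_ward_cluster(df)
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        expected = ward_greedy_oracle(dist)
        got = scipy_merge_leafsets(tree)
        for (ea, eb, eh), (ga, gb, gh) in zip(expected, got):
            assert {ea, eb} == {ga, gb}
            assert gh == pytest.approx(eh, abs=1e-10)

    def test_newick_contains_all_labels(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((10, 4)), columns=list("abcd"))
        nwk = pearson_ward_cluster(df).to_newick()
        assert nwk.endswith(";")
        for lab in "abcd":
            assert lab in nwk


def rda_oracle(response: pd.DataFrame, explanatory: pd.DataFrame):
    """Direct regression + eigendecomposition of the fitted covariance."""
    Y = response.to_numpy(float).T
    Y = Y - Y.mean(axis=0)
    X = explanatory.to_numpy(float)
    X = X - X.mean(axis=0)
    X = X / X.std(axis=0, ddof=1)  # continuous covariates standardized
    X = X - X.mean(axis=0)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B
    total = (Y**2).sum()
    fraction = (Yhat**2).sum() / total
    eigvals = np.linalg.eigvalsh(Yhat.T @ Yhat)[::-1]
    eigvals = eigvals[eigvals > 1e-12 * max(eigvals.max(), 1.0)]
    return fraction, eigvals / total


class TestRda:
    def _random_case(self, rng, n=8, p=5, q=2):
        response = pd.DataFrame(
            rng.normal(size=(p, n)), index=[f"f{i}" for i in range(p)],
            columns=[f"s{i}" for i in range(n)],
        )
        explanatory = pd.DataFrame(
            rng.normal(size=(n, q)), index=response.columns,
            columns=[f"x{i}" for i in range(q)],
        )
        return response, explanatory

    def test_full_indicator_set_saturates_at_one(self):
        rng = np.random.default_rng(3)
        response, _ = self._random_case(rng, n=5)
        explanatory = pd.DataFrame(
            {"sample": response.columns}, index=response.columns
        )
        with pytest.warns(UserWarning, match="saturates"):
            res = rda_fit(response, explanatory)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_explanatory_gives_zero_fraction(self):
        # response varies only between first/second half; explanatory is
        # exactly balanced within halves -> zero sample covariance
        samples = [f"s{i}" for i in range(4)]
        response = pd.DataFrame([[1.0, 1.0, -1.0, -1.0]], index=["f1"], columns=samples)
        explanatory = pd.DataFrame({"x": [1.0, -1.0, 1.0, -1.0]}, index=samples)
        res = rda_fit(response, explanatory)
        assert res.constrained_fraction == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_linear_algebra_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            response, explanatory = self._random_case(rng)
            res = rda_fit(response, explanatory)
            frac, axis = rda_oracle(response, explanatory)
            assert res.constrained_fraction == pytest.approx(frac, abs=1e-10)
            assert np.allclose(res.axis_fractions, axis, atol=1e-10)

    def test_axis_fractions_non_increasing(self):
        rng = np.random.default_rng(5)
        response, explanatory = self._random_case(rng, n=10, p=6, q=3)
        res = rda_fit(response, explanatory)
        assert (np.diff(res.axis_fractions) <= 1e-12).all()

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        response, explanatory = self._random_case(rng)
        explanatory["x_dup"] = explanatory["x0"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            res = rda_fit(response, explanatory)
        assert res.constrained_fraction <= 1.0


class TestSpeciesFilter:
    def test_feature_in_axis_plane_retained_orthogonal_dropped(self):
        samples = [f"s{i}" for i in range(6)]
        rng = np.random.default_rng(7)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        explained = pd.DataFrame(
            {"f_in": x, "f_in2": 0.5 * x + y},
            index=samples,
        ).T
        noise = rng.normal(size=6)
        explanatory = pd.DataFrame({"x": x, "y": y}, index=samples)
        response = pd.concat(
            [explained, pd.DataFrame([noise], index=["f_out"], columns=samples)]
        )
        res = rda_fit(response, explanatory)
        kept = species_axis_filter(res, threshold=0.5)
        assert "f_in" in kept and "f_in2" in kept

    def test_matches_per_feature_variance_decomposition(self):
        rng = np.random.default_rng(8)
        response = pd.DataFrame(
            rng.normal(size=(7, 9)), index=[f"f{i}" for i in range(7)],
            columns=[f"s{i}" for i in range(9)],
        )
        explanatory = pd.DataFrame(
            rng.normal(size=(9, 3)), index=response.columns, columns=["a", "b", "c"]
        )
        res = rda_fit(response, explanatory)
        kept = species_axis_filter(res, threshold=0.5)
        Y = response.to_numpy(float).T
        Y = Y - Y.mean(axis=0)
        U2 = res._axes[:, :2]
        expected = []
        for j, fid in enumerate(response.index):
            captured = ((U2.T @ Y[:, j]) ** 2).sum()
            if captured / (Y[:, j] ** 2).sum() >= 0.5:
                expected.append(fid)
        assert kept == expected


class TestPermutationTest:
    def test_noise_free_relationship_attains_minimum_p(self):
        rng = np.random.default_rng(9)
        samples = [f"s{i}" for i in range(10)]
        X = pd.DataFrame({"x": rng.normal(size=10)}, index=samples)
        response = pd.DataFrame(
            np.outer([1.0, -2.0, 0.5], X["x"]), index=["f1", "f2", "f3"], columns=samples
        )
        p, res = rda_permutation_test(response, X, n_permutations=99, seed=0)
        assert p == pytest.approx(1 / 100)
        assert res.constrained_fraction == pytest.approx(1.0, abs=1e-10)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(10)
        samples = [f"s{i}" for i in range(8)]
        response = pd.DataFrame(
            rng.normal(size=(4, 8)), index=list("wxyz"), columns=samples
        )
        X = pd.DataFrame({"x": rng.normal(size=8)}, index=samples)
        p1, _ = rda_permutation_test(response, X, n_permutations=199, seed=123)
        p2, _ = rda_permutation_test(response, X, n_permutations=199, seed=123)
        assert p1 == p2

    def test_invariant_to_joint_sample_relabeling(self):
        rng = np.random.default_rng(11)
        samples = [f"s{i}" for i in range(8)]
        response = pd.DataFrame(
            rng.normal(size=(5, 8)), index=[f"f{i}" for i in range(5)], columns=samples
        )
        X = pd.DataFrame({"x": rng.normal(size=8)}, index=samples)
        perm = rng.permutation(8)
        response2 = response.iloc[:, perm]
        X2 = X.iloc[perm]
        p1, _ = rda_permutation_test(response, X, n_permutations=199, seed=5)
        p2, _ = rda_permutation_test(response2, X2, n_permutations=199, seed=5)
        assert p1 == p2
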