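"""Correlation matrices vs hand oracles, Ward vs exhaustive agglomeration."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from flowmon.correlate import (
    DegenerateParameterError,
    correlation_analysis,
    export_heatmap,
    holm_adjust,
    pearson_pairwise,
    spearman_pairwise,
    standardize,
    ward_cluster,
)


class TestStandardize:
    def test_tiny_exact(self):
        out = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert out["a"].tolist() == [-1.0, 0.0, 1.0]

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(5, 3, size=(200, 3)), columns=list("abc"))
        z = standardize(table)
        assert np.allclose(z.mean(), 0.0, atol=1e-12)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_missing_preserved(self):
        table = pd.DataFrame({"a": [1.0, np.nan, 3.0, 5.0]})
        z = standardize(table)
        assert np.isnan(z["a"].iloc[1])

    def test_constant_parameter_error(self):
        with pytest.raises(DegenerateParameterError, match="b"):
            standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 4.0, 4.0]}))


def hand_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    n = len(x)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, p


class TestPearson:
    def test_self_correlation(self):
        table = pd.DataFrame({"x": [1.0, 4.0, 2.0, 8.0], "y": [1.0, 4.0, 2.0, 8.0]})
        r, p, n = pearson_pairwise(table)
        assert r.at["x", "y"] == pytest.approx(1.0)
        assert (np.diag(r) == 1.0).all()
        assert (np.diag(p) == 0.0).all()

    def test_five_point_toy_matches_closed_form(self):
        x = [1.0, 2.0, 4.0, 5.0, 9.0]
        y = [2.0, 1.0, 5.0, 4.0, 8.0]
        r, p, n = pearson_pairwise(pd.DataFrame({"x": x, "y": y}))
        r_hand, p_hand = hand_pearson(x, y)
        assert r.at["x", "y"] == pytest.approx(r_hand, abs=1e-12)
        assert p.at["x", "y"] == pytest.approx(p_hand, rel=1e-9)
        assert n.at["x", "y"] == 5

    def test_pairwise_complete_deletion(self):
        table = pd.DataFrame(
            {
                "x": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0],
                "y": [2.0, 4.0, 5.0, np.nan, 9.0, 13.0],
            }
        )
        r, p, n = pearson_pairwise(table)
        assert n.at["x", "y"] == 4
        mask = table.dropna()
        r_hand, _ = hand_pearson(mask["x"], mask["y"])
        assert r.at["x", "y"] == pytest.approx(r_hand)

    def test_too_few_pairs_left_missing(self):
        table = pd.DataFrame({"x": [1.0, 2.0, np.nan, np.nan], "y": [np.nan, 3.0, 4.0, 5.0]})
        r, p, n = pearson_pairwise(table)
        assert np.isnan(r.at["x", "y"]) and n.at["x", "y"] == 1

    def test_standardization_invariance(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        r_raw, _, _ = pearson_pairwise(table)
        r_std, _, _ = pearson_pairwise(standardize(table))
        pd.testing.assert_frame_equal(r_raw, r_std, atol=1e-12)

    def test_type_one_error_calibration_under_null(self):
        rng = np.random.default_rng(2013)
        reps, n = 1000, 100
        hits = 0
        for _ in range(reps):
            table = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
            _, p, _ = pearson_pairwise(table)
            hits += p.at["x", "y"] < 0.05
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se


class TestSpearman:
    def test_monotone_transform_is_one(self):
        x = np.array([0.5, 1.2, 3.0, 7.7, 9.1])
        table = pd.DataFrame({"x": x, "y": np.exp(x)})
        rho, _, _ = spearman_pairwise(table)
        assert rho.at["x", "y"] == pytest.approx(1.0)

    def test_six_points_with_tie_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 5.0, 4.0, 9.0, 7.0]

        def midranks(v):
            v = np.asarray(v)
            out = np.empty(len(v))
            for i, a in enumerate(v):
                less = (v < a).sum()
                equal = (v == a).sum()
                out[i] = less + (equal + 1) / 2.0
            return out

        rho, _, _ = spearman_pairwise(pd.DataFrame({"x": x, "y": y}))
        r_hand, _ = hand_pearson(midranks(x), midranks(y))
        assert rho.at["x", "y"] == pytest.approx(r_hand, abs=1e-12)

    def test_close_to_pearson_on_gaussian(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=400)
        table = pd.DataFrame({"x": z + rng.normal(scale=0.5, size=400), "y": z})
        r, _, _ = pearson_pairwise(table)
        rho, _, _ = spearman_pairwise(table)
        assert abs(r.at["x", "y"] - rho.at["x", "y"]) < 0.05


def brute_force_ward(d: np.ndarray):
    """Exhaustive Lance-Williams Ward agglomeration (heights + member sets)."""
    n = d.shape[0]
    clusters = {i: {i} for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], tuple(sorted(k))))
        i, j = sorted(pair)
        h = dist[pair]
        merged = clusters[i] | clusters[j]
        merges.append((h, frozenset(merged)))
        ni, nj = sizes[i], sizes[j]
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik, djk, dij = dist[frozenset((i, k))], dist[frozenset((j, k))], h
            new_dists[k] = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
        del clusters[i], clusters[j], sizes[i], sizes[j]
        dist = {k: v for k, v in dist.items() if not (k & {i, j})}
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        for k, v in new_dists.items():
            dist[frozenset((next_id, k))] = v
        next_id += 1
    return merges


def linkage_merges(linkage: np.ndarray, n: int):
    members = {i: frozenset((i,)) for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        merges.append((h, merged))
    return merges


class TestWard:
    def test_two_parameters_single_merge(self):
        pcc = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        linkage, order = ward_cluster(pcc)
        assert linkage.shape == (1, 4)
        assert linkage[0, 2] == pytest.approx(0.6)
        assert order == ["a", "b"]

    @pytest.mark.parametrize("k", [4, 5, 6])
    def test_merge_sequence_matches_brute_force(self, k):
        rng = np.random.default_rng(100 + k)
        r = np.clip(rng.uniform(-0.9, 0.9, size=(k, k)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = list("abcdefgh"[:k])
        pcc = pd.DataFrame(r, index=labels, columns=labels)
        linkage, _ = ward_cluster(pcc)
        got = linkage_merges(linkage, k)
        expected = brute_force_ward(1.0 - r)
        for (h1, m1), (h2, m2) in zip(got, expected):
            assert h1 == pytest.approx(h2, rel=1e-9)
            assert {frozenset(labels[i] for i in m1)} == {frozenset(labels[i] for i in m2)}

    def test_monotone_heights(self):
        rng = np.random.default_rng(55)
        r = rng.uniform(-0.5, 0.9, size=(7, 7))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = [f"p{i}" for i in range(7)]
        linkage, _ = ward_cluster(pd.DataFrame(r, index=labels, columns=labels))
        assert (np.diff(linkage[:, 2]) >= -1e-12).all()

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ward_cluster(bad)

    def test_leaf_order_is_permutation_and_deterministic(self):
        rng = np.random.default_rng(77)
        r = rng.uniform(-0.8, 0.8, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        labels = list("fedcba")
        pcc = pd.DataFrame(r, index=labels, columns=labels)
        _, order1 = ward_cluster(pcc)
        _, order2 = ward_cluster(pcc)
        assert sorted(order1) == sorted(labels)
        assert order1 == order2


class TestAnalysisAndExport:
    def _table(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=300)
        return pd.DataFrame(
            {
                "a": z + rng.normal(scale=0.3, size=300),
                "b": -z + rng.normal(scale=0.6, size=300),
                "c": rng.normal(size=300),
                "d": z + rng.normal(scale=1.2, size=300),
            }
        )

    def test_matrix_invariants(self):
        res = correlation_analysis(self._table())
        for mat in (res.pcc, res.scc):
            assert np.allclose(mat, mat.T)
            assert (np.diag(mat) == 1.0).all()
            assert (mat.to_numpy() >= -1).all() and (mat.to_numpy() <= 1).all()
        for p in (res.p_pcc, res.p_scc):
            arr = p.to_numpy()
            assert (arr >= 0).all() and (arr <= 1).all()

    def test_pcc_equals_mean_crossproduct_on_standardized(self):
        z = standardize(self._table())
        r, _, _ = pearson_pairwise(z)
        zz = z.to_numpy()
        n = len(zz)
        cross = zz.T @ zz / (n - 1)
        np.testing.assert_allclose(r.to_numpy(), cross, atol=1e-12)

    def test_holm_adjustment_monotone(self):
        res = correlation_analysis(self._table())
        adj = holm_adjust(res.p_pcc)
        iu = np.triu_indices(4, 1)
        assert (adj.to_numpy()[iu] >= res.p_pcc.to_numpy()[iu] - 1e-15).all()

    def test_export_heatmap_roundtrip_and_order(self, tmp_path):
        res = correlation_analysis(self._table())
        paths = export_heatmap(res, tmp_path / "heatmap")
        back = pd.read_csv(paths["csv"], index_col=0)
        assert list(back.columns) == res.leaf_order
        np.testing.assert_allclose(
            back.to_numpy(), res.pcc.loc[res.leaf_order, res.leaf_order].to_numpy()
        )
        assert paths["figure"].exists()
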