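"""Connectivity transforms and the three feature families, checked against
naive double-loop oracles and closed forms."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsfcnet.connectivity import (ConnectivityMatrix, ZMatrix,
                                  build_feature_tables, correlation_matrix,
                                  edge_features, edge_names,
                                  exponential_conversion, fisher_z,
                                  network_fc, nodal_integrity)
from rsfcnet.preprocess import SubjectTimeSeries

from conftest import (make_toy_parcellation, oracle_integrity,
                      oracle_network_fc, oracle_pearson, random_symmetric_z)


def _cleaned(data, sid="s1"):
    return SubjectTimeSeries(subject_id=sid, data=np.asarray(data, float),
                             tr=0.8, stage="cleaned")


def _cm(r, sid="s1"):
    return ConnectivityMatrix(subject_id=sid, r=np.asarray(r, float))


class TestCorrelation:
    @pytest.mark.parametrize("y, expected", [
        ([2, 4, 6, 8], 1.0),
        ([4, 3, 2, 1], -1.0),
    ])
    def test_perfect_linear_pairs(self, y, expected):
        data = np.column_stack([[1, 2, 3, 4], y])
        cm = correlation_matrix(_cleaned(data))
        assert cm.r[0, 1] == pytest.approx(expected)

    def test_hand_computed_pearson(self):
        x, y = [1, 2, 3, 5], [1, 1, 2, 2]
        cm = correlation_matrix(_cleaned(np.column_stack([x, y])))
        # Sum-based Pearson formula by hand: sum dx dy = 2.5, sum dx^2 = 8.75,
        # sum dy^2 = 1
        assert cm.r[0, 1] == pytest.approx(2.5 / np.sqrt(8.75), abs=1e-12)
        assert cm.r[0, 1] == pytest.approx(oracle_pearson(x, y), abs=1e-12)

    def test_requires_cleaned_stage(self, rng):
        raw = SubjectTimeSeries(subject_id="s", data=rng.normal(size=(10, 2)),
                                tr=0.8, stage="raw")
        with pytest.raises(ValueError, match="cleaned"):
            correlation_matrix(raw)

    def test_zero_variance_column_rejected(self, rng):
        data = rng.normal(size=(10, 3))
        data[:, 1] = 4.2
        ts = SubjectTimeSeries(subject_id="s", data=data, tr=0.8,
                               stage="cleaned", bad_rois=(1,))
        with pytest.raises(ValueError, match=r"\[1\]"):
            correlation_matrix(ts)


class TestFisherZ:
    def test_closed_forms(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 1.0], [0.5, 1.0, 1.0]])
        zm = fisher_z(_cm(r))
        assert zm.z[0, 1] == 0.0
        assert zm.z[0, 2] == pytest.approx(0.5 * np.log(3.0), abs=1e-12)
        # |r| = 1 is clipped to a finite value, the transform of clip_r
        assert zm.z[1, 2] == pytest.approx(np.arctanh(0.999999))
        assert np.isfinite(zm.z).all()
        assert (np.diag(zm.z) == 0).all()


class TestExponentialConversion:
    def test_closed_forms_and_monotonicity(self):
        r = np.array([[1.0, 1.0, -1.0], [1.0, 1.0, 0.2],
                      [-1.0, 0.2, 1.0]])
        c = exponential_conversion(_cm(r))
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(np.exp(-2.0))
        grid = np.linspace(-1, 1, 101)
        vals = np.exp(grid - 1.0)
        assert (np.diff(vals) > 0).all()
        assert (np.diag(c) == 0).all()

    def test_unknown_conversion_rejected(self):
        with pytest.raises(ValueError, match="unknown conversion"):
            exponential_conversion(_cm(np.eye(2)), conversion="nope")


class TestNodalIntegrity:
    def test_constant_offdiagonal(self):
        c = np.full((5, 5), 0.7)
        np.fill_diagonal(c, 0.0)
        np.testing.assert_allclose(nodal_integrity(c), 0.7)

    def test_three_node_hand_means(self):
        c = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
        np.testing.assert_allclose(nodal_integrity(c), [0.3, 0.4, 0.5])

    def test_permutation_equivariance(self, rng):
        c = np.abs(random_symmetric_z(rng, 7))
        perm = rng.permutation(7)
        np.testing.assert_allclose(nodal_integrity(c[np.ix_(perm, perm)]),
                                   nodal_integrity(c)[perm], atol=1e-12)

    def test_monotone_in_each_entry(self, rng):
        r = np.clip(random_symmetric_z(rng, 6) / 4, -0.9, 0.9)
        np.fill_diagonal(r, 1.0)
        eta = nodal_integrity(exponential_conversion(_cm(r)))
        r2 = r.copy()
        r2[1, 4] = r2[4, 1] = r[1, 4] + 0.05
        eta2 = nodal_integrity(exponential_conversion(_cm(r2)))
        assert eta2[1] > eta[1] and eta2[4] > eta[4]
        others = [i for i in range(6) if i not in (1, 4)]
        np.testing.assert_allclose(eta2[others], eta[others], atol=1e-14)


class TestNetworkFC:
    def test_hand_enumerated_toy(self):
        parc = make_toy_parcellation({"VSN": 2, "SMN": 2})
        z = np.array([[0.0, 0.6, 0.1, 0.1],
                      [0.6, 0.0, 0.1, 0.1],
                      [0.1, 0.1, 0.0, 0.2],
                      [0.1, 0.1, 0.2, 0.0]])
        out = network_fc(ZMatrix("s", z, 0.999999), parc)
        assert out["intra_VSN"] == pytest.approx(0.6)
        assert out["intra_SMN"] == pytest.approx(0.2)
        assert out["inter_VSN_SMN"] == pytest.approx(0.1)

    def test_all_equal_entries(self):
        parc = make_toy_parcellation({"VSN": 3, "SMN": 2, "DGN": 2})
        z = np.full((7, 7), 0.37)
        np.fill_diagonal(z, 0.0)
        out = network_fc(ZMatrix("s", z, 0.999999), parc)
        np.testing.assert_allclose(out.to_numpy(), 0.37)

    def test_singleton_network_flagged_missing(self):
        parc = make_toy_parcellation({"VSN": 3, "DGN": 1})
        z = random_symmetric_z(np.random.default_rng(0), 4)
        out = network_fc(ZMatrix("s", z, 0.999999), parc)
        assert np.isnan(out["intra_DGN"])
        assert np.isfinite(out["inter_VSN_DGN"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle(self, seed, toy_parc):
        rng = np.random.default_rng(seed)
        z = random_symmetric_z(rng, toy_parc.n_nodes)
        got = network_fc(ZMatrix("s", z, 0.999999), toy_parc)
        labels = toy_parc.table["network"].tolist()
        want = oracle_network_fc(z, labels, list(toy_parc.networks))
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_aggregation_conservation(self, seed):
        """Pair-count-weighted mean of all block means equals the grand mean
        of the off-diagonal z entries."""
        rng = np.random.default_rng(seed)
        parc = make_toy_parcellation({"VSN": 4, "SMN": 3, "DGN": 3})
        z = random_symmetric_z(rng, 10)
        out = network_fc(ZMatrix("s", z, 0.999999), parc)
        sizes = {"VSN": 4, "SMN": 3, "DGN": 3}
        total, weight = 0.0, 0
        for net, m in sizes.items():
            npairs = m * (m - 1) // 2
            total += out[f"intra_{net}"] * npairs
            weight += npairs
        for (a, b) in [("VSN", "SMN"), ("VSN", "DGN"), ("SMN", "DGN")]:
            npairs = sizes[a] * sizes[b]
            total += out[f"inter_{a}_{b}"] * npairs
            weight += npairs
        grand = z[np.triu_indices(10, k=1)].mean()
        assert total / weight == pytest.approx(grand, abs=1e-12)


class TestEdgeFeatures:
    def test_counts_and_order(self):
        z3 = random_symmetric_z(np.random.default_rng(1), 3)
        e3 = edge_features(ZMatrix("s", z3, 0.999999))
        assert list(e3.index) == ["1_2", "1_3", "2_3"]
        assert len(edge_names(90)) == 4005

    def test_roundtrip_identity(self, rng):
        z = random_symmetric_z(rng, 8)
        vec = edge_features(ZMatrix("s", z, 0.999999))
        rebuilt = np.zeros((8, 8))
        iu, ju = np.triu_indices(8, k=1)
        rebuilt[iu, ju] = vec.to_numpy()
        rebuilt += rebuilt.T
        np.testing.assert_array_equal(
            edge_features(ZMatrix("s", rebuilt, 0.999999)).to_numpy(),
            vec.to_numpy())


class TestFeatureTables:
    def _subjects(self, rng, n_subj, parc):
        return [_cleaned(rng.normal(size=(30, parc.n_nodes)), f"s{i}")
                for i in range(n_subj)]

    def test_shapes_at_full_scale(self, rng, default_parc):
        tables = build_feature_tables(self._subjects(rng, 2, default_parc),
                                      default_parc)
        assert tables["integrity"].shape == (2, 90)
        assert tables["network"].shape == (2, 36)   # 8 intra + 28 inter
        assert tables["edge"].shape == (2, 4005)    # 90 * 89 / 2

    def test_single_subject_row(self, rng, toy_parc):
        tables = build_feature_tables(self._subjects(rng, 1, toy_parc),
                                      toy_parc)
        assert all(df.shape[0] == 1 for df in tables.values())

    def test_subject_order_permutes_rows_only(self, rng, toy_parc):
        subs = self._subjects(rng, 4, toy_parc)
        t1 = build_feature_tables(subs, toy_parc)
        t2 = build_feature_tables(subs[::-1], toy_parc)
        for level in t1:
            assert list(t2[level].index) == list(t1[level].index[::-1])
            np.testing.assert_allclose(
                t2[level].loc[t1[level].index].to_numpy(),
                t1[level].to_numpy())

    def test_bad_roi_marks_dependent_features_missing(self, rng, toy_parc,
                                                      caplog):
        subs = self._subjects(rng, 2, toy_parc)
        data = subs[0].data.copy()
        data[:, 0] = 1.0  # first VSN node flat
        subs[0] = SubjectTimeSeries(subject_id="s0", data=data, tr=0.8,
                                    stage="cleaned", bad_rois=(0,))
        with caplog.at_level(logging.WARNING):
            tables = build_feature_tables(subs, toy_parc)
        assert "zero-variance" in caplog.text
        assert np.isnan(tables["integrity"].iloc[0, 0])
        assert np.isnan(tables["network"].iloc[0]["intra_VSN"])
        assert np.isnan(tables["edge"].iloc[0]["1_2"])
        # unaffected blocks of the same subject stay finite
        assert np.isfinite(tables["network"].iloc[0]["intra_DGN"])
        # the clean subject is untouched
        assert tables["edge"].iloc[1].notna().all()

    def test_matches_naive_oracles(self, rng, toy_parc):
        """All three families agree with double-loop recomputation."""
        subs = self._subjects(rng, 3, toy_parc)
        tables = build_feature_tables(subs, toy_parc)
        labels = toy_parc.table["network"].tolist()
        for k, ts in enumerate(subs):
            r = np.corrcoef(ts.data, rowvar=False)
            z = np.arctanh(np.clip(r, -0.999999, 0.999999))
            np.fill_diagonal(z, 0.0)
            conv = np.exp(r - 1.0)
            np.fill_diagonal(conv, 0.0)
            np.testing.assert_allclose(tables["integrity"].iloc[k].to_numpy(),
                                       oracle_integrity(conv), atol=1e-12)
            want = oracle_network_fc(z, labels, list(toy_parc.networks))
            for key, val in want.items():
                assert tables["network"].iloc[k][key] == pytest.approx(
                    val, abs=1e-12)
            n = toy_parc.n_nodes
            for i in range(n):
                for j in range(i + 1, n):
                    assert tables["edge"].iloc[k][f"{i + 1}_{j + 1}"] == \
                        pytest.approx(z[i, j], abs=1e-12)
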