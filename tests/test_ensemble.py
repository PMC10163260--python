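"""Stream fusion, diversity selection and ensemble aggregation."""

import numpy as np
import pytest

from hcpl.ensemble import (FusionPolicy, aggregate_apply, classwise_correlation,
                           fuse_streams, select_diverse)


class TestClasswiseCorrelation:
    def _labels(self, n, c):
        return np.ones((n, c))

    def test_identical_vectors_r_one(self, rng):
        p = rng.uniform(size=(10, 1))
        r = classwise_correlation(p, p, self._labels(10, 1))
        assert r[0] == pytest.approx(1.0)

    def test_negated_about_mean_r_minus_one(self):
        a = np.array([[0.1], [0.2], [0.3], [0.4]])
        b = np.array([[0.4], [0.3], [0.2], [0.1]])
        r = classwise_correlation(a, b, self._labels(4, 1))
        assert r[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a = rng.uniform(size=(50, 3))
        b = rng.uniform(size=(50, 3))
        r = classwise_correlation(a, b, self._labels(50, 3))
        for c in range(3):
            expected = np.corrcoef(a[:, c], b[:, c])[0, 1]
            assert abs(r[c] - expected) < 1e-12

    def test_restricted_to_labelled_cells(self, rng):
        a = rng.uniform(size=(40, 1))
        b = a.copy()
        labels = np.zeros((40, 1))
        labels[:20] = 1.0
        b[20:] = rng.uniform(size=(20, 1))  # garbage outside the labelled set
        r = classwise_correlation(a, b, labels)
        assert r[0] == pytest.approx(1.0)

    def test_degenerate_cases_default_to_zero(self):
        const = np.full((5, 1), 0.5)
        varying = np.linspace(0, 1, 5)[:, None]
        r = classwise_correlation(const, varying, np.ones((5, 1)))
        assert r[0] == 0.0
        with pytest.warns(UserWarning, match="fewer than 2"):
            r = classwise_correlation(varying, varying, np.zeros((5, 1)))
        assert r[0] == 0.0


class TestFuseStreams:
    def test_product_rule_above_threshold(self):
        pol = FusionPolicy(r=np.array([0.9]))
        out = fuse_streams(np.array([0.8]), np.array([0.5]), pol)
        assert out[0] == pytest.approx(0.4)

    def test_cell_only_below_threshold(self):
        pol = FusionPolicy(r=np.array([0.1]))
        out = fuse_streams(np.array([0.8]), np.array([0.5]), pol)
        assert out[0] == pytest.approx(0.5)

    def test_image_probability_one_is_identity(self, rng):
        cell = rng.uniform(size=4)
        for r in (np.full(4, -1.0), np.full(4, 1.0)):
            out = fuse_streams(np.ones(4), cell, FusionPolicy(r=r))
            assert np.allclose(out, cell)

    def test_threshold_limits(self, rng):
        img, cell = rng.uniform(size=3), rng.uniform(size=3)
        r = rng.uniform(-1, 1, size=3)
        pure_product = fuse_streams(img, cell, FusionPolicy(r=r, rho_th=-np.inf))
        assert np.allclose(pure_product, img * cell)
        pure_cell = fuse_streams(img, cell, FusionPolicy(r=r, rho_th=np.inf))
        assert np.allclose(pure_cell, cell)

    def test_default_threshold_is_032(self):
        pol = FusionPolicy(r=np.array([0.33, 0.31]))
        assert pol.rho_th == 0.32
        assert list(pol.mode) == ["product", "cell_only"]

    def test_outputs_stay_in_unit_interval(self, rng):
        img, cell = rng.uniform(size=6), rng.uniform(size=6)
        out = fuse_streams(img, cell, FusionPolicy(r=rng.uniform(-1, 1, 6)))
        assert (out >= 0).all() and (out <= 1).all()

    def test_policy_json_round_trip(self):
        pol = FusionPolicy(r=np.array([0.5, -0.2]), rho_th=0.32)
        back = FusionPolicy.from_json(pol.to_json())
        assert np.allclose(back.r, pol.r)
        assert back.rho_th == pol.rho_th


class TestSelectDiverse:
    def test_argmax_within_family(self):
        spec = select_diverse([("a", "f1", 0.5), ("b", "f1", 0.7), ("c", "f1", 0.6)])
        assert spec.members == [("b", "f1")]

    def test_one_member_per_family(self):
        spec = select_diverse([("a", "f1", 0.5), ("b", "f2", 0.4)])
        assert len(spec.members) == 2

    def test_tie_broken_lexicographically(self):
        spec = select_diverse([("zeta", "f1", 0.5), ("alpha", "f1", 0.5)])
        assert spec.members == [("alpha", "f1")]

    def test_identical_models_give_all_ones_matrix(self, rng):
        m = rng.uniform(size=(10, 3))
        spec = select_diverse(
            [("a", "f1", 0.5), ("b", "f2", 0.5)],
            prob_matrices={"a": m, "b": m})
        assert np.allclose(spec.correlation_matrix, 1.0)


class TestEnsembleDominance:
    def test_ensemble_not_worse_than_best_member(self, reference_runs):
        """On the reference benchmark, averaging three comparably trained
        cell-level models never falls more than 0.01 mAP below the best
        single member, across three seeds."""
        from hcpl import pipeline
        for seed, run in reference_runs.items():
            table = run["table"]
            tr_rows = table.rows_of_images(run["train_ids"])
            va_rows = table.rows_of_images(run["val_ids"])
            member_probs, member_maps = [], []
            for k in range(3):
                model = pipeline.train_cla(table, table.weak_labels, tr_rows,
                                           seed=seed * 10 + k, epochs=8)
                probs = model.predict_probs(table.crops[va_rows])
                member_probs.append(probs)
                member_maps.append(pipeline.score_rows(probs, table, va_rows).map)
            policy = FusionPolicy(r=np.full(table.n_classes, -1.0))  # cell-only
            combined = aggregate_apply(member_probs, member_probs, policy,
                                       np.ones(len(va_rows)))
            ens_map = pipeline.score_rows(combined, table, va_rows).map
            assert ens_map >= max(member_maps) - 0.01, \
                f"seed {seed}: ensemble {ens_map:.4f} vs best {max(member_maps):.4f}"


class TestAggregateApply:
    def test_single_member_reduces_to_fuse_streams(self, rng):
        cell = rng.uniform(size=(5, 3))
        img = rng.uniform(size=(5, 3))
        pol = FusionPolicy(r=rng.uniform(-1, 1, 3))
        out = aggregate_apply([cell], [img], pol, np.ones(5))
        expected = np.stack([fuse_streams(img[i], cell[i], pol) for i in range(5)])
        assert np.allclose(out, expected)

    def test_duplicate_members_equal_single(self, rng):
        cell = rng.uniform(size=(4, 2))
        img = rng.uniform(size=(4, 2))
        pol = FusionPolicy(r=np.array([1.0, -1.0]))
        one = aggregate_apply([cell], [img], pol, np.ones(4))
        two = aggregate_apply([cell, cell], [img, img], pol, np.ones(4))
        assert np.allclose(one, two)

    def test_three_member_elementwise_oracle(self, rng):
        cells = [rng.uniform(size=(6, 4)) for _ in range(3)]
        imgs = [rng.uniform(size=(6, 4)) for _ in range(3)]
        families = ["f1", "f1", "f2"]
        w_v = rng.uniform(size=6)
        pol = FusionPolicy(r=rng.uniform(-1, 1, 4))
        out = aggregate_apply(cells, imgs, pol, w_v, families=families)
        for i in range(6):
            for c in range(4):
                fam1_c = (cells[0][i, c] + cells[1][i, c]) / 2
                cell_mean = (fam1_c + cells[2][i, c]) / 2
                fam1_i = (imgs[0][i, c] + imgs[1][i, c]) / 2
                img_mean = (fam1_i + imgs[2][i, c]) / 2
                if pol.r[c] > pol.rho_th:
                    expected = img_mean * cell_mean
                else:
                    expected = cell_mean
                assert abs(out[i, c] - expected * w_v[i]) < 1e-12

    def test_member_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_apply([rng.uniform(size=(3, 2))],
                            [rng.uniform(size=(4, 2))],
                            FusionPolicy(r=np.zeros(2)), np.ones(3))

    def test_outputs_bounded_by_unit_interval(self, rng):
        cells = [rng.uniform(size=(8, 3)) for _ in range(2)]
        imgs = [rng.uniform(size=(8, 3)) for _ in range(2)]
        out = aggregate_apply(cells, imgs, FusionPolicy(r=np.ones(3)),
                              rng.uniform(size=8))
        assert (out >= 0).all() and (out <= 1).all()
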