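"""KNN recommender: Gower similarity, neighbour prediction, cold start."""

import itertools

import numpy as np
import pandas as pd
import pytest

from parweb import knn
from parweb.networks import MetaNetwork, TraitTable
from conftest import make_trait_row


class TestGowerSimilarity:
    def test_identical_rows_have_similarity_one(self, small_traits):
        df = small_traits.df.copy()
        df.loc["P:x2"] = df.loc["P:x"]
        sim = knn.gower_similarity(TraitTable(df.reset_index()), "parasitoid",
                                   ("body_size", "phenology", "nd"))
        assert sim.loc["P:x", "P:x2"] == pytest.approx(1.0)

    def test_hand_worked_two_trait_case(self):
        # one continuous trait with values 2 and 7 over a range of 10
        # (realised by a third species at 12) and matching phenology:
        # dissimilarity (0.5 + 0)/2 = 0.25
        rows = [
            make_trait_row("P:a", "parasitoid", 2.0, [1, 1, 0, 0, 0, 0, 0]),
            make_trait_row("P:b", "parasitoid", 7.0, [1, 1, 0, 0, 0, 0, 0]),
            make_trait_row("P:c", "parasitoid", 12.0, [1, 0, 0, 0, 0, 0, 0]),
        ]
        sim = knn.gower_similarity(TraitTable(pd.DataFrame(rows)), "parasitoid",
                                   ("body_size", "phenology"))
        assert sim.loc["P:a", "P:b"] == pytest.approx(0.75)

    def test_symmetric_with_unit_diagonal(self, small_traits):
        sim = knn.gower_similarity(small_traits, "parasitoid",
                                   ("body_size", "phenology", "nd"))
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)

    def test_zero_range_trait_dropped_with_warning(self):
        rows = [
            make_trait_row("P:a", "parasitoid", 5.0, [1, 0, 0, 0, 0, 0, 0], nd=0.5),
            make_trait_row("P:b", "parasitoid", 5.0, [0, 1, 0, 0, 0, 0, 0], nd=0.5),
        ]
        with pytest.warns(UserWarning, match="zero range"):
            sim = knn.gower_similarity(TraitTable(pd.DataFrame(rows)), "parasitoid",
                                       ("body_size", "phenology"))
        # only the phenology block remains: disjoint months -> similarity 0
        assert sim.loc["P:a", "P:b"] == pytest.approx(0.0)

    def test_no_usable_traits_errors(self):
        rows = [
            make_trait_row("P:a", "parasitoid", 5.0, [1, 0, 0, 0, 0, 0, 0]),
            make_trait_row("P:b", "parasitoid", 5.0, [0, 1, 0, 0, 0, 0, 0]),
        ]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable traits"):
                knn.gower_similarity(TraitTable(pd.DataFrame(rows)), "parasitoid",
                                     ("body_size",))


@pytest.fixture
def sim_and_meta(small_traits, small_meta):
    sim = knn.gower_similarity(small_traits, "parasitoid",
                               ("body_size", "phenology", "nd"))
    return sim, small_meta


class TestKnnPredict:
    def test_twin_copy_with_k1(self, small_traits, small_meta):
        df = small_traits.df.copy()
        df.loc["P:new"] = df.loc["P:y"]  # exact trait twin of P:y
        traits = TraitTable(df.reset_index())
        sim = knn.gower_similarity(traits, "parasitoid",
                                   ("body_size", "phenology", "nd"))
        pred = knn.knn_predict(small_meta, sim, knn.KNNHyperparams(k=1, seed=0),
                               "P:new", small_meta.hosts)
        expected = small_meta.counts["P:y"].astype(float)
        pd.testing.assert_series_equal(pred, expected, check_names=False)

    def test_uniform_mean_of_two_neighbours(self, sim_and_meta):
        sim, meta = sim_and_meta
        hp = knn.KNNHyperparams(k=2, weighting="uniform", seed=0)
        pred = knn.knn_predict(meta, sim, hp, "P:x", meta.hosts, exclude_self=True)
        # neighbours are P:y and P:z; H:a frequencies are 0 and 0 -> 0;
        # H:b: (3 + 0)/2 ; H:c: (0 + 5)/2
        assert pred["H:b"] == pytest.approx(1.5)
        assert pred["H:c"] == pytest.approx(2.5)

    def test_self_exclusion_uses_next_nearest(self, sim_and_meta):
        sim, meta = sim_and_meta
        hp = knn.KNNHyperparams(k=1, seed=0)
        pred = knn.knn_predict(meta, sim, hp, "P:x", meta.hosts, exclude_self=True)
        assert not np.allclose(pred.to_numpy(),
                               meta.counts["P:x"].to_numpy(dtype=float))

    def test_convex_combination_bounds(self, sim_and_meta):
        sim, meta = sim_and_meta
        for k, weighting in itertools.product((1, 2, 3), ("uniform", "similarity")):
            hp = knn.KNNHyperparams(k=k, weighting=weighting, seed=1)
            pred = knn.knn_predict(meta, sim, hp, "P:y", meta.hosts,
                                   exclude_self=True)
            others = meta.counts.drop(columns="P:y").astype(float)
            assert (pred >= others.min(axis=1) - 1e-12).all()
            assert (pred <= others.max(axis=1) + 1e-12).all()

    def test_brute_force_oracle_matches(self, sim_and_meta):
        """Exhaustive neighbour search reproduces knn_predict exactly."""
        sim, meta = sim_and_meta
        for focal in meta.parasitoids:
            hp = knn.KNNHyperparams(k=2, weighting="similarity", seed=3)
            pred = knn.knn_predict(meta, sim, hp, focal, meta.hosts,
                                   exclude_self=True)
            pool = [p for p in meta.parasitoids if p != focal]
            # distinct similarities here, so the top-k set is unambiguous
            best = sorted(pool, key=lambda p: -sim.loc[focal, p])[:2]
            w = np.array([sim.loc[focal, p] for p in best])
            w = w / w.sum()
            oracle = sum(
                wi * meta.counts[p].astype(float) for wi, p in zip(w, best)
            )
            assert np.allclose(pred.to_numpy(), oracle.to_numpy())

    def test_order_permutation_invariance(self, small_traits, small_meta):
        sim = knn.gower_similarity(small_traits, "parasitoid",
                                   ("body_size", "phenology", "nd"))
        hp = knn.KNNHyperparams(k=2, seed=5)
        a = knn.knn_predict(small_meta, sim, hp, "P:x", small_meta.hosts)
        shuffled = MetaNetwork(small_meta.counts[["P:z", "P:x", "P:y"]],
                               "weighted", "combined")
        b = knn.knn_predict(shuffled, sim, hp, "P:x", small_meta.hosts)
        pd.testing.assert_series_equal(a, b)

    def test_k_clamped_with_warning_and_empty_pool_errors(self, sim_and_meta):
        sim, meta = sim_and_meta
        with pytest.warns(UserWarning, match="neighbours available"):
            knn.knn_predict(meta, sim, knn.KNNHyperparams(k=5, seed=0), "P:x",
                            meta.hosts)
        lone = MetaNetwork(meta.counts[["P:x"]], "weighted", "combined")
        with pytest.raises(ValueError, match="no eligible neighbours"):
            knn.knn_predict(lone, sim, knn.KNNHyperparams(k=1, seed=0), "P:x",
                            meta.hosts)


class TestAddNewHosts:
    def test_twin_host_copies_profile(self, small_traits, small_meta):
        df = small_traits.df.copy()
        df.loc["H:new"] = df.loc["H:b"]
        traits = TraitTable(df.reset_index())
        host_sim = knn.gower_similarity(
            traits, "host", ("body_size", "phenology", "nd", "status")
        )
        aug = knn.add_new_hosts(small_meta, ["H:new"], host_sim,
                                knn.KNNHyperparams(k=1, seed=0))
        assert np.allclose(aug.counts.loc["H:new"],
                           small_meta.counts.loc["H:b"].astype(float))

    def test_training_rows_unchanged_and_shape(self, small_traits, small_meta):
        df = small_traits.df.copy()
        df.loc["H:new"] = df.loc["H:a"]
        traits = TraitTable(df.reset_index())
        host_sim = knn.gower_similarity(
            traits, "host", ("body_size", "phenology", "nd", "status")
        )
        aug = knn.add_new_hosts(small_meta, ["H:new"], host_sim,
                                knn.KNNHyperparams(k=2, seed=0))
        assert len(aug.counts) == len(small_meta.counts) + 1
        pd.testing.assert_frame_equal(
            aug.counts.loc[small_meta.hosts],
            small_meta.counts.astype(float),
        )

    def test_elementwise_mean_of_neighbour_rows(self):
        rows = [
            make_trait_row("H:a", "host", 2.0, [1, 0, 0, 0, 0, 0, 0]),
            make_trait_row("H:b", "host", 4.0, [0, 1, 0, 0, 0, 0, 0]),
            make_trait_row("H:new", "host", 3.0, [1, 1, 0, 0, 0, 0, 0]),
        ]
        traits = TraitTable(pd.DataFrame(rows))
        host_sim = knn.gower_similarity(traits, "host", ("body_size",),
                                        species=["H:a", "H:b", "H:new"])
        meta = MetaNetwork(
            pd.DataFrame([[2, 0], [0, 4]], index=["H:a", "H:b"],
                         columns=["P:x", "P:y"]),
            "weighted", "combined",
        )
        aug = knn.add_new_hosts(meta, ["H:new"], host_sim,
                                knn.KNNHyperparams(k=2, weighting="uniform", seed=0))
        assert list(aug.counts.loc["H:new"]) == [1.0, 2.0]

    def test_existing_host_rejected(self, small_traits, small_meta):
        host_sim = knn.gower_similarity(
            small_traits, "host", ("body_size", "phenology", "nd", "status")
        )
        with pytest.raises(ValueError, match="already present"):
            knn.add_new_hosts(small_meta, ["H:a"], host_sim,
                              knn.KNNHyperparams(k=1, seed=0))


class TestPredictSiteFrequencies:
    def test_full_matrix_nonnegative(self, small_traits, small_meta):
        sim = knn.gower_similarity(small_traits, "parasitoid",
                                   ("body_size", "phenology", "nd"))
        out = knn.predict_site_frequencies(
            small_meta, sim, knn.KNNHyperparams(k=2, seed=0), "site1",
            small_meta.hosts, small_meta.parasitoids,
        )
        assert out.shape == (3, 3)
        assert (out.to_numpy() >= 0).all()

    def test_zero_meta_propagates_zero(self, small_traits, small_meta):
        sim = knn.gower_similarity(small_traits, "parasitoid",
                                   ("body_size", "phenology", "nd"))
        zero = MetaNetwork(small_meta.counts * 0, "weighted", "combined")
        out = knn.predict_site_frequencies(
            zero, sim, knn.KNNHyperparams(k=2, seed=0), "site1",
            zero.hosts, zero.parasitoids,
        )
        assert (out.to_numpy() == 0).all()


class TestTuneKnn:
    def test_grid_of_one_returned(self, small_traits, small_meta):
        builder = lambda mask: knn.gower_similarity(small_traits, "parasitoid", mask)
        hp = knn.KNNHyperparams(k=1, mask=("body_size", "phenology"), seed=0)
        best, table = knn.tune_knn(small_meta, builder, [hp], folds=2)
        assert best == hp

    def test_informative_mask_wins(self):
        """Host use tracks body size; a size-based mask must beat a
        noise-trait (nd-only) mask in leave-species-out error."""
        rng = np.random.default_rng(0)
        rows, cols = [], {}
        hosts = [f"H:h{i}" for i in range(6)]
        for i, h in enumerate(hosts):
            rows.append(make_trait_row(h, "host", float(2 + i), [1] * 7))
        for j in range(8):
            size = float(2 + (j % 6))
            rows.append(make_trait_row(f"P:p{j}", "parasitoid", size, [1] * 7,
                                       nd=float(rng.uniform(0, 1))))
            # parasitoid attacks the host matching its size
            cols[f"P:p{j}"] = [8 if i == (j % 6) else 0 for i in range(6)]
        traits = TraitTable(pd.DataFrame(rows))
        meta = MetaNetwork(pd.DataFrame(cols, index=hosts), "weighted", "combined")
        builder = lambda mask: knn.gower_similarity(traits, "parasitoid", mask)
        grid = [
            knn.KNNHyperparams(k=1, mask=("body_size",), seed=0),
            knn.KNNHyperparams(k=1, mask=("nd",), seed=0),
        ]
        best, table = knn.tune_knn(meta, builder, grid, folds=2)
        assert best.mask == ("body_size",)
        assert table.loc[0, "cv_rmse"] < table.loc[1, "cv_rmse"]

    def test_too_many_folds_errors(self, small_traits, small_meta):
        builder = lambda mask: knn.gower_similarity(small_traits, "parasitoid", mask)
        with pytest.raises(ValueError, match="folds"):
            knn.tune_knn(small_meta, builder,
                         [knn.KNNHyperparams(k=1, seed=0)], folds=10)
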