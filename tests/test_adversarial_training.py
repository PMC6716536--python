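"""Adversarial update correctness, batching, warmup, and mining."""

import numpy as np
import pytest

from stainshift.adversarial_training import (
    ArchitectureSpec,
    DannClassifier,
    TrainConfig,
    balanced_batches,
    augment_minority_class,
    build_model,
    dann_step,
    mine_hard_negatives,
    records_to_arrays,
)
from stainshift.nn import Dense, Flatten, GradientReversal, ReLU, Sequential
from stainshift.synthetic_cohort import PatchRecord, make_centers, make_patch

from conftest import clean_cohort_config

TINY_ARCH = ArchitectureSpec(
    input_size=(8, 8, 3), conv_channels=(), feature_dim=8, domain_hidden=4,
    dropout_rate=0.0,
)


def tiny_records(n_per_domain=6, n_domains=2, size=8, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for d in range(n_domains):
        for i in range(n_per_domain):
            img = rng.integers(0, 256, size=(size, size, 3)).astype(np.uint8)
            records.append(
                PatchRecord(img, 0, 0, i % 2, f"dom{d}", "train")
            )
    return records


class TestBuildModel:
    def test_baseline_has_single_head(self, rng):
        model = build_model(TINY_ARCH, 2, adversarial=False, init_rng=rng)
        assert model.domain_head is None and not model.adversarial

    def test_adversarial_needs_two_domains(self, rng):
        with pytest.raises(ValueError):
            build_model(TINY_ARCH, 1, adversarial=True, init_rng=rng,
                        domain_init_rng=np.random.default_rng(1))

    def test_trunk_params_unchanged_by_domain_head(self):
        a = build_model(TINY_ARCH, 3, adversarial=False,
                        init_rng=np.random.default_rng(5))
        b = build_model(TINY_ARCH, 3, adversarial=True,
                        init_rng=np.random.default_rng(5),
                        domain_init_rng=np.random.default_rng(6))
        assert a.trunk.n_parameters() == b.trunk.n_parameters()
        for (la, na), (lb, nb) in zip(a.task_head.parameters(),
                                      b.task_head.parameters()):
            np.testing.assert_array_equal(la.params[na], lb.params[nb])

    def test_reversal_is_identity_at_inference(self, rng):
        model = build_model(TINY_ARCH, 2, adversarial=True,
                            init_rng=np.random.default_rng(2),
                            domain_init_rng=np.random.default_rng(3))
        x = rng.normal(size=(4, 8, 8, 3))
        f = model.features(x)
        # forward through the domain head ignores the reversal node
        np.testing.assert_array_equal(model.grl.forward(f), f)


class TestSaddlePointUpdate:
    def test_matches_hand_derived_linear_update(self):
        """One step on a 1-feature linear model against closed-form
        gradients of L_y and L_d (binary logistic in both heads)."""
        w_f, w_y, w_d = 0.7, np.array([0.3, -0.2]), np.array([-0.5, 0.4])
        mu, lam = 0.05, 0.8
        x0, y0, d0 = 1.5, 1, 0

        trunk = Sequential([Dense(1, 1, np.random.default_rng(0), bias=False)])
        trunk.layers[0].params["W"][:] = w_f
        task = Sequential([Dense(1, 2, np.random.default_rng(0), bias=False)])
        task.layers[0].params["W"][:] = w_y
        grl = GradientReversal()
        dom = Sequential([grl, Dense(1, 2, np.random.default_rng(0), bias=False)])
        dom.layers[1].params["W"][:] = w_d

        from stainshift.adversarial_training import TwoHeadNetwork
        model = TwoHeadNetwork(trunk, task, dom, grl)
        dann_step(model, np.array([[x0]]), np.array([y0]),
                  np.array([[1.0, 0.0]]), mu, lam)

        # hand-derived: f = w_f x; softmax over logits f*w; dL/dlogit = p - onehot
        def soft(v):
            e = np.exp(v - v.max())
            return e / e.sum()

        f = w_f * x0
        py = soft(f * w_y)
        pd = soft(f * w_d)
        ey = py - np.array([0.0, 1.0])   # task label 1
        ed = pd - np.array([1.0, 0.0])   # domain 0
        dLy_dwy = f * ey
        dLd_dwd = f * ed
        dLy_df = np.dot(ey, w_y)
        dLd_df = np.dot(ed, w_d)
        dLy_dwf = dLy_df * x0
        dLd_dwf = dLd_df * x0
        np.testing.assert_allclose(
            trunk.layers[0].params["W"].ravel(),
            w_f - mu * (dLy_dwf - lam * dLd_dwf), atol=1e-6,
        )
        np.testing.assert_allclose(
            task.layers[0].params["W"].ravel(), w_y - mu * dLy_dwy, atol=1e-6
        )
        np.testing.assert_allclose(
            dom.layers[1].params["W"].ravel(), w_d - mu * lam * dLd_dwd, atol=1e-6
        )

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0, 2.0])
    def test_finite_difference_on_small_model(self, lam):
        """The realized updates equal -mu * finite-difference gradients of
        the correct objectives: L_y - lam L_d for the trunk, L_y for the
        task head, L_d for the domain head."""
        from stainshift.adversarial_training import TwoHeadNetwork
        from stainshift.nn import softmax_cross_entropy

        rng = np.random.default_rng(7)
        x = rng.normal(size=(4, 2))
        y = np.array([0, 1, 1, 0])
        d = np.eye(2)[[0, 0, 1, 1]]
        mu = 0.01

        def fresh():
            trunk = Sequential([Dense(2, 2, np.random.default_rng(1), bias=False)])
            task = Sequential([Dense(2, 2, np.random.default_rng(2), bias=False)])
            grl = GradientReversal()
            dom = Sequential([grl, Dense(2, 2, np.random.default_rng(3),
                                         bias=False)])
            return TwoHeadNetwork(trunk, task, dom, grl)

        model = fresh()

        def losses(m):
            f = m.trunk.forward(x)
            ly, _ = softmax_cross_entropy(m.task_head.forward(f), y)
            ld, _ = softmax_cross_entropy(m.domain_head.forward(f), d)
            return ly, ld

        # numerical gradients for all 12 parameters
        eps = 1e-6
        expected = {}
        for net_name in ("trunk", "task_head", "domain_head"):
            net = getattr(model, net_name)
            for layer, name in net.parameters():
                p = layer.params[name]
                g_y = np.zeros_like(p)
                g_d = np.zeros_like(p)
                it = np.nditer(p, flags=["multi_index"])
                for _ in it:
                    i = it.multi_index
                    orig = p[i]
                    p[i] = orig + eps
                    ly_p, ld_p = losses(model)
                    p[i] = orig - eps
                    ly_m, ld_m = losses(model)
                    p[i] = orig
                    g_y[i] = (ly_p - ly_m) / (2 * eps)
                    g_d[i] = (ld_p - ld_m) / (2 * eps)
                if net_name == "trunk":
                    step = -mu * (g_y - lam * g_d)
                elif net_name == "task_head":
                    step = -mu * g_y
                else:
                    step = -mu * lam * g_d
                expected[(net_name, name)] = p + step

        dann_step(model, x, y, d, mu, lam)
        for net_name in ("trunk", "task_head", "domain_head"):
            net = getattr(model, net_name)
            for layer, name in net.parameters():
                np.testing.assert_allclose(
                    layer.params[name], expected[(net_name, name)], atol=1e-4,
                    err_msg=f"{net_name}.{name} at lam={lam}",
                )

    def test_divergence_aborts(self):
        from stainshift.adversarial_training import TwoHeadNetwork

        trunk = Sequential([Dense(1, 1, np.random.default_rng(0))])
        task = Sequential([Dense(1, 2, np.random.default_rng(0))])
        trunk.layers[0].params["W"][:] = np.nan
        model = TwoHeadNetwork(trunk, task, None, None)
        with pytest.raises(RuntimeError, match="diverged"):
            dann_step(model, np.ones((2, 1)), np.array([0, 1]), None, 0.1, 0.0)


class TestLambdaZeroEquivalence:
    def test_lam_zero_matches_baseline_trajectory(self):
        records = tiny_records(n_per_domain=10)
        cfg = TrainConfig(iterations=15, warmup_iters=0, lam=0.0, batch_size=4,
                          seed=3, balance_minority=False)
        base = DannClassifier(records, cfg, TINY_ARCH, adversarial=False).fit()
        dann = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit()
        for a, b in zip(base.model.trunk.state(), dann.model.trunk.state()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(base.model.task_head.state(), dann.model.task_head.state()):
            np.testing.assert_array_equal(a, b)

    def test_warmup_keeps_trunk_on_baseline_path(self):
        records = tiny_records(n_per_domain=10)
        cfg = TrainConfig(iterations=10, warmup_iters=10, lam=1.0, batch_size=4,
                          seed=3, balance_minority=False)
        base = DannClassifier(records, cfg, TINY_ARCH, adversarial=False).fit()
        dann = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit()
        for a, b in zip(base.model.trunk.state(), dann.model.trunk.state()):
            np.testing.assert_array_equal(a, b)
        assert (dann.history["lam"] == 0.0).all()

    def test_lambda_schedule_recorded(self):
        records = tiny_records(n_per_domain=10)
        cfg = TrainConfig(iterations=8, warmup_iters=5, lam=1.5, batch_size=4,
                          seed=0, balance_minority=False)
        fit = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit()
        assert len(fit.history) == 8
        assert (fit.history["lam"][:5] == 0.0).all()
        assert (fit.history["lam"][5:] == 1.5).all()

    def test_same_seed_same_history(self):
        records = tiny_records(n_per_domain=10)
        cfg = TrainConfig(iterations=10, warmup_iters=2, batch_size=4, seed=11,
                          balance_minority=False)
        h1 = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit().history
        h2 = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit().history
        assert h1.equals(h2)


class TestBalancedBatches:
    def test_exact_composition_over_100_batches(self, rng):
        d = np.array([0] * 50 + [1] * 7 + [2] * 23)
        stream = balanced_batches(d, 30, 3, rng)
        for _ in range(100):
            idx, onehot = next(stream)
            counts = np.bincount(d[idx], minlength=3)
            np.testing.assert_array_equal(counts, [10, 10, 10])
            assert onehot.shape == (30, 3)
            np.testing.assert_array_equal(onehot.sum(axis=1), 1.0)

    def test_indivisible_batch_size_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            next(balanced_batches(np.array([0, 1, 2]), 10, 3, rng))

    def test_empty_domain_rejected(self, rng):
        with pytest.raises(ValueError, match="no records"):
            next(balanced_batches(np.array([0, 0, 2]), 3, 3, rng))


class TestMinorityAugmentation:
    def test_balances_with_dihedral_copies(self):
        records = [
            PatchRecord(np.full((4, 4, 3), v, dtype=np.uint8), 0, 0,
                        1 if v < 2 else 0, "d", "train")
            for v in range(10)
        ]
        out = augment_minority_class(records)
        n_pos = sum(r.task_label == 1 for r in out)
        n_neg = sum(r.task_label == 0 for r in out)
        assert n_neg == 8 and n_pos == 8
        assert all(r.task_label in (0, 1) for r in out)

    def test_no_op_when_balanced(self):
        records = tiny_records(n_per_domain=4)
        assert len(augment_minority_class(records)) == len(records)


class TestInferenceIndependence:
    def test_prediction_never_reads_domain_label(self):
        records = tiny_records(n_per_domain=8)
        cfg = TrainConfig(iterations=5, warmup_iters=0, batch_size=4, seed=0,
                          balance_minority=False)
        fit = DannClassifier(records, cfg, TINY_ARCH, adversarial=True).fit()
        relabeled = [
            PatchRecord(r.image, r.x, r.y, r.task_label, "unknown-center",
                        r.partition)
            for r in records
        ]
        np.testing.assert_array_equal(
            fit.predict_proba(records), fit.predict_proba(relabeled)
        )


class TestHardNegativeMining:
    def _mining_setup(self, threshold):
        config = clean_cohort_config()
        center = make_centers(config)[0]
        rng = np.random.default_rng(21)
        positives = [make_patch(center, 1, config, rng) for _ in range(25)]
        plain = [make_patch(center, 0, config, rng) for _ in range(40)]
        # plants: positive-like morphology recorded as negatives
        plants = []
        for _ in range(10):
            rec = make_patch(center, 1, config, rng)
            plants.append(PatchRecord(rec.image, rec.x, rec.y, 0,
                                      rec.domain_label, "train"))
        candidates = plain + plants
        arch = ArchitectureSpec(input_size=(64, 64, 3),
                                conv_channels=(4, 4, 8, 8, 8),
                                feature_dim=16, dropout_rate=0.0)
        cfg = TrainConfig(iterations=150, warmup_iters=0, batch_size=10,
                          seed=2, balance_minority=False, mu=0.02)
        return positives, candidates, plants, cfg, arch, threshold

    def test_mined_set_is_subset_and_enriched_for_plants(self):
        positives, candidates, plants, cfg, arch, _ = self._mining_setup(0.5)
        mined, scores = mine_hard_negatives(positives, candidates, cfg, arch,
                                            threshold=0.5)
        assert len(scores) == len(candidates)
        ids = {id(r) for r in candidates}
        assert all(id(r) in ids for r in mined)
        plant_ids = {id(r) for r in plants}
        frac_pool = len(plants) / len(candidates)
        frac_mined = sum(id(r) in plant_ids for r in mined) / max(len(mined), 1)
        assert frac_mined > 2 * frac_pool

    def test_impossible_threshold_falls_back_to_top_k(self):
        positives, candidates, _, cfg, arch, _ = self._mining_setup(1.0)
        with pytest.warns(UserWarning, match="falling back"):
            mined, scores = mine_hard_negatives(
                positives, candidates, cfg, arch, threshold=1.0, fallback_k=5
            )
        assert len(mined) == 5
        top = set(np.argsort(scores)[::-1][:5])
        by_identity = {id(c): i for i, c in enumerate(candidates)}
        assert {by_identity[id(r)] for r in mined} == top
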