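"""Tests for the bootstrapping loop: buffer law, mixed updates, invariants."""

import math

import numpy as np
import pytest

from confboot.bootstrap import (
    Buffer,
    BootstrapConfig,
    buffer_sample,
    rollout,
    run_bootstrapping,
    update,
)
from confboot.confidence import OracleConfidence
from confboot.diffusion import Adam, ScoreMLP, WeightFn, train_score_model
from confboot.toytask import TAU, ToyComplex, make_task


def _buffer_with(cs):
    buf = Buffer()
    for i, c in enumerate(cs):
        buf.add(np.array([float(i), 0.0]), np.zeros(2), c)
    return buf


class TestBufferSample:
    def test_errors(self):
        with pytest.raises(ValueError):
            buffer_sample(Buffer(), 1, 1.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            buffer_sample(_buffer_with([0.0]), 0, 1.0, np.random.default_rng(0))

    def test_equal_confidences_sample_uniformly(self):
        buf = _buffer_with([0.7, 0.7, 0.7])
        draws = buffer_sample(buf, 60_000, 1.0, np.random.default_rng(1))
        counts = np.bincount([int(x[0][0]) for x in draws], minlength=3)
        # 3-sigma multinomial band around n*p
        p = 1 / 3
        sigma = math.sqrt(60_000 * p * (1 - p))
        assert np.all(np.abs(counts - 60_000 * p) < 3 * sigma)

    def test_log_ratio_confidences_give_exact_odds(self):
        """c = [0, ln 2] at temperature 1 yields probabilities [1/3, 2/3]."""
        buf = _buffer_with([0.0, math.log(2.0)])
        draws = buffer_sample(buf, 60_000, 1.0, np.random.default_rng(2))
        frac1 = np.mean([int(x[0][0]) == 1 for x in draws])
        sigma = math.sqrt((2 / 3) * (1 / 3) / 60_000)
        assert abs(frac1 - 2 / 3) < 3 * sigma

    def test_temperature_flattens_distribution(self):
        buf = _buffer_with([0.0, 5.0])
        hot = buffer_sample(buf, 20_000, 10.0, np.random.default_rng(3))
        cold = buffer_sample(buf, 20_000, 0.5, np.random.default_rng(3))
        hot1 = np.mean([int(x[0][0]) == 1 for x in hot])
        cold1 = np.mean([int(x[0][0]) == 1 for x in cold])
        assert cold1 > hot1 > 0.5

    def test_capacity_evicts_oldest(self):
        buf = Buffer(capacity=3)
        for c in range(5):
            buf.add(np.zeros(2), np.zeros(2), float(c))
        assert len(buf) == 3
        assert list(buf.confidences) == [2.0, 3.0, 4.0]


@pytest.fixture(scope="module")
def small_task():
    return make_task(2, 1, 10, seed=7)


@pytest.fixture(scope="module")
def small_model(small_task, schedule):
    from confboot.pipeline import pretrain_generator

    return pretrain_generator(small_task, schedule, seed=7, n_steps=800)


class TestRollout:
    def test_cardinality_and_determinism(self, small_task, small_model, schedule):
        complexes = small_task[1][:10]
        conf = OracleConfidence()
        a = rollout(small_model, complexes, conf, 4, schedule, np.random.default_rng(5))
        b = rollout(small_model, complexes, conf, 4, schedule, np.random.default_rng(5))
        assert len(a) == 40
        assert np.allclose(a.confidences, b.confidences)
        assert all(np.array_equal(x1, x2) for (x1, _, _), (x2, _, _)
                   in zip(a.entries, b.entries))

    def test_arguments_validated(self, small_task, small_model, schedule):
        with pytest.raises(ValueError):
            rollout(small_model, [], OracleConfidence(), 4, schedule,
                    np.random.default_rng(0))
        with pytest.raises(ValueError):
            rollout(small_model, small_task[1][:2], OracleConfidence(), 0, schedule,
                    np.random.default_rng(0))

    def test_oracle_scores_good_poses_above_bad(self, small_task, small_model, schedule):
        complexes = small_task[1]
        buf = rollout(small_model, complexes, OracleConfidence(), 8, schedule,
                      np.random.default_rng(9))
        by_cplx = {id(c): c for c in complexes}
        good, bad = [], []
        for (x, d, c), cplx in zip(buf.entries,
                                   [c for c in complexes for _ in range(8)]):
            (good if np.linalg.norm(x - cplx.x_star) < TAU else bad).append(c)
        if good and bad:
            assert np.mean(good) > np.mean(bad)


class TestUpdate:
    def test_zero_buffer_weight_reduces_to_plain_dsm(self, small_task, schedule):
        """With lambda' = 0 the update trajectory is identical to plain DSM
        training on the real pairs with the same seed and optimizer."""
        train_pairs = [(x.x_star, x.d) for x in small_task[1][:10]]
        buf = _buffer_with([0.0, 1.0])
        cfg = BootstrapConfig(sgd_steps_per_iter=20, batch_size=16,
                              lambda_buffer=WeightFn("buffer_weight", scale=0.0))

        m1 = ScoreMLP(2, len(train_pairs[0][1]), hidden=16, seed=0)
        m1.attach_schedule(schedule)
        update(m1, train_pairs, buf, cfg, schedule, np.random.default_rng(77),
               optimizer=Adam(m1.params, lr=cfg.lr))

        m2 = ScoreMLP(2, len(train_pairs[0][1]), hidden=16, seed=0)
        train_score_model(m2, train_pairs, schedule, cfg.lambda_train,
                          n_steps=20, batch_size=8, lr=cfg.lr,
                          rng=np.random.default_rng(77))
        for k in m1.params:
            assert np.allclose(m1.params[k], m2.params[k], atol=1e-12)

    def test_no_real_samples_ignores_train_set(self, small_task, schedule):
        """Under the buffer-only ablation the parameter trajectory does not
        depend on the real training pairs at all."""
        ctx = len(small_task[1][0].d)
        buf = Buffer()
        for i, c in enumerate([0.2, 0.5, 1.0, -0.3]):
            buf.add(np.array([float(i), 0.0]), np.full(ctx, 0.1), c)
        cfg = BootstrapConfig(sgd_steps_per_iter=15, batch_size=8, no_real_samples=True)
        outs = []
        for pairs in ([(x.x_star, x.d) for x in small_task[1][:10]],
                      [(np.full(2, 1e6), np.zeros(len(small_task[1][0].d)))]):
            m = ScoreMLP(2, len(small_task[1][0].d), hidden=16, seed=3)
            m.attach_schedule(schedule)
            update(m, pairs, buf, cfg, schedule, np.random.default_rng(5),
                   optimizer=Adam(m.params, lr=cfg.lr))
            outs.append({k: v.copy() for k, v in m.params.items()})
        for k in outs[0]:
            assert np.array_equal(outs[0][k], outs[1][k])

    def test_no_data_at_all_errors(self, schedule):
        m = ScoreMLP(2, 4, hidden=8, seed=0)
        cfg = BootstrapConfig(no_real_samples=True)
        with pytest.raises(ValueError):
            update(m, [], Buffer(), cfg, schedule, np.random.default_rng(0))


class TestRunBootstrapping:
    def test_k_zero_is_identity(self, small_task, small_model, schedule):
        cfg = BootstrapConfig(K=0)
        model, history = run_bootstrapping(small_model, OracleConfidence(),
                                           small_task, cfg, schedule)
        assert history["iterations"] == []
        for k in model.params:
            assert np.array_equal(model.params[k], small_model.params[k])

    def test_input_model_never_mutated(self, small_task, small_model, schedule):
        before = {k: v.copy() for k, v in small_model.params.items()}
        cfg = BootstrapConfig(K=1, sgd_steps_per_iter=5)
        run_bootstrapping(small_model, OracleConfidence(), small_task, cfg, schedule)
        for k in before:
            assert np.array_equal(before[k], small_model.params[k])

    def test_history_schema(self, small_task, small_model, schedule):
        cfg = BootstrapConfig(K=2, sgd_steps_per_iter=5)
        _, history = run_bootstrapping(small_model, OracleConfidence(),
                                       small_task, cfg, schedule)
        assert len(history["iterations"]) == 2
        for row in history["iterations"]:
            for key in ("median_confidence", "success_rate", "median_distance",
                        "per_cluster"):
                assert key in row

    def test_heldout_poses_never_leak_into_training(self, small_task, schedule):
        """Garbling every held-out true pose changes evaluation metrics only:
        the fine-tuned parameters are bit-identical."""
        from confboot.pipeline import fit_confidence, pretrain_generator

        model = pretrain_generator(small_task, schedule, seed=7, n_steps=400)
        conf = fit_confidence(small_task, model, schedule, seed=7)
        cfg = BootstrapConfig(K=2, sgd_steps_per_iter=10, seed=1)

        clusters, complexes = small_task
        garbled = [
            ToyComplex(x.complex_id, x.cluster_id, x.ligand_feature,
                       np.full_like(x.x_star, 1e3), x.d, x.cluster)
            if x.cluster.role == "heldout" else x
            for x in complexes
        ]
        m1, h1 = run_bootstrapping(model, conf, (clusters, complexes), cfg, schedule)
        m2, h2 = run_bootstrapping(model, conf, (clusters, garbled), cfg, schedule)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])
        assert (h1["iterations"][-1]["success_rate"]
                != h2["iterations"][-1]["success_rate"])

    def test_accumulate_policy_grows_buffer(self, small_task, small_model, schedule):
        complexes = small_task[1][:5]
        rng = np.random.default_rng(0)
        buf = rollout(small_model, complexes, OracleConfidence(), 2, schedule, rng)
        assert len(buf) == 10
        buf = rollout(small_model, complexes, OracleConfidence(), 2, schedule, rng,
                      buffer=buf)
        assert len(buf) == 20
        cfg = BootstrapConfig(K=2, sgd_steps_per_iter=3, buffer_policy="accumulate",
                              rollouts_per_complex=2)
        _, history = run_bootstrapping(small_model, OracleConfidence(),
                                       small_task, cfg, schedule)
        assert len(history["iterations"]) == 2

    def test_time_alpha_changes_training_distribution(self, small_task,
                                                      small_model, schedule):
        """The high-noise-skewed time sampling (alpha=3) runs to completion
        and produces a different parameter trajectory than uniform times."""
        outs = []
        for alpha in (1.0, 3.0):
            cfg = BootstrapConfig(K=1, sgd_steps_per_iter=10, seed=0,
                                  time_alpha=alpha)
            m, _ = run_bootstrapping(small_model, OracleConfidence(),
                                     small_task, cfg, schedule)
            outs.append(m.params["W3"].copy())
        assert not np.allclose(outs[0], outs[1])

    def test_requires_heldout_clusters(self, schedule, small_model):
        clusters, complexes = make_task(2, 1, 8, seed=0)
        train_only = ([c for c in clusters if c.role == "train"],
                      [x for x in complexes if x.cluster.role == "train"])
        with pytest.raises(ValueError):
            run_bootstrapping(small_model, OracleConfidence(), train_only,
                              BootstrapConfig(K=1), schedule)


def test_config_validation():
    with pytest.raises(ValueError):
        BootstrapConfig(K=-1)
    with pytest.raises(ValueError):
        BootstrapConfig(temperature=0.0)
    with pytest.raises(ValueError):
        BootstrapConfig(buffer_policy="banana")
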