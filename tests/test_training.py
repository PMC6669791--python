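import numpy as np
import pytest

from bibnet import nn
from bibnet.models import BibNetConfig, build_bibnet
from bibnet.phantoms import PhantomSpec, generate_cohort
from bibnet.training import (
    TrainConfig,
    TrainingDiverged,
    lr_at_epoch,
    normalize_intensity,
    recalibrate_batchnorm,
    run_tournament_schedule,
    tournament_select,
    tournament_train,
    train_step,
)


def micro_net(seed=0, out_channels=1):
    cfg = BibNetConfig(
        n_levels=2, base_filters=2, enc_blocks=(1, 1), lat_blocks=(1, 1),
        dec_blocks=(1,), dropout_rate=0.0, out_channels=out_channels, seed=seed,
    )
    return build_bibnet(cfg)


class TestLearningRateSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = TrainConfig(planned_epochs=121)
        assert lr_at_epoch(cfg, 0) == pytest.approx(1e-2)
        assert lr_at_epoch(cfg, 120) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 500) == pytest.approx(1e-5)
        assert lr_at_epoch(cfg, 60) == pytest.approx((1e-2 + 1e-5) / 2)

    def test_rejects_negative_epoch(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), -1)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_initial=1e-5, lr_final=1e-2)
        with pytest.raises(ValueError):
            TrainConfig(tournament_schedule=((20, 4), (40, 4), (80, 1)))
        with pytest.raises(ValueError):
            TrainConfig(tournament_schedule=((20, 4), (40, 2), (80, 2)))


class TestTournamentSelection:
    def test_keeps_lowest_losses(self):
        losses = {"a": 0.5, "b": 0.1, "c": 0.3, "d": 0.9}
        assert sorted(tournament_select(losses, 2)) == ["b", "c"]

    def test_two_networks_single_drop(self):
        traces = {"n0": [0.4], "n1": [0.2]}
        out = run_tournament_schedule(traces, [(1, 1)])
        assert out == {1: ["n1"]}

    def test_stubbed_traces_match_brute_force(self):
        """8 -> 4 -> 2 -> 1 at epochs 20/40/80 equals sort-and-keep."""
        rng = np.random.default_rng(99)
        traces = {f"net_{i}": rng.uniform(0.0, 1.0, size=100).tolist() for i in range(8)}
        schedule = [(20, 4), (40, 2), (80, 1)]
        got = run_tournament_schedule(traces, schedule)

        alive = sorted(traces)
        expected = {}
        for epoch, keep in schedule:
            ranked = sorted(alive, key=lambda k: (traces[k][epoch - 1], k))
            alive = ranked[:keep]
            expected[epoch] = sorted(alive)
        for epoch in expected:
            assert sorted(got[epoch]) == expected[epoch]
        assert len(got[80]) == 1

    def test_survivor_counts_follow_schedule(self):
        rng = np.random.default_rng(1)
        traces = {f"net_{i}": rng.uniform(size=90).tolist() for i in range(8)}
        got = run_tournament_schedule(traces, [(20, 4), (40, 2), (80, 1)])
        assert [len(got[e]) for e in (20, 40, 80)] == [4, 2, 1]

    def test_invalid_keep_count(self):
        with pytest.raises(ValueError):
            tournament_select({"a": 0.1}, 2)


class TestTrainStep:
    def test_loss_decreases_on_repeated_batch(self):
        net = micro_net(seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(0.4, 0.2, size=(1, 1, 12, 12, 8)).astype(np.float32)
        y = np.zeros((1, 1, 12, 12, 8), np.float32)
        y[0, 0, 3:9, 3:9, 2:6] = 1.0
        opt = nn.NesterovAdam(net.parameters())
        first = train_step(net, (x, y), opt, lr=1e-3)
        last = None
        for _ in range(200):
            last = train_step(net, (x, y), opt, lr=1e-3)
        assert last < first

    def test_zero_lr_keeps_parameters(self):
        net = micro_net(seed=2)
        before = {k: v.copy() for k, v in net.state_dict().items()}
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        y = np.zeros((1, 1, 8, 8, 8), np.float32)
        y[0, 0, :4] = 1.0
        opt = nn.NesterovAdam(net.parameters())
        train_step(net, (x, y), opt, lr=0.0)
        after = net.state_dict()
        for k in before:
            if "running" in k:  # batch-norm statistics do update in train mode
                continue
            np.testing.assert_array_equal(before[k], after[k], err_msg=k)

    def test_non_finite_loss_aborts(self):
        net = micro_net(seed=3)
        for p in net.parameters():
            p.data[:] = np.float32(1e30)
        x = np.full((1, 1, 8, 8, 8), 1e10, dtype=np.float32)
        y = np.zeros((1, 1, 8, 8, 8), np.float32)
        y[0, 0, 0, 0, 0] = 1.0
        opt = nn.NesterovAdam(net.parameters())
        with pytest.raises(TrainingDiverged), np.errstate(all="ignore"):
            for _ in range(5):
                train_step(net, (x, y), opt, lr=1.0)


class TestNormalizeIntensity:
    def test_window_maps_to_unit_interval(self):
        v = np.array([[[-2000.0, -1024.0, 0.0, 1024.0, 5000.0]]])
        out = normalize_intensity(v)
        assert out.min() == 0.0 and out.max() == 1.0
        assert out[0, 0, 2] == pytest.approx(0.5)


def small_cohort(n, seed, shape=(32, 32, 16)):
    spec = PhantomSpec(shape=shape, noise_sd=10.0)
    cases = generate_cohort(spec, n, seed=seed)
    return [(c.image, c.structures) for c in cases]


@pytest.fixture(scope="module")
def tiny_run():
    train_cases = small_cohort(2, seed=21)
    val_cases = small_cohort(1, seed=22)
    cfg = TrainConfig(
        planned_epochs=3,
        tournament_schedule=((1, 1),),
        n_initializations=2,
        patch_size=(16, 16, 8),
        batch_size=1,
        steps_per_epoch=3,
        patience=2,
        seed=5,
    )

    def factory(seed):
        return build_bibnet(
            BibNetConfig(
                n_levels=2, base_filters=2, enc_blocks=(1, 1), lat_blocks=(1, 1),
                dec_blocks=(1,), dropout_rate=0.0, out_channels=3, seed=seed,
            )
        )

    net, state = tournament_train(factory, train_cases, val_cases, cfg)
    return net, state, cfg


class TestTournamentTrain:

    def test_survivor_counts(self, tiny_run):
        _, state, _ = tiny_run
        assert len(state.survivors) == 1
        assert state.survivors[0] in state.history

    def test_winner_not_worse_than_dropped(self, tiny_run):
        _, state, _ = tiny_run
        drop_epoch = 1
        losses = {nid: state.history[nid][drop_epoch - 1] for nid in state.history}
        winner = state.survivors[0]
        assert losses[winner] == min(losses.values())

    def test_history_lengths_match_epochs(self, tiny_run):
        _, state, _ = tiny_run
        winner = state.survivors[0]
        assert len(state.history[winner]) == state.epoch

    def test_reproducible_loss_trajectories(self):
        train_cases = small_cohort(1, seed=31)
        val_cases = small_cohort(1, seed=32)
        cfg = TrainConfig(
            planned_epochs=2, tournament_schedule=((1, 1),), n_initializations=2,
            patch_size=(16, 16, 8), batch_size=1, steps_per_epoch=2, patience=5, seed=9,
        )

        def factory(seed):
            return build_bibnet(
                BibNetConfig(n_levels=2, base_filters=2, enc_blocks=(1, 1),
                             lat_blocks=(1, 1), dec_blocks=(1,), dropout_rate=0.2,
                             out_channels=3, seed=seed)
            )

        _, s1 = tournament_train(factory, train_cases, val_cases, cfg)
        _, s2 = tournament_train(factory, train_cases, val_cases, cfg)
        assert s1.history == s2.history

    def test_empty_cohorts_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            tournament_train(lambda s: micro_net(s), [], small_cohort(1, 1), cfg)


class TestBatchNormRecalibration:
    def test_running_stats_average_volume_statistics(self):
        net = micro_net(seed=4)
        vols = [np.random.default_rng(i).normal(-500, 300, size=(16, 16, 8)) for i in range(3)]
        recalibrate_batchnorm(net, vols)
        bn_first = [m for m in net.modules() if isinstance(m, nn.BatchNorm3d)][0]
        assert not np.allclose(bn_first.running_mean, 0.0)
        assert not net.training
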