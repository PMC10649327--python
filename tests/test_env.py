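"""MDP mechanics against brute-force pixel-set oracles: IoU, reward sign,
boundary reset, termination strategies, and start-position distribution."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sp_stats

from hippoloc import env
from hippoloc.env import (
    Action,
    EnvConfig,
    TerminationStrategy,
    apply_action,
    compute_reward,
    iou,
    reset,
    step,
)
from hippoloc.preprocess import BoundingBox, SliceSample


def _pixel_set(box):
    return {
        (y, x)
        for y in range(box.y, box.y + box.height)
        for x in range(box.x, box.x + box.width)
    }


def _oracle_iou(a, b):
    pa, pb = _pixel_set(a), _pixel_set(b)
    return len(pa & pb) / len(pa | pb)


def _random_box(rng, size=(50, 65), bound=256):
    w, h = size
    return BoundingBox(
        x=int(rng.integers(-10, bound - w + 10)),
        y=int(rng.integers(-10, bound - h + 10)),
        width=w,
        height=h,
    )


@pytest.fixture(scope="module")
def sample_slice(test_slices):
    return test_slices[0]


class TestIoU:
    def test_identity_disjoint_and_exact_third(self):
        a = BoundingBox(x=0, y=0, width=50, height=65)
        assert iou(a, a) == 1.0
        assert iou(a, BoundingBox(x=200, y=0, width=50, height=65)) == 0.0
        b = BoundingBox(x=25, y=0, width=50, height=65)
        assert iou(a, b) == pytest.approx(1625 / 4875)
        assert iou(a, b) == _oracle_iou(a, b)

    def test_symmetry_and_range_on_random_pairs(self, rng):
        for _ in range(200):
            a, b = _random_box(rng), _random_box(rng)
            v = iou(a, b)
            assert v == iou(b, a)
            assert 0.0 <= v <= 1.0

    def test_zero_area_box_rejected(self):
        with pytest.raises(ValueError):
            BoundingBox(x=0, y=0, width=0, height=5)


class TestApplyAction:
    CFG = EnvConfig()

    def test_direction_conventions(self):
        box = self.CFG.make_box(100, 100)
        shape = (256, 256)
        assert apply_action(box, Action.UP, self.CFG, shape)[0].y == 95
        assert apply_action(box, Action.DOWN, self.CFG, shape)[0].y == 105
        assert apply_action(box, Action.LEFT, self.CFG, shape)[0].x == 95
        assert apply_action(box, Action.RIGHT, self.CFG, shape)[0].x == 105

    def test_boundary_crossing_resets_to_fixed_position(self):
        box = self.CFG.make_box(2, 100)
        moved, flag = apply_action(box, Action.LEFT, self.CFG, (256, 256))
        assert flag and (moved.x, moved.y) == (100, 100)

    def test_up_then_down_is_identity_in_interior(self):
        box = self.CFG.make_box(120, 90)
        up, _ = apply_action(box, Action.UP, self.CFG, (256, 256))
        back, _ = apply_action(up, Action.DOWN, self.CFG, (256, 256))
        assert back == box

    def test_terminate_is_not_a_move(self):
        with pytest.raises(ValueError):
            apply_action(self.CFG.make_box(0, 0), Action.TERMINATE, self.CFG, (256, 256))

    def test_3d_moves_and_mode_guard(self):
        cfg3 = EnvConfig(mode="3d", reset_position=(100, 100, 50), box_depth=20)
        box = cfg3.make_box(100, 100, 60)
        top, _ = apply_action(box, Action.TOP, cfg3, (145, 256, 256))
        assert top.z == 55
        with pytest.raises(ValueError):
            apply_action(self.CFG.make_box(0, 0), Action.TOP, self.CFG, (256, 256))


class TestReward:
    def test_reward_is_sign_of_oracle_iou_delta(self, rng, sample_slice):
        cfg = env.FAST_ENV_CONFIG
        gt = sample_slice.gt_box
        n_ties = 0
        for _ in range(200):
            box = cfg.make_box(
                int(rng.integers(0, 128 - cfg.box_width + 1)),
                int(rng.integers(0, 128 - cfg.box_height + 1)),
            )
            action = Action(int(rng.integers(0, 4)))
            new, _ = apply_action(box, action, cfg, sample_slice.image.shape)
            expected = np.sign(_oracle_iou(new, gt) - _oracle_iou(box, gt))
            got = compute_reward(box, new, gt)
            n_ties += got == 0
            assert got == expected
        assert n_ties > 0  # the zero-change tie case must actually occur

    def test_tie_reward_flag(self):
        gt = BoundingBox(x=200, y=200, width=20, height=20)
        a = BoundingBox(x=0, y=0, width=20, height=20)
        b = BoundingBox(x=5, y=0, width=20, height=20)
        assert compute_reward(a, b, gt) == 0
        assert compute_reward(a, b, gt, tie_reward=-1) == -1


class TestReset:
    def test_positions_within_bounds_and_deterministic(self, sample_slice):
        cfg = env.FAST_ENV_CONFIG
        rng = np.random.default_rng(5)
        xs, ys = [], []
        for _ in range(2000):
            s = reset(sample_slice, cfg, rng)
            xs.append(s.box.x)
            ys.append(s.box.y)
            assert s.steps_taken == 0
            assert s.observation.shape == (cfg.box_height, cfg.box_width)
        assert 0 <= min(xs) and max(xs) <= 128 - cfg.box_width
        assert 0 <= min(ys) and max(ys) <= 128 - cfg.box_height
        a = reset(sample_slice, cfg, np.random.default_rng(7))
        b = reset(sample_slice, cfg, np.random.default_rng(7))
        assert a.box == b.box

    def test_start_positions_are_uniform(self, sample_slice):
        cfg = env.FAST_ENV_CONFIG
        rng = np.random.default_rng(11)
        n, bins = 10_000, 8
        xs = np.array([reset(sample_slice, cfg, rng).box.x for _ in range(n)])
        hi = 128 - cfg.box_width + 1
        counts, _ = np.histogram(xs, bins=bins, range=(0, hi))
        # bin widths are equal up to the integer lattice; chi-square at alpha=0.01
        edges = np.linspace(0, hi, bins + 1)
        expected = np.diff(np.floor(edges)) / hi * n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert sp_stats.chi2.sf(chi2, bins - 1) > 0.01

    def test_image_smaller_than_box_fails(self, sample_slice):
        cfg = EnvConfig()  # 50x65 box vs 128x128 image is fine; force failure
        tiny = SliceSample(
            image=np.zeros((40, 40)),
            gt_box=BoundingBox(x=1, y=1, width=5, height=5),
            label=0,
            subject_id="t",
            slice_index=0,
        )
        with pytest.raises(ValueError):
            reset(tiny, cfg, np.random.default_rng(0))


class TestStep:
    def test_immediate_terminate_rewards_by_success_iou(self, sample_slice):
        cfg = dataclasses.replace(env.FAST_ENV_CONFIG,
                                  termination_strategy=TerminationStrategy.IMMEDIATE)
        gt = sample_slice.gt_box
        on_target = env.AgentState(
            box=cfg.make_box(gt.x + (gt.width - cfg.box_width) // 2,
                             gt.y + (gt.height - cfg.box_height) // 2),
            observation=np.zeros((cfg.box_height, cfg.box_width)),
        )
        out = step(on_target, Action.TERMINATE, sample_slice, cfg)
        assert out.done and out.reward == 1
        off_target = env.AgentState(
            box=cfg.make_box(0, 0), observation=np.zeros((cfg.box_height, cfg.box_width))
        )
        out = step(off_target, Action.TERMINATE, sample_slice, cfg)
        assert out.done and out.reward == -1

    def test_noop_terminate_does_not_move_or_end(self, sample_slice):
        cfg = dataclasses.replace(env.FAST_ENV_CONFIG,
                                  termination_strategy=TerminationStrategy.NOOP)
        state = env.AgentState(box=cfg.make_box(40, 40),
                               observation=np.zeros((cfg.box_height, cfg.box_width)),
                               steps_taken=39)
        out = step(state, Action.TERMINATE, sample_slice, cfg)
        assert not out.done
        assert out.next_state.box == state.box
        assert out.next_state.steps_taken == 40

    def test_step_cap_and_finished_episode_guard(self, sample_slice):
        cfg = env.FAST_ENV_CONFIG
        rng = np.random.default_rng(1)
        state = reset(sample_slice, cfg, rng)
        for _ in range(cfg.max_steps_per_episode):
            out = step(state, Action.RIGHT, sample_slice, cfg)
            state = out.next_state
        assert out.done and state.steps_taken == 100
        with pytest.raises(ValueError):
            step(state, Action.RIGHT, sample_slice, cfg)

    def test_box_never_leaves_bounds_under_random_actions(self, sample_slice, rng):
        cfg = env.FAST_ENV_CONFIG
        state = reset(sample_slice, cfg, rng)
        for _ in range(cfg.max_steps_per_episode):
            action = Action(int(rng.integers(0, 4)))
            out = step(state, action, sample_slice, cfg)
            assert out.next_state.box.within(sample_slice.image.shape)
            state = out.next_state
            if out.done:
                break

    def test_rewards_always_in_unit_set(self, sample_slice, rng):
        cfg = env.FAST_ENV_CONFIG
        state = reset(sample_slice, cfg, rng)
        for _ in range(50):
            out = step(state, Action(int(rng.integers(0, 5))), sample_slice, cfg)
            assert out.reward in (-1, 0, 1)
            state = out.next_state
            if out.done:
                break


class Test3DTrack:
    """3D geometry and a minimal training smoke run (full-scale 3D training
    is out of scope)."""

    def _volume_sample(self, rng):
        import types

        img = rng.random((40, 64, 64)).astype(np.float32)
        gt = BoundingBox(x=20, y=22, width=20, height=22, z=8, depth=16)
        return types.SimpleNamespace(image=img, gt_box=gt, label=0,
                                     subject_id="v0", slice_index=0)

    def _cfg(self):
        return EnvConfig(mode="3d", box_width=32, box_height=32, box_depth=32,
                         step=4, reset_position=(10, 10, 4),
                         max_steps_per_episode=30,
                         termination_strategy=TerminationStrategy.NOOP)

    def test_3d_episode_runs_and_stays_in_bounds(self, rng):
        cfg = self._cfg()
        s = self._volume_sample(rng)
        state = reset(s, cfg, rng)
        assert state.observation.shape == (cfg.box_depth, cfg.box_height, cfg.box_width)
        for _ in range(cfg.max_steps_per_episode):
            action = env.Action(int(rng.integers(0, 7)))
            out = step(state, action, s, cfg)
            assert out.next_state.box.within(s.image.shape)
            state = out.next_state
            if out.done:
                break
        assert state.steps_taken <= cfg.max_steps_per_episode

    def test_3d_training_smoke(self, rng):
        import dataclasses as dc

        from hippoloc import dqn as dqn_mod

        cfg = self._cfg()
        samples = [self._volume_sample(rng) for _ in range(2)]
        dcfg = dc.replace(dqn_mod.FAST_DQN_CONFIG, epochs=1, batch_size=8,
                          warmup_episodes=1, update_interval=10)
        agent = dqn_mod.train_dqn(samples, cfg, dcfg)
        assert len(agent.log) == 2
        q = agent.target_net.forward(
            np.zeros((1, 1, cfg.box_depth, cfg.box_height, cfg.box_width),
                     dtype=np.float32))
        assert q.shape == (1, 7) and np.isfinite(q).all()
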