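"""Bounding-box localization MDP.

A fixed-size box moves over a preprocessed slice (or volume) in discrete
steps; the observation is the image crop under the box, the reward is the
sign of the IoU change against the ground-truth box, and crossing an image
boundary teleports the box to a fixed reset position without ending the
episode.  Two episode-termination strategies are supported: IMMEDIATE (the
Terminate action ends the episode, with a terminal reward of +1 when the
final IoU clears ``success_iou`` and -1 otherwise) and NOOP (Terminate does
nothing; the episode runs to the step cap).

IoU and rewards are computed in exact integer arithmetic so they can be
checked against brute-force pixel-set oracles without floating-point slack.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .preprocess import BoundingBox, SliceSample

__all__ = [
    "Action",
    "TerminationStrategy",
    "EnvConfig",
    "AgentState",
    "StepOutcome",
    "actions_for_mode",
    "iou",
    "apply_action",
    "compute_reward",
    "reset",
    "step",
    "run_episode",
    "DEFAULT_ENV_CONFIG",
    "FAST_ENV_CONFIG",
]


class Action(enum.IntEnum):
    UP = 0
    DOWN = 1
    LEFT = 2
    RIGHT = 3
    TERMINATE = 4
    TOP = 5      # 3D only: toward smaller z
    BOTTOM = 6   # 3D only: toward larger z


class TerminationStrategy(enum.Enum):
    IMMEDIATE = "immediate"
    NOOP = "noop"


def actions_for_mode(mode: str) -> tuple[Action, ...]:
    if mode == "2d":
        return (Action.UP, Action.DOWN, Action.LEFT, Action.RIGHT, Action.TERMINATE)
    if mode == "3d":
        return tuple(Action)
    raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")


@dataclass(frozen=True)
class EnvConfig:
    box_width: int = 50
    box_height: int = 65
    box_depth: int = 50
    step: int = 5
    reset_position: tuple[int, ...] = (100, 100)  # (x, y) or (x, y, z)
    max_steps_per_episode: int = 100
    success_iou: float = 0.5
    termination_strategy: TerminationStrategy = TerminationStrategy.IMMEDIATE
    tie_reward: int = 0  # reward when the IoU is unchanged; the sign rule says 0
    mode: str = "2d"

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if min(self.box_width, self.box_height, self.box_depth) <= 0:
            raise ValueError("box dimensions must be positive")
        if not 0.0 < self.success_iou <= 1.0:
            raise ValueError("success_iou must lie in (0, 1]")
        if self.tie_reward not in (0, -1):
            raise ValueError("tie_reward must be 0 or -1")
        actions_for_mode(self.mode)

    def make_box(self, x: int, y: int, z: int | None = None) -> BoundingBox:
        if self.mode == "3d":
            zz = self.reset_position[2] if z is None else z
            return BoundingBox(x=x, y=y, width=self.box_width, height=self.box_height,
                               z=zz, depth=self.box_depth)
        return BoundingBox(x=x, y=y, width=self.box_width, height=self.box_height)


DEFAULT_ENV_CONFIG = EnvConfig()

#: Matches FAST_PHANTOM_CONFIG: 128x128 slices, 25x32 box, 3-px moves.
FAST_ENV_CONFIG = EnvConfig(box_width=25, box_height=32, box_depth=8, step=3,
                            reset_position=(50, 50))


@dataclass
class AgentState:
    box: BoundingBox
    observation: np.ndarray
    steps_taken: int = 0


@dataclass
class StepOutcome:
    next_state: AgentState
    reward: int
    done: bool
    info: dict = field(default_factory=dict)


def _interval_overlap(a0: int, alen: int, b0: int, blen: int) -> int:
    return max(0, min(a0 + alen, b0 + blen) - max(a0, b0))


def _inter_union(a: BoundingBox, b: BoundingBox) -> tuple[int, int]:
    if a.area <= 0 or b.area <= 0:
        raise ValueError("IoU requires boxes of positive area")
    inter = _interval_overlap(a.x, a.width, b.x, b.width) * _interval_overlap(
        a.y, a.height, b.y, b.height
    )
    if a.is_3d and b.is_3d:
        inter *= _interval_overlap(a.z, a.depth, b.z, b.depth)
    elif a.is_3d or b.is_3d:
        raise ValueError("cannot mix 2D and 3D boxes")
    return inter, a.area + b.area - inter


def iou(box_a: BoundingBox, box_b: BoundingBox) -> float:
    """Intersection-over-union in covered pixels, area(a n b) / area(a u b)."""
    inter, union = _inter_union(box_a, box_b)
    return inter / union


_MOVES = {
    Action.UP: (0, -1, 0),
    Action.DOWN: (0, 1, 0),
    Action.LEFT: (-1, 0, 0),
    Action.RIGHT: (1, 0, 0),
    Action.TOP: (0, 0, -1),
    Action.BOTTOM: (0, 0, 1),
}


def apply_action(
    box: BoundingBox,
    action: Action,
    config: EnvConfig,
    image_shape: tuple[int, ...],
) -> tuple[BoundingBox, bool]:
    """Shift the box by one step; boundary crossings reset to the fixed position.

    Returns ``(new_box, boundary_reset_flag)``.  The episode is never ended
    here — resets just teleport the box.
    """
    if action == Action.TERMINATE:
        raise ValueError("TERMINATE is not a move action")
    if action in (Action.TOP, Action.BOTTOM) and config.mode != "3d":
        raise ValueError(f"{action.name} is only available in 3D mode")
    dx, dy, dz = _MOVES[action]
    s = config.step
    moved = replace(box, x=box.x + dx * s, y=box.y + dy * s)
    if box.is_3d:
        moved = replace(moved, z=box.z + dz * s)
    if moved.within(image_shape):
        return moved, False
    rp = config.reset_position
    reset_box = config.make_box(rp[0], rp[1], rp[2] if len(rp) > 2 else None)
    return reset_box, True


def compute_reward(
    prev_box: BoundingBox, new_box: BoundingBox, gt_box: BoundingBox, tie_reward: int = 0
) -> int:
    """sign(IoU(new, gt) - IoU(prev, gt)), via exact integer cross-multiplication."""
    i1, u1 = _inter_union(new_box, gt_box)
    i0, u0 = _inter_union(prev_box, gt_box)
    diff = i1 * u0 - i0 * u1
    if diff > 0:
        return 1
    if diff < 0:
        return -1
    return tie_reward


def _crop(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    return np.ascontiguousarray(image[box.as_slices()])


def reset(sample: SliceSample, config: EnvConfig, rng: np.random.Generator) -> AgentState:
    """Start an episode with the box uniformly over all fully-in-bounds positions."""
    h, w = sample.image.shape[-2:]
    if w < config.box_width or h < config.box_height:
        raise ValueError(
            f"image {sample.image.shape} cannot contain a "
            f"{config.box_width}x{config.box_height} box"
        )
    x = int(rng.integers(0, w - config.box_width + 1))
    y = int(rng.integers(0, h - config.box_height + 1))
    z = None
    if config.mode == "3d":
        d = sample.image.shape[0]
        if d < config.box_depth:
            raise ValueError("volume shallower than the box depth")
        z = int(rng.integers(0, d - config.box_depth + 1))
    box = config.make_box(x, y, z)
    return AgentState(box=box, observation=_crop(sample.image, box), steps_taken=0)


def step(
    state: AgentState, action: Action, sample: SliceSample, config: EnvConfig
) -> StepOutcome:
    """One environment transition; raises if the episode is already finished."""
    if state.steps_taken >= config.max_steps_per_episode:
        raise ValueError("episode already finished (step cap reached)")
    gt = sample.gt_box
    n = state.steps_taken + 1
    info: dict = {"iou_before": iou(state.box, gt), "boundary_reset": False}
    if action == Action.TERMINATE:
        if config.termination_strategy is TerminationStrategy.IMMEDIATE:
            final_iou = info["iou_before"]
            reward = 1 if final_iou >= config.success_iou else -1
            nxt = AgentState(box=state.box, observation=state.observation, steps_taken=n)
            info["iou_after"] = final_iou
            return StepOutcome(next_state=nxt, reward=reward, done=True, info=info)
        # NOOP strategy: terminate is a no-op move
        nxt = AgentState(box=state.box, observation=state.observation, steps_taken=n)
        info["iou_after"] = info["iou_before"]
        return StepOutcome(
            next_state=nxt,
            reward=config.tie_reward,
            done=n >= config.max_steps_per_episode,
            info=info,
        )
    new_box, reset_flag = apply_action(state.box, action, config, sample.image.shape)
    reward = compute_reward(state.box, new_box, gt, config.tie_reward)
    nxt = AgentState(box=new_box, observation=_crop(sample.image, new_box), steps_taken=n)
    info["iou_after"] = iou(new_box, gt)
    info["boundary_reset"] = reset_flag
    return StepOutcome(
        next_state=nxt, reward=reward, done=n >= config.max_steps_per_episode, info=info
    )


def run_episode(
    policy: Callable[[AgentState], Action],
    sample: SliceSample,
    config: EnvConfig,
    rng: np.random.Generator,
    start: AgentState | None = None,
) -> list[StepOutcome]:
    """Roll one episode under ``policy``; returns the list of step outcomes."""
    state = reset(sample, config, rng) if start is None else start
    out: list[StepOutcome] = []
    done = False
    while not done:
        action = policy(state)
        outcome = step(state, action, sample, config)
        out.append(outcome)
        state = outcome.next_state
        done = outcome.done
    return out


def _center_dist(a: BoundingBox, b: BoundingBox) -> float:
    d = abs((2 * a.x + a.width) - (2 * b.x + b.width)) / 2.0
    d += abs((2 * a.y + a.height) - (2 * b.y + b.height)) / 2.0
    if a.is_3d and b.is_3d:
        d += abs((2 * a.z + a.depth) - (2 * b.z + b.depth)) / 2.0
    return d


def oracle_q_values(state: AgentState, sample: SliceSample, config: EnvConfig) -> np.ndarray:
    """Next-step IoU for each action — the cheating value function used to
    validate that the action grammar and step size can solve the task at all.

    TERMINATE scores the current IoU, so the oracle terminates exactly when no
    move improves on staying put.  Exact IoU ties (in particular the flat
    zero-overlap region) are broken toward decreasing center distance, at a
    scale (1e-12/px) far below the smallest genuine IoU difference.
    """
    actions = actions_for_mode(config.mode)
    vals = np.empty(len(actions))
    for i, a in enumerate(actions):
        if a == Action.TERMINATE:
            box = state.box
        else:
            box, _ = apply_action(state.box, a, config, sample.image.shape)
        vals[i] = iou(box, sample.gt_box) - 1e-12 * _center_dist(box, sample.gt_box)
    return vals


def oracle_policy(sample: SliceSample, config: EnvConfig) -> Callable[[AgentState], Action]:
    """Greedy policy over :func:`oracle_q_values` (ties -> lowest action index)."""
    actions = actions_for_mode(config.mode)

    def _policy(state: AgentState) -> Action:
        return actions[int(np.argmax(oracle_q_values(state, sample, config)))]

    return _policy


__all__.append("oracle_policy")


__all__.append("oracle_q_values")
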