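"""Deep Q-learning for box localization: Policy/Target networks, epsilon-greedy
exploration with a random warm-up, Smooth-L1 TD updates from a uniform replay
buffer, periodic target synchronization, and greedy localization rollouts.

The Q-network follows the shared conv stack used across this package: three
convolutions (kernel 5/5/3, stride 2/1/2, channels in->32->64->64) with leaky
rectifiers and max-pooling between, then Dense(256) -> Dense(n_actions) with a
linear head (TD targets may be negative, so no squashing).  Only the Target
Net is used for prediction at test time; it is never trained directly, only
overwritten with the Policy Net's weights every ``target_sync_interval``
episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .env import (
    Action,
    AgentState,
    EnvConfig,
    TerminationStrategy,
    actions_for_mode,
    iou,
    reset,
    step,
)
from .preprocess import SliceSample

__all__ = [
    "DQNConfig",
    "QNetworkSpec",
    "Transition",
    "ReplayBuffer",
    "EpisodeResult",
    "TrainedAgent",
    "build_qnet",
    "select_action",
    "td_target",
    "update_policy",
    "sync_target",
    "train_dqn",
    "localize",
    "FAST_DQN_CONFIG",
]


@dataclass(frozen=True)
class QNetworkSpec:
    """Three conv blocks then two dense layers (see module docstring)."""

    channels: tuple[int, ...] = (32, 64, 64)
    kernels: tuple[int, ...] = (5, 5, 3)
    strides: tuple[int, ...] = (2, 1, 2)
    hidden: int = 256

    def __post_init__(self) -> None:
        if not len(self.channels) == len(self.kernels) == len(self.strides):
            raise ValueError("channels, kernels and strides must have equal length")


@dataclass(frozen=True)
class DQNConfig:
    gamma: float = 0.9
    epsilon: float = 0.2
    warmup_episodes: int = 10
    lr: float = 0.01
    epochs: int = 10
    target_sync_interval: int = 10
    replay_capacity: int = 10_000
    batch_size: int = 32
    update_interval: int = 1  # environment steps between gradient updates
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for name in ("warmup_episodes", "epochs", "target_sync_interval",
                     "replay_capacity", "batch_size", "update_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


#: Scaled-down training profile paired with the fast phantom/env profiles:
#: sparser updates (every 6th step) and a smaller Adam step than the
#: full-scale default, sized for ~320 episodes of 100 steps.
FAST_DQN_CONFIG = DQNConfig(lr=1e-3, epochs=8, update_interval=6)


@dataclass
class Transition:
    state: np.ndarray
    action: int
    reward: int
    next_state: np.ndarray
    done: bool

    def __post_init__(self) -> None:
        if self.reward not in (-1, 0, 1):
            raise ValueError(f"reward must be in {{-1,0,1}}, got {self.reward}")
        if self.state.shape != self.next_state.shape:
            raise ValueError("state/next_state shape mismatch")


class ReplayBuffer:
    """Uniform-sampling ring buffer of transitions."""

    def __init__(self, capacity: int) -> None:
        self.capacity = capacity
        self._data: list[Transition] = []
        self._pos = 0

    def push(self, t: Transition) -> None:
        if len(self._data) < self.capacity:
            self._data.append(t)
        else:
            self._data[self._pos] = t
        self._pos = (self._pos + 1) % self.capacity

    def __len__(self) -> int:
        return len(self._data)

    def sample(self, batch_size: int, rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(0, len(self._data), size=batch_size)
        return [self._data[i] for i in idx]


def _conv_stack(spec: QNetworkSpec, in_channels: int, ndim: int,
                rng: np.random.Generator) -> list[nn.Layer]:
    pools = [(2,) * ndim, (1, 2, 2)[-ndim:], (2,) * ndim]
    layers: list[nn.Layer] = []
    prev = in_channels
    for ch, k, s, p in zip(spec.channels, spec.kernels, spec.strides, pools):
        layers += [nn.Conv(prev, ch, k, s, ndim, rng), nn.LeakyReLU(), nn.MaxPool(p)]
        prev = ch
    return layers


def build_conv_net(
    spec: QNetworkSpec,
    input_shape: tuple[int, ...],
    out_dim: int,
    rng: np.random.Generator,
    sigmoid_head: bool = False,
) -> nn.Sequential:
    """Assemble the shared conv stack + two dense layers for a given input.

    ``input_shape`` is ``(channels, H, W)`` or ``(channels, D, H, W)``.  The
    flattened feature width is discovered with a dry forward pass; a spatial
    input too small for the stack fails naming the offending layer.
    """
    ndim = len(input_shape) - 1
    if ndim not in (2, 3):
        raise ValueError(f"input must be (C, H, W) or (C, D, H, W); got {input_shape}")
    convs = _conv_stack(spec, input_shape[0], ndim, rng)
    dummy = np.zeros((1,) + tuple(input_shape), dtype=np.float32)
    for i, layer in enumerate(convs):
        try:
            dummy = layer.forward(dummy)
        except ValueError as exc:
            raise ValueError(
                f"input shape {input_shape} too small at conv-stack layer "
                f"{i} ({type(layer).__name__}): {exc}"
            ) from exc
    flat = int(np.prod(dummy.shape[1:]))
    layers = convs + [
        nn.Flatten(),
        nn.Dense(flat, spec.hidden, rng),
        nn.ReLU(),
        nn.Dense(spec.hidden, out_dim, rng),
    ]
    if sigmoid_head:
        layers.append(nn.Sigmoid())
    return nn.Sequential(layers)


def build_qnet(
    mode: str,
    input_shape: tuple[int, ...],
    seed: int,
    spec: QNetworkSpec = QNetworkSpec(),
) -> nn.Sequential:
    """Q-network for the given mode; output length = size of the action set."""
    n_actions = len(actions_for_mode(mode))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    return build_conv_net(spec, input_shape, n_actions, rng, sigmoid_head=False)


def _obs_tensor(observation: np.ndarray) -> np.ndarray:
    return observation[None, ...].astype(np.float32)  # add channel axis


def select_action(
    qnet: nn.Sequential,
    observation: np.ndarray,
    episode_index: int,
    config: DQNConfig,
    rng: np.random.Generator,
    actions: Sequence[Action],
) -> Action:
    """Epsilon-greedy with a fully random warm-up over the first episodes."""
    n = len(actions)
    if episode_index < config.warmup_episodes or rng.random() < config.epsilon:
        return actions[int(rng.integers(0, n))]
    q = qnet.forward(_obs_tensor(observation)[None, ...])  # (1, 1, *spatial)
    return actions[int(np.argmax(q[0]))]


def td_target(reward: float, next_state_values: np.ndarray, done: bool, gamma: float) -> float:
    """r + gamma * max_a' Q(s', a'), with the bootstrap suppressed at terminals."""
    next_state_values = np.asarray(next_state_values)
    if next_state_values.size == 0:
        raise ValueError("next_state_values must be non-empty")
    if done:
        return float(reward)
    return float(reward + gamma * next_state_values.max())


def update_policy(
    policy_net: nn.Sequential,
    target_net: nn.Sequential,
    batch: Sequence[Transition],
    optimizer: nn.Adam,
    config: DQNConfig,
) -> float:
    """One Smooth-L1 TD step on the policy net; the target net is untouched.

    Gradient flows only through the Q value of each transition's chosen action.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    obs = np.stack([t.state for t in batch]).astype(np.float32)
    nxt = np.stack([t.next_state for t in batch]).astype(np.float32)
    actions = np.array([t.action for t in batch])
    next_q = target_net.forward(nxt)
    targets = np.array(
        [
            td_target(t.reward, next_q[i], t.done, config.gamma)
            for i, t in enumerate(batch)
        ],
        dtype=np.float32,
    )
    preds_all = policy_net.forward(obs)
    rows = np.arange(len(batch))
    preds = preds_all[rows, actions]
    loss, dpred = nn.smooth_l1_loss(preds, targets)
    dall = np.zeros_like(preds_all)
    dall[rows, actions] = dpred
    policy_net.zero_grad()
    policy_net.backward(dall)
    optimizer.step()
    return loss


def sync_target(policy_net: nn.Sequential, target_net: nn.Sequential) -> None:
    """Overwrite the target net's parameters with the policy net's."""
    target_net.load_state(policy_net.state())


@dataclass
class EpisodeResult:
    final_box: object
    final_iou: float
    success: bool
    steps: int
    trajectory: list[dict] = field(default_factory=list)


@dataclass
class TrainedAgent:
    policy_net: nn.Sequential
    target_net: nn.Sequential
    env_config: EnvConfig
    dqn_config: DQNConfig
    input_shape: tuple[int, ...]
    log: pd.DataFrame


def _state_obs(state: AgentState, mode: str) -> np.ndarray:
    return state.observation[None, ...].astype(np.float32)


def train_dqn(
    train_slices: Sequence[SliceSample],
    env_config: EnvConfig,
    dqn_config: DQNConfig,
) -> TrainedAgent:
    """Train the Policy/Target pair over ``epochs`` passes of the training set.

    Each sample contributes one episode per epoch (at most
    ``max_steps_per_episode`` transitions, pushed to the replay buffer); the
    policy net takes one Adam/Smooth-L1 step every ``update_interval``
    environment steps once the buffer holds a full batch, and the target net
    is synchronized every ``target_sync_interval`` episodes (and once more at
    the end).  Fully deterministic for a fixed seed.
    """
    if len(train_slices) == 0:
        raise ValueError("empty training set")
    actions = actions_for_mode(env_config.mode)
    if env_config.mode == "2d":
        input_shape = (1, env_config.box_height, env_config.box_width)
    else:
        input_shape = (1, env_config.box_depth, env_config.box_height, env_config.box_width)
    policy = build_qnet(env_config.mode, input_shape, dqn_config.seed)
    target = build_qnet(env_config.mode, input_shape, dqn_config.seed)
    sync_target(policy, target)
    optimizer = nn.Adam(policy.params(), lr=dqn_config.lr)
    buffer = ReplayBuffer(dqn_config.replay_capacity)
    rng = np.random.default_rng(np.random.SeedSequence((dqn_config.seed, 1)))

    records = []
    episode_idx = 0
    global_step = 0
    for epoch in range(dqn_config.epochs):
        for sample in train_slices:
            state = reset(sample, env_config, rng)
            ep_return = 0.0
            losses = []
            done = False
            while not done:
                obs = _state_obs(state, env_config.mode)
                if episode_idx < dqn_config.warmup_episodes or rng.random() < dqn_config.epsilon:
                    action = actions[int(rng.integers(0, len(actions)))]
                else:
                    q = policy.forward(obs[None, ...])
                    action = actions[int(np.argmax(q[0]))]
                outcome = step(state, action, sample, env_config)
                buffer.push(
                    Transition(
                        state=obs,
                        action=int(actions.index(action)),
                        reward=outcome.reward,
                        next_state=_state_obs(outcome.next_state, env_config.mode),
                        done=outcome.done,
                    )
                )
                ep_return += outcome.reward
                global_step += 1
                if (
                    len(buffer) >= dqn_config.batch_size
                    and global_step % dqn_config.update_interval == 0
                ):
                    losses.append(
                        update_policy(policy, target, buffer.sample(dqn_config.batch_size, rng),
                                      optimizer, dqn_config)
                    )
                state = outcome.next_state
                done = outcome.done
            episode_idx += 1
            if episode_idx % dqn_config.target_sync_interval == 0:
                sync_target(policy, target)
            records.append(
                dict(
                    episode=episode_idx,
                    epoch=epoch,
                    subject_id=sample.subject_id,
                    steps=state.steps_taken,
                    episode_return=ep_return,
                    final_iou=iou(state.box, sample.gt_box),
                    mean_loss=float(np.mean(losses)) if losses else np.nan,
                )
            )
    sync_target(policy, target)
    return TrainedAgent(
        policy_net=policy,
        target_net=target,
        env_config=env_config,
        dqn_config=dqn_config,
        input_shape=input_shape,
        log=pd.DataFrame.from_records(records),
    )


def localize(
    target_net: nn.Sequential,
    sample: SliceSample,
    env_config: EnvConfig,
    rng: np.random.Generator | None = None,
    start: AgentState | None = None,
    qvalue_fn=None,
) -> EpisodeResult:
    """Greedy (epsilon = 0) rollout of the target net on one sample.

    Deterministic given the network and the start position.  ``qvalue_fn``
    (state -> action-value vector) can replace the net, e.g. with the
    next-step-IoU oracle, to separate environment bugs from learning failures.
    """
    actions = actions_for_mode(env_config.mode)
    if start is None:
        if rng is None:
            raise ValueError("either a start state or an rng for reset() is required")
        state = reset(sample, env_config, rng)
    else:
        state = start
    trajectory = []
    done = False
    while not done:
        if qvalue_fn is not None:
            q = np.asarray(qvalue_fn(state))
        else:
            q = target_net.forward(_state_obs(state, env_config.mode)[None, ...])[0]
        action = actions[int(np.argmax(q))]
        outcome = step(state, action, sample, env_config)
        trajectory.append(
            dict(
                step=state.steps_taken + 1,
                action=action.name,
                reward=outcome.reward,
                box=(outcome.next_state.box.x, outcome.next_state.box.y),
                iou=outcome.info["iou_after"],
                boundary_reset=outcome.info["boundary_reset"],
            )
        )
        state = outcome.next_state
        done = outcome.done
    final_iou = iou(state.box, sample.gt_box)
    return EpisodeResult(
        final_box=state.box,
        final_iou=final_iou,
        success=final_iou >= env_config.success_iou,
        steps=state.steps_taken,
        trajectory=trajectory,
    )
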