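"""Experiment scaffolding for the effort-based visuomotor task.

All spatial quantities are expressed as fractions of screen width in [0, 1];
pixel conversion happens only at I/O via ``TaskDesign.screen_width_px``.
Force signals are in newtons, sampled at a fixed rate (default 60 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskDesign",
    "TrialSequence",
    "ForceTrace",
    "EstimationGrid",
    "ConstraintError",
    "build_task_design",
    "calibrate_max_force",
    "compute_force_response",
    "compute_force_error",
    "build_estimation_grid",
]


class ConstraintError(ValueError):
    """A task-design constraint set is infeasible or violated."""


@dataclass(frozen=True)
class TaskDesign:
    """Static description of one testing session.

    Defaults reproduce the study design: 4 blocks of 30 trials (20 basic +
    10 estimation), a 12-option estimation grid spanning 30% of the screen
    with the veridical option drawn uniformly from positions 3..10, and
    effort targets at 35% / 65% of maximum force crossed with reward on/off.
    """

    n_blocks: int = 4
    trials_per_block: int = 30
    basic_per_block: int = 20
    estimation_per_block: int = 10
    effort_levels: tuple[float, ...] = (0.35, 0.65)
    reward_levels: tuple[str, ...] = ("off", "on")
    n_response_options: int = 12
    grid_width_frac: float = 0.30
    veridical_index_range: tuple[int, int] = (3, 10)
    screen_width_px: int = 1920
    n_leading_basic: int = 3  # first trials of each block are always basic

    def __post_init__(self) -> None:
        if self.trials_per_block != self.basic_per_block + self.estimation_per_block:
            raise ConstraintError(
                "trials_per_block must equal basic_per_block + estimation_per_block"
            )
        lo, hi = self.veridical_index_range
        if not (1 <= lo <= hi <= self.n_response_options):
            raise ConstraintError(
                "veridical_index_range must lie within [1, n_response_options]"
            )
        if not 0.0 < self.grid_width_frac < 1.0:
            raise ConstraintError("grid_width_frac must lie in (0, 1)")
        if self.basic_per_block < self.n_leading_basic and self.estimation_per_block > 0:
            raise ConstraintError(
                "not enough basic trials to fill the leading all-basic positions"
            )
        # After the leading basic trials, estimation trials must fit without
        # two of them being adjacent: at most ceil(m / 2) of m slots.
        m = self.trials_per_block - self.n_leading_basic
        if self.estimation_per_block > (m + 1) // 2:
            raise ConstraintError(
                "estimation_per_block too large to avoid consecutive estimation trials"
            )

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    @property
    def n_estimation(self) -> int:
        return self.n_blocks * self.estimation_per_block

    @property
    def option_spacing(self) -> float:
        """Distance between adjacent grid-option centres (screen fraction).

        Convention: ``grid_width_frac`` is the outer-edge-to-outer-edge
        footprint of the option cells, so spacing = width / n options and the
        outermost centres are ``grid_width_frac - spacing`` apart.
        """
        return self.grid_width_frac / self.n_response_options


@dataclass(frozen=True)
class TrialSequence:
    """Ordered trial schedule for one session.

    Each row of :meth:`to_frame` is one trial with its block, 1-based trial
    index within the block, trial type, effort level and reward level.
    """

    block: np.ndarray        # 1-based block index, int
    trial: np.ndarray        # 1-based trial index within block, int
    trial_type: np.ndarray   # "basic" | "estimation"
    effort: np.ndarray       # target position, screen fraction
    reward: np.ndarray       # "on" | "off"
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.block)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block,
                "trial": self.trial,
                "trial_type": self.trial_type,
                "effort": self.effort,
                "reward": self.reward,
            }
        )

    def validate(self, design: TaskDesign) -> None:
        """Raise ``ConstraintError`` if any structural invariant is violated."""
        df = self.to_frame()
        for b, g in df.groupby("block"):
            types = g.sort_values("trial")["trial_type"].to_numpy()
            if (types[: design.n_leading_basic] != "basic").any():
                raise ConstraintError(f"block {b}: leading trials are not all basic")
            est = types == "estimation"
            if (est[:-1] & est[1:]).any():
                raise ConstraintError(f"block {b}: two consecutive estimation trials")
            if est.sum() != design.estimation_per_block:
                raise ConstraintError(f"block {b}: estimation trial count mismatch")
            if (~est).sum() != design.basic_per_block:
                raise ConstraintError(f"block {b}: basic trial count mismatch")


@dataclass(frozen=True)
class ForceTrace:
    """A force signal in newtons sampled at a fixed rate."""

    samples: np.ndarray
    rate: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate


@dataclass(frozen=True)
class EstimationGrid:
    """The response grid shown on an estimation trial.

    ``centres`` are the option centres in screen fraction (index 0 is option
    1); ``veridical_index`` is 1-based; ``clamped`` records whether the grid
    had to be translated to stay on screen (in which case the veridical
    option is no longer exactly centred on the ball).
    """

    centres: np.ndarray
    veridical_index: int
    clamped: bool = False

    @property
    def n_options(self) -> int:
        return len(self.centres)


def _block_conditions(design: TaskDesign, rng: np.random.Generator):
    """Assign one effort x reward combination to each block, in random order."""
    combos = [(e, r) for e in design.effort_levels for r in design.reward_levels]
    if len(combos) == design.n_blocks:
        order = rng.permutation(len(combos))
        return [combos[i] for i in order]
    # Fallback for non-factorial overrides: cycle through combinations.
    return [combos[i % len(combos)] for i in range(design.n_blocks)]


def _block_types(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """One block's trial-type vector satisfying the structural constraints.

    Rejection sampling over permutations of the non-leading slots: uniform
    over all valid orderings, deterministic given the generator state.
    """
    m = design.trials_per_block - design.n_leading_basic
    k = design.estimation_per_block
    base = np.array(["basic"] * (m - k) + ["estimation"] * k)
    while True:
        perm = rng.permutation(base)
        est = perm == "estimation"
        if not (est[:-1] & est[1:]).any():
            break
    return np.concatenate([np.repeat("basic", design.n_leading_basic), perm])


def build_task_design(
    config: dict | None = None, seed: int | np.random.Generator | None = None
) -> tuple[TaskDesign, TrialSequence]:
    """Build a task design and a pseudorandom trial sequence.

    Parameters
    ----------
    config
        Field overrides for :class:`TaskDesign` (e.g. ``{"estimation_per_block": 0}``).
    seed
        Seed or generator controlling block-condition order and trial
        interleaving; the same seed reproduces the same sequence.
    """
    design = TaskDesign(**(config or {}))
    rng = np.random.default_rng(seed)
    conditions = _block_conditions(design, rng)
    blocks, trials, types, efforts, rewards = [], [], [], [], []
    for b in range(design.n_blocks):
        effort, reward = conditions[b]
        t = _block_types(design, rng)
        blocks.append(np.full(design.trials_per_block, b + 1))
        trials.append(np.arange(1, design.trials_per_block + 1))
        types.append(t)
        efforts.append(np.full(design.trials_per_block, effort))
        rewards.append(np.repeat(reward, design.trials_per_block))
    seq = TrialSequence(
        block=np.concatenate(blocks),
        trial=np.concatenate(trials),
        trial_type=np.concatenate(types),
        effort=np.concatenate(efforts),
        reward=np.concatenate(rewards),
        seed=seed if isinstance(seed, int) else None,
    )
    seq.validate(design)
    return design, seq


def calibrate_max_force(
    traces: Sequence[ForceTrace], window_s: float = 5.0
) -> float:
    """Maximum sustainable force from repeated maximal presses.

    For each trace, a window of ``window_s`` seconds slides one sample at a
    time; the window with the lowest variance is selected and its mean force
    taken as that trace's response.  The calibration value is the maximum of
    these means across traces (the study used three 10-s presses with a 5-s
    window).
    """
    if len(traces) == 0:
        raise ValueError("at least one trace is required")
    means = []
    for tr in traces:
        n_win = int(round(window_s * tr.rate))
        if n_win <= 0:
            raise ValueError("window must span at least one sample")
        if len(tr.samples) < n_win:
            raise ValueError(
                f"trace of {tr.duration:.2f}s is shorter than the {window_s:.2f}s window"
            )
        windows = np.lib.stride_tricks.sliding_window_view(tr.samples, n_win)
        variances = windows.var(axis=1)
        best = int(np.argmin(variances))
        means.append(windows[best].mean())
    return float(max(means))


def compute_force_response(
    trace: ForceTrace, max_force: float, window: tuple[float, float] = (1.5, 2.5)
) -> float:
    """Relative force: mean force over ``window`` (default [1.5, 2.5) s)
    divided by the participant's maximum force."""
    if max_force <= 0:
        raise ValueError("max_force must be positive")
    t0, t1 = window
    t = trace.times
    mask = (t >= t0) & (t < t1)
    if not mask.any():
        raise ValueError("trace does not span the response window")
    return float(trace.samples[mask].mean() / max_force)


def compute_force_error(force_response: float, required_force: float) -> float:
    """Signed force error in percentage points of maximum force."""
    return (force_response - required_force) * 100.0


def build_estimation_grid(
    ball_pos: float,
    design: TaskDesign,
    seed: int | np.random.Generator | None = None,
) -> EstimationGrid:
    """Construct the estimation grid for a trial.

    The grid has ``n_response_options`` evenly spaced option centres with the
    veridical option (drawn uniformly from ``veridical_index_range``) centred
    on the true final ball position.  If the grid would extend past the
    screen edges it is translated minimally to fit and flagged ``clamped``.
    """
    if not 0.0 <= ball_pos <= 1.0:
        raise ValueError("ball_pos must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = design.veridical_index_range
    vidx = int(rng.integers(lo, hi + 1))
    spacing = design.option_spacing
    n = design.n_response_options
    centres = ball_pos + (np.arange(1, n + 1) - vidx) * spacing
    clamped = False
    left_edge = centres[0] - spacing / 2
    right_edge = centres[-1] + spacing / 2
    if left_edge < 0.0:
        centres = centres - left_edge
        clamped = True
    elif right_edge > 1.0:
        centres = centres - (right_edge - 1.0)
        clamped = True
    return EstimationGrid(centres=centres, veridical_index=vidx, clamped=clamped)
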