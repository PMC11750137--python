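"""Simulation of the two-port probabilistic switching task.

A freely moving mouse initiates a trial at a center port, then chooses a left
or right side port. Each side port delivers water with a fixed probability
(e.g. 0.9 on the "high" side, 0.1 on the "low" side). Once the animal has
earned ``rewards_per_block`` rewards within a block, the two probabilities
swap sides (a *block transition*) with no cue. Every trial is annotated with
five event timestamps: center entry (CE), center exit (CX), side entry (SE),
first lick (FL) and side exit (SX).

Choice behavior is pluggable through the :class:`Agent` contract; the package
ships a recursively-formulated-logistic-regression agent
(:class:`RFLRAgent`), a uniform-random agent, a win-stay/lose-shift agent and
a constant-side agent for degenerate checks.

Side coding convention used throughout the package: left = +1, right = -1,
so positive choice log-odds mean "left more likely".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LEFT = "left"
RIGHT = "right"
SIDES = (LEFT, RIGHT)

#: Column order of the canonical per-trial table.
SESSION_COLUMNS = [
    "mouse_id", "session_id", "trial", "block", "high_side", "choice",
    "rewarded", "t_CE", "t_CX", "t_SE", "t_FL", "t_SX",
]

EVENT_NAMES = ("CE", "CX", "SE", "FL", "SX")


def side_sign(side: str) -> int:
    """Signed coding of a port side: left = +1, right = -1."""
    if side == LEFT:
        return 1
    if side == RIGHT:
        return -1
    raise ValueError(f"unknown side {side!r}")


def sign_side(c: int) -> str:
    return LEFT if c > 0 else RIGHT


def other_side(side: str) -> str:
    return RIGHT if side == LEFT else LEFT


class ConfigError(ValueError):
    """Raised for invalid task configuration."""


@dataclass(frozen=True)
class LatencyParams:
    """Log-normal latency parameters (mu, sigma of log-seconds) per segment.

    Defaults give a quick center poke, ~0.5 s travel to the side port, and on
    rewarded trials ~1 s of lick/consumption occupancy before side exit;
    unrewarded trials exit quickly. Median full trial (CE to SX) lands in the
    2-3 s range typical of a trained animal. Draws are clipped at ``clip_s``
    so that no latency can exceed the 8 s side-poke deadline.
    """

    ce_to_cx: tuple[float, float] = (math.log(0.25), 0.40)
    cx_to_se: tuple[float, float] = (math.log(0.55), 0.35)
    se_to_fl: tuple[float, float] = (math.log(0.30), 0.30)
    fl_to_sx_rewarded: tuple[float, float] = (math.log(1.10), 0.25)
    fl_to_sx_unrewarded: tuple[float, float] = (math.log(0.20), 0.40)
    iti_extra: tuple[float, float] = (math.log(0.40), 0.50)
    clip_s: float = 7.0


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the switching task.

    ``p_high``/``p_low`` are per-port reward probabilities (90/10 means 0.9
    and 0.1; they need not sum to 1). A block ends after the trial on which
    the ``rewards_per_block``-th reward of that block is delivered.
    """

    p_high: float = 0.9
    p_low: float = 0.1
    rewards_per_block: int = 50
    n_trials: int = 500
    min_iti: float = 1.0
    side_poke_deadline: float = 8.0
    initial_high_side: str = LEFT
    latency: LatencyParams = field(default_factory=LatencyParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_low <= 1.0 and 0.0 <= self.p_high <= 1.0):
            raise ConfigError("p_high and p_low must be probabilities")
        if self.p_high <= self.p_low:
            raise ConfigError("p_high must exceed p_low")
        if self.rewards_per_block < 1:
            raise ConfigError("rewards_per_block must be >= 1")
        if self.initial_high_side not in SIDES:
            raise ConfigError("initial_high_side must be 'left' or 'right'")
        if self.min_iti < 0:
            raise ConfigError("min_iti must be >= 0")


@dataclass
class SessionTable:
    """One behavioral session: a per-trial table plus metadata.

    ``trials`` is a :class:`pandas.DataFrame` with :data:`SESSION_COLUMNS`.
    ``t_FL`` may be NaN on unrewarded trials.
    """

    trials: pd.DataFrame
    mouse_id: str = "m0"
    session_id: str = "s0"
    config: Optional[TaskConfig] = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices_signed(self) -> np.ndarray:
        return np.where(self.trials["choice"].to_numpy() == LEFT, 1, -1)

    @property
    def rewards(self) -> np.ndarray:
        return self.trials["rewarded"].to_numpy().astype(int)

    @property
    def high_port_chosen(self) -> np.ndarray:
        t = self.trials
        return (t["choice"] == t["high_side"]).to_numpy()

    @property
    def switches(self) -> np.ndarray:
        """Boolean per trial n>=1: choice(n) != choice(n-1); first trial NaN-free
        by convention (excluded from p(switch) denominators)."""
        c = self.trials["choice"].to_numpy()
        return c[1:] != c[:-1]

    def transition_indices(self) -> np.ndarray:
        """Trial indices (0-based) of the first trial of each new block."""
        b = self.trials["block"].to_numpy()
        return np.flatnonzero(np.diff(b) != 0) + 1

    def flipped(self) -> "SessionTable":
        """Session with left/right globally relabeled (for symmetry checks)."""
        t = self.trials.copy()
        swap = {LEFT: RIGHT, RIGHT: LEFT}
        t["choice"] = t["choice"].map(swap)
        t["high_side"] = t["high_side"].map(swap)
        return SessionTable(t, self.mouse_id, self.session_id, self.config)


class Agent:
    """Contract for a choice policy interacting with the task.

    ``choose(rng)`` returns 'left' or 'right'; ``observe(choice, rewarded)``
    feeds back the trial outcome; ``reset()`` clears any internal state.
    """

    def reset(self) -> None:  # pragma: no cover - trivial default
        pass

    def observe(self, choice: str, rewarded: bool) -> None:  # pragma: no cover
        pass

    def choose(self, rng: np.random.Generator) -> str:
        raise NotImplementedError


class UniformRandomAgent(Agent):
    """Chooses each side with probability 1/2, ignoring history."""

    def choose(self, rng: np.random.Generator) -> str:
        return LEFT if rng.random() < 0.5 else RIGHT


class ConstantAgent(Agent):
    """Always chooses the same side (degenerate baseline)."""

    def __init__(self, side: str = LEFT):
        if side not in SIDES:
            raise ValueError(side)
        self.side = side

    def choose(self, rng: np.random.Generator) -> str:
        return self.side


class WinStayLoseShiftAgent(Agent):
    """Repeats a rewarded choice, switches after an unrewarded one.

    ``epsilon`` is a lapse rate (probability of inverting the rule); 0 gives
    the strict deterministic policy.
    """

    def __init__(self, epsilon: float = 0.0):
        self.epsilon = epsilon
        self.reset()

    def reset(self) -> None:
        self._intended: Optional[str] = None

    def observe(self, choice: str, rewarded: bool) -> None:
        self._intended = choice if rewarded else other_side(choice)

    def choose(self, rng: np.random.Generator) -> str:
        if self._intended is None:
            return LEFT if rng.random() < 0.5 else RIGHT
        if self.epsilon > 0 and rng.random() < self.epsilon:
            return other_side(self._intended)
        return self._intended


class RFLRAgent(Agent):
    """Agent whose choice law is the recursive logistic-regression model.

    State: evidence accumulator phi and log-odds psi. After each trial with
    signed choice c in {+1,-1} and reward r in {0,1}:

        phi <- c*r + exp(-1/tau) * phi
        psi <- alpha*c + beta*phi

    and the next choice is left with probability sigmoid(psi). Before any
    history exists the choice is uniform.
    """

    def __init__(self, alpha: float, beta: float, tau: float):
        if tau <= 0:
            raise ValueError("tau must be > 0")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.tau = float(tau)
        self.reset()

    def reset(self) -> None:
        self.phi = 0.0
        self.psi: Optional[float] = None

    def observe(self, choice: str, rewarded: bool) -> None:
        c = side_sign(choice)
        r = 1.0 if rewarded else 0.0
        self.phi = c * r + math.exp(-1.0 / self.tau) * self.phi
        self.psi = self.alpha * c + self.beta * self.phi

    def p_left(self) -> float:
        if self.psi is None:
            return 0.5
        return 1.0 / (1.0 + math.exp(-self.psi))

    def choose(self, rng: np.random.Generator) -> str:
        return LEFT if rng.random() < self.p_left() else RIGHT


def _draw_latency(rng: np.random.Generator, mu_sigma: tuple[float, float],
                  clip_s: float) -> float:
    mu, sigma = mu_sigma
    return float(min(rng.lognormal(mu, sigma), clip_s))


def sample_trial_timing(rewarded: bool, rng: np.random.Generator,
                        latency: LatencyParams = LatencyParams()) -> dict:
    """Draw within-trial event offsets (seconds from center entry).

    Returns a dict with keys CE, CX, SE, FL, SX; CE is always 0. Rewarded
    trials carry ~1 s of licking occupancy between first lick and side exit;
    unrewarded trials exit quickly. All latencies are strictly positive so
    CE < CX < SE < FL < SX by construction.
    """
    t_cx = _draw_latency(rng, latency.ce_to_cx, latency.clip_s)
    t_se = t_cx + _draw_latency(rng, latency.cx_to_se, latency.clip_s)
    t_fl = t_se + _draw_latency(rng, latency.se_to_fl, latency.clip_s)
    seg = latency.fl_to_sx_rewarded if rewarded else latency.fl_to_sx_unrewarded
    t_sx = t_fl + _draw_latency(rng, seg, latency.clip_s)
    return {"CE": 0.0, "CX": t_cx, "SE": t_se, "FL": t_fl, "SX": t_sx}


def simulate_session(agent: Agent, config: TaskConfig, rng_seed: int,
                     mouse_id: str = "m0", session_id: str = "s0") -> SessionTable:
    """Run one session of the switching task under the given agent.

    Rewards are independent Bernoulli draws with the chosen port's current
    probability (no baiting of the unchosen port). The block flips after the
    trial on which the ``rewards_per_block``-th reward of the block is
    delivered. Bit-identical output for identical (agent, config, seed).
    """
    rng = np.random.default_rng(rng_seed)
    agent.reset()
    high_side = config.initial_high_side
    block = 0
    rewards_in_block = 0
    t = 0.0
    rows = []
    for n in range(config.n_trials):
        choice = agent.choose(rng)
        p = config.p_high if choice == high_side else config.p_low
        rewarded = bool(rng.random() < p)
        offs = sample_trial_timing(rewarded, rng, config.latency)
        rows.append({
            "mouse_id": mouse_id, "session_id": session_id,
            "trial": n, "block": block, "high_side": high_side,
            "choice": choice, "rewarded": rewarded,
            "t_CE": t + offs["CE"], "t_CX": t + offs["CX"],
            "t_SE": t + offs["SE"], "t_FL": t + offs["FL"],
            "t_SX": t + offs["SX"],
        })
        agent.observe(choice, rewarded)
        if rewarded:
            rewards_in_block += 1
            if rewards_in_block == config.rewards_per_block:
                block += 1
                rewards_in_block = 0
                high_side = other_side(high_side)
        iti = config.min_iti + _draw_latency(rng, config.latency.iti_extra,
                                             config.latency.clip_s)
        t = t + offs["SX"] + iti
    trials = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    return SessionTable(trials, mouse_id, session_id, config)


def simulate_cohort(agent_factory, config: TaskConfig, n_mice: int,
                    sessions_per_mouse: int, seed: int) -> list[SessionTable]:
    """Simulate ``n_mice * sessions_per_mouse`` sessions with derived seeds.

    ``agent_factory()`` must return a fresh agent; each session gets a
    deterministic child seed of ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(n_mice * sessions_per_mouse))
    out = []
    for m in range(n_mice):
        for s in range(sessions_per_mouse):
            sub_seed = int(next(child).generate_state(1)[0] % (2 ** 31))
            out.append(simulate_session(
                agent_factory(), config, sub_seed,
                mouse_id=f"m{m}", session_id=f"s{s}"))
    return out
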