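"""Single-state linear learner with hand-vector-centred generalization.

The synthetic cohort's trial-to-trial adaptation follows the minimal
state-space process consistent with classic visuomotor-rotation curves.
A state ``x(theta)`` (degrees of compensatory hand deviation, CCW positive)
is kept at each cardinal hand direction. On every trial with movement
feedback the whole state vector retains by ``A`` and is nudged by the
experienced cursor error, weighted by a Gaussian tuning curve centred on
the *planned hand vector* of that trial:

    x_{t+1}(theta) = A * x_t(theta) + B * e_t * exp(-d(theta, plan_t)^2 / (2 * sigma^2))

where ``e_t`` is the negated angular cursor error (so learning drives the
cursor back onto the target) and ``d`` is angular distance. Learning is
therefore carried across visual contexts: the state is indexed by hand
direction only, which is the shared-internal-model regime the analysis
pipeline is designed to detect.

With updates at a single hand direction every trial the fixed point is the
familiar ``30 * B / (1 - A + B)`` compensation for a 30-degree rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import INVERTED_BOTH, INVERTED_LOOK, INVERTED_VERTICAL_ONLY, wrap_angle
from .schedule import Schedule

__all__ = [
    "LearnerParams",
    "planned_hand_direction",
    "simulate_learner",
    "fit_state_space",
]

HAND_DIRECTIONS = np.array([0.0, 90.0, 180.0, 270.0])


@dataclass(frozen=True)
class LearnerParams:
    """Generator parameters for one synthetic participant.

    retention_A, learning_rate_B : unitless in [0, 1]
        State retention and error-correction gain of the learner.
    gen_sigma : degrees
        Width of the Gaussian generalization tuning about the planned hand
        vector.
    motor_noise_sd : degrees
        White angular execution noise added to each planned reach.
    p_jump_start : probability
        Chance of launching a movement toward an uncued target 90 degrees
        away (a "jump start").
    glitch_rate : probability
        Per-trial chance of a single-frame input glitch being injected into
        the recorded trajectory.
    rt_limit_threshold_ms, rt_limit_slope_ms : ms
        Location and slope of the logistic psychometric function mapping the
        staircased time limit to success probability (the threshold is the
        limit at which the participant succeeds 50% of the time).
    """

    retention_A: float = 0.99
    learning_rate_B: float = 0.08
    gen_sigma: float = 45.0
    motor_noise_sd: float = 4.0
    p_jump_start: float = 0.05
    glitch_rate: float = 0.003
    rt_limit_threshold_ms: float = 750.0
    rt_limit_slope_ms: float = 100.0

    def __post_init__(self):
        for name in ("retention_A", "learning_rate_B"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("p_jump_start", "glitch_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.gen_sigma <= 0:
            raise ValueError("gen_sigma must be positive")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be non-negative")

    def noiseless(self) -> "LearnerParams":
        return replace(self, motor_noise_sd=0.0, p_jump_start=0.0, glitch_rate=0.0)


def planned_hand_direction(target_angle: float, context: str, inverted_axes: str = INVERTED_BOTH) -> float:
    """Hand-space direction required to acquire a target in a context.

    Point/Look share the target direction; Inverted Look requires the
    opposite hand direction (both axes inverted) or the vertical mirror
    (vertical-only inversion).
    """
    if context != INVERTED_LOOK:
        return float(target_angle) % 360.0
    if inverted_axes == INVERTED_BOTH:
        return (float(target_angle) + 180.0) % 360.0
    if inverted_axes == INVERTED_VERTICAL_ONLY:
        return (-float(target_angle)) % 360.0
    raise ValueError(f"unknown inverted_axes {inverted_axes!r}")


def _angular_distance(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 360.0
    return np.minimum(d, 360.0 - d)


def _compile_schedule(schedule: Schedule, inverted_axes: str = INVERTED_BOTH):
    trials = schedule.trials
    hand_dirs = np.array(
        [
            planned_hand_direction(t, c, inverted_axes)
            for t, c in zip(trials["target_angle"], trials["context"])
        ]
    )
    dir_index = np.searchsorted(HAND_DIRECTIONS, hand_dirs % 360.0)
    return {
        "hand_dir": hand_dirs,
        "dir_index": dir_index,
        "rotation_deg": trials["rotation_deg"].to_numpy(dtype=float),
        "online_check": trials["online_check"].to_numpy(dtype=bool),
    }


def _simulate_core(A, B, sigma, noise_sd, p_jump, compiled, rng):
    """Run the learner over a compiled schedule; vector ops on 4 states.

    Jump-start handling follows the task logic: where the online take-off
    check is active the jump start is aborted and the trial is repeated, so
    the scheduled trial still gets a valid execution and a learning update
    (the aborted attempt is flagged for the trajectory generator). Without
    the online check the jump start *is* the trial: the movement goes to an
    uncued target and no learning update is applied.
    """
    n = len(compiled["hand_dir"])
    rot = compiled["rotation_deg"]
    dir_index = compiled["dir_index"]
    hand_dir = compiled["hand_dir"]
    online_check = compiled["online_check"]

    x = np.zeros(4)
    aim = np.empty(n)
    noise = np.zeros(n)
    jump = np.zeros(n, dtype=bool)
    if rng is not None:
        if noise_sd > 0:
            noise = rng.normal(0.0, noise_sd, size=n)
        if p_jump > 0:
            jump = rng.random(n) < p_jump
        jump_sign = rng.choice([-90.0, 90.0], size=n)
    else:
        jump_sign = np.zeros(n)

    uncorrected_jump = jump & ~online_check
    aborted_attempt = jump & online_check

    for t in range(n):
        aim[t] = x[dir_index[t]]
        if uncorrected_jump[t]:
            # movement launched at an uncued neighbouring target with no
            # online abort: feedback is off-plan, so no learning update,
            # but passive retention still applies
            x *= A
            continue
        executed = aim[t] + noise[t]
        e = -(executed + rot[t])  # negated cursor error, CCW positive
        plan = hand_dir[t] + aim[t]
        w = np.exp(-(_angular_distance(HAND_DIRECTIONS, plan) ** 2) / (2.0 * sigma**2))
        x = A * x + B * e * w
    executed_dev = aim + noise + uncorrected_jump * jump_sign
    return aim, noise, jump, aborted_attempt, executed_dev


def simulate_learner(
    params: LearnerParams,
    schedule: Schedule,
    seed: int = 0,
    noise: bool = True,
    inverted_axes: str = INVERTED_BOTH,
) -> pd.DataFrame:
    """Simulate per-trial planned aim angles for one participant.

    Returns a DataFrame aligned with ``schedule.trials`` carrying the
    deterministic state (``aim_deg``, relative to the planned hand
    direction), the executed hand deviation including motor noise and jump
    starts (``executed_dev_deg``), the absolute planned hand direction and a
    jump-start flag. Deterministic given ``seed``.
    """
    compiled = _compile_schedule(schedule, inverted_axes)
    rng = np.random.default_rng(seed) if noise else None
    p_jump = params.p_jump_start if noise else 0.0
    noise_sd = params.motor_noise_sd if noise else 0.0
    aim, motor_noise, jump, aborted, executed = _simulate_core(
        params.retention_A,
        params.learning_rate_B,
        params.gen_sigma,
        noise_sd,
        p_jump,
        compiled,
        rng,
    )
    return pd.DataFrame(
        {
            "schedule_index": schedule.trials["schedule_index"].to_numpy(),
            "hand_dir_deg": compiled["hand_dir"],
            "aim_deg": aim,
            "motor_noise_deg": motor_noise,
            "jump_start": jump,
            "aborted_attempt": aborted,
            "executed_dev_deg": wrap_angle(executed),
        }
    )


def _normalized_cycle_means(aim: np.ndarray, rotation_direction: str, n_per_cycle: int = 4):
    sign = -1.0 if rotation_direction == "ccw" else 1.0
    usable = len(aim) - len(aim) % n_per_cycle
    return sign * aim[:usable].reshape(-1, n_per_cycle).mean(axis=1)


def fit_state_space(
    observed_cycle_means: np.ndarray,
    schedule: Schedule,
    params: LearnerParams = LearnerParams(),
    x0=(0.9, 0.2),
) -> tuple:
    """Least-squares fit of (A, B) to a normalized cycle-mean series.

    The generalization width and the schedule are taken as known; residuals
    compare the observed series against the noise-free learner trajectory.
    Returns ``(A_hat, B_hat)``.
    """
    observed = np.asarray(observed_cycle_means, dtype=float)
    compiled = _compile_schedule(schedule)
    direction = schedule.rotation_direction

    def residuals(theta):
        A, B = theta
        aim = _simulate_core(A, B, params.gen_sigma, 0.0, 0.0, compiled, None)[0]
        model = _normalized_cycle_means(aim, direction)
        return model[: len(observed)] - observed

    fit = least_squares(residuals, x0=x0, bounds=([0.0, 0.0], [1.0, 1.0]))
    return float(fit.x[0]), float(fit.x[1])
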