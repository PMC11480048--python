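"""The three RQ control policies.

* **MHC** — an automated emulation of the manual-heuristic strategy: at
  fixed check instants, if RQ exceeds 1.6 the agitation is increased by a
  scheduled step; the stirrer is never slowed down.
* **BLC** — the Boolean-logic controller: every 10 min, step up by a
  scheduled amount when RQ > 1.4, step down 10 rpm when RQ < 1.3, do
  nothing inside the deadband.
* **APC** — the adaptive-proportional controller: every minute a gain
  model predicts the agitation required to hold RQ at the set-point; the
  proportional law delta_rpm = epsilon * K_P (epsilon = RQ - set-point)
  is applied only when at least 7 min have passed since the last action
  and |delta_rpm| >= 2 rpm.

All policies share the ``reset()`` / ``decide(t, rq, ctx)`` protocol used
by :func:`rqcontrol.twin.simulate` and emit :class:`ControlAction`
records carrying their provenance (rule fired, epsilon, K_P).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import ControllerConfig, N_MIN_RPM, StepScheduleConfig

__all__ = [
    "ControlAction",
    "StepSchedule",
    "MHController",
    "BooleanLogicController",
    "AdaptiveProportionalController",
    "NullController",
    "make_controller",
]

RULES = ("MHC_UP", "BLC_UP", "BLC_DOWN", "APC", "NONE")


@dataclass(frozen=True)
class ControlAction:
    """A timestamped agitation change with its provenance."""

    t: float
    delta_rpm: float
    new_N: float
    rule: str
    epsilon: float = math.nan
    K_P: float = math.nan

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.new_N <= 0:
            raise ValueError("new_N must be positive")


def _none(t: float, N: float) -> ControlAction:
    return ControlAction(t=t, delta_rpm=0.0, new_N=N, rule="NONE")


class StepSchedule:
    """Piecewise-constant step magnitude over fed-batch time."""

    def __init__(self, config: StepScheduleConfig):
        self._breaks = list(config.breakpoints)

    def delta(self, t: float) -> float:
        out = self._breaks[0][1]
        for start, magnitude in self._breaks:
            if t >= start - 1e-12:
                out = magnitude
        return out


class _Clocked:
    """Shared clock machinery: act only at multiples of the check interval."""

    def __init__(self, check_interval_min: float, initial_N: float, smoothing: int):
        self.check_interval_h = check_interval_min / 60.0
        self.initial_N = initial_N
        self.rq_smoothing_window = smoothing
        self.reset()

    def reset(self) -> None:
        self._next_check = self.check_interval_h

    def _at_check(self, t: float) -> bool:
        if t >= self._next_check - 1e-9:
            while self._next_check <= t + 1e-9:
                self._next_check += self.check_interval_h
            return True
        return False


class MHController(_Clocked):
    """Automated stand-in for the human heuristic (never slows the stirrer)."""

    def __init__(self, config: ControllerConfig | None = None):
        config = config or ControllerConfig(type="mhc")
        self.threshold = config.mhc_threshold
        self.schedule = StepSchedule(config.mhc_schedule)
        super().__init__(
            config.mhc_check_interval_min,
            config.initial_N if config.initial_N is not None else 600.0,
            config.rq_smoothing_window,
        )

    def decide(self, t: float, rq: float, ctx: dict) -> ControlAction:
        n = ctx["N"]
        if not self._at_check(t) or not math.isfinite(rq) or rq <= self.threshold:
            return _none(t, n)
        delta = self.schedule.delta(t)
        return ControlAction(t=t, delta_rpm=delta, new_N=n + delta, rule="MHC_UP")


class BooleanLogicController(_Clocked):
    """Threshold law with a deadband, evaluated on a 10-min clock."""

    def __init__(self, config: ControllerConfig | None = None):
        config = config or ControllerConfig(type="blc")
        self.up_threshold = config.blc_up_threshold
        self.down_threshold = config.blc_down_threshold
        self.up_schedule = StepSchedule(config.blc_up_schedule)
        self.down_step = config.blc_down_step
        super().__init__(
            config.blc_check_interval_min,
            config.initial_N if config.initial_N is not None else 550.0,
            config.rq_smoothing_window,
        )

    def decide(self, t: float, rq: float, ctx: dict) -> ControlAction:
        n = ctx["N"]
        if not self._at_check(t) or not math.isfinite(rq):
            return _none(t, n)
        # down-rule first; mutually exclusive with the up-rule by thresholds
        if rq < self.down_threshold:
            delta = -self.down_step
            new_n = max(N_MIN_RPM, n + delta)
            return ControlAction(t=t, delta_rpm=delta, new_N=new_n, rule="BLC_DOWN")
        if rq > self.up_threshold:
            delta = self.up_schedule.delta(t)
            return ControlAction(t=t, delta_rpm=delta, new_N=n + delta, rule="BLC_UP")
        return _none(t, n)


class AdaptiveProportionalController:
    """Proportional RQ control with a learned, state-dependent gain.

    The gain model predicts the agitation speed required to hold the
    set-point; K_P is derived so that epsilon * K_P reproduces the
    predicted correction, then clamped to a non-negative range (clamping
    can shrink but never flip the sign of the move).
    """

    def __init__(self, model=None, config: ControllerConfig | None = None):
        config = config or ControllerConfig(type="apc")
        self.model = model
        self.set_point = config.set_point
        self.min_gap_h = config.apc_min_action_gap_min / 60.0
        self.deadband = config.apc_deadband_rpm
        self.kp_min, self.kp_max = config.apc_kp_range
        self.initial_N = config.initial_N if config.initial_N is not None else 550.0
        self.rq_smoothing_window = config.rq_smoothing_window
        self.warnings: list[str] = []
        self.reset()

    def reset(self) -> None:
        self._last_action_t = -math.inf
        self.warnings = []

    def decide(self, t: float, rq: float, ctx: dict) -> ControlAction:
        n = ctx["N"]
        if self.model is None:
            self.warnings.append(f"t={t:.3f} h: no gain model available")
            return _none(t, n)
        if not math.isfinite(rq):
            return _none(t, n)
        eps = rq - self.set_point
        if abs(eps) < 1e-12:
            return _none(t, n)
        from .gain_model import derive_kp

        n_pred, kp = derive_kp(
            self.model, ctx, current_N=n, rq=rq, set_point=self.set_point,
            kp_range=(self.kp_min, self.kp_max),
        )
        delta = eps * kp
        if t - self._last_action_t < self.min_gap_h - 1e-9:
            return _none(t, n)
        if abs(delta) < self.deadband:
            return _none(t, n)
        self._last_action_t = t
        new_n = max(N_MIN_RPM, n + delta)
        return ControlAction(
            t=t, delta_rpm=new_n - n, new_N=new_n, rule="APC", epsilon=eps, K_P=kp
        )


class NullController:
    """Keeps the initial agitation forever (open-loop reference)."""

    def __init__(self, initial_N: float = 575.0):
        self.initial_N = initial_N
        self.rq_smoothing_window = 1

    def reset(self) -> None:
        pass

    def decide(self, t: float, rq: float, ctx: dict) -> ControlAction:
        return _none(t, ctx["N"])


def make_controller(config: ControllerConfig, model=None):
    """Instantiate the policy named by ``config.type``."""
    if config.type == "mhc":
        return MHController(config)
    if config.type == "blc":
        return BooleanLogicController(config)
    if config.type == "apc":
        return AdaptiveProportionalController(model=model, config=config)
    return NullController(config.initial_N or 575.0)
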