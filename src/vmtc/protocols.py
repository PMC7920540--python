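"""Declarative current-clamp protocols of the study.

Four virtual experiments, run on any assembled cell (optionally under a
pharmacology overlay):

* F-I: 2 s depolarizing steps (default 30-360 pA in 30 pA increments) on
  top of a bias current holding the soma near -64 mV so the T-type
  calcium current is inactivated and the response is tonic firing.
* Rebound: -100 pA hyperpolarizing steps of 200/500/2000 ms from a
  ~-71 mV hold, each followed by a >= 1 s observation window for the
  post-inhibitory rebound burst.
* Sag: 2 s hyperpolarizing steps (-50 to -200 pA) from rest with no bias.
* Passive: the fixed -10 pA/100 ms input-resistance pulse and the
  -1 nA/0.5 ms time-constant pulse.

Every returned trace carries the stimulus, hold current, pharmacology and
solver settings needed to re-run it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulator import (
    CellModel,
    SimState,
    Stimulus,
    Trace,
    find_holding_current_batch,
    integrate,
    integrate_batch,
    settle,
)

__all__ = [
    "ProtocolSpec",
    "FI_AMPLITUDES",
    "run_fi",
    "run_rebound",
    "run_sag",
    "run_passive",
]

#: default F-I step amplitudes, pA
FI_AMPLITUDES = tuple(range(30, 361, 30))
SAG_AMPLITUDES = (-50.0, -100.0, -150.0, -200.0)
REBOUND_DURATIONS = (200.0, 500.0, 2000.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """Declarative description of one protocol run."""

    name: str  # fi_curve | rebound | sag | rin_pulse | tau_pulse
    hold_target: float | None = None  # mV
    step_amplitudes: tuple[float, ...] = ()
    step_duration: float = 2000.0
    pharmacology: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name == "fi_curve" and any(a <= 0 for a in self.step_amplitudes):
            raise ValueError("F-I steps must be depolarizing")
        if self.name in ("rebound", "sag") and any(
            a >= 0 for a in self.step_amplitudes
        ):
            raise ValueError(f"{self.name} steps must be hyperpolarizing")


def _annotate(traces, hold_pA, dt):
    for tr in traces:
        tr.metadata.update(hold_current_pA=float(hold_pA), dt=dt)
    return traces


#: bias search range for protocol holds (wider than the default search
#: bracket: a fully KM-blocked cell needs a large bias to keep its
#: interspike baseline at -64 mV)
HOLD_BRACKET = (-600.0, 1000.0)


def run_fi(
    cell: CellModel,
    amplitudes=FI_AMPLITUDES,
    hold_target: float = -64.0,
    step_duration: float = 2000.0,
    dt: float = 0.025,
    post_ms: float = 200.0,
) -> list[Trace]:
    """Tonic-firing steps on top of a bias holding the soma near -64 mV."""
    amplitudes = [float(a) for a in amplitudes]
    if not amplitudes:
        return []
    if any(a <= 0 for a in amplitudes):
        raise ValueError("F-I amplitudes must be positive")
    (hold,), (state,) = find_holding_current_batch(
        [cell], hold_target, dt=dt, bracket=HOLD_BRACKET
    )
    cells = [cell] * len(amplitudes)
    stims = [
        Stimulus(
            bias_current=hold,
            step_current=a,
            step_onset=200.0,
            step_duration=step_duration,
            total_duration=200.0 + step_duration + post_ms,
        )
        for a in amplitudes
    ]
    traces = integrate_batch(cells, stims, dt=dt, states=[state] * len(amplitudes))
    return _annotate(traces, hold, dt)


def run_rebound(
    cell: CellModel,
    amplitude: float = -100.0,
    durations=REBOUND_DURATIONS,
    hold_target: float = -71.0,
    dt: float = 0.025,
    post_ms: float = 1000.0,
) -> list[Trace]:
    """Hyperpolarizing steps from a ~-71 mV hold with a rebound window.

    Each trace keeps >= ``post_ms`` (default 1 s) after the step so the
    low-threshold rebound burst completes inside the trace.
    """
    if amplitude >= 0:
        raise ValueError("rebound steps must be hyperpolarizing")
    durations = [float(d) for d in durations]
    if not durations:
        return []
    (hold,), (state,) = find_holding_current_batch(
        [cell], hold_target, dt=dt, bracket=HOLD_BRACKET
    )
    traces = []
    for d in durations:  # durations differ -> separate kernel calls
        stim = Stimulus(
            bias_current=hold,
            step_current=amplitude,
            step_onset=200.0,
            step_duration=d,
            total_duration=200.0 + d + post_ms,
        )
        tr = integrate(cell, stim, dt=dt, state=state)
        traces.append(tr)
    return _annotate(traces, hold, dt)


def run_sag(
    cell: CellModel,
    amplitudes=SAG_AMPLITUDES,
    step_duration: float = 2000.0,
    dt: float = 0.025,
    post_ms: float = 300.0,
) -> list[Trace]:
    """2 s hyperpolarizing steps from rest (no bias current)."""
    amplitudes = [float(a) for a in amplitudes]
    if any(a >= 0 for a in amplitudes):
        raise ValueError("sag amplitudes must be negative")
    if not amplitudes:
        return []
    state, _ = settle(cell, 0.0, duration=2000.0, dt=dt)
    stims = [
        Stimulus(
            step_current=a,
            step_onset=200.0,
            step_duration=step_duration,
            total_duration=200.0 + step_duration + post_ms,
        )
        for a in amplitudes
    ]
    traces = integrate_batch(
        [cell] * len(amplitudes), stims, dt=dt, states=[state] * len(amplitudes)
    )
    return _annotate(traces, 0.0, dt)


def run_passive(cell: CellModel, dt: float = 0.025) -> dict[str, Trace]:
    """The fixed passive-property pulses from rest.

    Returns {'rin_trace': -10 pA/100 ms, 'tau_trace': -1 nA/0.5 ms}, both
    sampled at <= 0.025 ms.
    """
    state, _ = settle(cell, 0.0, duration=2000.0, dt=dt)
    rin = integrate(
        cell,
        Stimulus(step_current=-10.0, step_onset=100.0, step_duration=100.0,
                 total_duration=250.0),
        dt=dt,
        state=state,
    )
    tau = integrate(
        cell,
        Stimulus(step_current=-1000.0, step_onset=50.0, step_duration=0.5,
                 total_duration=250.0),
        dt=min(dt, 0.025),
        state=state,
    )
    _annotate([rin, tau], 0.0, dt)
    return {"rin_trace": rin, "tau_trace": tau}
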