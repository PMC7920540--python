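"""Cell assembly, current-clamp integration and passive calibration.

`assemble` realizes the channel-density table over a discretized
morphology; `integrate` advances the resulting compartmental model under a
current-clamp stimulus with a fixed-step implicit scheme (default dt
0.025 ms); `apply_pharmacology` scales channel densities (0 = exact
blockade); `find_holding_current` locates the bias current that holds the
soma at a target voltage; `calibrate_passive` tunes the surrogate
morphology's free knobs until the model reproduces the target passive
properties (input resistance, membrane time constant, capacitance,
resting potential) measured with the model's own virtual protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _engine
from .morphology import (
    CompartmentGrid,
    Morphology,
    SurrogateConfig,
    build_surrogate,
    classify_regions,
    discretize,
)
from .membrane import (
    CA_OUT_MM,
    CA_REST_MM,
    CA_INFLUX_K,
    CAL_CDI_EC50_MM,
    CHANNEL_NAMES,
    ChannelSpec,
    DistributionTable,
    ANO2_EC50_MM,
    ANO2_HILL,
    SK_EC50_MM,
    SK_HILL,
    default_channels,
    default_distribution_table,
    ghk_coefficients,
)

__all__ = [
    "PassiveParams",
    "Stimulus",
    "Trace",
    "SimState",
    "CellModel",
    "SolverError",
    "assemble",
    "build_cell",
    "default_cell",
    "integrate",
    "integrate_batch",
    "apply_pharmacology",
    "find_holding_current",
    "find_holding_current_batch",
    "calibrate_passive",
    "CalibrationResult",
    "PASSIVE_TARGETS",
    "DEFAULT_CALIBRATION",
]

#: expected gate structure (gate count per channel, exponents) of the kernel
_GATE_LAYOUT = (
    ("NaF", (3, 1)),
    ("NaP", (3, 1)),
    ("KDR", (2,)),
    ("KA", (4, 1)),
    ("KM", (1,)),
    ("CaL", (2,)),
    ("CaT", (2, 1)),
    ("IH", (1,)),
)


class SolverError(RuntimeError):
    """Numerical divergence of the voltage solve."""

    def __init__(self, t_ms: float):
        super().__init__(f"voltage diverged (|V| > 200 mV) at t = {t_ms:.3f} ms")
        self.t_ms = t_ms


@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive membrane parameters.

    ``rm`` is the specific membrane resistance in kOhm*cm^2 (26 kOhm*cm^2
    gives the expected ~26 ms passive time constant with cm = 1 uF/cm^2),
    ``ri`` the axial resistivity in Ohm*cm, ``cm`` in uF/cm^2.
    """

    rm: float = 26.0
    ri: float = 60.0
    cm: float = 1.0
    e_pas: float = -75.75

    def __post_init__(self) -> None:
        if self.rm <= 0 or self.ri <= 0 or self.cm <= 0:
            raise ValueError("rm, ri, cm must be > 0")


@dataclass(frozen=True)
class Stimulus:
    """Somatic current-clamp stimulus: a constant bias plus one step."""

    bias_current: float = 0.0  # pA, on from t = 0
    step_current: float = 0.0  # pA
    step_onset: float = 0.0  # ms
    step_duration: float = 0.0  # ms
    total_duration: float = 1000.0  # ms
    injection_site: int | None = None  # compartment index; None = soma

    def __post_init__(self) -> None:
        if self.step_onset < 0:
            raise ValueError("step_onset must be >= 0")
        if self.step_onset + self.step_duration > self.total_duration + 1e-9:
            raise ValueError("step must end within total_duration")


@dataclass
class Trace:
    """A sampled somatic voltage trace with its stimulus and provenance."""

    times: np.ndarray  # ms, uniform
    voltage: np.ndarray  # mV
    stimulus: Stimulus
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ms": self.times, "voltage_mV": self.voltage})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SimState:
    """Dynamic state of a model (voltage, gates, calcium pools)."""

    v: np.ndarray  # (n,)
    gates: np.ndarray  # (12, n)
    ca: np.ndarray  # (3, n)

    def copy(self) -> "SimState":
        return SimState(self.v.copy(), self.gates.copy(), self.ca.copy())


@dataclass
class CellModel:
    """Assembled compartmental model."""

    morphology: Morphology
    grid: CompartmentGrid
    comp_label: list[str]  # density-column label per compartment
    passive: PassiveParams
    distribution: DistributionTable
    channels: dict[str, ChannelSpec]
    pharmacology: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, f in self.pharmacology.items():
            if f < 0:
                raise ValueError(f"pharmacology factor for {ch} must be >= 0")

    @property
    def n_comp(self) -> int:
        return self.grid.n

    @property
    def soma_index(self) -> int:
        return int(np.flatnonzero(self.grid.is_soma)[0])

    def density(self, channel: str) -> np.ndarray:
        """Effective per-compartment density (S/cm^2 or cm/s) incl. pharmacology."""
        base = np.array(
            [self.distribution.get(channel, lab) for lab in self.comp_label]
        )
        return base * self.pharmacology.get(channel, 1.0)

    def total_conductance(self, channel: str) -> float:
        """Area-weighted total (S for ohmic channels, cm^3/s for GHK)."""
        return float(np.sum(self.density(channel) * self.grid.area_um2 * 1e-8))


def assemble(
    m: Morphology,
    dist: DistributionTable | None = None,
    pas: PassiveParams | None = None,
    channels: dict[str, ChannelSpec] | None = None,
    proximal_path_cutoff: float = 100.0,
    max_seg_length: float = 40.0,
) -> CellModel:
    """Assemble a compartmental cell from a morphology and a density table."""
    dist = dist if dist is not None else default_distribution_table()
    pas = pas if pas is not None else PassiveParams()
    channels = channels if channels is not None else default_channels()
    _check_gate_layout(channels)
    labels = classify_regions(m, proximal_path_cutoff=proximal_path_cutoff)
    for ch, row in dist.density.items():
        for region in row:
            if region not in ("ais", "soma", "dend_class_1", "dend_class_2", "dend_class_3"):
                raise ValueError(f"unknown region label {region!r} in density table")
    grid = discretize(m, max_seg_length=max_seg_length)
    comp_label = [labels[int(sid)] for sid in grid.section_id]
    return CellModel(
        morphology=m,
        grid=grid,
        comp_label=comp_label,
        passive=pas,
        distribution=dist,
        channels=channels,
    )


def _check_gate_layout(channels: dict[str, ChannelSpec]) -> None:
    for name, exps in _GATE_LAYOUT:
        spec = channels.get(name)
        if spec is None:
            raise ValueError(f"channel catalogue is missing {name}")
        got = tuple(g.exponent for g in spec.gates)
        if got != exps:
            raise ValueError(
                f"{name}: gate exponents {got} do not match the kernel layout {exps}"
            )
    for name in ("SK", "ANO2"):
        if channels.get(name) is None or channels[name].gates:
            raise ValueError(f"{name} must be present with calcium-only gating")


def apply_pharmacology(cell: CellModel, scales: dict[str, float]) -> CellModel:
    """Return a copy with channel scale factors composed multiplicatively."""
    for ch, f in scales.items():
        if ch not in CHANNEL_NAMES:
            raise ValueError(f"unknown channel {ch!r}")
        if f < 0:
            raise ValueError("pharmacology factors must be >= 0")
    pharm = dict(cell.pharmacology)
    for ch, f in scales.items():
        pharm[ch] = pharm.get(ch, 1.0) * f
    return replace(cell, pharmacology=pharm)


# ---------------------------------------------------------------------------
# gate/GHK lookup tables
# ---------------------------------------------------------------------------

_V_GRID = np.linspace(_engine.V_TAB_MIN, _engine.V_TAB_MAX, _engine.N_TAB)
_TABLE_CACHE: dict = {}

_GATE_ORDER = (
    ("NaF", 0),
    ("NaF", 1),
    ("NaP", 0),
    ("NaP", 1),
    ("KDR", 0),
    ("KA", 0),
    ("KA", 1),
    ("KM", 0),
    ("CaL", 0),
    ("CaT", 0),
    ("CaT", 1),
    ("IH", 0),
)


def _catalogue_key(channels: dict[str, ChannelSpec]):
    parts = []
    for ch, gi in _GATE_ORDER:
        g = channels[ch].gates[gi]
        parts.append((ch, gi, id(g.steady_state), id(g.time_constant), g.voltage_shift))
    return tuple(parts)


def _tables_for(channels: dict[str, ChannelSpec], dt: float):
    key = (_catalogue_key(channels), round(dt, 9))
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    inf_tab = np.empty((_engine.N_GATES, _engine.N_TAB))
    efac_tab = np.empty_like(inf_tab)
    for row, (ch, gi) in enumerate(_GATE_ORDER):
        g = channels[ch].gates[gi]
        inf_tab[row] = g.inf(_V_GRID)
        tau = np.maximum(g.tau(_V_GRID), 1e-6)
        efac_tab[row] = np.exp(-dt / tau)
    a, b = ghk_coefficients(_V_GRID)
    da = np.gradient(a, _engine.V_TAB_STEP)
    db = np.gradient(b, _engine.V_TAB_STEP)
    out = (inf_tab, efac_tab, a, b, da, db)
    _TABLE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# packing and integration
# ---------------------------------------------------------------------------

def _pack_cells(cells: Sequence[CellModel]):
    """Concatenate cells into one forest for the kernel."""
    ref = cells[0]
    n_tot = sum(c.n_comp for c in cells)
    parent = np.empty(n_tot, dtype=np.int64)
    g_ax = np.empty(n_tot)
    c_nf = np.empty(n_tot)
    g_leak = np.empty(n_tot)
    area_s = np.empty(n_tot)
    g_us = np.zeros((_engine.N_CHANNELS, n_tot))
    p_cms = np.zeros((_engine.N_CHANNELS, n_tot))
    soma_idx = np.empty(len(cells), dtype=np.int64)
    offsets = []
    off = 0
    for k, cell in enumerate(cells):
        n = cell.n_comp
        sl = slice(off, off + n)
        offsets.append(off)
        pa = cell.grid.parent.copy()
        pa[pa >= 0] += off
        parent[sl] = pa
        g_ax[sl] = cell.grid.axial_conductance_uS(cell.passive.ri)
        area_cm2 = cell.grid.area_um2 * 1e-8
        area_s[sl] = area_cm2 * 1e6
        c_nf[sl] = cell.passive.cm * area_cm2 * 1e3
        g_leak[sl] = area_cm2 * 1e6 / (cell.passive.rm * 1e3)
        for ci, ch in enumerate(CHANNEL_NAMES):
            dens = cell.density(ch)
            if ch in ("CaL", "CaT"):
                p_cms[ci, sl] = dens
            else:
                g_us[ci, sl] = dens * area_cm2 * 1e6
        soma_idx[k] = off + cell.soma_index
        off += n
    e_rev = np.array(
        [
            (cells[0].channels[ch].reversal if not cells[0].channels[ch].is_ghk else 0.0)
            for ch in CHANNEL_NAMES
        ]
    )
    return parent, g_ax, c_nf, g_leak, area_s, g_us, p_cms, e_rev, soma_idx, offsets


def _init_state(cell: CellModel, v_init: float | None = None) -> SimState:
    v0 = cell.passive.e_pas if v_init is None else v_init
    v = np.full(cell.n_comp, float(v0))
    inf_tab, _, _, _, _, _ = _tables_for(cell.channels, 0.025)
    pos = (v0 - _engine.V_TAB_MIN) / _engine.V_TAB_STEP
    i0 = int(np.clip(pos, 0, _engine.N_TAB - 2))
    f = pos - i0
    gates = np.empty((_engine.N_GATES, cell.n_comp))
    for g in range(_engine.N_GATES):
        gates[g, :] = inf_tab[g, i0] * (1 - f) + inf_tab[g, i0 + 1] * f
    ca = np.full((3, cell.n_comp), CA_REST_MM)
    return SimState(v=v, gates=gates, ca=ca)


def integrate_batch(
    cells: Sequence[CellModel],
    stims: Sequence[Stimulus],
    dt: float = 0.025,
    record_dt: float | None = None,
    states: Sequence[SimState] | None = None,
    return_states: bool = False,
):
    """Integrate several cells at once (one tree per cell, shared kernel call).

    Returns a list of somatic Traces, plus final SimStates when requested.
    Raises SolverError on divergence.
    """
    if len(cells) != len(stims):
        raise ValueError("one stimulus per cell required")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    record_dt = dt if record_dt is None else record_dt
    rec_every = max(1, int(round(record_dt / dt)))
    record_dt = rec_every * dt

    total = stims[0].total_duration
    for s in stims:
        if abs(s.total_duration - total) > 1e-9:
            raise ValueError("batched stimuli must share total_duration")
    n_steps = int(round(total / dt))

    packed = _pack_cells(cells)
    parent, g_ax, c_nf, g_leak, area_s, g_us, p_cms, e_rev, soma_idx, offsets = packed

    if states is None:
        st = [_init_state(c) for c in cells]
    else:
        st = [s.copy() for s in states]
    v = np.concatenate([s.v for s in st])
    gates = np.concatenate([s.gates for s in st], axis=1)
    ca = np.concatenate([s.ca for s in st], axis=1)

    inf_tab, efac_tab, ghk_a, ghk_b, ghk_da, ghk_db = _tables_for(
        cells[0].channels, dt
    )

    stim_comp = np.empty(len(cells), dtype=np.int64)
    bias_na = np.empty(len(cells))
    step_na = np.empty(len(cells))
    step_on = np.empty(len(cells), dtype=np.int64)
    step_off = np.empty(len(cells), dtype=np.int64)
    for k, (cell, s) in enumerate(zip(cells, stims)):
        site = cell.soma_index if s.injection_site is None else s.injection_site
        stim_comp[k] = offsets[k] + site
        bias_na[k] = s.bias_current * 1e-3
        step_na[k] = s.step_current * 1e-3
        step_on[k] = int(round(s.step_onset / dt))
        step_off[k] = int(round((s.step_onset + s.step_duration) / dt))

    n_samples = n_steps // rec_every + 1
    out_v = np.empty((len(cells), n_samples))
    pools_frac = np.array([0.258, 0.742, 1.0])
    pools_tau = np.array([14.0, 50.0, 50.0])
    pools_efac = np.exp(-dt / pools_tau)

    code, t_end, n_got = _engine.run(
        v, gates, ca, n_steps, dt,
        parent, g_ax, c_nf, g_leak, cells[0].passive.e_pas, area_s,
        g_us, p_cms, e_rev,
        inf_tab, efac_tab,
        ghk_a, ghk_b, ghk_da, ghk_db, CA_OUT_MM,
        pools_frac, pools_efac, pools_tau, CA_REST_MM, CA_INFLUX_K,
        SK_EC50_MM, SK_HILL, ANO2_EC50_MM, ANO2_HILL, CAL_CDI_EC50_MM,
        stim_comp, bias_na, step_na, step_on, step_off,
        soma_idx, rec_every, out_v,
    )
    if code == _engine.DIVERGED:
        raise SolverError(t_end)

    times = np.arange(n_samples) * record_dt
    traces = []
    for k, (cell, s) in enumerate(zip(cells, stims)):
        traces.append(
            Trace(
                times=times.copy(),
                voltage=out_v[k].copy(),
                stimulus=s,
                metadata={
                    "dt": dt,
                    "record_dt": record_dt,
                    "pharmacology": dict(cells[k].pharmacology),
                    "solver": "implicit-hines-fixed-step",
                },
            )
        )
    if return_states:
        final = []
        for k, cell in enumerate(cells):
            sl = slice(offsets[k], offsets[k] + cell.n_comp)
            final.append(SimState(v[sl].copy(), gates[:, sl].copy(), ca[:, sl].copy()))
        return traces, final
    return traces


def integrate(
    cell: CellModel,
    stim: Stimulus,
    dt: float = 0.025,
    record_dt: float | None = None,
    state: SimState | None = None,
    return_state: bool = False,
):
    """Integrate one cell under a current-clamp stimulus; see integrate_batch."""
    res = integrate_batch(
        [cell],
        [stim],
        dt=dt,
        record_dt=record_dt,
        states=None if state is None else [state],
        return_states=return_state,
    )
    if return_state:
        traces, states = res
        return traces[0], states[0]
    return res[0]


#: default initialization voltage: slightly depolarized so the T-type
#: current starts inactivated and the settle relaxes to the quiet resting
#: state instead of firing a spurious initial low-threshold burst (the
#: model, like real TC neurons, can be bistable between a quiet rest and a
#: burst limit cycle)
V_INIT_MV = -65.0


def settle(
    cell: CellModel,
    bias_pA: float = 0.0,
    duration: float = 2000.0,
    dt: float = 0.025,
    state: SimState | None = None,
    v_init: float = V_INIT_MV,
) -> tuple[SimState, float]:
    """Relax the model to its quiet steady state under a bias current.

    Returns the final state and the mean somatic voltage over the last
    100 ms.
    """
    if state is None:
        state = _init_state(cell, v_init=v_init)
    tr, st = integrate(
        cell,
        Stimulus(bias_current=bias_pA, total_duration=duration),
        dt=dt,
        record_dt=max(dt, 0.5),
        state=state,
        return_state=True,
    )
    tail = tr.voltage[tr.times >= duration - 100.0]
    return st, float(np.mean(tail))


# ---------------------------------------------------------------------------
# holding current
# ---------------------------------------------------------------------------

def steady_state_injection(cell: CellModel, v: float) -> float:
    """Injected current (pA) that balances all membrane currents at a
    spatially uniform voltage ``v`` with gates at steady state and calcium
    at rest (the analytic first guess for the holding-current search)."""
    from .membrane import CA_REST_MM as _car

    area = cell.grid.area_um2 * 1e-8  # cm^2
    total_na = 0.0
    for ch in CHANNEL_NAMES:
        spec = cell.channels[ch]
        dens = cell.density(ch)
        open_frac = 1.0
        for g in spec.gates:
            open_frac = open_frac * float(g.inf(v)) ** g.exponent
        if spec.calcium_dependence is not None:
            _, act = spec.calcium_dependence
            open_frac = open_frac * float(act(_car))
        if spec.is_ghk:
            a, b = ghk_coefficients(np.array([v]))
            i_dens = open_frac * (float(a[0]) * _car - float(b[0]) * CA_OUT_MM)
        else:
            i_dens = open_frac * (v - spec.reversal)
        total_na += float(np.sum(dens * area)) * i_dens * 1e6
    g_leak = area * 1e6 / (cell.passive.rm * 1e3)
    total_na += float(np.sum(g_leak)) * (v - cell.passive.e_pas)
    return total_na * 1e3  # nA -> pA


def find_holding_current_batch(
    cells: Sequence[CellModel],
    v_target: float,
    tol: float = 0.5,
    bracket: tuple[float, float] = (-500.0, 500.0),
    dt: float = 0.05,
    settle_ms: float = 1000.0,
    max_iter: int = 12,
    strict: bool = True,
):
    """Secant search for the bias current holding each soma at ``v_target``.

    The search starts from the target-voltage steady state (gates at their
    ``v_target`` values, so the T-type current is already inactivated at
    depolarized targets, mirroring the experimental bias procedure) with an
    analytic uniform-voltage current guess.  Returns (currents_pA, states)
    with each state settled at its final current.
    """
    if not (-90.0 <= v_target <= -40.0):
        raise ValueError("v_target outside the supported [-90, -40] mV range")
    n = len(cells)
    states = [_init_state(c, v_init=v_target) for c in cells]
    i_cur = np.array(
        [
            min(max(steady_state_injection(c, v_target), bracket[0]), bracket[1])
            for c in cells
        ]
    )
    i_prev = np.full(n, np.nan)
    v_prev = np.full(n, np.nan)
    err = np.full(n, np.inf)
    for it in range(max_iter):
        stims = [
            Stimulus(bias_current=float(i_cur[k]), total_duration=settle_ms)
            for k in range(n)
        ]
        traces, states = integrate_batch(
            cells, stims, dt=dt, record_dt=0.5, states=states, return_states=True
        )
        v_cur = np.array(
            [np.median(t.voltage[t.times >= settle_ms - 200.0]) for t in traces]
        )
        err = v_cur - v_target
        if np.all(np.abs(err) < tol):
            return i_cur, states
        slope = np.where(
            np.isfinite(v_prev) & (np.abs(v_cur - v_prev) > 1e-6),
            (i_cur - i_prev) / np.where(np.abs(v_cur - v_prev) > 1e-6, v_cur - v_prev, 1.0),
            6.0,
        )
        slope = np.clip(slope, 1.0, 60.0)  # pA/mV
        i_prev, v_prev = i_cur.copy(), v_cur.copy()
        i_cur = np.clip(i_cur - err * slope, *bracket)
    bad = np.abs(err) >= tol
    if not strict:
        return i_cur, states
    if np.any(bad & ((i_cur <= bracket[0] + 1e-9) | (i_cur >= bracket[1] - 1e-9))):
        raise RuntimeError(
            f"holding target {v_target} mV unreachable within {bracket} pA"
        )
    raise RuntimeError(
        f"holding-current search did not converge (residual {np.max(np.abs(err[bad])):.2f} mV)"
    )


def find_holding_current(
    cell: CellModel,
    v_target: float,
    tol: float = 0.5,
    **kwargs,
) -> float:
    """Bias current (pA) holding the soma within ``tol`` of ``v_target``."""
    i, _ = find_holding_current_batch([cell], v_target, tol=tol, **kwargs)
    return float(i[0])


# ---------------------------------------------------------------------------
# passive calibration
# ---------------------------------------------------------------------------

#: passive targets of the model (input resistance, slow time constant,
#: capacitance = tau/Rin, resting potential)
PASSIVE_TARGETS = {"Rin": 218.2, "tau": 19.1, "C": 87.4, "Vrest": -77.3}

#: calibration bounds: the specific membrane resistance (kOhm*cm^2) and the
#: effective reversal (mV) of the lumped background/leak conductance
RM_BOUNDS = (26.0, 220.0)
E_PAS_BOUNDS = (-90.0, 45.0)

#: calibrated surrogate knobs shipped as the package default (reproduced by
#: calibrate_passive from any nearby start)
DEFAULT_CALIBRATION = {
    "stem_diameter": 3.0825,
    "section_length_mean": 40.0,
    "rm": 88.7532,
    "e_pas": -70.4883,
}


@dataclass
class CalibrationResult:
    cell: CellModel
    config: SurrogateConfig
    passive: PassiveParams
    measured: dict[str, float]
    targets: dict[str, float]
    knobs: dict[str, float]
    n_evals: int
    converged: bool


def measure_passive_properties(
    cell: CellModel, dt: float = 0.025, settle_ms: float = 2500.0
) -> dict[str, float]:
    """Measure Rin, tau, C and Vrest with the model's own protocols.

    Rin: -10 pA, 100 ms somatic pulse; deflection at 100 ms / current.
    tau: slowest time constant of a double-exponential fit to the decay
    after a -1 nA, 0.5 ms pulse.  C = tau / Rin.  Vrest: steady-state
    somatic voltage with no injected current.
    """
    from . import features

    state, vrest = settle(cell, 0.0, duration=settle_ms, dt=dt)
    rin_tr = integrate(
        cell,
        Stimulus(step_current=-10.0, step_onset=100.0, step_duration=100.0,
                 total_duration=250.0),
        dt=dt,
        state=state,
    )
    rin = features.input_resistance(rin_tr)
    tau_tr = integrate(
        cell,
        Stimulus(step_current=-1000.0, step_onset=50.0, step_duration=0.5,
                 total_duration=250.0),
        dt=min(dt, 0.025),
        state=state,
    )
    tau = features.estimate_tau(tau_tr, method="double_exp")
    return {"Rin": rin, "tau": tau, "C": features.capacitance(tau, rin), "Vrest": vrest}


def build_cell(
    stem_diameter: float | None = None,
    section_length_mean: float | None = None,
    rm: float | None = None,
    e_pas: float | None = None,
    config: SurrogateConfig | None = None,
    dist: DistributionTable | None = None,
    channels: dict[str, ChannelSpec] | None = None,
    passive: PassiveParams | None = None,
    **assemble_kwargs,
) -> CellModel:
    """Build a surrogate-morphology cell, defaulting to the calibrated knobs."""
    cfg = config or SurrogateConfig()
    cfg = replace(
        cfg,
        stem_diameter=stem_diameter
        if stem_diameter is not None
        else DEFAULT_CALIBRATION["stem_diameter"],
        section_length_mean=section_length_mean
        if section_length_mean is not None
        else DEFAULT_CALIBRATION["section_length_mean"],
    )
    pas = passive or PassiveParams(
        rm=rm if rm is not None else DEFAULT_CALIBRATION["rm"],
        e_pas=e_pas if e_pas is not None else DEFAULT_CALIBRATION["e_pas"],
    )
    if passive is not None:
        if e_pas is not None:
            pas = replace(pas, e_pas=e_pas)
        if rm is not None:
            pas = replace(pas, rm=rm)
    m = build_surrogate(cfg)
    return assemble(m, dist=dist, pas=pas, channels=channels, **assemble_kwargs)


def default_cell(**kwargs) -> CellModel:
    """The calibrated default model cell."""
    return build_cell(**kwargs)


def calibrate_passive(
    targets: dict[str, float] | None = None,
    base_config: SurrogateConfig | None = None,
    passive: PassiveParams | None = None,
    dist: DistributionTable | None = None,
    channels: dict[str, ChannelSpec] | None = None,
    rtol: dict[str, float] | None = None,
    max_evals: int = 60,
    dt: float = 0.05,
) -> CalibrationResult:
    """Tune the surrogate's free knobs to the passive targets.

    Knobs: dendritic stem diameter (geometry / total membrane load), the
    specific membrane resistance rm, and the effective reversal of the
    lumped background conductance e_pas.  Derivative-free Broyden iteration
    on the (Rin, tau, Vrest) residuals; capacitance follows as tau/Rin.
    Acceptance tolerances: Rin 5%, tau 10%, C 10%, Vrest 1.5 mV; the
    internal stopping tolerances are tighter.
    """
    targets = dict(PASSIVE_TARGETS, **(targets or {}))
    # converge well inside the acceptance bands (Rin 5%, tau 10%, C 10%,
    # Vrest 1.5 mV) so the shipped model sits near the targets themselves
    tol = {"Rin": 0.02, "tau": 0.05, "C": 0.05, "Vrest": 0.5}
    if rtol:
        tol.update(rtol)
    cfg0 = base_config or SurrogateConfig(
        stem_diameter=DEFAULT_CALIBRATION["stem_diameter"],
        section_length_mean=DEFAULT_CALIBRATION["section_length_mean"],
    )
    pas0 = passive or PassiveParams(
        rm=DEFAULT_CALIBRATION["rm"], e_pas=DEFAULT_CALIBRATION["e_pas"]
    )
    n_evals = 0

    def make(d_stem: float, rm: float, e_pas: float) -> CellModel:
        return build_cell(
            stem_diameter=d_stem,
            section_length_mean=cfg0.section_length_mean,
            config=cfg0,
            dist=dist,
            channels=channels,
            passive=replace(pas0, rm=rm, e_pas=e_pas),
        )

    def evaluate(d_stem: float, rm: float, e_pas: float):
        nonlocal n_evals
        cell = make(d_stem, rm, e_pas)
        meas = measure_passive_properties(cell, dt=dt)
        n_evals += 1
        return cell, meas

    def within(meas):
        return (
            abs(meas["Rin"] / targets["Rin"] - 1.0) < tol["Rin"]
            and abs(meas["tau"] / targets["tau"] - 1.0) < tol["tau"]
            and abs(meas["C"] / targets["C"] - 1.0) < tol["C"]
            and abs(meas["Vrest"] - targets["Vrest"]) < tol["Vrest"]
        )

    lo = np.array([0.5, RM_BOUNDS[0], E_PAS_BOUNDS[0]])
    hi = np.array([8.0, RM_BOUNDS[1], E_PAS_BOUNDS[1]])
    x = np.clip(np.array([cfg0.stem_diameter, pas0.rm, pas0.e_pas]), lo, hi)
    cell, meas = evaluate(*x)
    best = (cell, meas, x.copy())

    def err_of(meas, key):
        if key == "Vrest":
            return meas["Vrest"] - targets["Vrest"]
        return meas[key] / targets[key] - 1.0

    def solve_knob(knob, key, cell, meas, step0, tol_k, iters):
        """1D secant on one knob against one measurement, bounds-clipped."""
        nonlocal n_evals
        e0 = err_of(meas, key)
        if abs(e0) < tol_k:
            return cell, meas
        x_prev, e_prev = x[knob], e0
        x[knob] = np.clip(x[knob] + step0 * (-np.sign(e0) if step0 > 0 else 1.0), lo[knob], hi[knob])
        for _ in range(iters):
            cell, meas = evaluate(*x)
            e1 = err_of(meas, key)
            if abs(e1) < tol_k:
                return cell, meas
            de = e1 - e_prev
            if abs(de) < 1e-12 or abs(x[knob] - x_prev) < 1e-12:
                return cell, meas
            slope = de / (x[knob] - x_prev)
            x_prev, e_prev = x[knob], e1
            x[knob] = np.clip(x[knob] - e1 / slope, lo[knob], hi[knob])
        cell, meas = evaluate(*x)
        return cell, meas

    # sequential coordinate passes: rm sets tau (saturating, so first),
    # the background reversal sets Vrest, the stem diameter sets Rin
    for _ in range(4):
        if within(meas):
            break
        cell, meas = solve_knob(1, "tau", cell, meas, 0.25 * x[1], 0.6 * tol["tau"], 3)
        cell, meas = solve_knob(2, "Vrest", cell, meas, 8.0, 0.5 * tol["Vrest"], 4)
        cell, meas = solve_knob(0, "Rin", cell, meas, 0.12 * x[0], 0.4 * tol["Rin"], 4)
        if np.isfinite(meas["Rin"]) and (
            abs(err_of(meas, "Rin")) + abs(err_of(meas, "tau"))
            <= abs(err_of(best[1], "Rin")) + abs(err_of(best[1], "tau"))
            or within(meas)
        ):
            best = (cell, meas, x.copy())
        if n_evals >= max_evals:
            break
    if within(meas):
        best = (cell, meas, x.copy())
    return _calib_result(best, cfg0, targets, n_evals, within(best[1]))


def _calib_result(best, cfg0, targets, n_evals, converged) -> CalibrationResult:
    cell, meas, x = best
    e_pas = x[2]
    cfg = replace(cfg0, stem_diameter=float(x[0]))
    return CalibrationResult(
        cell=cell,
        config=cfg,
        passive=cell.passive,
        measured=dict(meas),
        targets=dict(targets),
        knobs={
            "stem_diameter": float(x[0]),
            "rm": float(x[1]),
            "e_pas": float(e_pas),
        },
        n_evals=n_evals,
        converged=converged,
    )
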