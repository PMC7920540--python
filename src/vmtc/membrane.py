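"""Voltage- and calcium-gated conductances of the thalamocortical model.

Ten channel classes are distributed over the morphology: fast sodium (NaF),
persistent sodium (NaP, derived from NaF by a hyperpolarizing voltage
shift), delayed-rectifier potassium (KDR), transient A-type potassium (KA),
M-type/Kv7 potassium (KM), high-threshold L-type calcium (CaL), small-
conductance calcium-activated potassium (SK), calcium-activated chloride
(ANO2), low-threshold T-type calcium (CaT) and the hyperpolarization-
activated cation current (IH).

Kinetics for the channels not defined by the M-current equation are a
versioned catalogue of standard published thalamocortical / cortical
parameterizations (see docs/methods.md): Colbert & Pan-type transient Na,
a Kv3-family delayed rectifier, Korngreen & Sakmann-type transient K, a
Budde-type IH, Destexhe-type GHK T-current, a GHK L-current and Hill-gated
SK/ANO2.  All rate functions are evaluated at the simulated temperature of
27 C through per-channel Q10 factors.  The catalogue is swappable: any
ChannelSpec with the same gate structure can be substituted.

Calcium entering through CaL binds two somatodendritic microdomains
(fractions 25.8% and 74.2%, decay 14 and 50 ms) that gate SK and ANO2
respectively; calcium entering through CaT binds a third 50-ms microdomain
that gates nothing (bookkeeping only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "DistributionTable",
    "CalciumPools",
    "TEMPERATURE_C",
    "E_NA",
    "E_K",
    "E_H",
    "E_ANO2",
    "CA_OUT_MM",
    "CA_REST_MM",
    "CHANNEL_NAMES",
    "km_steady_state",
    "km_time_constant",
    "derive_nap_from_naf",
    "shift_ih_inactivation",
    "default_channels",
    "default_distribution_table",
    "default_calcium_pools",
    "channel_current",
    "update_calcium",
    "ghk_coefficients",
]

#: simulated temperature (C), the average slice-recording temperature
TEMPERATURE_C = 27.0

E_NA = 50.0  # mV
E_K = -85.0  # mV
E_H = -35.0  # mV
E_ANO2 = -86.0  # mV, fixed chloride reversal of the ANO2 current

CA_OUT_MM = 2.0  # external calcium, matching 2 mM CaCl2 ACSF
CA_REST_MM = 5e-5  # resting microdomain calcium (50 nM)

FARADAY = 96485.332  # C/mol
GAS_R = 8.31446  # J/(mol K)

CHANNEL_NAMES = ("NaF", "NaP", "KDR", "KA", "KM", "CaL", "SK", "ANO2", "CaT", "IH")

_VCLIP = (-120.0, 40.0)


def _q10(q10: float, t_ref: float, t: float = TEMPERATURE_C) -> float:
    return q10 ** ((t - t_ref) / 10.0)


@dataclass(frozen=True)
class GateSpec:
    """One Hodgkin-Huxley gating variable.

    ``steady_state`` and ``time_constant`` are base curves; a nonzero
    ``voltage_shift`` dv translates both along the voltage axis so that
    the half-activation voltage moves by exactly dv (curves are evaluated
    at v - dv).
    """

    name: str
    steady_state: Callable[[np.ndarray], np.ndarray]
    time_constant: Callable[[np.ndarray], np.ndarray]
    exponent: int = 1
    voltage_shift: float = 0.0

    def inf(self, v):
        return self.steady_state(np.asarray(v, dtype=float) - self.voltage_shift)

    def tau(self, v):
        return self.time_constant(np.asarray(v, dtype=float) - self.voltage_shift)

    def translated(self, dv: float) -> "GateSpec":
        return replace(self, voltage_shift=self.voltage_shift + dv)


@dataclass(frozen=True)
class ChannelSpec:
    """A channel: gates, reversal (or GHK flux model) and calcium coupling.

    ``reversal`` is a potential in mV for ohmic channels or ``None`` for
    the GHK calcium channels.  ``calcium_dependence`` names the microdomain
    pool whose concentration gates the channel, together with a Hill
    activation function of calcium (mM).
    """

    name: str
    gates: tuple[GateSpec, ...]
    reversal: float | None
    calcium_dependence: tuple[str, Callable[[np.ndarray], np.ndarray]] | None = None

    @property
    def is_ghk(self) -> bool:
        return self.reversal is None


# ---------------------------------------------------------------------------
# rate-function helpers
# ---------------------------------------------------------------------------

def _efun(x):
    """x / (exp(x) - 1) with the removable singularity at x = 0 handled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))


def _sig(v, half, k):
    """Rising sigmoid 1/(1+exp(-(v-half)/k))."""
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - half) / k))


# ---------------------------------------------------------------------------
# M-current (Kv7): activation from the adopted printed equation
# ---------------------------------------------------------------------------

#: additive open-fraction offset of the M-current activation curve
KM_OFFSET = 0.025
KM_HALF = -36.7
KM_SLOPE = 9.48


def km_steady_state(v):
    """M-current activation 0.025 + 1/(1 + exp(-(v + 36.7)/9.48)).

    The constant term raises the resting open fraction (lowering the model
    resting potential); the curve deliberately exceeds 1 (max 1.025) and is
    not clamped.
    """
    return KM_OFFSET + _sig(v, KM_HALF, KM_SLOPE)


_KM_QT = _q10(2.3, 21.0)


def km_time_constant(v):
    """Kv7 activation time constant (ms), Adams/Yamada-type kinetics."""
    v = np.asarray(v, dtype=float)
    alpha = 6.6e-3 * np.exp(0.1 * (v + 35.0))
    beta = 6.6e-3 * np.exp(-0.1 * (v + 35.0))
    return 1.0 / (alpha + beta) / _KM_QT


# ---------------------------------------------------------------------------
# catalogue rate functions
# ---------------------------------------------------------------------------

# Traub-style transient sodium (the classic thalamocortical relay-cell
# parameterization); rates accelerate with temperature (Q10 3, 36 C ref),
# so at 27 C they run ~2.7x slower than at the reference
_NA_TADJ = _q10(3.0, 36.0)
_NA_VTRAUB = -63.0  # threshold-setting translation of the rate functions


def _naf_m_rates(v):
    v2 = np.asarray(v, dtype=float) - _NA_VTRAUB
    a = 1.28 * _efun((13.0 - v2) / 4.0)
    b = 1.4 * _efun((v2 - 40.0) / 5.0)
    return a * _NA_TADJ, b * _NA_TADJ


def _naf_m_inf(v):
    a, b = _naf_m_rates(v)
    return a / (a + b)


def _naf_m_tau(v):
    a, b = _naf_m_rates(v)
    return 1.0 / (a + b)


def _naf_h_rates(v):
    v2 = np.asarray(v, dtype=float) - _NA_VTRAUB
    a = 0.128 * np.exp((17.0 - v2) / 18.0)
    b = 4.0 / (1.0 + np.exp((40.0 - v2) / 5.0))
    return a * _NA_TADJ, b * _NA_TADJ


def _naf_h_inf(v):
    a, b = _naf_h_rates(v)
    return a / (a + b)


def _naf_h_tau(v):
    a, b = _naf_h_rates(v)
    return 1.0 / (a + b)


_KDR_QT = _q10(3.0, 23.0)


def _kdr_inf(v):
    # Kv3-family high-threshold rectifier, n^2 gating: effectively closed
    # below -40 mV, strongly activated at spike peaks
    return _sig(v, -15.0, 7.0)


def _kdr_tau(v):
    v = np.asarray(v, dtype=float)
    return (0.8 + 6.0 / (1.0 + np.exp((v + 15.0) / 12.0))) / _KDR_QT


_KA_QT = _q10(2.3, 21.0)


def _ka_m_inf(v):
    return _sig(v, -10.0, 19.0)


def _ka_m_tau(v):
    v = np.asarray(v, dtype=float)
    return (0.34 + 0.92 * np.exp(-(((v + 81.0) / 59.0) ** 2))) / _KA_QT


def _ka_h_inf(v):
    return _sig(v, -76.0, -10.0)


def _ka_h_tau(v):
    v = np.asarray(v, dtype=float)
    return (8.0 + 49.0 * np.exp(-(((v + 83.0) / 23.0) ** 2))) / _KA_QT


def _ih_inf(v):
    # falling curve: the channel opens on hyperpolarization
    return _sig(v, -86.4, -11.2)


def _ih_tau(v):
    # double-exponential rate form with a 100 ms floor: HCN activation does
    # not become arbitrarily fast at deep hyperpolarization
    v = np.asarray(v, dtype=float)
    tau = 1.0 / (np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v))
    return np.maximum(tau, 100.0)


_CAT_QT = _q10(2.5, 24.0)
_CAT_SHIFT = 2.0  # depolarizing screening-charge shift for 2 mM [Ca]_out


def _cat_m_inf(v):
    return _sig(v, -57.0 + _CAT_SHIFT, 6.2)  # half -55 mV


def _cat_m_tau(v):
    v = np.asarray(v, dtype=float) - _CAT_SHIFT
    return (
        0.612 + 1.0 / (np.exp(-(v + 131.6) / 16.7) + np.exp((v + 16.8) / 18.2))
    ) / _CAT_QT


def _cat_h_inf(v):
    return _sig(v, -81.0 + _CAT_SHIFT, -4.0)  # half -79 mV


def _cat_h_tau(v):
    v = np.asarray(v, dtype=float) - _CAT_SHIFT
    slow = np.exp((v + 467.0) / 66.6)
    fast = 28.0 + np.exp(-(v + 21.9) / 10.5)
    return np.where(v < -81.0, slow, fast) / _CAT_QT


_CAL_QT = 1.0  # high-voltage-activated L-type; source rates used as-is


def _cal_rates(v):
    # Reuveni-type HVA calcium activation: steep, half near -20 mV, with
    # no subthreshold tail (the L-current is spike-driven only)
    v = np.asarray(v, dtype=float)
    a = 0.209 * _efun((-27.0 - v) / 3.8)
    b = 0.94 * np.exp((-75.0 - v) / 17.0)
    return a, b


def _cal_m_inf(v):
    a, b = _cal_rates(v)
    return a / (a + b)


def _cal_m_tau(v):
    a, b = _cal_rates(v)
    return 1.0 / (a + b) / _CAL_QT


#: calcium-dependent inactivation of the L-type channel: its open fraction
#: is multiplied by EC50/(EC50 + [Ca]) of its coupled microdomain (1 uM
#: half-inactivation), the calmodulin-mediated brake on sustained L-current
CAL_CDI_EC50_MM = 0.001
#: fixed reversal of the ohmic L-type current
E_CA_L = 120.0


def cal_cdi_factor(ca_mm):
    ca = np.asarray(ca_mm, dtype=float)
    return CAL_CDI_EC50_MM / (CAL_CDI_EC50_MM + ca)

# calcium-activated channels: Hill activation of the coupled microdomain
SK_EC50_MM = 3e-4  # 0.3 uM
SK_HILL = 4
ANO2_EC50_MM = 1e-3  # 1 uM
ANO2_HILL = 2


def sk_activation(ca_mm):
    ca = np.asarray(ca_mm, dtype=float)
    return ca**SK_HILL / (ca**SK_HILL + SK_EC50_MM**SK_HILL)


def ano2_activation(ca_mm):
    ca = np.asarray(ca_mm, dtype=float)
    return ca**ANO2_HILL / (ca**ANO2_HILL + ANO2_EC50_MM**ANO2_HILL)


# ---------------------------------------------------------------------------
# channel constructors and the shift operations
# ---------------------------------------------------------------------------

def _naf_spec() -> ChannelSpec:
    return ChannelSpec(
        name="NaF",
        gates=(
            GateSpec("m", _naf_m_inf, _naf_m_tau, exponent=3),
            GateSpec("h", _naf_h_inf, _naf_h_tau, exponent=1),
        ),
        reversal=E_NA,
    )


NAP_SHIFT_MV = 14.0  # hyperpolarizing by convention: NaP activates below NaF


def derive_nap_from_naf(naf: ChannelSpec, shift: float = NAP_SHIFT_MV) -> ChannelSpec:
    """Derive the persistent sodium channel from NaF.

    Both activation and inactivation curves are translated so their
    half-voltages move by ``-shift`` mV (a positive ``shift`` is a
    hyperpolarizing translation: NaP is active at more negative voltages
    than NaF, giving a persistent current near rest).
    """
    gates = tuple(g.translated(-shift) for g in naf.gates)
    return replace(naf, name="NaP", gates=gates)


def shift_ih_inactivation(ih: ChannelSpec, dv: float = -11.0) -> ChannelSpec:
    """Translate the IH gating curve by ``dv`` mV (default -11).

    The IH gate has a falling steady-state curve (HCN channels open on
    hyperpolarization), which is the 'inactivation-shaped' curve the shift
    applies to; its half-voltage moves by exactly ``dv``.  The shift moves
    the IH operating range to more hyperpolarized potentials, which makes
    the sag amplitude grow monotonically over -50 to -200 pA steps.
    """
    gates = tuple(g.translated(dv) for g in ih.gates)
    return replace(ih, name=ih.name, gates=gates)


IH_SHIFT_MV = -11.0


def default_channels(
    ih_shift: float = IH_SHIFT_MV, nap_shift: float = NAP_SHIFT_MV
) -> dict[str, ChannelSpec]:
    """The ten-channel catalogue at 27 C with the model's modifications."""
    naf = _naf_spec()
    ih = ChannelSpec(
        name="IH", gates=(GateSpec("m", _ih_inf, _ih_tau, exponent=1),), reversal=E_H
    )
    chans = {
        "NaF": naf,
        "NaP": derive_nap_from_naf(naf, shift=nap_shift),
        "KDR": ChannelSpec(
            "KDR", (GateSpec("n", _kdr_inf, _kdr_tau, exponent=2),), reversal=E_K
        ),
        "KA": ChannelSpec(
            "KA",
            (
                GateSpec("m", _ka_m_inf, _ka_m_tau, exponent=4),
                GateSpec("h", _ka_h_inf, _ka_h_tau, exponent=1),
            ),
            reversal=E_K,
        ),
        "KM": ChannelSpec(
            "KM",
            (GateSpec("m", km_steady_state, km_time_constant, exponent=1),),
            reversal=E_K,
        ),
        "CaL": ChannelSpec(
            "CaL",
            (GateSpec("m", _cal_m_inf, _cal_m_tau, exponent=2),),
            reversal=E_CA_L,
            calcium_dependence=("ca_ano2", cal_cdi_factor),
        ),
        "SK": ChannelSpec(
            "SK", (), reversal=E_K, calcium_dependence=("ca_sk", sk_activation)
        ),
        "ANO2": ChannelSpec(
            "ANO2",
            (),
            reversal=E_ANO2,
            calcium_dependence=("ca_ano2", ano2_activation),
        ),
        "CaT": ChannelSpec(
            "CaT",
            (
                GateSpec("m", _cat_m_inf, _cat_m_tau, exponent=2),
                GateSpec("h", _cat_h_inf, _cat_h_tau, exponent=1),
            ),
            reversal=None,
        ),
        "IH": shift_ih_inactivation(ih, dv=ih_shift),
    }
    return chans


# ---------------------------------------------------------------------------
# channel density table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionTable:
    """Maximal conductance densities (S/cm^2) per channel and region.

    For the GHK calcium channels (CaT, CaL) the numbers are permeabilities
    in cm/s.  Defaults are the model's printed subcellular distribution.
    """

    density: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for ch, row in self.density.items():
            for region, g in row.items():
                if g < 0:
                    raise ValueError(f"negative density for {ch} at {region}")

    def get(self, channel: str, region: str) -> float:
        return self.density.get(channel, {}).get(region, 0.0)

    def scaled(self, factors: dict[str, float]) -> "DistributionTable":
        new = {
            ch: {r: g * factors.get(ch, 1.0) for r, g in row.items()}
            for ch, row in self.density.items()
        }
        return DistributionTable(new)

    def to_dict(self) -> dict:
        return {ch: dict(row) for ch, row in self.density.items()}


_REGION_COLS = ("ais", "soma", "dend_class_1", "dend_class_2", "dend_class_3")

# printed subcellular distribution: columns AIS, soma, distal dendrites
# (class 1), proximal first-order (class 2), proximal second-order-or-above
# (class 3); CaT/CaL entries are GHK permeabilities (cm/s)
_DEFAULT_DENSITY_ROWS = {
    "NaF": (0.008, 0.152, 0.008, 0.008, 0.004),
    "NaP": (0.0019, 0.0001, 0.0001, 0.0001, 0.0001),
    "KDR": (0.08, 1.52, 0.08, 0.08, 0.08),
    "KA": (0.005, 0.095, 0.005, 0.005, 0.005),
    "KM": (0.0165, 0.00033, 0.00033, 0.00033, 0.00033),
    "CaL": (0.0041, 0.0041, 0.0041, 0.00205, 0.00205),
    "SK": (0.0008, 0.0008, 0.0008, 0.0004, 0.0004),
    "ANO2": (0.00275, 0.00275, 0.00275, 0.001375, 0.001375),
    "CaT": (0.0, 0.0, 0.000085, 0.00017, 0.0000425),
    "IH": (0.0, 0.0, 0.000035, 0.000035, 0.000035),
}


def default_distribution_table() -> DistributionTable:
    return DistributionTable(
        {
            ch: dict(zip(_REGION_COLS, row))
            for ch, row in _DEFAULT_DENSITY_ROWS.items()
        }
    )


# ---------------------------------------------------------------------------
# calcium microdomains
# ---------------------------------------------------------------------------

#: submembrane shell depth (um) and free (unbuffered) calcium fraction of
#: the rapid-buffer approximation; together they convert an inward calcium
#: current density into a free-concentration rate, mM/ms per mA/cm^2
CA_SHELL_DEPTH_UM = 0.1
CA_FREE_FRACTION = 0.01
CA_INFLUX_K = CA_FREE_FRACTION * 1e4 / (2.0 * FARADAY * CA_SHELL_DEPTH_UM)


@dataclass
class CalciumPools:
    """Three first-order calcium microdomains.

    d[Ca]/dt = -f * i_Ca * k - ([Ca] - rest)/tau per pool, with the CaL
    flux split 25.8% / 74.2% between the SK- and ANO2-coupled pools and the
    CaT flux feeding an uncoupled bookkeeping pool.
    """

    fractions: tuple[float, float, float] = (0.258, 0.742, 1.0)
    taus_ms: tuple[float, float, float] = (14.0, 50.0, 50.0)
    sources: tuple[str, str, str] = ("CaL", "CaL", "CaT")
    coupled: tuple[str | None, str | None, str | None] = ("SK", "ANO2", None)
    rest_mm: float = CA_REST_MM
    concentrations: np.ndarray | None = None  # (3, n_comp) mM

    def init(self, n_comp: int) -> "CalciumPools":
        self.concentrations = np.full((3, n_comp), self.rest_mm)
        return self


def default_calcium_pools(n_comp: int = 1) -> CalciumPools:
    """The three-microdomain configuration, initialized at rest."""
    return CalciumPools().init(n_comp)


def update_calcium(
    pools: CalciumPools, i_cal, i_cat, dt: float
) -> CalciumPools:
    """Advance the microdomain concentrations by one step (exponential Euler).

    ``i_cal``/``i_cat`` are calcium current densities in mA/cm^2 (negative =
    inward), held constant over the step.  With zero influx each pool
    relaxes exponentially to rest with its own tau.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if pools.concentrations is None:
        raise ValueError("pools not initialized")
    i_cal = np.asarray(i_cal, dtype=float)
    i_cat = np.asarray(i_cat, dtype=float)
    for p in range(3):
        f, tau = pools.fractions[p], pools.taus_ms[p]
        src = i_cal if pools.sources[p] == "CaL" else i_cat
        influx = np.maximum(-f * src * CA_INFLUX_K, 0.0)  # mM/ms, influx only
        target = pools.rest_mm + influx * tau
        e = math.exp(-dt / tau)
        pools.concentrations[p] = target + (pools.concentrations[p] - target) * e
    return pools


# ---------------------------------------------------------------------------
# instantaneous currents
# ---------------------------------------------------------------------------

def ghk_coefficients(v, z: int = 2, t_c: float = TEMPERATURE_C):
    """Per-unit-permeability GHK flux coefficients.

    Returns (a, b) such that the current density is
    i = P * gates * (a(v) * c_in - b(v) * c_out)  [mA/cm^2]
    with P in cm/s and concentrations in mM.
    """
    v = np.asarray(v, dtype=float)
    T = t_c + 273.15
    xi = z * FARADAY * (v * 1e-3) / (GAS_R * T)
    # i[mA/cm^2] = P * zF*1e-3 * xi * (ci*e^xi - co)/(e^xi - 1), c in mM
    scale = z * FARADAY * 1e-3
    a = scale * _efun(-xi)
    b = scale * _efun(xi)
    return a, b


def channel_current(
    spec: ChannelSpec,
    gbar: float,
    v,
    gate_states=None,
    ca: float | None = None,
) -> np.ndarray:
    """Instantaneous current density (mA/cm^2) through one channel.

    Ohmic channels return gbar * prod(gate^p) * (v - E); GHK channels use
    the flux formulation with [Ca]_out = 2 mM; calcium-activated channels
    multiply by their Hill activation of ``ca`` (mM).  ``gate_states``
    defaults to the steady-state values at ``v``.
    """
    if gbar < 0:
        raise ValueError("negative gbar")
    v = np.asarray(v, dtype=float)
    open_frac = np.ones_like(v)
    if spec.gates:
        if gate_states is None:
            gate_states = [g.inf(v) for g in spec.gates]
        for g, x in zip(spec.gates, gate_states):
            open_frac = open_frac * np.asarray(x, dtype=float) ** g.exponent
    if spec.calcium_dependence is not None:
        if ca is None:
            ca = CA_REST_MM
        _, act = spec.calcium_dependence
        open_frac = open_frac * act(ca)
    if spec.is_ghk:
        cai = ca if ca is not None else CA_REST_MM
        a, b = ghk_coefficients(v)
        return gbar * open_frac * (a * cai - b * CA_OUT_MM)
    return gbar * open_frac * (v - spec.reversal)
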