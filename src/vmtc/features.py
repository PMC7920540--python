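"""Intrinsic-excitability feature extraction from current-clamp traces.

Implements the analysis conventions of the study: spike detection at the
dV/dt > 10 mV/ms threshold criterion, firing rates with a 50 ms onset
exclusion, Boltzmann F-I fits and rheobase read off at a criterion rate
(3 Hz by default, 10 Hz as an alternative), sag percentage
100*(1 - V_ss/V_peak) under 2 s hyperpolarizing steps with a 15% sag
classification threshold, rebound-burst quantification binned by the
hyperpolarization reached at the end of the step, passive-property
estimates (Rin at 100 ms under -10 pA; tau by 33%-decay or
double-exponential fit; C = tau/Rin) and the Henderson liquid-junction
potential of the recording solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .simulator import Stimulus, Trace

__all__ = [
    "SpikeTrain",
    "FICurve",
    "SagMeasure",
    "PassiveEstimates",
    "detect_spikes",
    "firing_rate",
    "fit_fi_boltzmann",
    "rheobase",
    "sag_percent",
    "classify_sag",
    "rebound_metrics",
    "estimate_tau",
    "input_resistance",
    "capacitance",
    "junction_potential",
    "PIPETTE_SOLUTION",
    "ACSF_SOLUTION",
    "IONIC_MOBILITIES",
    "JUNCTION_POTENTIAL_MV",
]

DVDT_THRESHOLD = 10.0  # mV/ms
ONSET_EXCLUSION_MS = 50.0
SAG_CLASSIFY_CUTOFF = 15.0  # %
REBOUND_WINDOW_MS = 500.0
REBOUND_BINS = ((0.0, 20.0), (20.0, 40.0), (40.0, 60.0))  # mV hyperpolarization


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # ms, strictly increasing
    threshold_voltages: np.ndarray  # mV, one per spike
    dvdt_threshold: float = DVDT_THRESHOLD

    @property
    def n(self) -> int:
        return self.spike_times.size


@dataclass
class FICurve:
    currents: np.ndarray  # pA
    rates: np.ndarray  # Hz
    fmax: float | None = None
    i_half: float | None = None
    slope: float | None = None
    converged: bool = False
    residual: float = math.nan

    @property
    def points(self):
        return list(zip(self.currents, self.rates))


@dataclass
class SagMeasure:
    baseline: float  # mV
    v_peak_deflection: float  # mV (positive magnitude)
    v_ss_deflection: float  # mV (positive magnitude)
    sag_percent: float  # %


@dataclass
class PassiveEstimates:
    rin: float  # MOhm
    tau: float  # ms
    tau_method: str
    capacitance: float  # pF
    vrest: float  # mV


def _uniform(trace: Trace) -> float:
    d = np.diff(trace.times)
    if d.size == 0 or np.max(np.abs(d - d[0])) > 1e-6 * d[0]:
        raise ValueError("non-uniform trace; resampling required")
    return float(d[0])


def detect_spikes(trace: Trace, dvdt_threshold: float = DVDT_THRESHOLD) -> SpikeTrain:
    """Detect action potentials as upward dV/dt threshold crossings.

    A crossing counts as a spike when the voltage reaches a peak above
    -10 mV within 5 ms; the threshold voltage is the voltage at the
    crossing sample.  Crossings within a 2 ms merge window of the previous
    accepted spike are ignored.
    """
    dt = _uniform(trace)
    if dt > 0.05 + 1e-9:
        raise ValueError("sampling interval must be <= 0.05 ms for spike detection")
    v = trace.voltage
    dvdt = np.diff(v) / dt
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    win = max(1, int(round(5.0 / dt)))
    merge = 2.0
    times, thresholds = [], []
    last = -np.inf
    for idx in crossings:
        t = trace.times[idx]
        if t - last < merge:
            continue
        seg = v[idx : idx + win + 1]
        if seg.size and np.max(seg) > -10.0:
            times.append(t)
            thresholds.append(v[idx])
            last = t
    return SpikeTrain(
        spike_times=np.asarray(times),
        threshold_voltages=np.asarray(thresholds),
        dvdt_threshold=dvdt_threshold,
    )


def firing_rate(
    spikes: SpikeTrain,
    step_onset: float,
    step_duration: float,
    onset_exclusion: float = ONSET_EXCLUSION_MS,
) -> float:
    """Spikes per second inside [onset + exclusion, onset + duration]."""
    if step_duration <= onset_exclusion:
        raise ValueError("step shorter than the onset exclusion window")
    t0 = step_onset + onset_exclusion
    t1 = step_onset + step_duration
    n = int(np.count_nonzero((spikes.spike_times >= t0) & (spikes.spike_times <= t1)))
    return n / ((step_duration - onset_exclusion) * 1e-3)


def _boltzmann(i, fmax, i_half, k):
    return fmax / (1.0 + np.exp((i_half - i) / k))


def fit_fi_boltzmann(fi: FICurve) -> FICurve:
    """Least-squares Boltzmann sigmoid fit rate(I) = Fmax/(1+exp((I50-I)/k))."""
    I = np.asarray(fi.currents, dtype=float)
    r = np.asarray(fi.rates, dtype=float)
    if I.size < 4:
        raise ValueError("need at least 4 F-I points to fit")
    out = FICurve(currents=I, rates=r)
    if np.all(r == 0):
        return out  # fit not possible; rheobase undefined
    fmax0 = max(r.max() * 1.05, 1.0)
    above = I[r >= fmax0 / 2.0]
    ihalf0 = float(above[0]) if above.size else float(I.mean())
    k0 = max((I.max() - I.min()) / 10.0, 1.0)
    try:
        p, _ = curve_fit(
            _boltzmann,
            I,
            r,
            p0=(fmax0, ihalf0, k0),
            bounds=([1e-3, I.min() - 10 * k0, 1e-3], [10 * fmax0, I.max() + 10 * k0, 1e4]),
            maxfev=20000,
        )
        out.fmax, out.i_half, out.slope = (float(x) for x in p)
        out.residual = float(np.sqrt(np.mean((r - _boltzmann(I, *p)) ** 2)))
        out.converged = True
    except (RuntimeError, ValueError):
        out.converged = False
    return out


def rheobase(
    fit: FICurve, target_rate: float = 3.0, method: str = "boltzmann"
) -> float:
    """Current (pA) at which the F-I relation reaches ``target_rate`` Hz.

    ``boltzmann``: inverts the fitted sigmoid, I = I50 - k ln(Fmax/f - 1).
    ``interp``: linear interpolation on the raw points (the alternative
    reading of the analysis description).  Returns NaN when undefined
    (no fit, or target at/above Fmax, or never reached).
    """
    if method == "boltzmann":
        if not fit.converged or fit.fmax is None:
            return math.nan
        if target_rate >= fit.fmax:
            return math.nan
        return float(fit.i_half - fit.slope * math.log(fit.fmax / target_rate - 1.0))
    if method == "interp":
        I = np.asarray(fit.currents, dtype=float)
        r = np.asarray(fit.rates, dtype=float)
        order = np.argsort(I)
        I, r = I[order], r[order]
        idx = np.flatnonzero(r >= target_rate)
        if idx.size == 0:
            return math.nan
        j = idx[0]
        if j == 0 or r[j] == r[j - 1]:
            return float(I[j])
        w = (target_rate - r[j - 1]) / (r[j] - r[j - 1])
        return float(I[j - 1] + w * (I[j] - I[j - 1]))
    raise ValueError(f"unknown rheobase method {method!r}")


def _step_window(trace: Trace):
    s = trace.stimulus
    return s.step_onset, s.step_onset + s.step_duration


def _last_index_in_step(trace: Trace, offset: float) -> int:
    """Index of the last sample strictly inside the step (t < offset)."""
    idx = int(np.searchsorted(trace.times, offset - 1e-9)) - 1
    if idx < 0:
        raise ValueError("no samples inside the step")
    return idx


def _baseline(trace: Trace, onset: float, window: float = 100.0) -> float:
    mask = (trace.times >= max(0.0, onset - window)) & (trace.times < onset)
    if not np.any(mask):
        raise ValueError("no pre-step baseline available")
    return float(np.mean(trace.voltage[mask]))


def sag_percent(trace: Trace) -> SagMeasure:
    """Sag of a 2 s hyperpolarizing step: 100*(1 - Vss/Vpeak).

    Deflections are measured from the 100 ms pre-onset baseline; V_peak is
    the peak negative deflection during the step, V_ss the deflection at
    2000 ms after onset (the step end).
    """
    s = trace.stimulus
    if s.step_current >= 0:
        raise ValueError("sag requires a hyperpolarizing step")
    onset, offset = _step_window(trace)
    base = _baseline(trace, onset)
    in_step = (trace.times >= onset) & (trace.times < offset)
    v_step = trace.voltage[in_step]
    peak = base - float(np.min(v_step))
    ss = base - float(trace.voltage[_last_index_in_step(trace, offset)])
    sag = 0.0 if peak == 0 else 100.0 * (1.0 - ss / peak)
    return SagMeasure(
        baseline=base, v_peak_deflection=peak, v_ss_deflection=ss, sag_percent=sag
    )


def classify_sag(sag: SagMeasure, cutoff: float = SAG_CLASSIFY_CUTOFF) -> str:
    """'sag_expressing' when sag% strictly exceeds the cutoff, else 'no_sag'."""
    return "sag_expressing" if sag.sag_percent > cutoff else "no_sag"


def rebound_metrics(trace: Trace, window_ms: float = REBOUND_WINDOW_MS) -> dict:
    """Quantify the rebound burst after a hyperpolarizing step.

    Returns the end-of-step hyperpolarization (baseline minus voltage at
    step end, mV), the spike count in the post-step window, and the
    hyperpolarization bin among [0,20), [20,40), [40,60) mV.
    """
    s = trace.stimulus
    onset, offset = _step_window(trace)
    base = _baseline(trace, onset)
    hyper = base - float(trace.voltage[_last_index_in_step(trace, offset)])
    spikes = detect_spikes(trace)
    n = int(
        np.count_nonzero(
            (spikes.spike_times > offset) & (spikes.spike_times <= offset + window_ms)
        )
    )
    bin_label = None
    for lo, hi in REBOUND_BINS:
        if lo <= hyper < hi:
            bin_label = f"{lo:.0f}-{hi:.0f}"
            break
    return {
        "end_of_step_hyperpolarization": hyper,
        "rebound_spike_count": n,
        "bin": bin_label,
    }


def estimate_tau(trace: Trace, method: str = "double_exp") -> float:
    """Membrane time constant from a -1 nA, 0.5 ms pulse response.

    ``decay33``: elapsed time for the response to decay back to 33% of its
    peak amplitude (the raw experimental readout; for a single exponential
    this is tau*ln(1/0.33) ~ 1.11*tau).  ``double_exp``: slowest time
    constant of a two-exponential least-squares fit to the decay phase.
    """
    s = trace.stimulus
    onset, offset = _step_window(trace)
    base = _baseline(trace, onset, window=min(50.0, onset) or 10.0)
    after = trace.times >= offset
    t = trace.times[after]
    v = trace.voltage[after]
    if v.size < 10:
        raise ValueError("trace too short after the pulse")
    ipk = int(np.argmax(base - v))  # peak (most hyperpolarized) after pulse
    peak_amp = base - v[ipk]
    if peak_amp <= 1e-9:
        raise ValueError("estimation failure: no deflection after the pulse")
    t0 = t[ipk]
    td = t[ipk:] - t0
    amp = base - v[ipk:]
    if method == "decay33":
        below = np.flatnonzero(amp <= 0.33 * peak_amp)
        if below.size == 0:
            raise ValueError("estimation failure: no decay to 33% within the trace")
        return float(td[below[0]])
    if method == "double_exp":
        mask = td <= 150.0
        td, amp = td[mask], amp[mask]

        def model(t, a, tau1, c, tau2):
            return a * np.exp(-t / tau1) + c * np.exp(-t / tau2)

        p0 = (peak_amp * 0.5, 2.0, peak_amp * 0.5, 20.0)
        p, _ = curve_fit(
            model, td, amp, p0=p0,
            bounds=([0.0, 0.05, 0.0, 0.05], [np.inf, 500.0, np.inf, 500.0]),
            maxfev=20000,
        )
        return float(max(p[1], p[3]))
    raise ValueError(f"unknown tau method {method!r}")


def input_resistance(trace: Trace) -> float:
    """Rin (MOhm) from a -10 pA, 100 ms pulse: deflection at 100 ms / I."""
    s = trace.stimulus
    if s.step_current == 0:
        raise ValueError("zero-amplitude pulse")
    onset, offset = _step_window(trace)
    base = _baseline(trace, onset)
    deflection = trace.voltage[_last_index_in_step(trace, offset)] - base  # mV
    return float(deflection / s.step_current * 1e3)  # mV/pA -> MOhm


def capacitance(tau: float, rin: float) -> float:
    """C = tau / Rin (ms / MOhm -> nF -> pF)."""
    if rin <= 0:
        raise ValueError("Rin must be positive")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    return tau / rin * 1e3  # ms/MOhm = nF; *1e3 -> pF


# ---------------------------------------------------------------------------
# liquid junction potential (Henderson equation)
# ---------------------------------------------------------------------------

#: limiting equivalent conductances at 25 C (S cm^2/equiv), the bundled
#: mobility table; organic anion values follow the JPcalc conventions
#: (gluconate and large organic anions ~1/3 of K+)
IONIC_MOBILITIES = {
    "K": (1, 73.5),
    "Na": (1, 50.11),
    "Li": (1, 38.7),
    "Cs": (1, 77.3),
    "H": (1, 349.8),
    "Ca": (2, 59.5),
    "Mg": (2, 53.06),
    "Cl": (-1, 76.35),
    "Br": (-1, 78.1),
    "HCO3": (-1, 44.5),
    "H2PO4": (-1, 33.0),
    "OH": (-1, 198.0),
    "acetate": (-1, 40.9),
    "gluconate": (-1, 24.3),
    "HEPES": (-1, 22.05),
    "phosphocreatine": (-2, 25.0),
    "GTP": (-2, 22.0),
    "EGTA": (-2, 22.0),
    "spermine": (4, 25.0),
}

#: ionized composition (mM) of the printed K-gluconate pipette solution:
#: 130 K-gluconate, 10 NaCl, 10 KCl, 10 HEPES, 1 MgCl2, 0.5 Na-GTP (di-Na),
#: 1 Mg-ATP (neutral complex), 5 phosphocreatine (di-Na salt), 0.1 spermine,
#: 0.2 EGTA, titrated to pH 7.2 with KOH (~5 mM K+; HEPES ~31% anionic at
#: pH 7.2, pKa 7.55)
PIPETTE_SOLUTION = {
    "K": 145.0,
    "Na": 21.0,
    "Cl": 22.4,
    "gluconate": 130.0,
    "HEPES": 3.1,
    "Mg": 2.0,
    "GTP": 0.5,
    "phosphocreatine": 5.0,
    "spermine": 0.1,
    "EGTA": 0.2,
}

#: ionized composition (mM) of the printed recording ACSF: 124 NaCl,
#: 2.5 KCl, 1.25 NaH2PO4, 26 NaHCO3, 10 glucose (neutral), 2 CaCl2,
#: 1.3 MgCl2
ACSF_SOLUTION = {
    "Na": 151.25,
    "K": 2.5,
    "Cl": 133.1,
    "HCO3": 26.0,
    "H2PO4": 1.25,
    "Ca": 2.0,
    "Mg": 1.3,
}

#: the junction potential of the recording configuration (mV); computed by
#: junction_potential(); it is NOT subtracted from reported voltages,
#: matching the experimental convention
JUNCTION_POTENTIAL_MV = 14.2


def junction_potential(
    internal: dict[str, float] | None = None,
    external: dict[str, float] | None = None,
    temperature: float = 27.0,
    mobilities: dict[str, tuple[int, float]] | None = None,
) -> float:
    """Stationary Henderson liquid-junction potential (mV), bath minus pipette.

    ``internal``/``external`` map ion species to concentrations (mM);
    charges and limiting equivalent conductances come from the bundled
    mobility table.  A positive value means the bath is positive relative
    to the pipette interior, the sign convention under which the
    K-gluconate internal against ACSF gives +14.2 mV.
    """
    internal = PIPETTE_SOLUTION if internal is None else internal
    external = ACSF_SOLUTION if external is None else external
    mob = IONIC_MOBILITIES if mobilities is None else mobilities
    species = sorted(set(internal) | set(external))
    missing = [s for s in species if s not in mob]
    if missing:
        raise KeyError(f"no mobility for species: {', '.join(missing)}")
    RT_F = 8.31446 * (temperature + 273.15) / 96485.332 * 1e3  # mV

    num = den = sp = sb = 0.0
    for s in species:
        z, lam_eq = mob[s]
        u = lam_eq  # mobility per unit charge is proportional to lambda_eq
        cp = internal.get(s, 0.0)
        cb = external.get(s, 0.0)
        dc = cb - cp
        num += (u * z / abs(z)) * dc if z != 0 else 0.0
        den += u * abs(z) * dc
        sp += u * abs(z) * cp
        sb += u * abs(z) * cb
    if sp <= 0 or sb <= 0 or den == 0:
        return 0.0
    return float(RT_F * (num / den) * math.log(sp / sb))
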