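"""In-silico experimental protocols and electrophysiological features.

Mirrors the standard current-clamp workflow: a family of depolarizing and
hyperpolarizing somatic current steps, selection of standardized steps
(rheobase, standard negative, steady state, maximal activity), extraction
of named features from each response, postsynaptic-potential attenuation
scans in the silent and high-conductance states, firing-rate curves driven
by random synaptic bombardment, sinusoidally rate-modulated (theta) drive
with circular statistics, and validation of model features against
reference means and standard deviations (the 2-SD criterion).

Spike detection: upward crossing of a threshold voltage (default -20 mV)
with a minimum slope guard and a 1 ms refractory period.  Spike-dependent
features are ``None`` (undefined), never zero, when no spikes occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cable import CompartmentalModel, SynapseKinetics, Trace, TonicMap
from .synapse_map import PredictedCounts, place_synapses

__all__ = [
    "StepProtocol", "ResponseSet", "StandardizedSteps", "FeatureVector",
    "ThetaModulationResult", "RateCurve", "detect_spikes",
    "run_step_protocol", "select_standard_steps", "extract_features",
    "psp_attenuation_scan", "synapse_drive_curve", "theta_modulation",
    "validate_against_features", "rayleigh_test", "mean_vector_length",
    "PAPER_STEP_AMPLITUDES_PA",
]

#: the in vitro step family: 23 short steps and 4 long large steps (pA)
PAPER_STEP_AMPLITUDES_PA = (
    20, -20, 40, -40, 60, -60, 80, -80, 100, -100, 120, -120, 140, -140,
    160, -160, 180, -180, 200, 220, 240, 260, 280, 300, 400, 500, 600)


@dataclass(frozen=True)
class StepProtocol:
    """A family of somatic current steps."""

    amplitudes_pA: tuple = PAPER_STEP_AMPLITUDES_PA
    duration_ms: float = 800.0
    delay_ms: float = 200.0        # pre-stimulus baseline
    tail_ms: float = 200.0         # post-stimulus window
    holding_mV: float = -65.0

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError("step duration must be positive")

    @property
    def total_ms(self) -> float:
        return self.delay_ms + self.duration_ms + self.tail_ms


@dataclass
class ResponseSet:
    """One trace per step amplitude."""

    protocol: StepProtocol
    traces: list[Trace]

    def __len__(self):
        return len(self.traces)

    def amplitude(self, i: int) -> float:
        return self.protocol.amplitudes_pA[i]


def run_step_protocol(model: CompartmentalModel, protocol: StepProtocol,
                      dt: float = 0.025, probe: int = 0) -> ResponseSet:
    """Simulate every step of the protocol from the holding potential."""
    traces = []
    for amp in protocol.amplitudes_pA:
        model.clear_stimuli()
        model.inject_step(probe, amp * 1e-3,  # pA -> nA
                          protocol.delay_ms,
                          protocol.delay_ms + protocol.duration_ms)
        traces.append(model.simulate(protocol.total_ms, dt=dt,
                                     probes=(probe,),
                                     v_init=protocol.holding_mV))
    model.clear_stimuli()
    return ResponseSet(protocol=protocol, traces=traces)


# -- spike detection and standardized steps ----------------------------------

def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = -20.0,
                  min_slope_mv_per_ms: float = 5.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Spike times (ms): upward threshold crossings with a dV/dt guard."""
    v = np.asarray(v); t = np.asarray(t)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    cross = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold))
    times = []
    last = -np.inf
    for i in cross:
        slope = (v[i + 1] - v[i]) / dt
        if slope < min_slope_mv_per_ms:
            continue
        if t[i + 1] - last < refractory_ms:
            continue
        times.append(t[i + 1])
        last = t[i + 1]
    return np.asarray(times)


@dataclass
class StandardizedSteps:
    """Indices of the four standardized current steps within a ResponseSet.

    ``None`` marks a step that does not exist for this cell (e.g. no step
    elicited spikes).
    """

    rheobase: int | None
    standard_negative: int | None
    steady_state: int | None
    maxspike: int | None


def select_standard_steps(rs: ResponseSet, min_steady_spikes: int = 8,
                          standard_negative_pA: float = -100.0,
                          **spike_kwargs) -> StandardizedSteps:
    """Select the standardized steps from spike counts.

    rheobase: smallest amplitude with >= 1 spike; steady state: smallest
    amplitude with >= ``min_steady_spikes`` spikes; maxspike: the most
    spikes (ties broken toward the smaller amplitude); standard negative:
    amplitude closest to -100 pA (ties toward smaller magnitude).
    """
    amps = np.array([rs.amplitude(i) for i in range(len(rs))], float)
    nsp = np.array([len(detect_spikes(tr.t, tr.probe(0), **spike_kwargs))
                    for tr in rs.traces])
    rheo = steady = maxs = None
    spiking = [(amps[i], i) for i in range(len(rs)) if nsp[i] >= 1]
    if spiking:
        rheo = min(spiking)[1]
    steadying = [(amps[i], i) for i in range(len(rs))
                 if nsp[i] >= min_steady_spikes]
    if steadying:
        steady = min(steadying)[1]
    if spiking:
        best = max(nsp)
        maxs = min((amps[i], i) for i in range(len(rs)) if nsp[i] == best)[1]
    neg = [(abs(amps[i] - standard_negative_pA), abs(amps[i]), i)
           for i in range(len(rs)) if amps[i] < 0]
    stdneg = min(neg)[2] if neg else None
    return StandardizedSteps(rheobase=rheo, standard_negative=stdneg,
                             steady_state=steady, maxspike=maxs)


# -- feature extraction ------------------------------------------------------

@dataclass
class FeatureVector:
    """Named electrophysiological features of one step response.

    Spike-dependent entries are None when undefined.  Units: times ms,
    voltages mV, frequencies Hz, resistance MOhm.
    """

    values: dict[str, float | None] = field(default_factory=dict)

    def __getitem__(self, k):
        return self.values[k]

    def __contains__(self, k):
        return k in self.values

    def defined(self) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if v is not None}


def _exp_tau_fit(t: np.ndarray, v: np.ndarray, v_inf: float) -> float | None:
    """Time constant from a log-linear fit of |v - v_inf| (ms)."""
    d = np.abs(v - v_inf)
    mask = d > 1e-6
    if mask.sum() < 4:
        return None
    tt, dd = t[mask], np.log(d[mask])
    slope = np.polyfit(tt, dd, 1)[0]
    if slope >= 0:
        return None
    return float(-1.0 / slope)


def extract_features(trace: Trace, stim_amp_pA: float, delay_ms: float,
                     duration_ms: float, threshold: float = -20.0,
                     **spike_kwargs) -> FeatureVector:
    """Compute the feature set from one voltage response to one step.

    Sag features come from hyperpolarizing steps: sag amplitude is the
    steady-state voltage minus the minimum voltage, the sag ratio divides
    that by the base-to-minimum deflection.  Input resistance is the
    steady-state deflection over the injected current.
    """
    t, v = trace.t, trace.probe(0)
    on, off = delay_ms, delay_ms + duration_ms
    pre = v[t < on]
    stim = (t >= on) & (t < off)
    vstim, tstim = v[stim], t[stim]
    f: dict[str, float | None] = {}
    vbase = float(np.mean(pre)) if pre.size else float(v[0])
    f["voltage_base"] = vbase
    # steady state: mean of the last tenth of the stimulus window
    tail = tstim >= off - 0.1 * duration_ms
    vss = float(np.mean(vstim[tail])) if tail.any() else float(vstim[-1])
    f["steady_state_voltage"] = vss
    f["maximum_voltage"] = float(vstim.max()) if vstim.size else None
    i_nA = stim_amp_pA * 1e-3
    f["input_resistance"] = abs((vss - vbase) / i_nA) if i_nA else None

    spikes = detect_spikes(tstim, vstim, threshold=threshold, **spike_kwargs)
    n = len(spikes)
    f["spike_count"] = float(n)
    if stim_amp_pA < 0:
        vmin = float(vstim.min())
        imin = int(np.argmin(vstim))
        f["minimum_voltage"] = vmin
        f["sag_amplitude"] = vss - vmin
        defl = vbase - vmin
        f["sag_ratio"] = (vss - vmin) / defl if defl > 1e-9 else None
        f["sag_time_constant"] = _exp_tau_fit(
            tstim[imin:] - tstim[imin], vstim[imin:], vss)
    spike_features = [
        "time_to_first_spike", "time_to_second_spike", "mean_frequency",
        "inv_isi_1", "inv_isi_2", "inv_isi_3", "inv_isi_4", "isi_cv",
        "adaptation_index", "isi_log_slope", "single_burst_ratio",
        "ap_peak_1", "ap_peak_2", "ap_amplitude_1", "ap_mean_height",
        "ap_half_width", "fast_ahp", "slow_ahp_depth"]
    for k in spike_features:
        f.setdefault(k, None)
    if n >= 1:
        f["time_to_first_spike"] = float(spikes[0] - on)
        f["mean_frequency"] = 1000.0 * n / duration_ms
        pk1 = _ap_peak(tstim, vstim, spikes[0])
        f["ap_peak_1"] = pk1
        f["ap_amplitude_1"] = pk1 - vbase if pk1 is not None else None
        f["ap_half_width"] = _ap_half_width(tstim, vstim, spikes[0],
                                            vbase, threshold)
        f["fast_ahp"] = _fast_ahp(tstim, vstim, spikes[0], threshold)
        peaks = [_ap_peak(tstim, vstim, s) for s in spikes]
        peaks = [p for p in peaks if p is not None]
        if peaks:
            f["ap_mean_height"] = float(np.mean(peaks))
    if n >= 2:
        f["time_to_second_spike"] = float(spikes[1] - on)
        f["ap_peak_2"] = _ap_peak(tstim, vstim, spikes[1])
        isi = np.diff(spikes)
        for j in range(min(4, len(isi))):
            f[f"inv_isi_{j+1}"] = 1000.0 / isi[j]
        if len(isi) >= 2:
            f["isi_cv"] = float(np.std(isi) / np.mean(isi))
            f["adaptation_index"] = float(np.mean(
                (isi[1:] - isi[:-1]) / (isi[1:] + isi[:-1])))
            f["isi_log_slope"] = float(np.polyfit(
                np.arange(len(isi)), np.log(isi), 1)[0])
        if len(isi) >= 3:
            rest = np.median(isi[1:])
            f["single_burst_ratio"] = float(isi[0] / rest) if rest else None
        # slow AHP depth: deepest post-spike hyperpolarization between the
        # last spike and stimulus end, relative to steady state
        after = tstim > spikes[-1] + 2.0
        if after.any():
            f["slow_ahp_depth"] = float(vss - vstim[after].min())
    return FeatureVector(values=f)


def _ap_peak(t, v, spike_time, window=3.0):
    m = (t >= spike_time - 0.5) & (t <= spike_time + window)
    return float(v[m].max()) if m.any() else None


def _ap_half_width(t, v, spike_time, vbase, threshold, window=5.0):
    m = (t >= spike_time - 2.0) & (t <= spike_time + window)
    if not m.any():
        return None
    tv, vv = t[m], v[m]
    pk = vv.max()
    half = threshold + 0.5 * (pk - threshold)
    above = vv >= half
    if not above.any():
        return None
    idx = np.flatnonzero(above)
    return float(tv[idx[-1]] - tv[idx[0]])


def _fast_ahp(t, v, spike_time, threshold, window=5.0):
    m = (t > spike_time) & (t <= spike_time + window)
    if not m.any():
        return None
    return float(threshold - v[m].min())


# -- PSP attenuation ---------------------------------------------------------

def psp_attenuation_scan(model: CompartmentalModel, kin: SynapseKinetics,
                         compartments=None, settle_ms: float = 300.0,
                         window_ms: float = 150.0, dt: float = 0.05,
                         probe: int = 0):
    """Somatic PSP amplitude for single synapses at different locations.

    One synapse at a time is activated after a settling period; the somatic
    peak deviation from the pre-event baseline is recorded.  The model's
    tonic map (if any) defines the state: silent (no map) or
    high-conductance.  Returns (path_distances, amplitudes_mV).
    """
    g = model.grid
    if compartments is None:
        compartments = [i for i in range(g.n) if g.section_index[i] >= 0]
    dists, amps = [], []
    for comp in compartments:
        model.clear_synapses()
        model.attach_synapse(comp, kin, event_times_ms=[settle_ms])
        tr = model.simulate(settle_ms + window_ms, dt=dt, probes=(probe,))
        v = tr.probe(0)
        base = v[np.searchsorted(tr.t, settle_ms) - 1]
        after = v[tr.t >= settle_ms]
        amps.append(float(np.max(np.abs(after - base))))
        dists.append(float(g.path_distance[comp]))
    model.clear_synapses()
    return np.asarray(dists), np.asarray(amps)


# -- synapse-count drive curves ----------------------------------------------

@dataclass
class RateCurve:
    """Firing rate versus number (and percentage) of active synapses."""

    counts: np.ndarray
    rates_hz: np.ndarray
    percentages: np.ndarray    # 100 * count / total predicted in range
    distance_range: tuple | None


def synapse_drive_curve(model: CompartmentalModel, pc: PredictedCounts,
                        counts=(20, 40, 60, 80, 100, 200, 300, 400, 500),
                        distance_range=None, rate_hz: float = 10.0,
                        T_ms: float = 2000.0, dt: float = 0.05,
                        kin: SynapseKinetics | None = None,
                        seed: int = 0, kind: str = "glut",
                        **spike_kwargs) -> RateCurve:
    """Firing rate as a function of the number of active synapses.

    Each synapse receives an independent Poisson spike train at
    ``rate_hz``; placements follow the predicted density restricted to
    ``distance_range``.  The percentage axis divides the count by the total
    predicted number of synapses of this kind in the range.
    """
    from .cable import default_exc_kinetics
    kin = kin or default_exc_kinetics()
    rng = np.random.default_rng(seed)
    w = pc.counts[kind].copy()
    w[pc.grid.section_index < 0] = 0.0
    if distance_range is not None:
        lo, hi = distance_range
        w[(pc.grid.path_distance < lo) | (pc.grid.path_distance > hi)] = 0.0
    total_in_range = w.sum()
    if total_in_range <= 0:
        raise ValueError("no predicted synapses in the requested range")
    rates = []
    for n in counts:
        placements = place_synapses(pc, n=n, kind=kind,
                                    distance_range=distance_range, seed=rng)
        model.clear_synapses()
        for p in placements:
            idx = model.attach_synapse(p.compartment, kin)
            nev = rng.poisson(rate_hz * T_ms / 1000.0)
            model.add_events(idx, np.sort(rng.uniform(0.0, T_ms, nev)))
        tr = model.simulate(T_ms, dt=dt)
        spikes = detect_spikes(tr.t, tr.probe(0), **spike_kwargs)
        rates.append(1000.0 * len(spikes) / T_ms)
    model.clear_synapses()
    counts = np.asarray(counts, float)
    return RateCurve(counts=counts, rates_hz=np.asarray(rates),
                     percentages=100.0 * counts / total_in_range,
                     distance_range=distance_range)


# -- theta modulation --------------------------------------------------------

def mean_vector_length(phases: np.ndarray) -> float:
    """R = |sum exp(i*theta)| / n; 0 for uniform, 1 for perfect locking."""
    phases = np.asarray(phases, float)
    if phases.size == 0:
        raise ValueError("no phases: mean vector length undefined")
    return float(np.abs(np.exp(1j * phases).mean()))


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (R, p) with the standard large-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)).
    """
    phases = np.asarray(phases, float)
    n = phases.size
    if n == 0:
        raise ValueError("no phases: Rayleigh test undefined")
    r = mean_vector_length(phases)
    z = n * r * r
    p = math.exp(math.sqrt(1.0 + 4 * n + 4 * (n * n - n * n * r * r))
                 - (1.0 + 2 * n))
    return r, min(p, 1.0)


@dataclass
class ThetaModulationResult:
    spike_phases: np.ndarray      # radians in [0, 2pi)
    bin_edges: np.ndarray
    binned_rates: np.ndarray      # Hz per phase bin
    R: float | None
    p: float | None
    n_spikes: int
    flagged: str | None = None    # set when R undefined (no spikes)


def sine_rate(t_ms: np.ndarray, f_hz: float, rate_min: float,
              rate_max: float) -> np.ndarray:
    """Sinusoidal rate with phase 0 at the rate minimum."""
    mid = 0.5 * (rate_min + rate_max)
    amp = 0.5 * (rate_max - rate_min)
    return mid - amp * np.cos(2 * np.pi * f_hz * t_ms / 1000.0)


def inhomogeneous_poisson(rng, T_ms: float, f_hz: float, rate_min: float,
                          rate_max: float) -> np.ndarray:
    """Event times of a sinusoidally rate-modulated Poisson process
    (thinning)."""
    lam_max = rate_max / 1000.0  # per ms
    n = rng.poisson(lam_max * T_ms)
    t = np.sort(rng.uniform(0.0, T_ms, n))
    keep = rng.uniform(0.0, 1.0, n) * rate_max < sine_rate(
        t, f_hz, rate_min, rate_max)
    return t[keep]


def theta_modulation(model: CompartmentalModel, pc: PredictedCounts,
                     fraction: float = 0.05, f_hz: float = 7.0,
                     rate_range=(1.0, 21.0), T_ms: float = 30000.0,
                     n_bins: int = 16, dt: float = 0.05,
                     kin: SynapseKinetics | None = None, seed: int = 0,
                     kind: str = "glut",
                     **spike_kwargs) -> ThetaModulationResult:
    """Drive a fraction of excitatory synapses with theta-modulated input
    and measure the phase locking of the output spikes.

    Each selected synapse fires as an independent inhomogeneous Poisson
    process whose rate swings sinusoidally over ``rate_range`` at the theta
    frequency.  Spike phases are referenced to the input-rate sinusoid with
    phase 0 at its minimum.  Returns the mean vector length R and the
    Rayleigh uniformity p; both are None (flagged) when the model fires no
    spikes — the standard remedy is to raise ``fraction``.
    """
    from .cable import default_exc_kinetics
    kin = kin or default_exc_kinetics()
    rng = np.random.default_rng(seed)
    placements = place_synapses(pc, fraction=fraction, kind=kind, seed=rng)
    model.clear_synapses()
    rmin, rmax = rate_range
    for p in placements:
        idx = model.attach_synapse(p.compartment, kin)
        ev = inhomogeneous_poisson(rng, T_ms, f_hz, rmin, rmax)
        if ev.size:
            model.add_events(idx, ev)
    tr = model.simulate(T_ms, dt=dt, record_stride=4)
    model.clear_synapses()
    spikes = detect_spikes(tr.t, tr.probe(0), **spike_kwargs)
    edges = np.linspace(0.0, 2 * np.pi, n_bins + 1)
    if spikes.size == 0:
        return ThetaModulationResult(
            spike_phases=np.array([]), bin_edges=edges,
            binned_rates=np.zeros(n_bins), R=None, p=None, n_spikes=0,
            flagged="no spikes: raise the activated fraction")
    phases = (2 * np.pi * f_hz * spikes / 1000.0) % (2 * np.pi)
    counts, _ = np.histogram(phases, bins=edges)
    cycle_per_bin = (T_ms / 1000.0) * f_hz / n_bins
    r, p = rayleigh_test(phases)
    return ThetaModulationResult(
        spike_phases=phases, bin_edges=edges,
        binned_rates=counts / cycle_per_bin, R=r, p=p,
        n_spikes=int(spikes.size))


# -- validation --------------------------------------------------------------

def validate_against_features(model_features: dict,
                              reference: dict[str, tuple[float, float]],
                              z_threshold: float = 2.0) -> dict:
    """Fraction of model features within ``z_threshold`` SD of reference.

    ``reference`` maps feature name -> (mean, sd).  Features with sd == 0
    are excluded and reported.  Returns per-feature z-scores, the pass
    list, and the summary fraction.
    """
    z: dict[str, float] = {}
    excluded, missing = [], []
    for name, (mean, sd) in reference.items():
        if name not in model_features or model_features[name] is None:
            missing.append(name)
            continue
        if sd == 0:
            excluded.append(name)
            continue
        z[name] = (model_features[name] - mean) / sd
    passed = {k: abs(v) <= z_threshold for k, v in z.items()}
    n = len(passed)
    return {
        "z": z,
        "passed": passed,
        "n_pass": sum(passed.values()),
        "n_total": n,
        "fraction_pass": (sum(passed.values()) / n) if n else float("nan"),
        "excluded_zero_sd": excluded,
        "missing": missing,
    }
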