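"""Multicompartmental electrical models of reconstructed neurons.

The model couples the compartment grid of a morphology with a spatially
uniform passive membrane (cm, g_pas, e_pas, fixed axial resistivity Ra), a
two-component hyperpolarization-activated current (Ih) with fast and slow
activation kinetics, optional tonic "high-conductance-state" fields that
represent time-averaged background synaptic bombardment as ohmic leaks with
their own reversal potentials, event-driven difference-of-exponentials
synapses, and a generic plug-in framework for voltage-gated channels.

Integration is first-order implicit (backward Euler) on the branched tree,
which is unconditionally stable; the default step is 0.025 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._solver import simulate_core
from .morphology import CompartmentGrid

__all__ = [
    "PassiveParams", "IhParams", "SynapseKinetics", "TonicMap", "Trace",
    "GateSpec", "ChannelSpec", "CompartmentalModel", "build_model",
    "tonic_map", "exp2_peak_time",
]

# unit helpers ---------------------------------------------------------------
UM2_TO_CM2 = 1e-8
S_TO_US = 1e6
UF_TO_NF = 1e3


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and cytoplasm.

    Defaults follow the convention used for passive interneuron models:
    Ra fixed at 100 Ohm cm (300 for active models), cm around 1 uF/cm^2.
    """

    cm: float = 1.0        # uF/cm^2
    g_pas: float = 1e-4    # S/cm^2
    e_pas: float = -65.0   # mV
    ra: float = 100.0      # Ohm cm

    def __post_init__(self):
        if min(self.cm, self.g_pas, self.ra) <= 0:
            raise ValueError("cm, g_pas and Ra must be positive")


@dataclass(frozen=True)
class IhParams:
    """Hyperpolarization-activated current with fast and slow components.

    Total activation is fastRatio_H * m_fast + (1 - fastRatio_H) * m_slow;
    both gates share the activation curve (v_half, slope) but relax with
    different time constants.  Kinetic defaults are documented placeholders
    in the range reported for hippocampal interneuron Ih; supply measured
    values through configuration for quantitative work.
    """

    gmax_h: float = 0.0        # S/cm^2
    fast_ratio: float = 0.8    # dimensionless in [0, 1]
    e_h: float = -30.0         # mV
    v_half: float = -82.0      # mV
    slope: float = -9.0        # mV (negative: activates on hyperpolarization)
    tau_fast: float = 40.0     # ms
    tau_slow: float = 300.0    # ms

    def __post_init__(self):
        if not 0.0 <= self.fast_ratio <= 1.0:
            raise ValueError("fast_ratio must lie in [0, 1]")
        if self.gmax_h < 0:
            raise ValueError("gmax_h must be non-negative")

    def steady_state(self, v: float) -> float:
        return 1.0 / (1.0 + math.exp(-(v - self.v_half) / self.slope))


@dataclass(frozen=True)
class SynapseKinetics:
    """Difference-of-exponentials conductance synapse.

    g(t) = gmax * norm * (exp(-t/tau_decay) - exp(-t/tau_rise)), normalized
    to peak at gmax.  ``hs_inh_scale`` is the cell-type conductance factor
    applied to inhibitory synapses on HS cells (their synapses are ~15%
    larger).  Reversal defaults (0 / -75 mV) are conventional placeholders.
    """

    kind: str = "exc"          # "exc" or "inh"
    tau_rise: float = 0.3      # ms
    tau_decay: float = 3.0     # ms
    gmax: float = 1.0          # nS
    e_rev: float = 0.0         # mV
    hs_inh_scale: float = 1.15

    def __post_init__(self):
        if self.tau_decay <= self.tau_rise:
            raise ValueError("tau_decay must exceed tau_rise")
        if self.tau_rise <= 0:
            raise ValueError("tau_rise must be positive")

    def scaled_for(self, cell_type: str) -> "SynapseKinetics":
        if self.kind == "inh" and cell_type.upper() == "HS":
            return replace(self, gmax=self.gmax * self.hs_inh_scale)
        return self


def default_exc_kinetics() -> SynapseKinetics:
    return SynapseKinetics(kind="exc", tau_rise=0.3, tau_decay=3.0,
                           gmax=1.0, e_rev=0.0)


def default_inh_kinetics() -> SynapseKinetics:
    return SynapseKinetics(kind="inh", tau_rise=0.5, tau_decay=8.0,
                           gmax=1.0, e_rev=-75.0)


def exp2_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of peak of the difference of exponentials."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) \
        * math.log(tau_decay / tau_rise)


def _exp2_norm(tau_rise: float, tau_decay: float) -> float:
    tp = exp2_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


@dataclass
class TonicMap:
    """Per-compartment tonic conductance densities (S/cm^2) and reversals."""

    g_exc: np.ndarray           # (n,) S/cm^2
    g_inh: np.ndarray           # (n,) S/cm^2
    e_exc: float = 0.0          # mV
    e_inh: float = -75.0        # mV

    def __post_init__(self):
        self.g_exc = np.asarray(self.g_exc, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if np.any(self.g_exc < 0) or np.any(self.g_inh < 0):
            raise ValueError("tonic conductances must be non-negative")


@dataclass
class Trace:
    """Uniformly sampled voltage trace(s) with the stimulus on record."""

    t: np.ndarray               # ms
    v: np.ndarray               # (nprobe, nt) mV
    probes: np.ndarray
    stimulus: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def probe(self, i: int = 0) -> np.ndarray:
        return self.v[i]

    def to_frame(self):
        import pandas as pd
        data = {"time_ms": self.t}
        for i, p in enumerate(self.probes):
            data[f"v_comp{int(p)}_mV"] = self.v[i]
        return pd.DataFrame(data)


@dataclass(frozen=True)
class GateSpec:
    """One Boltzmann gate: m_inf = 1/(1+exp(-(v-v_half)/slope)) raised to
    ``power``; tau(v) = tau0 + 2*tau_amp/(exp((v-tv)/tk)+exp(-(v-tv)/tk))."""

    power: float = 1.0
    v_half: float = -40.0
    slope: float = 5.0
    tau0: float = 1.0
    tau_amp: float = 0.0
    tau_vhalf: float = -40.0
    tau_k: float = 15.0


@dataclass(frozen=True)
class ChannelSpec:
    """Generic voltage-gated channel: g = gbar * prod(gate^power)."""

    name: str
    gbar: float                 # S/cm^2
    e_rev: float                # mV
    gates: tuple[GateSpec, ...] = ()

    def __post_init__(self):
        if len(self.gates) > 2:
            raise ValueError("at most two gates per channel")


def spiking_channels(g_na: float = 0.05, g_kdr: float = 0.015,
                     e_na: float = 55.0, e_k: float = -90.0):
    """A generic fast-Na / delayed-rectifier pair for prototype spiking
    models (plug-in demonstration channels, not measured kinetics)."""
    na = ChannelSpec("na_fast", g_na, e_na, gates=(
        GateSpec(power=3, v_half=-32.0, slope=6.5, tau0=0.1),
        GateSpec(power=1, v_half=-52.0, slope=-6.5, tau0=0.4,
                 tau_amp=3.0, tau_vhalf=-55.0, tau_k=15.0),
    ))
    kdr = ChannelSpec("k_dr", g_kdr, e_k, gates=(
        GateSpec(power=4, v_half=-40.0, slope=10.0, tau0=0.8,
                 tau_amp=2.5, tau_vhalf=-50.0, tau_k=25.0),
    ))
    return [na, kdr]


class CompartmentalModel:
    """Assembled electrical model ready to integrate.

    Build through :func:`build_model`.  Synapses and channels are attached
    after construction; ``simulate`` integrates with backward Euler.
    """

    def __init__(self, grid: CompartmentGrid, passive: PassiveParams,
                 ih: IhParams | None = None, tonic: TonicMap | None = None,
                 cell_type: str = "OLM"):
        self.grid = grid
        self.passive = passive
        self.ih = ih or IhParams()
        self.tonic = tonic
        self.cell_type = cell_type
        self.channels: list[ChannelSpec] = []
        self._syn: list[dict] = []
        self._events: list[tuple[float, int, float]] = []
        self._stims: list[tuple[int, float, float, float]] = []
        n = grid.n
        if n < 1 or grid.parent[0] != -1 or np.any(grid.parent[1:] >= np.arange(1, n)):
            raise ValueError("grid compartments must be topologically ordered")
        if np.any(grid.parent[1:] < 0):
            raise ValueError("grid is disconnected: non-root compartment without parent")
        self._ra = passive.ra
        self._axial = self._axial_conductances()

    # -- assembly ----------------------------------------------------------

    def _axial_conductances(self) -> np.ndarray:
        """Axial coupling conductance (uS) between each compartment and its
        parent: series half-cylinder resistances."""
        g = self.grid
        n = g.n
        # half resistance of compartment i (Ohm): Ra * (L/2) / (pi r^2)
        half_r = np.empty(n)
        for i in range(n):
            r_cm = (g.diameter[i] / 2.0) * 1e-4
            l_cm = (g.length[i] / 2.0) * 1e-4
            half_r[i] = self._ra * l_cm / (math.pi * r_cm ** 2)
        gax = np.zeros(n)
        for i in range(1, n):
            gax[i] = 1.0 / (half_r[i] + half_r[g.parent[i]]) * 1e6  # S->uS
        return gax

    def set_axial_resistivity(self, ra: float) -> None:
        if ra <= 0:
            raise ValueError("Ra must be positive")
        self._ra = ra
        self._axial = self._axial_conductances()

    @property
    def axial_resistivity(self) -> float:
        return self._ra

    def mito_axial_correction(self, mito_fraction: float) -> "CompartmentalModel":
        """Compensate for mitochondria reducing the cross-section available
        to axial current: Ra <- Ra / (1 - fraction), uniform in the cell."""
        if not 0.0 <= mito_fraction < 1.0:
            raise ValueError("mito fraction must lie in [0, 1)")
        self.set_axial_resistivity(self._ra / (1.0 - mito_fraction))
        return self

    def add_channel(self, spec: ChannelSpec,
                    where: np.ndarray | None = None) -> None:
        """Attach a voltage-gated channel; ``where`` is an optional boolean
        mask restricting it to a compartment subset."""
        self.channels.append(spec)
        mask = np.ones(self.grid.n, bool) if where is None \
            else np.asarray(where, bool)
        if not hasattr(self, "_chan_masks"):
            self._chan_masks = []
        self._chan_masks.append(mask)

    def attach_synapse(self, comp: int, kin: SynapseKinetics,
                       event_times_ms=()) -> int:
        """Attach one synapse at compartment ``comp``; returns synapse index."""
        kin = kin.scaled_for(self.cell_type)
        idx = len(self._syn)
        self._syn.append({"comp": int(comp), "kin": kin})
        for t in event_times_ms:
            self._events.append((float(t), idx, 1.0))
        return idx

    def add_events(self, syn_index: int, times_ms, weight: float = 1.0) -> None:
        for t in np.atleast_1d(times_ms):
            self._events.append((float(t), syn_index, weight))

    def clear_synapses(self) -> None:
        self._syn = []
        self._events = []

    def inject_step(self, comp: int, amp_nA: float, t_on: float,
                    t_off: float) -> None:
        self._stims.append((int(comp), float(t_on), float(t_off), float(amp_nA)))

    def clear_stimuli(self) -> None:
        self._stims = []

    # -- derived quantities -------------------------------------------------

    def membrane_conductances(self) -> dict[str, np.ndarray]:
        """Absolute leak and tonic conductances per compartment (uS)."""
        a = self.grid.area * UM2_TO_CM2
        gleak = self.passive.g_pas * a * S_TO_US
        if self.tonic is not None:
            gte = self.tonic.g_exc * a * S_TO_US
            gti = self.tonic.g_inh * a * S_TO_US
        else:
            gte = np.zeros(self.grid.n)
            gti = np.zeros(self.grid.n)
        return {"leak": gleak, "tonic_exc": gte, "tonic_inh": gti}

    def equilibrium_potentials(self, include_ih: bool = False,
                               v_ih: float | None = None) -> np.ndarray:
        """Local equilibrium potential per compartment: the conductance-
        weighted mean of the reversal potentials of leak and tonic currents.

        Ih is voltage dependent and excluded by default; with
        ``include_ih=True`` its conductance is evaluated at ``v_ih`` (or at
        e_pas) using the steady-state activation.
        """
        g = self.membrane_conductances()
        num = (g["leak"] * self.passive.e_pas
               + g["tonic_exc"] * (self.tonic.e_exc if self.tonic else 0.0)
               + g["tonic_inh"] * (self.tonic.e_inh if self.tonic else 0.0))
        den = g["leak"] + g["tonic_exc"] + g["tonic_inh"]
        if include_ih and self.ih.gmax_h > 0:
            v = self.passive.e_pas if v_ih is None else v_ih
            gh = self.ih.gmax_h * self.ih.steady_state(v) \
                * self.grid.area * UM2_TO_CM2 * S_TO_US
            num = num + gh * self.ih.e_h
            den = den + gh
        if np.any(den <= 0):
            raise ValueError("equilibrium potential undefined: zero conductance")
        return num / den

    def input_resistance(self, comp: int = 0) -> float:
        """DC input resistance (MOhm) at a compartment from the linearized
        steady-state system (leak + tonic; Ih at steady state of e_pas)."""
        n = self.grid.n
        g = self.membrane_conductances()
        gm = g["leak"] + g["tonic_exc"] + g["tonic_inh"]
        if self.ih.gmax_h > 0:
            gm = gm + self.ih.gmax_h * self.ih.steady_state(self.passive.e_pas) \
                * self.grid.area * UM2_TO_CM2 * S_TO_US
        d = gm.copy()
        rhs = np.zeros(n)
        rhs[comp] = 1.0  # nA
        gax = self._axial
        par = self.grid.parent
        d2 = d.copy(); b2 = rhs.copy()
        for i in range(1, n):
            d2[i] += gax[i]
            d2[par[i]] += gax[i]
        for i in range(n - 1, 0, -1):
            f = gax[i] / d2[i]
            d2[par[i]] -= gax[i] * f
            b2[par[i]] += b2[i] * f
        v = np.zeros(n)
        v[0] = b2[0] / d2[0]
        for i in range(1, n):
            v[i] = (b2[i] + gax[i] * v[par[i]]) / d2[i]
        return float(v[comp])  # mV per nA = MOhm

    # -- integration ---------------------------------------------------------

    def _pack_channels(self):
        chans = []
        # Ih as two one-gate channels sharing the activation curve
        if self.ih.gmax_h > 0:
            for ratio, tau in ((self.ih.fast_ratio, self.ih.tau_fast),
                               (1.0 - self.ih.fast_ratio, self.ih.tau_slow)):
                if ratio <= 0:
                    continue
                chans.append((ChannelSpec(
                    "ih", self.ih.gmax_h * ratio, self.ih.e_h,
                    gates=(GateSpec(1.0, self.ih.v_half, self.ih.slope, tau),)),
                    np.ones(self.grid.n, bool)))
        masks = getattr(self, "_chan_masks", [])
        for spec, mask in zip(self.channels, masks):
            chans.append((spec, mask))
        nchan = len(chans)
        n = self.grid.n
        gbar = np.zeros((max(nchan, 1), n))
        erev = np.zeros(max(nchan, 1))
        ngates = np.zeros(max(nchan, 1), np.int64)
        gparams = np.zeros((max(nchan, 1), 2, 8))
        a_cm2 = self.grid.area * UM2_TO_CM2
        for c, (spec, mask) in enumerate(chans):
            gbar[c, mask] = spec.gbar * a_cm2[mask] * S_TO_US
            erev[c] = spec.e_rev
            ngates[c] = len(spec.gates)
            for gi, gs in enumerate(spec.gates):
                gparams[c, gi] = (gs.power, gs.v_half, gs.slope, gs.tau0,
                                  gs.tau_amp, gs.tau_vhalf, gs.tau_k, 0.0)
        return nchan, gbar, erev, ngates, gparams

    def simulate(self, T: float, dt: float = 0.025, probes=(0,),
                 v_init: float | None = None,
                 record_stride: int = 1) -> Trace:
        """Integrate for ``T`` ms and return voltage at ``probes``.

        Raises a RuntimeError with a diagnostic if the state goes non-finite.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        n = self.grid.n
        nsteps = int(round(T / dt))
        v0_val = self.passive.e_pas if v_init is None else v_init
        v0 = np.full(n, float(v0_val))

        g = self.membrane_conductances()
        a = self.grid.area * UM2_TO_CM2
        cap = self.passive.cm * a * UF_TO_NF
        eleak = np.full(n, self.passive.e_pas)
        ete = self.tonic.e_exc if self.tonic is not None else 0.0
        eti = self.tonic.e_inh if self.tonic is not None else -75.0

        nchan, gbar, erev, ngates, gparams = self._pack_channels()
        gate_state = np.zeros((max(nchan, 1), 2, n))
        for c in range(nchan):
            for gi in range(ngates[c]):
                vh, kk = gparams[c, gi, 1], gparams[c, gi, 2]
                gate_state[c, gi, :] = 1.0 / (1.0 + np.exp(-(v0 - vh) / kk))

        nsyn = len(self._syn)
        syn_comp = np.zeros(max(nsyn, 1), np.int64)
        syn_erev = np.zeros(max(nsyn, 1))
        syn_gpn = np.zeros(max(nsyn, 1))
        syn_ar = np.ones(max(nsyn, 1))
        syn_ad = np.ones(max(nsyn, 1))
        for i, s in enumerate(self._syn):
            kin = s["kin"]
            syn_comp[i] = s["comp"]
            syn_erev[i] = kin.e_rev
            syn_gpn[i] = kin.gmax * 1e-3 * _exp2_norm(kin.tau_rise, kin.tau_decay)
            syn_ar[i] = math.exp(-dt / kin.tau_rise)
            syn_ad[i] = math.exp(-dt / kin.tau_decay)
        events = sorted(self._events)
        ev_step = np.array([int(math.floor(t / dt)) + 1 for t, _, _ in events],
                           np.int64).reshape(-1)
        ev_syn = np.array([s for _, s, _ in events], np.int64).reshape(-1)
        ev_w = np.array([w for _, _, w in events]).reshape(-1)

        nstim = len(self._stims)
        st_comp = np.zeros(max(nstim, 1), np.int64)
        st_on = np.zeros(max(nstim, 1)); st_off = np.zeros(max(nstim, 1))
        st_amp = np.zeros(max(nstim, 1))
        for i, (c, t0, t1, amp) in enumerate(self._stims):
            st_comp[i], st_on[i], st_off[i], st_amp[i] = c, t0, t1, amp
        if nstim == 0:
            st_off[:] = -1.0

        probes_arr = np.asarray(probes, np.int64)
        out = simulate_core(
            self.grid.parent, self._axial, cap, g["leak"], eleak,
            g["tonic_exc"], ete, g["tonic_inh"], eti,
            gbar[:nchan] if nchan else gbar[:0], erev[:nchan] if nchan else erev[:0],
            ngates[:nchan] if nchan else ngates[:0],
            gparams[:nchan] if nchan else gparams[:0],
            gate_state[:nchan] if nchan else gate_state[:0],
            syn_comp[:nsyn], syn_erev[:nsyn], syn_gpn[:nsyn],
            syn_ar[:nsyn], syn_ad[:nsyn],
            ev_step, ev_syn, ev_w,
            st_comp[:nstim], st_on[:nstim], st_off[:nstim], st_amp[:nstim],
            v0, dt, nsteps, probes_arr, record_stride)
        if not np.all(np.isfinite(out)):
            raise RuntimeError("simulation diverged (non-finite voltage)")
        t = np.arange(out.shape[1]) * dt * record_stride
        return Trace(t=t, v=out, probes=probes_arr,
                     stimulus={"stims": list(self._stims)})


def build_model(grid: CompartmentGrid, passive: PassiveParams,
                ih: IhParams | None = None, tonic: TonicMap | None = None,
                cell_type: str = "OLM") -> CompartmentalModel:
    """Assemble a compartmental model from a grid and membrane parameters."""
    return CompartmentalModel(grid, passive, ih=ih, tonic=tonic,
                              cell_type=cell_type)


def tonic_map(grid: CompartmentGrid, exc_density, inh_density,
              rates: tuple[float, float] = (3.0, 30.0),
              exc_kin: SynapseKinetics | None = None,
              inh_kin: SynapseKinetics | None = None,
              cell_type: str = "OLM") -> TonicMap:
    """Time-averaged background synaptic conductance per membrane area.

    For each input class, conductance per area = synapse density (um^-2)
    x presynaptic rate (Hz) x peak conductance (nS) x decay tau (ms),
    converted to S/cm^2.  Defaults: 3 Hz excitatory, 30 Hz inhibitory
    presynaptic rates.

    ``exc_density``/``inh_density`` may be scalars or per-compartment arrays.
    """
    rate_e, rate_i = rates
    if rate_e < 0 or rate_i < 0:
        raise ValueError("rates must be non-negative")
    exc_kin = (exc_kin or default_exc_kinetics()).scaled_for(cell_type)
    inh_kin = (inh_kin or default_inh_kinetics()).scaled_for(cell_type)
    de = np.broadcast_to(np.asarray(exc_density, float), (grid.n,))
    di = np.broadcast_to(np.asarray(inh_density, float), (grid.n,))
    # nS ms Hz / um^2 -> S/cm^2: 1e-3 (ms*Hz) * 1e-9/1e-8 (nS/um^2 -> S/cm^2)
    conv = 1e-4
    g_exc = de * rate_e * exc_kin.gmax * exc_kin.tau_decay * conv
    g_inh = di * rate_i * inh_kin.gmax * inh_kin.tau_decay * conv
    return TonicMap(g_exc=g_exc, g_inh=g_inh,
                    e_exc=exc_kin.e_rev, e_inh=inh_kin.e_rev)
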