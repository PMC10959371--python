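"""Protocols: steps, features, PSP scans, drive curves, theta, validation."""

import math

import numpy as np
import pytest

from dendarch import cable as C
from dendarch import protocols as P
from dendarch.synapse_map import DensityModel, predict_counts

from conftest import make_cylinder_grid, make_soma_cable_grid

PASSIVE = C.PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-65.0, ra=100.0)


# -- step protocol -----------------------------------------------------------

def test_empty_amplitude_list_gives_empty_set(passive_model):
    proto = P.StepProtocol(amplitudes_pA=())
    rs = P.run_step_protocol(passive_model, proto)
    assert len(rs) == 0


def test_negative_step_obeys_ohms_law():
    """-100 pA on a passive isopotential compartment: dV = I R."""
    grid = make_cylinder_grid(L=10.0, d=31.8309886, n=1)
    m = C.build_model(grid, PASSIVE)
    proto = P.StepProtocol(amplitudes_pA=(-100.0,), duration_ms=600.0,
                           delay_ms=100.0, tail_ms=50.0)
    rs = P.run_step_protocol(m, proto)
    fv = P.extract_features(rs.traces[0], -100.0, 100.0, 600.0)
    R = m.input_resistance(0)
    assert fv["input_resistance"] == pytest.approx(R, rel=1e-3)
    assert fv["steady_state_voltage"] == pytest.approx(-65.0 - 0.1 * R,
                                                       rel=1e-3)


def test_paper_step_family_accepted_verbatim():
    proto = P.StepProtocol()
    assert len(proto.amplitudes_pA) == 27  # 23 short + 4 long steps
    assert proto.amplitudes_pA[:4] == (20, -20, 40, -40)
    assert proto.amplitudes_pA[-4:] == (300, 400, 500, 600)


# -- spike detection and standardized steps ----------------------------------

def _trace_with_spikes(spike_times, T=800.0, dt=0.1, base=-65.0):
    """Plant triangular spikes on a flat baseline."""
    t = np.arange(0, T + dt, dt)
    v = np.full_like(t, base)
    for ts in spike_times:
        mask = np.abs(t - ts) <= 1.0
        v[mask] = np.maximum(v[mask], 30.0 - 60.0 * np.abs(t[mask] - ts))
    return C.Trace(t=t, v=v[None, :], probes=np.array([0]))


def test_planted_spikes_recovered_within_one_sample():
    planted = [100.0, 150.0, 400.0]
    tr = _trace_with_spikes(planted)
    found = P.detect_spikes(tr.t, tr.probe(0))
    assert len(found) == 3
    assert np.all(np.abs(found - np.array(planted)) <= 1.0)


def test_refractory_guard_merges_double_crossings():
    t = np.arange(0, 10, 0.05)
    v = np.full_like(t, -65.0)
    v[(t > 2) & (t < 2.6)] = 10.0
    v[(t > 2.2) & (t < 2.3)] = -30.0  # dip below threshold within 1 ms
    found = P.detect_spikes(t, v)
    assert len(found) == 1


class _FakeResponseSet:
    """Amplitude/spike-count stub satisfying select_standard_steps."""

    def __init__(self, table):
        self.table = table
        self.protocol = P.StepProtocol(amplitudes_pA=tuple(table))
        self.traces = [_trace_with_spikes(
            [200.0 + 10.0 * k for k in range(n)]) for n in table.values()]

    def __len__(self):
        return len(self.table)

    def amplitude(self, i):
        return list(self.table)[i]


def test_rheobase_definition():
    rs = _FakeResponseSet({20.0: 0, 40.0: 0, 60.0: 2})
    sel = P.select_standard_steps(rs)
    assert rs.amplitude(sel.rheobase) == 60.0


def test_standard_negative_closest_to_minus_100():
    rs = _FakeResponseSet({-20.0: 0, -100.0: 0, -160.0: 0})
    sel = P.select_standard_steps(rs)
    assert rs.amplitude(sel.standard_negative) == -100.0


def test_steady_state_and_maxspike_with_tie_rule():
    rs = _FakeResponseSet({100.0: 5, 200.0: 9, 300.0: 9})
    sel = P.select_standard_steps(rs)
    assert rs.amplitude(sel.steady_state) == 200.0
    assert rs.amplitude(sel.maxspike) == 200.0  # tie -> smaller amplitude


def test_no_spiking_steps_flagged_absent():
    rs = _FakeResponseSet({20.0: 0, 40.0: 0})
    sel = P.select_standard_steps(rs)
    assert sel.rheobase is None and sel.maxspike is None
    assert sel.steady_state is None


@pytest.mark.parametrize("seed", range(5))
def test_standard_steps_match_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    amps = sorted(rng.choice(np.arange(-200, 320, 20), 12, replace=False))
    table = {float(a): (int(rng.integers(0, 12)) if a > 0 else 0)
             for a in amps}
    rs = _FakeResponseSet(table)
    sel = P.select_standard_steps(rs)
    amps_l = list(table)
    spiking = [(a, i) for i, a in enumerate(amps_l) if table[a] >= 1]
    assert (sel.rheobase is None) == (not spiking)
    if spiking:
        assert rs.amplitude(sel.rheobase) == min(spiking)[0]
        best = max(table.values())
        assert rs.amplitude(sel.maxspike) == min(
            a for a in amps_l if table[a] == best)
    steady = [a for a in amps_l if table[a] >= 8]
    if steady:
        assert rs.amplitude(sel.steady_state) == min(steady)
    negs = [a for a in amps_l if a < 0]
    if negs:
        assert rs.amplitude(sel.standard_negative) == min(
            negs, key=lambda a: (abs(a + 100.0), abs(a)))


# -- features ----------------------------------------------------------------

def test_inverse_isi_from_planted_spikes():
    """Spikes at 100 and 110 ms give a first inverse ISI of 100 Hz."""
    tr = _trace_with_spikes([100.0, 110.0, 130.0])
    fv = P.extract_features(tr, 200.0, 50.0, 700.0)
    assert fv["inv_isi_1"] == pytest.approx(100.0, rel=0.02)
    assert fv["time_to_first_spike"] == pytest.approx(50.0, abs=1.5)


def test_sag_feature_arithmetic():
    """Base -65, minimum -80, steady -70: amplitude 10, ratio 2/3."""
    t = np.arange(0.0, 1000.0, 0.1)
    v = np.full_like(t, -65.0)
    stim = (t >= 100.0) & (t < 900.0)
    v[stim] = -70.0
    dip = (t >= 100.0) & (t < 250.0)
    v[dip] = -80.0 + 10.0 * (t[dip] - 100.0) / 150.0
    tr = C.Trace(t=t, v=v[None, :], probes=np.array([0]))
    fv = P.extract_features(tr, -100.0, 100.0, 800.0)
    assert fv["sag_amplitude"] == pytest.approx(10.0, abs=0.1)
    assert fv["sag_ratio"] == pytest.approx(10.0 / 15.0, abs=0.01)


def test_constant_trace_spike_features_undefined():
    t = np.arange(0.0, 500.0, 0.1)
    v = np.full_like(t, -70.0)
    tr = C.Trace(t=t, v=v[None, :], probes=np.array([0]))
    fv = P.extract_features(tr, -50.0, 100.0, 300.0)
    assert fv["spike_count"] == 0
    assert fv["inv_isi_1"] is None and fv["ap_peak_1"] is None
    assert fv["input_resistance"] is not None


# -- PSP attenuation ---------------------------------------------------------

def test_somatic_synapse_has_no_attenuation():
    grid = make_soma_cable_grid()
    m = C.build_model(grid, PASSIVE)
    kin = C.default_exc_kinetics()
    d, a = P.psp_attenuation_scan(m, kin, compartments=[0], settle_ms=50.0)
    assert a[0] > 0.0 and d[0] == 0.0


def test_psp_amplitude_monotone_in_distance_on_passive_cylinder():
    grid = make_cylinder_grid(L=600.0, d=1.5, n=60)
    m = C.build_model(grid, PASSIVE)
    kin = C.default_exc_kinetics()
    comps = list(range(0, 60, 6))
    d, a = P.psp_attenuation_scan(m, kin, compartments=comps, settle_ms=50.0)
    assert np.all(np.diff(a) < 0.0)


def test_hcs_shunts_psps_everywhere():
    """Under a tonic background map the somatic PSP is never larger than in
    the silent state, at any synapse location."""
    grid = make_soma_cable_grid(n=30, L=400.0)
    kin = C.default_exc_kinetics()
    comps = list(range(1, 31, 4))
    silent = C.build_model(grid, PASSIVE)
    _, a_sil = P.psp_attenuation_scan(silent, kin, compartments=comps,
                                      settle_ms=80.0)
    tm = C.tonic_map(grid, exc_density=0.5, inh_density=0.08)
    hcs = C.build_model(grid, PASSIVE, tonic=tm)
    _, a_hcs = P.psp_attenuation_scan(hcs, kin, compartments=comps,
                                      settle_ms=80.0)
    assert np.all(a_hcs <= a_sil + 1e-12)


# -- drive curve -------------------------------------------------------------

def _active_soma_cable(n=20, L=300.0):
    """Passive dendrite with spike initiation restricted to the soma, so
    synaptic charge must reach the soma to matter."""
    grid = make_soma_cable_grid(n=n, L=L, soma_area=1500.0)
    m = C.build_model(grid, PASSIVE)
    soma_only = grid.section_index < 0
    for ch in C.spiking_channels(g_na=0.12, g_kdr=0.02):
        m.add_channel(ch, where=soma_only)
    return grid, m


def test_zero_synapses_zero_spikes():
    grid, m = _active_soma_cable()
    pc = predict_counts(DensityModel("OLM", "glut", 0.5, 0, 0), grid)
    curve = P.synapse_drive_curve(m, pc, counts=(0,), T_ms=300.0, seed=0)
    assert curve.rates_hz[0] == 0.0


def test_firing_rate_nondecreasing_with_synapse_count():
    """More active synapses never produce a lower rate (within Monte-Carlo
    tolerance across seeds)."""
    grid, m = _active_soma_cable()
    pc = predict_counts(DensityModel("OLM", "glut", 0.5, 0, 0), grid)
    gains = []
    for seed in range(5):
        curve = P.synapse_drive_curve(
            m, pc, counts=(20, 100, 300), T_ms=500.0, seed=seed,
            kin=C.SynapseKinetics(kind="exc", tau_rise=0.3, tau_decay=3.0,
                                  gmax=1.0, e_rev=0.0))
        gains.append(curve.rates_hz)
    mean = np.mean(gains, axis=0)
    assert mean[1] >= mean[0] and mean[2] >= mean[1]
    assert mean[2] > 0.0


def test_fewer_proximal_synapses_needed_than_distal():
    """Proximal placements drive spiking at least as hard as distal ones
    for the same synapse count."""
    grid, m = _active_soma_cable(n=40, L=450.0)
    pc = predict_counts(DensityModel("OLM", "glut", 0.5, 0, 0), grid)
    rates = {}
    for rng_name, band in (("prox", (0.0, 100.0)), ("dist", (300.0, 400.0))):
        per_seed = []
        for seed in range(3):
            c = P.synapse_drive_curve(m, pc, counts=(120,),
                                      distance_range=band, T_ms=500.0,
                                      seed=seed)
            per_seed.append(c.rates_hz[0])
        rates[rng_name] = np.mean(per_seed)
    assert rates["prox"] >= rates["dist"]
    assert rates["prox"] > 0.0


def test_percentage_axis_invariant_to_uniform_density_rescale():
    """Scaling the predicted counts leaves count/total percentages fixed."""
    grid, m = _active_soma_cable()
    pc1 = predict_counts(DensityModel("OLM", "glut", 0.5, 0, 0), grid)
    pc2 = predict_counts(DensityModel("OLM", "glut", 1.0, 0, 0), grid)
    c1 = P.synapse_drive_curve(m, pc1, counts=(50,), T_ms=100.0, seed=0)
    c2 = P.synapse_drive_curve(m, pc2, counts=(50,), T_ms=100.0, seed=0)
    assert c2.percentages[0] == pytest.approx(c1.percentages[0] / 2.0)


# -- circular statistics -----------------------------------------------------

def test_mean_vector_length_edge_cases():
    assert P.mean_vector_length(np.full(10, 1.3)) == pytest.approx(1.0)
    eighth = 2 * np.pi * np.arange(8) / 8
    assert P.mean_vector_length(eighth) == pytest.approx(0.0, abs=1e-12)


def test_rayleigh_r_matches_trig_sum_oracle():
    rng = np.random.default_rng(0)
    phases = rng.uniform(0, 2 * np.pi, 20)
    r, p = P.rayleigh_test(phases)
    r2 = math.hypot(np.cos(phases).sum(), np.sin(phases).sum()) / 20
    assert r == pytest.approx(r2, abs=1e-12)
    n = 20
    z = n * r2 * r2
    p2 = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - z * n)) - (1 + 2 * n))
    assert p == pytest.approx(p2, abs=1e-12)


def test_theta_modulation_on_active_model_detects_locking():
    grid, m = _active_soma_cable()
    pc = predict_counts(DensityModel("OLM", "glut", 0.8, 0, 0), grid)
    res = P.theta_modulation(m, pc, fraction=0.12, T_ms=4000.0, seed=1)
    assert res.n_spikes > 5
    assert 0.0 <= res.R <= 1.0
    assert res.p < 0.05  # sinusoidal drive phase-locks the output


def test_theta_modulation_flags_silent_model():
    grid = make_soma_cable_grid()
    m = C.build_model(grid, PASSIVE)  # passive: never spikes
    pc = predict_counts(DensityModel("OLM", "glut", 0.5, 0, 0), grid)
    res = P.theta_modulation(m, pc, fraction=0.05, T_ms=500.0, seed=0,
                             kin=C.SynapseKinetics(kind="exc", gmax=0.01,
                                                   tau_rise=0.3,
                                                   tau_decay=3.0))
    assert res.R is None and res.flagged is not None


# -- validation --------------------------------------------------------------

def test_model_equal_to_means_passes_everywhere():
    ref = {"a": (1.0, 0.1), "b": (-3.0, 0.5)}
    out = P.validate_against_features({"a": 1.0, "b": -3.0}, ref)
    assert out["fraction_pass"] == 1.0


def test_one_outlier_in_ten():
    ref = {f"f{i}": (0.0, 1.0) for i in range(10)}
    feats = {f"f{i}": 0.0 for i in range(10)}
    feats["f0"] = 3.0
    out = P.validate_against_features(feats, ref)
    assert out["n_pass"] == 9 and out["n_total"] == 10


def test_zero_sd_feature_excluded_and_reported():
    ref = {"a": (1.0, 0.0), "b": (2.0, 0.5)}
    out = P.validate_against_features({"a": 1.0, "b": 2.0}, ref)
    assert out["excluded_zero_sd"] == ["a"]
    assert out["n_total"] == 1


def test_self_consistency_validation_passes():
    """Features validated against reference tables jittered from the same
    model pass >= 95% at 2 SD."""
    from dendarch.synthetic import (generate_reference_features,
                                    ground_truth_model, olm_spec)
    spec = olm_spec()
    table = generate_reference_features(spec, seed=3, jitter=0.1,
                                        amplitudes_pA=(-100, 200))
    model = ground_truth_model(spec)
    proto = P.StepProtocol(amplitudes_pA=(-100, 200), duration_ms=800.0,
                           delay_ms=100.0, tail_ms=100.0)
    rs = P.run_step_protocol(model, proto)
    feats = {}
    for i, tr in enumerate(rs.traces):
        fv = P.extract_features(tr, proto.amplitudes_pA[i], 100.0, 800.0)
        tag = f"step{int(proto.amplitudes_pA[i]):+d}"
        feats.update({f"{k}@{tag}": v for k, v in fv.defined().items()})
    out = P.validate_against_features(feats, table)
    assert out["fraction_pass"] >= 0.95
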