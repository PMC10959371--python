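"""Synthetic morphologies, EM segment tables and reference feature tables.

The generators emulate the statistical structure the analysis pipeline
assumes for the two interneuron types, so that every downstream stage is
testable without any external data:

* segment tables with planted linear density coefficients (density =
  a + b*distance + c*diameter plus noise), log-normal synapse sizes whose
  log-median drifts with somatic distance (up for OLM-like cells, down for
  HS-like cells), and mitochondrial volume tied to the cross-section;
* planar-biased binary-tree morphologies with exponential diameter taper,
  high thickness variability, and per-type constraints on total length,
  first-order dendrite count and maximal Euclidean reach (HS-like cells
  reach beyond 500 um from the soma, OLM-like cells do not);
* reference feature tables (mean +/- SD) produced by jittering features of
  a known ground-truth model, closing the loop for the fitter and the 2-SD
  validation.

All generators are deterministic under their seed, and every generated
object carries its ground truth for oracle-style tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .emstats import SegmentRecord, SynapseRecord
from .morphology import DENDRITE, SOMA, MorphNode, NeuronMorphology

__all__ = [
    "EmulationSpec", "olm_spec", "hs_spec",
    "generate_segment_table", "generate_morphology",
    "generate_reference_features",
]


@dataclass(frozen=True)
class EmulationSpec:
    """Target summary statistics for one cell type.

    Density targets are medians in um^-2 of membrane; the planted linear
    model is density = a + b*distance + c*diameter with ``a`` chosen so the
    median over the sampling distributions hits the target.  Noise scales
    are standard deviations; ``count_model`` selects how discrete synapse
    counts arise from expected counts ("poisson", "gaussian" on the
    density, or "none" for exact real-valued counts).
    """

    cell_type: str = "OLM"
    # surface densities (um^-2): medians and planted slopes
    exc_density_median: float = 0.522
    inh_density_median: float = 0.075
    exc_b_distance: float = -4e-4      # um^-2 per um
    exc_c_diameter: float = 0.12       # um^-2 per um
    inh_b_distance: float = -4e-5
    inh_c_diameter: float = 0.02
    density_noise_sd: float = 0.08     # um^-2, on the excitatory density
    count_model: str = "poisson"
    # synapse sizes (um^2): proximal log-median and per-um log drift
    syn_size_median: float = 0.125
    syn_size_trend: float = 6.7e-4     # sign +: distal synapses larger
    syn_size_sigma: float = 0.55       # log-normal shape
    gaba_size_median: float = 0.13
    # mitochondria
    mito_fraction_pct: float = 9.3
    mito_fraction_sd: float = 2.5
    # segment geometry
    seg_length_median_um: float = 15.7
    seg_length_sigma: float = 0.35
    max_distance_um: float = 420.0
    diam_proximal_um: float = 1.35     # taper anchor at the soma
    diam_taper_um: float = 500.0       # e-fold distance of the taper
    diam_noise_sigma: float = 0.45     # log-normal thickness variability
    # spine targeting (fraction of excitatory inputs, proximal -> distal)
    spine_frac_proximal: float = 0.06
    spine_frac_distal: float = 0.24
    # whole-cell morphology
    total_length_range: tuple = (3800.0, 8100.0)
    first_order_range: tuple = (4, 6)
    ensure_extent_um: float | None = None   # force one branch beyond this
    mean_section_um: float = 65.0
    # ground-truth active model (reference feature generation)
    g_na: float = 0.10
    g_kdr: float = 0.015

    def __post_init__(self):
        if self.exc_density_median <= 0 or self.inh_density_median <= 0:
            raise ValueError("density medians must be positive")
        if not 0 < self.mito_fraction_pct < 100:
            raise ValueError("mito fraction must lie in (0, 100)")


def olm_spec(**overrides) -> EmulationSpec:
    """OLM-like defaults: sparser inputs, ~9.3% mitochondria, synapse size
    increasing with distance, arbor within 500 um of the soma."""
    return replace(EmulationSpec(), **overrides)


def hs_spec(**overrides) -> EmulationSpec:
    """HS-like defaults: denser inputs, ~12.3% mitochondria, synapse size
    decreasing with distance, at least one branch beyond 500 um."""
    base = EmulationSpec(
        cell_type="HS",
        exc_density_median=0.763, inh_density_median=0.135,
        exc_b_distance=-9e-4, exc_c_diameter=0.15,
        inh_b_distance=-1.2e-4, inh_c_diameter=0.03,
        syn_size_median=0.164, syn_size_trend=-8e-4,
        gaba_size_median=0.15,
        mito_fraction_pct=12.3,
        seg_length_median_um=11.1,
        spine_frac_proximal=0.045, spine_frac_distal=0.13,
        total_length_range=(6600.0, 8100.0),
        first_order_range=(4, 6),
        ensure_extent_um=520.0,
        g_na=0.16, g_kdr=0.012,
    )
    return replace(base, **overrides)


# -- segment tables ----------------------------------------------------------

def _intercept_for(spec: EmulationSpec, kind: str) -> float:
    """Intercept that puts the planted density median on target.

    Uses the theoretical medians of the sampling distributions: distances
    are uniform on [0, max_distance], diameters taper exponentially.
    """
    med_dist = spec.max_distance_um / 2.0
    med_diam = spec.diam_proximal_um * math.exp(-med_dist / spec.diam_taper_um)
    if kind == "glut":
        return (spec.exc_density_median - spec.exc_b_distance * med_dist
                - spec.exc_c_diameter * med_diam)
    return (spec.inh_density_median - spec.inh_b_distance * med_dist
            - spec.inh_c_diameter * med_diam)


def planted_coefficients(spec: EmulationSpec) -> dict:
    """The (a, b, c) ground truth the generator embeds, per synapse kind."""
    return {
        "glut": (_intercept_for(spec, "glut"), spec.exc_b_distance,
                 spec.exc_c_diameter),
        "gaba": (_intercept_for(spec, "gaba"), spec.inh_b_distance,
                 spec.inh_c_diameter),
    }


def _draw_counts(rng, expected: float, model: str) -> float:
    if model == "poisson":
        return float(rng.poisson(max(expected, 0.0)))
    # "gaussian" noise acts on the density upstream; here counts are exact
    return max(expected, 0.0)


def generate_segment_table(spec: EmulationSpec, n_segments: int, seed: int = 0,
                           with_synapses: bool = True
                           ) -> tuple[list[SegmentRecord], dict]:
    """Generate EM-style dendritic segment records plus their ground truth.

    Returns ``(records, truth)`` where ``truth`` holds the planted density
    coefficients, the noise model, and the per-segment true densities.
    Infeasible specs (densities driven negative over the sampled range)
    raise before any record is built.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    coeffs = planted_coefficients(spec)
    # feasibility: density must stay positive over the sampled ranges
    for kind, (a, b, c) in coeffs.items():
        worst = a + min(b * spec.max_distance_um, 0.0)
        if worst <= 0:
            raise ValueError(
                f"infeasible spec: {kind} density goes non-positive "
                f"(a={a:.4f}, b={b:.2e} over 0-{spec.max_distance_um} um)")

    records: list[SegmentRecord] = []
    true_density = {"glut": [], "gaba": []}
    orders_pool = np.arange(1, 9)
    for i in range(n_segments):
        dist = float(rng.uniform(0.0, spec.max_distance_um))
        order = int(np.clip(1 + dist // 60 + rng.integers(-1, 2), 1, 10))
        length = float(spec.seg_length_median_um
                       * rng.lognormal(0.0, spec.seg_length_sigma))
        diam = float(spec.diam_proximal_um
                     * math.exp(-dist / spec.diam_taper_um)
                     * rng.lognormal(0.0, spec.diam_noise_sigma))
        diam = max(diam, 0.2)
        surface = math.pi * diam * length
        volume = math.pi * diam * diam / 4.0 * length
        mito_pct = float(np.clip(
            rng.normal(spec.mito_fraction_pct, spec.mito_fraction_sd),
            0.5, 60.0))
        counts = {}
        for kind, (a, b, c) in coeffs.items():
            dens = a + b * dist + c * diam
            noise_sd = spec.density_noise_sd if kind == "glut" \
                else spec.density_noise_sd * 0.4
            if spec.count_model == "gaussian":
                dens_obs = dens + rng.normal(0.0, noise_sd)
            else:
                dens_obs = dens
            true_density[kind].append(max(dens, 0.0))
            expected = max(dens_obs, 0.0) * surface
            if spec.count_model == "poisson":
                counts[kind] = _draw_counts(rng, expected, "poisson")
            else:
                counts[kind] = expected
        synapses = []
        if with_synapses:
            spine_p = np.interp(dist, [0.0, spec.max_distance_um],
                                [spec.spine_frac_proximal,
                                 spec.spine_frac_distal])
            for kind, med0 in (("glut", spec.syn_size_median),
                               ("gaba", spec.gaba_size_median)):
                n_syn = int(round(counts[kind]))
                logmed = math.log(med0) + spec.syn_size_trend * dist
                for _ in range(n_syn):
                    on_spine = bool(rng.uniform() < spine_p)
                    shift = -0.15 if on_spine else 0.0  # spine synapses smaller
                    area = float(np.exp(rng.normal(logmed + shift,
                                                   spec.syn_size_sigma)))
                    synapses.append(SynapseRecord(kind=kind, area=area,
                                                  on_spine=on_spine))
        records.append(SegmentRecord(
            cell_type=spec.cell_type, cell_id=f"{spec.cell_type}_syn0",
            segment_id=f"{spec.cell_type}_seg{i:04d}", kind="dendrite",
            distance_um=dist, order=order, length_um=length,
            surface_um2=surface, volume_um3=volume,
            mito_volume_um3=volume * mito_pct / 100.0,
            synapses=synapses,
            annotations={"n_glut": counts["glut"], "n_gaba": counts["gaba"]}))
    truth = {
        "coefficients": coeffs,
        "count_model": spec.count_model,
        "density_noise_sd": spec.density_noise_sd,
        "true_density": {k: np.asarray(v) for k, v in true_density.items()},
    }
    return records, truth


# -- morphologies ------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _jitter_direction(rng, d: np.ndarray, angle_sd: float,
                      planar_bias: float = 0.15) -> np.ndarray:
    """Perturb a direction; the z component is damped to keep arbors
    planar (the cells' dendrites spread in a near-horizontal sheet)."""
    nd = d + rng.normal(0.0, angle_sd, 3)
    nd[2] *= planar_bias
    return _unit(nd)


def generate_morphology(spec: EmulationSpec, seed: int = 0,
                        step_um: float = 10.0) -> NeuronMorphology:
    """Grow a planar-biased branched tree matching the spec's constraints.

    Total dendritic length lands inside ``total_length_range``; the number
    of first-order dendrites is drawn from ``first_order_range``; diameters
    taper exponentially with path distance with strong multiplicative
    noise.  When ``ensure_extent_um`` is set, the first primary dendrite is
    grown nearly straight until the tree reaches beyond that Euclidean
    radius.  The realized totals are recorded in ``metadata`` as ground
    truth.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.total_length_range
    target = float(rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo)))
    n_first = int(rng.integers(spec.first_order_range[0],
                               spec.first_order_range[1] + 1))
    soma_r = 7.0
    nodes = [MorphNode(1, SOMA, 0.0, 0.0, 0.0, soma_r, -1)]
    next_id = 2
    total = 0.0

    def radius_at(path: float) -> float:
        r = 0.5 * spec.diam_proximal_um * math.exp(-path / spec.diam_taper_um)
        return max(r * rng.lognormal(0.0, spec.diam_noise_sigma), 0.12)

    # active tips: (position, direction, path distance, parent node id,
    #               straight-run flag)
    tips = []
    for k in range(n_first):
        phi = 2 * math.pi * k / n_first + rng.normal(0.0, 0.2)
        d = np.array([math.cos(phi), math.sin(phi), rng.normal(0.0, 0.1)])
        tips.append({"pos": np.array([0.0, 0.0, 0.0]), "dir": _unit(d),
                     "path": 0.0, "parent": 1,
                     "straight": (k == 0 and spec.ensure_extent_um)})
    p_branch = step_um / spec.mean_section_um
    extent_reached = spec.ensure_extent_um is None
    guard = 0
    while tips and total < target and guard < 100000:
        guard += 1
        # grow the straight runner first so the extent constraint is met
        idx = 0 if any(t["straight"] for t in tips) and not extent_reached \
            else int(rng.integers(0, len(tips)))
        if not extent_reached:
            idx = next(i for i, t in enumerate(tips) if t["straight"])
        tip = tips.pop(idx)
        angle_sd = 0.05 if tip["straight"] and not extent_reached else 0.35
        d = _jitter_direction(rng, tip["dir"], angle_sd)
        pos = tip["pos"] + d * step_um
        path = tip["path"] + step_um
        r = radius_at(path)
        nodes.append(MorphNode(next_id, DENDRITE, *pos, r, tip["parent"]))
        nid = next_id
        next_id += 1
        # the soma-to-first-sample edge is not part of the dendritic cable,
        # so it is excluded from the ground-truth total length
        if tip["parent"] != 1:
            total += step_um
        if not extent_reached and np.linalg.norm(pos) > spec.ensure_extent_um:
            extent_reached = True
        # termination: bounded reach, unless this is the straight runner
        max_path = spec.max_distance_um + 30.0
        if tip["straight"] and not extent_reached:
            max_path = spec.ensure_extent_um / 0.85
        if path >= max_path:
            continue
        if (not tip["straight"] and rng.uniform() < p_branch
                and total < target):
            for sgn in (1.0, -1.0):
                dd = _jitter_direction(rng, d + sgn * 0.5
                                       * np.array([-d[1], d[0], 0.0]), 0.2)
                tips.append({"pos": pos, "dir": dd, "path": path,
                             "parent": nid, "straight": False})
        else:
            tips.append({"pos": pos, "dir": d, "path": path,
                         "parent": nid, "straight": tip["straight"]})
    m = NeuronMorphology(nodes, cell_type=spec.cell_type,
                         cell_id=f"{spec.cell_type}_synth{seed}",
                         metadata={"true_total_length_um": total,
                                   "seed": seed})
    return m


# -- reference feature tables ------------------------------------------------

def ground_truth_model(spec: EmulationSpec, area_um2: float = 12000.0):
    """A small single-compartment active model serving as ground truth for
    reference-feature generation (plug-in demonstration channels)."""
    from .cable import (ChannelSpec, GateSpec, PassiveParams, build_model,
                        spiking_channels)
    from .morphology import CompartmentGrid
    d = math.sqrt(area_um2 / math.pi)
    grid = CompartmentGrid(
        parent=np.array([-1]), length=np.array([d]),
        area=np.array([area_um2]), diameter=np.array([d]),
        path_distance=np.array([0.0]),
        section_index=np.array([-1], dtype=np.int64),
        arc_position=np.array([0.5]), order=np.array([0], dtype=np.int64))
    model = build_model(grid, PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-65.0))
    for ch in spiking_channels(g_na=spec.g_na, g_kdr=spec.g_kdr):
        model.add_channel(ch)
    return model


def generate_reference_features(spec: EmulationSpec, seed: int = 0,
                                jitter: float = 0.1,
                                amplitudes_pA=(-100, 100, 200, 300),
                                sd_floor: float = 1e-6) -> dict:
    """Reference feature table (name -> (mean, sd)) from a known model.

    Features of the spec's ground-truth model are extracted from a short
    step protocol, then jittered: mean = value * (1 + jitter * z) with z a
    standard normal truncated to [-1.5, 1.5] (a reference population whose
    mean stays within 1.5 SD of the generating model), sd = |value| *
    jitter (floored).  With zero jitter the means equal the model's own
    features and the SDs collapse to the floor, so validating the
    ground-truth model passes everywhere; at 10% jitter it passes the 2-SD
    criterion on every feature by construction.
    """
    from .protocols import StepProtocol, extract_features, run_step_protocol
    rng = np.random.default_rng(seed)
    model = ground_truth_model(spec)
    proto = StepProtocol(amplitudes_pA=tuple(amplitudes_pA),
                         duration_ms=800.0, delay_ms=100.0, tail_ms=100.0)
    rs = run_step_protocol(model, proto, dt=0.025)
    table: dict[str, tuple[float, float]] = {}
    for i, tr in enumerate(rs.traces):
        fv = extract_features(tr, proto.amplitudes_pA[i], proto.delay_ms,
                              proto.duration_ms)
        tag = f"step{int(proto.amplitudes_pA[i]):+d}"
        for name, val in fv.defined().items():
            z = float(np.clip(rng.standard_normal(), -1.5, 1.5))
            mean = val * (1.0 + jitter * z)
            sd = max(abs(val) * jitter, sd_floor)
            table[f"{name}@{tag}"] = (float(mean), float(sd))
    return table
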