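"""Morphology data model, SWC I/O, ordering, Sholl, discretization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendarch import morphology as M
from dendarch.cable import PassiveParams

from conftest import bifurcating_morphology, straight_dendrite_morphology


# -- SWC I/O -----------------------------------------------------------------

def test_read_swc_minimal_tree(tmp_path):
    """A soma plus two chained dendrite nodes is one first-order section."""
    p = tmp_path / "min.swc"
    p.write_text("# minimal\n"
                 "1 1 0 0 0 5 -1\n"
                 "2 3 10 0 0 1 1\n"
                 "3 3 20 0 0 1 2\n")
    m = M.read_swc(p)
    assert len(m.nodes) == 3
    secs = m.sections()
    assert len(secs) == 1
    assert secs[0].order == 1
    assert secs[0].path_distance_at_start == 0.0
    assert secs[0].length == pytest.approx(10.0)  # node2 -> node3 edge only


def test_swc_round_trip_preserves_geometry(tmp_path):
    m = bifurcating_morphology()
    p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
    M.write_swc(m, p1)
    m2 = M.read_swc(p1)
    M.write_swc(m2, p2)
    assert p1.read_text().splitlines()[1:] == p2.read_text().splitlines()[1:]
    assert m2.total_dendritic_length() == pytest.approx(
        m.total_dendritic_length(), rel=1e-6)


def test_read_swc_reports_bad_line_number(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 ten 0 0 1 1\n")
    with pytest.raises(ValueError, match=":2:"):
        M.read_swc(p)


def test_read_swc_rejects_multiple_roots(tmp_path):
    p = tmp_path / "two_roots.swc"
    p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 -1\n")
    with pytest.raises(M.MorphologyError):
        M.read_swc(p)


def test_synthetic_morphology_length_matches_generator_truth():
    from dendarch.synthetic import generate_morphology, olm_spec
    m = generate_morphology(olm_spec(), seed=11)
    truth = m.metadata["true_total_length_um"]
    assert m.total_dendritic_length() == pytest.approx(truth, rel=1e-3)


# -- orders and path distances ----------------------------------------------

def _recount_orders(m):
    """Independent branch-order oracle from raw node topology."""
    soma = {n.id for n in m.soma_nodes()}
    orders = {}
    for sec in m.sections():
        first = sec.node_ids[1] if len(sec.node_ids) > 1 else sec.node_ids[0]
        order = 1
        nid = m.node(first).parent_id
        while nid != -1 and nid not in soma:
            if len(m.children(nid)) > 1:
                order += 1
            nid = m.node(nid).parent_id
        orders[sec.index] = order
    return orders


def test_unbranched_dendrite_single_first_order_section():
    m = straight_dendrite_morphology()
    secs = m.sections()
    assert len(secs) == 1
    assert secs[0].order == 1 and secs[0].path_distance_at_start == 0.0


def test_symmetric_bifurcation_daughters_are_second_order():
    m = bifurcating_morphology(stem=100.0)
    secs = m.sections()
    daughters = [s for s in secs if s.order == 2]
    assert len(daughters) == 2
    for s in daughters:
        assert s.path_distance_at_start == pytest.approx(100.0)


@pytest.mark.parametrize("seed", range(10))
def test_orders_match_independent_recount_on_random_trees(seed):
    from dendarch.synthetic import generate_morphology, olm_spec
    m = generate_morphology(olm_spec(), seed=seed)
    oracle = _recount_orders(m)
    for sec in m.sections():
        assert sec.order == oracle[sec.index]


def test_section_geometry_additive_over_repartition():
    """Splitting edges in half leaves lengths/areas/volumes unchanged."""
    m = bifurcating_morphology()
    # refine: insert midpoints on every edge
    nodes = [m.nodes[0]]
    nid = 1000
    remap = {m.nodes[0].id: m.nodes[0].id}
    new_nodes = []
    for n in m.nodes[1:]:
        p = m.node(n.parent_id)
        mid = M.MorphNode(nid, n.structure, (p.x + n.x) / 2, (p.y + n.y) / 2,
                          (p.z + n.z) / 2, (p.radius + n.radius) / 2,
                          remap[p.id])
        new_nodes.append(mid)
        new_nodes.append(M.MorphNode(n.id, n.structure, n.x, n.y, n.z,
                                     n.radius, nid))
        remap[n.id] = n.id
        nid += 1
    m2 = M.NeuronMorphology([m.nodes[0]] + new_nodes)
    for f in ("length", "membrane_area", "volume"):
        tot1 = sum(getattr(s, f) for s in m.sections())
        tot2 = sum(getattr(s, f) for s in m2.sections())
        assert tot2 == pytest.approx(tot1, rel=1e-9)


# -- discretization ----------------------------------------------------------

def test_halving_d_lambda_does_not_reduce_compartments():
    m = bifurcating_morphology()
    g1 = M.discretize(m, d_lambda=0.1)
    g2 = M.discretize(m, d_lambda=0.05)
    assert g2.n >= g1.n


def test_d_lambda_bound_holds_with_closed_form_dc_lambda():
    """On a uniform cylinder every compartment is below 0.1 lambda_DC."""
    m = straight_dendrite_morphology(length=500.0, radius=1.0)
    p = PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-65.0, ra=100.0)
    g = M.discretize(m, d_lambda=0.1, freq=0.0, passive=p)
    lam = M.lambda_dc(2.0, 1e4, 100.0)
    dend = g.section_index >= 0
    assert np.all(g.length[dend] <= 0.1 * lam * (1 + 1e-12))


def test_compartment_areas_sum_to_section_areas():
    m = bifurcating_morphology()
    g = M.discretize(m, d_lambda=0.05)
    for sec in m.sections():
        mask = g.section_index == sec.index
        assert g.area[mask].sum() == pytest.approx(sec.membrane_area,
                                                   rel=1e-9)


def test_grid_refinement_converges_input_resistance():
    from dendarch.cable import build_model
    m = bifurcating_morphology(stem=200.0, daughter=150.0)
    p = PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-65.0)
    r = [build_model(M.discretize(m, d_lambda=dl, passive=p), p)
         .input_resistance(0) for dl in (0.1, 0.05)]
    assert abs(r[1] - r[0]) / r[0] < 0.005


# -- Sholl -------------------------------------------------------------------

def test_sholl_straight_dendrite_intersections():
    """A 120 um straight dendrite crosses the 50 and 100 um spheres once."""
    m = straight_dendrite_morphology(length=120.0)
    prof = M.sholl(m, dr=50.0)
    assert list(prof.intersections[:3]) == [1, 1, 0]


def test_sholl_length_sums_to_total_length():
    m = bifurcating_morphology()
    prof = M.sholl(m, dr=50.0)
    assert prof.length.sum() == pytest.approx(m.total_dendritic_length(),
                                              rel=1e-6)


def test_sholl_shell_lengths_match_sampling_oracle():
    """Analytic edge clipping equals a dense-sampling oracle."""
    from dendarch.synthetic import generate_morphology, olm_spec
    m = generate_morphology(olm_spec(), seed=5)
    dr = 50.0
    prof = M.sholl(m, dr=dr)
    center = m.soma_center()
    oracle = np.zeros_like(prof.length)
    for sec in m.sections():
        nodes = [m.node(i) for i in sec.node_ids]
        for a, b in zip(nodes[:-1], nodes[1:]):
            c0 = np.array([a.x, a.y, a.z]); c1 = np.array([b.x, b.y, b.z])
            e = np.linalg.norm(c1 - c0)
            ts = np.linspace(0, 1, 4001)
            mids = c0 + np.outer((ts[:-1] + ts[1:]) / 2, c1 - c0)
            dist = np.linalg.norm(mids - center, axis=1)
            k = np.minimum((dist // dr).astype(int), len(oracle) - 1)
            np.add.at(oracle, k, e / 4000)
    assert np.allclose(prof.length, oracle, atol=0.2)


def test_sholl_extent_olm_within_hs_beyond_500um():
    """HS-like trees reach shells beyond 500 um; OLM-like trees do not."""
    from dendarch.synthetic import generate_morphology, hs_spec, olm_spec
    olm = generate_morphology(olm_spec(), seed=2)
    hs = generate_morphology(hs_spec(), seed=2)
    p_olm, p_hs = M.sholl(olm, dr=50.0), M.sholl(hs, dr=50.0)
    beyond = lambda p: p.length[p.radii > 500.0].sum() if np.any(
        p.radii > 500.0) else 0.0
    assert beyond(p_olm) == 0.0
    assert beyond(p_hs) > 0.0


# -- equivalent cylinders ----------------------------------------------------

def test_equivalent_cylinder_exact_cylinder():
    L, d = 10.0, 2.0
    ec = M.equivalent_cylinder(L, math.pi * L, 2 * math.pi * L, math.pi * d)
    assert (ec.d_volume, ec.d_surface, ec.d_perimeter) == pytest.approx(
        (2.0, 2.0, 2.0))


def test_equivalent_cylinder_frustum_closed_form():
    """Frustum L=10, radii 1->2: the three diameters follow closed forms."""
    L, r1, r2 = 10.0, 1.0, 2.0
    V = math.pi * L * (r1 ** 2 + r1 * r2 + r2 ** 2) / 3
    S = math.pi * (r1 + r2) * math.hypot(L, r2 - r1)
    P = math.pi * (r1 + r2)
    ec = M.equivalent_cylinder(L, V, S, P)
    assert ec.d_volume == pytest.approx(2 * math.sqrt(V / (math.pi * L)))
    assert ec.d_volume == pytest.approx(3.055, abs=2e-3)
    assert ec.d_surface == pytest.approx(3.015, abs=2e-3)
    assert ec.d_perimeter == pytest.approx(3.0, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0.2, 5.0), st.floats(1.0, 200.0))
def test_equivalent_cylinder_inverts_on_true_cylinders(d, L):
    ec = M.equivalent_cylinder(L, math.pi * d * d / 4 * L, math.pi * d * L,
                               math.pi * d)
    assert ec.d_volume == pytest.approx(d, rel=1e-12)
    assert ec.d_surface == pytest.approx(d, rel=1e-12)
    assert ec.d_perimeter == pytest.approx(d, rel=1e-12)


def test_equivalent_diameters_rank_correlated_on_synthetic_segments():
    """The three estimates vary together across irregular segments."""
    from scipy.stats import spearmanr
    rng = np.random.default_rng(0)
    d_v, d_s = [], []
    for _ in range(60):
        L = rng.uniform(5, 30)
        r = rng.uniform(0.2, 1.5)
        wob = rng.uniform(1.0, 1.6)           # surface in excess of cylinder
        V = math.pi * r * r * L
        S = math.pi * 2 * r * L * wob
        ec = M.equivalent_cylinder(L, V, S, 2 * math.pi * r * wob ** 0.5)
        d_v.append(ec.d_volume); d_s.append(ec.d_surface)
    rho = spearmanr(d_v, d_s).statistic
    assert rho > 0.5


def test_equivalent_cylinder_zero_length_rejected():
    with pytest.raises(ValueError):
        M.equivalent_cylinder(0.0, 1.0, 1.0, 1.0)


# -- corrections -------------------------------------------------------------

def test_corrections_identity_when_all_factors_one():
    pts = np.random.default_rng(1).uniform(-10, 10, (20, 3))
    out = M.apply_corrections(pts, M.CorrectionFactors())
    assert np.allclose(out, pts)


def test_cf3_scales_single_axis_volume():
    """cf3=1.25 on a unit cube raises volume 1.25x before the isotropic step."""
    cube = np.array([[0, 0, 0], [1, 1, 1.]])
    cf = M.CorrectionFactors(cf3_compression=1.25, cutting_axis=1)
    out = M.apply_corrections(cube, cf)
    sides = out[1] - out[0]
    assert np.prod(sides) == pytest.approx(1.25)
    assert sides[0] == sides[2] == 1.0


def test_volume_scales_by_cf1_cf2_product():
    """cf1*cf2 = 1.2: volumes gain 20%, radii the cube root."""
    cf = M.CorrectionFactors(cf1_volume=1.5, cf2_area=0.8)
    pts = np.array([[1.0, 2.0, 3.0]])
    out, radii = M.apply_corrections(pts, cf, radii=np.array([2.0]))
    assert radii[0] == pytest.approx(2.0 * 1.2 ** (1 / 3))
    assert np.allclose(out, pts * 1.2 ** (1 / 3))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(0.5, 2.0), st.floats(0.5, 2.0))
def test_cf1_cf2_commute(cf1, cf2):
    pts = np.array([[1.0, -2.0, 0.5], [3.0, 0.0, -1.0]])
    a = M.apply_corrections(pts, M.CorrectionFactors(cf1_volume=cf1,
                                                     cf2_area=cf2))
    b = M.apply_corrections(pts, M.CorrectionFactors(cf1_volume=cf2 * cf1,
                                                     cf2_area=1.0))
    c = M.apply_corrections(pts, M.CorrectionFactors(cf1_volume=1.0,
                                                     cf2_area=cf1 * cf2))
    assert np.allclose(a, b) and np.allclose(a, c)


# -- morphometry -------------------------------------------------------------

def test_morphometry_single_unbranched_dendrite():
    m = straight_dendrite_morphology(length=100.0)
    s = M.morphometry_summary(m)
    assert s["total_length_um"] == pytest.approx(100.0, rel=1e-9)
    assert s["nodes"] == 0 and s["endings"] == 1 and s["first_order"] == 1


def test_morphometry_one_bifurcation_counts():
    m = bifurcating_morphology()
    s = M.morphometry_summary(m)
    assert s["nodes"] == 1 and s["endings"] == 2 and s["first_order"] == 1
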