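"""Neuronal morphology data model and morphometry.

A reconstruction is a rooted tree of 3D sample points with radii (the SWC
convention).  Consecutive samples define truncated cones (frusta), whose
lateral areas and volumes are exactly additive under subdivision, so every
derived quantity (section length, membrane area, compartment areas) is
additive over any re-partition of the tree.

The module provides SWC I/O, branch ordering and path distances, spatial
discretization for cable simulation (d-lambda rule), Sholl analysis in
concentric spherical shells around the soma, equivalent-cylinder diameters
for measured segments, and the shrinkage/compression correction factors
applied to EM-derived geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MorphNode",
    "NeuronMorphology",
    "Section",
    "CompartmentGrid",
    "ShollProfile",
    "EquivalentCylinder",
    "CorrectionFactors",
    "read_swc",
    "write_swc",
    "sholl",
    "equivalent_cylinder",
    "apply_corrections",
    "morphometry_summary",
    "lambda_ac",
    "lambda_dc",
    "discretize",
]

# SWC structure identifiers
SOMA = 1
AXON = 2
DENDRITE = 3  # basal; 4 (apical) is also treated as dendrite

_STRUCTURE_NAMES = {SOMA: "soma", AXON: "axon", DENDRITE: "dendrite", 4: "dendrite"}


class MorphologyError(ValueError):
    """Structural problem in a morphology (cycles, multiple roots, bad radii)."""


@dataclass(frozen=True)
class MorphNode:
    """One SWC sample point."""

    id: int
    structure: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def structure_name(self) -> str:
        return _STRUCTURE_NAMES.get(self.structure, "dendrite")


@dataclass
class Section:
    """Unbranched node path between consecutive branch points (or soma/tips).

    ``order`` follows the anatomical convention: first-order sections leave
    the soma, and every daughter is one order higher than its parent.
    """

    index: int
    node_ids: list[int]
    parent_section: int  # -1 for first-order sections
    order: int
    path_distance_at_start: float  # um, along the tree from the soma surface
    length: float  # um
    membrane_area: float  # um^2
    volume: float  # um^3
    structure: int = DENDRITE

    @property
    def mean_diameter(self) -> float:
        """Equal-surface diameter: the cylinder of identical length and area."""
        if self.length == 0:
            return 0.0
        return self.membrane_area / (math.pi * self.length)


def _frustum_area(r1: float, r2: float, length: float) -> float:
    slant = math.hypot(length, r1 - r2)
    return math.pi * (r1 + r2) * slant

def _frustum_volume(r1: float, r2: float, length: float) -> float:
    return math.pi * length * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


class NeuronMorphology:
    """A single reconstructed neuron.

    Parameters
    ----------
    nodes:
        SWC samples, ids unique, every parent preceding its children.
    cell_type:
        "OLM" or "HS" (free-form accepted).
    cell_id:
        identifier carried through exports.
    """

    def __init__(self, nodes: Sequence[MorphNode], cell_type: str = "OLM",
                 cell_id: str = "cell", metadata: dict | None = None):
        self.nodes = list(nodes)
        self.cell_type = cell_type
        self.cell_id = cell_id
        self.metadata = dict(metadata or {})
        self._validate()
        self._index = {n.id: i for i, n in enumerate(self.nodes)}
        self._children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                self._children[n.parent_id].append(n.id)
        self._sections: list[Section] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        seen: set[int] = set()
        roots = 0
        for n in self.nodes:
            if n.id in seen:
                raise MorphologyError(f"duplicate node id {n.id}")
            if n.radius <= 0:
                raise MorphologyError(f"non-positive radius at node {n.id}")
            if n.parent_id == -1:
                roots += 1
            elif n.parent_id not in seen:
                raise MorphologyError(
                    f"node {n.id} references parent {n.parent_id} "
                    "which does not precede it (cycle or multiple roots?)")
            seen.add(n.id)
        if roots != 1:
            raise MorphologyError(f"expected exactly one root, found {roots}")

    def node(self, node_id: int) -> MorphNode:
        return self.nodes[self._index[node_id]]

    def children(self, node_id: int) -> list[int]:
        return self._children[node_id]

    @property
    def root(self) -> MorphNode:
        return self.nodes[0]

    def soma_nodes(self) -> list[MorphNode]:
        return [n for n in self.nodes if n.structure == SOMA]

    def soma_center(self) -> np.ndarray:
        soma = self.soma_nodes() or [self.root]
        return np.mean([[n.x, n.y, n.z] for n in soma], axis=0)

    def soma_surface_area(self) -> float:
        """Somatic membrane area (um^2).

        A single soma sample is read as a sphere of its radius; a sample
        chain is read as a frustum sequence.  An EM-measured override may be
        stored in ``metadata['soma_surface_um2']``.
        """
        if "soma_surface_um2" in self.metadata:
            return float(self.metadata["soma_surface_um2"])
        soma = self.soma_nodes()
        if not soma:
            return 0.0
        if len(soma) == 1:
            return 4.0 * math.pi * soma[0].radius ** 2
        area = 0.0
        for a, b in zip(soma[:-1], soma[1:]):
            length = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            area += _frustum_area(a.radius, b.radius, length)
        return area

    # -- sections ----------------------------------------------------------

    def sections(self, structure: int = DENDRITE) -> list[Section]:
        """Dendritic sections with branch orders and start path distances.

        Branch points, the soma boundary and structure changes delimit
        sections.  Start distance is measured along the tree from the first
        non-soma node of the branch (path distance 0 at the soma surface).
        """
        if self._sections is None:
            self._sections = self._build_sections()
        return [s for s in self._sections if s.structure == structure]

    def _build_sections(self) -> list[Section]:
        soma_ids = {n.id for n in self.soma_nodes()}
        sections: list[Section] = []

        # Section start nodes: children of soma nodes, and children of branch
        # points.  Walk each section to the next branch point or tip.
        def is_branch(nid: int) -> bool:
            return len(self._children[nid]) > 1

        # (start node id, parent section idx, order, start path distance)
        stack: list[tuple[int, int, int, float]] = []
        root_id = self.root.id
        if root_id in soma_ids:
            for sid in soma_ids:
                for c in self._children[sid]:
                    if c not in soma_ids:
                        stack.append((c, -1, 1, 0.0))
        else:
            stack.append((root_id, -1, 1, 0.0))

        while stack:
            start, parent_sec, order, dist0 = stack.pop()
            path = [start]
            node = self.node(start)
            # include the attachment point for geometry but not distance:
            # the first inter-node edge starts at the parent sample unless
            # the parent is a soma node (the soma is not part of the cable).
            prev = node.parent_id
            length = area = volume = 0.0
            if prev != -1 and prev not in soma_ids:
                path.insert(0, prev)
            cur = start
            while True:
                kids = self._children[cur]
                if len(kids) != 1:
                    break
                nxt = kids[0]
                path.append(nxt)
                cur = nxt
            # geometry over the node chain
            for a_id, b_id in zip(path[:-1], path[1:]):
                a, b = self.node(a_id), self.node(b_id)
                seg_len = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                if seg_len == 0:  # coincident samples carry no membrane
                    continue
                length += seg_len
                area += _frustum_area(a.radius, b.radius, seg_len)
                volume += _frustum_volume(a.radius, b.radius, seg_len)
            sec = Section(
                index=len(sections), node_ids=path, parent_section=parent_sec,
                order=order, path_distance_at_start=dist0, length=length,
                membrane_area=area, volume=volume, structure=node.structure)
            sections.append(sec)
            for c in self._children[cur]:
                stack.append((c, sec.index, order + 1, dist0 + length))
        return sections

    # -- morphometry -------------------------------------------------------

    def total_dendritic_length(self) -> float:
        return sum(s.length for s in self.sections(DENDRITE))

    def coordinates(self, structure: int | None = DENDRITE) -> np.ndarray:
        nodes = [n for n in self.nodes
                 if structure is None or n.structure == structure]
        return np.array([[n.x, n.y, n.z] for n in nodes]).reshape(-1, 3)

    def max_euclidean_extent(self) -> float:
        """Largest Euclidean distance of any dendritic sample from the soma."""
        pts = self.coordinates(DENDRITE)
        if pts.size == 0:
            return 0.0
        return float(np.max(np.linalg.norm(pts - self.soma_center(), axis=1)))


def morphometry_summary(m: NeuronMorphology) -> dict[str, float]:
    """Totals over the dendritic structure.

    Returns total dendritic length (um), the number of branch nodes, the
    number of dendritic endings, and the number of first-order dendrites —
    the quantities tabulated for completely reconstructed trees.
    """
    secs = m.sections(DENDRITE)
    children: dict[int, int] = {}
    for s in secs:
        children[s.index] = 0
    for s in secs:
        if s.parent_section >= 0 and s.parent_section in children:
            children[s.parent_section] += 1
    nodes = sum(1 for s in secs if children[s.index] > 1)
    endings = sum(1 for s in secs if children[s.index] == 0)
    return {
        "total_length_um": sum(s.length for s in secs),
        "nodes": nodes,
        "endings": endings,
        "first_order": sum(1 for s in secs if s.order == 1),
    }


# -- SWC I/O ---------------------------------------------------------------

def read_swc(path, cell_type: str = "OLM", cell_id: str | None = None) -> NeuronMorphology:
    """Read a 7-column SWC file.

    Raises a parse error with the offending line number on malformed input
    and a :class:`MorphologyError` on structural problems.
    """
    nodes: list[MorphNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, struct = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            nodes.append(MorphNode(nid, struct, x, y, z, r, parent))
    if cell_id is None:
        cell_id = str(path)
    return NeuronMorphology(nodes, cell_type=cell_type, cell_id=cell_id)


def write_swc(m: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {m.cell_type} {m.cell_id}\n")
        for n in m.nodes:
            fh.write(f"{n.id} {n.structure} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
                     f"{n.radius:.6f} {n.parent_id}\n")


# -- space constant and discretization --------------------------------------

def lambda_ac(diam_um: float, freq_hz: float, ra_ohm_cm: float,
              cm_uf_cm2: float) -> float:
    """AC length constant (um) at frequency ``freq_hz``.

    lambda_f = sqrt(d / (4 pi f Ra Cm)) with the 1e5 factor converting the
    mixed units (um, Ohm cm, uF/cm^2) to um.
    """
    if min(diam_um, freq_hz, ra_ohm_cm, cm_uf_cm2) <= 0:
        raise ValueError("lambda_ac requires positive arguments")
    return 1e5 * math.sqrt(diam_um / (4.0 * math.pi * freq_hz * ra_ohm_cm * cm_uf_cm2))


def lambda_dc(diam_um: float, rm_ohm_cm2: float, ra_ohm_cm: float) -> float:
    """DC length constant (um): lambda = sqrt(d Rm / (4 Ra))."""
    if min(diam_um, rm_ohm_cm2, ra_ohm_cm) <= 0:
        raise ValueError("lambda_dc requires positive arguments")
    return 1e2 * math.sqrt(diam_um * rm_ohm_cm2 / (4.0 * ra_ohm_cm))


@dataclass
class CompartmentGrid:
    """Spatial discretization of a morphology for cable simulation.

    Compartment 0 is the soma.  ``parent[i]`` indexes the adjacent
    compartment toward the soma.  Areas are exactly additive over the
    sections they partition.
    """

    parent: np.ndarray          # (n,) int, -1 for the soma compartment
    length: np.ndarray          # (n,) um (soma: equivalent cylinder length)
    area: np.ndarray            # (n,) um^2
    diameter: np.ndarray        # (n,) um
    path_distance: np.ndarray   # (n,) um at the compartment midpoint
    section_index: np.ndarray   # (n,) int, -1 for the soma
    arc_position: np.ndarray    # (n,) midpoint position in [0,1] within section
    order: np.ndarray           # (n,) int branch order, 0 for the soma

    @property
    def n(self) -> int:
        return len(self.parent)

    def compartment_at(self, section_index: int, arc: float) -> int:
        """Compartment containing arc position ``arc`` of a section."""
        idx = np.flatnonzero(self.section_index == section_index)
        if idx.size == 0:
            raise KeyError(f"no compartments for section {section_index}")
        return int(idx[np.argmin(np.abs(self.arc_position[idx] - arc))])


def discretize(m: NeuronMorphology, d_lambda: float = 0.1, freq: float = 100.0,
               passive=None, min_per_section: int = 1) -> CompartmentGrid:
    """Discretize by the d-lambda rule.

    Each section gets enough compartments that every compartment is shorter
    than ``d_lambda`` times the local space constant, computed per section
    from its equal-surface diameter at ``freq`` Hz (``freq=0`` selects the
    DC constant).  ``passive`` supplies Ra, cm and g_pas (defaults:
    Ra=100 Ohm cm, cm=1 uF/cm^2, g_pas=1e-4 S/cm^2).
    """
    from .cable import PassiveParams  # cycle-free: cable imports nothing from here
    if passive is None:
        passive = PassiveParams()
    if d_lambda <= 0:
        raise ValueError("d_lambda must be positive")

    parent, length, area, diam, pathd, sec_i, arc, order = ([] for _ in range(8))

    # soma compartment: equivalent cylinder of the somatic surface
    s_area = m.soma_surface_area()
    if s_area <= 0:
        raise MorphologyError("morphology has no soma surface")
    s_diam = math.sqrt(s_area / math.pi)  # L = d cylinder with same area
    parent.append(-1); length.append(s_diam); area.append(s_area)
    diam.append(s_diam); pathd.append(0.0); sec_i.append(-1)
    arc.append(0.5); order.append(0)

    sec_first_comp: dict[int, tuple[int, int]] = {}  # sec idx -> (first, last)
    secs = m.sections(DENDRITE)
    by_index = {s.index: s for s in secs}
    # process in index order; parents always have smaller start distance but
    # not necessarily smaller index, so iterate until resolved (tree order).
    pending = sorted(secs, key=lambda s: (s.order, s.path_distance_at_start))
    for sec in pending:
        if sec.length <= 0:
            # degenerate (a branch at the very first sample): alias to the
            # parent's attachment compartment so children stay connected
            par = 0 if sec.parent_section == -1 \
                else sec_first_comp[sec.parent_section][1]
            sec_first_comp[sec.index] = (par, par)
            continue
        d_sec = max(sec.mean_diameter, 1e-3)
        if freq > 0:
            lam = lambda_ac(d_sec, freq, passive.ra, passive.cm)
        else:
            lam = lambda_dc(d_sec, 1.0 / passive.g_pas, passive.ra)
        nseg = max(min_per_section, math.ceil(sec.length / (d_lambda * lam)))
        # per-compartment geometry by clipping node-chain frusta to arc bins
        nodes = [m.node(i) for i in sec.node_ids]
        edge_len = [math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
                    for a, b in zip(nodes[:-1], nodes[1:])]
        cum = np.concatenate([[0.0], np.cumsum(edge_len)])
        total = cum[-1]
        bounds = np.linspace(0.0, total, nseg + 1)

        def radius_at(s: float) -> float:
            j = min(np.searchsorted(cum, s, side="right") - 1, len(edge_len) - 1)
            j = max(j, 0)
            if edge_len[j] == 0:
                return nodes[j].radius
            t = (s - cum[j]) / edge_len[j]
            return nodes[j].radius * (1 - t) + nodes[j + 1].radius * t

        first = len(parent)
        for k in range(nseg):
            s0, s1 = bounds[k], bounds[k + 1]
            # accumulate frustum pieces within [s0, s1]
            a_k = v_k = 0.0
            cuts = [s0] + [c for c in cum if s0 < c < s1] + [s1]
            for u0, u1 in zip(cuts[:-1], cuts[1:]):
                r0, r1 = radius_at(u0), radius_at(u1)
                a_k += _frustum_area(r0, r1, u1 - u0)
                v_k += _frustum_volume(r0, r1, u1 - u0)
            seg_len = s1 - s0
            if k == 0:
                if sec.parent_section == -1:
                    par = 0
                else:
                    par = sec_first_comp[sec.parent_section][1]
            else:
                par = len(parent) - 1
            parent.append(par); length.append(seg_len); area.append(a_k)
            diam.append(a_k / (math.pi * seg_len) if seg_len else 0.0)
            pathd.append(sec.path_distance_at_start + 0.5 * (s0 + s1))
            sec_i.append(sec.index); arc.append(0.5 * (s0 + s1) / total)
            order.append(sec.order)
        sec_first_comp[sec.index] = (first, len(parent) - 1)

    return CompartmentGrid(
        parent=np.asarray(parent, dtype=np.int64),
        length=np.asarray(length), area=np.asarray(area),
        diameter=np.asarray(diam), path_distance=np.asarray(pathd),
        section_index=np.asarray(sec_i, dtype=np.int64),
        arc_position=np.asarray(arc), order=np.asarray(order, dtype=np.int64))


# -- Sholl analysis ----------------------------------------------------------

@dataclass
class ShollProfile:
    radii: np.ndarray          # outer shell radii, k*dr
    intersections: np.ndarray  # crossings of each sphere
    length: np.ndarray         # dendritic length per shell (um)
    area: np.ndarray           # membrane area per shell (um^2)
    volume: np.ndarray         # um^3
    mean_diameter: np.ndarray  # length-weighted, um
    nodes: np.ndarray          # branch points per shell
    endings: np.ndarray        # terminations per shell


def _sphere_crossings(d0: float, d1: float, c0: np.ndarray, c1: np.ndarray,
                      center: np.ndarray, r: float) -> int:
    """Number of times the straight edge c0->c1 crosses the sphere |x-c|=r."""
    p = c0 - center
    d = c1 - c0
    a = float(d @ d)
    if a == 0:
        return 0
    b = 2.0 * float(p @ d)
    c = float(p @ p) - r * r
    disc = b * b - 4 * a * c
    if disc <= 0:
        return 0
    sq = math.sqrt(disc)
    count = 0
    for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if 0.0 <= t < 1.0:
            count += 1
    return count


def sholl(m: NeuronMorphology, dr: float = 50.0) -> ShollProfile:
    """Sholl analysis in concentric spherical shells of width ``dr``.

    Distances are Euclidean from the soma centroid.  Edge lengths are clipped
    analytically against the shell spheres; per-shell areas and volumes are
    apportioned by the in-shell length fraction of each edge.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    center = m.soma_center()
    secs = m.sections(DENDRITE)
    rmax = max(m.max_euclidean_extent(), dr)
    nshell = int(math.ceil(rmax / dr))
    radii = dr * np.arange(1, nshell + 1)
    length = np.zeros(nshell); area = np.zeros(nshell)
    volume = np.zeros(nshell); inter = np.zeros(nshell, dtype=int)
    nodes_c = np.zeros(nshell, dtype=int); endings = np.zeros(nshell, dtype=int)
    dl_sum = np.zeros(nshell)  # for length-weighted diameter

    children: dict[int, int] = {s.index: 0 for s in secs}
    for s in secs:
        if s.parent_section in children:
            children[s.parent_section] += 1

    def shell_of(dist: float) -> int:
        return min(int(dist // dr), nshell - 1)

    for s in secs:
        node_objs = [m.node(i) for i in s.node_ids]
        for a, b in zip(node_objs[:-1], node_objs[1:]):
            c0 = np.array([a.x, a.y, a.z]); c1 = np.array([b.x, b.y, b.z])
            e_len = float(np.linalg.norm(c1 - c0))
            if e_len == 0:
                continue
            e_area = _frustum_area(a.radius, b.radius, e_len)
            e_vol = _frustum_volume(a.radius, b.radius, e_len)
            e_diam = e_area / (math.pi * e_len)
            # partition t in [0,1] at radii crossings
            ts = [0.0, 1.0]
            p = c0 - center; d = c1 - c0
            aa = float(d @ d); bb = 2.0 * float(p @ d)
            for r in radii:
                cc = float(p @ p) - r * r
                disc = bb * bb - 4 * aa * cc
                if disc > 0:
                    sq = math.sqrt(disc)
                    for t in ((-bb - sq) / (2 * aa), (-bb + sq) / (2 * aa)):
                        if 0.0 < t < 1.0:
                            ts.append(t)
            ts = sorted(set(ts))
            for t0, t1 in zip(ts[:-1], ts[1:]):
                mid = c0 + (0.5 * (t0 + t1)) * d
                k = shell_of(float(np.linalg.norm(mid - center)))
                frac = t1 - t0
                length[k] += frac * e_len
                area[k] += frac * e_area
                volume[k] += frac * e_vol
                dl_sum[k] += frac * e_len * e_diam
            for ki, r in enumerate(radii):
                inter[ki] += _sphere_crossings(0, 0, c0, c1, center, r)
        end_node = node_objs[-1]
        dist_end = float(np.linalg.norm(
            np.array([end_node.x, end_node.y, end_node.z]) - center))
        if children[s.index] == 0:
            endings[shell_of(dist_end)] += 1
        elif children[s.index] > 1:
            nodes_c[shell_of(dist_end)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(length > 0, dl_sum / np.maximum(length, 1e-300), 0.0)
    return ShollProfile(radii=radii, intersections=inter, length=length,
                        area=area, volume=volume, mean_diameter=mean_d,
                        nodes=nodes_c, endings=endings)


# -- equivalent cylinders ----------------------------------------------------

@dataclass(frozen=True)
class EquivalentCylinder:
    """Three diameter estimates for a measured segment of fixed length.

    d_volume matches the segment's volume, d_surface its membrane surface,
    d_perimeter its average cross-sectional perimeter.  All three coincide
    for an exact circular cylinder.
    """

    length: float
    d_volume: float
    d_surface: float
    d_perimeter: float


def equivalent_cylinder(length: float, volume: float, surface: float,
                        mean_perimeter: float) -> EquivalentCylinder:
    if length <= 0:
        raise ValueError("segment length must be positive")
    if min(volume, surface, mean_perimeter) <= 0:
        raise ValueError("volume, surface and perimeter must be positive")
    return EquivalentCylinder(
        length=length,
        d_volume=2.0 * math.sqrt(volume / (math.pi * length)),
        d_surface=surface / (math.pi * length),
        d_perimeter=mean_perimeter / math.pi,
    )


# -- correction factors ------------------------------------------------------

@dataclass(frozen=True)
class CorrectionFactors:
    """Tissue-processing corrections applied to EM geometry.

    cf1: native/fixed brain volume ratio (perfusion shrinkage).
    cf2: reference/processed section area ratio (dehydration/embedding).
    cf3: block-face width / EM section width along the cutting axis
         (diamond-knife compression; applied to exactly one axis).
    """

    cf1_volume: float = 1.0
    cf2_area: float = 1.0
    cf3_compression: float = 1.0
    cutting_axis: int = 1  # 0=x, 1=y, 2=z

    def __post_init__(self):
        if min(self.cf1_volume, self.cf2_area, self.cf3_compression) <= 0:
            raise ValueError("correction factors must be positive")

    @property
    def isotropic_linear(self) -> float:
        """Linear factor of the combined cf1*cf2 volume correction."""
        return (self.cf1_volume * self.cf2_area) ** (1.0 / 3.0)


def apply_corrections(coords: np.ndarray, cf: CorrectionFactors,
                      radii: np.ndarray | None = None):
    """Correct raw EM coordinates (n,3) for shrinkage and compression.

    First the cutting axis is stretched by cf3 (decompression), then all
    linear dimensions are scaled by (cf1*cf2)^(1/3) so volumes scale by
    cf1*cf2.  Radii, if given, take only the isotropic step.
    """
    out = np.array(coords, dtype=float, copy=True)
    out[..., cf.cutting_axis] *= cf.cf3_compression
    out *= cf.isotropic_linear
    if radii is not None:
        return out, np.asarray(radii, dtype=float) * cf.isotropic_linear
    return out


def correct_morphology(m: NeuronMorphology, cf: CorrectionFactors) -> NeuronMorphology:
    coords = np.array([[n.x, n.y, n.z] for n in m.nodes])
    radii = np.array([n.radius for n in m.nodes])
    coords, radii = apply_corrections(coords, cf, radii)
    nodes = [MorphNode(n.id, n.structure, *xyz, r, n.parent_id)
             for n, xyz, r in zip(m.nodes, coords, radii)]
    return NeuronMorphology(nodes, m.cell_type, m.cell_id, m.metadata)
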