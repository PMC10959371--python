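"""Shared fixtures: small analytic geometries and model builders."""

import math

import numpy as np
import pytest

from dendarch.cable import PassiveParams, build_model
from dendarch.morphology import (DENDRITE, SOMA, CompartmentGrid, MorphNode,
                                 NeuronMorphology)


def make_cylinder_grid(L=1000.0, d=2.0, n=200):
    """Uniform unbranched cable, no soma (pure cylinder oracle geometry)."""
    h = L / n
    return CompartmentGrid(
        parent=np.arange(-1, n - 1), length=np.full(n, h),
        area=np.full(n, math.pi * d * h), diameter=np.full(n, d),
        path_distance=(np.arange(n) + 0.5) * h,
        section_index=np.zeros(n, np.int64),
        arc_position=(np.arange(n) + 0.5) / n,
        order=np.ones(n, np.int64))


def make_soma_cable_grid(n=20, L=400.0, d=1.5, soma_area=900.0):
    """Soma compartment plus one uniform dendrite."""
    h = L / n
    s_d = math.sqrt(soma_area / math.pi)
    return CompartmentGrid(
        parent=np.concatenate([[-1], np.arange(n)]),
        length=np.concatenate([[s_d], np.full(n, h)]),
        area=np.concatenate([[soma_area], np.full(n, math.pi * d * h)]),
        diameter=np.concatenate([[s_d], np.full(n, d)]),
        path_distance=np.concatenate([[0.0], (np.arange(n) + 0.5) * h]),
        section_index=np.concatenate([[-1], np.zeros(n, np.int64)]).astype(np.int64),
        arc_position=np.concatenate([[0.5], (np.arange(n) + 0.5) / n]),
        order=np.concatenate([[0], np.ones(n, np.int64)]).astype(np.int64))


def straight_dendrite_morphology(length=120.0, step=10.0, radius=0.5,
                                 soma_radius=5.0):
    """Soma sphere plus one straight dendrite along +x.

    The first dendrite sample sits at the soma centre so the measured
    dendritic length equals ``length`` exactly.
    """
    nodes = [MorphNode(1, SOMA, 0.0, 0.0, 0.0, soma_radius, -1)]
    n = int(length / step)
    for i in range(n + 1):
        nodes.append(MorphNode(2 + i, DENDRITE, i * step, 0.0, 0.0,
                               radius, 1 + i))
    return NeuronMorphology(nodes)


def bifurcating_morphology(stem=100.0, daughter=80.0, step=10.0, radius=0.6):
    """Soma, one stem of exact length ``stem``, symmetric bifurcation, two
    daughters of exact length ``daughter`` each."""
    nodes = [MorphNode(1, SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    nid = 2
    for i in range(int(stem / step) + 1):
        nodes.append(MorphNode(nid, DENDRITE, i * step, 0.0, 0.0,
                               radius, nid - 1))
        nid += 1
    fork = nid - 1
    for direction in (1.0, -1.0):
        parent = fork
        for i in range(int(daughter / step)):
            x = stem + (i + 1) * step * math.cos(math.pi / 4)
            y = direction * (i + 1) * step * math.sin(math.pi / 4)
            nodes.append(MorphNode(nid, DENDRITE, x, y, 0.0, radius, parent))
            parent = nid
            nid += 1
    return NeuronMorphology(nodes)


@pytest.fixture
def cylinder_grid():
    return make_cylinder_grid()


@pytest.fixture
def soma_cable_grid():
    return make_soma_cable_grid()


@pytest.fixture
def passive_model(soma_cable_grid):
    return build_model(soma_cable_grid,
                       PassiveParams(cm=1.0, g_pas=1e-4, e_pas=-65.0))
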