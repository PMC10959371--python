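"""Synapse-density regression and projection onto full morphologies.

The number of synapses per unit membrane area on a dendritic segment is
modelled as a linear function of the segment's distance from the soma and
its diameter:

    density = a + b * distance + c * diameter        (per um^2)

fitted by ordinary least squares per cell type and synapse kind.  Predicted
densities, clipped at zero, times the membrane area of each compartment of
a discretized morphology give real-valued expected synapse counts, which
are binned by somatic distance, summarized by skewness, and sampled from
when discrete synapse placements are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .emstats import SegmentRecord, StatSummary, _describe, segment_metrics
from .morphology import CompartmentGrid

__all__ = [
    "DensityModel", "PredictedCounts", "SynapseDistribution", "PlacedSynapse",
    "fit_density_model", "predict_counts", "bin_distribution",
    "compare_skewness", "place_synapses", "weighted_skewness",
]


@dataclass
class DensityModel:
    """Linear synapse-density model for one cell type x synapse kind.

    Coefficients: ``a`` (um^-2 intercept), ``b`` (um^-2 per um of somatic
    distance), ``c`` (um^-2 per um of diameter).  Predicted densities are
    clipped at zero so no segment ever receives a negative expected count.
    """

    cell_type: str
    synapse_kind: str
    a: float
    b: float
    c: float
    stderr: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    r2: float = np.nan
    r2_adj: float = np.nan
    n: int = 0

    def density(self, distance_um, diameter_um) -> np.ndarray:
        d = self.a + self.b * np.asarray(distance_um, float) \
            + self.c * np.asarray(diameter_um, float)
        return np.clip(d, 0.0, None)

    def as_dict(self) -> dict:
        return {"cell_type": self.cell_type, "synapse_kind": self.synapse_kind,
                "a": self.a, "b": self.b, "c": self.c,
                "stderr": list(self.stderr), "r2": self.r2,
                "r2_adj": self.r2_adj, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "DensityModel":
        return cls(cell_type=d["cell_type"], synapse_kind=d["synapse_kind"],
                   a=d["a"], b=d["b"], c=d["c"],
                   stderr=tuple(d.get("stderr", (np.nan,) * 3)),
                   r2=d.get("r2", np.nan), r2_adj=d.get("r2_adj", np.nan),
                   n=d.get("n", 0))


def _segment_diameter(r: SegmentRecord, which: str = "surface") -> float:
    """Equivalent diameter of a measured segment.

    Defaults to the equal-surface diameter (densities are area-referenced);
    "volume" and "perimeter" variants are available.
    """
    if which == "surface":
        return r.surface_um2 / (np.pi * r.length_um)
    if which == "volume":
        return 2.0 * np.sqrt(r.volume_um3 / (np.pi * r.length_um))
    if which == "perimeter":
        p = r.annotations.get("mean_perimeter_um")
        if p is None:
            raise ValueError("record lacks mean_perimeter_um annotation")
        return float(p) / np.pi
    raise ValueError(f"unknown diameter definition {which!r}")


def fit_density_model(records, synapse_kind: str = "glut",
                      cell_type: str | None = None,
                      predictors=("distance", "diameter"),
                      diameter_def: str = "surface") -> DensityModel:
    """Fit the density regression by unweighted OLS over dendritic segments.

    The response is synapses of ``synapse_kind`` per um^2 of membrane.
    Records are pooled across cells within a cell type.  Requires at least
    three more records than predictors.  Collinear predictors raise a
    singular-fit error.
    """
    recs = [r for r in records if r.kind == "dendrite"
            and (cell_type is None or r.cell_type == cell_type)
            and r.surface_um2 > 0 and r.length_um > 0]
    k = len(predictors)
    if len(recs) < k + 3:
        raise ValueError(f"need at least {k + 3} dendritic segments, "
                         f"have {len(recs)}")
    y = np.array([r.count(synapse_kind) / r.surface_um2 for r in recs])
    cols = []
    for p in predictors:
        if p == "distance":
            cols.append([r.distance_um for r in recs])
        elif p == "diameter":
            cols.append([_segment_diameter(r, diameter_def) for r in recs])
        elif p == "order":
            cols.append([float(r.order) for r in recs])
        else:
            raise ValueError(f"unknown predictor {p!r}")
    X = sm.add_constant(np.column_stack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear predictors: singular fit")
    fit = sm.OLS(y, X).fit()
    coef = dict(zip(["const"] + list(predictors), fit.params))
    se = dict(zip(["const"] + list(predictors), fit.bse))
    ct = cell_type or (recs[0].cell_type if recs else "pooled")
    return DensityModel(
        cell_type=ct, synapse_kind=synapse_kind,
        a=float(coef.get("const", 0.0)),
        b=float(coef.get("distance", 0.0)),
        c=float(coef.get("diameter", 0.0)),
        stderr=(float(se.get("const", np.nan)),
                float(se.get("distance", np.nan)),
                float(se.get("diameter", np.nan))),
        r2=float(fit.rsquared), r2_adj=float(fit.rsquared_adj), n=len(recs))


def rank_predictor_sets(records, synapse_kind="glut", cell_type=None,
                        candidate_sets=(("distance",), ("diameter",),
                                        ("distance", "diameter"),
                                        ("distance", "order"),
                                        ("order", "diameter"))):
    """Rank candidate predictor sets by adjusted R^2 (best first)."""
    fits = []
    for ps in candidate_sets:
        try:
            m = fit_density_model(records, synapse_kind, cell_type,
                                  predictors=ps)
            fits.append((ps, m.r2_adj, m))
        except (ValueError, np.linalg.LinAlgError):
            continue
    return sorted(fits, key=lambda t: -t[1])


@dataclass
class PredictedCounts:
    """Real-valued expected synapse counts per compartment, per kind."""

    grid: CompartmentGrid
    counts: dict[str, np.ndarray]       # kind -> (n,) expected counts
    densities: dict[str, np.ndarray]    # kind -> (n,) per um^2

    def total(self, kind: str) -> float:
        return float(self.counts[kind].sum())

    def totals(self) -> dict[str, float]:
        return {k: self.total(k) for k in self.counts}

    def gaba_fraction_pct(self, exc="glut", inh="gaba") -> float:
        te, ti = self.total(exc), self.total(inh)
        return 100.0 * ti / (te + ti)


def predict_counts(models, grid: CompartmentGrid,
                   include_soma: bool = True) -> PredictedCounts:
    """Expected synapse counts per compartment for each density model.

    count_i = clip(a + b*distance_i + c*diameter_i, 0) * area_i.  The soma
    compartment uses distance 0 and its equivalent-cylinder diameter; set
    ``include_soma=False`` to restrict to dendrites.
    """
    if isinstance(models, DensityModel):
        models = [models]
    counts, dens = {}, {}
    soma_mask = grid.section_index < 0
    for m in models:
        d = m.density(grid.path_distance, grid.diameter)
        if not include_soma:
            d = np.where(soma_mask, 0.0, d)
        dens[m.synapse_kind] = d
        counts[m.synapse_kind] = d * grid.area
    return PredictedCounts(grid=grid, counts=counts, densities=dens)


# -- distributions -----------------------------------------------------------

def weighted_skewness(values: np.ndarray, weights: np.ndarray) -> float:
    """Fisher-Pearson moment skewness of a weighted sample.

    Returns 0.0 for a degenerate (zero-variance) distribution; callers that
    need to distinguish that case should test the variance themselves.
    """
    w = np.asarray(weights, float)
    x = np.asarray(values, float)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    mu = np.average(x, weights=w)
    m2 = np.average((x - mu) ** 2, weights=w)
    if m2 <= 0:
        return 0.0
    m3 = np.average((x - mu) ** 3, weights=w)
    return float(m3 / m2 ** 1.5)


@dataclass
class SynapseDistribution:
    """Synapse counts binned by somatic path distance."""

    bin_edges: np.ndarray        # (nbins+1,) um
    counts: dict[str, np.ndarray]
    skewness: dict[str, float]
    degenerate: dict[str, bool] = field(default_factory=dict)

    def total(self, kind: str) -> float:
        return float(self.counts[kind].sum())


def bin_distribution(pc: PredictedCounts, bin_um: float = 50.0
                     ) -> SynapseDistribution:
    """Bin expected counts by path distance (default 50 um bins) and
    compute the count-weighted skewness of the distance distribution."""
    if bin_um <= 0:
        raise ValueError("bin width must be positive")
    dist = pc.grid.path_distance
    edges = np.arange(0.0, dist.max() + bin_um, bin_um)
    if len(edges) < 2:
        edges = np.array([0.0, bin_um])
    counts, skew, degen = {}, {}, {}
    for kind, c in pc.counts.items():
        h, _ = np.histogram(dist, bins=edges, weights=c)
        counts[kind] = h
        skew[kind] = weighted_skewness(dist, c)
        nonempty = int(np.sum(h > 0))
        degen[kind] = nonempty <= 2
    return SynapseDistribution(bin_edges=edges, counts=counts,
                               skewness=skew, degenerate=degen)


def compare_skewness(group_a, group_b, label_a="A", label_b="B") -> StatSummary:
    """Welch two-sample t test on per-cell skewness values."""
    from scipy import stats as sps
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two skewness values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.allclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero variance in both groups: t undefined")
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return StatSummary(
        variable="skewness", test="welch-t",
        groups={label_a: _describe(a), label_b: _describe(b)},
        statistic=float(t), p=float(p))


# -- sampling ----------------------------------------------------------------

@dataclass(frozen=True)
class PlacedSynapse:
    """A discrete synapse placed on a compartment."""

    compartment: int
    section_index: int
    arc_position: float
    path_distance: float
    kind: str


def place_synapses(pc: PredictedCounts, n: int | None = None,
                   fraction: float | None = None, kind: str = "glut",
                   distance_range: tuple[float, float] | None = None,
                   seed: int | np.random.Generator = 0,
                   dendrites_only: bool = True) -> list[PlacedSynapse]:
    """Sample discrete synapse placements from the predicted distribution.

    Placement probability per compartment is proportional to its expected
    count, restricted to ``distance_range`` (um) when given.  Exactly one
    of ``n`` and ``fraction`` selects the sample size (``fraction`` of the
    expected count in range, rounded).  Sampling is with replacement and
    reproducible under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = pc.counts[kind].astype(float).copy()
    if dendrites_only:
        w[pc.grid.section_index < 0] = 0.0
    if distance_range is not None:
        lo, hi = distance_range
        w[(pc.grid.path_distance < lo) | (pc.grid.path_distance > hi)] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError("no expected synapses in the requested range")
    if (n is None) == (fraction is None):
        raise ValueError("specify exactly one of n and fraction")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        n = int(round(fraction * total))
    if n < 0:
        raise ValueError("n must be non-negative")
    comp = rng.choice(len(w), size=n, p=w / total)
    g = pc.grid
    return [PlacedSynapse(compartment=int(i),
                          section_index=int(g.section_index[i]),
                          arc_position=float(g.arc_position[i]),
                          path_distance=float(g.path_distance[i]),
                          kind=kind)
            for i in comp]
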