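"""Descriptive and inferential statistics of EM-reconstructed segments.

One record describes one 3D-reconstructed piece of membrane — a dendritic
segment, a branching point, a (full or partial) soma, or an axonal segment —
with its geometry, mitochondrial content and the excitatory (putative
glutamatergic) and inhibitory (putative GABAergic, gephyrin-positive)
synapses it carries.  The module ingests such tables from delimited text,
computes per-segment densities and fractions, and runs the group
comparisons used throughout the study: Mann-Whitney U between groups,
Spearman rank correlations within groups, and the Bonferroni convention for
the large physiological feature screen.

All synapses on a segment inherit the segment's start distance from the
soma (segments are short relative to the dendrites, so within-segment
position is ignored).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynapseRecord", "SegmentRecord", "StatSummary",
    "read_segment_table", "write_segment_table", "segment_metrics",
    "group_summary", "correlate", "compare_paired_classes",
    "bonferroni_threshold", "gaba_fraction_from_counts",
    "linear_density_extrapolation", "DISTANCE_BANDS",
]

#: distance bands used for proximal / middle / distal comparisons (um)
DISTANCE_BANDS = ((0.0, 100.0), (100.0, 250.0), (250.0, float("inf")))

SEGMENT_COLUMNS = ["cell_type", "cell_id", "segment_id", "kind",
                   "distance_um", "order", "length_um", "surface_um2",
                   "volume_um3", "mito_volume_um3", "n_glut", "n_gaba"]
SYNAPSE_COLUMNS = ["segment_id", "kind", "area_um2", "on_spine", "host"]


@dataclass(frozen=True)
class SynapseRecord:
    """One reconstructed synaptic contact."""

    kind: str                 # "glut" or "gaba"
    area: float               # um^2
    on_spine: bool = False
    host: str = "dendrite"    # dendrite | soma | axon_output

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("synapse area must be positive")


@dataclass
class SegmentRecord:
    """One EM-reconstructed segment with geometry and synapse lists."""

    cell_type: str
    cell_id: str
    segment_id: str
    kind: str                 # dendrite | branch_point | soma_full | soma_partial | axon
    distance_um: float        # start point along the tree from the soma
    order: int
    length_um: float
    surface_um2: float
    volume_um3: float
    mito_volume_um3: float
    synapses: list[SynapseRecord] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mito_volume_um3 > self.volume_um3 + 1e-12:
            raise ValueError(
                f"segment {self.segment_id}: mitochondria exceed volume")
        if self.distance_um < 0:
            raise ValueError("distance must be non-negative")
        if self.kind == "dendrite" and self.order < 1:
            raise ValueError("dendritic order must be >= 1")

    def count(self, kind: str) -> float:
        """Synapse count of a kind; real-valued counts (expected numbers
        from calibration generators) are passed through unrounded."""
        n = self.annotations.get(f"n_{kind}")
        if n is not None:
            return float(n)
        return float(sum(1 for s in self.synapses if s.kind == kind))

    def synapse_areas(self, kind: str) -> np.ndarray:
        return np.array([s.area for s in self.synapses if s.kind == kind])


@dataclass
class StatSummary:
    """Per-group descriptives plus the test that compared them."""

    variable: str
    groups: dict[str, dict]   # name -> {n, median, q1, q3}
    test: str = ""
    statistic: float = float("nan")
    p: float = float("nan")
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"variable": self.variable, "groups": self.groups,
                "test": self.test, "statistic": self.statistic, "p": self.p,
                **self.extra}


def _describe(values) -> dict:
    v = np.asarray(values, float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"n": int(v.size), "median": float(med),
            "q1": float(q1), "q3": float(q3)}


# -- table I/O ---------------------------------------------------------------

class SchemaError(ValueError):
    pass


def read_segment_table(path, synapse_path=None, dialect: dict | None = None
                       ) -> list[SegmentRecord]:
    """Read a delimited segment table (and optional per-synapse table).

    Mandatory columns: cell_type, cell_id, segment_id, kind, distance_um,
    order, length_um, surface_um2, volume_um3, mito_volume_um3.  Synapse
    counts come either from n_glut/n_gaba columns or from the synapse table
    (columns segment_id, kind, area_um2, on_spine, host).  Unknown columns
    are preserved as annotations.
    """
    opts = {"sep": None, "engine": "python"}
    opts.update(dialect or {})
    df = pd.read_csv(path, **opts)
    missing = [c for c in SEGMENT_COLUMNS[:10] if c not in df.columns]
    if missing:
        raise SchemaError(f"segment table is missing columns: {missing}")
    syn_by_seg: dict[str, list[SynapseRecord]] = {}
    if synapse_path is not None:
        sdf = pd.read_csv(synapse_path, **opts)
        smissing = [c for c in SYNAPSE_COLUMNS[:3] if c not in sdf.columns]
        if smissing:
            raise SchemaError(f"synapse table is missing columns: {smissing}")
        for _, row in sdf.iterrows():
            rec = SynapseRecord(
                kind=str(row["kind"]), area=float(row["area_um2"]),
                on_spine=bool(row["on_spine"]) if "on_spine" in sdf else False,
                host=str(row["host"]) if "host" in sdf else "dendrite")
            syn_by_seg.setdefault(str(row["segment_id"]), []).append(rec)
    records = []
    known = set(SEGMENT_COLUMNS)
    for _, row in df.iterrows():
        ann = {c: row[c] for c in df.columns if c not in known}
        for c in ("n_glut", "n_gaba"):
            if c in df.columns:
                ann[c] = float(row[c])
        records.append(SegmentRecord(
            cell_type=str(row["cell_type"]), cell_id=str(row["cell_id"]),
            segment_id=str(row["segment_id"]), kind=str(row["kind"]),
            distance_um=float(row["distance_um"]), order=int(row["order"]),
            length_um=float(row["length_um"]),
            surface_um2=float(row["surface_um2"]),
            volume_um3=float(row["volume_um3"]),
            mito_volume_um3=float(row["mito_volume_um3"]),
            synapses=syn_by_seg.get(str(row["segment_id"]), []),
            annotations=ann))
    return records


def write_segment_table(records: list[SegmentRecord], path,
                        synapse_path=None) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in SEGMENT_COLUMNS[:10]}
        row["n_glut"] = r.count("glut")
        row["n_gaba"] = r.count("gaba")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if synapse_path is not None:
        srows = [{"segment_id": r.segment_id, "kind": s.kind,
                  "area_um2": s.area, "on_spine": s.on_spine, "host": s.host}
                 for r in records for s in r.synapses]
        pd.DataFrame(srows, columns=SYNAPSE_COLUMNS).to_csv(
            synapse_path, index=False)


# -- per-segment metrics -----------------------------------------------------

def gaba_fraction_from_counts(n_gaba: float, n_glut: float) -> float:
    """Percentage of inhibitory inputs among all inputs."""
    total = n_gaba + n_glut
    if total <= 0:
        raise ValueError("no synapses: GABA fraction undefined")
    return 100.0 * n_gaba / total


def segment_metrics(r: SegmentRecord, min_inputs_for_fraction: int = 10
                    ) -> dict:
    """Surface and linear synapse densities, coverage, and fractions.

    The inhibitory percentage is reported only on segments whose total
    input count reaches ``min_inputs_for_fraction`` (default 10); on
    sparser segments it is None (undefined, not zero).
    """
    if r.surface_um2 <= 0:
        raise ValueError("segment surface must be positive")
    ng, ni = r.count("glut"), r.count("gaba")
    total = ng + ni
    out = {
        "glut_per_um2": ng / r.surface_um2,
        "gaba_per_um2": ni / r.surface_um2,
        "glut_per_um": ng / r.length_um if r.length_um > 0 else np.nan,
        "gaba_per_um": ni / r.length_um if r.length_um > 0 else np.nan,
        "mito_fraction_pct": 100.0 * r.mito_volume_um3 / r.volume_um3
        if r.volume_um3 > 0 else np.nan,
    }
    areas = [s.area for s in r.synapses]
    out["coverage_fraction"] = (sum(areas) / r.surface_um2) if areas else 0.0
    if total >= max(min_inputs_for_fraction, 1):
        out["gaba_fraction_pct"] = gaba_fraction_from_counts(ni, ng)
    else:
        out["gaba_fraction_pct"] = None  # undefined (too few inputs), not 0
    return out


# -- inference ---------------------------------------------------------------

def _mannwhitney(a, b) -> tuple[float, float, str]:
    a = np.asarray(a, float); b = np.asarray(b, float)
    exact = (a.size + b.size) <= 20 and len(np.unique(np.concatenate([a, b]))) \
        == a.size + b.size
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def _value_of(r, variable, metric_kwargs):
    if callable(variable):
        return variable(r)
    if hasattr(r, variable):
        return getattr(r, variable)
    return segment_metrics(r, **(metric_kwargs or {}))[variable]


def group_summary(records, variable, grouping="cell_type",
                  metric_kwargs: dict | None = None) -> StatSummary:
    """Compare a per-segment variable between two groups (Mann-Whitney U).

    ``variable`` may be a SegmentRecord attribute, a key of
    :func:`segment_metrics`, or a callable record -> float.  ``grouping``
    is an attribute name or callable; exactly two non-empty groups are
    required.  The exact U distribution is used for combined n <= 20
    without ties, the tie-corrected normal approximation otherwise.
    """
    def group_of(r):
        return grouping(r) if callable(grouping) else getattr(r, grouping)

    groups: dict[str, list[float]] = {}
    for r in records:
        v = _value_of(r, variable, metric_kwargs)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        groups.setdefault(str(group_of(r)), []).append(float(v))
    if len(groups) != 2 or any(len(v) == 0 for v in groups.values()):
        raise ValueError(f"need exactly two non-empty groups, got "
                         f"{ {k: len(v) for k, v in groups.items()} }")
    (na, va), (nb, vb) = sorted(groups.items())
    u, p, method = _mannwhitney(va, vb)
    name = variable if isinstance(variable, str) else variable.__name__
    return StatSummary(
        variable=name,
        groups={na: _describe(va), nb: _describe(vb)},
        test=f"mann-whitney-u ({method})", statistic=u, p=p)


def correlate(records, x, y, metric_kwargs: dict | None = None) -> StatSummary:
    """Spearman rank correlation between two per-record variables."""
    xs, ys = [], []
    for r in records:
        vx = _value_of(r, x, metric_kwargs)
        vy = _value_of(r, y, metric_kwargs)
        if vx is None or vy is None:
            continue
        if np.isfinite(vx) and np.isfinite(vy):
            xs.append(float(vx)); ys.append(float(vy))
    if len(xs) < 3:
        raise ValueError("Spearman correlation needs at least 3 paired values")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise ValueError("constant variable: Spearman rho undefined")
    rho, p = stats.spearmanr(xs, ys)
    xname = x if isinstance(x, str) else x.__name__
    yname = y if isinstance(y, str) else y.__name__
    return StatSummary(
        variable=f"spearman({xname}, {yname})",
        groups={"pooled": _describe(xs)},
        test="spearman", statistic=float(rho), p=float(p),
        extra={"n": len(xs)})


def compare_paired_classes(records, selector_a, selector_b,
                           label_a="A", label_b="B",
                           value=lambda s: s.area) -> StatSummary:
    """Compare synapse-level values between two synapse subsets.

    Selectors are predicates over (segment, synapse) pairs — e.g. spine vs
    shaft synapses, somatic vs proximal-dendritic synapses, or distance
    bands.  Mann-Whitney U, two-sided.
    """
    va, vb = [], []
    for r in records:
        for s in r.synapses:
            if selector_a(r, s):
                va.append(float(value(s)))
            elif selector_b(r, s):
                vb.append(float(value(s)))
    if not va or not vb:
        raise ValueError("one of the synapse subsets is empty")
    u, p, method = _mannwhitney(va, vb)
    return StatSummary(
        variable=f"{label_a} vs {label_b}",
        groups={label_a: _describe(va), label_b: _describe(vb)},
        test=f"mann-whitney-u ({method})", statistic=u, p=p)


def distance_band_selector(band: tuple[float, float], kind: str = "glut"):
    lo, hi = band
    return lambda r, s: (s.kind == kind and s.host == "dendrite"
                         and lo <= r.distance_um < hi)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m for m simultaneous comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def linear_density_extrapolation(axon_length_um: float,
                                 synapses_per_um: float) -> float:
    """Total synapse count from axon length x linear synapse density."""
    if axon_length_um < 0 or synapses_per_um < 0:
        raise ValueError("length and density must be non-negative")
    return axon_length_um * synapses_per_um
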