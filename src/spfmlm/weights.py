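"""Spatial weight matrices over neighborhoods.

Binary, symmetric contiguity weights: ``v_ij = 1`` when areas *i* and *j* are
neighbors, 0 otherwise, with a zero diagonal.  No row-standardization is
applied anywhere in the package — both the Moran statistic and the eigenvector
extraction consume the raw binary entries.

Construction paths: Queen contiguity from polygons, an explicit edge list, or
a GAL neighbor-list file.  All paths funnel through :class:`SpatialWeights`,
which validates symmetry, the zero diagonal, and id uniqueness on creation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpatialWeights",
    "build_queen_contiguity",
    "from_edge_list",
    "read_gal",
    "write_gal",
    "read_edge_csv",
    "read_geojson",
    "islands",
]


class WeightsError(ValueError):
    """Invalid spatial-weights input (asymmetry, bad ids, malformed file)."""


def _order_ids(ids: Iterable[str], explicit: Sequence[str] | None) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise WeightsError(f"duplicate area ids: {dupes}")
    if explicit is not None:
        if sorted(explicit) != sorted(ids):
            raise WeightsError("explicit ordering must be a permutation of the area ids")
        return list(explicit)
    # default: lexical order, shared by every matrix and vector downstream
    return sorted(ids)


@dataclass(frozen=True)
class SpatialWeights:
    """Symmetric binary adjacency among ``n_areas`` areas.

    Parameters
    ----------
    area_ids
        Ordered area identifiers; internal indexing is 0-based in this order.
    matrix
        Dense 0/1 adjacency, symmetric with zero diagonal.
    """

    area_ids: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise WeightsError("weight matrix must be square")
        if m.shape[0] != len(self.area_ids):
            raise WeightsError("matrix size does not match number of area ids")
        if len(set(self.area_ids)) != len(self.area_ids):
            raise WeightsError("duplicate area ids")
        if not np.array_equal(m, m.T):
            i, j = np.argwhere(m != m.T)[0]
            raise WeightsError(
                f"asymmetric weights: v[{self.area_ids[i]},{self.area_ids[j]}] != "
                f"v[{self.area_ids[j]},{self.area_ids[i]}]"
            )
        if np.any(np.diag(m) != 0):
            raise WeightsError("nonzero diagonal entry (self-neighbor)")
        if not np.all((m == 0) | (m == 1)):
            raise WeightsError("weights must be binary 0/1")
        object.__setattr__(self, "matrix", m)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def s0(self) -> float:
        """Sum of all entries, Σ_i Σ_j v_ij."""
        return float(self.matrix.sum())

    @property
    def cardinalities(self) -> np.ndarray:
        """Neighbor count per area (row sums)."""
        return self.matrix.sum(axis=1)

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise WeightsError(f"unknown area id: {area_id!r}") from None

    def neighbors(self, area_id: str) -> list[str]:
        i = self.index_of(area_id)
        return [self.area_ids[j] for j in np.flatnonzero(self.matrix[i])]

    def subset(self, keep: Sequence[str]) -> "SpatialWeights":
        """Restrict to the given areas (order preserved from ``keep``)."""
        idx = [self.index_of(a) for a in keep]
        return SpatialWeights(tuple(keep), self.matrix[np.ix_(idx, idx)])

    def drop_islands(self) -> "SpatialWeights":
        keep = [a for a, c in zip(self.area_ids, self.cardinalities) if c > 0]
        if not keep:
            raise WeightsError("all areas are islands")
        return self.subset(keep)


def build_queen_contiguity(
    polygons: Mapping[str, object], ordering: Sequence[str] | None = None
) -> SpatialWeights:
    """Queen-contiguity weights: neighbors share at least one boundary point.

    ``polygons`` maps area id → shapely geometry.  Two areas are coded 1 when
    their geometries share a boundary segment *or* a single vertex.
    """
    from shapely import STRtree
    from shapely.geometry.base import BaseGeometry

    if not polygons:
        raise WeightsError("empty polygon collection")
    ids = _order_ids(polygons.keys(), ordering)
    geoms = []
    for a in ids:
        g = polygons[a]
        if not isinstance(g, BaseGeometry) or g.is_empty:
            raise WeightsError(f"invalid or empty geometry for area {a!r}")
        if not g.is_valid:
            raise WeightsError(f"invalid geometry for area {a!r}")
        geoms.append(g)
    n = len(ids)
    m = np.zeros((n, n))
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    for i, j in zip(left, right):
        if i != j:
            m[i, j] = m[j, i] = 1.0
    return SpatialWeights(tuple(ids), m)


def from_edge_list(
    edges: Iterable[tuple[str, str]],
    area_ids: Sequence[str],
    ordering: Sequence[str] | None = None,
) -> SpatialWeights:
    """Build weights from undirected edges; symmetric closure, duplicates collapsed."""
    ids = _order_ids(area_ids, ordering)
    pos = {a: k for k, a in enumerate(ids)}
    m = np.zeros((len(ids), len(ids)))
    for a, b in edges:
        if a == b:
            raise WeightsError(f"self-loop on area {a!r}")
        for x in (a, b):
            if x not in pos:
                raise WeightsError(f"unknown area id in edge list: {x!r}")
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = 1.0
    return SpatialWeights(tuple(ids), m)


def read_edge_csv(path: str | Path, area_ids: Sequence[str] | None = None) -> SpatialWeights:
    """Read an edge-list CSV with columns ``src,dst``."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    for col in ("src", "dst"):
        if col not in df.columns:
            raise WeightsError(f"edge CSV missing column {col!r}")
    edges = list(zip(df["src"], df["dst"]))
    if area_ids is None:
        area_ids = sorted({a for e in edges for a in e})
    return from_edge_list(edges, area_ids)


def read_geojson(path: str | Path, id_field: str) -> SpatialWeights:
    """Queen contiguity from a GeoJSON FeatureCollection keyed by ``id_field``."""
    import json

    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise WeightsError("expected a GeoJSON FeatureCollection")
    polys: dict[str, object] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise WeightsError(f"feature missing id field {id_field!r}")
        aid = str(props[id_field])
        if aid in polys:
            raise WeightsError(f"duplicate area ids: ['{aid}']")
        polys[aid] = shape(feat["geometry"])
    return build_queen_contiguity(polys)


def read_gal(path: str | Path) -> SpatialWeights:
    """Read a GAL neighbor-list file.

    Accepts the plain header (``n``) and the 4-token pysal-style header, whose
    second token is the area count.  Neighbor lists must be symmetric.
    """
    raw = Path(path).read_text().splitlines()
    lines = [ln for ln in raw if ln.strip()]
    if not lines:
        raise WeightsError("empty GAL file")
    head = lines[0].split()
    n_declared = int(head[1]) if len(head) == 4 else int(head[0])
    tokens = [t for ln in lines[1:] for t in ln.split()]
    neigh: dict[str, list[str]] = {}
    order: list[str] = []
    pos = 0
    for _ in range(n_declared):
        if pos + 2 > len(tokens):
            raise WeightsError(f"GAL declares {n_declared} areas but the body ends early")
        aid, cnt_s = tokens[pos], tokens[pos + 1]
        pos += 2
        try:
            cnt = int(cnt_s)
        except ValueError:
            raise WeightsError(f"malformed neighbor count for area {aid!r}: {cnt_s!r}") from None
        if pos + cnt > len(tokens):
            raise WeightsError(f"area {aid!r}: declared {cnt} neighbors, body ends early")
        neigh[aid] = tokens[pos : pos + cnt]
        pos += cnt
        order.append(aid)
    if pos != len(tokens):
        raise WeightsError("trailing tokens after the declared GAL body")
    for a, nbrs in neigh.items():
        for b in nbrs:
            if b not in neigh:
                raise WeightsError(f"neighbor {b!r} of {a!r} is not a declared area")
            if a not in neigh[b]:
                raise WeightsError(f"asymmetric neighbor lists: {a!r} lists {b!r} but not vice versa")
    edges = [(a, b) for a, nbrs in neigh.items() for b in nbrs if a < b]
    return from_edge_list(edges, order, ordering=order)


def write_gal(weights: SpatialWeights, path: str | Path) -> None:
    """Write ``weights`` as a GAL neighbor-list file (read∘write is identity)."""
    out = [str(weights.n_areas)]
    for i, aid in enumerate(weights.area_ids):
        nbrs = [weights.area_ids[j] for j in np.flatnonzero(weights.matrix[i])]
        out.append(f"{aid} {len(nbrs)}")
        out.append(" ".join(nbrs))
    Path(path).write_text("\n".join(out) + "\n")


def islands(weights: SpatialWeights) -> list[str]:
    """Area ids with zero neighbors."""
    return [a for a, c in zip(weights.area_ids, weights.cardinalities) if c == 0]
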