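"""Neighborhood graphs over areal units.

Areal disease-mapping models borrow strength between geographically adjacent
units, so every model in this package is parameterised by a symmetric binary
adjacency structure W (w_ij = 1 iff areas i and j are neighbors).  This module
builds that structure from edge lists, GAL neighbor files, regular lattices or
polygon collections (queen contiguity), validates it, and precomputes the
spectral quantities the Leroux sampler needs: degrees d_i and the eigenvalues
of the graph Laplacian D - W, which give the log-determinant of the Leroux
precision rho*(D - W) + (1 - rho)*I in O(n) per evaluation.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "graph_from_edge_list",
    "graph_from_polygons",
    "structure_eigenvalues",
    "leroux_precision",
]


class AdjacencyGraph:
    """Symmetric, binary, loop-free neighborhood structure over areal units.

    Parameters
    ----------
    area_ids
        Ordered unique identifiers, one per area.  Order fixes the index
        convention used by every vector in the package.
    edges
        Undirected index pairs ``(i, j)`` with ``i != j``; duplicates and
        orientation are normalised away.

    Attributes
    ----------
    n : number of areas.
    degrees : integer array, d_i = number of neighbors of area i.
    neighbors : list of sorted integer arrays, neighbors[i] = indices j ~ i.
    """

    def __init__(self, area_ids: Sequence, edges: Iterable[tuple[int, int]]):
        area_ids = list(area_ids)
        if len(set(area_ids)) != len(area_ids):
            raise ValueError("duplicate area ids")
        self.area_ids = area_ids
        self.n = len(area_ids)
        self.index = {a: i for i, a in enumerate(area_ids)}

        seen: set[tuple[int, int]] = set()
        for i, j in edges:
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"edge ({i}, {j}) out of range for n={self.n}")
            if i == j:
                raise ValueError(f"self-loop at index {i} not allowed")
            seen.add((min(i, j), max(i, j)))
        self.edges = sorted(seen)

        nb: list[list[int]] = [[] for _ in range(self.n)]
        for i, j in self.edges:
            nb[i].append(j)
            nb[j].append(i)
        self.neighbors = [np.array(sorted(x), dtype=np.intp) for x in nb]
        self.degrees = np.array([len(x) for x in nb], dtype=np.intp)

        isolates = int(np.sum(self.degrees == 0))
        if isolates and self.n > 1:
            logger.warning(
                "%d area(s) have no neighbors; the Leroux conditional for them "
                "reduces to N(0, tau2/(1-rho))", isolates)

        self._eigenvalues: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_edge_list(cls, area_ids: Sequence, edges: Iterable[tuple]) -> "AdjacencyGraph":
        """Build from edges given as pairs of area ids (not indices)."""
        index = {a: i for i, a in enumerate(area_ids)}
        if len(index) != len(list(area_ids)):
            raise ValueError("duplicate area ids")
        idx_edges = []
        for a, b in edges:
            if a not in index:
                raise ValueError(f"unknown area id in edge: {a!r}")
            if b not in index:
                raise ValueError(f"unknown area id in edge: {b!r}")
            idx_edges.append((index[a], index[b]))
        return cls(area_ids, idx_edges)

    @classmethod
    def lattice(cls, nx: int, ny: int) -> "AdjacencyGraph":
        """Regular nx-by-ny grid with rook (edge-sharing) adjacency."""
        if nx < 1 or ny < 1:
            raise ValueError("lattice dimensions must be positive")
        ids = [f"A{r * nx + c:04d}" for r in range(ny) for c in range(nx)]
        edges = []
        for r in range(ny):
            for c in range(nx):
                i = r * nx + c
                if c + 1 < nx:
                    edges.append((i, i + 1))
                if r + 1 < ny:
                    edges.append((i, i + nx))
        return cls(ids, edges)

    @classmethod
    def from_gal(cls, path) -> "AdjacencyGraph":
        """Read a GAL neighbor file (plain-text spatial weights format)."""
        with open(path) as fh:
            tokens = fh.read().split("\n")
        lines = [ln.strip() for ln in tokens if ln.strip()]
        if not lines:
            raise ValueError("empty GAL file")
        header = lines[0].split()
        # header is either "n" or "0 n <shp> <key>"
        n = int(header[1]) if len(header) > 1 else int(header[0])
        ids: list[str] = []
        raw: list[tuple[str, list[str]]] = []
        k = 1
        for _ in range(n):
            ident, deg = lines[k].split()[0], int(lines[k].split()[1])
            neigh = lines[k + 1].split() if deg > 0 else []
            if deg > 0:
                k += 2
            else:
                # a zero-degree record may or may not carry an (empty) line
                k += 1
                if k < len(lines) and len(lines[k].split()) == 0:
                    k += 1
            if len(neigh) != deg:
                raise ValueError(f"GAL record for {ident}: expected {deg} neighbors, got {len(neigh)}")
            ids.append(ident)
            raw.append((ident, neigh))
        edges = [(ident, other) for ident, neigh in raw for other in neigh]
        return cls.from_edge_list(ids, edges)

    def to_gal(self, path) -> None:
        """Write the graph as a GAL neighbor file; round-trips exactly."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, a in enumerate(self.area_ids):
                fh.write(f"{a} {self.degrees[i]}\n")
                if self.degrees[i]:
                    fh.write(" ".join(str(self.area_ids[j]) for j in self.neighbors[i]) + "\n")

    @classmethod
    def from_edge_csv(cls, path) -> "AdjacencyGraph":
        """Read an edge-list CSV with columns ``src,dst``; ids are the union of endpoints."""
        import pandas as pd

        df = pd.read_csv(path, dtype=str)
        if not {"src", "dst"}.issubset(df.columns):
            raise ValueError("edge-list CSV must have columns 'src' and 'dst'")
        ids = sorted(set(df["src"]) | set(df["dst"]))
        return cls.from_edge_list(ids, list(zip(df["src"], df["dst"])))

    @classmethod
    def from_geojson(cls, source, id_property: str = "area_id") -> "AdjacencyGraph":
        """Queen contiguity from a GeoJSON FeatureCollection.

        Areas sharing at least one boundary point are neighbors (queen
        contiguity, the common default for irregular administrative units).
        ``source`` may be a path or an already-parsed mapping.
        """
        from shapely.errors import GEOSException
        from shapely.geometry import shape
        from shapely.strtree import STRtree

        if isinstance(source, dict):
            obj = source
        elif hasattr(source, "read"):
            obj = json.load(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        feats = obj.get("features", [])
        ids, geoms = [], []
        for k, feat in enumerate(feats):
            props = feat.get("properties") or {}
            if id_property not in props:
                raise ValueError(f"feature {k} lacks property {id_property!r}")
            ident = props[id_property]
            if ident in ids:
                raise ValueError(f"duplicate area id {ident!r} in feature {k}")
            try:
                geom = shape(feat["geometry"])
            except (GEOSException, ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"invalid geometry for feature {ident!r}: {exc}") from exc
            if geom.is_empty or geom.geom_type not in ("Polygon", "MultiPolygon"):
                raise ValueError(f"feature {ident!r} is not a polygonal geometry")
            ids.append(ident)
            geoms.append(geom)
        tree = STRtree(geoms)
        # queen contiguity: geometries intersect in at least a point
        edges = []
        for i, g in enumerate(geoms):
            for j in map(int, tree.query(g)):
                if j <= i:
                    continue
                inter = g.intersection(geoms[j])
                if not inter.is_empty:
                    edges.append((i, j))
        return cls(ids, edges)

    # ------------------------------------------------------------------ #
    # derived structure

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix W."""
        if not self.edges:
            return sp.csr_matrix((self.n, self.n))
        rows = [i for i, j in self.edges] + [j for i, j in self.edges]
        cols = [j for i, j in self.edges] + [i for i, j in self.edges]
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W."""
        L = -self.adjacency_matrix().toarray()
        L[np.diag_indices(self.n)] = self.degrees
        return L

    def structure_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of D - W, ascending; cached after the first call.

        The number of (numerically) zero eigenvalues equals the number of
        connected components.  All eigenvalues are >= 0 (Laplacian PSD).
        """
        if self._eigenvalues is None:
            lam = np.linalg.eigvalsh(self.laplacian())
            lam[np.abs(lam) < 1e-12] = 0.0
            self._eigenvalues = lam
        return self._eigenvalues

    @property
    def n_components(self) -> int:
        ncomp, _ = connected_components(self.adjacency_matrix(), directed=False)
        return int(ncomp)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def subgraph(self, keep_ids: Sequence) -> "AdjacencyGraph":
        """Induced subgraph on ``keep_ids`` (order taken from the argument)."""
        keep = list(keep_ids)
        missing = [a for a in keep if a not in self.index]
        if missing:
            raise ValueError(f"unknown area ids: {missing[:5]}")
        old = [self.index[a] for a in keep]
        remap = {o: k for k, o in enumerate(old)}
        edges = [(remap[i], remap[j]) for i, j in self.edges if i in remap and j in remap]
        return AdjacencyGraph(keep, edges)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AdjacencyGraph(n={self.n}, edges={self.n_edges}, components={self.n_components})"


def graph_from_edge_list(area_ids: Sequence, edges: Iterable[tuple]) -> AdjacencyGraph:
    """Functional alias for :meth:`AdjacencyGraph.from_edge_list`."""
    return AdjacencyGraph.from_edge_list(area_ids, edges)


def graph_from_polygons(source, id_property: str = "area_id") -> AdjacencyGraph:
    """Functional alias for :meth:`AdjacencyGraph.from_geojson` (queen contiguity)."""
    return AdjacencyGraph.from_geojson(source, id_property=id_property)


def structure_eigenvalues(graph: AdjacencyGraph) -> np.ndarray:
    """Eigenvalues of D - W for ``graph`` (ascending, cached on the graph)."""
    return graph.structure_eigenvalues()


def leroux_precision(graph: AdjacencyGraph, rho: float, tau2: float) -> np.ndarray:
    """Dense Leroux precision Q = [rho*(D - W) + (1 - rho)*I] / tau2.

    Positive definite for rho in [0, 1) and tau2 > 0: its eigenvalues are
    (rho*lambda_k + 1 - rho)/tau2 >= (1 - rho)/tau2 > 0.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1) for a proper Leroux precision")
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    return (rho * graph.laplacian() + (1.0 - rho) * np.eye(graph.n)) / tau2
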