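"""Structured meshes of the two-phase spherical cell.

The reference geometry is a nucleus of radius 5 µm concentric inside a
cell of radius 10 µm.  Exploiting symmetry, two discretizations are built:

* a 3D octant (X, Y, Z >= 0) with 10-node quadratic tetrahedra, produced by
  radially layering a latitude/longitude grid and splitting each (possibly
  degenerate) hexahedral cell with the translation-invariant Kuhn scheme,
  which guarantees a conforming triangulation;
* an axisymmetric quarter disc in the (R, Z) half-plane with 6-node
  quadratic triangles.

A grid layer is placed exactly on the nucleus-cytoplasm interface (r = 5),
so the interface is conforming, and a latitude row is placed exactly at the
Dirichlet band edge.  Mid-edge nodes of edges lying on a constant-radius
layer are snapped to that sphere/circle, so curved facets are integrated
isoparametrically.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .fem import FESpace, RefTet10, RefTri6

NUCLEUS, CYTOPLASM = 0, 1
_TOL = 1e-9


@dataclasses.dataclass
class Mesh:
    """Reference-configuration FE mesh with phase labels and tagged sets.

    ``conn`` follows VTK quadratic orderings (tetra10 / triangle6).
    ``node_sets`` maps tag names to node-index arrays; ``facet_tags`` maps
    tag names to arrays of corner-node tuples (for conformity checks and
    export).  ``h`` is the target edge length the mesh was built for.
    """

    dim: int
    coords: np.ndarray            # (nnodes, dim) µm
    conn: np.ndarray              # (nel, 10|6)
    phase: np.ndarray             # (nel,) NUCLEUS | CYTOPLASM
    node_sets: dict
    facet_tags: dict
    r_nucleus: float
    r_cell: float
    band_halfwidth_deg: float
    h: float

    @property
    def nnodes(self) -> int:
        return len(self.coords)

    @property
    def nelements(self) -> int:
        return len(self.conn)

    def radius(self, nodes=None) -> np.ndarray:
        c = self.coords if nodes is None else self.coords[nodes]
        return np.linalg.norm(c, axis=1)

    def latitude_deg(self, nodes=None) -> np.ndarray:
        """Latitude above the equatorial plane, degrees (3D: asin(z/r);
        2D axisymmetric: atan2(Z, R))."""
        c = self.coords if nodes is None else self.coords[nodes]
        r = np.linalg.norm(c, axis=1)
        z = c[:, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            lat = np.degrees(np.arcsin(np.clip(z / np.where(r > 0, r, 1.0), -1, 1)))
        lat[r == 0] = 0.0
        return lat


def _radial_layers(r_nucleus, r_cell, n_rn, n_rc):
    return np.concatenate([
        np.linspace(0.0, r_nucleus, n_rn + 1),
        np.linspace(r_nucleus, r_cell, n_rc + 1)[1:],
    ])


def _latitude_rows(band_deg, n_lat):
    """Row latitudes in degrees with a row exactly at the band edge; the
    band interval is subdivided at a spacing comparable to the upper part."""
    upper = np.linspace(band_deg, 90.0, n_lat + 1)
    dlat = (90.0 - band_deg) / n_lat
    nb = max(1, round(band_deg / dlat))
    lower = np.linspace(0.0, band_deg, nb + 1)[:-1]
    return np.concatenate([lower, upper])


def _counts_from_h(r_nucleus, r_cell, h, band_deg):
    n_rn = max(2, round(r_nucleus / h))
    n_rc = max(2, round((r_cell - r_nucleus) / h))
    arc = math.radians(90.0 - band_deg) * r_cell
    n_lat = max(3, round(arc / h))
    n_phi = max(3, round(math.radians(90.0) * r_cell / h))
    return n_rn, n_rc, n_lat, n_phi


def _snap_midnodes(coords, edge_nodes):
    """Snap mid-edge nodes whose endpoints share a radius onto that sphere."""
    for (n1, n2), mid in edge_nodes.items():
        r1 = np.linalg.norm(coords[n1])
        r2 = np.linalg.norm(coords[n2])
        if r1 > _TOL and abs(r1 - r2) <= 1e-8 * max(r1, 1.0):
            p = coords[mid]
            nrm = np.linalg.norm(p)
            if nrm > _TOL:
                coords[mid] = p * (r1 / nrm)


def build_octant_mesh(r_nucleus: float = 5.0, r_cell: float = 10.0,
                      h: float = 1.4, band_halfwidth: float = 5.0,
                      counts: tuple | None = None) -> Mesh:
    """Octant mesh of the two concentric spheres with quadratic tetrahedra.

    ``band_halfwidth`` (degrees of latitude) fixes the edge of the Dirichlet
    band on the outer surface; a latitude row is placed exactly there.
    ``counts`` optionally overrides (n_r_nucleus, n_r_cyto, n_lat, n_phi).
    """
    if not 0 < r_nucleus < r_cell:
        raise ValueError("need 0 < r_nucleus < r_cell")
    if h <= 0:
        raise ValueError("h must be positive")
    if not 0 < band_halfwidth < 45:
        raise ValueError("band_halfwidth must be in (0, 45) degrees")
    n_rn, n_rc, n_lat, n_phi = counts or _counts_from_h(
        r_nucleus, r_cell, h, band_halfwidth)
    if min(n_rn, n_rc) < 1 or n_lat < 2 or n_phi < 2:
        raise ValueError("h too coarse to resolve the interface and the band")

    radii = _radial_layers(r_nucleus, r_cell, n_rn, n_rc)
    lats = np.radians(_latitude_rows(band_halfwidth, n_lat))
    phis = np.radians(np.linspace(0.0, 90.0, n_phi + 1))
    nr, nt, np_ = len(radii), len(lats), len(phis)

    coords = []
    ids = {}

    def node(ir, it, ip):
        if ir == 0:
            key = ("c",)
        elif it == nt - 1:          # pole: phi collapses
            key = ("p", ir)
        else:
            key = (ir, it, ip)
        if key not in ids:
            r, la = radii[ir], lats[min(it, nt - 1)]
            if key == ("c",):
                coords.append((0.0, 0.0, 0.0))
            elif key[0] == "p":
                coords.append((0.0, 0.0, r))
            else:
                ph = phis[ip]
                coords.append((r * math.cos(la) * math.cos(ph),
                               r * math.cos(la) * math.sin(ph),
                               r * math.sin(la)))
            ids[key] = len(coords) - 1
        return ids[key]

    perms = list(itertools.permutations(range(3)))
    tets, phases = [], []
    for ir in range(nr - 1):
        for it in range(nt - 1):
            for ip in range(np_ - 1):
                corner = {}
                for d in itertools.product((0, 1), repeat=3):
                    corner[d] = node(ir + d[0], it + d[1], ip + d[2])
                for perm in perms:
                    path = [(0, 0, 0)]
                    cur = [0, 0, 0]
                    for ax in perm:
                        cur[ax] += 1
                        path.append(tuple(cur))
                    tet = [corner[p] for p in path]
                    if len(set(tet)) < 4:
                        continue
                    tets.append(tet)
                    phases.append(NUCLEUS if radii[ir + 1] <= r_nucleus + 1e-9
                                  else CYTOPLASM)
    coords = np.array(coords, float)
    tets = np.array(tets, int)

    # orient positively
    v = coords[tets]
    vol6 = np.linalg.det(v[:, 1:] - v[:, :1])
    flip = vol6 < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    keep = np.abs(vol6) > 1e-12
    tets, phases = tets[keep], np.array(phases)[keep]

    coords, conn, edge_nodes = _add_midedge_nodes(coords, tets, RefTet10.edges)
    _snap_midnodes(coords, edge_nodes)

    mesh = Mesh(3, coords, conn, phases, {}, {}, r_nucleus, r_cell,
                band_halfwidth, h)
    _tag_octant(mesh)
    FESpace(mesh, degree=2)   # validate positive mapping Jacobians
    return mesh


def _add_midedge_nodes(coords, cells, edge_list):
    """Append unique mid-edge nodes; return (coords, quadratic conn, edges)."""
    coords = list(map(tuple, coords))
    edge_nodes = {}
    conn = []
    for cell in cells:
        row = list(cell)
        for (i, j) in edge_list:
            key = (min(cell[i], cell[j]), max(cell[i], cell[j]))
            if key not in edge_nodes:
                mid = tuple((np.array(coords[key[0]]) + coords[key[1]]) / 2.0)
                coords.append(mid)
                edge_nodes[key] = len(coords) - 1
            row.append(edge_nodes[key])
        conn.append(row)
    return np.array(coords, float), np.array(conn, int), edge_nodes


def _tag_octant(mesh: Mesh):
    tol = 1e-6 * mesh.r_cell
    r = mesh.radius()
    lat = mesh.latitude_deg()
    c = mesh.coords
    ns = mesh.node_sets
    ns["sym_x"] = np.flatnonzero(np.abs(c[:, 0]) < tol)
    ns["sym_y"] = np.flatnonzero(np.abs(c[:, 1]) < tol)
    ns["sym_z"] = np.flatnonzero(np.abs(c[:, 2]) < tol)
    ns["outer"] = np.flatnonzero(np.abs(r - mesh.r_cell) < tol)
    ns["interface"] = np.flatnonzero(np.abs(r - mesh.r_nucleus) < tol)
    ns["dirichlet_band"] = np.flatnonzero(
        (np.abs(r - mesh.r_cell) < tol)
        & (lat <= mesh.band_halfwidth_deg + 1e-9))
    if len(ns["dirichlet_band"]) == 0:
        raise ValueError("mesh resolves no Dirichlet band nodes")
    mesh.facet_tags.update(_boundary_facets_3d(mesh))


def _corner_faces(conn):
    """Corner-node faces of each tet (sorted triples)."""
    f = []
    for loc in [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]:
        f.append(np.sort(conn[:, loc], axis=1))
    return np.concatenate(f, axis=0)          # (4*nel, 3)


def _boundary_facets_3d(mesh: Mesh):
    faces = _corner_faces(mesh.conn)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    bdry = uniq[counts == 1]
    tol = 1e-6 * mesh.r_cell
    c, out = mesh.coords, {}
    r = np.linalg.norm(c, axis=1)

    def allmatch(pred):
        return bdry[np.all(pred[bdry], axis=1)]

    out["outer"] = allmatch(np.abs(r - mesh.r_cell) < tol)
    out["sym_x"] = allmatch(np.abs(c[:, 0]) < tol)
    out["sym_y"] = allmatch(np.abs(c[:, 1]) < tol)
    out["sym_z"] = allmatch(np.abs(c[:, 2]) < tol)
    lat = mesh.latitude_deg()
    on_outer = np.abs(r - mesh.r_cell) < tol
    out["dirichlet_band"] = bdry[np.all(
        (on_outer & (lat <= mesh.band_halfwidth_deg + 1e-9))[bdry], axis=1)]
    # interface facets: internal faces whose corners all sit at r_nucleus
    on_if = np.abs(r - mesh.r_nucleus) < tol
    internal = uniq[counts == 2]
    out["interface"] = internal[np.all(on_if[internal], axis=1)]
    return out


def interface_facet_phase_check(mesh: Mesh) -> bool:
    """True iff every interface facet is shared by exactly one nucleus and
    one cytoplasm element (conformity invariant)."""
    if mesh.dim == 3:
        faces = _corner_faces(mesh.conn)
        per_el = 4
        key = mesh.facet_tags["interface"]
    else:
        faces = _corner_edges(mesh.conn)
        per_el = 3
        key = mesh.facet_tags["interface"]
    el_idx = np.tile(np.arange(mesh.nelements), per_el)
    lookup = {}
    for row, el in zip(map(tuple, faces), el_idx):
        lookup.setdefault(row, []).append(el)
    for f in map(tuple, key):
        els = lookup.get(f, [])
        if len(els) != 2:
            return False
        ph = sorted(mesh.phase[e] for e in els)
        if ph != [NUCLEUS, CYTOPLASM]:
            return False
    return True


# ---------------------------------------------------------------------------
# Axisymmetric quarter disc

def _corner_edges(conn):
    e = []
    for loc in [(0, 1), (1, 2), (2, 0)]:
        e.append(np.sort(conn[:, loc], axis=1))
    return np.concatenate(e, axis=0)


def build_axisymmetric_mesh(r_nucleus: float = 5.0, r_cell: float = 10.0,
                            h: float = 0.35, band_halfwidth: float = 5.0,
                            counts: tuple | None = None) -> Mesh:
    """Quarter disc in the (R, Z) half-plane with quadratic triangles.

    Coordinates are (R, Z), R the cylindrical radius.  Tags: ``axis``
    (R = 0), ``sym_z`` (Z = 0), ``outer`` arc, ``dirichlet_band`` (outer arc
    within the band latitude), ``interface`` (r = r_nucleus arc).
    """
    if not 0 < r_nucleus < r_cell:
        raise ValueError("need 0 < r_nucleus < r_cell")
    if h <= 0:
        raise ValueError("h must be positive")
    if counts is None:
        n_rn = max(2, round(r_nucleus / h))
        n_rc = max(2, round((r_cell - r_nucleus) / h))
        n_lat = max(3, round(math.radians(90 - band_halfwidth) * r_cell / h))
    else:
        n_rn, n_rc, n_lat = counts
    radii = _radial_layers(r_nucleus, r_cell, n_rn, n_rc)
    lats = np.radians(_latitude_rows(band_halfwidth, n_lat))
    nr, nt = len(radii), len(lats)

    coords, ids = [], {}

    def node(ir, it):
        key = ("c",) if ir == 0 else (ir, it)
        if key not in ids:
            if key == ("c",):
                coords.append((0.0, 0.0))
            else:
                r, la = radii[ir], lats[it]
                coords.append((r * math.cos(la), r * math.sin(la)))
            ids[key] = len(coords) - 1
        return ids[key]

    tris, phases = [], []
    for ir in range(nr - 1):
        for it in range(nt - 1):
            c00, c10 = node(ir, it), node(ir + 1, it)
            c01, c11 = node(ir, it + 1), node(ir + 1, it + 1)
            for tri in ([c00, c10, c11], [c00, c11, c01]):
                if len(set(tri)) < 3:
                    continue
                tris.append(tri)
                phases.append(NUCLEUS if radii[ir + 1] <= r_nucleus + 1e-9
                              else CYTOPLASM)
    coords = np.array(coords, float)
    tris = np.array(tris, int)
    v = coords[tris]
    d1, d2 = v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]
    area2 = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    flip = area2 < 0
    tris[flip, 1], tris[flip, 2] = tris[flip, 2].copy(), tris[flip, 1].copy()

    coords, conn, edge_nodes = _add_midedge_nodes(coords, tris, RefTri6.edges)
    _snap_midnodes(coords, edge_nodes)

    mesh = Mesh(2, coords, conn, np.array(phases), {}, {}, r_nucleus, r_cell,
                band_halfwidth, h)
    tol = 1e-6 * r_cell
    r = mesh.radius()
    lat = mesh.latitude_deg()
    ns = mesh.node_sets
    ns["axis"] = np.flatnonzero(np.abs(mesh.coords[:, 0]) < tol)
    ns["sym_z"] = np.flatnonzero(np.abs(mesh.coords[:, 1]) < tol)
    ns["outer"] = np.flatnonzero(np.abs(r - r_cell) < tol)
    ns["interface"] = np.flatnonzero(np.abs(r - r_nucleus) < tol)
    ns["dirichlet_band"] = np.flatnonzero(
        (np.abs(r - r_cell) < tol) & (lat <= band_halfwidth + 1e-9))
    edges = _corner_edges(conn)
    uniq, counts_ = np.unique(edges, axis=0, return_counts=True)
    on_if = np.abs(r - r_nucleus) < tol
    internal = uniq[counts_ == 2]
    mesh.facet_tags["interface"] = internal[np.all(on_if[internal], axis=1)]
    FESpace(mesh, degree=2)
    return mesh
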