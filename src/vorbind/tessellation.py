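"""Weighted Voronoi (power / Laguerre) tessellation of heavy atoms.

Each atom is a weighted site (weight = squared van der Waals radius). The
power cell of site i is the set of points p with
``|p - c_i|^2 - w_i <= |p - c_j|^2 - w_j`` for every other site j, clipped
here to an axis-aligned bounding box expanded by a padding margin. Faces
against the box are counted as solvent-exposed surface; faces against atoms
of another residue accumulate into residue-residue contact area.

Cells are built one at a time as halfspace intersections: every bisector
(radical plane) contributes the halfspace ``2(c_j - c_i) . p <= (|c_j|^2 -
w_j) - (|c_i|^2 - w_i)`` and the box contributes six more. For speed, only
nearby sites are offered initially; the resulting cell vertices are then
verified against *all* sites and the cell is rebuilt with any violating
sites added, so the final diagram is exact, not approximate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError, cKDTree

from .structure_model import ResidueKey, Structure

logger = logging.getLogger(__name__)

#: sentinel neighbor id for box (solvent-facing) faces
BOUNDARY = -1

#: van der Waals radii in angstrom; weights are the squares
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70

#: contact areas below this are treated as zero
AREA_EPS = 1e-9


@dataclass(frozen=True)
class WeightedSite:
    center: tuple[float, float, float]
    weight: float
    owner: tuple[ResidueKey, int] | None = None

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("site weight must be positive")


@dataclass
class Face:
    neighbor: int  # site index or BOUNDARY
    area: float


@dataclass
class Cell:
    volume: float
    faces: list[Face] = field(default_factory=list)


@dataclass
class Tessellation:
    sites: list[WeightedSite]
    cells: list[Cell]
    box_lo: np.ndarray
    box_hi: np.ndarray

    @property
    def box_volume(self) -> float:
        return float(np.prod(self.box_hi - self.box_lo))

    def total_cell_volume(self) -> float:
        return sum(c.volume for c in self.cells)

    def face_area(self, i: int, j: int) -> float:
        for f in self.cells[i].faces:
            if f.neighbor == j:
                return f.area
        return 0.0


@dataclass
class ResidueAreas:
    res_type: str
    total: float = 0.0
    surface: float = 0.0
    contact: dict[ResidueKey, float] = field(default_factory=dict)

    @property
    def surface_ratio(self) -> float:
        if self.total <= 0:
            raise ValueError("residue has no tessellation cell (total area 0)")
        return self.surface / self.total


def sites_from_structure(structure: Structure, radii: dict[str, float] | None = None) -> list[WeightedSite]:
    """Weighted sites for every heavy atom (weight = vdW radius squared)."""
    table = VDW_RADII if radii is None else radii
    sites = []
    for sub in structure.subunits:
        for res in sub.residues:
            for idx, atom in enumerate(res.atoms):
                if not atom.is_heavy:
                    continue
                r = table.get(atom.element, DEFAULT_RADIUS)
                sites.append(WeightedSite(atom.coord, r * r, (res.key, idx)))
    return sites


def _box_halfspaces(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # A x + b <= 0 rows for the six box planes
    hs = []
    for ax in range(3):
        row = np.zeros(4)
        row[ax], row[3] = 1.0, -hi[ax]
        hs.append(row.copy())
        row[ax], row[3] = -1.0, lo[ax]
        hs.append(row.copy())
    return np.asarray(hs)


def _bisector_halfspaces(centers: np.ndarray, weights: np.ndarray, i: int,
                         js: np.ndarray) -> np.ndarray:
    ci, wi = centers[i], weights[i]
    cj, wj = centers[js], weights[js]
    a = 2.0 * (cj - ci)
    b = -((np.einsum("ij,ij->i", cj, cj) - wj) - (ci @ ci - wi))
    return np.hstack([a, b[:, None]])


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev center of the polytope; None if (near-)empty."""
    a, b = halfspaces[:, :3], halfspaces[:, 3]
    norms = np.linalg.norm(a, axis=1)
    res = linprog(
        c=[0.0, 0.0, 0.0, -1.0],
        A_ub=np.hstack([a, norms[:, None]]),
        b_ub=-b,
        bounds=[(None, None)] * 3 + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[3] < 1e-7:
        return None
    return res.x[:3]


def _cell_geometry(halfspaces: np.ndarray, interior: np.ndarray,
                   plane_tol: float = 1e-7):
    """Vertices, volume and per-halfspace polygon areas of the cell."""
    hsi = HalfspaceIntersection(halfspaces, interior)
    verts = hsi.intersections
    hull = ConvexHull(verts)
    volume = hull.volume
    areas = np.zeros(len(halfspaces))
    scale = max(1.0, np.abs(verts).max())
    on_plane = np.abs(verts @ halfspaces[:, :3].T + halfspaces[:, 3]) <= (
        plane_tol * scale * np.maximum(np.linalg.norm(halfspaces[:, :3], axis=1), 1.0)
    )
    for k in range(len(halfspaces)):
        pts = verts[on_plane[:, k]]
        if len(pts) < 3:
            continue
        normal = halfspaces[k, :3]
        normal = normal / np.linalg.norm(normal)
        # orthonormal in-plane basis
        u = np.eye(3)[np.argmin(np.abs(normal))]
        u = u - (u @ normal) * normal
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        pts2 = np.column_stack([pts @ u, pts @ v])
        try:
            areas[k] = ConvexHull(pts2).volume  # 2D hull "volume" is area
        except QhullError:
            areas[k] = 0.0  # degenerate (collinear) trace
    return verts, volume, areas


def build_tessellation(sites: list[WeightedSite], padding: float = 5.0,
                       jitter_seed: int = 0) -> Tessellation:
    """Power diagram of the sites clipped to the padded bounding box.

    Near-degenerate inputs (cospherical sites) are resolved by a seeded
    symbolic jitter of 1e-8 A, logged when triggered.
    """
    if not sites:
        raise ValueError("need at least one site")
    centers = np.asarray([s.center for s in sites], dtype=float)
    weights = np.asarray([s.weight for s in sites], dtype=float)
    n = len(sites)
    if n > 1:
        tree = cKDTree(centers)
        d, idx = tree.query(centers, k=2)
        if np.any(d[:, 1] < 1e-9):
            raise ValueError("duplicate site centers")
    lo = centers.min(axis=0) - padding
    hi = centers.max(axis=0) + padding
    box_hs = _box_halfspaces(lo, hi)
    box_diag = float(np.linalg.norm(hi - lo))

    jittered = False
    rng = np.random.default_rng(jitter_seed)

    def build_all(ctr: np.ndarray) -> list[Cell]:
        tree = cKDTree(ctr) if n > 1 else None
        cells = []
        for i in range(n):
            # candidate neighbors: start local, verify against everyone
            if n > 1:
                r0 = 4.0 * padding + 2.0 * np.sqrt(weights.max())
                cand = set(tree.query_ball_point(ctr[i], min(r0, box_diag))) - {i}
            else:
                cand = set()
            while True:
                js = np.fromiter(sorted(cand), dtype=int) if cand else np.empty(0, dtype=int)
                hs = box_hs if len(js) == 0 else np.vstack(
                    [_bisector_halfspaces(ctr, weights, i, js), box_hs])
                interior = _interior_point(hs)
                if interior is None:
                    cells.append(Cell(volume=0.0, faces=[]))
                    break
                verts, volume, areas = _cell_geometry(hs, interior)
                # exactness check: no excluded site may win at any vertex
                others = np.setdiff1d(np.arange(n), np.append(js, i))
                if len(others) and len(verts):
                    pw_i = ((verts - ctr[i]) ** 2).sum(axis=1) - weights[i]
                    pw_o = ((verts[:, None, :] - ctr[others][None]) ** 2).sum(axis=2) - weights[others]
                    bad = others[np.unique(np.where(pw_o < pw_i[:, None] - 1e-9)[1])]
                    if len(bad):
                        cand.update(bad.tolist())
                        continue
                faces = []
                for k, a in enumerate(areas):
                    if a <= AREA_EPS:
                        continue
                    neighbor = int(js[k]) if k < len(js) else BOUNDARY
                    faces.append(Face(neighbor, float(a)))
                cells.append(Cell(volume=float(volume), faces=faces))
                break
        return cells

    try:
        cells = build_all(centers)
    except (QhullError, ValueError) as exc:
        jittered = True
        logger.warning("degenerate configuration (%s); applying seeded symbolic jitter", exc)
        jitter = rng.uniform(-1e-8, 1e-8, size=centers.shape)
        cells = build_all(centers + jitter)
    if jittered:
        logger.info("tessellation built after symbolic perturbation (seed=%d)", jitter_seed)
    return Tessellation(sites=list(sites), cells=cells, box_lo=lo, box_hi=hi)


def residue_areas(tess: Tessellation, structure: Structure) -> dict[ResidueKey, ResidueAreas]:
    """Aggregate atomic face areas into per-residue total/surface/contact.

    Intra-residue faces are excluded; faces against the box accumulate into
    surface; inter-residue faces into the contact map. The area of an
    unordered atom-pair face is taken from the lower-index cell so that
    contact(x, y) == contact(y, x) holds exactly and
    surface + sum(contact) == total by construction of a single shared value
    per face.
    """
    res_types = {r.key: r.res_type for r in structure.residues()}
    site_res: list[ResidueKey] = []
    for s in tess.sites:
        if s.owner is None:
            raise ValueError("tessellation site lacks a residue owner")
        rkey = s.owner[0]
        if rkey not in res_types:
            raise ValueError(f"orphan site owner {rkey!r} not in structure")
        site_res.append(rkey)

    out = {k: ResidueAreas(res_type=t) for k, t in res_types.items()}
    for i, cell in enumerate(tess.cells):
        ri = site_res[i]
        for face in cell.faces:
            if face.neighbor == BOUNDARY:
                out[ri].surface += face.area
                out[ri].total += face.area
                continue
            j = face.neighbor
            rj = site_res[j]
            if rj == ri:
                continue
            if j < i:  # counted from the lower-index side
                continue
            out[ri].contact[rj] = out[ri].contact.get(rj, 0.0) + face.area
            out[rj].contact[ri] = out[rj].contact.get(ri, 0.0) + face.area
            out[ri].total += face.area
            out[rj].total += face.area
    for areas in out.values():
        areas.contact = {k: v for k, v in areas.contact.items() if v > AREA_EPS}
    return out


def mc_area_oracle(sites: list[WeightedSite], box_lo, box_hi, n_samples: int,
                   seed: int, slab_halfwidth: float = 0.05,
                   chunk: int = 200_000):
    """Monte-Carlo estimates of per-cell volumes and pair face areas.

    Uniform points in the box are assigned to the site of minimum power
    distance; a face area for the pair of the two smallest powers is
    estimated from points within ``slab_halfwidth`` of the radical plane
    (perpendicular distance = power gap / (2 |c_j - c_i|)).

    Returns (volumes, volume_se, face_areas, face_se) with faces keyed by
    sorted index pairs.
    """
    if n_samples < 10 ** 5:
        raise ValueError("need at least 1e5 samples")
    centers = np.asarray([s.center for s in sites], dtype=float)
    weights = np.asarray([s.weight for s in sites], dtype=float)
    lo = np.asarray(box_lo, dtype=float)
    hi = np.asarray(box_hi, dtype=float)
    vol_box = float(np.prod(hi - lo))
    n = len(sites)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n, dtype=np.int64)
    face_counts: dict[tuple[int, int], int] = {}
    sep = np.linalg.norm(centers[:, None] - centers[None], axis=2)

    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        pts = rng.uniform(lo, hi, size=(m, 3))
        power = ((pts[:, None, :] - centers[None]) ** 2).sum(axis=2) - weights[None]
        order = np.argsort(power, axis=1)
        best = order[:, 0]
        np.add.at(counts, best, 1)
        if n > 1:
            second = order[:, 1]
            gap = power[np.arange(m), second] - power[np.arange(m), best]
            plane_dist = gap / (2.0 * sep[best, second])
            near = plane_dist <= slab_halfwidth
            bi, bj = best[near], second[near]
            lo_idx, hi_idx = np.minimum(bi, bj), np.maximum(bi, bj)
            flat = np.bincount(lo_idx * n + hi_idx, minlength=n * n)
            for k in np.nonzero(flat)[0]:
                key = (int(k // n), int(k % n))
                face_counts[key] = face_counts.get(key, 0) + int(flat[k])
        done += m

    frac = counts / n_samples
    volumes = frac * vol_box
    vol_se = vol_box * np.sqrt(frac * (1 - frac) / n_samples)
    face_areas, face_se = {}, {}
    for key, c in face_counts.items():
        p = c / n_samples
        face_areas[key] = p * vol_box / (2.0 * slab_halfwidth)
        face_se[key] = vol_box * np.sqrt(p * (1 - p) / n_samples) / (2.0 * slab_halfwidth)
    return volumes, vol_se, face_areas, face_se


def residue_areas_to_tsv(areas: dict[ResidueKey, ResidueAreas]) -> tuple[str, str]:
    """(per-residue areas TSV, pairwise contact areas TSV)."""
    res_lines = ["chain\tresid\ttotal_A2\tsurface_A2"]
    for key in sorted(areas):
        a = areas[key]
        res_lines.append(f"{key[0]}\t{key[1]}\t{a.total:.6f}\t{a.surface:.6f}")
    pair_lines = ["chain_a\tresid_a\tchain_b\tresid_b\tarea_A2"]
    for key in sorted(areas):
        for other, val in sorted(areas[key].contact.items()):
            if key < other:
                pair_lines.append(f"{key[0]}\t{key[1]}\t{other[0]}\t{other[1]}\t{val:.6f}")
    return "\n".join(res_lines) + "\n", "\n".join(pair_lines) + "\n"
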