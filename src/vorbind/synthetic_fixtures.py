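"""Deterministic generators of synthetic inputs.

Everything here is a pure function of its parameters and a seed: jittered
lattices of weighted sites for tessellation work, toy two-chain complexes
with an exactly planted contact interface, property-pair samples from a
planted bivariate normal (with matched independent decoys), and perturbed
pose sets for the docking scorer and the CAPRI metrics.

Toy-complex geometry: residues sit 9.5 A apart along the chain axis with
all atoms within ~1 A of the residue center; planted ligand residues face
their receptor partner at a 4.0 A center offset. This guarantees planted
pairs have heavy atoms closer than 6 A, every other cross-chain pair stays
beyond 8 A, and consecutive Calpha remain inside the 10 A patch-graph
radius.
"""

from __future__ import annotations

import numpy as np

from . import evaluation
from .features_and_property import SITE_FEATURE_TABLE
from .pair_statistics import BivariateNormalParams
from .structure_model import Atom, ContactPair, Residue, Structure, Subunit, superpose
from .tessellation import DEFAULT_RADIUS, VDW_RADII, WeightedSite

_ELEMENT_CYCLE = ("C", "N", "O", "S")

RES_SPACING = 9.5     # A between consecutive residue centers along the chain
CONTACT_OFFSET = 4.0  # A center-center offset for planted contact pairs
ATOM_SPREAD = 1.0     # max distance of any atom from its residue center

# idealized pseudo-residue: backbone N, CA, C, O plus one side-chain atom,
# all within ATOM_SPREAD of the center
_ATOM_OFFSETS = {
    "N": (-0.9, 0.3, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (0.9, 0.3, 0.0),
    "O": (0.9, 0.3, 0.9),
    "CB": (0.0, -0.9, 0.4),
}
_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def make_lattice_atoms(n_atoms: int, spacing: float = 3.0, jitter: float = 0.4,
                       seed: int = 0) -> list[WeightedSite]:
    """Jittered cubic-lattice weighted sites with cycled element radii."""
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter >= spacing / 2:
        raise ValueError("jitter must be below spacing/2 to avoid collisions")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n_atoms ** (1 / 3)))
    pts = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                pts.append((ix * spacing, iy * spacing, iz * spacing))
                if len(pts) == n_atoms:
                    break
            if len(pts) == n_atoms:
                break
        if len(pts) == n_atoms:
            break
    pts = np.asarray(pts, dtype=float)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    sites = []
    for i, p in enumerate(pts):
        elem = _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)]
        r = VDW_RADII.get(elem, DEFAULT_RADIUS)
        sites.append(WeightedSite(tuple(p), r * r, ((("X", str(i + 1))), 0)))
    return sites


def _make_residue(chain_id: str, seq: int, res_type: str, center: np.ndarray,
                  rng: np.random.Generator, jitter: float = 0.1) -> Residue:
    atoms = []
    for name, off in _ATOM_OFFSETS.items():
        pos = center + np.asarray(off) * 0.9 + rng.uniform(-jitter, jitter, 3)
        atoms.append(Atom(name=name, element=_ATOM_ELEMENTS[name],
                          coord=tuple(np.round(pos, 3)), is_heavy=True))
    return Residue(chain_id, str(seq), res_type, atoms)


def make_toy_complex(n_res_a: int, n_res_b: int, n_contact_pairs: int,
                     gap: float = 20.0, seed: int = 0,
                     composition: list[str] | None = None
                     ) -> tuple[Subunit, Subunit, set[ContactPair]]:
    """Two pseudo-protein chains with an exactly planted contact block.

    Receptor residues lie on the z = 0 line; a contiguous block of ligand
    residues sits opposite its receptor partners at the contact offset, the
    remaining ligand residues at z = gap. Planted pairs are the only
    cross-chain residue pairs with heavy atoms under 6 A; all others stay
    beyond 8 A.
    """
    if n_contact_pairs > min(n_res_a, n_res_b):
        raise ValueError("n_contact_pairs exceeds the shorter chain")
    if gap < 12.0:
        raise ValueError(f"gap {gap} too small: non-contact residues could fall under 8 A")
    rng = np.random.default_rng(seed)
    types = composition or sorted(SITE_FEATURE_TABLE)
    start = int(rng.integers(0, min(n_res_a, n_res_b) - n_contact_pairs + 1)) \
        if n_contact_pairs else 0
    planted_idx = set(range(start, start + n_contact_pairs))

    res_a, res_b = [], []
    planted: set[ContactPair] = set()
    for i in range(n_res_a):
        center = np.array([i * RES_SPACING, 0.0, 0.0])
        res_a.append(_make_residue("A", i + 1, types[int(rng.integers(len(types)))], center, rng))
    for j in range(n_res_b):
        z = CONTACT_OFFSET if j in planted_idx else gap
        center = np.array([j * RES_SPACING, 0.0, z])
        res_b.append(_make_residue("B", j + 1, types[int(rng.integers(len(types)))], center, rng))
    sub_a, sub_b = Subunit("A", res_a), Subunit("B", res_b)
    for j in sorted(planted_idx):
        ra, rb = res_a[j], res_b[j]
        dmin = min(np.linalg.norm(a.xyz - b.xyz) for a in ra.heavy_atoms()
                   for b in rb.heavy_atoms())
        planted.add(ContactPair(ra.key, rb.key, float(dmin)))
    return sub_a, sub_b, planted


def sample_property_pairs(params: BivariateNormalParams, n: int, seed: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """n correlated pairs from the planted joint plus n independent decoy
    pairs drawn from the product of its marginals."""
    if n < 1:
        raise ValueError("need at least one sample")
    cov = np.array([
        [params.sd1 ** 2, params.rho * params.sd1 * params.sd2],
        [params.rho * params.sd1 * params.sd2, params.sd2 ** 2],
    ])
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise ValueError("covariance not positive definite")
    rng = np.random.default_rng(seed)
    pairs = rng.multivariate_normal([params.mu1, params.mu2], cov, size=n)
    decoys = np.column_stack([
        rng.normal(params.mu1, params.sd1, size=n),
        rng.normal(params.mu2, params.sd2, size=n),
    ])
    return pairs, decoys


def _rigid_perturb(subunit: Subunit, angle_rad: float, translation: float,
                   rng: np.random.Generator) -> Subunit:
    coords = np.vstack([a.xyz for r in subunit.residues for a in r.atoms])
    centroid = coords.mean(axis=0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = axis
    kmat = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    rot = np.eye(3) + np.sin(angle_rad) * kmat + (1 - np.cos(angle_rad)) * kmat @ kmat
    shift = rng.normal(size=3)
    shift = shift / np.linalg.norm(shift) * translation
    residues = []
    for res in subunit.residues:
        atoms = [Atom(a.name, a.element,
                      tuple(np.round(rot @ (a.xyz - centroid) + centroid + shift, 3)),
                      a.is_heavy) for a in res.atoms]
        residues.append(Residue(res.chain_id, res.seq_id, res.res_type, atoms))
    return Subunit(subunit.id, residues)


def make_pose_set(native: tuple[Subunit, Subunit], n_near: int, n_far: int,
                  near_scale: tuple[float, float] = (0.05, 0.5),
                  far_scale: tuple[float, float] = (1.5, 25.0),
                  seed: int = 0) -> list[dict]:
    """Perturbed poses of the native complex with internally computed labels.

    near/far scales are (rotation radians, translation A); near must be
    strictly smaller than far in both. Each entry carries pose_id, kind,
    the pose (receptor fixed, ligand perturbed) and its interface RMSD
    against the native.
    """
    if not (near_scale[0] < far_scale[0] and near_scale[1] < far_scale[1]):
        raise ValueError("near perturbation scales must be below far scales")
    rng = np.random.default_rng(seed)
    sub_a, sub_b = native
    poses = []
    for kind, count, (ang, tr) in (("near", n_near, near_scale), ("far", n_far, far_scale)):
        for i in range(count):
            moved = _rigid_perturb(sub_b, ang, tr, rng)
            pose = (sub_a, moved)
            try:
                label = evaluation.irmsd(pose, native)
            except ValueError:
                label = float("inf")  # interface destroyed
            poses.append({"pose_id": f"{kind}_{i}", "kind": kind,
                          "pose": pose, "i_rmsd": label})
    return poses
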