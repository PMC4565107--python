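"""Interface-level energy terms and linear pose rescoring.

Two terms are implemented natively: the structural neighborhood energy (sum
of the pair log-odds score S over all interface residue pairs at the 6 A
heavy-atom cutoff) and the amino-acid energy (negative log probability of
the interface residue composition). Further terms — pi-pi geometry,
dihedral-angle statistics, side-chain packing energies — plug in through
the same evaluator contract. A linear combination of term values ranks
candidate poses; coefficients are fitted by least squares on labelled
poses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import pair_statistics, tessellation
from .features_and_property import SITE_FEATURE_TABLE, property_profile
from .pair_statistics import PairStatModel
from .structure_model import Structure, Subunit, heavy_atom_contacts, interface_residues

logger = logging.getLogger(__name__)

Pose = tuple[Subunit, Subunit]
Evaluator = Callable[[Pose], float]


@dataclass
class EnergyTerm:
    name: str
    evaluate: Evaluator


@dataclass
class EnergyModel:
    terms: list[EnergyTerm]
    coefficients: np.ndarray
    aa_probs: dict[str, float] | None = None

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise ValueError("one coefficient per term required")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")
        if self.aa_probs is not None:
            vals = np.array(list(self.aa_probs.values()))
            if np.any(vals <= 0) or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("aa_probs must be strictly positive and sum to 1")

    def term_vector(self, pose: Pose) -> np.ndarray:
        return np.array([t.evaluate(pose) for t in self.terms], dtype=float)

    def energy(self, pose: Pose) -> float:
        return combine(self.term_vector(pose), self.coefficients)


def _pose_profiles(pose: Pose, padding: float = 5.0):
    profiles = []
    for sub in pose:
        st = Structure([sub])
        sites = tessellation.sites_from_structure(st)
        tess = tessellation.build_tessellation(sites, padding=padding)
        areas = tessellation.residue_areas(tess, st)
        profiles.append(property_profile(st, areas))
    return profiles


def neighborhood_energy(pose: Pose, model: PairStatModel, cutoff: float = 6.0,
                        use_updated: bool = False, padding: float = 5.0) -> float:
    """Sum of the pair energy S over all interface residue pairs of the pose.

    With use_updated=True the neighborhood-updated S' is summed instead.
    Pairs whose residues are buried (no property profile) are skipped.
    """
    sub_a, sub_b = pose
    contacts = heavy_atom_contacts(sub_a, sub_b, cutoff)
    if not contacts:
        raise ValueError("pose has no interface pair at the contact cutoff")
    profile_a, profile_b = _pose_profiles(pose, padding)
    pair_keys = {(c.res_a, c.res_b) for c in contacts
                 if c.res_a in profile_a.surface_ratio and c.res_b in profile_b.surface_ratio}
    if not pair_keys:
        raise ValueError("no interface pair with surface profiles on both sides")
    feats = sorted(model.marginals)
    if use_updated:
        scores = pair_statistics.score_all_pairs(profile_a, profile_b, model)
        scores = pair_statistics.neighborhood_update(scores, sub_a, sub_b)
        return float(sum(s.S_prime for s in scores if (s.res_a, s.res_b) in pair_keys))
    total = 0.0
    for ka, kb in sorted(pair_keys):
        va = {f: profile_a.get(ka, f) for f in feats}
        vb = {f: profile_b.get(kb, f) for f in feats}
        total += pair_statistics.pair_energy(va, vb, model)
    return total


def fit_aa_probs(interfaces: list[list[str]], pseudocount: float = 1.0) -> dict[str, float]:
    """Interface amino-acid probabilities from lists of interface residue
    types, with additive smoothing so every standard type stays positive."""
    counts = {t: pseudocount for t in SITE_FEATURE_TABLE}
    for residues in interfaces:
        for t in residues:
            if t not in counts:
                raise KeyError(f"unknown residue type {t!r}")
            counts[t] += 1
    total = sum(counts.values())
    return {t: c / total for t, c in counts.items()}


def amino_acid_energy(pose: Pose, aa_probs: dict[str, float], cutoff: float = 6.0) -> float:
    """-sum(ln aa_probs(type)) over interface residues of both sides."""
    sub_a, sub_b = pose
    try:
        keys_a, keys_b = interface_residues(sub_a, sub_b, cutoff)
    except ValueError:
        return 0.0
    energy = 0.0
    for sub, keys in ((sub_a, keys_a), (sub_b, keys_b)):
        for key in sorted(keys):
            t = sub.residue(key).res_type
            if t not in aa_probs:
                raise KeyError(f"residue type {t!r} missing from aa_probs table")
            energy -= math.log(aa_probs[t])
    return energy


def combine(values, coefficients) -> float:
    """Linear combination of term values (the initial energy function)."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if v.shape != c.shape:
        raise ValueError(f"length mismatch: {v.shape} values vs {c.shape} coefficients")
    return float(v @ c)


def fit_coefficients(term_matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, dict]:
    """Least-squares coefficients mapping per-pose term vectors to labels
    (near-native flag or interface RMSD). Requires a full-rank design."""
    x = np.atleast_2d(np.asarray(term_matrix, dtype=float))
    y = np.asarray(labels, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 labelled poses")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns involved in the deficiency via pivoted QR
        from scipy.linalg import qr
        _, r, piv = qr(x, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(int(piv[i]) for i in range(len(diag)) if diag[i] < 1e-10 * max(diag.max(), 1.0))
        bad = bad or sorted(int(p) for p in piv[rank:])
        raise ValueError(f"rank-deficient term matrix; offending columns: {bad}")
    coeffs, residuals, _, _ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(residuals[0]) if len(residuals) else float(((x @ coeffs - y) ** 2).sum())
    diagnostics = {"rss": rss, "rank": int(rank), "n_poses": int(x.shape[0])}
    return coeffs, diagnostics


def rank_poses(poses: list[tuple[str, Pose]], energy_fn: Callable[[Pose], float],
               k: int) -> tuple[list[tuple[str, float]], list[str]]:
    """Top-k pose ids by ascending energy (stable; ties keep input order).

    Returns (ranked [(id, energy)], unscoreable ids). Poses whose evaluation
    raises are reported, never silently dropped.
    """
    scored, failed = [], []
    for pid, pose in poses:
        try:
            scored.append((pid, float(energy_fn(pose))))
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.warning("pose %s unscoreable: %s", pid, exc)
            failed.append(pid)
    if not scored:
        raise ValueError("all poses unscoreable")
    order = sorted(range(len(scored)), key=lambda i: (scored[i][1], i))
    if k > len(scored):
        logger.warning("k=%d exceeds %d scoreable poses; returning all", k, len(scored))
    return [scored[i] for i in order[:k]], failed


def energies_to_tsv(rows: list[tuple[str, np.ndarray, float]], term_names: list[str]) -> str:
    header = "pose_id\t" + "\t".join(term_names) + "\ttotal"
    lines = [header]
    for pid, vec, total in rows:
        lines.append(pid + "\t" + "\t".join(f"{v:.6f}" for v in vec) + f"\t{total:.6f}")
    return "\n".join(lines) + "\n"
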