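"""Harvest interacting residue pairs, rank them, and cluster into patches.

Pairs with S <= s_th are "interacting"; each interacting residue is ranked
by its best (lowest) neighborhood-updated score S'; the retained residues
are clustered per protein side into connected components of the 10 A
Calpha-distance graph, and components below a minimum size are discarded as
weak signal. The surviving patches are the predicted interface residues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import pair_statistics, tessellation
from .features_and_property import property_profile
from .pair_statistics import PairScore, PairStatModel
from .structure_model import ResidueKey, Subunit

logger = logging.getLogger(__name__)


@dataclass
class ExtractionConfig:
    s_th: float = 0.0
    top_k: int | str = 100  # count, or "all"
    edge_radius: float = 10.0
    min_patch_size: int = 3

    def __post_init__(self):
        if self.edge_radius <= 0:
            raise ValueError("edge_radius must be positive")
        if self.min_patch_size < 1:
            raise ValueError("min_patch_size must be >= 1")
        if self.top_k != "all" and (not isinstance(self.top_k, int) or self.top_k < 1):
            raise ValueError("top_k must be a positive integer or 'all'")


@dataclass
class PatchSet:
    patches_a: list[set[ResidueKey]] = field(default_factory=list)
    patches_b: list[set[ResidueKey]] = field(default_factory=list)
    provenance: dict[tuple[str, ResidueKey], float] = field(default_factory=dict)

    def residues_a(self) -> set[ResidueKey]:
        return set().union(*self.patches_a) if self.patches_a else set()

    def residues_b(self) -> set[ResidueKey]:
        return set().union(*self.patches_b) if self.patches_b else set()


def harvest_pairs(scores: list[PairScore], s_th: float) -> list[PairScore]:
    """Pairs with S <= s_th, in deterministic (key_a, key_b) order."""
    kept = [s for s in scores if s.S <= s_th]
    kept.sort(key=lambda s: (s.res_a, s.res_b))
    return kept


def rank_residues(pairs: list[PairScore], top_k: int | str = "all"
                  ) -> list[tuple[str, ResidueKey, float]]:
    """Interacting residues of both sides ranked by best (lowest) S'.

    Each residue is keyed by the minimum S' over its pairs; ties break on
    (side, chain, resid). Returns the top_k prefix of
    (side 'a'|'b', residue key, best S').
    """
    best: dict[tuple[str, ResidueKey], float] = {}
    for p in pairs:
        sp = p.S_prime if p.S_prime is not None else p.S
        for side, key in (("a", p.res_a), ("b", p.res_b)):
            cur = best.get((side, key))
            if cur is None or sp < cur:
                best[(side, key)] = sp
    ranked = sorted(((side, key, v) for (side, key), v in best.items()),
                    key=lambda t: (t[2], t[0], t[1]))
    if top_k != "all":
        ranked = ranked[: int(top_k)]
    return ranked


def cluster_patches(residues: list[tuple[str, ResidueKey, float]],
                    subunit_a: Subunit, subunit_b: Subunit,
                    config: ExtractionConfig) -> PatchSet:
    """Per-side connected components under the Calpha-distance graph.

    An undirected edge joins residues of the same side whose Calpha atoms
    are within edge_radius; components smaller than min_patch_size are
    discarded.
    """
    out = PatchSet(provenance={(side, key): v for side, key, v in residues})
    for side, subunit in (("a", subunit_a), ("b", subunit_b)):
        keys = sorted({key for s, key, _ in residues if s == side})
        coords = {}
        for k in keys:
            ca = subunit.residue(k).ca()
            if ca is None:
                logger.warning("residue %s lacks Calpha; excluded from clustering", k)
                continue
            coords[k] = np.asarray(ca.coord)
        g = nx.Graph()
        g.add_nodes_from(coords)
        ks = sorted(coords)
        for i, ki in enumerate(ks):
            for kj in ks[i + 1:]:
                if np.linalg.norm(coords[ki] - coords[kj]) <= config.edge_radius:
                    g.add_edge(ki, kj)
        patches = [set(c) for c in nx.connected_components(g) if len(c) >= config.min_patch_size]
        patches.sort(key=lambda c: sorted(c)[0])
        if side == "a":
            out.patches_a = patches
        else:
            out.patches_b = patches
    return out


def predict_interface(subunit_a: Subunit, subunit_b: Subunit, model: PairStatModel,
                      config: ExtractionConfig, padding: float = 5.0
                      ) -> tuple[PatchSet, dict]:
    """End-to-end binding-site prediction for a pair of unbound proteins.

    Pipeline: tessellate each subunit -> residue areas -> property profile
    -> score all surface cross-pairs -> neighborhood update -> harvest at
    s_th -> rank by S' -> cluster into patches. Deterministic for a fixed
    config.
    """
    from .structure_model import Structure

    report: dict = {"config": {
        "s_th": config.s_th, "top_k": config.top_k,
        "edge_radius": config.edge_radius, "min_patch_size": config.min_patch_size,
    }}
    profiles = []
    for stage, sub in (("a", subunit_a), ("b", subunit_b)):
        st = Structure([sub])
        sites = tessellation.sites_from_structure(st)
        if not sites:
            raise ValueError(f"stage tessellate[{stage}]: no heavy atoms")
        tess = tessellation.build_tessellation(sites, padding=padding)
        areas = tessellation.residue_areas(tess, st)
        profiles.append(property_profile(st, areas))
    profile_a, profile_b = profiles
    if not profile_a.surface_ratio or not profile_b.surface_ratio:
        report["n_harvested"] = 0
        report["n_ranked"] = 0
        return PatchSet(), report

    scores = pair_statistics.score_all_pairs(profile_a, profile_b, model)
    scores = pair_statistics.neighborhood_update(scores, subunit_a, subunit_b,
                                                 radius=config.edge_radius)
    harvested = harvest_pairs(scores, config.s_th)
    ranked = rank_residues(harvested, config.top_k)
    patches = cluster_patches(ranked, subunit_a, subunit_b, config)
    report["n_scored"] = len(scores)
    report["n_harvested"] = len(harvested)
    report["n_ranked"] = len(ranked)
    report["n_patches_a"] = len(patches.patches_a)
    report["n_patches_b"] = len(patches.patches_b)
    return patches, report


def patches_to_tsv(patches: PatchSet, subunit_a: Subunit, subunit_b: Subunit) -> str:
    lines = ["side\tpatch_id\tchain\tresid\tres_type\tbest_S_prime"]
    for side, plist, sub in (("a", patches.patches_a, subunit_a),
                             ("b", patches.patches_b, subunit_b)):
        for pid, patch in enumerate(plist):
            for key in sorted(patch):
                res = sub.residue(key)
                sp = patches.provenance.get((side, key), float("nan"))
                lines.append(f"{side}\t{pid}\t{key[0]}\t{key[1]}\t{res.res_type}\t{sp:.6f}")
    return "\n".join(lines) + "\n"


def summary_json(patches: PatchSet, report: dict) -> str:
    doc = dict(report)
    doc["residues_a"] = sorted(f"{c}:{r}" for c, r in patches.residues_a())
    doc["residues_b"] = sorted(f"{c}:{r}" for c, r in patches.residues_b())
    return json.dumps(doc, indent=2, sort_keys=True)
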