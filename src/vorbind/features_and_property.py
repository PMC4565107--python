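"""Per-residue physicochemical features and the structural neighboring property.

Three site features characterize each amino-acid type: Kyte-Doolittle
hydrophobicity, integer electrostatic charge, and the count of potential
hydrogen bonds. The structural neighboring property of a surface residue x is

    p'(x) = (surface(x)/total(x)) * p(x)
            + sum over y with contact(x, y) > 0 of (surface(y)/total(y)) * p(y)

i.e. the residue's own feature weighted by its solvent-exposure ratio plus
the exposure-weighted features of every residue sharing a Voronoi face with
it. Buried residues (zero exposure everywhere in the neighborhood) score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure_model import ResidueKey, Structure
from .tessellation import ResidueAreas

FEATURES = ("hydrophobicity", "electrostatic", "hbonds")

#: (hydrophobicity, electrostatic potential, potential hydrogen bonds)
SITE_FEATURE_TABLE: dict[str, tuple[float, int, int]] = {
    "ALA": (1.8, 0, 2),
    "ARG": (-4.5, 1, 4),
    "ASN": (-3.5, 0, 4),
    "ASP": (-3.5, -1, 4),
    "CYS": (2.5, 0, 2),
    "GLN": (-3.5, 0, 4),
    "GLU": (-3.5, -1, 4),
    "GLY": (-0.4, 0, 2),
    "HIS": (-3.2, 0, 4),
    "ILE": (4.5, 0, 2),
    "LEU": (3.8, 0, 2),
    "LYS": (-3.9, 1, 2),
    "MET": (1.9, 0, 2),
    "PHE": (2.8, 0, 2),
    "PRO": (-1.6, 0, 2),
    "SER": (-0.8, 0, 4),
    "THR": (-0.7, 0, 4),
    "TRP": (0.9, 0, 3),
    "TYR": (-1.3, 0, 3),
    "VAL": (4.2, 0, 2),
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class SiteFeatures:
    hydrophobicity: float
    electrostatic: int
    hbonds: int

    def value(self, feature: str) -> float:
        if feature not in FEATURES:
            raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
        return float(getattr(self, feature))


def site_features(res_type: str) -> SiteFeatures:
    """Feature triple for a standard amino acid (1- or 3-letter code)."""
    code = res_type.upper()
    if len(code) == 1:
        code = ONE_TO_THREE.get(code, code)
    if code not in SITE_FEATURE_TABLE:
        raise ValueError(
            f"unknown residue type {res_type!r}; valid codes: {sorted(SITE_FEATURE_TABLE)}")
    h, e, b = SITE_FEATURE_TABLE[code]
    return SiteFeatures(h, e, b)


@dataclass
class PropertyProfile:
    """p' per (surface residue, feature) plus solvent-exposure ratios."""

    values: dict[tuple[ResidueKey, str], float] = field(default_factory=dict)
    surface_ratio: dict[ResidueKey, float] = field(default_factory=dict)
    res_types: dict[ResidueKey, str] = field(default_factory=dict)

    @property
    def residues(self) -> list[ResidueKey]:
        return sorted(self.surface_ratio)

    def get(self, key: ResidueKey, feature: str) -> float:
        return self.values[(key, feature)]

    def vector(self, key: ResidueKey) -> dict[str, float]:
        return {f: self.values[(key, f)] for f in FEATURES}


def neighboring_property(x: ResidueKey, areas: dict[ResidueKey, ResidueAreas],
                         feature: str, feature_table=None,
                         same_chain_only: bool = True) -> float:
    """Structural neighboring property p'(x) for one feature.

    Neighbors are the residues sharing positive Voronoi contact area with x,
    restricted by default to x's own chain (the property is defined on an
    isolated protein before pairing).
    """
    if x not in areas:
        raise KeyError(f"no areas for residue {x!r}")
    ax = areas[x]
    if ax.total <= 0:
        raise ValueError(f"residue {x!r} has no tessellation cell (total area 0)")

    def p(res_type: str) -> float:
        if feature_table is not None:
            return float(feature_table[res_type][FEATURES.index(feature)])
        return site_features(res_type).value(feature)

    val = ax.surface_ratio * p(ax.res_type)
    for y, area in ax.contact.items():
        if area <= 0:
            continue
        if same_chain_only and y[0] != x[0]:
            continue
        ay = areas[y]
        if ay.total <= 0:
            raise ValueError(f"neighbor {y!r} has no tessellation cell")
        val += ay.surface_ratio * p(ay.res_type)
    return val


def property_profile(structure: Structure, areas: dict[ResidueKey, ResidueAreas],
                     feature_table=None, same_chain_only: bool = True) -> PropertyProfile:
    """p' for every surface residue (surface area > 0) and all three features."""
    profile = PropertyProfile()
    for res in structure.residues():
        a = areas.get(res.key)
        if a is None or a.total <= 0 or a.surface <= 0:
            continue
        profile.surface_ratio[res.key] = a.surface_ratio
        profile.res_types[res.key] = res.res_type
        for feat in FEATURES:
            profile.values[(res.key, feat)] = neighboring_property(
                res.key, areas, feat, feature_table=feature_table,
                same_chain_only=same_chain_only)
    return profile


def profile_to_tsv(profile: PropertyProfile) -> str:
    lines = ["chain\tresid\tres_type\tsurface_ratio\tpprime_hydro\tpprime_elec\tpprime_hbond"]
    for key in profile.residues:
        v = profile.vector(key)
        lines.append(
            f"{key[0]}\t{key[1]}\t{profile.res_types[key]}\t{profile.surface_ratio[key]:.6f}"
            f"\t{v['hydrophobicity']:.6f}\t{v['electrostatic']:.6f}\t{v['hbonds']:.6f}")
    return "\n".join(lines) + "\n"
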