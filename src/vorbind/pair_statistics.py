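"""Distribution fitting over interface properties and the pair energy.

For each feature, the neighboring property p' of interface residues is
modelled with a univariate normal F(x) (one side of the interface) and the
pair (p'(x1), p'(x2)) across the interface with a bivariate normal
F(x1, x2). The effective free energy of an interacting pair is the
log-odds score

    s_f(x1, x2) = -kB*T * ln[ F(x1, x2) / (F(x1) * F(x2)) ]

per feature, combined into S = sum_f w_f * s_f. Negative S indicates that
the pair of property values co-occurs on interfaces more often than
independence would predict.

A distance-weighted neighborhood update then propagates support from nearby
residues (Calpha distance <= radius, default 10 A):

    S'(x1, x2) = S(x1, x2) + sum_{ri near x1} S(ri, x2)/dis(x1, ri)
                            + sum_{rj near x2} S(x1, rj)/dis(x2, rj)
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features_and_property import FEATURES, PropertyProfile
from .structure_model import ResidueKey, Subunit, heavy_atom_contacts

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-6
MODEL_SCHEMA_VERSION = 1


@dataclass
class NormalParams:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= SD_FLOOR:
            raise ValueError(f"standard deviation {self.sd} below floor {SD_FLOOR}")

    def logpdf(self, x) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2 * math.pi)


@dataclass
class BivariateNormalParams:
    mu1: float
    mu2: float
    sd1: float
    sd2: float
    rho: float

    def __post_init__(self):
        if self.sd1 <= SD_FLOOR or self.sd2 <= SD_FLOOR:
            raise ValueError("bivariate sd below floor")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("correlation must lie strictly inside (-1, 1)")

    def logpdf(self, x1, x2) -> np.ndarray:
        z1 = (np.asarray(x1, dtype=float) - self.mu1) / self.sd1
        z2 = (np.asarray(x2, dtype=float) - self.mu2) / self.sd2
        r = self.rho
        q = (z1 * z1 - 2 * r * z1 * z2 + z2 * z2) / (1 - r * r)
        return (-0.5 * q - math.log(2 * math.pi) - math.log(self.sd1)
                - math.log(self.sd2) - 0.5 * math.log(1 - r * r))


@dataclass
class PairStatModel:
    marginals: dict[str, NormalParams]
    joints: dict[str, BivariateNormalParams]
    kbt: float = 1.0
    epsilon: float = 1e-12
    weights: dict[str, float] = field(default_factory=lambda: {f: 1.0 for f in FEATURES})

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("density floor must be positive")
        if any(w < 0 for w in self.weights.values()) or not any(self.weights.values()):
            raise ValueError("feature weights must be non-negative and not all zero")

    def to_json(self) -> str:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kBT": self.kbt,
            "epsilon": self.epsilon,
            "weights": self.weights,
            "features": {
                f: {
                    "marginal": {"mean": self.marginals[f].mean, "sd": self.marginals[f].sd},
                    "joint": {
                        "mu": [self.joints[f].mu1, self.joints[f].mu2],
                        "sigma": [self.joints[f].sd1, self.joints[f].sd2],
                        "rho": self.joints[f].rho,
                    },
                }
                for f in self.marginals
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PairStatModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {doc.get('schema_version')!r}")
        marginals, joints = {}, {}
        for f, entry in doc["features"].items():
            marginals[f] = NormalParams(entry["marginal"]["mean"], entry["marginal"]["sd"])
            j = entry["joint"]
            joints[f] = BivariateNormalParams(j["mu"][0], j["mu"][1],
                                              j["sigma"][0], j["sigma"][1], j["rho"])
        return cls(marginals=marginals, joints=joints, kbt=doc["kBT"],
                   epsilon=doc["epsilon"], weights=doc["weights"])


@dataclass(frozen=True)
class PairScore:
    res_a: ResidueKey
    res_b: ResidueKey
    S: float
    S_prime: float | None = None


@dataclass
class TrainingComplex:
    """One bound complex: the two subunits plus their property profiles."""

    subunit_a: Subunit
    subunit_b: Subunit
    profile_a: PropertyProfile
    profile_b: PropertyProfile


def fit_bivariate(pairs: np.ndarray, symmetrize: bool = True) -> BivariateNormalParams:
    """Maximum-likelihood bivariate normal moments for an n x 2 sample.

    Interfaces have no canonical side ordering, so by default every pair is
    counted in both orders, which forces mu1 == mu2 and sd1 == sd2.
    """
    x = np.asarray(pairs, dtype=float)
    if symmetrize:
        x = np.vstack([x, x[:, ::-1]])
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # MLE (ddof=0)
    if np.any(sd <= SD_FLOOR):
        raise ValueError("zero-variance sample in bivariate fit")
    z = (x - mu) / sd
    rho = float(np.clip((z[:, 0] * z[:, 1]).mean(), -0.999999, 0.999999))
    return BivariateNormalParams(float(mu[0]), float(mu[1]), float(sd[0]), float(sd[1]), rho)


def fit_model(training: list[TrainingComplex], cutoff: float = 6.0,
              kbt: float = 1.0, epsilon: float = 1e-12,
              weights: dict[str, float] | None = None,
              min_pairs: int = 30) -> PairStatModel:
    """Fit per-feature marginal and joint normals from bound complexes.

    Interface residue pairs are harvested at the heavy-atom contact cutoff;
    only pairs where both residues carry a property profile (surface
    residues) contribute. The univariate fit pools p' of interface residues
    from both sides; the bivariate fit is symmetrized over pair order.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training complexes")
    singles: dict[str, list[float]] = {f: [] for f in FEATURES}
    pairs: dict[str, list[tuple[float, float]]] = {f: [] for f in FEATURES}
    n_pairs = 0
    for tc in training:
        contacts = heavy_atom_contacts(tc.subunit_a, tc.subunit_b, cutoff)
        seen_a, seen_b = set(), set()
        for c in sorted(contacts):
            if c.res_a not in tc.profile_a.surface_ratio or c.res_b not in tc.profile_b.surface_ratio:
                continue
            n_pairs += 1
            for f in FEATURES:
                pa = tc.profile_a.get(c.res_a, f)
                pb = tc.profile_b.get(c.res_b, f)
                pairs[f].append((pa, pb))
            seen_a.add(c.res_a)
            seen_b.add(c.res_b)
        for f in FEATURES:
            singles[f].extend(tc.profile_a.get(k, f) for k in sorted(seen_a))
            singles[f].extend(tc.profile_b.get(k, f) for k in sorted(seen_b))
    if n_pairs < min_pairs:
        raise ValueError(f"insufficient interface pairs for fitting: {n_pairs} < {min_pairs}")

    marginals, joints = {}, {}
    for f in FEATURES:
        vals = np.asarray(singles[f], dtype=float)
        sd = float(vals.std())
        if sd <= SD_FLOOR:
            raise ValueError(f"zero-variance feature: {f}")
        marginals[f] = NormalParams(float(vals.mean()), sd)
        joints[f] = fit_bivariate(np.asarray(pairs[f], dtype=float))
    return PairStatModel(marginals=marginals, joints=joints, kbt=kbt, epsilon=epsilon,
                         weights=weights or {f: 1.0 for f in FEATURES})


def fit_model_from_samples(samples: dict[str, np.ndarray], **kwargs) -> PairStatModel:
    """Fit directly from per-feature n x 2 property-pair arrays (e.g. planted
    synthetic samples); marginals are pooled over both columns."""
    marginals, joints = {}, {}
    for f, arr in samples.items():
        x = np.asarray(arr, dtype=float)
        pooled = x.ravel()
        sd = float(pooled.std())
        if sd <= SD_FLOOR:
            raise ValueError(f"zero-variance feature: {f}")
        marginals[f] = NormalParams(float(pooled.mean()), sd)
        joints[f] = fit_bivariate(x)
    weights = kwargs.pop("weights", None) or {f: 1.0 for f in samples}
    return PairStatModel(marginals=marginals, joints=joints, weights=weights, **kwargs)


def pair_energy(p1: dict[str, float] | float, p2: dict[str, float] | float,
                model: PairStatModel) -> float:
    """S(x1, x2): weighted sum of per-feature log-odds scores.

    Scalar inputs are accepted when the model carries a single feature.
    Densities are floored at the model epsilon so far-tail evaluations stay
    finite.
    """
    feats = sorted(model.marginals)
    if not isinstance(p1, dict):
        if len(feats) != 1:
            raise ValueError("scalar property given but model has several features")
        p1 = {feats[0]: float(p1)}
        p2 = {feats[0]: float(p2)}
    s = 0.0
    for f in feats:
        w = model.weights.get(f, 0.0)
        if w == 0.0:
            continue
        lj = float(model.joints[f].logpdf(p1[f], p2[f]))
        lm1 = float(model.marginals[f].logpdf(p1[f]))
        lm2 = float(model.marginals[f].logpdf(p2[f]))
        leps = math.log(model.epsilon)
        s += w * (-model.kbt) * (max(lj, leps) - max(lm1, leps) - max(lm2, leps))
    return s


def score_all_pairs(profile_a: PropertyProfile, profile_b: PropertyProfile,
                    model: PairStatModel) -> list[PairScore]:
    """S for every (surface residue of A) x (surface residue of B), in
    deterministic (key_a, key_b) order."""
    if not profile_a.surface_ratio or not profile_b.surface_ratio:
        raise ValueError("empty property profile")
    scores = []
    for ka in profile_a.residues:
        va = profile_a.vector(ka)
        va = {f: va[f] for f in model.marginals}
        for kb in profile_b.residues:
            vb = profile_b.vector(kb)
            vb = {f: vb[f] for f in model.marginals}
            scores.append(PairScore(ka, kb, pair_energy(va, vb, model)))
    return scores


def _ca_coords(subunit: Subunit, keys: list[ResidueKey]) -> tuple[np.ndarray, np.ndarray]:
    coords = np.full((len(keys), 3), np.nan)
    ok = np.zeros(len(keys), dtype=bool)
    for i, k in enumerate(keys):
        ca = subunit.residue(k).ca()
        if ca is None:
            logger.warning("residue %s lacks a Calpha; skipped in neighborhood update", k)
            continue
        coords[i] = ca.coord
        ok[i] = True
    return coords, ok


def neighborhood_update(scores: list[PairScore], subunit_a: Subunit, subunit_b: Subunit,
                        radius: float = 10.0) -> list[PairScore]:
    """S' per pair: S plus 1/distance-weighted S of same-side neighbors
    within the Calpha sphere of the given radius (boundary inclusive).

    Neighbor sums range over all residues with a computed score against the
    partner residue; self terms are excluded; residues lacking a Calpha are
    skipped with a warning.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    keys_a = sorted({s.res_a for s in scores})
    keys_b = sorted({s.res_b for s in scores})
    ia = {k: i for i, k in enumerate(keys_a)}
    ib = {k: i for i, k in enumerate(keys_b)}
    smat = np.full((len(keys_a), len(keys_b)), np.nan)
    for s in scores:
        smat[ia[s.res_a], ib[s.res_b]] = s.S
    filled = np.nan_to_num(smat, nan=0.0)
    known = ~np.isnan(smat)

    def weight_matrix(subunit, keys):
        coords, ok = _ca_coords(subunit, keys)
        n = len(keys)
        w = np.zeros((n, n))
        if n > 1:
            d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where((d > 1e-9) & (d <= radius), 1.0 / d, 0.0)
            w[~ok, :] = 0.0
            w[:, ~ok] = 0.0
            np.fill_diagonal(w, 0.0)
        w = np.nan_to_num(w)
        return w

    wa = weight_matrix(subunit_a, keys_a)  # wa[x1, ri]
    wb = weight_matrix(subunit_b, keys_b)  # wb[x2, rj]
    # only neighbors with a known score against the partner contribute
    sprime = smat + (wa @ (filled * known)) + ((filled * known) @ wb.T)
    return [PairScore(s.res_a, s.res_b, s.S, float(sprime[ia[s.res_a], ib[s.res_b]]))
            for s in scores]


def scores_to_tsv(scores: list[PairScore]) -> str:
    lines = ["chain_a\tresid_a\tchain_b\tresid_b\tS\tS_prime"]
    for s in scores:
        sp = "" if s.S_prime is None else f"{s.S_prime:.6f}"
        lines.append(f"{s.res_a[0]}\t{s.res_a[1]}\t{s.res_b[0]}\t{s.res_b[1]}\t{s.S:.6f}\t{sp}")
    return "\n".join(lines) + "\n"
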