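"""CAPRI-style assessment: F_nat, F_non-nat, interface RMSD, and the
binding-site P-value.

Evaluation contacts follow the CAPRI wording — a residue pair is in contact
when any of their atoms are within (<=) 6 A — which deliberately differs
from the strict heavy-atom-only rule used to define training interfaces.
I_rmsd superposes the backbone atoms (N, CA, C, O) of the native-interface
residues and reports the minimized RMSD. The P-value is the binomial upper
tail: the probability of at least n correct residues among N predictions
when a single random pick succeeds with probability m/M.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .structure_model import (
    BACKBONE_ATOMS,
    ResidueKey,
    Subunit,
    _pairwise_min_dists,
    superpose,
)

logger = logging.getLogger(__name__)

EVAL_CUTOFF = 6.0

ContactSet = set[tuple[ResidueKey, ResidueKey]]


@dataclass(frozen=True)
class CapriMetrics:
    f_nat: float
    f_nonnat: float
    i_rmsd: float


@dataclass(frozen=True)
class PValueInputs:
    N: int  # predicted interface residues
    n: int  # correctly predicted among them
    M: int  # all surface residues
    m: int  # true interface residues among the surface residues

    def __post_init__(self):
        if not (0 <= self.n <= self.N):
            raise ValueError("need 0 <= n <= N")
        if not (0 <= self.m <= self.M) or self.M == 0:
            raise ValueError("need 0 <= m <= M with M > 0")
        if self.n > self.m:
            raise ValueError("cannot have more correct predictions than true residues (n <= m)")
        if self.N > self.M:
            raise ValueError("cannot predict more residues than exist on the surface (N <= M)")


def eval_contacts(sub_a: Subunit, sub_b: Subunit, cutoff: float = EVAL_CUTOFF) -> ContactSet:
    """Residue pairs with any atom pair within (<=) the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    best = _pairwise_min_dists(sub_a, sub_b, cutoff, heavy_only=False, inclusive=True)
    return set(best)


def fnat(pred_contacts: ContactSet, native_contacts: ContactSet) -> float:
    """Fraction of native contacts reproduced in the prediction."""
    if not native_contacts:
        raise ValueError("native contact set is empty")
    return len(pred_contacts & native_contacts) / len(native_contacts)


def fnonnat(pred_contacts: ContactSet, native_contacts: ContactSet) -> float:
    """Fraction of predicted contacts that are not native."""
    if not pred_contacts:
        raise ValueError("predicted contact set is empty")
    return len(pred_contacts - native_contacts) / len(pred_contacts)


def _interface_backbone(pred: tuple[Subunit, Subunit], native: tuple[Subunit, Subunit],
                        cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    contacts = eval_contacts(*native, cutoff=cutoff)
    if not contacts:
        raise ValueError("native complex has no interface at the cutoff")
    iface = [("a", k) for k in sorted({ka for ka, _ in contacts})] + \
            [("b", k) for k in sorted({kb for _, kb in contacts})]
    ref, mov = [], []
    for side, key in iface:
        nat_sub = native[0] if side == "a" else native[1]
        prd_sub = pred[0] if side == "a" else pred[1]
        try:
            nat_res = nat_sub.residue(key)
            prd_res = prd_sub.residue(key)
        except KeyError:
            raise ValueError(f"interface residue {key!r} unmatched in prediction") from None
        for name in BACKBONE_ATOMS:
            na, pa = nat_res.atom(name), prd_res.atom(name)
            if na is None or pa is None:
                if name == "O":
                    logger.warning("missing backbone O for %s; tolerated", key)
                    continue
                raise ValueError(f"missing backbone atom {name} for residue {key!r}")
            ref.append(na.coord)
            mov.append(pa.coord)
    if len(ref) < 3:
        raise ValueError("fewer than 3 matched interface backbone atoms")
    return np.asarray(ref, dtype=float), np.asarray(mov, dtype=float)


def irmsd(pred: tuple[Subunit, Subunit], native: tuple[Subunit, Subunit],
          cutoff: float = EVAL_CUTOFF) -> float:
    """Interface RMSD: backbone atoms of native-interface residues after
    optimal rigid superposition of predicted onto native interface."""
    ref, mov = _interface_backbone(pred, native, cutoff)
    _, _, rmsd = superpose(ref, mov)
    return rmsd


def capri_metrics(pred: tuple[Subunit, Subunit], native: tuple[Subunit, Subunit],
                  cutoff: float = EVAL_CUTOFF) -> CapriMetrics:
    native_c = eval_contacts(*native, cutoff=cutoff)
    pred_c = eval_contacts(*pred, cutoff=cutoff)
    return CapriMetrics(
        f_nat=fnat(pred_c, native_c),
        f_nonnat=fnonnat(pred_c, native_c) if pred_c else 0.0,
        i_rmsd=irmsd(pred, native, cutoff),
    )


def binding_site_pvalue(inputs: PValueInputs) -> float:
    """P(X >= n) for X ~ Binomial(N, m/M): chance that random picking does
    at least as well as the prediction. Equals 1 exactly at n = 0."""
    q = inputs.m / inputs.M
    if not 0.0 <= q <= 1.0:
        raise ValueError("success probability m/M outside [0, 1]")
    if inputs.n == 0:
        return 1.0
    return float(binom.sf(inputs.n - 1, inputs.N, q))
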