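"""Typed residue-residue contacts at a binary protein-protein interface.

A residue pair (one residue from each side of the interface) is a contact
when it can plausibly form at least one of three noncovalent interactions,
judged purely by heavy-atom distances:

* hydrogen bond — minimum distance between electronegative heavy atoms
  (N, O, S) of the two residues <= 3.5 A;
* salt bridge — minimum distance between charged-group atoms of a basic
  residue (K, R, H) and an acidic residue (D, E) <= 4.0 A;
* hydrophobic — minimum distance between apolar side-chain carbons of two
  hydrophobic residues <= 4.0 A, or any heavy atom of one residue within
  4.0 A of the aromatic-ring centroid of the other.

No hydrogens or angle terms are used.  Main-chain atoms participate by
default; ``scope="side_chain_only"`` restricts hydrogen bonds to
side-chain atoms (the convention used when comparing against mutagenesis,
which probes side chains only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sequences import one_letter
from .structure import Residue, ResidueRef, StructureModel

HBOND, SALT_BRIDGE, HYDROPHOBIC = "hydrogen_bond", "salt_bridge", "hydrophobic"

CUTOFFS = {HBOND: 3.5, SALT_BRIDGE: 4.0, HYDROPHOBIC: 4.0}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: charged-group heavy atoms per residue (1-letter code)
CHARGED_ATOMS = {
    "K": {"NZ"}, "R": {"NH1", "NH2", "NE"}, "H": {"ND1", "NE2"},
    "D": {"OD1", "OD2"}, "E": {"OE1", "OE2"},
}
BASIC, ACIDIC = {"K", "R", "H"}, {"D", "E"}

HYDROPHOBIC_RESIDUES = {"A", "V", "L", "I", "P", "F", "M", "W"}

#: ring heavy atoms defining the aromatic centroid
AROMATIC_RINGS = {
    "F": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "Y": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "W": {"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "H": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class Contact:
    residue_a: ResidueRef  # on partner A
    residue_b: ResidueRef  # on partner B
    type: str
    min_distance: float
    side_chain_only: bool  # True if realizable without main-chain atoms

    def __post_init__(self) -> None:
        if self.min_distance > CUTOFFS[self.type] + 1e-9:
            raise ContactError(f"{self.type} contact at {self.min_distance:.2f} A "
                               f"exceeds cutoff {CUTOFFS[self.type]} A")


class ContactSet:
    """Contacts of one model; (pair, type) combinations are unique."""

    def __init__(self, contacts: Iterable[Contact], source: str = "") -> None:
        self.contacts: list[Contact] = []
        seen = set()
        for c in contacts:
            key = (c.residue_a, c.residue_b, c.type)
            if key in seen:
                raise ContactError(f"duplicate contact {key}")
            seen.add(key)
            self.contacts.append(c)
        self.source = source

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def pairs(self) -> set[tuple[ResidueRef, ResidueRef]]:
        return {(c.residue_a, c.residue_b) for c in self.contacts}

    def typed_pairs(self) -> set[tuple[ResidueRef, ResidueRef, str]]:
        return {(c.residue_a, c.residue_b, c.type) for c in self.contacts}

    def residues_on_side(self, side: str) -> set[ResidueRef]:
        if side not in {"A", "B"}:
            raise ValueError("side must be 'A' or 'B'")
        return {c.residue_a if side == "A" else c.residue_b for c in self.contacts}

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "source": self.source,
            "chain_a": c.residue_a.chain, "resnum_a": c.residue_a.number,
            "chain_b": c.residue_b.chain, "resnum_b": c.residue_b.number,
            "type": c.type, "min_distance": c.min_distance,
            "side_chain_only": c.side_chain_only,
        } for c in self.contacts]
        return pd.DataFrame(rows, columns=["source", "chain_a", "resnum_a", "chain_b",
                                           "resnum_b", "type", "min_distance",
                                           "side_chain_only"])


def _min_dist(xs: np.ndarray, ys: np.ndarray) -> float:
    if len(xs) == 0 or len(ys) == 0:
        return float("inf")
    d2 = np.sum((xs[:, None, :] - ys[None, :, :]) ** 2, axis=2)
    return float(np.sqrt(d2.min()))


def _atom_coords(res: Residue, names: set[str] | None = None,
                 side_chain: bool | None = None, carbons_only: bool = False) -> np.ndarray:
    out = []
    for a in res.atoms:
        if a.element == "H":
            continue
        if names is not None and a.name not in names:
            continue
        if side_chain is True and a.name in BACKBONE_ATOMS:
            continue
        if carbons_only and a.element != "C":
            continue
        out.append(a.pos)
    return np.asarray(out, float).reshape(-1, 3)


def _electroneg(res: Residue, side_chain: bool) -> np.ndarray:
    out = [a.pos for a in res.atoms
           if a.element in {"N", "O", "S"}
           and not (side_chain and a.name in BACKBONE_ATOMS)]
    return np.asarray(out, float).reshape(-1, 3)


def _ring_centroid(res: Residue) -> np.ndarray | None:
    code = one_letter(res.name)
    ring = AROMATIC_RINGS.get(code)
    if ring is None:
        return None
    pts = _atom_coords(res, names=ring)
    if len(pts) < 3:
        return None
    return pts.mean(axis=0)


def _classify_pair(ra: Residue, rb: Residue, side_chain_only: bool) -> list[Contact]:
    """Apply the three criteria to one cross-interface residue pair."""
    code_a, code_b = one_letter(ra.name), one_letter(rb.name)
    found: list[Contact] = []

    d_hb = _min_dist(_electroneg(ra, side_chain_only), _electroneg(rb, side_chain_only))
    if d_hb <= CUTOFFS[HBOND]:
        d_sc = _min_dist(_electroneg(ra, True), _electroneg(rb, True))
        found.append(Contact(ra.ref, rb.ref, HBOND, d_hb, d_sc <= CUTOFFS[HBOND]))

    basic_acidic = ((code_a in BASIC and code_b in ACIDIC)
                    or (code_a in ACIDIC and code_b in BASIC))
    if basic_acidic:
        d_sb = _min_dist(_atom_coords(ra, names=CHARGED_ATOMS.get(code_a, set())),
                         _atom_coords(rb, names=CHARGED_ATOMS.get(code_b, set())))
        if d_sb <= CUTOFFS[SALT_BRIDGE]:
            found.append(Contact(ra.ref, rb.ref, SALT_BRIDGE, d_sb, True))

    d_best = float("inf")
    if code_a in HYDROPHOBIC_RESIDUES and code_b in HYDROPHOBIC_RESIDUES:
        d_best = _min_dist(_atom_coords(ra, side_chain=True, carbons_only=True),
                           _atom_coords(rb, side_chain=True, carbons_only=True))
    for first, second in ((ra, rb), (rb, ra)):
        centroid = _ring_centroid(second)
        if centroid is not None:
            pts = _atom_coords(first, side_chain=side_chain_only or None)
            if len(pts):
                d_best = min(d_best, float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).min())))
    if d_best <= CUTOFFS[HYDROPHOBIC]:
        found.append(Contact(ra.ref, rb.ref, HYDROPHOBIC, d_best, True))
    return found


def detect_contacts(s: StructureModel, chains_a: Sequence[str], chains_b: Sequence[str],
                    scope: str = "all", source: str = "") -> ContactSet:
    """Detect typed contacts between two chain groups of one structure.

    ``scope="all"`` considers main-chain and side-chain atoms;
    ``scope="side_chain_only"`` restricts hydrogen-bond (and ring-contact
    probe) atoms to side chains.  Charged-group and apolar-carbon sets are
    side-chain atoms by construction.
    """
    if scope not in {"all", "side_chain_only"}:
        raise ContactError(f"scope must be 'all' or 'side_chain_only', got {scope!r}")
    set_a, set_b = set(chains_a), set(chains_b)
    if set_a & set_b:
        raise ContactError(f"partitions overlap: {sorted(set_a & set_b)}")
    res_a = [r for r in s.residues if r.chain in set_a]
    res_b = [r for r in s.residues if r.chain in set_b]
    side_chain_only = scope == "side_chain_only"

    # prefilter candidate pairs by any-heavy-atom proximity
    coords_b, owner_b = [], []
    for j, rb in enumerate(res_b):
        for a in rb.atoms:
            if a.element != "H":
                coords_b.append(a.pos)
                owner_b.append(j)
    contacts: list[Contact] = []
    if coords_b:
        tree = cKDTree(np.asarray(coords_b))
        owner_b = np.asarray(owner_b)
        reach = max(CUTOFFS.values()) + 3.0  # ring-centroid rule can span extra
        for ra in res_a:
            pts = np.asarray([a.pos for a in ra.atoms if a.element != "H"])
            if not len(pts):
                continue
            hits = tree.query_ball_point(pts, reach)
            partners = sorted({int(owner_b[j]) for lst in hits for j in lst})
            for j in partners:
                contacts.extend(_classify_pair(ra, res_b[j], side_chain_only))
    return ContactSet(contacts, source=source)


def unique_contact_residues(ensemble_contacts: Sequence[ContactSet],
                            reference_contacts: ContactSet, side: str = "A",
                            ) -> pd.DataFrame:
    """Residues contacting the partner in the ensemble but never in the reference.

    The interaction frequency of a residue counts (model, contact)
    incidences across the ensemble.  Rows are sorted by descending
    frequency, ties broken by residue address.
    """
    reference = reference_contacts.residues_on_side(side)
    tally: dict[ResidueRef, int] = {}
    for cs in ensemble_contacts:
        for c in cs:
            res = c.residue_a if side == "A" else c.residue_b
            if res not in reference:
                tally[res] = tally.get(res, 0) + 1
    rows = [{"chain": r.chain, "resnum": r.number, "icode": r.icode, "frequency": n}
            for r, n in tally.items()]
    df = pd.DataFrame(rows, columns=["chain", "resnum", "icode", "frequency"])
    return df.sort_values(["frequency", "chain", "resnum", "icode"],
                          ascending=[False, True, True, True], ignore_index=True)


def structures_containing_contacts(ensemble_contacts: Sequence[ContactSet],
                                   query: Sequence[tuple[ResidueRef, ResidueRef, str]],
                                   ) -> tuple[int, np.ndarray]:
    """How many models contain at least one queried (pair, type) contact."""
    qset = {(a, b, t) for a, b, t in query}
    flags = np.array([bool(cs.typed_pairs() & qset) for cs in ensemble_contacts])
    return int(flags.sum()), flags


def contact_census(ensemble_contacts: Sequence[ContactSet]) -> dict[str, int]:
    """Three tallies over an ensemble: unique pairs, unique typed pairs,
    and (model, pair) incidences."""
    pairs, typed, incidences = set(), set(), 0
    for cs in ensemble_contacts:
        pairs |= cs.pairs()
        typed |= cs.typed_pairs()
        incidences += len(cs.pairs())
    return {"residue_pairs": len(pairs), "typed_pairs": len(typed),
            "model_pair_incidences": incidences}


def write_contact_csv(sets: Sequence[ContactSet], path: str | Path) -> None:
    pd.concat([cs.to_frame() for cs in sets], ignore_index=True).to_csv(path, index=False)
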