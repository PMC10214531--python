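"""Ground-truth synthetic complexes, cross-links and decoy configurations.

The toy generator builds a multi-body complex with idealized alpha-helical
Calpha geometry inside each rigid body (1.5 A rise and 100 degrees of turn
per residue on a 2.3 A helix radius) and extended linkers between
consecutive bodies of a chain.  Idealized geometry keeps every oracle
analytic: the ground-truth configuration, the feasible cross-link set and
the planted-cluster structure of perturbed ensembles are all known by
construction.  Real structures differ in side-chain packing, irregular
secondary structure and atomic detail, which the generator deliberately
does not emulate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .crosslinks import (CrossLink, CrossLinkSet, LinkerSpec, canonical_pair,
                         distance_threshold, enumerate_theoretical_links,
                         _reactive_sites)
from .modeling import Configuration
from .sequences import three_letter
from .structure import Atom, Residue, ResidueRef, StructureModel

#: default residue-type mix: reactive residues for the common chemistries
#: (K, R, D, E, S, T, Y) plus a hydrophobic/other remainder.
DEFAULT_ALPHABET = {
    "K": 0.12, "R": 0.08, "D": 0.08, "E": 0.10, "S": 0.08, "T": 0.06,
    "Y": 0.04, "A": 0.14, "L": 0.14, "V": 0.08, "G": 0.08,
}


class SynthError(ValueError):
    pass


#: simplified terminal side-chain atom (name, element, reach from CA in A)
#: giving toy residues just enough chemistry for contact/SASA analysis
_SIDECHAIN_TIP = {
    "K": ("NZ", "N", 5.0), "R": ("NH1", "N", 5.5),
    "D": ("OD1", "O", 2.9), "E": ("OE1", "O", 3.8),
    "S": ("OG", "O", 2.4), "T": ("OG1", "O", 2.4), "Y": ("OH", "O", 6.0),
}


@dataclass
class ToySpec:
    """Recipe for a deterministic toy complex of helical rigid bodies."""

    n_bodies: int = 3
    residues_per_body: int = 30
    linker_length: int = 8  # residues between consecutive bodies of a chain
    alphabet: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHABET))
    seed: int = 0
    body_spacing: float = 24.0  # A between consecutive body centers
    chains: list[int] | None = None  # body index -> chain index; default: all one chain
    with_sidechains: bool = False  # add CB + terminal polar/charged atom per residue

    def __post_init__(self) -> None:
        if self.n_bodies < 1 or self.residues_per_body < 3:
            raise SynthError("need >= 1 body with >= 3 residues each")
        total = sum(self.alphabet.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise SynthError(f"alphabet fractions must sum to 1, got {total}")
        if self.chains is not None and len(self.chains) != self.n_bodies:
            raise SynthError("chains must assign one chain index per body")


@dataclass
class ToyComplex:
    structure: StructureModel
    body_spec: dict[str, list[ResidueRef]]  # body name -> ordered residues
    linker_residues: list[ResidueRef]
    truth_body_centers: np.ndarray  # (n_bodies, 3)


def _helix_coords(n: int, rise: float = 1.5, twist_deg: float = 100.0,
                  radius: float = 2.3) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def _body_centers(n: int, spacing: float) -> np.ndarray:
    """Compact body placement: mutually adjacent centers, like the packed
    subunits of a real multi-domain complex.

    2 bodies sit ``spacing`` apart; 3 form an equilateral triangle; 4 a
    regular tetrahedron; more are placed on a ring with neighbour chord
    ``spacing``.
    """
    if n == 1:
        return np.zeros((1, 3))
    if n == 2:
        return np.array([[0.0, 0, 0], [spacing, 0, 0]])
    if n == 3:
        h = spacing * math.sqrt(3) / 2
        return np.array([[0.0, 0, 0], [spacing, 0, 0], [spacing / 2, h, 0]])
    if n == 4:
        verts = np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        return spacing / (2 * math.sqrt(2)) * verts  # edge length = spacing
    radius = spacing / (2 * math.sin(math.pi / n))
    theta = 2 * math.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                            np.zeros(n)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def generate_toy_complex(spec: ToySpec) -> ToyComplex:
    """Build a toy complex with known body placement.

    Bodies sit at ``body_spacing`` intervals along x with seeded random
    orientations; each is an ideal helix.  Consecutive bodies on the same
    chain are joined by an extended linker interpolated between the
    flanking body ends.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    chain_of = spec.chains or [0] * spec.n_bodies
    chain_names = [chr(ord("A") + c) for c in chain_of]

    local = _helix_coords(spec.residues_per_body)
    local = local - local.mean(axis=0)
    centers0 = _body_centers(spec.n_bodies, spec.body_spacing)
    # seeded rejection sampling of orientations; restart the whole layout if
    # an earlier body boxes a later vertex in
    body_coords: list[np.ndarray] = []
    for restart in range(60):
        body_coords = []
        ok = True
        for b in range(spec.n_bodies):
            for attempt in range(100):
                coords = local @ _random_rotation(rng).T + centers0[b]
                dmin = min((np.sqrt(((coords[:, None] - prev[None]) ** 2).sum(-1)
                                    ).min() for prev in body_coords), default=np.inf)
                if dmin >= 4.0:
                    break
            else:
                ok = False
                break
            body_coords.append(coords)
        if ok:
            break
    else:
        raise SynthError("bodies cannot be placed without overlap; "
                         "increase body_spacing")
    centers = np.asarray([c.mean(axis=0) for c in body_coords])

    codes = list(spec.alphabet)
    probs = np.array([spec.alphabet[c] for c in codes])

    residues: list[Residue] = []
    body_spec: dict[str, list[ResidueRef]] = {}
    linker_refs: list[ResidueRef] = []
    counters: dict[str, int] = {}

    def add_residue(chain: str, pos: np.ndarray, outward: np.ndarray | None = None,
                    ) -> ResidueRef:
        counters[chain] = counters.get(chain, 0) + 1
        num = counters[chain]
        code = rng.choice(codes, p=probs)
        pos = np.asarray(pos, float)
        atoms = [Atom("CA", "C", pos)]
        if spec.with_sidechains and code != "G":
            u = outward if outward is not None else rng.normal(size=3)
            u = u / np.linalg.norm(u)
            atoms.append(Atom("CB", "C", pos + 1.53 * u))
            tip = _SIDECHAIN_TIP.get(code)
            if tip is not None:
                name, element, reach = tip
                atoms.append(Atom(name, element, pos + reach * u))
        res = Residue(chain, num, three_letter(code), "", atoms)
        residues.append(res)
        return res.ref

    all_body_coords = np.vstack(body_coords)
    prev_body_of_chain: dict[str, int] = {}
    for b in range(spec.n_bodies):
        chain = chain_names[b]
        prev = prev_body_of_chain.get(chain)
        if prev is not None and spec.linker_length > 0:
            start = body_coords[prev][-1]
            end = body_coords[b][0]
            init = np.array([start + k / (spec.linker_length + 1) * (end - start)
                             + rng.normal(scale=0.3, size=3)
                             for k in range(1, spec.linker_length + 1)])
            relaxed = _relax_linker(init, start, end, all_body_coords)
            for pos in relaxed:
                linker_refs.append(add_residue(chain, pos))
        refs = [add_residue(chain, pos, outward=pos - centers[b]) for pos in body_coords[b]]
        body_spec[f"body{b}"] = refs
        prev_body_of_chain[chain] = b

    structure = StructureModel(residues, label=f"toy(seed={spec.seed})")
    return ToyComplex(structure, body_spec, linker_refs, centers)


def _relax_linker(init: np.ndarray, anchor0: np.ndarray, anchor1: np.ndarray,
                  obstacles: np.ndarray, clearance: float = 6.5,
                  bond_d0: float = 3.8) -> np.ndarray:
    """Push linker beads out of the rigid bodies while staying chain-like.

    Minimises the same functional forms the sampler scores — stretch of
    consecutive bonds beyond ``bond_d0`` plus quadratic overlap of each
    bead with body residues (at the largest bead-pair clearance) and with
    its non-bonded linker neighbours — so a generated complex is a
    low-energy configuration of its own restraint set.  Deterministic.
    """
    from scipy.optimize import minimize

    n = len(init)
    # the bonded flanking residues are not obstacles
    keep = (np.linalg.norm(obstacles - anchor0, axis=1) > 1e-9) \
        & (np.linalg.norm(obstacles - anchor1, axis=1) > 1e-9)
    obstacles = obstacles[keep]

    def objective(flat: np.ndarray) -> float:
        x = flat.reshape(n, 3)
        chain = np.vstack([anchor0, x, anchor1])
        bond = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        e = np.sum(np.maximum(0.0, bond - bond_d0) ** 2)
        d_obs = np.linalg.norm(x[:, None, :] - obstacles[None, :, :], axis=2)
        e += np.sum(np.maximum(0.0, clearance - d_obs) ** 2)
        for gap in range(2, n):
            d = np.linalg.norm(x[:-gap] - x[gap:], axis=1)
            e += np.sum(np.maximum(0.0, clearance - d) ** 2)
        return float(e)

    res = minimize(objective, init.ravel(), method="L-BFGS-B",
                   options={"maxiter": 400})
    return res.x.reshape(n, 3)


def simulate_crosslinks(s: StructureModel, linker: LinkerSpec, n: int,
                        false_positive_rate: float = 0.0, seed: int = 0,
                        ) -> tuple[CrossLinkSet, dict[tuple, bool]]:
    """Draw a cross-link set from a structure with a planted error rate.

    True links are sampled uniformly from the feasible (within-threshold)
    reactive pairs; false positives are sampled from reactivity-compatible
    pairs *exceeding* the threshold, so chemistry filters cannot remove
    them trivially.  Returns the set plus a truth map keyed by the
    canonical pair key (True = genuine link).  Replicate counts are set
    to 2, mimicking links surviving the reproducibility filter.
    """
    if not 0.0 <= false_positive_rate <= 1.0:
        raise SynthError("false_positive_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    feasible, _ = enumerate_theoretical_links(s, linker)
    if not feasible:
        raise SynthError(f"no feasible {linker.name} pairs in structure")

    threshold = distance_threshold(linker)
    alpha = _reactive_sites(s, linker.alpha_reactivity)
    beta = _reactive_sites(s, linker.beta_reactivity)
    compatible = set()
    for a in alpha:
        for b in beta:
            if (a.chain, a.number, a.icode) != (b.chain, b.number, b.icode):
                compatible.add(canonical_pair(a, b))
    infeasible = sorted(compatible - feasible,
                        key=lambda p: (p[0].chain, p[0].number, p[1].chain, p[1].number))
    feasible_sorted = sorted(feasible,
                             key=lambda p: (p[0].chain, p[0].number, p[1].chain, p[1].number))

    n_false = int(round(n * false_positive_rate))
    n_true = n - n_false
    if n_true > len(feasible_sorted):
        warnings.warn(f"requested {n_true} true links but only {len(feasible_sorted)} "
                      "feasible pairs; capping", stacklevel=2)
        n_true = len(feasible_sorted)
    if n_false > len(infeasible):
        warnings.warn(f"requested {n_false} false links but only {len(infeasible)} "
                      "over-threshold pairs; capping", stacklevel=2)
        n_false = len(infeasible)

    chosen_true = [feasible_sorted[i] for i in
                   rng.choice(len(feasible_sorted), size=n_true, replace=False)]
    chosen_false = [infeasible[i] for i in
                    rng.choice(len(infeasible), size=n_false, replace=False)]

    links, truth = [], {}
    for pair, is_true in [(p, True) for p in chosen_true] + [(p, False) for p in chosen_false]:
        link = CrossLink(pair[0], pair[1], linker.name, replicate_count=2, best_evalue=1e-5)
        links.append(link)
        truth[link.pair_key] = is_true
    links.sort(key=lambda l: l.pair_key)
    return CrossLinkSet(links, provenance={
        "simulated": True, "seed": seed, "fpr": false_positive_rate,
        "linker": linker.name, "threshold": threshold}), truth


def perturb_configuration(truth: Configuration, translation_sigma: float = 0.0,
                          rotation_sigma_deg: float = 0.0, seed: int = 0,
                          ) -> Configuration:
    """Random rigid perturbation of every body of a configuration.

    Each body receives an independent gaussian translation (sigma per
    axis, A) and a rotation by a gaussian angle about a random axis.
    Bead positions are left untouched.  ``sigma = 0`` returns an exact
    copy; deterministic per seed.
    """
    if translation_sigma < 0 or rotation_sigma_deg < 0:
        raise SynthError("perturbation sigmas must be >= 0")
    rng = np.random.default_rng(seed)
    out = truth.copy()
    for b in range(len(out.body_rotations)):
        if rotation_sigma_deg > 0:
            angle = math.radians(rng.normal(scale=rotation_sigma_deg))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
            out.body_rotations[b] = rot @ out.body_rotations[b]
        if translation_sigma > 0:
            out.body_translations[b] = out.body_translations[b] \
                + rng.normal(scale=translation_sigma, size=3)
    return out
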