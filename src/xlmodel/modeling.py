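"""Coarse-grained integrative structure modeling.

The complex is represented at one bead per residue (bead at the Calpha
position).  Residues named in the body specification form rigid bodies
whose internal coordinates are frozen from the input structure; all other
residues are flexible beads.  A configuration is scored by a sum of four
non-negative terms:

* cross-link: flat-bottom harmonic ``max(0, d - threshold)^2 / sigma^2``
  per link, zero while the link is satisfied;
* connectivity: ``max(0, d - d0)^2`` over consecutive-residue pairs not
  frozen inside one body, with ``d0 = 3.8 A`` (the Calpha virtual bond);
* excluded volume: ``max(0, r_i + r_j - d)^2`` over non-bonded bead pairs
  not frozen inside one body;
* membrane: squared out-of-slab displacement of designated transmembrane
  residues for a flat slab normal to z (half-thickness 15 A by default).

Sampling is single-temperature Metropolis Monte Carlo over rigid-body
rotations/translations and bead translations, with deterministic replay
for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, ks_2samp

from .crosslinks import CrossLinkSet, DEFAULT_LINKERS, LinkerSpec, distance_threshold
from .sequences import one_letter
from .structure import (Atom, Residue, ResidueRef, StructureModel,
                        pairwise_rmsd_matrix, write_structure)

logger = logging.getLogger(__name__)


class ModelingConfigError(ValueError):
    pass


#: per-residue bead radii (A) by side-chain volume class
_SMALL = set("GASC")
_LARGE = set("FWYRKHML")
BEAD_RADIUS = {"small": 2.3, "medium": 2.8, "large": 3.2}


def bead_radius_for(code: str) -> float:
    if code in _SMALL:
        return BEAD_RADIUS["small"]
    if code in _LARGE:
        return BEAD_RADIUS["large"]
    return BEAD_RADIUS["medium"]


# ---------------------------------------------------------------------------
# Representation
# ---------------------------------------------------------------------------


@dataclass
class Representation:
    """Partition of all residues into rigid bodies and flexible beads."""

    residue_refs: list[ResidueRef]  # canonical order = structure order
    reference_coords: np.ndarray  # (n, 3) Calpha positions from the source
    body_names: list[str]
    body_members: list[np.ndarray]  # per body, indices into residue_refs
    bead_indices: np.ndarray  # flexible single-residue beads
    bead_radii: np.ndarray  # (n,) per-residue radius, A
    connectivity_pairs: np.ndarray  # (m, 2) consecutive pairs not frozen in a body
    ev_mask: np.ndarray  # (n, n) bool: pairs subject to excluded volume
    interpolated: list[ResidueRef] = field(default_factory=list)  # placed by interpolation

    @property
    def n_residues(self) -> int:
        return len(self.residue_refs)

    @property
    def n_bodies(self) -> int:
        return len(self.body_members)

    def index_of(self, ref: ResidueRef) -> int:
        try:
            return self._index[(ref.chain, ref.number, ref.icode)]
        except AttributeError:
            self._index = {(r.chain, r.number, r.icode): i
                           for i, r in enumerate(self.residue_refs)}
            return self.index_of(ref)

    def membership(self, ref: ResidueRef) -> tuple[str, int]:
        i = self.index_of(ref)
        for b, members in enumerate(self.body_members):
            if i in members:
                return ("body", b)
        return ("bead", i)


def build_representation(s: StructureModel,
                         body_spec: Mapping[str, Sequence[ResidueRef]],
                         ss_annotation: Mapping[ResidueRef, str] | None = None,
                         xl: CrossLinkSet | None = None,
                         linkers: Mapping[str, LinkerSpec] | None = None,
                         ) -> Representation:
    """Build the rigid-body/bead representation of a structure.

    ``body_spec`` maps body names to ordered residue lists; the ranges
    must not overlap.  Residues outside every body become single-residue
    beads.  If ``ss_annotation`` is given (per-residue ``helix``/``sheet``/
    ``coil``), maximal helix/sheet runs of >= 3 residues outside the named
    bodies are promoted to additional rigid bodies — unless freezing the
    run would violate a cross-link internal to it (checked against ``xl``
    when provided).

    A residue lacking a Calpha atom is placed by linear interpolation
    between the nearest flanking residues of its chain that have one, and
    flagged in ``Representation.interpolated``.
    """
    refs = [r.ref for r in s.residues]
    index = {(r.chain, r.number, r.icode): i for i, r in enumerate(refs)}

    coords = np.zeros((len(refs), 3))
    interpolated: list[ResidueRef] = []
    chain_positions: dict[str, list[int]] = {}
    for i, res in enumerate(s.residues):
        chain_positions.setdefault(res.chain, []).append(i)
        ca = res.ca
        coords[i] = ca.pos if ca is not None else np.nan
    for chain, idxs in chain_positions.items():
        have = [i for i in idxs if np.isfinite(coords[i]).all()]
        if not have:
            raise ModelingConfigError(f"chain {chain} has no Calpha atoms at all")
        for pos, i in enumerate(idxs):
            if np.isfinite(coords[i]).all():
                continue
            before = [j for j in have if idxs.index(j) < pos]
            after = [j for j in have if idxs.index(j) > pos]
            if before and after:
                a, b = before[-1], after[0]
                frac = (pos - idxs.index(a)) / (idxs.index(b) - idxs.index(a))
                coords[i] = coords[a] + frac * (coords[b] - coords[a])
            else:
                anchor = before[-1] if before else after[0]
                coords[i] = coords[anchor] + np.array([3.8, 0, 0])
            interpolated.append(refs[i])

    assigned = np.full(len(refs), -1)
    body_names: list[str] = []
    body_members: list[np.ndarray] = []

    def add_body(name: str, members: Sequence[ResidueRef]) -> None:
        if len(members) < 3:
            raise ModelingConfigError(f"rigid body {name!r} has {len(members)} residues; "
                                      "minimum is 3")
        idx = []
        for ref in members:
            key = (ref.chain, ref.number, ref.icode)
            if key not in index:
                raise ModelingConfigError(f"body {name!r}: residue {ref} not in structure")
            i = index[key]
            if assigned[i] >= 0:
                raise ModelingConfigError(
                    f"residue {ref} assigned to both {body_names[assigned[i]]!r} and {name!r}")
            idx.append(i)
        for i in idx:
            assigned[i] = len(body_names)
        body_names.append(name)
        body_members.append(np.asarray(sorted(idx)))

    for name, members in body_spec.items():
        add_body(name, list(members))

    if ss_annotation:
        linkers = linkers or DEFAULT_LINKERS
        for chain, idxs in chain_positions.items():
            run: list[int] = []
            for i in idxs + [-1]:
                ss = ss_annotation.get(refs[i], "coil") if i >= 0 else "coil"
                if i >= 0 and assigned[i] < 0 and ss in {"helix", "sheet"}:
                    run.append(i)
                    continue
                if len(run) >= 3 and _run_respects_links(run, refs, coords, xl, linkers):
                    add_body(f"auto_{chain}_{refs[run[0]].number}", [refs[j] for j in run])
                run = []

    bead_indices = np.flatnonzero(assigned < 0)
    radii = np.array([bead_radius_for(one_letter(res.name)) for res in s.residues])

    # consecutive pairs within a chain, skipping pairs frozen inside one body
    conn = []
    for chain, idxs in chain_positions.items():
        for a, b in zip(idxs, idxs[1:]):
            if assigned[a] >= 0 and assigned[a] == assigned[b]:
                continue
            conn.append((a, b))
    conn = np.asarray(conn, int).reshape(-1, 2)

    n = len(refs)
    same_body = np.zeros((n, n), bool)
    for members in body_members:
        same_body[np.ix_(members, members)] = True
    ev_mask = ~same_body
    np.fill_diagonal(ev_mask, False)
    for a, b in conn:
        ev_mask[a, b] = ev_mask[b, a] = False
    ev_mask &= np.triu(np.ones((n, n), bool), 1)

    return Representation(refs, coords, body_names, body_members, bead_indices,
                          radii, conn, ev_mask, interpolated)


def _run_respects_links(run, refs, coords, xl, linkers) -> bool:
    """Would freezing this run violate any cross-link internal to it?"""
    if xl is None:
        return True
    keys = {(refs[i].chain, refs[i].number, refs[i].icode): i for i in run}
    for link in xl:
        ka = (link.site_a.chain, link.site_a.number, link.site_a.icode)
        kb = (link.site_b.chain, link.site_b.number, link.site_b.icode)
        if ka in keys and kb in keys:
            d = float(np.linalg.norm(coords[keys[ka]] - coords[keys[kb]]))
            if d > distance_threshold(linkers[link.linker]):
                return False
    return True


# ---------------------------------------------------------------------------
# Configurations and scoring
# ---------------------------------------------------------------------------


@dataclass
class Configuration:
    """Pose of every rigid body plus positions of all flexible beads."""

    body_rotations: np.ndarray  # (n_bodies, 3, 3), proper rotations
    body_translations: np.ndarray  # (n_bodies, 3)
    bead_positions: np.ndarray  # (n_beads, 3)

    @classmethod
    def identity(cls, rep: Representation) -> "Configuration":
        nb = rep.n_bodies
        return cls(np.broadcast_to(np.eye(3), (nb, 3, 3)).copy(),
                   np.zeros((nb, 3)),
                   rep.reference_coords[rep.bead_indices].copy())

    def copy(self) -> "Configuration":
        return Configuration(self.body_rotations.copy(), self.body_translations.copy(),
                             self.bead_positions.copy())

    def coords(self, rep: Representation) -> np.ndarray:
        """Bead coordinates of every residue, (n, 3), in canonical order."""
        out = rep.reference_coords.copy()
        for b, members in enumerate(rep.body_members):
            ref = rep.reference_coords[members]
            center = ref.mean(axis=0)
            out[members] = (ref - center) @ self.body_rotations[b].T \
                + center + self.body_translations[b]
        out[rep.bead_indices] = self.bead_positions
        return out


@dataclass
class MembraneSlab:
    """Flat membrane slab normal to z restraining designated residues."""

    residues: list[ResidueRef] = field(default_factory=list)
    half_thickness: float = 15.0
    center_z: float = 0.0


@dataclass
class ScoreBreakdown:
    crosslink_term: float
    membrane_term: float
    connectivity_term: float
    excluded_volume_term: float
    total: float


class Scorer:
    """Precompiled scoring function for one representation + restraint set.

    Cross-linked residues that cannot be resolved in the representation
    are excluded from scoring with a logged warning.
    """

    CONNECTIVITY_D0 = 3.8  # A, consecutive-residue Calpha spacing

    def __init__(self, rep: Representation, xl: CrossLinkSet | None = None,
                 membrane: MembraneSlab | None = None,
                 linkers: Mapping[str, LinkerSpec] | None = None,
                 crosslink_sigma: float = 1.0) -> None:
        self.rep = rep
        self.sigma2 = crosslink_sigma ** 2
        linkers = linkers or DEFAULT_LINKERS
        xl_pairs, xl_thresholds = [], []
        self.unmappable: list = []
        for link in (xl or []):
            try:
                ia = rep.index_of(link.site_a)
                ib = rep.index_of(link.site_b)
            except KeyError:
                self.unmappable.append(link)
                continue
            xl_pairs.append((ia, ib))
            xl_thresholds.append(distance_threshold(linkers[link.linker]))
        if self.unmappable:
            logger.warning("%d cross-links not resolvable in representation; excluded",
                           len(self.unmappable))
        self.xl_pairs = np.asarray(xl_pairs, int).reshape(-1, 2)
        self.xl_thresholds = np.asarray(xl_thresholds)
        self.membrane = membrane
        if membrane is not None and membrane.residues:
            self.membrane_idx = np.asarray([rep.index_of(r) for r in membrane.residues])
        else:
            self.membrane_idx = np.zeros(0, int)
        iu, ju = np.nonzero(rep.ev_mask)
        self.ev_i, self.ev_j = iu, ju
        self.ev_sum_radii = rep.bead_radii[iu] + rep.bead_radii[ju]

    def __call__(self, config: Configuration) -> ScoreBreakdown:
        return self.score_coords(config.coords(self.rep))

    def score_coords(self, coords: np.ndarray) -> ScoreBreakdown:
        xl_term = 0.0
        if len(self.xl_pairs):
            d = np.linalg.norm(coords[self.xl_pairs[:, 0]] - coords[self.xl_pairs[:, 1]],
                               axis=1)
            xl_term = float(np.sum(np.maximum(0.0, d - self.xl_thresholds) ** 2) / self.sigma2)

        conn_term = 0.0
        cp = self.rep.connectivity_pairs
        if len(cp):
            d = np.linalg.norm(coords[cp[:, 0]] - coords[cp[:, 1]], axis=1)
            conn_term = float(np.sum(np.maximum(0.0, d - self.CONNECTIVITY_D0) ** 2))

        ev_term = 0.0
        if len(self.ev_i):
            d = np.linalg.norm(coords[self.ev_i] - coords[self.ev_j], axis=1)
            ev_term = float(np.sum(np.maximum(0.0, self.ev_sum_radii - d) ** 2))

        mem_term = 0.0
        if len(self.membrane_idx):
            z = coords[self.membrane_idx, 2] - self.membrane.center_z
            excess = np.maximum(0.0, np.abs(z) - self.membrane.half_thickness)
            mem_term = float(np.sum(excess ** 2))

        total = xl_term + mem_term + conn_term + ev_term
        return ScoreBreakdown(xl_term, mem_term, conn_term, ev_term, total)


def score(config: Configuration, rep: Representation, xl: CrossLinkSet | None = None,
          membrane: MembraneSlab | None = None,
          linkers: Mapping[str, LinkerSpec] | None = None,
          crosslink_sigma: float = 1.0) -> ScoreBreakdown:
    """Score one configuration (convenience wrapper around :class:`Scorer`)."""
    return Scorer(rep, xl, membrane, linkers, crosslink_sigma)(config)


# ---------------------------------------------------------------------------
# Monte Carlo sampling
# ---------------------------------------------------------------------------


@dataclass
class MoveSizes:
    body_translation: float = 2.0  # A, gaussian sigma per axis
    body_rotation_deg: float = 10.0  # gaussian sigma of rotation angle
    bead_translation: float = 1.0


@dataclass
class ConfigurationEnsemble:
    """Recorded configurations of one sampling run (or a loaded ensemble)."""

    representation: Representation
    configurations: list[Configuration]
    scores: list[ScoreBreakdown]
    meta: dict = field(default_factory=dict)
    cluster_labels: np.ndarray | None = None
    precision: float | None = None

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def totals(self) -> np.ndarray:
        return np.array([s.total for s in self.scores])

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.totals))

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords(self.representation) for c in self.configurations])

    def subsample(self, n: int, seed: int = 0) -> "ConfigurationEnsemble":
        """Seeded uniform draw of n configurations (without replacement)."""
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(self), size=min(n, len(self)), replace=False))
        return ConfigurationEnsemble(
            self.representation,
            [self.configurations[i] for i in idx],
            [self.scores[i] for i in idx],
            {**self.meta, "subsampled_from": len(self), "subsample_seed": seed})

    def score_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "model": i, "crosslink": s.crosslink_term, "membrane": s.membrane_term,
            "connectivity": s.connectivity_term, "excluded_volume": s.excluded_volume_term,
            "total": s.total,
        } for i, s in enumerate(self.scores)])


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def sample_monte_carlo(rep: Representation, xl: CrossLinkSet | None = None,
                       membrane: MembraneSlab | None = None, n_steps: int = 50_000,
                       seed: int = 0, move_sizes: MoveSizes | None = None,
                       temperature_schedule: Sequence[tuple[float, float]] | float = 1.0,
                       record_every: int | None = None,
                       start: Configuration | None = None,
                       randomize_start: bool = True,
                       burn_in: float = 0.2,
                       linkers: Mapping[str, LinkerSpec] | None = None,
                       ) -> ConfigurationEnsemble:
    """Metropolis Monte Carlo over body poses and bead positions.

    ``temperature_schedule`` is either a constant temperature or a list of
    ``(fraction_of_run, temperature)`` breakpoints.  Every ``record_every``
    steps after the burn-in fraction of the run the current configuration
    is recorded with its score breakdown; the best-scoring configuration
    seen is always recorded last.  Identical
    ``(seed, inputs)`` reproduce the trajectory exactly.  If no move is
    accepted within a calibration window, move sizes are halved with a
    logged warning.
    """
    if n_steps < 1:
        raise ModelingConfigError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    move_sizes = move_sizes or MoveSizes()
    trans_sigma = move_sizes.body_translation
    rot_sigma = math.radians(move_sizes.body_rotation_deg)
    bead_sigma = move_sizes.bead_translation
    record_every = record_every or max(1, n_steps // 500)
    scorer = Scorer(rep, xl, membrane, linkers)

    current = (start.copy() if start is not None else Configuration.identity(rep))
    if start is None and randomize_start:
        for b in range(rep.n_bodies):
            current.body_rotations[b] = _axis_angle_matrix(
                rng.normal(size=3), rng.uniform(0, math.pi))
            current.body_translations[b] = rng.normal(scale=5.0, size=3)
        current.bead_positions += rng.normal(scale=2.0, size=current.bead_positions.shape)

    current_score = scorer(current)
    best = current.copy()
    best_score = current_score

    n_bodies, n_beads = rep.n_bodies, len(rep.bead_indices)
    n_movers = n_bodies + n_beads
    if n_movers == 0:
        raise ModelingConfigError("representation has nothing to move")

    def temperature_at(step: int) -> float:
        if isinstance(temperature_schedule, (int, float)):
            return float(temperature_schedule)
        frac = step / n_steps
        temp = temperature_schedule[0][1]
        for f, t in temperature_schedule:
            if frac >= f:
                temp = t
        return float(temp)

    configs: list[Configuration] = []
    breakdowns: list[ScoreBreakdown] = []
    accepted_in_window = 0
    window = max(200, record_every)
    n_accept = 0

    for step in range(1, n_steps + 1):
        # bodies and beads each get half the moves: bead counts usually dwarf
        # body counts and would otherwise starve pose sampling
        if n_bodies and n_beads:
            if rng.random() < 0.5:
                mover = int(rng.integers(n_bodies))
            else:
                mover = n_bodies + int(rng.integers(n_beads))
        else:
            mover = int(rng.integers(n_movers))
        proposal = current.copy()
        if mover < n_bodies:
            kind = int(rng.integers(2))
            if kind == 0:
                proposal.body_translations[mover] += rng.normal(scale=trans_sigma, size=3)
            else:
                angle = rng.normal(scale=rot_sigma)
                rot = _axis_angle_matrix(rng.normal(size=3), angle)
                proposal.body_rotations[mover] = rot @ proposal.body_rotations[mover]
        else:
            proposal.bead_positions[mover - n_bodies] += rng.normal(scale=bead_sigma, size=3)

        new_score = scorer(proposal)
        delta = new_score.total - current_score.total
        temp = temperature_at(step)
        if delta <= 0 or rng.random() < math.exp(-delta / max(temp, 1e-12)):
            current, current_score = proposal, new_score
            n_accept += 1
            accepted_in_window += 1
            if current_score.total < best_score.total:
                best, best_score = current.copy(), current_score

        if step % window == 0:
            if accepted_in_window == 0:
                trans_sigma *= 0.5
                rot_sigma *= 0.5
                bead_sigma *= 0.5
                logger.warning("no acceptances in %d steps at step %d; halving move sizes",
                               window, step)
            accepted_in_window = 0

        if step % record_every == 0 and step > burn_in * n_steps:
            configs.append(current.copy())
            breakdowns.append(current_score)

    configs.append(best.copy())
    breakdowns.append(best_score)
    meta = {"seed": seed, "n_steps": n_steps, "record_every": record_every,
            "burn_in": burn_in,
            "acceptance_rate": n_accept / n_steps,
            "temperature_schedule": temperature_schedule,
            "n_unmappable_links": len(scorer.unmappable)}
    return ConfigurationEnsemble(rep, configs, breakdowns, meta)


# ---------------------------------------------------------------------------
# Clustering and convergence
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-model cluster id, 0-based, largest cluster first
    populations: np.ndarray  # models per cluster
    precisions: np.ndarray  # mean member-to-centroid RMSD per cluster, A
    centroids: np.ndarray  # model index of each cluster centroid
    ensemble_precision: float  # same statistic over the whole ensemble
    rmsd_matrix: np.ndarray

    @property
    def main_cluster_fraction(self) -> float:
        return float(self.populations[0] / self.populations.sum())


def _centroid_and_precision(rmsd: np.ndarray, members: np.ndarray) -> tuple[int, float]:
    sub = rmsd[np.ix_(members, members)]
    centroid_local = int(np.argmin(sub.sum(axis=1)))
    precision = float(sub[centroid_local].mean())
    return int(members[centroid_local]), precision


def cluster_ensemble(e: ConfigurationEnsemble, threshold: float,
                     rmsd_matrix: np.ndarray | None = None) -> ClusterResult:
    """Single-linkage clustering of an ensemble at an RMSD threshold (A).

    Pairwise RMSDs use optimal superposition of bead coordinates.  The
    per-cluster precision is the mean RMSD of members to the cluster
    centroid (the member minimising the summed RMSD); label 0 is the most
    populated cluster.  Labels and precision are stored on the ensemble.
    """
    if threshold <= 0:
        raise ModelingConfigError("clustering threshold must be > 0")
    if len(e) < 2:
        raise ModelingConfigError("clustering needs >= 2 configurations")
    if rmsd_matrix is None:
        rmsd_matrix = pairwise_rmsd_matrix(list(e.coords_array()))
    condensed = squareform(rmsd_matrix, checks=False)
    raw = fcluster(linkage(condensed, method="single"), t=threshold, criterion="distance")
    sizes = {c: int((raw == c).sum()) for c in np.unique(raw)}
    order = sorted(sizes, key=lambda c: (-sizes[c], c))
    labels = np.array([order.index(c) for c in raw])

    populations, precisions, centroids = [], [], []
    for c in range(len(order)):
        members = np.flatnonzero(labels == c)
        centroid, prec = _centroid_and_precision(rmsd_matrix, members)
        populations.append(len(members))
        precisions.append(prec)
        centroids.append(centroid)
    _, ens_prec = _centroid_and_precision(rmsd_matrix, np.arange(len(e)))
    e.cluster_labels = labels
    e.precision = precisions[0]
    return ClusterResult(labels, np.asarray(populations), np.asarray(precisions),
                         np.asarray(centroids), ens_prec, rmsd_matrix)


@dataclass
class ConvergenceReport:
    score_ks_statistic: float
    score_ks_pvalue: float
    contingency_pvalue: float
    cluster_populations: pd.DataFrame  # clusters x runs
    sampling_precision: float  # smallest threshold with indistinguishable populations
    converged: bool


def _contingency_pvalue(table: np.ndarray) -> float:
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2:
        return 1.0
    return float(chi2_contingency(table)[1])


def assess_sampling(run1: ConfigurationEnsemble, run2: ConfigurationEnsemble,
                    threshold_grid: Sequence[float] | None = None,
                    alpha: float = 0.05) -> ConvergenceReport:
    """Compare two independent-seed runs on identical inputs.

    Reports a two-sample KS test on total scores, a chi-square contingency
    test on joint-cluster populations, and the sampling precision: the
    smallest clustering threshold at which the two runs' cluster
    populations are statistically indistinguishable (p > alpha).  The run
    pair is flagged converged when both tests pass at that precision.
    """
    if run1.representation.n_residues != run2.representation.n_residues:
        raise ModelingConfigError("runs were sampled from different representations")
    ks_stat, ks_p = ks_2samp(run1.totals, run2.totals)

    coords = list(run1.coords_array()) + list(run2.coords_array())
    origin = np.array([0] * len(run1) + [1] * len(run2))
    rmsd = pairwise_rmsd_matrix(coords)
    if threshold_grid is None:
        off_diag = squareform(rmsd, checks=False)
        threshold_grid = np.quantile(off_diag, np.linspace(0.05, 1.0, 20))
    condensed = squareform(rmsd, checks=False)
    link = linkage(condensed, method="single")

    sampling_precision = float(threshold_grid[-1])
    best_p = 0.0
    table_at_precision = None
    for thr in sorted(set(float(t) for t in threshold_grid)):
        labels = fcluster(link, t=thr, criterion="distance")
        clusters = np.unique(labels)
        table = np.array([[int(((labels == c) & (origin == r)).sum()) for r in (0, 1)]
                          for c in clusters])
        p = _contingency_pvalue(table)
        if p > alpha:
            sampling_precision = thr
            best_p = p
            table_at_precision = pd.DataFrame(table, index=[f"cluster{c}" for c in clusters],
                                              columns=["run1", "run2"])
            break
    if table_at_precision is None:
        labels = fcluster(link, t=threshold_grid[-1], criterion="distance")
        clusters = np.unique(labels)
        table_at_precision = pd.DataFrame(
            [[int(((labels == c) & (origin == r)).sum()) for r in (0, 1)] for c in clusters],
            index=[f"cluster{c}" for c in clusters], columns=["run1", "run2"])
        best_p = _contingency_pvalue(table_at_precision.to_numpy())

    converged = bool(ks_p > alpha and best_p > alpha)
    return ConvergenceReport(float(ks_stat), float(ks_p), best_p, table_at_precision,
                             sampling_precision, converged)


# ---------------------------------------------------------------------------
# Interchange with atomic-structure tooling
# ---------------------------------------------------------------------------


def configuration_to_structure(rep: Representation, config: Configuration,
                               label: str = "model") -> StructureModel:
    """Materialise a configuration as a Calpha-only structure."""
    coords = config.coords(rep)
    residues = [
        Residue(ref.chain, ref.number, ref.name or "ALA", ref.icode,
                [Atom("CA", "C", coords[i])])
        for i, ref in enumerate(rep.residue_refs)
    ]
    return StructureModel(residues, label=label)


def write_ensemble_pdb(e: ConfigurationEnsemble, path: str | Path,
                       indices: Sequence[int] | None = None) -> None:
    """Write recorded configurations as a multi-model Calpha PDB."""
    indices = range(len(e)) if indices is None else indices
    models = [configuration_to_structure(e.representation, e.configurations[i],
                                         label=f"model{i}") for i in indices]
    write_structure(models, path, format="pdb")
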