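"""Post-sampling ensemble analytics.

These functions characterise a sampled ensemble relative to a reference
structure: the conformational landscape via PCA over rigid-body mass
centers (after anchoring every model on a common alignment selection,
e.g. a transmembrane bundle), per-domain RMSD distributions, helix
reorientation angles, and cross-link satisfaction statistics across
models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .crosslinks import (CrossLinkSet, LinkerSpec, classify_satisfaction)
from .modeling import ConfigurationEnsemble, configuration_to_structure
from .structure import (ResidueRef, StructureModel, pairwise_rmsd_matrix,
                        superpose_coords)


class AnalysisConfigError(ValueError):
    pass


@dataclass
class PcaProfile:
    coordinates: np.ndarray  # (n_models, n_components) PC coordinates
    explained_variance: np.ndarray  # non-increasing
    cluster_labels: np.ndarray  # k-means labels, 0-based
    pca_centroid: int  # model nearest the mean in PC1-PC2
    ensemble_centroid: int  # model minimising summed RMSD to all others
    features: np.ndarray  # aligned mass-center features fed to the PCA

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates,
                          columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])])
        df["cluster"] = self.cluster_labels
        return df


def _aligned_coords(e: ConfigurationEnsemble, align_idx: np.ndarray) -> np.ndarray:
    """All model coordinates aligned to the first model on a selection."""
    coords = e.coords_array()
    ref_sel = coords[0][align_idx]
    out = np.empty_like(coords)
    out[0] = coords[0]
    for m in range(1, len(coords)):
        sp = superpose_coords(coords[m][align_idx], ref_sel)
        out[m] = sp.apply(coords[m])
    return out


def _selection_indices(e: ConfigurationEnsemble,
                       selection: Sequence[ResidueRef]) -> np.ndarray:
    rep = e.representation
    return np.asarray([rep.index_of(r) for r in selection])


def pca_rigid_body_centers(e: ConfigurationEnsemble,
                           align_selection: Sequence[ResidueRef],
                           n_clusters: int = 3,
                           bodies: Sequence[str] | None = None,
                           n_components: int = 2,
                           seed: int = 0,
                           centroid_rule: str = "nearest_to_mean") -> PcaProfile:
    """PCA of the ensemble over rigid-body mass centers.

    Every model is first aligned to the first model on
    ``align_selection``; the feature vector of a model is the
    concatenated mass centers (unit residue masses, i.e. mean bead
    position) of the designated bodies (default: all).  Clusters come
    from seeded k-means in PC space.  ``pca_centroid`` is the model
    nearest the ensemble mean in PC1-PC2 (``centroid_rule=
    "cluster_medoid"`` instead picks the medoid of the largest k-means
    cluster); ``ensemble_centroid`` minimises the summed pairwise RMSD.
    """
    if len(e) < 2:
        raise AnalysisConfigError("PCA needs >= 2 models")
    if n_clusters > len(e):
        raise AnalysisConfigError(f"n_clusters={n_clusters} exceeds ensemble size {len(e)}")
    rep = e.representation
    body_names = list(bodies) if bodies is not None else list(rep.body_names)
    unknown = [b for b in body_names if b not in rep.body_names]
    if unknown:
        raise AnalysisConfigError(f"unknown bodies: {unknown}")

    aligned = _aligned_coords(e, _selection_indices(e, align_selection))
    feats = []
    for m in range(len(e)):
        centers = [aligned[m][rep.body_members[rep.body_names.index(b)]].mean(axis=0)
                   for b in body_names]
        feats.append(np.concatenate(centers))
    feats = np.asarray(feats)

    n_comp = min(n_components, feats.shape[1], len(e))
    pca = PCA(n_components=n_comp, random_state=seed)
    pcs = pca.fit_transform(feats)
    labels = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(pcs)

    pc12 = pcs[:, : min(2, pcs.shape[1])]
    if centroid_rule == "nearest_to_mean":
        pca_centroid = int(np.argmin(np.linalg.norm(pc12 - pc12.mean(axis=0), axis=1)))
    elif centroid_rule == "cluster_medoid":
        main = np.argmax(np.bincount(labels))
        members = np.flatnonzero(labels == main)
        sub = pc12[members]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=2).sum(axis=1)
        pca_centroid = int(members[np.argmin(d)])
    else:
        raise AnalysisConfigError(f"unknown centroid_rule {centroid_rule!r}")

    rmsd = pairwise_rmsd_matrix(list(e.coords_array()))
    ensemble_centroid = int(np.argmin(rmsd.sum(axis=1)))
    return PcaProfile(pcs, pca.explained_variance_, labels, pca_centroid,
                      ensemble_centroid, feats)


def per_component_rmsd(e: ConfigurationEnsemble, reference: StructureModel,
                       components: Mapping[str, Sequence[ResidueRef]],
                       anchor_selection: Sequence[ResidueRef]) -> pd.DataFrame:
    """Per-model RMSD of named components against a reference structure.

    Each model is superposed on the reference over ``anchor_selection``
    (Calpha), then the RMSD of every component selection is evaluated in
    that common frame (no per-component refit).  Returns a tidy frame
    with one row per (model, component) plus median/IQR summaries in
    ``DataFrame.attrs['summary']``.
    """
    for name, sel in components.items():
        if not len(sel):
            raise AnalysisConfigError(f"component {name!r} is empty")
    rep = e.representation
    anchor_idx = _selection_indices(e, anchor_selection)
    ref_anchor = reference.ca_coords(anchor_selection)
    comp_idx = {name: _selection_indices(e, sel) for name, sel in components.items()}
    ref_comp = {name: reference.ca_coords(sel) for name, sel in components.items()}

    rows = []
    coords = e.coords_array()
    for m in range(len(e)):
        sp = superpose_coords(coords[m][anchor_idx], ref_anchor)
        moved = sp.apply(coords[m])
        for name in components:
            diff = moved[comp_idx[name]] - ref_comp[name]
            rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
            rows.append({"model": m, "component": name, "rmsd": rmsd})
    df = pd.DataFrame(rows)
    summary = df.groupby("component")["rmsd"].agg(
        median="median",
        iqr=lambda x: float(np.subtract(*np.percentile(x, [75, 25]))),
        mean="mean", min="min", max="max")
    df.attrs["summary"] = summary
    return df


def helix_axis(coords: np.ndarray) -> np.ndarray:
    """Unit helix axis from >= 4 Calpha coordinates, oriented N->C."""
    coords = np.asarray(coords, float)
    if len(coords) < 4:
        raise AnalysisConfigError(f"helix axis needs >= 4 Calpha atoms, got {len(coords)}")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise AnalysisConfigError("degenerate helix: all atoms coincide")
    axis = vt[0]
    if np.dot(axis, coords[-1] - coords[0]) < 0:  # disambiguate N->C
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_rotation_angle(model: StructureModel, reference: StructureModel,
                         helix_selection: Sequence[ResidueRef],
                         anchor_selection: Sequence[ResidueRef]) -> float:
    """Angle (degrees, [0, 180]) between a helix in a model vs a reference.

    The model is first superposed on the reference over the anchor
    selection; the helix axis is the first principal axis of the helix
    Calpha coordinates, oriented N to C.  Symmetric in (model,
    reference).
    """
    sp = superpose_coords(model.ca_coords(anchor_selection),
                          reference.ca_coords(anchor_selection))
    model_helix = sp.apply(model.ca_coords(helix_selection))
    axis_m = helix_axis(model_helix)
    axis_r = helix_axis(reference.ca_coords(helix_selection))
    cosang = float(np.clip(np.dot(axis_m, axis_r), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def satisfaction_percentages(e: ConfigurationEnsemble, xl: CrossLinkSet,
                             linkers: Mapping[str, LinkerSpec] | None = None,
                             ) -> pd.DataFrame:
    """Percent of links satisfied per model and linker type, with ranges.

    Returns a tidy frame (model, linker, pct_satisfied); the per-linker
    min/max/mean across the ensemble is in ``attrs['summary']``.  The
    range endpoints are by construction attained by actual models.
    """
    rows = []
    by_linker = xl.by_linker()
    for m, config in enumerate(e.configurations):
        s = configuration_to_structure(e.representation, config, label=f"model{m}")
        for name, subset in by_linker.items():
            rep = classify_satisfaction(subset, s, linkers)
            mapped = rep.counts["satisfied"] + rep.counts["violated"]
            pct = 100.0 * rep.counts["satisfied"] / mapped if mapped else float("nan")
            rows.append({"model": m, "linker": name, "pct_satisfied": pct})
    df = pd.DataFrame(rows)
    df.attrs["summary"] = df.groupby("linker")["pct_satisfied"].agg(["min", "max", "mean"])
    return df
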