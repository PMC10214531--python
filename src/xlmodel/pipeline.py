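"""End-to-end orchestration of the cross-link/modeling/analysis stages.

A run is described by a single YAML config (paths, stage toggles, seeds,
analysis parameters).  Every output file carries provenance: the SHA-256
hash of the canonicalised config and the master seed.  Reruns with an
identical config produce byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import analysis, contacts, crosslinks, modeling, sasa, synth
from .crosslinks import CrossLinkSet, DEFAULT_LINKERS, load_linker_config
from .structure import StructureModel, read_structure

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs remain in the output directory."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    structure: Path | None = None
    linker_config: Path | None = None
    synthetic: dict | None = None  # ToySpec fields; used when no structure given
    crosslinks: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    pca: dict = field(default_factory=dict)
    contacts: dict = field(default_factory=dict)
    sasa: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_mapping(raw, base=Path(path).parent)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], base: Path | None = None) -> "RunConfig":
        base = base or Path(".")

        def respath(key):
            val = raw.get(key)
            if val is None:
                return None
            p = Path(val)
            p = p if p.is_absolute() else base / p
            if not p.exists():
                raise PipelineError(f"config path {key}={val!r} does not exist")
            return p

        cfg = cls(
            output_dir=Path(raw.get("output_dir", "xlmodel_out")),
            seed=int(raw.get("seed", 0)),
            structure=respath("structure"),
            linker_config=respath("linker_config"),
            synthetic=raw.get("synthetic"),
            crosslinks=dict(raw.get("crosslinks", {})),
            stages=dict(raw.get("stages", {})),
            sampling=dict(raw.get("sampling", {})),
            clustering=dict(raw.get("clustering", {})),
            pca=dict(raw.get("pca", {})),
            contacts=dict(raw.get("contacts", {})),
            sasa=dict(raw.get("sasa", {})),
            raw=dict(raw),
        )
        if cfg.structure is None and cfg.synthetic is None:
            raise PipelineError("config needs either 'structure' or 'synthetic'")
        return cfg

    def stage_enabled(self, name: str, default: bool = True) -> bool:
        return bool(self.stages.get(name, default))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.raw, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance_header(cfg: RunConfig) -> str:
    return f"# xlmodel run config_hash={cfg.config_hash} seed={cfg.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(cfg))
        df.to_csv(fh, index=False)


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"_provenance": {"config_hash": cfg.config_hash, "seed": cfg.seed},
               **obj}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run report.

    Stage order: inputs -> cross-link set -> violation map -> theoretical
    enumeration -> sampling (optional) -> clustering -> PCA -> contacts ->
    buried surface area.  A stage failure raises :class:`PipelineError`
    naming the stage; outputs of earlier stages are preserved.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config_hash": cfg.config_hash, "seed": cfg.seed,
                              "stages": {}}
    linkers = (load_linker_config(cfg.linker_config) if cfg.linker_config
               else dict(DEFAULT_LINKERS))
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        toy = None
        if cfg.structure is not None:
            structure = read_structure(cfg.structure)
        else:
            synth_params = dict(cfg.synthetic or {})
            synth_params.setdefault("seed", cfg.seed)
            spec = synth.ToySpec(**synth_params)
            toy = synth.generate_toy_complex(spec)
            structure = toy.structure
        report["stages"][stage] = {
            "n_residues": len(structure), "chains": structure.chains,
            "wall_s": round(time.perf_counter() - t0, 3)}

        stage = "crosslinks"
        t0 = time.perf_counter()
        xl = _stage_crosslinks(cfg, structure, linkers, out)
        report["stages"][stage] = {
            "n_links": len(xl),
            "intra": sum(1 for l in xl if l.scope == "intra"),
            "inter": sum(1 for l in xl if l.scope == "inter"),
            "wall_s": round(time.perf_counter() - t0, 3)}

        stage = "satisfaction"
        t0 = time.perf_counter()
        sat = crosslinks.classify_satisfaction(xl, structure, linkers)
        _write_csv(sat.table, out / "satisfaction.csv", cfg)
        crosslinks.write_pseudobonds(sat, out / "pseudobonds.txt")
        report["stages"][stage] = {**sat.counts,
                                   "wall_s": round(time.perf_counter() - t0, 3)}

        stage = "enumeration"
        t0 = time.perf_counter()
        enum_counts = {}
        for name, spec_l in linkers.items():
            _, counts = crosslinks.enumerate_theoretical_links(structure, spec_l)
            enum_counts[name] = counts
        _write_json({"theoretical_links": enum_counts}, out / "theoretical_links.json", cfg)
        report["stages"][stage] = {"by_linker": enum_counts,
                                   "wall_s": round(time.perf_counter() - t0, 3)}

        ensemble = None
        if cfg.stage_enabled("sample"):
            stage = "sampling"
            t0 = time.perf_counter()
            body_spec = (toy.body_spec if toy is not None
                         else _body_spec_from_config(cfg, structure))
            rep = modeling.build_representation(structure, body_spec)
            params = dict(cfg.sampling)
            membrane = None
            ensemble = modeling.sample_monte_carlo(
                rep, xl, membrane,
                n_steps=int(params.get("n_steps", 20_000)),
                seed=cfg.seed,
                record_every=params.get("record_every"),
                temperature_schedule=params.get("temperature", 1.0),
                linkers=linkers)
            modeling.write_ensemble_pdb(ensemble, out / "ensemble.pdb")
            _write_csv(ensemble.score_table(), out / "scores.csv", cfg)
            report["stages"][stage] = {
                "n_models": len(ensemble),
                "best_total": float(ensemble.totals.min()),
                "acceptance_rate": ensemble.meta["acceptance_rate"],
                "wall_s": round(time.perf_counter() - t0, 3)}

        if ensemble is not None and cfg.stage_enabled("cluster"):
            stage = "clustering"
            t0 = time.perf_counter()
            threshold = float(cfg.clustering.get("threshold", 10.0))
            clusters = modeling.cluster_ensemble(ensemble, threshold)
            _write_json({
                "threshold": threshold,
                "populations": clusters.populations,
                "precisions": clusters.precisions,
                "centroids": clusters.centroids,
                "main_cluster_fraction": clusters.main_cluster_fraction,
            }, out / "clusters.json", cfg)
            report["stages"][stage] = {
                "n_clusters": len(clusters.populations),
                "main_cluster_fraction": clusters.main_cluster_fraction,
                "main_precision": float(clusters.precisions[0]),
                "wall_s": round(time.perf_counter() - t0, 3)}

        if ensemble is not None and cfg.stage_enabled("pca"):
            stage = "pca"
            t0 = time.perf_counter()
            rep = ensemble.representation
            align_body = cfg.pca.get("align_body", rep.body_names[0])
            align_sel = [rep.residue_refs[i]
                         for i in rep.body_members[rep.body_names.index(align_body)]]
            profile = analysis.pca_rigid_body_centers(
                ensemble, align_sel,
                n_clusters=int(cfg.pca.get("n_clusters", 3)),
                seed=cfg.seed)
            _write_csv(profile.to_frame(), out / "pca.csv", cfg)
            sat_pct = analysis.satisfaction_percentages(ensemble, xl, linkers)
            _write_csv(sat_pct, out / "ensemble_satisfaction.csv", cfg)
            report["stages"][stage] = {
                "explained_variance": profile.explained_variance,
                "pca_centroid": profile.pca_centroid,
                "ensemble_centroid": profile.ensemble_centroid,
                "satisfaction_summary": json.loads(
                    sat_pct.attrs["summary"].to_json(orient="index")),
                "wall_s": round(time.perf_counter() - t0, 3)}

        partition = _interface_partition(cfg, structure)
        if partition and cfg.stage_enabled("contacts"):
            stage = "contacts"
            t0 = time.perf_counter()
            chains_a, chains_b = partition
            cset = contacts.detect_contacts(structure, chains_a, chains_b,
                                            scope=cfg.contacts.get("scope", "all"),
                                            source=structure.label)
            contacts.write_contact_csv([cset], out / "contacts.csv")
            census = contacts.contact_census([cset])
            report["stages"][stage] = {**census,
                                       "wall_s": round(time.perf_counter() - t0, 3)}

        if partition and cfg.stage_enabled("sasa"):
            stage = "sasa"
            t0 = time.perf_counter()
            chains_a, chains_b = partition
            n_points = int(cfg.sasa.get("n_points", 240))
            bsa = sasa.interface_buried_area(structure, chains_a, chains_b,
                                             n_points=n_points)
            _write_json({"bsa": bsa.bsa, "interface_area": bsa.interface_area,
                         "sasa_a": bsa.sasa_a, "sasa_b": bsa.sasa_b,
                         "sasa_complex": bsa.sasa_complex},
                        out / "bsa.json", cfg)
            report["stages"][stage] = {"bsa": bsa.bsa,
                                       "interface_area": bsa.interface_area,
                                       "wall_s": round(time.perf_counter() - t0, 3)}
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_json({"report": report}, out / "report.json", cfg)
    return report


def _stage_crosslinks(cfg: RunConfig, structure: StructureModel,
                      linkers, out: Path) -> CrossLinkSet:
    xcfg = cfg.crosslinks
    if "pairs_csv" in xcfg:
        xl = CrossLinkSet.from_csv(xcfg["pairs_csv"])
    elif "reports" in xcfg:
        records = []
        for entry in xcfg["reports"]:
            recs, _ = crosslinks.parse_crosslink_report(entry["path"],
                                                        linkers[entry["linker"]])
            records.extend(recs)
        xl = crosslinks.collapse_to_residue_pairs(
            records,
            min_replicates=int(xcfg.get("min_replicates", 2)),
            max_fdr=float(xcfg.get("max_fdr", 0.05)),
            max_evalue=float(xcfg.get("max_evalue", 0.001)))
    elif "simulate" in xcfg:
        sim = dict(xcfg["simulate"])
        linker = linkers[sim.get("linker", "BS3")]
        xl, _ = synth.simulate_crosslinks(
            structure, linker, n=int(sim.get("n", 100)),
            false_positive_rate=float(sim.get("false_positive_rate", 0.0)),
            seed=int(sim.get("seed", cfg.seed)))
    else:
        raise PipelineError("crosslinks config needs 'pairs_csv', 'reports' or 'simulate'")
    xl.to_csv(out / "crosslinks.csv")
    return xl


def _body_spec_from_config(cfg: RunConfig, structure: StructureModel):
    spec = cfg.sampling.get("bodies")
    if not spec:
        raise PipelineError("sampling stage needs 'sampling.bodies' "
                            "(name -> [chain, first_resnum, last_resnum]) "
                            "when the structure is not synthetic")
    out = {}
    for name, (chain, lo, hi) in spec.items():
        out[name] = [r.ref for r in structure.chain_residues(chain)
                     if lo <= r.number <= hi]
    return out


def _interface_partition(cfg: RunConfig, structure: StructureModel):
    chains_a = cfg.contacts.get("chains_a") or cfg.sasa.get("chains_a")
    chains_b = cfg.contacts.get("chains_b") or cfg.sasa.get("chains_b")
    if chains_a and chains_b:
        return list(chains_a), list(chains_b)
    chains = structure.chains
    if len(chains) >= 2:
        return [chains[0]], chains[1:]
    return None
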