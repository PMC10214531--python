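"""Cross-link chemistry, identification filtering and structural mapping.

A chemical cross-linker covalently tethers two reactive residues; the
identified residue pair then implies an upper bound on their Calpha-Calpha
distance: the maximal spacer length of the reagent plus a tolerance
(default 10 A) that absorbs side-chain lengths and backbone-position
uncertainty.  A link whose Calpha-Calpha distance in a given structure
exceeds that threshold is *violated* by the structure; distances equal to
the threshold count as satisfied.

The built-in linker table covers the five reagents commonly combined for
GPCR complexes (BS3, DSG, EDC, KArGO, PDH).  Reactive-residue sets and
linker/mono masses follow standard search-engine settings; spacer lengths
are configuration values with widely used defaults, and can be overridden
from a YAML file.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .structure import (MissingAtomError, ResidueRef, StructureError,
                        StructureModel, ca_distance)

NTERM = "NTERM"  # pseudo-residue-code marking protein N-terminus reactivity


class CrosslinkConfigError(ValueError):
    """Invalid linker specification or filter parameters."""


@dataclass(frozen=True)
class LinkerSpec:
    """Chemistry of one cross-linking reagent.

    ``alpha_reactivity``/``beta_reactivity`` are sets of 1-letter residue
    codes, optionally including :data:`NTERM` for protein N-terminus
    reactivity.  ``spacer_length`` is the maximal reach of the linker arm
    in Angstrom; ``tolerance`` (default 10 A) is added to it to form the
    Calpha-Calpha distance threshold.  Masses are in Dalton and used only
    for provenance/validation of search reports.
    """

    name: str
    alpha_reactivity: frozenset[str]
    beta_reactivity: frozenset[str]
    spacer_length: float
    linker_mass: float = 0.0
    mono_mass: float = 0.0
    tolerance: float = 10.0

    def __post_init__(self) -> None:
        if self.spacer_length < 0:
            raise CrosslinkConfigError(f"{self.name}: spacer_length must be >= 0")
        if self.spacer_length + self.tolerance <= 0:
            raise CrosslinkConfigError(f"{self.name}: distance threshold must be > 0")
        if not self.alpha_reactivity or not self.beta_reactivity:
            raise CrosslinkConfigError(f"{self.name}: reactivity sets must be non-empty")


def distance_threshold(linker: LinkerSpec) -> float:
    """Calpha-Calpha distance threshold: spacer length + tolerance (A)."""
    return linker.spacer_length + linker.tolerance


def _load_builtin_linkers() -> dict[str, LinkerSpec]:
    raw = yaml.safe_load(resources.files(__package__).joinpath("linkers.yaml")
                         .read_text())
    return {
        name: LinkerSpec(
            name=name,
            alpha_reactivity=frozenset(fields["alpha_reactivity"]),
            beta_reactivity=frozenset(fields["beta_reactivity"]),
            spacer_length=float(fields["spacer_length"]),
            linker_mass=float(fields.get("linker_mass", 0.0)),
            mono_mass=float(fields.get("mono_mass", 0.0)),
            tolerance=float(fields.get("tolerance", 10.0)),
        )
        for name, fields in raw.items()
    }


#: Default reagent table, shipped as editable configuration (linkers.yaml).
DEFAULT_LINKERS: dict[str, LinkerSpec] = _load_builtin_linkers()


def load_linker_config(path: str | Path) -> dict[str, LinkerSpec]:
    """Load (or override) linker specs from a YAML mapping of name -> fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    specs = dict(DEFAULT_LINKERS)
    for name, fields in raw.items():
        base = specs.get(name)
        merged = {
            "alpha_reactivity": frozenset(fields.get(
                "alpha_reactivity", base.alpha_reactivity if base else ())),
            "beta_reactivity": frozenset(fields.get(
                "beta_reactivity", base.beta_reactivity if base else ())),
            "spacer_length": float(fields.get(
                "spacer_length", base.spacer_length if base else 0.0)),
            "linker_mass": float(fields.get("linker_mass", base.linker_mass if base else 0.0)),
            "mono_mass": float(fields.get("mono_mass", base.mono_mass if base else 0.0)),
            "tolerance": float(fields.get("tolerance", base.tolerance if base else 10.0)),
        }
        specs[name] = LinkerSpec(name=name, **merged)
    return specs


# ---------------------------------------------------------------------------
# Cross-link records and sets
# ---------------------------------------------------------------------------


def canonical_pair(a: ResidueRef, b: ResidueRef) -> tuple[ResidueRef, ResidueRef]:
    """Order an unordered residue pair by (chain, number, icode)."""
    ka = (a.chain, a.number, a.icode)
    kb = (b.chain, b.number, b.icode)
    return (a, b) if ka <= kb else (b, a)


@dataclass(frozen=True)
class CrossLink:
    """One nonredundant residue-to-residue cross-link."""

    site_a: ResidueRef
    site_b: ResidueRef
    linker: str
    replicate_count: int = 1
    best_evalue: float = float("nan")

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.site_a, self.site_b)
        object.__setattr__(self, "site_a", a)
        object.__setattr__(self, "site_b", b)
        if (a.chain, a.number, a.icode) == (b.chain, b.number, b.icode):
            raise CrosslinkConfigError(f"self-link at {a} is not a cross-link")
        if self.replicate_count < 1:
            raise CrosslinkConfigError("replicate_count must be >= 1")

    @property
    def scope(self) -> str:
        return "intra" if self.site_a.chain == self.site_b.chain else "inter"

    @property
    def pair_key(self) -> tuple:
        a, b = self.site_a, self.site_b
        return (a.chain, a.number, a.icode, b.chain, b.number, b.icode)


class CrossLinkSet:
    """A set of nonredundant cross-links with provenance."""

    def __init__(self, links: Iterable[CrossLink], provenance: Mapping | None = None) -> None:
        self.links: list[CrossLink] = []
        seen: set[tuple] = set()
        for link in links:
            key = (link.linker,) + link.pair_key
            if key in seen:
                raise CrosslinkConfigError(f"duplicate cross-link {link.site_a}-{link.site_b} "
                                           f"for linker {link.linker}")
            seen.add(key)
            self.links.append(link)
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    def pairs(self) -> set[tuple]:
        """Canonical residue-pair keys, ignoring linker identity."""
        return {link.pair_key for link in self.links}

    def by_linker(self) -> dict[str, "CrossLinkSet"]:
        groups: dict[str, list[CrossLink]] = {}
        for link in self.links:
            groups.setdefault(link.linker, []).append(link)
        return {k: CrossLinkSet(v, self.provenance) for k, v in groups.items()}

    # -- plain-text IO ------------------------------------------------------

    CSV_COLUMNS = ["chain_a", "resnum_a", "chain_b", "resnum_b", "linker",
                   "replicate_count", "best_evalue"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain_a": l.site_a.chain, "resnum_a": l.site_a.number,
                "chain_b": l.site_b.chain, "resnum_b": l.site_b.number,
                "linker": l.linker, "replicate_count": l.replicate_count,
                "best_evalue": l.best_evalue,
            }
            for l in self.links
        ]
        return pd.DataFrame(rows, columns=self.CSV_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CrossLinkSet":
        df = pd.read_csv(path)
        links = [
            CrossLink(
                ResidueRef(str(r.chain_a), int(r.resnum_a)),
                ResidueRef(str(r.chain_b), int(r.resnum_b)),
                str(r.linker),
                int(getattr(r, "replicate_count", 1)),
                float(getattr(r, "best_evalue", float("nan"))),
            )
            for r in df.itertuples()
        ]
        return cls(links, provenance={"source": str(path)})


# ---------------------------------------------------------------------------
# Parsing peptide-level identification reports
# ---------------------------------------------------------------------------


@dataclass
class PeptideRecord:
    """One cross-linked peptide identification mapped to residue sites."""

    site_a: ResidueRef
    site_b: ResidueRef
    residue_a: str  # 1-letter code at site a
    residue_b: str
    linker: str
    evalue: float
    replicate: str
    fdr: float = float("nan")


@dataclass
class ParseDiagnostic:
    row: int
    reason: str


_REPORT_COLUMNS = {"chain_a", "pos_a", "aa_a", "chain_b", "pos_b", "aa_b",
                   "evalue", "replicate"}


def _site_reactive(aa: str, pos: int, reactivity: frozenset[str]) -> bool:
    return aa in reactivity or (pos == 1 and NTERM in reactivity)


def parse_crosslink_report(path: str | Path | io.TextIOBase, linker: LinkerSpec,
                           ) -> tuple[list[PeptideRecord], list[ParseDiagnostic]]:
    """Parse a tabular cross-linked peptide report for one reagent.

    Expected columns (CSV or TSV, extra columns pass through unused):
    ``chain_a, pos_a, aa_a, chain_b, pos_b, aa_b, evalue, replicate``
    and optionally ``fdr``.  Positions are author residue numbers within
    the named chain; ``aa_*`` are 1-letter residue codes at the linked
    sites.  Site chemistry is validated against the reagent's alpha/beta
    reactivity (either orientation); an N-terminal site (position 1)
    additionally matches N-terminus reactivity.

    Malformed rows and chemistry-incompatible rows are excluded and
    reported as diagnostics rather than aborting the parse.
    """
    sep = None
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = _REPORT_COLUMNS - set(df.columns)
    if missing:
        raise CrosslinkConfigError(f"report is missing columns: {sorted(missing)}")

    records: list[PeptideRecord] = []
    diagnostics: list[ParseDiagnostic] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            pos_a, pos_b = int(row.pos_a), int(row.pos_b)
            evalue = float(row.evalue)
            aa_a, aa_b = str(row.aa_a).strip().upper(), str(row.aa_b).strip().upper()
            chain_a, chain_b = str(row.chain_a).strip(), str(row.chain_b).strip()
            if not chain_a or not chain_b or len(aa_a) != 1 or len(aa_b) != 1:
                raise ValueError("empty chain or bad residue code")
            fdr = float(getattr(row, "fdr", "nan"))
        except (TypeError, ValueError) as exc:
            diagnostics.append(ParseDiagnostic(i, f"malformed row: {exc}"))
            continue
        forward = (_site_reactive(aa_a, pos_a, linker.alpha_reactivity)
                   and _site_reactive(aa_b, pos_b, linker.beta_reactivity))
        backward = (_site_reactive(aa_b, pos_b, linker.alpha_reactivity)
                    and _site_reactive(aa_a, pos_a, linker.beta_reactivity))
        if not (forward or backward):
            diagnostics.append(ParseDiagnostic(
                i, f"site chemistry {aa_a}{pos_a}-{aa_b}{pos_b} incompatible with "
                   f"{linker.name} reactivity"))
            continue
        records.append(PeptideRecord(
            ResidueRef(chain_a, pos_a), ResidueRef(chain_b, pos_b),
            aa_a, aa_b, linker.name, evalue, str(row.replicate).strip(), fdr))
    for d in diagnostics:
        warnings.warn(f"{linker.name} report row {d.row}: {d.reason}", stacklevel=2)
    return records, diagnostics


def collapse_to_residue_pairs(records: Sequence[PeptideRecord], min_replicates: int = 2,
                              max_fdr: float = 0.05, max_evalue: float = 0.001,
                              ) -> CrossLinkSet:
    """Collapse peptide-level records to nonredundant residue pairs.

    A record passes if its E-value is below ``max_evalue`` and its FDR
    (when reported) does not exceed ``max_fdr``.  A residue pair is
    retained iff passing records exist in at least ``min_replicates``
    distinct replicates; the replicate count and best (lowest) E-value
    are recorded.  Collapsing an already-collapsed set is the identity.
    """
    groups: dict[tuple, dict] = {}
    for rec in records:
        if not (rec.evalue < max_evalue):
            continue
        if not np.isnan(rec.fdr) and rec.fdr > max_fdr:
            continue
        a, b = canonical_pair(rec.site_a, rec.site_b)
        key = (rec.linker, a.chain, a.number, a.icode, b.chain, b.number, b.icode)
        g = groups.setdefault(key, {"a": a, "b": b, "linker": rec.linker,
                                    "replicates": set(), "best": rec.evalue})
        g["replicates"].add(rec.replicate)
        g["best"] = min(g["best"], rec.evalue)
    links = [
        CrossLink(g["a"], g["b"], g["linker"], len(g["replicates"]), g["best"])
        for g in groups.values()
        if len(g["replicates"]) >= min_replicates
    ]
    links.sort(key=lambda l: (l.linker,) + l.pair_key)
    return CrossLinkSet(links, provenance={
        "min_replicates": min_replicates, "max_fdr": max_fdr, "max_evalue": max_evalue})


# ---------------------------------------------------------------------------
# Structural mapping
# ---------------------------------------------------------------------------

SATISFIED, VIOLATED, UNMAPPABLE = "satisfied", "violated", "unmappable"


@dataclass
class SatisfactionReport:
    """Per-link classification against one structure, with summaries."""

    table: pd.DataFrame  # one row per link: status, distance, threshold ...
    counts: dict[str, int]
    by_scope: pd.DataFrame  # rows intra/inter, columns satisfied/violated/unmappable
    by_chain_pair: pd.DataFrame

    @property
    def satisfied_fraction(self) -> float:
        mapped = self.counts[SATISFIED] + self.counts[VIOLATED]
        if mapped == 0:
            raise ZeroDivisionError("no mappable links")
        return self.counts[SATISFIED] / mapped


def classify_satisfaction(xl: CrossLinkSet, s: StructureModel,
                          linkers: Mapping[str, LinkerSpec] | None = None,
                          ) -> SatisfactionReport:
    """Classify every link as satisfied / violated / unmappable on a structure.

    A link is satisfied iff the Calpha-Calpha distance is <= the linker's
    threshold (boundary counts as satisfied); unmappable if either residue
    or its Calpha is absent from the structure.
    """
    linkers = linkers or DEFAULT_LINKERS
    rows = []
    for link in xl:
        try:
            spec = linkers[link.linker]
        except KeyError:
            raise CrosslinkConfigError(f"no LinkerSpec for linker {link.linker!r}")
        threshold = distance_threshold(spec)
        try:
            d = ca_distance(s, link.site_a, link.site_b)
            status = SATISFIED if d <= threshold else VIOLATED
        except (StructureError, MissingAtomError):
            d, status = float("nan"), UNMAPPABLE
        rows.append({
            "chain_a": link.site_a.chain, "resnum_a": link.site_a.number,
            "chain_b": link.site_b.chain, "resnum_b": link.site_b.number,
            "linker": link.linker, "scope": link.scope,
            "distance": d, "threshold": threshold, "status": status,
        })
    table = pd.DataFrame(rows, columns=["chain_a", "resnum_a", "chain_b", "resnum_b",
                                        "linker", "scope", "distance", "threshold", "status"])
    counts = {k: int((table["status"] == k).sum()) for k in (SATISFIED, VIOLATED, UNMAPPABLE)}
    if len(table):
        by_scope = table.pivot_table(index="scope", columns="status", aggfunc="size",
                                     fill_value=0)
        pair = table.apply(lambda r: "-".join(sorted([r.chain_a, r.chain_b])), axis=1)
        by_chain_pair = table.assign(chain_pair=pair).pivot_table(
            index="chain_pair", columns="status", aggfunc="size", fill_value=0)
    else:
        by_scope = pd.DataFrame()
        by_chain_pair = pd.DataFrame()
    return SatisfactionReport(table, counts, by_scope, by_chain_pair)


def write_pseudobonds(report: SatisfactionReport, path: str | Path) -> None:
    """Write one 'chain:resnum chain:resnum distance status' line per link."""
    with open(path, "w") as fh:
        for r in report.table.itertuples():
            fh.write(f"{r.chain_a}:{r.resnum_a} {r.chain_b}:{r.resnum_b} "
                     f"{r.distance:.2f} {r.status}\n")


def _reactive_sites(s: StructureModel, reactivity: frozenset[str]) -> list[ResidueRef]:
    from .sequences import one_letter  # local import; tiny table module
    sites = []
    firsts = {c: s.first_residue(c).ref for c in s.chains}
    for res in s:
        code = one_letter(res.name)
        if code in reactivity or (NTERM in reactivity and res.ref == firsts[res.chain]):
            if res.ca is not None:
                sites.append(res.ref)
    return sites


def enumerate_theoretical_links(s: StructureModel, linker: LinkerSpec,
                                ) -> tuple[set[tuple[ResidueRef, ResidueRef]], dict[str, int]]:
    """All residue pairs that the reagent could cross-link on this structure.

    A pair is feasible when one residue is alpha-reactive and the other
    beta-reactive (either orientation; the N-terminal residue of each
    chain also matches N-terminus reactivity) and the Calpha-Calpha
    distance is within the linker threshold.  Returns the canonical pair
    set and intra/inter counts.
    """
    threshold = distance_threshold(linker)
    alpha = _reactive_sites(s, linker.alpha_reactivity)
    beta = _reactive_sites(s, linker.beta_reactivity)
    if not alpha or not beta:
        return set(), {"intra": 0, "inter": 0}
    coords_a = s.ca_coords(alpha)
    coords_b = s.ca_coords(beta)
    tree_b = cKDTree(coords_b)
    pairs: set[tuple[ResidueRef, ResidueRef]] = set()
    for i, neighbors in enumerate(tree_b.query_ball_point(coords_a, threshold)):
        for j in neighbors:
            a, b = alpha[i], beta[j]
            if (a.chain, a.number, a.icode) == (b.chain, b.number, b.icode):
                continue
            pairs.add(canonical_pair(a, b))
    counts = {"intra": sum(1 for a, b in pairs if a.chain == b.chain),
              "inter": sum(1 for a, b in pairs if a.chain != b.chain)}
    return pairs, counts


def overlap_statistics(a: CrossLinkSet, b: CrossLinkSet) -> dict[str, float]:
    """Linkage overlap between two cross-link sets (by residue pair).

    The headline ``shared_fraction`` uses the union as denominator, so
    shared + unique_to_a + unique_to_b = 1.  Per-set fractions
    (|A&B|/|A|, |A&B|/|B|) are also reported.
    """
    pa, pb = a.pairs(), b.pairs()
    union = pa | pb
    if not union:
        raise ZeroDivisionError("overlap of two empty cross-link sets is undefined")
    inter = pa & pb
    return {
        "shared_fraction": len(inter) / len(union),
        "unique_to_a_fraction": len(pa - pb) / len(union),
        "unique_to_b_fraction": len(pb - pa) / len(union),
        "shared_of_a": len(inter) / len(pa) if pa else float("nan"),
        "shared_of_b": len(inter) / len(pb) if pb else float("nan"),
        "n_a": len(pa), "n_b": len(pb), "n_shared": len(inter), "n_union": len(union),
    }
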