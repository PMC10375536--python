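"""Curation of literature-style ligand affinity tables.

Amyloid-fibril ligand affinities are scattered across many papers and are
reported in heterogeneous ways: different concentration units, limiting
values (``Kd > 1 uM``), direct versus competition assays, and repeated
measurements of the same compound. This module parses such tables into
:class:`LigandRecord` objects, merges duplicate structures, assigns ligands
to the common FBH binding site (defined operationally by displacement of a
set of reference radioligands in competition assays), and produces curated
consensus affinities suitable for model training.

All affinities are handled as log10(Kd / M). Averaging of repeated reports
is done on this log scale (i.e. a geometric mean of Kd), consistent with how
affinity models and class bins are expressed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Conversion factors from supported concentration units to molar.
UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}

#: Default identifiers of the eight reference radioligands whose displacement
#: in a competition assay defines the FBH site.
DEFAULT_REFERENCE_IDS = frozenset(f"ref{i}" for i in range(1, 9))

#: Columns expected in a ligand-table CSV.
CSV_COLUMNS = ("smiles", "kd_value", "kd_units", "kd_is_limit", "assay",
               "competitor_id", "source")


class UnknownUnitError(ValueError):
    """Raised when a Kd is reported in an unrecognized concentration unit."""


def kd_to_log10_molar(value: float, units: str) -> float:
    """Convert a dissociation constant to log10(Kd / M).

    Parameters
    ----------
    value : Kd in the given units; must be > 0.
    units : one of ``M, mM, uM, nM, pM``.
    """
    try:
        factor = UNIT_FACTORS[units]
    except KeyError:
        raise UnknownUnitError(
            f"unknown Kd unit {units!r}; expected one of {sorted(UNIT_FACTORS)}"
        ) from None
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"Kd must be a positive finite number, got {value!r}")
    return math.log10(value * factor)


def log10_molar_to_kd(log_kd: float, units: str = "nM") -> float:
    """Inverse of :func:`kd_to_log10_molar` (round-trips to ~15 digits)."""
    try:
        factor = UNIT_FACTORS[units]
    except KeyError:
        raise UnknownUnitError(
            f"unknown Kd unit {units!r}; expected one of {sorted(UNIT_FACTORS)}"
        ) from None
    return 10.0 ** log_kd / factor


def neg_log_kd_molar(value: float, units: str) -> float:
    """-log10(Kd / M), the affinity scale used for ranking and selection."""
    return -kd_to_log10_molar(value, units)


@dataclass(frozen=True)
class AffinityMeasurement:
    """One literature report of a dissociation constant.

    ``log_kd`` is log10(Kd/M). ``is_limiting`` is ``None`` for a point value,
    ``"gt"`` for an upper bound on affinity (Kd > x, so log_kd > bound) and
    ``"lt"`` for Kd < x. ``competitor_id`` is required for competition assays
    and forbidden otherwise.
    """

    log_kd: float
    is_limiting: str | None = None  # None | "gt" | "lt"
    assay_kind: str = "direct"      # "direct" | "competition"
    competitor_id: str | None = None
    source_ref: str = ""

    def __post_init__(self):
        if not math.isfinite(self.log_kd):
            raise ValueError("log_kd must be finite")
        if self.is_limiting not in (None, "gt", "lt"):
            raise ValueError(f"is_limiting must be None/'gt'/'lt', got {self.is_limiting!r}")
        if self.assay_kind not in ("direct", "competition"):
            raise ValueError(f"assay_kind must be 'direct' or 'competition', got {self.assay_kind!r}")
        if (self.assay_kind == "competition") != (self.competitor_id is not None):
            raise ValueError("competitor_id must be present iff assay_kind == 'competition'")

    @property
    def is_point_value(self) -> bool:
        return self.is_limiting is None


@dataclass
class LigandRecord:
    """A molecule with its affinity reports and (optional) site assignment."""

    ligand_id: str
    structure: str  # SMILES
    measurements: list[AffinityMeasurement] = field(default_factory=list)
    site_tag: str = "unassigned"  # "FBH" | "unassigned"

    def fbh_measurements(self, reference_ids: frozenset[str] | set[str] = DEFAULT_REFERENCE_IDS
                         ) -> list[AffinityMeasurement]:
        """Measurements that report on the FBH site (competition vs a reference)."""
        return [m for m in self.measurements
                if m.assay_kind == "competition" and m.competitor_id in reference_ids]


@dataclass
class CuratedEntry:
    """Consensus affinity for one ligand after curation.

    ``consensus_log_kd`` is the arithmetic mean of point-valued log10(Kd/M)
    reports (``None`` when only limiting values exist). ``bound`` carries the
    tightest limiting bound as ``("gt"|"lt", log_kd)`` for class deduction.
    """

    ligand_id: str
    consensus_log_kd: float | None
    regression_eligible: bool
    class_eligible: bool
    n_reports: int
    n_limiting: int
    bound: tuple[str, float] | None = None


@dataclass
class CurationResult:
    """Curated entries plus bookkeeping counts."""

    entries: list[CuratedEntry]
    excluded: list[str]  # ligand ids dropped (contradictory bounds / no data)

    @property
    def n_regression_eligible(self) -> int:
        return sum(e.regression_eligible for e in self.entries)

    @property
    def n_class_eligible(self) -> int:
        return sum(e.class_eligible for e in self.entries)

    @property
    def n_limiting_only(self) -> int:
        return sum(not e.regression_eligible for e in self.entries)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_LIMIT_PREFIXES = {">": "gt", "<": "lt", "＞": "gt", "＜": "lt",
                   "≥": "gt", "≤": "lt"}


def _parse_kd_field(raw, units: str, limit_flag: str | None):
    """Parse a Kd cell, which may embed a '>'/'<' prefix, into (log_kd, limit)."""
    limit = None if limit_flag in (None, "", "none") else limit_flag
    if isinstance(raw, str):
        txt = raw.strip()
        if txt and txt[0] in _LIMIT_PREFIXES:
            limit = _LIMIT_PREFIXES[txt[0]]
            txt = txt[1:].strip()
        value = float(txt)
    else:
        value = float(raw)
    return kd_to_log10_molar(value, units), limit


def _row_to_record(ligand_id: str, smiles: str, kd_raw, units: str,
                   limit_flag, assay: str, competitor, source) -> LigandRecord | None:
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        logger.warning("rejecting row %s: unparseable SMILES %r", ligand_id, smiles)
        return None
    log_kd, limit = _parse_kd_field(kd_raw, units, limit_flag)
    competitor = None if competitor in (None, "", float("nan")) or (
        isinstance(competitor, float) and math.isnan(competitor)) else str(competitor)
    meas = AffinityMeasurement(
        log_kd=log_kd, is_limiting=limit, assay_kind=assay,
        competitor_id=competitor if assay == "competition" else None,
        source_ref="" if source is None else str(source),
    )
    return LigandRecord(ligand_id=ligand_id, structure=smiles, measurements=[meas])


def parse_ligand_table(path: str | Path, format: str = "csv") -> list[LigandRecord]:
    """Read a ligand affinity table into one :class:`LigandRecord` per row.

    CSV files must carry the columns ``smiles, kd_value, kd_units,
    kd_is_limit, assay, competitor_id, source``; SDF files the same names as
    SD tags. Kd values are converted to log10 molar whatever the input unit.
    Rows with unparseable SMILES are rejected (logged); an unknown unit is a
    hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[LigandRecord] = []
    if format == "csv":
        import pandas as pd

        # no comment handling: '#' is a legal SMILES character (triple bond)
        df = pd.read_csv(path, dtype={"kd_value": str})
        missing = {"smiles", "kd_value", "kd_units"} - set(df.columns)
        if missing:
            raise ValueError(f"ligand CSV missing required columns: {sorted(missing)}")
        for i, row in df.iterrows():
            rec = _row_to_record(
                ligand_id=str(row.get("ligand_id", f"L{i:05d}")),
                smiles=row["smiles"], kd_raw=row["kd_value"],
                units=str(row["kd_units"]),
                limit_flag=(None if "kd_is_limit" not in df.columns
                            else (None if pd.isna(row["kd_is_limit"]) else str(row["kd_is_limit"]))),
                assay=str(row.get("assay", "direct")),
                competitor=row.get("competitor_id"), source=row.get("source"),
            )
            if rec is not None:
                records.append(rec)
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("rejecting SDF entry %d: unparseable structure", i)
                continue
            props = mol.GetPropsAsDict()
            rec = _row_to_record(
                ligand_id=str(props.get("ligand_id", f"L{i:05d}")),
                smiles=Chem.MolToSmiles(mol), kd_raw=props["kd_value"],
                units=str(props["kd_units"]),
                limit_flag=props.get("kd_is_limit"),
                assay=str(props.get("assay", "direct")),
                competitor=props.get("competitor_id"), source=props.get("source"),
            )
            if rec is not None:
                records.append(rec)
    else:
        raise ValueError(f"format must be 'csv' or 'sdf', got {format!r}")
    return records


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def canonical_parent_smiles(smiles: str) -> str:
    """Canonical SMILES of the neutral, salt-stripped parent structure.

    Stereochemistry is retained, so stereoisomers remain distinct entries.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    parent = rdMolStandardize.FragmentParent(mol)  # largest fragment, neutralized
    return Chem.MolToSmiles(parent)


def deduplicate(records: Sequence[LigandRecord]) -> list[LigandRecord]:
    """Merge records that share a canonicalized structure.

    Measurements are concatenated in input order; the first-seen ligand_id and
    SMILES rendering are kept. Idempotent.
    """
    merged: dict[str, LigandRecord] = {}
    for rec in records:
        key = canonical_parent_smiles(rec.structure)
        if key in merged:
            merged[key].measurements.extend(rec.measurements)
        else:
            merged[key] = LigandRecord(
                ligand_id=rec.ligand_id, structure=rec.structure,
                measurements=list(rec.measurements), site_tag=rec.site_tag)
    return list(merged.values())


# ---------------------------------------------------------------------------
# Site assignment and curation
# ---------------------------------------------------------------------------

def assign_fbh_site(record: LigandRecord,
                    reference_ids: Iterable[str] = DEFAULT_REFERENCE_IDS) -> LigandRecord:
    """Tag a record as an FBH-site binder if it qualifies.

    A ligand reports on the FBH site iff at least one of its measurements is
    a competition assay displacing one of the reference radioligands.
    """
    refs = frozenset(reference_ids)
    if not refs:
        raise ValueError("reference_ids must be nonempty")
    tag = "FBH" if record.fbh_measurements(refs) else "unassigned"
    return replace(record, site_tag=tag)


def _class_from_bound(kind: str, log_kd: float,
                      edges: Sequence[float] = (-8.0, -7.0, -6.0)) -> bool:
    """Whether a limiting bound pins a unique affinity class.

    ``gt`` (Kd > x) pins the weakest class when the bound sits at or above the
    last edge; ``lt`` pins the strongest class at or below the first edge.
    """
    if kind == "gt":
        return log_kd >= edges[-1]
    return log_kd <= edges[0]


def curate(records: Sequence[LigandRecord],
           reference_ids: Iterable[str] = DEFAULT_REFERENCE_IDS) -> CurationResult:
    """Build consensus affinities from site-assigned records.

    For FBH-tagged ligands only the FBH-qualifying measurements contribute;
    for unassigned ligands all measurements do. The consensus is the mean of
    point-valued log10(Kd/M) reports. A ligand is regression-eligible only
    when no contributing report is limiting; a limiting-only ligand stays
    class-eligible when its bound pins a unique class. Ligands whose limiting
    bounds contradict each other are excluded (logged).
    """
    refs = frozenset(reference_ids)
    entries: list[CuratedEntry] = []
    excluded: list[str] = []
    for rec in records:
        contributing = rec.fbh_measurements(refs) if rec.site_tag == "FBH" else list(rec.measurements)
        if not contributing:
            logger.warning("excluding %s: no contributing measurements", rec.ligand_id)
            excluded.append(rec.ligand_id)
            continue
        points = [m.log_kd for m in contributing if m.is_point_value]
        limits = [(m.is_limiting, m.log_kd) for m in contributing if not m.is_point_value]
        gt = [v for k, v in limits if k == "gt"]
        lt = [v for k, v in limits if k == "lt"]
        if not points and gt and lt and max(gt) >= min(lt):
            logger.warning("excluding %s: contradictory limiting bounds", rec.ligand_id)
            excluded.append(rec.ligand_id)
            continue
        consensus = sum(points) / len(points) if points else None
        bound = None
        if limits and not points:
            # tightest bound: largest gt / smallest lt
            kind, val = ("gt", max(gt)) if gt else ("lt", min(lt))
            bound = (kind, val)
        class_ok = bool(points) or (bound is not None and _class_from_bound(*bound))
        entries.append(CuratedEntry(
            ligand_id=rec.ligand_id,
            consensus_log_kd=consensus,
            regression_eligible=bool(points) and not limits,
            class_eligible=class_ok,
            n_reports=len(contributing),
            n_limiting=len(limits),
            bound=bound,
        ))
    return CurationResult(entries=entries, excluded=excluded)
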