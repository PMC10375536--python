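"""Molecular property filter — step 1 of the screening pipeline.

Candidate compounds are profiled for molecular weight, an atom-contribution
(Crippen) logP estimate, and net formal charge, and kept only when all three
fall inside a configurable window. The defaults reproduce the envelope of the
known fibril-ligand database: 200-500 Da, logP 3.5-5.5, neutral molecules
only. Window boundaries are closed (values exactly at an edge pass).

Charge is the formal charge of the structure as drawn; no pH-dependent
protonation model is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors


@dataclass(frozen=True)
class PropertyWindow:
    """Closed acceptance window on MW / logP / net formal charge."""

    mw_min: float = 200.0
    mw_max: float = 500.0
    logp_min: float = 3.5
    logp_max: float = 5.5
    allowed_net_charge: frozenset[int] = frozenset({0})

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be < logp_max")


@dataclass(frozen=True)
class PropertyProfile:
    ligand_id: str
    mw: float
    logp: float
    net_charge: int

    def __post_init__(self):
        if not self.mw > 0:
            raise ValueError("molecular weight must be positive")


#: Provenance tag recorded with filter output so windows can be recalibrated
#: if a different logP estimator is substituted.
LOGP_METHOD = "rdkit-crippen"


def profile(structure: str, ligand_id: str | None = None) -> PropertyProfile:
    """Compute the MW / logP / formal-charge profile of one SMILES.

    Deterministic; raises ``ValueError`` naming the SMILES on parse failure.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {structure!r}")
    return PropertyProfile(
        ligand_id=structure if ligand_id is None else ligand_id,
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        net_charge=Chem.GetFormalCharge(mol),
    )


@dataclass
class FilterResult:
    """Per-ligand verdicts plus counts per rejection reason."""

    table: pd.DataFrame  # ligand_id, mw, logp, net_charge, passed, fail_reasons
    window: PropertyWindow

    @property
    def passed_ids(self) -> list[str]:
        return self.table.loc[self.table["passed"], "ligand_id"].tolist()

    @property
    def counts(self) -> dict[str, int]:
        n = len(self.table)
        reasons = self.table["fail_reasons"].str.split("|").explode()
        c = reasons[reasons != ""].value_counts().to_dict()
        return {"total": n, "passed": int(self.table["passed"].sum()),
                **{f"fail_{k}": int(v) for k, v in c.items()}}


def apply_property_filter(profiles: Sequence[PropertyProfile] | Iterable[PropertyProfile],
                          window: PropertyWindow | None = None) -> FilterResult:
    """Apply the property window; pass requires all three criteria (closed intervals)."""
    window = window or PropertyWindow()
    rows = []
    for p in profiles:
        reasons = []
        if not (window.mw_min <= p.mw <= window.mw_max):
            reasons.append("mw")
        if not (window.logp_min <= p.logp <= window.logp_max):
            reasons.append("logp")
        if p.net_charge not in window.allowed_net_charge:
            reasons.append("charge")
        rows.append({"ligand_id": p.ligand_id, "mw": p.mw, "logp": p.logp,
                     "net_charge": p.net_charge, "passed": not reasons,
                     "fail_reasons": "|".join(reasons),
                     "logp_method": LOGP_METHOD})
    cols = ["ligand_id", "mw", "logp", "net_charge", "passed", "fail_reasons", "logp_method"]
    return FilterResult(table=pd.DataFrame(rows, columns=cols), window=window)
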