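"""Chemical descriptor tables, standardization, and correlation pruning.

The affinity models consume a fixed panel of 45 descriptors per ligand —
1D compositional (e.g. molecular weight), 2D topological (e.g. topological
polar surface area) and 3D conformational (e.g. asphericity) — computed with
RDKit. 3D descriptors are evaluated on the lowest-energy member of a small
seeded conformer ensemble (ETKDG embedding + MMFF relaxation), so the whole
table is reproducible from a seed.

Each descriptor column X is standardized to (X - mu) / sigma, with mu and
sigma the mean and *population* standard deviation over the fitting table;
parameters are fitted on training rows only and applied unchanged to held-out
rows. Near-duplicate descriptors are removed by greedy pruning of pairs whose
absolute Pearson correlation reaches a threshold (default 0.9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors as _D, Descriptors3D as _D3

logger = logging.getLogger(__name__)

PARAMS_SCHEMA_VERSION = 1


def aliphatic_chain_count(mol: Chem.Mol) -> int:
    """Number of maximal acyclic aliphatic-carbon chains (connected components
    of non-ring, non-aromatic carbon atoms)."""
    idx = [a.GetIdx() for a in mol.GetAtoms()
           if a.GetSymbol() == "C" and not a.GetIsAromatic() and not a.IsInRing()]
    keep = set(idx)
    seen: set[int] = set()
    n = 0
    for start in idx:
        if start in seen:
            continue
        n += 1
        stack = [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            stack.extend(nb.GetIdx() for nb in mol.GetAtomWithIdx(i).GetNeighbors()
                         if nb.GetIdx() in keep)
    return n


#: name -> (callable(mol) -> float, needs_3d)
_REGISTRY: dict[str, tuple[Callable, bool]] = {}


def _register_2d(name: str, fn: Callable) -> None:
    _REGISTRY[name] = (fn, False)


def _register_3d(name: str, fn: Callable) -> None:
    _REGISTRY[name] = (fn, True)


for _name in ["MolWt", "HeavyAtomCount", "NumHeteroatoms", "NumHDonors",
              "NumHAcceptors", "NumRotatableBonds", "FractionCSP3", "NHOHCount",
              "NOCount", "MolLogP", "MolMR", "NumAromaticHeterocycles",
              "NumAromaticCarbocycles", "TPSA", "LabuteASA", "BalabanJ",
              "BertzCT", "Chi0v", "Chi1v", "Chi2v", "Chi3v", "Chi4v",
              "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3", "NumAromaticRings",
              "NumAliphaticRings", "NumSaturatedRings", "RingCount",
              "NumAliphaticCarbocycles", "NumAliphaticHeterocycles",
              "MaxPartialCharge", "MinPartialCharge"]:
    _register_2d(_name, getattr(_D, _name))
_register_2d("AliphaticChainCount", aliphatic_chain_count)
for _name in ["Asphericity", "Eccentricity", "InertialShapeFactor", "NPR1",
              "NPR2", "PMI1", "PMI2", "PMI3", "RadiusOfGyration",
              "SpherocityIndex"]:
    _register_3d(_name, getattr(_D3, _name))


def default_descriptor_names(with_3d: bool = True) -> list[str]:
    """The shipped 45-name panel (35 of them when 3D names are omitted)."""
    cfg = yaml.safe_load(
        resources.files("amyloidvs.data").joinpath("descriptors_default.yaml").read_text())
    names = list(cfg["compositional"]) + list(cfg["topological"])
    if with_3d:
        names += list(cfg["conformational"])
    return names


def _embed_lowest_energy(mol: Chem.Mol, seed: int, n_confs: int) -> Chem.Mol | None:
    """Embed a seeded conformer ensemble, MMFF-relax it, keep the lowest-energy
    conformer. Returns None when embedding fails."""
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=n_confs, params=params)
    if not ids:
        return None
    results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    energies = [(e if ok == 0 else np.inf) for ok, e in results]
    if not np.isfinite(min(energies)):
        energies = [e for _, e in results]  # keep best even if not converged
    best = int(np.argmin(energies))
    keep = Chem.Mol(molh)
    keep.RemoveAllConformers()
    keep.AddConformer(molh.GetConformer(int(ids[best])), assignId=True)
    return keep


def compute_descriptors(structures: Sequence[str],
                        ligand_ids: Sequence[str] | None = None,
                        with_3d: bool = True,
                        seed: int = 0,
                        n_confs: int = 10,
                        names: Sequence[str] | None = None) -> pd.DataFrame:
    """Compute the descriptor table for a list of SMILES.

    Returns a DataFrame indexed by ligand_id with one column per descriptor.
    Ligands whose 3D embedding fails are excluded from the returned table
    (logged), so the table is complete for every retained row.
    """
    names = list(names) if names is not None else default_descriptor_names(with_3d)
    unknown = [n for n in names if n not in _REGISTRY]
    if unknown:
        raise KeyError(f"unknown descriptor names: {unknown}")
    if ligand_ids is None:
        ligand_ids = [f"L{i:05d}" for i in range(len(structures))]
    needs_3d = any(_REGISTRY[n][1] for n in names)
    rows, index = [], []
    for lid, smi in zip(ligand_ids, structures):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {lid}: {smi!r}")
        mol3d = None
        if needs_3d:
            mol3d = _embed_lowest_energy(mol, seed=seed, n_confs=n_confs)
            if mol3d is None:
                logger.warning("3D embedding failed for %s; excluded from table", lid)
                continue
        row = {}
        for n in names:
            fn, is3d = _REGISTRY[n]
            row[n] = float(fn(mol3d if is3d else mol))
        rows.append(row)
        index.append(lid)
    df = pd.DataFrame(rows, index=pd.Index(index, name="ligand_id"), columns=names)
    bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)] if len(df) else []
    for col in bad:
        logger.warning("descriptor %s produced non-finite values; filled with 0", col)
        df[col] = df[col].replace([np.inf, -np.inf], np.nan).fillna(0.0)
    return df


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizationParams:
    """Per-descriptor mean/SD (population) fitted on a training table."""

    mu: pd.Series
    sigma: pd.Series
    dropped: list[str] = field(default_factory=list)  # zero-variance columns

    def to_dict(self) -> dict:
        return {"schema_version": PARAMS_SCHEMA_VERSION,
                "mu": self.mu.to_dict(), "sigma": self.sigma.to_dict(),
                "dropped": list(self.dropped)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(mu=pd.Series(d["mu"]), sigma=pd.Series(d["sigma"]),
                   dropped=list(d.get("dropped", [])))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StandardizationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_standardization(table: pd.DataFrame) -> StandardizationParams:
    """Fit per-column mean and population SD; zero-variance columns are dropped."""
    if len(table) < 2:
        raise ValueError("standardization requires at least 2 rows")
    mu = table.mean(axis=0)
    sigma = table.std(axis=0, ddof=0)
    dropped = sigma.index[sigma == 0].tolist()
    for col in dropped:
        logger.warning("dropping zero-variance descriptor %s", col)
    keep = [c for c in table.columns if c not in dropped]
    return StandardizationParams(mu=mu[keep], sigma=sigma[keep], dropped=dropped)


def apply_standardization(table: pd.DataFrame,
                          params: StandardizationParams) -> pd.DataFrame:
    """(X - mu) / sigma per retained column, training-set parameters unchanged."""
    return (table[params.mu.index] - params.mu) / params.sigma


def invert_standardization(table: pd.DataFrame,
                           params: StandardizationParams) -> pd.DataFrame:
    return table[params.mu.index] * params.sigma + params.mu


# ---------------------------------------------------------------------------
# Correlation pruning
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, kept-partner, r)
    matrix: pd.DataFrame


def correlation_prune(table: pd.DataFrame, threshold: float = 0.9) -> CorrelationReport:
    """Greedily drop descriptors so no retained pair has |Pearson r| >= threshold.

    Columns are visited in table order; a column is dropped when it correlates
    at or above the threshold with any earlier-retained column (deterministic
    later-listed tie-break).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    corr = table.corr(method="pearson")
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for col in table.columns:
        partner = next((r for r in retained if abs(corr.loc[col, r]) >= threshold), None)
        if partner is None:
            retained.append(col)
        else:
            dropped.append((col, partner, float(corr.loc[col, partner])))
    return CorrelationReport(retained=retained, dropped=dropped, matrix=corr)
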