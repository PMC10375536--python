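"""Structural novelty of screening hits via fingerprint Tanimoto similarity.

Hashed topological-path fingerprints (RDKit's path-based fingerprint, paths
of 1-7 bonds hashed into 2048 bits by default) summarize each structure as a
bit set; the Tanimoto coefficient |A∩B| / |A∪B| then measures similarity on
[0, 1]. A hit whose maximum coefficient against the whole ligand database is
~0.5 has a scaffold essentially unrepresented in the known chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem

#: Fingerprint parameters recorded with every output for reproducibility.
DEFAULT_FP_PARAMS = {"family": "rdkit-topological-path", "min_path": 1,
                     "max_path": 7, "n_bits": 2048}


@dataclass(frozen=True)
class Fingerprint:
    ligand_id: str
    bits: frozenset[int]
    n_bits: int = 2048

    def __post_init__(self):
        if any(not 0 <= b < self.n_bits for b in self.bits):
            raise ValueError("bit indices must lie in [0, n_bits)")


def fingerprint(structure: str, ligand_id: str | None = None,
                n_bits: int = 2048, min_path: int = 1, max_path: int = 7) -> Fingerprint:
    """Hashed topological-path fingerprint of one SMILES (deterministic)."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {structure!r}")
    fp = Chem.RDKFingerprint(mol, minPath=min_path, maxPath=max_path, fpSize=n_bits)
    return Fingerprint(ligand_id=structure if ligand_id is None else ligand_id,
                       bits=frozenset(fp.GetOnBits()), n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A∩B| / |A∪B|; two empty fingerprints count as identical (warned)."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return len(a.bits & b.bits) / union


def max_similarity_vs_db(query: Fingerprint, db: list[Fingerprint]
                         ) -> tuple[str, float, pd.Series]:
    """Most-similar database member for one query.

    Returns (best ligand_id, best coefficient, full per-member coefficient
    profile for histogramming). Ties broken by lexicographic ligand id, so
    the result is invariant to database order.
    """
    if not db:
        raise ValueError("database must be nonempty")
    profile = pd.Series({m.ligand_id: tanimoto(query, m) for m in db}).sort_index()
    best_id = profile.idxmax()  # sorted index -> lexicographic tie-break
    return str(best_id), float(profile[best_id]), profile


def similarity_table(queries: list[Fingerprint], db: list[Fingerprint]) -> pd.DataFrame:
    """Long-format (query_id, db_id, tanimoto) pairs plus per-query maxima
    flagged in an ``is_max`` column."""
    rows = []
    for q in queries:
        best_id, best, profile = max_similarity_vs_db(q, db)
        for db_id, coef in profile.items():
            rows.append({"query_id": q.ligand_id, "db_id": db_id,
                         "tanimoto": coef, "is_max": db_id == best_id})
    return pd.DataFrame(rows)
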