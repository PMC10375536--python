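"""Synthetic fixtures with the statistical structure the pipeline assumes.

Every stage of the screening pipeline is testable without downloads through
three generators, each a pure function of its spec (seed included):

* :func:`synth_ligand_db` — a literature-style affinity table: structures
  drawn from a bundled scaffold library of recurring amyloid-ligand motifs,
  log10(Kd/M) drawn from a normal spread (default mean -7, SD 1, matching the
  observed distribution of fibril-ligand affinities), a chosen count of
  limiting values pinned at the Kd > 1 uM bound, mixed direct/competition
  assay kinds with reference-radioligand competitor ids, and injected
  duplicate rows so deduplication is exercised.
* :func:`synth_descriptor_table` — feature/target tables with a planted
  linear signal and known noise, for model-recovery tests.
* :func:`synth_titration` — three-phase ThT titration curves (dilution,
  direct, competition) generated through the equilibrium model with additive
  Gaussian noise, truth parameters embedded as metadata.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem

from .binding_assay import BindingParams, predict_intensity, solve_equilibrium
from .ligand_db import DEFAULT_REFERENCE_IDS


@dataclass(frozen=True)
class SynthSpec:
    """Knobs of the synthetic ligand-table generator.

    Affinity spread defaults emulate the log-normal Kd distribution of known
    fibril ligands; ``limiting_fraction`` entries are emitted as Kd > 1 uM
    bounds; ``duplicate_fraction`` extra rows repeat existing structures under
    an alternative SMILES rendering.
    """

    seed: int = 0
    n_ligands: int = 100
    affinity_mean: float = -7.0
    affinity_sd: float = 1.0
    limiting_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    competition_fraction: float = 0.7
    reference_competitor_fraction: float = 0.9
    limiting_bound_log_kd: float = -6.0

    def __post_init__(self):
        for name in ("limiting_fraction", "duplicate_fraction",
                     "competition_fraction", "reference_competitor_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_ligands < 1:
            raise ValueError("n_ligands must be >= 1")


def load_scaffold_library() -> tuple[dict[str, str], list[str]]:
    """Bundled scaffold templates (two {R1}/{R2} slots each) and substituents."""
    cfg = yaml.safe_load(
        resources.files("amyloidvs.data").joinpath("scaffolds.yaml").read_text())
    return dict(cfg["scaffolds"]), list(cfg["substituents"])


def _draw_structures(rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    """n unique (scaffold_name, canonical-unique SMILES) pairs."""
    scaffolds, subs = load_scaffold_library()
    names = sorted(scaffolds)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    max_tries = 200 * n
    for _ in range(max_tries):
        if len(out) == n:
            break
        name = names[rng.integers(len(names))]
        r1, r2 = subs[rng.integers(len(subs))], subs[rng.integers(len(subs))]
        smi = scaffolds[name].format(R1=r1, R2=r2)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - library is pre-validated
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        seen.add(canon)
        out.append((name, canon))
    if len(out) < n:
        raise ValueError(f"scaffold library capacity exceeded: got {len(out)} < {n}")
    return out


def _alt_rendering(smiles: str, rng: np.random.Generator) -> str:
    """A different but equivalent SMILES string for the same molecule."""
    mol = Chem.MolFromSmiles(smiles)
    for _ in range(20):
        root = int(rng.integers(mol.GetNumAtoms()))
        alt = Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=root)
        if alt != smiles and Chem.MolFromSmiles(alt) is not None:
            return alt
    return smiles


_UNIT_CHOICES = ("nM", "uM", "pM", "M")


def _kd_in_units(log_kd: float, units: str) -> float:
    from .ligand_db import UNIT_FACTORS
    return 10.0 ** log_kd / UNIT_FACTORS[units]


def synth_ligand_db(spec: SynthSpec, out_path: str | Path | None = None) -> pd.DataFrame:
    """Generate a literature-style ligand affinity table.

    Returns the table (columns of the ligand-CSV dialect); optionally writes
    it as CSV. Deterministic from ``spec`` — identical spec gives identical
    file bytes. Exactly ``round(limiting_fraction * n_ligands)`` rows are
    limiting, marked as upper bounds at the configured log Kd.
    """
    rng = np.random.default_rng(spec.seed)
    structures = _draw_structures(rng, spec.n_ligands)
    log_kds = rng.normal(spec.affinity_mean, spec.affinity_sd, size=spec.n_ligands)
    n_limiting = int(round(spec.limiting_fraction * spec.n_ligands))
    limiting_idx = set(rng.choice(spec.n_ligands, size=n_limiting, replace=False).tolist())
    refs = sorted(DEFAULT_REFERENCE_IDS)
    rows = []
    for i, (scaffold, smi) in enumerate(structures):
        is_limit = i in limiting_idx
        log_kd = spec.limiting_bound_log_kd if is_limit else float(log_kds[i])
        units = _UNIT_CHOICES[rng.integers(len(_UNIT_CHOICES))]
        is_comp = rng.random() < spec.competition_fraction
        if is_comp:
            vs_ref = rng.random() < spec.reference_competitor_fraction
            competitor = (refs[rng.integers(len(refs))] if vs_ref
                          else f"other_{rng.integers(1, 6)}")
        else:
            competitor = ""
        rows.append({
            "smiles": smi,
            "kd_value": f"{_kd_in_units(log_kd, units):.6g}",
            "kd_units": units,
            "kd_is_limit": "gt" if is_limit else "none",
            "assay": "competition" if is_comp else "direct",
            "competitor_id": competitor,
            "source": f"synth:{scaffold}",
        })
    n_dup = int(round(spec.duplicate_fraction * spec.n_ligands))
    if n_dup:
        dup_idx = rng.choice(spec.n_ligands, size=n_dup, replace=False)
        for j in dup_idx:
            base = dict(rows[int(j)])
            base["smiles"] = _alt_rendering(base["smiles"], rng)
            if base["kd_is_limit"] == "none":
                jitter = float(rng.normal(0.0, 0.1))
                orig_log = math.log10(float(rows[int(j)]["kd_value"])) + math.log10(
                    {"M": 1, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}[rows[int(j)]["kd_units"]])
                base["kd_value"] = f"{_kd_in_units(orig_log + jitter, base['kd_units']):.6g}"
            base["source"] += ";duplicate-report"
            rows.append(base)
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False, lineterminator="\n")
    return df


def synth_descriptor_table(n_samples: int = 200,
                           coefficients: Sequence[float] | dict[str, float] = (1.0, -0.5),
                           n_noise_features: int = 0,
                           noise_sd: float = 0.0,
                           intercept: float = -7.0,
                           seed: int = 0) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Feature table with a planted linear affinity signal.

    Features are iid standard normal. Targets are
    ``intercept + X @ coefficients + Normal(0, noise_sd)``; extra pure-noise
    columns can be appended. Returns (features, targets, truth) where truth
    records the planted coefficients for recovery tests.
    """
    rng = np.random.default_rng(seed)
    if isinstance(coefficients, dict):
        names = list(coefficients)
        coefs = np.array([coefficients[k] for k in names], dtype=float)
    else:
        coefs = np.asarray(coefficients, dtype=float)
        names = [f"d{i:02d}" for i in range(len(coefs))]
    noise_names = [f"noise{i:02d}" for i in range(n_noise_features)]
    X = pd.DataFrame(rng.normal(size=(n_samples, len(names) + n_noise_features)),
                     columns=names + noise_names,
                     index=pd.Index([f"L{i:05d}" for i in range(n_samples)],
                                    name="ligand_id"))
    y = pd.Series(intercept + X[names].to_numpy() @ coefs
                  + rng.normal(0.0, noise_sd, size=n_samples),
                  index=X.index, name="log_kd")
    truth = {"coefficients": dict(zip(names, coefs)), "intercept": intercept,
             "noise_sd": noise_sd, "seed": seed}
    return X, y, truth


#: Default concentration schedule mirroring a two-phase fibril experiment:
#: ThT diluted alone, then titrated into 500 nM (monomer-equivalent) fibrils,
#: then a competitor titrated into the fibril/ThT mixture at 1 uM ThT. Point
#: counts follow typical plate-reader titrations (~24 per phase).
DEFAULT_SCHEDULE = {
    "dilution_tht_M": tuple(np.linspace(0.0, 2e-6, 8)),
    "direct_tht_M": tuple(np.linspace(0.0, 3e-6, 24)),
    "competition_tht_M": 1e-6,
    "competition_l_M": (0.0,) + tuple(np.geomspace(1e-9, 3e-5, 23)),
    "fibril_conc_M": 5e-7,
}

#: Default simulation truth: ThT response enhanced ~200-fold on binding
#: (within the 100-1000x enhancement range typical of ThT on amyloid
#: fibrils), site dissociation constants at the values reported for ThT and
#: a nanomolar competitor on fibrils, and the fibril offering two equal site
#: pools of 250 nM each.
DEFAULT_TRUTH = dict(eps_f_phi_f=5e9, eps_b_phi_b=1e12,
                     kd_tht=10.0 ** -6.7, kd_l=10.0 ** -7.6,
                     s1_tot=250e-9, s2_tot=250e-9)


def default_truth_params() -> BindingParams:
    """The default simulation ground truth as a :class:`BindingParams`."""
    return BindingParams(**DEFAULT_TRUTH)


def synth_titration(params: BindingParams, schedule: dict | None = None,
                    noise_sd: float = 0.02, seed: int = 0,
                    replicate_id: str = "r1") -> pd.DataFrame:
    """Simulate a three-phase titration through the equilibrium model.

    ``noise_sd`` is additive Gaussian noise expressed as a fraction of the
    curve's dynamic range. Truth parameters are attached in ``df.attrs`` and
    written as ``#`` comment lines by :func:`write_titration_csv`.
    """
    sched = dict(DEFAULT_SCHEDULE, **(schedule or {}))
    rng = np.random.default_rng(seed)
    rows = []
    for t in sched["dilution_tht_M"]:
        rows.append(("dilution", t, 0.0, 0.0, params.eps_f_phi_f * t))
    for t in sched["direct_tht_M"]:
        st = solve_equilibrium(t, 0.0, params)
        rows.append(("direct", t, 0.0, sched["fibril_conc_M"],
                     predict_intensity(st, params)))
    t_comp = sched["competition_tht_M"]
    for l in sched["competition_l_M"]:
        st = solve_equilibrium(t_comp, l, params)
        rows.append(("competition", t_comp, l, sched["fibril_conc_M"],
                     predict_intensity(st, params)))
    df = pd.DataFrame(rows, columns=["phase", "tht_tot_M", "l_tot_M",
                                     "fibril_conc_M", "intensity_au"])
    dyn = float(df["intensity_au"].max() - df["intensity_au"].min())
    if noise_sd > 0:
        df["intensity_au"] += rng.normal(0.0, noise_sd * dyn, size=len(df))
    df["replicate_id"] = replicate_id
    df.attrs["truth"] = {
        "log10_kd_tht": math.log10(params.kd_tht),
        "log10_kd_l": math.log10(params.kd_l),
        "eps_f_phi_f": params.eps_f_phi_f, "eps_b_phi_b": params.eps_b_phi_b,
        "s1_tot_M": params.s1_tot, "s2_tot_M": params.s2_tot,
        "noise_sd": noise_sd, "seed": seed,
        "lambda_ex_nm": 440.0, "lambda_em_nm": 483.0,
    }
    return df


def write_titration_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with truth/metadata embedded as leading ``#`` comment lines."""
    buf = io.StringIO()
    for k, v in df.attrs.get("truth", {}).items():
        buf.write(f"# {k} = {v}\n")
    df.to_csv(buf, index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_titration_csv(path: str | Path) -> pd.DataFrame:
    """Read a titration CSV, recovering ``#``-comment metadata into attrs."""
    truth = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition("=")
            truth[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    df.attrs["truth"] = truth
    return df
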