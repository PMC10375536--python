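"""End-to-end orchestration of the three-step ligand-based screen.

Candidates flow through (1) the molecular property filter, (2) the
descriptor-based affinity model (threshold on predicted -log10(Kd/M) and/or
a top-n cut), and (3) an optional pluggable 3D re-ranking stage, ending in a
ranked shortlist with a provenance report of per-stage counts, seeds and
versions. The 3D stage in the original workflow relies on proprietary
molecular-field software; here it is abstracted behind the
:class:`Rank3DPlugin` interface, with a pass-through null plugin and an
illustrative shape-similarity plugin (NOT the field-point method) shipped as
examples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .affinity_models import fit_screening_model, rank_and_select
from .descriptors import (apply_standardization, compute_descriptors,
                          fit_standardization)
from .screen_filters import PropertyWindow, apply_property_filter, profile

logger = logging.getLogger(__name__)


@runtime_checkable
class Rank3DPlugin(Protocol):
    """Contract for a step-3 re-ranking stage.

    ``scores`` must return one row per candidate with columns ``ligand_id``,
    ``pred_log_kd`` and ``in_domain`` (the in-model flag mirrors a
    distance-to-model gate: out-of-domain candidates carry no usable score).
    """

    name: str

    def scores(self, candidates: pd.DataFrame, training: pd.DataFrame) -> pd.DataFrame:
        ...


class NullPlugin:
    """Pass-through: every candidate in-domain, step-2 prediction kept."""

    name = "null"

    def scores(self, candidates: pd.DataFrame, training: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({"ligand_id": candidates["ligand_id"],
                             "pred_log_kd": candidates["pred_log_kd"],
                             "in_domain": True})


class ShapeNeighborPlugin:
    """Illustrative 3D stage: USR shape-similarity nearest-neighbor scoring.

    Scores each candidate as the similarity-weighted mean log10(Kd/M) of its
    ``k`` most shape-similar training ligands (ultrafast shape recognition on
    a seeded conformer); candidates whose best shape similarity falls below
    ``domain_cutoff`` are flagged out-of-domain. This is a deliberately
    simple stand-in scoring function, not a molecular-field QSAR.
    """

    name = "shape-neighbor"

    def __init__(self, k: int = 5, domain_cutoff: float = 0.5, seed: int = 0):
        self.k, self.domain_cutoff, self.seed = k, domain_cutoff, seed

    @staticmethod
    def _usr(smiles: str, seed: int):
        from rdkit import Chem
        from rdkit.Chem import AllChem, rdMolDescriptors
        mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
        params = AllChem.ETKDGv3()
        params.randomSeed = seed & 0x7FFFFFFF
        if AllChem.EmbedMolecule(mol, params) != 0:
            return None
        return rdMolDescriptors.GetUSR(mol)

    def scores(self, candidates: pd.DataFrame, training: pd.DataFrame) -> pd.DataFrame:
        from rdkit.Chem import rdMolDescriptors
        train = [(r.ligand_id, self._usr(r.smiles, self.seed), r.log_kd)
                 for r in training.itertuples()]
        train = [(lid, u, y) for lid, u, y in train if u is not None]
        rows = []
        for r in candidates.itertuples():
            u = self._usr(r.smiles, self.seed)
            if u is None or not train:
                rows.append((r.ligand_id, np.nan, False))
                continue
            sims = np.array([rdMolDescriptors.GetUSRScore(u, tu) for _, tu, _ in train])
            order = np.argsort(-sims)[:self.k]
            w = sims[order]
            ys = np.array([train[j][2] for j in order])
            pred = float(np.average(ys, weights=w)) if w.sum() > 0 else float(np.mean(ys))
            rows.append((r.ligand_id, pred, bool(sims.max() >= self.domain_cutoff)))
        return pd.DataFrame(rows, columns=["ligand_id", "pred_log_kd", "in_domain"])


PLUGINS = {"null": NullPlugin, "shape-neighbor": ShapeNeighborPlugin}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a screening run."""

    window: PropertyWindow = field(default_factory=PropertyWindow)
    with_3d_descriptors: bool = False
    descriptor_names: list[str] | None = None
    model: str = "svm"
    task: str = "regression"
    seed: int = 0
    budget: int = 20
    threshold_neglog: float | None = None
    top_n: int | None = 50
    plugin: str | None = None
    plugin_top_n: int | None = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        win = raw.pop("window", None)
        cfg = cls(**raw)
        if win:
            if "allowed_net_charge" in win:
                win["allowed_net_charge"] = frozenset(win["allowed_net_charge"])
            cfg.window = PropertyWindow(**win)
        return cfg


@dataclass
class PipelineResult:
    shortlist: pd.DataFrame  # ligand_id, pred_log_kd (+ plugin columns)
    stage_counts: dict[str, int]
    provenance: dict


def run_pipeline(config: PipelineConfig, candidates: pd.DataFrame,
                 training: pd.DataFrame) -> PipelineResult:
    """Run filter → descriptor model → optional 3D plugin on a candidate table.

    ``candidates`` needs columns ``ligand_id, smiles``; ``training`` needs
    ``ligand_id, smiles, log_kd`` (curated consensus affinities). Returns the
    ranked shortlist plus per-stage survivor counts and full provenance.
    """
    counts = {"input": len(candidates)}
    # stage 1: property filter
    profiles = [profile(r.smiles, r.ligand_id) for r in candidates.itertuples()]
    fres = apply_property_filter(profiles, config.window)
    survivors = candidates[candidates["ligand_id"].isin(fres.passed_ids)].reset_index(drop=True)
    counts["property_filter"] = len(survivors)
    if survivors.empty:
        return PipelineResult(shortlist=survivors.assign(pred_log_kd=[]),
                              stage_counts=_finalize_counts(counts),
                              provenance=_provenance(config, counts))
    # stage 2: descriptor model
    X_train = compute_descriptors(training["smiles"].tolist(),
                                  training["ligand_id"].tolist(),
                                  with_3d=config.with_3d_descriptors,
                                  seed=config.seed, names=config.descriptor_names)
    y_train = training.set_index("ligand_id").loc[X_train.index, "log_kd"]
    std = fit_standardization(X_train)
    model, best_params = fit_screening_model(
        apply_standardization(X_train, std), y_train, task=config.task,
        model=config.model, seed=config.seed, budget=config.budget)
    X_cand = compute_descriptors(survivors["smiles"].tolist(),
                                 survivors["ligand_id"].tolist(),
                                 with_3d=config.with_3d_descriptors,
                                 seed=config.seed, names=config.descriptor_names)
    preds = pd.Series(model.predict(apply_standardization(X_cand, std).to_numpy()),
                      index=X_cand.index, name="pred_log_kd")
    selected = rank_and_select(preds, threshold_neglog=config.threshold_neglog,
                               top_n=config.top_n)
    step2 = (survivors.set_index("ligand_id").loc[selected]
             .assign(pred_log_kd=preds.loc[selected]).reset_index())
    counts["descriptor_model"] = len(step2)
    # stage 3: optional plugin
    if config.plugin and not step2.empty:
        plugin = PLUGINS[config.plugin]() if isinstance(config.plugin, str) else config.plugin
        sc = plugin.scores(step2, training)
        sc = sc[sc["in_domain"]]
        merged = step2.drop(columns=["pred_log_kd"]).merge(
            sc.rename(columns={"pred_log_kd": "pred_log_kd"}), on="ligand_id")
        keep = rank_and_select(merged.set_index("ligand_id")["pred_log_kd"],
                               top_n=config.plugin_top_n)
        shortlist = merged.set_index("ligand_id").loc[keep].reset_index()
        shortlist = shortlist.drop_duplicates(subset="ligand_id")
        counts["plugin_3d"] = len(shortlist)
    else:
        shortlist = step2
    counts["shortlist"] = len(shortlist)
    return PipelineResult(shortlist=shortlist,
                          stage_counts=_finalize_counts(counts),
                          provenance=_provenance(config, counts,
                                                 best_params=best_params if not survivors.empty else None))


def _finalize_counts(counts: dict) -> dict:
    order = ["input", "property_filter", "descriptor_model", "plugin_3d", "shortlist"]
    return {k: counts[k] for k in order if k in counts}


def _provenance(config: PipelineConfig, counts: dict, best_params=None) -> dict:
    return {"package_version": __version__, "seed": config.seed,
            "model": config.model, "task": config.task,
            "budget": config.budget, "best_params": best_params,
            "window": {"mw": [config.window.mw_min, config.window.mw_max],
                       "logp": [config.window.logp_min, config.window.logp_max],
                       "charge": sorted(config.window.allowed_net_charge)},
            "threshold_neglog": config.threshold_neglog, "top_n": config.top_n,
            "plugin": config.plugin, "stage_counts": _finalize_counts(counts)}


def average_scores(columns: pd.DataFrame) -> pd.Series:
    """Mean over any set of per-candidate score columns (used to combine the
    predictions of two models into one ranking)."""
    return columns.mean(axis=1)


def hit_rate(hits: int, assayed: int) -> float | None:
    """Experimental hit rate as a percentage (one decimal); None when nothing
    was assayed."""
    if assayed == 0:
        return None
    return round(100.0 * hits / assayed, 1)


def report(result: PipelineResult, hits: int | None = None,
           assayed: int | None = None) -> dict:
    """Machine-readable run summary (JSON-safe); includes hit-rate arithmetic
    once assay outcomes are attached."""
    preds = result.shortlist.get("pred_log_kd", pd.Series(dtype=float))
    summary = {
        "stage_counts": result.stage_counts,
        "provenance": result.provenance,
        "shortlist_size": len(result.shortlist),
        "pred_log_kd": ({"min": float(preds.min()), "median": float(preds.median()),
                         "max": float(preds.max())} if len(preds) else None),
        "hit_rate_percent": hit_rate(hits, assayed) if assayed is not None else None,
        "n_hits": hits, "n_assayed": assayed,
    }
    return summary


def report_text(summary: dict) -> str:
    lines = ["screening run summary", "---------------------"]
    for k, v in summary["stage_counts"].items():
        lines.append(f"{k:>18}: {v}")
    if summary["pred_log_kd"]:
        p = summary["pred_log_kd"]
        lines.append(f"predicted log(Kd/M): min {p['min']:.2f}, "
                     f"median {p['median']:.2f}, max {p['max']:.2f}")
    if summary["hit_rate_percent"] is not None:
        lines.append(f"hit rate: {summary['n_hits']}/{summary['n_assayed']} "
                     f"= {summary['hit_rate_percent']}%")
    elif summary["n_assayed"] is not None:
        lines.append("hit rate: undefined (0 assayed)")
    return "\n".join(lines)


def save_report(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str))
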