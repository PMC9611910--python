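"""End-to-end training and prediction of per-metal sensitivity models.

For one target ion the pipeline (i) parses every training structure,
(ii) builds the full shortest-path fragment count matrix, (iii) selects a
latent-variable count by leave-one-out CV and fits a first PLS model,
(iv) prunes descriptors whose weighted coefficients fall inside the
±threshold band and refits with a freshly selected LV count, and
(v) packages the result — vocabularies, model, calibration and validation
metrics before and after pruning, importance table, config snapshot and an
input digest — into a serializable bundle.

Metals are arbitrary labels: any ``sens_<label>`` column of the dataset
can be modeled, nothing is specific to Cu/Cd/Pb.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .datasets import SensitivityRecord
from .fragments import build_descriptor_matrix, enumerate_fragments
from .pls import ModelMetrics, PLSModel, compute_metrics, fit_pls, loo_cv, predict
from .selection import ImportanceReport, important_fragments, prune_descriptors
from .structures import ParseError, KekulizationError, parse_structure

PathLike = Union[str, Path]


@dataclass
class PipelineConfig:
    """Resolved configuration of one training run.

    ``threshold`` is on the weighted-coefficient scale (mV/dec per unit of
    autoscaled descriptor); ``coverage_warn`` is the applicability-domain
    coverage below which a prediction is flagged.
    """

    min_atoms: int = 2
    max_atoms: int = 9
    atoms_only: bool = False
    scale: bool = True
    max_lv: int = 15
    threshold: float = 0.05
    min_support: int = 5
    collapse_nested: bool = True
    nested_tol: float = 0.2
    iterative_pruning: bool = False
    coverage_warn: float = 0.5

    @classmethod
    def from_yaml(cls, path: PathLike) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_yaml(self, path: PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _dataset_digest(records: Sequence[SensitivityRecord], metal: str,
                    config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "metal": metal,
            "config": config.to_dict(),
            "rows": [[r.id, r.smiles, r.sensitivity.get(metal)] for r in records],
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class MetalModelBundle:
    """Everything needed to reuse or audit one per-metal model."""

    metal: str
    full_vocabulary: List[str]
    pruned_vocabulary: List[str]
    model: PLSModel
    metrics_full: Dict[str, ModelMetrics]      # calibration / loo_validation pre-pruning
    metrics_pruned: Dict[str, ModelMetrics]    # same, after pruning + refit
    selected_lv_full: int
    rmsecv_full: List[float]
    rmsecv_pruned: List[float]
    importance: ImportanceReport
    config: PipelineConfig
    input_digest: str
    n_training: int

    def to_dict(self) -> Dict:
        return {
            "metal": self.metal,
            "full_vocabulary": list(self.full_vocabulary),
            "pruned_vocabulary": list(self.pruned_vocabulary),
            "model": self.model.to_dict(),
            "metrics_full": {k: m.to_dict() for k, m in self.metrics_full.items()},
            "metrics_pruned": {k: m.to_dict() for k, m in self.metrics_pruned.items()},
            "selected_lv_full": int(self.selected_lv_full),
            "selected_lv_pruned": int(self.model.n_lv),
            "rmsecv_full": [float(v) for v in self.rmsecv_full],
            "rmsecv_pruned": [float(v) for v in self.rmsecv_pruned],
            "importance": self.importance.to_dict(),
            "config": self.config.to_dict(),
            "input_digest": self.input_digest,
            "n_training": int(self.n_training),
        }

    def to_json(self) -> str:
        # sorted keys + explicit separators → byte-identical re-serialization
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    def save(self, path: PathLike) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_dict(cls, d: Dict) -> "MetalModelBundle":
        from .selection import ImportanceEntry
        imp = d["importance"]
        report = ImportanceReport(
            entries=[ImportanceEntry(**e) for e in imp["entries"]],
            min_support=imp["min_support"],
            collapse_nested=imp["collapse_nested"],
            nested_tol=imp["nested_tol"],
        )
        return cls(
            metal=d["metal"],
            full_vocabulary=list(d["full_vocabulary"]),
            pruned_vocabulary=list(d["pruned_vocabulary"]),
            model=PLSModel.from_dict(d["model"]),
            metrics_full={k: ModelMetrics.from_dict(m) for k, m in d["metrics_full"].items()},
            metrics_pruned={k: ModelMetrics.from_dict(m) for k, m in d["metrics_pruned"].items()},
            selected_lv_full=int(d["selected_lv_full"]),
            rmsecv_full=list(d["rmsecv_full"]),
            rmsecv_pruned=list(d["rmsecv_pruned"]),
            importance=report,
            config=PipelineConfig(**d["config"]),
            input_digest=d["input_digest"],
            n_training=int(d["n_training"]),
        )

    @classmethod
    def load(cls, path: PathLike) -> "MetalModelBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train(records: Sequence[SensitivityRecord], metal: str,
          config: Optional[PipelineConfig] = None) -> MetalModelBundle:
    """Train the per-metal sensitivity model from dataset records.

    Records missing the target metal's sensitivity are excluded. The run is
    fully deterministic for a given dataset + config.
    """
    config = config or PipelineConfig()
    usable = [r for r in records if metal in r.sensitivity]
    if len(usable) < 5:
        raise ValueError(
            f"need >= 5 records with a {metal} sensitivity, found {len(usable)}"
        )
    y = np.array([r.sensitivity[metal] for r in usable], dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError(f"all {metal} sensitivities identical; nothing to model")
    graphs = [parse_structure(r.smiles, r.id) for r in usable]
    X_full = build_descriptor_matrix(graphs, min_atoms=config.min_atoms,
                                     max_atoms=config.max_atoms,
                                     atoms_only=config.atoms_only)
    max_lv = min(config.max_lv, len(usable) - 1)
    loo_full = loo_cv(X_full, y, max_lv=max_lv, scale=config.scale)
    model_full = fit_pls(X_full, y, n_lv=loo_full.selected_lv, scale=config.scale)
    metrics_full = {
        "calibration": compute_metrics(y, predict(model_full, X_full), "calibration"),
        "loo_validation": compute_metrics(y, loo_full.selected_predictions, "loo_validation"),
    }
    pruned = prune_descriptors(model_full, X_full, y, threshold=config.threshold,
                               max_lv=max_lv, scale=config.scale,
                               iterative=config.iterative_pruning)
    importance = important_fragments(pruned.model, pruned.matrix,
                                     min_support=config.min_support,
                                     collapse_nested=config.collapse_nested,
                                     nested_tol=config.nested_tol)
    return MetalModelBundle(
        metal=metal,
        full_vocabulary=list(X_full.columns),
        pruned_vocabulary=list(pruned.matrix.columns),
        model=pruned.model,
        metrics_full=metrics_full,
        metrics_pruned={"calibration": pruned.calibration,
                        "loo_validation": pruned.validation},
        selected_lv_full=loo_full.selected_lv,
        rmsecv_full=[float(v) for v in loo_full.rmsecv],
        rmsecv_pruned=[float(v) for v in pruned.loo.rmsecv],
        importance=importance,
        config=config,
        input_digest=_dataset_digest(usable, metal, config),
        n_training=len(usable),
    )


def predict_new(bundle: MetalModelBundle,
                smiles: Sequence[Union[str, Tuple[str, str]]]) -> pd.DataFrame:
    """Predict sensitivities for new structures under a trained bundle.

    ``smiles`` items are SMILES strings or (smiles, id) pairs. Descriptors
    are computed against the pruned vocabulary; vocabulary fragments absent
    from a molecule count zero and novel fragments are ignored. The result
    also reports the applicability coverage — the fraction of the
    molecule's distinct fragments present in the vocabulary — with a
    warning below ``config.coverage_warn``. Parse failures yield a row with
    an error message instead of aborting the batch.
    """
    items: List[Tuple[str, str]] = []
    for k, entry in enumerate(smiles):
        if isinstance(entry, str):
            items.append((entry, f"query{k}"))
        else:
            items.append((entry[0], entry[1]))
    config = bundle.config
    vocab = set(bundle.pruned_vocabulary)
    rows = []
    for smi, mol_id in items:
        row = {"id": mol_id, "smiles": smi, "predicted_mV_per_dec": np.nan,
               "coverage": np.nan, "warning": "", "error": ""}
        try:
            g = parse_structure(smi, mol_id)
        except (ParseError, KekulizationError) as exc:
            row["error"] = str(exc)
            rows.append(row)
            continue
        frags = enumerate_fragments(g, config.min_atoms, config.max_atoms,
                                    atoms_only=config.atoms_only)
        X = build_descriptor_matrix([g], vocabulary=bundle.pruned_vocabulary,
                                    min_atoms=config.min_atoms,
                                    max_atoms=config.max_atoms,
                                    atoms_only=config.atoms_only)
        row["predicted_mV_per_dec"] = float(predict(bundle.model, X)[0])
        coverage = (len(set(frags) & vocab) / len(frags)) if frags else 0.0
        row["coverage"] = coverage
        if coverage < config.coverage_warn:
            row["warning"] = (
                f"coverage {coverage:.2f} below {config.coverage_warn}: "
                "molecule is poorly represented by the model vocabulary"
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "smiles", "predicted_mV_per_dec",
                                       "coverage", "warning", "error"])


def report(bundle: MetalModelBundle,
           predictions: Optional[pd.DataFrame] = None) -> Dict:
    """Machine-readable summary of a trained bundle (plus optional predictions)."""
    out = {
        "metal": bundle.metal,
        "n_training": bundle.n_training,
        "vocabulary_size_full": len(bundle.full_vocabulary),
        "vocabulary_size_pruned": len(bundle.pruned_vocabulary),
        "selected_lv_full": bundle.selected_lv_full,
        "selected_lv_pruned": bundle.model.n_lv,
        "metrics": {
            "full": {k: m.to_dict() for k, m in bundle.metrics_full.items()},
            "pruned": {k: m.to_dict() for k, m in bundle.metrics_pruned.items()},
        },
        "importance": bundle.importance.to_dict(),
        "config": bundle.config.to_dict(),
        "input_digest": bundle.input_digest,
    }
    if predictions is not None:
        out["predictions"] = predictions.to_dict(orient="records")
    return out


def format_report(bundle: MetalModelBundle,
                  predictions: Optional[pd.DataFrame] = None) -> str:
    """Human-readable rendering of :func:`report`."""
    lines = [
        f"Sensitivity model for {bundle.metal} ({bundle.n_training} training structures)",
        f"  vocabulary: {len(bundle.full_vocabulary)} fragments "
        f"-> {len(bundle.pruned_vocabulary)} after pruning "
        f"(|coefficient| >= {bundle.config.threshold})",
        f"  latent variables: {bundle.selected_lv_full} (full) "
        f"-> {bundle.model.n_lv} (pruned), selected by LOO CV",
        "",
        f"  {'stage':<10} {'context':<16} {'slope':>7} {'RMSE':>7} {'R2':>6}",
    ]
    for stage, metrics in (("full", bundle.metrics_full), ("pruned", bundle.metrics_pruned)):
        for ctx in ("calibration", "loo_validation"):
            m = metrics[ctx]
            lines.append(f"  {stage:<10} {ctx:<16} {m.slope:>7.2f} {m.rmse:>7.2f} {m.r2:>6.2f}")
    if bundle.importance.entries:
        lines += ["", f"  top fragments (support >= {bundle.importance.min_support}):"]
        for e in bundle.importance.entries[:10]:
            lines.append(f"    {e.fragment:<20} coef {e.coefficient:+.3f}  support {e.support}")
    if predictions is not None and len(predictions):
        lines += ["", "  predictions (mV/dec):"]
        for row in predictions.itertuples(index=False):
            if row.error:
                lines.append(f"    {row.id:<14} ERROR: {row.error}")
            else:
                note = "  [low coverage]" if row.warning else ""
                lines.append(
                    f"    {row.id:<14} {row.predicted_mV_per_dec:6.1f}  "
                    f"coverage {row.coverage:.2f}{note}"
                )
    return "\n".join(lines)
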