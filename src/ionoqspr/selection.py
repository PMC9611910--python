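"""Coefficient-threshold descriptor pruning and fragment-importance reporting.

After a first PLS fit, descriptors whose weighted (autoscaled-space)
regression coefficients sit inside a narrow band around zero carry mostly
noise; removing them and refitting typically improves cross-validated
error. The surviving coefficients, filtered by how many training structures
contain each fragment, rank the fragments by importance with a sign showing
whether a fragment raises or lowers the predicted sensitivity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fragments import canonical_fragment, fragment_support
from .pls import LOOResult, ModelMetrics, PLSModel, compute_metrics, fit_pls, loo_cv, predict

PathLike = Union[str, Path]

_TOKEN = re.compile(r"[A-Z][a-z]?|[-=#]")
_BOND_ORDER = {"-": 1, "=": 2, "#": 3}


@dataclass
class ImportanceEntry:
    fragment: str
    coefficient: float   # weighted (autoscaled-space) coefficient
    support: int         # number of training structures containing it
    sign: int            # +1 / -1

    def to_dict(self) -> Dict:
        return {
            "fragment": self.fragment,
            "coefficient": float(self.coefficient),
            "support": int(self.support),
            "sign": int(self.sign),
        }


@dataclass
class ImportanceReport:
    """Fragments ranked by |weighted coefficient|, largest first."""

    entries: List[ImportanceEntry]
    min_support: int
    collapse_nested: bool
    nested_tol: float

    def fragments(self) -> List[str]:
        return [e.fragment for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.entries],
                            columns=["fragment", "coefficient", "support", "sign"])

    def to_tsv(self, path: PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_dict(self) -> Dict:
        return {
            "entries": [e.to_dict() for e in self.entries],
            "min_support": self.min_support,
            "collapse_nested": self.collapse_nested,
            "nested_tol": self.nested_tol,
        }


@dataclass
class PruneResult:
    matrix: pd.DataFrame
    model: PLSModel
    calibration: ModelMetrics
    validation: ModelMetrics
    loo: LOOResult
    removed: List[str]

    def __iter__(self):
        # tuple-style unpacking: (reduced matrix, refit model, new metrics)
        yield self.matrix
        yield self.model
        yield {"calibration": self.calibration, "loo_validation": self.validation}


def prune_descriptors(model: PLSModel, X: pd.DataFrame, y: Sequence[float],
                      threshold: float = 0.05, max_lv: int = 10,
                      scale: bool = True, iterative: bool = False) -> PruneResult:
    """Drop descriptors with |weighted coefficient| below ``threshold`` and refit.

    The threshold acts on the autoscaled-space coefficients, where the
    coefficient magnitudes of fragments with different prevalence are
    comparable. The latent-variable count of the refit model is re-selected
    by leave-one-out CV on the reduced matrix. One pass by default;
    ``iterative=True`` repeats until no further column falls below the
    threshold.
    """
    y = np.asarray(y, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold == 0:
        reduced = X
        removed: List[str] = []
    else:
        coef = pd.Series(model.b_weighted, index=model.kept_columns)
        keep = [c for c in X.columns if abs(coef.get(c, 0.0)) >= threshold]
        removed = [c for c in X.columns if c not in set(keep)]
        if not keep:
            raise ValueError(
                f"threshold {threshold} removes every descriptor; use a smaller threshold"
            )
        reduced = X[keep]
    max_lv_eff = min(max_lv, reduced.shape[0] - 1)
    loo = loo_cv(reduced, y, max_lv=max_lv_eff, scale=scale)
    refit = fit_pls(reduced, y, n_lv=loo.selected_lv, scale=scale)
    if iterative and removed and threshold > 0:
        inner = prune_descriptors(refit, reduced, y, threshold=threshold,
                                  max_lv=max_lv, scale=scale, iterative=True)
        if inner.removed:
            inner.removed = removed + inner.removed
            return inner
    calibration = compute_metrics(y, predict(refit, reduced), "calibration")
    validation = compute_metrics(y, loo.selected_predictions, "loo_validation")
    return PruneResult(matrix=reduced, model=refit, calibration=calibration,
                       validation=validation, loo=loo, removed=removed)


def _tokenize(fragment: str) -> Tuple[List[str], List[int]]:
    tokens = _TOKEN.findall(fragment)
    atoms = tokens[0::2]
    bonds = [_BOND_ORDER[b] for b in tokens[1::2]]
    return atoms, bonds


def _is_terminal_carbon_extension(longer: str, shorter: str) -> bool:
    """True if ``longer`` reduces to ``shorter`` by trimming only terminal
    carbon atoms (with their bonds) from either end."""
    atoms, bonds = _tokenize(longer)
    n = len(atoms)
    n_short = len(_tokenize(shorter)[0])
    if n_short >= n or n_short < 2:
        return False
    trim = n - n_short
    for head in range(trim + 1):
        tail = trim - head
        cut = atoms[:head] + (atoms[n - tail:] if tail else [])
        if any(a != "C" for a in cut):
            continue
        core_atoms = atoms[head:n - tail]
        core_bonds = bonds[head:head + len(core_atoms) - 1]
        if canonical_fragment(core_atoms, core_bonds) == shorter:
            return True
    return False


def important_fragments(model: PLSModel, X: pd.DataFrame, min_support: int = 5,
                        collapse_nested: bool = False, nested_tol: float = 0.2) -> ImportanceReport:
    """Rank fragments by |weighted coefficient| with a support filter.

    Fragments present in fewer than ``min_support`` training structures are
    excluded (guarding against accidental correlations in a small corpus).
    With ``collapse_nested`` on, a fragment that merely extends a retained
    fragment by terminal carbons is suppressed when their coefficients agree
    within ``nested_tol`` (relative to the larger magnitude).
    """
    coef = pd.Series(model.b_weighted, index=model.kept_columns)
    entries = []
    for frag, c in coef.items():
        support = fragment_support(X, frag) if frag in X.columns else 0
        if support < min_support:
            continue
        entries.append(ImportanceEntry(fragment=frag, coefficient=float(c),
                                       support=support, sign=1 if c >= 0 else -1))
    entries.sort(key=lambda e: (-abs(e.coefficient), e.fragment))
    if collapse_nested:
        kept: List[ImportanceEntry] = []
        for e in entries:
            suppressed = False
            for other in entries:
                if other.fragment == e.fragment:
                    continue
                if not _is_terminal_carbon_extension(e.fragment, other.fragment):
                    continue
                denom = max(abs(e.coefficient), abs(other.coefficient), 1e-12)
                if abs(e.coefficient - other.coefficient) / denom < nested_tol:
                    suppressed = True
                    break
            if not suppressed:
                kept.append(e)
        entries = kept
    return ImportanceReport(entries=entries, min_support=min_support,
                            collapse_nested=collapse_nested, nested_tol=nested_tol)


def plot_coefficients(model: PLSModel, path: PathLike, threshold: Optional[float] = 0.05) -> None:
    """Save a weighted-coefficient index plot, optionally marking the ±threshold band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(np.arange(1, len(model.b_weighted) + 1), model.b_weighted,
            lw=0.8, marker=".", ms=3)
    if threshold:
        ax.axhspan(-threshold, threshold, color="0.85", zorder=0)
        ax.axhline(threshold, color="0.5", lw=0.6)
        ax.axhline(-threshold, color="0.5", lw=0.6)
    ax.set_xlabel("descriptor index")
    ax.set_ylabel("weighted regression coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
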