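"""Coefficient-threshold pruning and fragment-importance reporting."""

import numpy as np
import pandas as pd
import pytest

from ionoqspr import (
    SyntheticSpec,
    build_descriptor_matrix,
    fit_pls,
    generate_molecules,
    important_fragments,
    loo_cv,
    plant_property,
    prune_descriptors,
)
from ionoqspr.selection import _is_terminal_carbon_extension


def model_with_coefficients(columns, b_weighted, n_rows=12, seed=0):
    """A fitted-shaped model whose weighted coefficients are set by hand,
    plus a matching random count matrix (for refit plumbing)."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.integers(0, 4, size=(n_rows, len(columns))), columns=columns)
    y = rng.normal(20, 3, size=n_rows)
    model = fit_pls(X, y, n_lv=2)
    model.b_weighted = np.asarray(b_weighted, dtype=float)
    model.kept_columns = list(columns)
    return model, X, y


class TestPruning:
    def test_threshold_keeps_large_coefficients(self):
        cols = ["A-A", "B-B", "C-C", "D-D"]
        model, X, y = model_with_coefficients(cols, [0.2, 0.01, -0.3, 0.04])
        result = prune_descriptors(model, X, y, threshold=0.05, max_lv=3)
        assert list(result.matrix.columns) == ["A-A", "C-C"]
        assert result.removed == ["B-B", "D-D"]

    def test_zero_threshold_is_identity(self):
        cols = ["A-A", "B-B"]
        model, X, y = model_with_coefficients(cols, [0.001, 0.002])
        result = prune_descriptors(model, X, y, threshold=0.0, max_lv=3)
        assert list(result.matrix.columns) == cols

    def test_monotone_in_threshold(self):
        cols = [f"f{i}-f{i}" for i in range(6)]
        model, X, y = model_with_coefficients(cols, [0.2, 0.04, -0.3, 0.06, 0.01, -0.08])
        kept_loose = set(prune_descriptors(model, X, y, 0.05, 3).matrix.columns)
        kept_tight = set(prune_descriptors(model, X, y, 0.07, 3).matrix.columns)
        assert kept_tight <= kept_loose

    def test_all_removed_raises_with_advice(self):
        cols = ["A-A", "B-B"]
        model, X, y = model_with_coefficients(cols, [0.001, 0.002])
        with pytest.raises(ValueError, match="smaller threshold"):
            prune_descriptors(model, X, y, threshold=0.05, max_lv=3)

    def test_refit_never_gains_columns_and_reselects_lv(self, rng):
        spec = SyntheticSpec(n_molecules=40, seed=5, size_range=(8, 14))
        graphs = [g for g, _ in generate_molecules(spec)]
        y, _ = plant_property(graphs, spec)
        X = build_descriptor_matrix(graphs)
        loo = loo_cv(X, y, max_lv=8)
        model = fit_pls(X, y, n_lv=loo.selected_lv)
        result = prune_descriptors(model, X, y, max_lv=8)
        assert result.matrix.shape[1] <= X.shape[1]
        assert set(result.model.kept_columns) <= set(result.matrix.columns)
        assert 1 <= result.model.n_lv <= 8

    def test_planted_actives_survive_default_threshold(self):
        """All 5 planted fragments stay in the pruned vocabulary in at least
        90% of 20 seeded replicates (vocabulary of a few hundred columns)."""
        survived_all = 0
        for seed in range(20):
            spec = SyntheticSpec(n_molecules=60, seed=seed, size_range=(8, 14))
            graphs = [g for g, _ in generate_molecules(spec)]
            y, truth = plant_property(graphs, spec)
            X = build_descriptor_matrix(graphs)
            loo = loo_cv(X, y, max_lv=10)
            model = fit_pls(X, y, n_lv=loo.selected_lv)
            kept = set(prune_descriptors(model, X, y, max_lv=10).matrix.columns)
            if all(f in kept for f in truth.active_fragments):
                survived_all += 1
        assert survived_all >= 18

    def test_planted_positive_weights_keep_positive_coefficients(self):
        """Sign stability: positive-weight planted fragments present in the
        pruned model carry positive coefficients in ≥90% of replicates."""
        stable = 0
        for seed in range(20):
            spec = SyntheticSpec(n_molecules=60, seed=seed, size_range=(8, 14))
            graphs = [g for g, _ in generate_molecules(spec)]
            y, truth = plant_property(graphs, spec)
            X = build_descriptor_matrix(graphs)
            loo = loo_cv(X, y, max_lv=10)
            model = fit_pls(X, y, n_lv=loo.selected_lv)
            refit = prune_descriptors(model, X, y, max_lv=10).model
            coef = dict(zip(refit.kept_columns, refit.b_weighted))
            positives = [f for f, w in zip(truth.active_fragments, truth.weights)
                         if w > 0 and f in coef]
            if all(coef[f] > 0 for f in positives):
                stable += 1
        assert stable >= 18


class TestImportance:
    def test_support_filter_and_sorting(self):
        cols = ["A-A", "B-B", "C-C"]
        rng = np.random.default_rng(2)
        # B-B present in only 4 of 12 rows -> excluded at min_support 5
        X = pd.DataFrame({
            "A-A": rng.integers(1, 3, 12),
            "B-B": [1, 1, 1, 1] + [0] * 8,
            "C-C": rng.integers(1, 3, 12),
        })
        y = rng.normal(size=12)
        model = fit_pls(X, y, n_lv=2)
        model.b_weighted = np.array([0.1, 0.5, -0.4])
        model.kept_columns = cols
        report = important_fragments(model, X, min_support=5)
        assert report.fragments() == ["C-C", "A-A"]
        assert [e.sign for e in report.entries] == [-1, 1]

    def test_no_filter_lists_everything_sorted(self):
        cols = ["A-A", "B-B", "C-C"]
        model, X, _ = model_with_coefficients(cols, [0.1, -0.7, 0.3])
        report = important_fragments(model, X, min_support=0)
        assert report.fragments() == ["B-B", "C-C", "A-A"]

    def test_nested_pair_collapsed(self):
        """A fragment extending another only by a terminal carbon is dropped
        when their coefficients agree within the tolerance."""
        cols = ["C-C-P-C=C", "C-C-P-C=C-C", "C-N=C"]
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.integers(1, 4, size=(12, 3)), columns=cols)
        y = rng.normal(size=12)
        model = fit_pls(X, y, n_lv=2)
        model.kept_columns = cols
        model.b_weighted = np.array([0.50, 0.55, 0.3])
        collapsed = important_fragments(model, X, min_support=0, collapse_nested=True)
        assert collapsed.fragments() == ["C-C-P-C=C", "C-N=C"]
        # distinct contributions: both family members stay
        model.b_weighted = np.array([0.50, 0.90, 0.3])
        kept = important_fragments(model, X, min_support=0, collapse_nested=True)
        assert "C-C-P-C=C-C" in kept.fragments()

    def test_report_tsv(self, tmp_path):
        cols = ["A-A", "B-B"]
        model, X, _ = model_with_coefficients(cols, [0.4, -0.2])
        report = important_fragments(model, X, min_support=0)
        path = tmp_path / "imp.tsv"
        report.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back["fragment"]) == ["A-A", "B-B"]


class TestTerminalCarbonExtension:
    @pytest.mark.parametrize(
        "longer, shorter, expected",
        [
            ("C-C-P-C=C-C", "C-C-P-C=C", True),   # one terminal C trimmed
            ("C-C-P-C=C", "C-P-C=C", True),       # trim from the front
            ("C-C-N-C-C", "C-N-C", True),         # both ends
            ("C-N=C", "C=N", True),               # core re-canonicalized
            ("C-C-O", "C-O-C", False),            # not a sub-path
            ("N-C-P", "C-P", False),              # trimmed atom is N, not C
            ("C-C-O", "C=O", False),              # bond order must match
        ],
    )
    def test_cases(self, longer, shorter, expected):
        assert _is_terminal_carbon_extension(longer, shorter) is expected
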