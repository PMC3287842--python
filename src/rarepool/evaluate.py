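"""Evaluation of gene-level tests: type I error, TPP/FPP, ROC, AUC, universes.

Every metric is a rejection proportion over (gene, replicate) units at a
significance level alpha:

* type I error — mean of I(p_{i,r} <= alpha) over all testable genes of a
  null dataset;
* true-positive proportion (TPP) — the same mean restricted to causal genes
  S_g (intersected with the test's universe; exclusions are counted);
* false-positive proportion (FPP) — restricted to the complement T_g \\ S_g.

Each test has its own gene universe T_g: a fixed-threshold test can only
evaluate genes with at least one polymorphic variant under its cutoff, while
the weighted-sum and variable-threshold tests cover every gene with a
polymorphic variant, giving the inclusion chain T1 ⊆ T5 ⊆ WS = VT.
Not-testable (gene, replicate) entries are excluded from numerator and
denominator alike.

ROC curves sweep alpha over a logarithmic grid, plot (FPP, TPP), extend the
polyline to (0,0) and (1,1), and integrate by the trapezoid rule for the AUC.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TEST_NAMES = ("T1", "T5", "WS", "VT")
FIXED_TEST_THRESHOLDS = {"T1": 0.01, "T5": 0.05}
#: default significance grid for ROC construction
DEFAULT_ALPHA_GRID = np.logspace(-5, 0, 200)


def build_universe(
    test_name: str, variants: pd.DataFrame, gene_index: Mapping[str, np.ndarray]
) -> set[str]:
    """Genes a test can evaluate.

    Fixed-threshold tests need >= 1 polymorphic variant with maf strictly
    below the cutoff; WS and VT need >= 1 polymorphic variant of any
    frequency.
    """
    maf = variants["maf"].to_numpy(dtype=float)
    if np.isnan(maf).any():
        raise ValueError("variant table maf column is unset; run compute_maf first")
    if test_name in FIXED_TEST_THRESHOLDS:
        T = FIXED_TEST_THRESHOLDS[test_name]
        keep = lambda m: bool(np.any((m > 0) & (m < T)))  # noqa: E731
    elif test_name in ("WS", "VT"):
        keep = lambda m: bool(np.any(m > 0))  # noqa: E731
    else:
        raise ValueError(f"unknown test name {test_name!r}")
    return {g for g, cols in gene_index.items() if keep(maf[np.asarray(cols, dtype=int)])}


@dataclasses.dataclass
class PValueGrid:
    """Per-test gene × replicate p-value matrices with universes attached.

    ``pvalues[test]`` is a DataFrame indexed by gene with one column per
    replicate; NaN marks a not-testable entry.
    """

    pvalues: dict[str, pd.DataFrame]
    universes: dict[str, set[str]]

    def matrix(self, test: str) -> pd.DataFrame:
        m = self.pvalues[test]
        return m.loc[sorted(self.universes[test] & set(m.index))]


def grid_from_results(
    replicate_results: Sequence[pd.DataFrame],
    universes: Mapping[str, set[str]],
    tests: Sequence[str] = TEST_NAMES,
) -> PValueGrid:
    """Assemble a PValueGrid from per-replicate results tables.

    A (gene, test) row absent from a replicate's table is not-testable there;
    genes never tested anywhere are still indexed (all-NaN rows) so exclusion
    counts stay visible.
    """
    all_genes = sorted(set().union(*(set(universes[t]) for t in tests)))
    pv: dict[str, pd.DataFrame] = {}
    for t in tests:
        mat = pd.DataFrame(
            np.nan, index=all_genes, columns=range(len(replicate_results))
        )
        for r, frame in enumerate(replicate_results):
            sub = frame[frame["test"] == t]
            mat.loc[sub["gene"].to_numpy(), r] = sub["p_value"].to_numpy(dtype=float)
        pv[t] = mat
    return PValueGrid(pv, {t: set(universes[t]) for t in tests})


def _rejection_rate(mat: pd.DataFrame, alpha: float) -> float:
    vals = mat.to_numpy(dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no testable (gene, replicate) entries")
    return float(np.mean(vals <= alpha))


def type1_error(grid: PValueGrid, test: str, alpha: float) -> float:
    """Rejection proportion over all testable genes of a null dataset."""
    return _rejection_rate(grid.matrix(test), alpha)


def true_positive_proportion(
    grid: PValueGrid, truth: set[str], test: str, alpha: float
) -> float:
    """Rejection proportion over causal genes inside the test's universe."""
    if not truth:
        raise ValueError("empty causal gene set")
    inside = truth & grid.universes[test]
    if not inside:
        raise ValueError(
            f"no causal gene lies in the {test} universe; excluded: {sorted(truth)}"
        )
    excluded = truth - inside
    if excluded:
        log.debug("%s: %d causal genes outside universe: %s", test, len(excluded), sorted(excluded))
    mat = grid.pvalues[test].loc[sorted(inside)]
    return _rejection_rate(mat, alpha)


def false_positive_proportion(
    grid: PValueGrid, truth: set[str], test: str, alpha: float
) -> float:
    """Rejection proportion over non-causal genes inside the test's universe."""
    comp = grid.universes[test] - truth
    if not comp:
        raise ValueError("universe minus causal set is empty")
    mat = grid.pvalues[test].loc[sorted(comp)]
    return _rejection_rate(mat, alpha)


def roc_curve(
    grid: PValueGrid,
    truth: set[str],
    test: str,
    alpha_grid: np.ndarray | None = None,
) -> np.ndarray:
    """(FPP, TPP) polyline over an alpha sweep, extended to (0,0) and (1,1)."""
    if not truth:
        raise ValueError("ROC needs a non-empty causal gene set")
    alphas = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    pts = np.array(
        [
            (
                false_positive_proportion(grid, truth, test, a),
                true_positive_proportion(grid, truth, test, a),
            )
            for a in alphas
        ]
    )
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    return np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])


def auc(points: np.ndarray) -> float:
    """Trapezoid-rule area under an (FPP, TPP) polyline."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


def tpp_at_fpp(points: np.ndarray, fpp: float) -> float:
    """TPP of an ROC polyline at a matched FPP, by linear interpolation."""
    points = np.asarray(points, dtype=float)
    return float(np.interp(fpp, points[:, 0], points[:, 1]))


def bonferroni_threshold(n_genes: int, fwer: float) -> float:
    """Per-gene significance level controlling the family-wise error rate."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not (0.0 < fwer < 1.0):
        raise ValueError("fwer must be in (0, 1)")
    return fwer / n_genes


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EvaluationResult:
    """Long-format metric table plus per-test summary (AUC, universe sizes)."""

    metrics: pd.DataFrame  # columns: test, alpha, metric, value
    summary: pd.DataFrame  # columns: test, auc, universe_size, causal_in_universe
    roc: dict[str, np.ndarray]


def evaluate_grid(
    grid: PValueGrid,
    truth: set[str],
    alphas: Sequence[float] = (1.56e-5, 0.001, 0.005, 0.01, 0.05, 0.1),
    alpha_grid: np.ndarray | None = None,
    tests: Sequence[str] = TEST_NAMES,
) -> EvaluationResult:
    """Compute every metric the grid supports.

    With an empty causal set only type I error is reported; otherwise TPP,
    FPP, ROC and AUC are added.
    """
    rows, summary, roc = [], [], {}
    for t in tests:
        uni = grid.universes[t]
        if not uni:
            log.warning("test %s has an empty gene universe; skipped", t)
            summary.append((t, np.nan, 0, 0))
            continue
        if truth:
            pts = roc_curve(grid, truth, t, alpha_grid)
            roc[t] = pts
            for a in alphas:
                rows.append((t, a, "tpp", true_positive_proportion(grid, truth, t, a)))
                rows.append((t, a, "fpp", false_positive_proportion(grid, truth, t, a)))
            summary.append((t, auc(pts), len(uni), len(truth & uni)))
        else:
            for a in alphas:
                rows.append((t, a, "type1", type1_error(grid, t, a)))
            summary.append((t, np.nan, len(uni), 0))
    return EvaluationResult(
        pd.DataFrame(rows, columns=["test", "alpha", "metric", "value"]),
        pd.DataFrame(summary, columns=["test", "auc", "universe_size", "causal_in_universe"]),
        roc,
    )


def write_evaluation(result: EvaluationResult, metrics_path, summary_path) -> None:
    result.metrics.to_csv(metrics_path, sep="\t", index=False, float_format="%.10g")
    result.summary.to_csv(summary_path, sep="\t", index=False, float_format="%.10g")
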