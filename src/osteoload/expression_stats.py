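"""Relative gene expression (2^dCt) and the study's statistical tests.

Expression is normalised to the TBP housekeeping gene by the 2^dCt method
with dCt = Ct_housekeeping - Ct_gene, so a gene amplifying later than TBP
(higher Ct) has expression below 1 and one cycle of earlier amplification
doubles the value.

The comparisons used across the pipeline are wrapped here with a common
result type: paired t (gene expression control vs treated), unpaired t
(Welch by default; contact/displacement preservation between regimes,
SV/BV between magnitudes), one-way ANOVA (SV/BV, sclerostin fractions
across groups) and OLS regression (dose-response). No multiple-testing
correction is applied — comparisons are reported per gene/per contrast;
see the methods note for the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loading_mechanics import DoseResponseFit, dose_response_fit

__all__ = [
    "TestResult",
    "relative_expression",
    "expression_table",
    "paired_t",
    "unpaired_t",
    "one_way_anova",
    "fit_ols",
]


@dataclass(frozen=True)
class TestResult:
    """Statistic, two-sided p-value and degrees of freedom of one test."""

    statistic: float
    p_value: float
    df: float
    test_name: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must lie in (0, 1]")


def _clamp_p(p: float) -> float:
    if not np.isfinite(p) or p <= 0:
        return float(np.nextafter(0.0, 1.0))
    return min(float(p), 1.0)


def relative_expression(ct_gene, ct_housekeeping):
    """2^(Ct_housekeeping - Ct_gene); scalar or elementwise on arrays."""
    g = np.asarray(ct_gene, dtype=float)
    h = np.asarray(ct_housekeeping, dtype=float)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(h))):
        raise ValueError("Ct values must be finite")
    out = np.power(2.0, h - g)
    return float(out) if out.ndim == 0 else out


def expression_table(
    ct_table: pd.DataFrame, housekeeping_gene: str = "TBP"
) -> pd.DataFrame:
    """Per-sample 2^dCt expression for every non-housekeeping gene.

    ``ct_table`` columns: sample_id, condition, gene, ct. Every
    (sample, condition) must carry a housekeeping Ct. Returns columns
    sample_id, condition, gene, expression.
    """
    required = {"sample_id", "condition", "gene", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    hk = ct_table[ct_table["gene"] == housekeeping_gene].set_index(
        ["sample_id", "condition"]
    )["ct"]
    genes = ct_table[ct_table["gene"] != housekeeping_gene]
    if genes.empty:
        raise ValueError("no target genes besides the housekeeping gene")
    missing = set(map(tuple, genes[["sample_id", "condition"]].values)) - set(hk.index)
    if missing:
        raise ValueError(f"missing housekeeping Ct for {sorted(missing)[:5]}")
    ref = hk.loc[
        pd.MultiIndex.from_frame(genes[["sample_id", "condition"]])
    ].to_numpy()
    out = genes[["sample_id", "condition", "gene"]].copy()
    out["expression"] = relative_expression(genes["ct"].to_numpy(), ref)
    return out.reset_index(drop=True)


def paired_t(control: np.ndarray, treated: np.ndarray) -> TestResult:
    """Two-sided paired t-test on per-sample differences.

    Degenerate variance is flagged: all-zero differences give t = 0, p = 1;
    constant nonzero differences give an effectively infinite t, p -> 0.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(treated, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("control and treated must be equal-length 1D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = b - a
    df = a.size - 1
    if np.ptp(d) == 0:
        if d[0] == 0:
            return TestResult(0.0, 1.0, df, "paired t", degenerate=True)
        return TestResult(
            float(np.inf) if d[0] > 0 else float(-np.inf),
            _clamp_p(0.0),
            df,
            "paired t",
            degenerate=True,
        )
    t, p = stats.ttest_rel(b, a)
    return TestResult(float(t), _clamp_p(p), df, "paired t")


def unpaired_t(
    group_a: np.ndarray, group_b: np.ndarray, *, welch: bool = True
) -> TestResult:
    """Two-sided two-sample t-test (Welch by default, pooled on request)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, a.size + b.size - 2, "unpaired t", True)
        return TestResult(
            float(np.inf) if b.mean() > a.mean() else float(-np.inf),
            _clamp_p(0.0),
            a.size + b.size - 2,
            "unpaired t",
            True,
        )
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else a.size + b.size - 2
    name = "unpaired t (Welch)" if welch else "unpaired t (pooled)"
    return TestResult(float(res.statistic), _clamp_p(res.pvalue), df, name)


def one_way_anova(*groups: np.ndarray) -> TestResult:
    """One-way ANOVA F test across two or more groups.

    For two groups, F equals the square of the pooled-variance unpaired t.
    All-identical constant groups are degenerate (F = 0, p = 1).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df = float(k - 1)
    if all(np.ptp(a) == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        if np.ptp(means) == 0:
            return TestResult(0.0, 1.0, df, "one-way ANOVA", True)
        return TestResult(float(np.inf), _clamp_p(0.0), df, "one-way ANOVA", True)
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return TestResult(float(np.inf), _clamp_p(0.0), df, "one-way ANOVA", True)
    return TestResult(float(f), _clamp_p(p), df, "one-way ANOVA")


def fit_ols(x: np.ndarray, y: np.ndarray) -> DoseResponseFit:
    """OLS line with R² and slope p-value for general (x, y) tables.

    Same contract as :func:`osteoload.loading_mechanics.dose_response_fit`.
    """
    return dose_response_fit(x, y)
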