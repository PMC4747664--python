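"""Group comparison: one-sided Welch two-sample t-test on per-sample SDIG.

The hypothesis is directional — mean diversity in tumor tissue exceeds
that in non-tumor tissue — so the test is the unequal-variance (Welch)
t-test with the upper-tail alternative:

    t = (mean_T - mean_N) / sqrt(s_T^2/n_T + s_N^2/n_N),

degrees of freedom by Welch–Satterthwaite, p = P(t_dof >= t). Sample
variances use the n-1 denominator. Significance is declared at p < alpha
(default 0.05).

The same two-sample test is applied to paired datasets as well; the pairing
enters only through PPS, not through a paired t-test. This sacrifices some
power when pairing is informative — a deliberate property of this analysis,
kept for comparability across paired and unpaired designs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .diversity import sdig_per_sample
from .errors import DegenerateInputError, ValidationError
from .pair_stats import PairSummary, summarize_dataset

__all__ = [
    "GroupTestResult",
    "welch_one_sided",
    "five_number_summary",
    "dataset_report",
]


@dataclass
class GroupTestResult:
    """Welch test outcome for tumor-vs-normal mean diversity."""

    mean_tumor: float
    mean_normal: float
    t_statistic: float
    dof: float
    p_value: float
    significant: bool
    alpha: float = 0.05


def welch_one_sided(tumor_d, normal_d, alpha: float = 0.05) -> GroupTestResult:
    """Welch two-sample t-test of H1: mean(tumor) > mean(normal).

    Each group needs at least two finite values; if both groups have zero
    variance the statistic is undefined and a
    :class:`~sdig.errors.DegenerateInputError` is raised.
    """
    t = np.asarray(tumor_d, dtype=float)
    n = np.asarray(normal_d, dtype=float)
    for name, arr in (("tumor", t), ("normal", n)):
        if arr.size < 2:
            raise ValidationError(
                f"{name} group needs >= 2 samples for a t-test, got {arr.size}"
            )
        if not np.isfinite(arr).all():
            raise ValidationError(f"{name} group contains non-finite values")
    if np.var(t, ddof=1) == 0.0 and np.var(n, ddof=1) == 0.0:
        raise DegenerateInputError(
            "both groups have zero variance; t statistic undefined"
        )
    res = stats.ttest_ind(t, n, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    return GroupTestResult(
        mean_tumor=float(np.mean(t)),
        mean_normal=float(np.mean(n)),
        t_statistic=float(res.statistic),
        dof=float(res.df),
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def five_number_summary(values) -> dict[str, float]:
    """Minimum, quartiles and maximum of a set of diversity values.

    Quartiles use linear interpolation between order statistics (the common
    default in scientific software).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty set of values")
    q = np.percentile(arr, [0, 25, 50, 75, 100])
    return {
        "min": float(q[0]),
        "q1": float(q[1]),
        "median": float(q[2]),
        "q3": float(q[3]),
        "max": float(q[4]),
    }


def dataset_report(
    matrix: ExpressionMatrix,
    paired: bool,
    dataset_id: str = "dataset",
    alpha: float = 0.05,
) -> dict:
    """Run diversity -> pair statistics -> Welch test for one dataset.

    Returns a dict with the summary row (dataset id, pairing status, PPS,
    Q, T, group means, P value), the per-sample ``diversity`` table, the
    :class:`PairSummary`, the :class:`GroupTestResult` and per-group
    five-number summaries ready for a box plot.
    """
    div = sdig_per_sample(matrix)
    if matrix.pair_id is not None:
        div = div.merge(
            matrix.pair_id.rename("pair_id"),
            left_on="sample_id", right_index=True, how="left",
        )
    summary: PairSummary = summarize_dataset(div, paired=paired)
    test = welch_one_sided(
        div.loc[div["group"] == "tumor", "D"],
        div.loc[div["group"] == "normal", "D"],
        alpha=alpha,
    )
    boxplot = pd.DataFrame(
        [
            {"dataset": dataset_id, "group": grp,
             **five_number_summary(div.loc[div["group"] == grp, "D"])}
            for grp in ("normal", "tumor")
        ]
    )
    row = {
        "dataset": dataset_id,
        "data_structure": "Paired" if paired else "Non-paired",
        "pps_pct": summary.PPS,
        "Q": summary.Q,
        "T_pct": summary.T,
        "mean_normal": test.mean_normal,
        "mean_tumor": test.mean_tumor,
        "p_value": test.p_value,
    }
    return {
        "row": row,
        "diversity": div,
        "pair_summary": summary,
        "test": test,
        "boxplot": boxplot,
    }
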