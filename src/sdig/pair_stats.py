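"""Positive-pair statistics over per-sample diversity values.

Given tumor diversities ``DT_1..DT_M`` and non-tumor diversities
``DN_1..DN_N``, a pair (j, k) of the full M x N cross product is *positive*
when ``DT_j > DN_k`` (strictly; ties are not positive). Three summaries are
derived:

* ``Q`` — the positive pair count;
* ``T`` (PPPN, proportion of positive pair number) — ``100 * Q / (M * N)``
  percent, with complement ``PNPN = 100 - T``;
* ``PPS`` (proportion of positive samples) — for datasets with matched
  tumor/normal pairs only: the percent of matched pairs in which the tumor
  diversity exceeds its own paired normal diversity. PPS is computed on the
  M matched pairs, never on the cross product, and is reported as
  not-available for unpaired designs.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "PairSummary",
    "count_positive_pairs",
    "pppn",
    "pps",
    "summarize_dataset",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention of printed tables.

    Needed because banker's rounding would e.g. take 85.75 to 85.8 at one
    decimal but a printed table may show 86 at zero decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def count_positive_pairs(tumor_d, normal_d) -> int:
    """Q: number of (tumor, normal) pairs with tumor diversity strictly greater.

    Evaluated over the full M x N cross product via a sort +
    ``searchsorted`` sweep, O((M+N) log N); agrees exactly with the
    definitional double loop.
    """
    t = np.asarray(tumor_d, dtype=float)
    n = np.asarray(normal_d, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise ValidationError("diversity values must be finite")
    n_sorted = np.sort(n)
    # for each tumor value, count normals strictly below it
    return int(np.searchsorted(n_sorted, t, side="left").sum())


def pppn(Q: int, M: int, N: int) -> float:
    """T = 100 * Q / (M * N), percent, at full precision."""
    if M < 1 or N < 1:
        raise ValidationError(f"need at least one sample per group (M={M}, N={N})")
    if not 0 <= Q <= M * N:
        raise ValidationError(f"Q={Q} outside [0, M*N={M * N}]")
    return 100.0 * Q / (M * N)


def pps(tumor_d: pd.Series, normal_d: pd.Series) -> float:
    """Percent of matched pairs whose tumor diversity strictly exceeds the
    paired normal diversity.

    Both series are indexed by pair id and must cover the same pairs.
    """
    if len(tumor_d) == 0:
        raise ValidationError("no matched pairs supplied")
    if set(tumor_d.index) != set(normal_d.index):
        raise ValidationError("tumor and normal pair ids do not match")
    normal_aligned = normal_d.loc[tumor_d.index]
    wins = int((tumor_d.to_numpy() > normal_aligned.to_numpy()).sum())
    return 100.0 * wins / len(tumor_d)


@dataclass
class PairSummary:
    """Positive-pair summary of one dataset.

    ``PPS`` is None for unpaired designs (reported as NA downstream).
    Invariants: 0 <= Q <= M*N and T + PNPN == 100.
    """

    M: int
    N: int
    Q: int
    T: float
    PNPN: float
    PPS: float | None = None


def summarize_dataset(diversity: pd.DataFrame, paired: bool) -> PairSummary:
    """Build a :class:`PairSummary` from a per-sample diversity table.

    Parameters
    ----------
    diversity
        Output of :func:`sdig.diversity.sdig_per_sample`: columns
        ``sample_id``, ``group``, ``D`` and, for paired datasets, a
        ``pair_id`` column.
    paired
        Whether the dataset has matched tumor/normal pairs; if so PPS is
        computed from ``pair_id``, otherwise PPS is None.
    """
    tumor = diversity[diversity["group"] == "tumor"]
    normal = diversity[diversity["group"] == "normal"]
    if len(tumor) == 0 or len(normal) == 0:
        raise ValidationError(
            "dataset must contain both tumor and normal samples "
            f"(tumor={len(tumor)}, normal={len(normal)})"
        )
    M, N = len(tumor), len(normal)
    Q = count_positive_pairs(tumor["D"], normal["D"])
    T = pppn(Q, M, N)
    pps_value: float | None = None
    if paired:
        if "pair_id" not in diversity.columns:
            raise ValidationError("paired dataset requires a pair_id column")
        pps_value = pps(
            tumor.set_index("pair_id")["D"], normal.set_index("pair_id")["D"]
        )
    return PairSummary(M=M, N=N, Q=Q, T=T, PNPN=100.0 - T, PPS=pps_value)
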