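"""Spot-level and matrix-level preprocessing for two-channel arrays,
log-scale matrices and FPKM matrices.

The two-channel stages follow the conventional order for cDNA arrays:

1. remove flagged spots (flag -50 no signal, -100 poor signal);
2. keep spots whose uncorrected intensity in *each* channel exceeds 1.5x
   the local background median ("well-measured" rule);
3. background-correct both channels, ``chNd_mean = chNi_mean - chNb_median``;
4. turn corrected intensities into per-gene expression values, either as
   the two channels directly (tumor / normal hybridized as channel 1 / 2)
   or as sample/reference ratios when one channel is a common reference;
5. across the assembled dataset, drop genes with fewer than two observed
   replicates, then impute the remaining missing cells so every sample has
   a complete vector.

Negative background-corrected intensities are never clamped: in
paired-channel mode they become missing values, in ratio mode a
non-positive *reference* drops the spot — a negative expression value has
no meaning as a proportion of total expression.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_spot_table
from .errors import ConfigError, DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# spot-level stages

def background_correct(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract the median background from each channel's mean intensity.

    Adds ``ch1d_mean = ch1i_mean - ch1b_median`` and the channel-2
    analogue. No filtering happens here; negative corrected values are
    retained for downstream stages to handle.
    """
    validate_spot_table(spots)
    out = spots.copy()
    out["ch1d_mean"] = out["ch1i_mean"] - out["ch1b_median"]
    out["ch2d_mean"] = out["ch2i_mean"] - out["ch2b_median"]
    return out


def flag_filter(spots: pd.DataFrame) -> pd.DataFrame:
    """Keep only flag == 0 spots; flagged spots (-50, -100) are removed."""
    validate_spot_table(spots)
    kept = spots[spots["flag"] == 0].copy()
    n_removed = len(spots) - len(kept)
    logger.info("flag_filter: kept %d, removed %d of %d spots",
                len(kept), n_removed, len(spots))
    if len(kept) == 0 and len(spots) > 0:
        logger.warning("flag_filter: all %d spots were flagged", len(spots))
    return kept


def well_measured_filter(spots: pd.DataFrame, factor: float = 1.5,
                         strict: bool = True) -> pd.DataFrame:
    """Keep spots whose intensity beats ``factor`` x background in both channels.

    The rule compares the *uncorrected* channel intensity against
    ``factor * background_median``; with ``strict`` (the default) a spot
    sitting exactly on the boundary is removed.
    """
    validate_spot_table(spots)
    op = np.greater if strict else np.greater_equal
    ok = op(spots["ch1i_mean"], factor * spots["ch1b_median"]) & op(
        spots["ch2i_mean"], factor * spots["ch2b_median"]
    )
    kept = spots[ok].copy()
    logger.info("well_measured_filter: kept %d, removed %d of %d spots",
                len(kept), len(spots) - len(kept), len(spots))
    return kept


def _collapse_duplicates(series: pd.Series) -> pd.Series:
    # duplicate spots for one gene within a sample are averaged post-filter
    return series.groupby(level=0).mean()


def ratio_expression(corrected: pd.DataFrame, reference_channel: int = 1) -> pd.Series:
    """Per-gene sample/reference expression ratios from corrected spots.

    With channel 1 as reference the expression value is
    ``ch2d_mean / ch1d_mean``. Spots whose reference-channel corrected
    intensity is <= 0 are dropped (the ratio is undefined) and counted in
    the log; duplicate spots per gene are averaged.
    """
    if reference_channel not in (1, 2):
        raise ConfigError(f"reference_channel must be 1 or 2, got {reference_channel}")
    ref = corrected[f"ch{reference_channel}d_mean"]
    sample = corrected[f"ch{3 - reference_channel}d_mean"]
    usable = ref > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("ratio_expression: dropped %d of %d spots with "
                    "non-positive reference intensity", n_dropped, len(corrected))
    if not usable.any():
        raise DegenerateInputError(
            "ratio_expression: no spot has positive reference intensity"
        )
    values = (sample[usable] / ref[usable])
    values.index = corrected.loc[usable, "gene_id"]
    return _collapse_duplicates(values)


def channel_expression(
    corrected: pd.DataFrame, channel_groups: dict[int, str]
) -> pd.DataFrame:
    """Per-gene expression for the two co-hybridized samples.

    ``channel_groups`` maps channel number to the group of the sample
    hybridized on it, e.g. ``{1: "tumor", 2: "normal"}``. Corrected channel
    intensities become the expression values; negative corrected values are
    set missing (NaN). Returns a two-column genes x {group} frame.
    """
    if set(channel_groups.keys()) != {1, 2} or None in channel_groups.values():
        raise ConfigError(
            f"channel_groups must assign both channels, got {channel_groups}"
        )
    columns = {}
    for channel, group in channel_groups.items():
        vals = corrected[f"ch{channel}d_mean"].astype(float).copy()
        vals[vals < 0] = np.nan
        vals.index = corrected["gene_id"]
        columns[group] = _collapse_duplicates(vals)
    return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# matrix-level stages

def replicate_filter(matrix: ExpressionMatrix, min_replicates: int = 2) -> ExpressionMatrix:
    """Drop genes observed in fewer than ``min_replicates`` samples.

    A gene's replicate count is its number of non-missing measurements
    across all samples of the dataset. The removed fraction is logged
    (comparable to a per-dataset "data removed" percentage).
    """
    counts = matrix.values.notna().sum(axis=1)
    keep = counts >= min_replicates
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info(
            "replicate_filter: removed %d of %d genes (%.2f%%) with < %d replicates",
            n_removed, matrix.n_genes, 100 * n_removed / matrix.n_genes,
            min_replicates,
        )
    if not keep.any():
        raise DegenerateInputError("replicate_filter removed every gene")
    out = matrix.copy()
    out.values = out.values.loc[keep]
    return out


def impute_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Fill missing cells with the gene's observed within-group mean.

    A missing cell takes the mean of the gene's observed values in the same
    group when at least one exists, and the gene's overall observed mean
    otherwise. Requires group labels; the result has no missing values.
    Deterministic and parameter-free; run after :func:`replicate_filter` so
    every gene has at least two observations somewhere.
    """
    if matrix.group is None:
        raise ValidationError("impute_missing requires group labels")
    if not matrix.has_missing():
        return matrix.copy()
    out = matrix.copy()
    vals = out.values
    overall = vals.mean(axis=1, skipna=True)
    if overall.isna().any():
        bad = overall.index[overall.isna()].tolist()
        raise DegenerateInputError(
            f"gene(s) {bad} have no observed values; run replicate_filter first"
        )
    for group in out.group.unique():
        cols = [s for s in out.sample_ids if out.group[s] == group]
        block = vals[cols]
        group_mean = block.mean(axis=1, skipna=True).fillna(overall)
        vals[cols] = block.apply(lambda col: col.fillna(group_mean))
    out.values = vals
    return out


def inverse_log_transform(matrix: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Map each value v to ``base ** v``, undoing a log transform.

    Missing cells stay missing. A value that overflows to infinity is an
    error (reported with its coordinates), since downstream proportions
    would be meaningless.
    """
    out = matrix.copy()
    with np.errstate(over="ignore"):
        arr = np.power(float(base), out.values.to_numpy(dtype=float))
    if np.isinf(arr).any():
        r, c = np.argwhere(np.isinf(arr))[0]
        raise ValidationError(
            f"inverse log transform overflows at gene "
            f"{out.gene_ids[r]!r}, sample {out.sample_ids[c]!r}"
        )
    out.values = pd.DataFrame(arr, index=out.gene_ids, columns=out.sample_ids)
    out.scale_hint = None
    return out
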