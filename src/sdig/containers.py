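"""In-memory containers shared across the pipeline.

The two central objects are

* a *spot table*: a :class:`pandas.DataFrame` with one row per microarray
  spot and the canonical columns ``spot_id, gene_id, ch1i_mean, ch1b_median,
  ch2i_mean, ch2b_median, flag`` (two-channel cDNA arrays: ``ch*i_mean`` is
  the uncorrected mean pixel intensity of a channel, ``ch*b_median`` the
  median background pixel intensity, ``flag`` the spot-quality code);
* :class:`ExpressionMatrix`: a non-negative genes x samples matrix with
  per-sample group labels (tumor / normal) and optional tumor-normal pairing.

Missing expression values are represented by NaN, never by 0 — zero is a
legal expression value.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical spot-table column order.
SPOT_COLUMNS = [
    "spot_id",
    "gene_id",
    "ch1i_mean",
    "ch1b_median",
    "ch2i_mean",
    "ch2b_median",
    "flag",
]

#: Spot-quality flags: 0 good signal, -50 no signal, -100 poor signal.
VALID_FLAGS = frozenset({0, -50, -100})

#: Allowed sample group labels.
GROUPS = ("tumor", "normal")

_INTENSITY_COLUMNS = ["ch1i_mean", "ch1b_median", "ch2i_mean", "ch2b_median"]


def validate_spot_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Check spot-table invariants and return the table unchanged.

    Raises
    ------
    ValidationError
        If a canonical column is absent, an intensity/background value is
        negative or non-finite, or a flag is outside {0, -50, -100}.
    """
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValidationError(f"spot table missing columns: {missing}")
    vals = spots[_INTENSITY_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("spot table contains non-finite intensity values")
    if (vals < 0).any():
        raise ValidationError("spot table contains negative intensity values")
    bad = set(spots["flag"].unique()) - VALID_FLAGS
    if bad:
        raise ValidationError(
            f"invalid flag values {sorted(bad)}; allowed: {sorted(VALID_FLAGS)}"
        )
    return spots


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample. Entries are
        non-negative expression values; NaN marks a missing measurement.
    group
        Per-sample label, ``"tumor"`` or ``"normal"``, indexed like the
        columns of ``values``. May be None for group-agnostic matrices
        (e.g. fresh off a series-matrix file).
    pair_id
        Optional per-sample identifier linking a tumor sample to its matched
        normal; NaN where a sample is unpaired.
    scale_hint
        ``"log2"`` (or another base tag) when the source file annotates the
        values as log-scale, so callers know to inverse-transform.
    """

    values: pd.DataFrame
    group: pd.Series | None = None
    pair_id: pd.Series | None = None
    scale_hint: str | None = None
    source_dataset: str = ""

    # -- conveniences -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, group: str) -> list[str]:
        if self.group is None:
            raise ValidationError("matrix carries no group labels")
        return [s for s in self.sample_ids if self.group[s] == group]

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            group=None if self.group is None else self.group.copy(),
            pair_id=None if self.pair_id is None else self.pair_id.copy(),
        )

    # -- invariants ---------------------------------------------------
    def validate(self, require_groups: bool = True) -> "ExpressionMatrix":
        """Check the container invariants; returns self for chaining.

        Non-missing values must be finite and >= 0; when group labels are
        present every sample must carry one of the allowed labels and every
        pair id must occur exactly once per group.
        """
        if self.n_genes < 1:
            raise ValidationError("expression matrix has no genes")
        vals = self.values.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        nan = np.isnan(vals)
        if not (finite | nan).all():
            raise ValidationError("expression matrix contains infinities")
        # log-scale values are legitimately negative until inverse-transformed
        if self.scale_hint is None and np.nanmin(vals, initial=0.0) < 0:
            r, c = np.argwhere(finite & (vals < 0))[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        if self.group is None:
            if require_groups:
                raise ValidationError("group labels required but absent")
            return self
        if list(self.group.index) != list(self.sample_ids):
            raise ValidationError("group labels do not match sample columns")
        bad = sorted(set(self.group) - set(GROUPS))
        if bad:
            raise ValidationError(
                f"unrecognized group label(s) {bad}; allowed labels: {list(GROUPS)}"
            )
        if self.pair_id is not None:
            pid = self.pair_id.dropna()
            for pair, members in pid.groupby(pid).groups.items():
                labels = sorted(self.group[list(members)])
                if labels != ["normal", "tumor"]:
                    raise ValidationError(
                        f"pair_id {pair!r} must occur exactly once in each "
                        f"group; found groups {labels}"
                    )
        return self

    def has_missing(self) -> bool:
        return bool(self.values.isna().any().any())


@dataclass
class SampleMetadata:
    """Descriptor for one sample: id, group, optional pairing, provenance."""

    sample_id: str
    group: str
    pair_id: str | None = None
    source_dataset: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unrecognized group label {self.group!r}; allowed: {list(GROUPS)}"
            )
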