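"""End-to-end orchestration: read -> preprocess -> diversity -> pair
statistics -> Welch test -> summary/boxplot tables.

A :class:`PipelineConfig` names the dataset, the preprocessing ``mode`` and
the input files. Modes:

``precomputed-matrix``
    Matrix + metadata TSV, used as-is (after replicate filter / imputation
    when missing values are present).
``fpkm``
    Same as ``precomputed-matrix``; FPKM values pass through untransformed.
``log-inverse``
    Matrix on log scale; values are inverse-transformed (``base ** v``,
    default base 2) before diversity.
``paired-channels``
    One two-channel spot table per hybridization, tumor and normal
    co-hybridized as the two channels; each table yields one tumor and one
    matched normal sample.
``reference-ratio``
    One spot table per hybridization with a common reference on one
    channel; expression is the sample/reference ratio and each table yields
    one sample whose group is given per file.

All randomness lives in :mod:`sdig.synthetic`; a pipeline run is
deterministic in its inputs, and every filter logs
``kept + removed = total``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from . import preprocess as pp
from .containers import ExpressionMatrix
from .errors import ConfigError
from .inference import dataset_report
from .study import HCC_DATASETS

logger = logging.getLogger(__name__)

MODES = (
    "precomputed-matrix",
    "fpkm",
    "log-inverse",
    "paired-channels",
    "reference-ratio",
)


@dataclass
class SpotInput:
    """One spot-table file and how to interpret it."""

    path: str
    #: paired-channels mode: id linking the tumor/normal pair from this array
    pair_id: str | None = None
    #: reference-ratio mode: sample id and its group label
    sample_id: str | None = None
    group: str | None = None


@dataclass
class PipelineConfig:
    dataset_id: str
    mode: str
    paired: bool = False
    matrix_path: str | None = None
    metadata_path: str | None = None
    spot_tables: list[SpotInput] = field(default_factory=list)
    #: paired-channels: which group sits on which channel
    channel_groups: dict[int, str] = field(
        default_factory=lambda: {1: "tumor", 2: "normal"}
    )
    #: reference-ratio: the reference channel number
    reference_channel: int = 1
    background_factor: float = 1.5
    min_replicates: int = 2
    log_base: float = 2.0
    alpha: float = 0.05
    dialect: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")

    def require_inputs(self) -> None:
        """Fail fast if the mode's input files are not configured.

        Deferred from construction so presets can carry mode/pairing with
        paths supplied later.
        """
        matrix_modes = {"precomputed-matrix", "fpkm", "log-inverse"}
        if self.mode in matrix_modes and not self.matrix_path:
            raise ConfigError(f"mode {self.mode!r} requires matrix_path")
        if self.mode not in matrix_modes and not self.spot_tables:
            raise ConfigError(f"mode {self.mode!r} requires spot_tables")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        spots = [SpotInput(**s) for s in raw.pop("spot_tables", [])]
        cg = raw.pop("channel_groups", None)
        cfg = cls(spot_tables=spots, **raw)
        if cg is not None:
            cfg.channel_groups = {int(k): v for k, v in cg.items()}
        return cfg


#: Per-accession preset configs for the six datasets of the source study
#: (paths left to the caller). Modes follow each dataset's platform: three
#: paired-channel microarrays, one reference-ratio microarray, one
#: log-scale aCGH set, one FPKM sequencing set.
PRESETS: dict[str, PipelineConfig] = {
    ds.accession: PipelineConfig(
        dataset_id=ds.accession, mode=ds.mode, paired=ds.paired
    )
    for ds in HCC_DATASETS
}


# ---------------------------------------------------------------------------

def _assemble_two_channel(config: PipelineConfig) -> ExpressionMatrix:
    """Spot tables -> genes x samples matrix, via the filter cascade."""
    columns: dict[str, pd.Series] = {}
    groups: dict[str, str] = {}
    pairs: dict[str, str | None] = {}
    for i, spot_input in enumerate(config.spot_tables):
        table = sio.read_two_channel_table(spot_input.path, dialect=config.dialect)
        table = pp.flag_filter(table)
        table = pp.well_measured_filter(table, factor=config.background_factor)
        corrected = pp.background_correct(table)
        if config.mode == "paired-channels":
            pair = spot_input.pair_id or f"pair{i + 1:03d}"
            both = pp.channel_expression(corrected, config.channel_groups)
            for group in both.columns:
                sid = f"{pair}_{group}"
                columns[sid] = both[group]
                groups[sid] = group
                pairs[sid] = pair
        else:  # reference-ratio
            if spot_input.group is None:
                raise ConfigError(
                    f"reference-ratio input {spot_input.path!r} needs a group label"
                )
            sid = spot_input.sample_id or f"sample{i + 1:03d}"
            columns[sid] = pp.ratio_expression(
                corrected, reference_channel=config.reference_channel
            )
            groups[sid] = spot_input.group
            pairs[sid] = None
    values = pd.DataFrame(columns)
    group = pd.Series({s: groups[s] for s in values.columns})
    pair_id = None
    if config.mode == "paired-channels":
        pair_id = pd.Series({s: pairs[s] for s in values.columns})
    return ExpressionMatrix(
        values=values, group=group, pair_id=pair_id,
        source_dataset=config.dataset_id,
    )


def prepare_matrix(config: PipelineConfig) -> ExpressionMatrix:
    """Run the mode-appropriate preprocessing and return a complete matrix."""
    config.require_inputs()
    if config.mode in ("precomputed-matrix", "fpkm"):
        matrix = sio.read_expression_matrix(config.matrix_path, config.metadata_path)
    elif config.mode == "log-inverse":
        matrix = sio.read_expression_matrix(config.matrix_path, config.metadata_path)
        matrix = pp.inverse_log_transform(matrix, base=config.log_base)
    else:
        matrix = _assemble_two_channel(config).validate()
    n_before = matrix.n_genes
    if matrix.has_missing():
        matrix = pp.replicate_filter(matrix, min_replicates=config.min_replicates)
        matrix = pp.impute_missing(matrix)
    logger.info(
        "%s: %d of %d genes retained across %d samples",
        config.dataset_id, matrix.n_genes, n_before, matrix.n_samples,
    )
    return matrix


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Full per-dataset analysis; optionally writes TSV outputs.

    Returns the :func:`sdig.inference.dataset_report` dict. When
    ``out_dir`` is given, writes ``diversity.tsv`` (per-sample SDIG),
    ``summary.tsv`` (one summary row plus the mean-T row) and
    ``boxplot.tsv`` (per-group five-number summaries).
    """
    matrix = prepare_matrix(config)
    report = dataset_report(
        matrix, paired=config.paired, dataset_id=config.dataset_id,
        alpha=config.alpha,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["diversity"].to_csv(out / "diversity.tsv", sep="\t", index=False)
        sio.write_summary_table([report["row"]], out / "summary.tsv")
        report["boxplot"].to_csv(out / "boxplot.tsv", sep="\t", index=False)
    return report
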