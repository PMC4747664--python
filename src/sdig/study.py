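"""Published descriptors of the six GEO hepatocellular-carcinoma datasets.

These are the inputs a re-analysis starts from: per dataset the GEO
accession, platform, preprocessing mode, sample counts (M tumor, N
non-tumor/normal), whether tumor and normal samples are matched, and the
published positive-pair count Q. ``t_decimals`` records the precision at
which the source table displays T for that dataset (four datasets print
whole percents, two print one decimal), so displayed values can be
compared like for like.
"""
from __future__ import annotations

from dataclasses import dataclass

from .pair_stats import pppn, round_half_up

__all__ = ["StudyDataset", "HCC_DATASETS", "displayed_pppn"]


@dataclass(frozen=True)
class StudyDataset:
    accession: str
    platform: str
    mode: str  # preprocessing mode understood by sdig.pipeline
    paired: bool
    n_tumor: int  # M
    n_normal: int  # N
    published_Q: int
    t_decimals: int  # decimals at which the source displays T


HCC_DATASETS: tuple[StudyDataset, ...] = (
    StudyDataset("GSE5093", "microarray", "paired-channels", True, 20, 20, 343, 0),
    StudyDataset("GSE3500", "microarray", "reference-ratio", False, 105, 76, 5150, 0),
    StudyDataset("GSE4024", "microarray", "paired-channels", True, 98, 98, 5283, 0),
    StudyDataset("GSE1898", "microarray", "paired-channels", True, 182, 182, 19543, 0),
    StudyDataset("GSE65484", "aCGH", "log-inverse", True, 14, 14, 146, 1),
    StudyDataset("GSE65485", "NGS", "fpkm", False, 50, 5, 238, 1),
)


def displayed_pppn(ds: StudyDataset, Q: int | None = None) -> float:
    """T = 100*Q/(M*N) rounded half-up at the dataset's display precision.

    ``Q`` defaults to the published positive-pair count.
    """
    q = ds.published_Q if Q is None else Q
    return round_half_up(pppn(q, ds.n_tumor, ds.n_normal), ds.t_decimals)
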