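"""Synthetic data with the statistical structure the analysis assumes.

Evenness is modeled with a symmetric Dirichlet on the simplex: a sample's
expression proportions are a Dirichlet(alpha, ..., alpha) draw over S
genes. Larger alpha means more even proportions and therefore higher
Gini–Simpson diversity; the expectation is available in closed form,

    E[sum p_i^2] = (alpha + 1) / (S * alpha + 1)
    E[D] = 1 - (alpha + 1) / (S * alpha + 1),

which anchors Monte-Carlo checks. Tumor samples are drawn with a larger
concentration than normals to emulate the tumor-more-even pattern; equal
concentrations give an exchangeable null.

Expression matrices scale the proportions by a global intensity and a
per-sample lognormal depth factor (diversity must be invariant to both),
and missing cells are injected at a configurable rate. Two-channel spot
tables are built as background + signal with quality flags, and the
generator records exactly which spots survive the flag and well-measured
rules — an oracle for the preprocessing filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SPOT_COLUMNS, ExpressionMatrix
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "expected_sdig",
    "simulate_proportions",
    "simulate_expression_matrix",
    "simulate_two_channel_table",
]


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults encode the headline study condition
    (tumor markedly more even than normal, 20 + 20 samples, 1000 genes).

    ``flag_rates`` are the probabilities of spot flags {0, -50, -100};
    ``background_level`` sets the scale of both the background medians and
    the exponential signal above them in spot tables (so the 1.5x
    well-measured rule fires for a realistic fraction of spots);
    ``intensity_scale`` is the total expression a matrix sample is scaled
    to and ``depth_sigma`` the sigma of its lognormal depth factor.
    """

    S: int = 1000
    n_tumor: int = 20
    n_normal: int = 20
    alpha_tumor: float = 2.0
    alpha_normal: float = 0.5
    intensity_scale: float = 1000.0
    flag_rates: dict[int, float] = field(
        default_factory=lambda: {0: 0.90, -50: 0.05, -100: 0.05}
    )
    background_level: float = 100.0
    missing_rate: float = 0.05
    depth_sigma: float = 0.3
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValidationError(f"need S >= 2 genes, got {self.S}")
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValidationError("need at least one sample per group")
        if self.alpha_tumor <= 0 or self.alpha_normal <= 0:
            raise ValidationError("Dirichlet concentrations must be positive")
        if set(self.flag_rates) - {0, -50, -100}:
            raise ValidationError(f"invalid flag keys in {self.flag_rates}")
        rates = np.array(list(self.flag_rates.values()), dtype=float)
        if (rates < 0).any() or abs(rates.sum() - 1.0) > 1e-9:
            raise ValidationError("flag_rates must be probabilities summing to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError(f"missing_rate {self.missing_rate} outside [0, 1)")
        if self.paired and self.n_tumor != self.n_normal:
            raise ValidationError("paired design needs n_tumor == n_normal")


def expected_sdig(S: int, alpha: float) -> float:
    """Closed-form E[D] for a symmetric Dirichlet(alpha) over S genes."""
    return 1.0 - (alpha + 1.0) / (S * alpha + 1.0)


def simulate_proportions(S: int, alpha: float, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """n draws from a symmetric Dirichlet over S genes; rows sum to 1."""
    if S < 2 or n < 1 or alpha <= 0:
        raise ValidationError(
            f"invalid parameters S={S}, alpha={alpha}, n={n}"
        )
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(S, float(alpha)), size=n)


def simulate_expression_matrix(config: SimulationConfig) -> tuple[ExpressionMatrix, dict]:
    """Expression matrix with known evenness ground truth.

    Per sample: Dirichlet proportions (group-specific alpha) scaled by
    ``intensity_scale`` times a lognormal depth factor, then missing cells
    injected completely at random at ``missing_rate``. Returns the matrix
    (groups and, if configured, tumor-normal pairing attached) plus a
    ground-truth dict with the per-group expected diversities.
    """
    rng = np.random.default_rng(config.seed)
    S = config.S
    blocks, groups, sample_ids, pair_ids = [], [], [], []
    for group, n, alpha in (
        ("tumor", config.n_tumor, config.alpha_tumor),
        ("normal", config.n_normal, config.alpha_normal),
    ):
        p = rng.dirichlet(np.full(S, float(alpha)), size=n)
        depth = rng.lognormal(mean=0.0, sigma=config.depth_sigma, size=n)
        blocks.append(p * (config.intensity_scale * depth)[:, None])
        groups += [group] * n
        sample_ids += [f"{group[0].upper()}{i + 1:03d}" for i in range(n)]
        pair_ids += [f"P{i + 1:03d}" for i in range(n)] if config.paired else [None] * n
    values = np.concatenate(blocks, axis=0).T  # genes x samples
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.copy()
        values[mask] = np.nan
    gene_ids = [f"g{i + 1:05d}" for i in range(S)]
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    group = pd.Series(groups, index=sample_ids, name="group")
    pair = (
        pd.Series(pair_ids, index=sample_ids, name="pair_id")
        if config.paired else None
    )
    matrix = ExpressionMatrix(
        values=frame, group=group, pair_id=pair, source_dataset="synthetic"
    ).validate()
    truth = {
        "expected_sdig_tumor": expected_sdig(S, config.alpha_tumor),
        "expected_sdig_normal": expected_sdig(S, config.alpha_normal),
        "alpha_tumor": config.alpha_tumor,
        "alpha_normal": config.alpha_normal,
        "S": S,
    }
    return matrix, truth


def simulate_two_channel_table(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-channel spot table plus the ground-truth survivor mask.

    One spot per gene. Background medians are gamma-distributed around
    ``background_level``; each channel's intensity is background plus an
    exponential signal on the background scale, so a realistic fraction of
    spots fails the 1.5x well-measured rule in each channel. Flags are
    drawn from ``flag_rates``. The returned boolean mask marks the spots that survive
    both the flag rule (flag == 0) and the well-measured rule
    (intensity > 1.5x background in both channels), recorded by the
    generator itself as an oracle for the preprocessing filters.
    """
    rng = np.random.default_rng(config.seed)
    n = config.S
    bg1 = rng.gamma(shape=20.0, scale=config.background_level / 20.0, size=n)
    bg2 = rng.gamma(shape=20.0, scale=config.background_level / 20.0, size=n)
    # exponential signal at the background scale: ~exp(-0.5) of spots clear
    # the 1.5x rule per channel, so both filter outcomes are well populated
    sig1 = rng.exponential(scale=config.background_level, size=n)
    sig2 = rng.exponential(scale=config.background_level, size=n)
    flags = rng.choice(
        np.array(list(config.flag_rates.keys()), dtype=int),
        size=n,
        p=np.array(list(config.flag_rates.values()), dtype=float),
    )
    table = pd.DataFrame(
        {
            "spot_id": [f"s{i + 1:05d}" for i in range(n)],
            "gene_id": [f"g{i + 1:05d}" for i in range(n)],
            "ch1i_mean": bg1 + sig1,
            "ch1b_median": bg1,
            "ch2i_mean": bg2 + sig2,
            "ch2b_median": bg2,
            "flag": flags,
        }
    )[SPOT_COLUMNS]
    survivors = (
        (flags == 0)
        & (table["ch1i_mean"].to_numpy() > 1.5 * bg1)
        & (table["ch2i_mean"].to_numpy() > 1.5 * bg2)
    )
    return table, survivors
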