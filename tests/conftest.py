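import numpy as np
import pandas as pd
import pytest

from sdig.containers import ExpressionMatrix

SPOT_HEADER = "ID\tGENE_ID\tCH1I_MEAN\tCH1B_MEDIAN\tCH2I_MEAN\tCH2B_MEDIAN\tFLAG"


def write_spot_file(path, rows):
    """rows: iterable of (spot, gene, ch1i, ch1b, ch2i, ch2b, flag)."""
    lines = [SPOT_HEADER] + ["\t".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def spot_file(tmp_path):
    return write_spot_file(
        tmp_path / "spots.tsv",
        [
            ("s1", "g1", 100.0, 20.0, 60.0, 30.0, 0),
            ("s2", "g2", 25.0, 20.0, 100.0, 20.0, -50),
            ("s3", "g3", 50.0, 10.0, 80.0, 10.0, -100),
        ],
    )


def make_matrix(values, groups, pair_ids=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = [f"s{i + 1}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    group = pd.Series(groups, index=sample_ids)
    pair = pd.Series(pair_ids, index=sample_ids) if pair_ids is not None else None
    return ExpressionMatrix(values=frame, group=group, pair_id=pair)


@pytest.fixture
def small_matrix():
    # two tumor, two normal samples over four genes, no missing values
    return make_matrix(
        [[1, 3, 9, 3], [2, 3, 1, 3], [3, 3, 1, 3], [4, 3, 1, 3]],
        ["tumor", "tumor", "normal", "normal"],
    )
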