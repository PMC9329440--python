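import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from prsconcord.io import CohortTable, DosagePanel, ScoreFile, ScoringVariant

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(rows, dosages, sample_ids=None, true_maf=None):
    """Build a small DosagePanel from (id, chrom, pos, a1, a2, info) tuples."""
    dosages = np.asarray(dosages, dtype=float)
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(dosages.shape[1] if dosages.size else 0)]
    meta = pd.DataFrame(
        rows, columns=["variant_id", "chromosome", "position", "allele1", "allele2", "info_score"]
    )
    return DosagePanel(sample_ids=sample_ids, variants=meta, dosages=dosages, true_maf=true_maf)


def make_score(entries, score_id="S", trait="t"):
    """Build a ScoreFile from (id, chrom, pos, effect, other, weight) tuples."""
    return ScoreFile(
        score_id,
        trait,
        [ScoringVariant(*e) for e in entries],
    )


def make_cohort(n, outcome=None, seed=0, flags=None):
    rng = np.random.default_rng(seed)
    if outcome is None:
        outcome = rng.integers(0, 2, size=n)
    df = pd.DataFrame(
        {
            "sample_id": [f"s{j}" for j in range(n)],
            "outcome": np.asarray(outcome, dtype=int),
            "age": rng.uniform(40, 70, n),
            "sex": rng.choice(["female", "male"], n),
            "array": rng.choice(["axiom", "bileve"], n, p=[0.9, 0.1]),
            **{f"pc{k}": rng.standard_normal(n) for k in range(1, 6)},
            "qc_flags": flags if flags is not None else [""] * n,
        }
    )
    return CohortTable(df)


@pytest.fixture
def tiny_panel():
    """Two variants x three individuals."""
    return make_panel(
        [
            ("rs1", "1", 100, "A", "G", 0.9),
            ("rs2", "1", 200, "C", "T", 0.8),
        ],
        [[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
    )


# ---------------------------------------------------------------------------
# the published 7x7 cross-classification (breast cancer, N = 171,490):
# rows = bins of the earlier score, columns = bins of the newer score

TABLE3_COUNTS = np.array(
    [
        [345, 1140, 176, 44, 9, 1, 0],
        [1117, 15409, 8818, 4696, 2052, 490, 1],
        [198, 8788, 9989, 8053, 5210, 2051, 9],
        [43, 4648, 7998, 8908, 8050, 4607, 44],
        [11, 2098, 5296, 7988, 10047, 8688, 170],
        [1, 497, 2006, 4574, 8736, 15674, 1095],
        [0, 3, 15, 35, 194, 1072, 396],
    ],
    dtype=int,
)

# printed cell percentages, in printed order (share of row bin, share of
# column bin, share of total), one decimal
TABLE3_ROW_PCT = np.array(
    [
        [20.1, 66.5, 10.3, 2.6, 0.5, 0.1, 0.0],
        [3.4, 47.3, 27.1, 14.4, 6.3, 1.5, 0.0],
        [0.6, 25.6, 29.1, 23.5, 15.2, 6.0, 0.0],
        [0.1, 13.6, 23.3, 26.0, 23.5, 13.4, 0.1],
        [0.0, 6.1, 15.4, 23.3, 29.3, 25.3, 0.5],
        [0.0, 1.5, 6.2, 14.0, 26.8, 48.1, 3.4],
        [0.0, 0.2, 0.9, 2.0, 11.3, 62.5, 23.1],
    ]
)
TABLE3_COL_PCT = np.array(
    [
        [20.1, 3.5, 0.5, 0.1, 0.0, 0.0, 0.0],
        [65.1, 47.3, 25.7, 13.7, 6.0, 1.5, 0.1],
        [11.5, 27.0, 29.1, 23.5, 15.2, 6.3, 0.5],
        [2.5, 14.3, 23.3, 26.0, 23.5, 14.1, 2.6],
        [0.6, 6.4, 15.4, 23.3, 29.3, 26.7, 9.9],
        [0.1, 1.5, 5.8, 13.3, 25.5, 48.1, 63.8],
        [0.0, 0.0, 0.0, 0.1, 0.6, 3.3, 23.1],
    ]
)
TABLE3_CELL_PCT = np.array(
    [
        [0.2, 0.7, 0.1, 0.0, 0.0, 0.0, 0.0],
        [0.7, 9.0, 5.1, 2.7, 1.2, 0.3, 0.0],
        [0.1, 5.1, 5.8, 4.7, 3.0, 1.2, 0.0],
        [0.0, 2.7, 4.7, 5.2, 4.7, 2.7, 0.0],
        [0.0, 1.2, 3.1, 4.7, 5.9, 5.1, 0.1],
        [0.0, 0.3, 1.2, 2.7, 5.1, 9.1, 0.6],
        [0.0, 0.0, 0.0, 0.0, 0.1, 0.6, 0.2],
    ]
)


@pytest.fixture
def table3_counts():
    return TABLE3_COUNTS.copy()
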