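"""Per-individual PRS computation, standardization, percentiles and risk bins.

The score of individual j is the weighted allele-dosage sum
``PRS_j = sum_i beta_i * dosage_ij`` over the variants retained after QC and
harmonization.  Percentile ranks use the symmetric convention
``100 * (rank - 0.5) / N`` with average ranks on ties, so the "top 1%" bin
holds the expected N/100 individuals.  The seven risk bins are the
percentile categories <1, 1-20, 20-40, 40-60, 60-80, 80-99, >=99; higher
score means higher predicted risk for both scores by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .errors import ValidationError
from .io import DosagePanel, ScoreFile

BIN_LABELS = ("<1", "1-20", "20-40", "40-60", "60-80", "80-99", ">=99")
#: inner percentile cut points; bins are half-open [lo, hi), top bin closed above
BIN_EDGES = (1.0, 20.0, 40.0, 60.0, 80.0, 99.0)
#: expected occupancy proportions of the seven bins, in percent
BIN_EXPECTED_PCT = (1, 19, 20, 20, 20, 19, 1)


@dataclass
class ScoreVector:
    """Per-individual values of one PRS, raw and derived."""

    sample_ids: list[str]
    raw: np.ndarray
    n_variants_used: int
    score_id: str = ""
    standardized: np.ndarray | None = None
    percentile: np.ndarray | None = None
    bin: np.ndarray | None = None  # labels from BIN_LABELS

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.sample_ids),):
            raise ValidationError("raw score length does not match sample ids")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def bin_index(self) -> np.ndarray:
        if self.bin is None:
            raise ValidationError("bins not assigned")
        lookup = {lab: i for i, lab in enumerate(BIN_LABELS)}
        return np.array([lookup[b] for b in self.bin], dtype=int)


def compute_prs(score: ScoreFile, panel: DosagePanel) -> ScoreVector:
    """Weighted dosage sum per individual, in scoring-file variant order.

    Expects a score already QC'd and harmonized against the panel; variants
    flagged ``flip_dosage`` contribute ``beta * (2 - d)``.
    """
    if len(score) == 0:
        raise ValidationError(f"score {score.score_id}: no variants retained, PRS undefined")
    idx = np.empty(len(score), dtype=int)
    for k, v in enumerate(score.variants):
        i = panel.index_of(v.variant_id, v.chromosome, v.position)
        if i is None:
            raise ValidationError(f"score {score.score_id}: variant {v.variant_id} absent from panel")
        idx[k] = i
    weights = np.array([v.weight for v in score.variants], dtype=float)
    flips = np.array([v.flip_dosage for v in score.variants], dtype=bool)
    d = panel.dosages[idx]
    d_eff = np.where(flips[:, None], 2.0 - d, d)
    raw = weights @ d_eff
    return ScoreVector(
        sample_ids=list(panel.sample_ids),
        raw=raw,
        n_variants_used=len(score),
        score_id=score.score_id,
    )


def standardize(v: ScoreVector) -> ScoreVector:
    """Center and scale to mean 0, population SD 1 (divisor N)."""
    mu = v.raw.mean()
    sd = v.raw.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"score {v.score_id}: zero variance, cannot standardize")
    return replace(v, standardized=(v.raw - mu) / sd)


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Symmetric percentile ranks 100*(rank-0.5)/N, average ranks on ties."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValidationError("cannot rank an empty vector")
    return 100.0 * (rankdata(values, method="average") - 0.5) / n


def bin_of_percentile(pct: np.ndarray) -> np.ndarray:
    """Map percentiles in [0, 100) to the seven risk-bin labels."""
    idx = np.searchsorted(np.asarray(BIN_EDGES), np.asarray(pct), side="right")
    return np.array(BIN_LABELS, dtype=object)[idx]


def assign_bins(v: ScoreVector) -> ScoreVector:
    """Attach percentile ranks and risk-bin labels (rank-based, so raw vs
    standardized is immaterial)."""
    pct = percentile_ranks(v.raw)
    return replace(v, percentile=pct, bin=bin_of_percentile(pct))
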