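"""Variant and sample quality control, and allele harmonization.

Variant QC mirrors the standard pipeline for applying a published PRS to an
imputed target cohort: strand-ambiguous (A/T, C/G) variants whose minor allele
frequency is so close to 0.5 that strand cannot be inferred are dropped
(MAF > 0.49), rare variants (MAF < 0.005) and poorly imputed variants
(info score <= 0.4) are dropped, and scoring-file alleles are aligned to the
panel's allele orientation, resolving unambiguous strand flips via base
complement.  Sample QC removes individuals carrying any upstream exclusion
flag (sex discordance, relatedness, heterozygosity/missingness outliers).

MAF is always computed from the target panel's dosages (folded to the minor
side); the allele-frequency source for the ambiguity rule is therefore the
analysis cohort itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import COMPLEMENT, CohortTable, DosagePanel, ScoreFile, is_palindromic
from dataclasses import replace as _replace


@dataclass(frozen=True)
class QcThresholds:
    """Variant-QC thresholds.

    ambiguous_maf_min: palindromic variants with MAF strictly above this are removed.
    rare_maf_max: variants with MAF strictly below this are removed.
    info_min: variants with imputation info score <= this are removed (strict keep rule).
    """

    ambiguous_maf_min: float = 0.49
    rare_maf_max: float = 0.005
    info_min: float = 0.4

    def __post_init__(self):
        if not (0 < self.rare_maf_max < self.ambiguous_maf_min <= 0.5):
            raise ValidationError(
                "require 0 < rare_maf_max < ambiguous_maf_min <= 0.5, got "
                f"({self.rare_maf_max}, {self.ambiguous_maf_min})"
            )


@dataclass
class QcReport:
    """Counts removed per rule plus counts retained for one QC stage."""

    stage: str
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    flipped: int = 0  # harmonization only: dosage-complemented variants (not removals)
    extra: dict[str, int] = field(default_factory=dict)  # informational, outside the removed/retained balance

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_removed + self.retained != self.n_input:
            raise ValidationError(
                f"{self.stage}: removed {self.n_removed} + retained {self.retained} != input {self.n_input}"
            )

    def to_dict(self) -> dict:
        d = {"stage": self.stage, "n_input": self.n_input, "retained": self.retained}
        d.update({f"removed_{k}": v for k, v in self.removed.items()})
        if self.stage == "harmonize":
            d["flipped"] = self.flipped
        d.update(self.extra)
        return d

    def summary(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.to_dict().items())


def compute_maf(panel: DosagePanel, variant) -> float:
    """Folded minor allele frequency of one panel variant from its dosages.

    ``variant`` is a variant_id or a row index.  The allele-1 frequency is
    mean(dosage)/2; the MAF is min(f, 1-f).
    """
    if panel.n_individuals == 0:
        raise ValidationError("cannot compute MAF on a panel with no individuals")
    i = variant if isinstance(variant, (int, np.integer)) else panel.index_of(str(variant))
    if i is None:
        raise ValidationError(f"variant {variant!r} not in panel")
    f = float(panel.dosages[i].mean()) / 2.0
    return min(f, 1.0 - f)


def panel_mafs(panel: DosagePanel) -> np.ndarray:
    """Folded MAF for every panel variant (vectorized)."""
    if panel.n_individuals == 0:
        raise ValidationError("cannot compute MAF on a panel with no individuals")
    f = panel.dosages.mean(axis=1) / 2.0
    return np.minimum(f, 1.0 - f)


def apply_variant_qc(
    score: ScoreFile, panel: DosagePanel, thresholds: QcThresholds = QcThresholds()
) -> tuple[ScoreFile, QcReport]:
    """Drop unmatched, ambiguous, rare and low-info variants from a score.

    Rules are tested in a fixed order per variant (absent-from-panel,
    ambiguous, rare, low-info) so each removal is attributed to exactly one
    rule; the order of retained variants is preserved.
    """
    report = QcReport(
        stage="variant_qc",
        n_input=len(score),
        removed={"unmatched": 0, "ambiguous": 0, "rare": 0, "low_info": 0},
    )
    mafs = panel_mafs(panel) if panel.n_individuals else None
    info = panel.variants["info_score"].to_numpy(dtype=float)
    keep = []
    for v in score.variants:
        i = panel.index_of(v.variant_id, v.chromosome, v.position)
        if i is None:
            report.removed["unmatched"] += 1
            continue
        maf = float(mafs[i])
        if v.palindromic and maf > thresholds.ambiguous_maf_min:
            report.removed["ambiguous"] += 1
            continue
        if maf < thresholds.rare_maf_max:
            report.removed["rare"] += 1
            continue
        if info[i] <= thresholds.info_min:
            report.removed["low_info"] += 1
            continue
        keep.append(v)
    report.retained = len(keep)
    report.check()
    return score.subset(keep), report


def harmonize_alleles(score: ScoreFile, panel: DosagePanel) -> tuple[ScoreFile, QcReport]:
    """Align scoring-file alleles to the panel's allele1/allele2 orientation.

    When the published effect allele is the panel's allele2, the variant is
    marked ``flip_dosage`` so the scoring engine uses ``2 - d``; published
    weights are never modified.  Strand flips (both alleles complement-match)
    are resolved only for non-palindromic pairs; anything else is removed as
    an allele mismatch.
    """
    report = QcReport(
        stage="harmonize",
        n_input=len(score),
        removed={"unmatched": 0, "allele_mismatch": 0},
    )
    keep = []
    for v in score.variants:
        i = panel.index_of(v.variant_id, v.chromosome, v.position)
        if i is None:
            report.removed["unmatched"] += 1
            continue
        a1 = panel.variants["allele1"].iat[i]
        a2 = panel.variants["allele2"].iat[i]
        e, o = v.effect_allele, v.other_allele
        ce, co = COMPLEMENT[e], COMPLEMENT[o]
        if (e, o) == (a1, a2):
            flip = False
        elif (e, o) == (a2, a1):
            flip = True
        elif not is_palindromic(e, o) and (ce, co) == (a1, a2):
            flip = False
        elif not is_palindromic(e, o) and (ce, co) == (a2, a1):
            flip = True
        else:
            report.removed["allele_mismatch"] += 1
            continue
        if flip:
            report.flipped += 1
        keep.append(_replace(v, flip_dosage=flip))
    report.retained = len(keep)
    report.check()
    return score.subset(keep), report


def apply_sample_qc(cohort: CohortTable) -> tuple[CohortTable, QcReport]:
    """Remove individuals with any sample-QC flag set."""
    flags = cohort.df["qc_flags"].astype(str)
    removed_counts: dict[str, int] = {}
    for name in ("sex_discordant", "related", "het_miss_outlier"):
        removed_counts[f"flag_{name}"] = int(flags.str.contains(name).sum())
    mask = cohort.flagged_mask()
    kept = cohort.df.loc[~mask].reset_index(drop=True)
    # per-flag counts can overlap, so they are informational extras rather
    # than removal attributions
    report = QcReport(
        stage="sample_qc",
        n_input=len(cohort),
        removed={"flagged": int(mask.sum())},
        retained=len(kept),
        extra=removed_counts,
    )
    report.check()
    if len(kept) == 0 and len(cohort) > 0:
        warnings.warn("sample QC removed every individual", stacklevel=2)
    return CohortTable(kept), report
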