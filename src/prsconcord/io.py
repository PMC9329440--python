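"""Readers, writers and domain containers for scoring files, dosage panels and cohorts.

Scoring files follow the PGS Catalog scoring-file layout: optional ``#``-prefixed
metadata lines, then a tab-separated table with columns ``rsID``, ``chr_name``,
``chr_position``, ``effect_allele``, ``other_allele``, ``effect_weight``.
Dosage panels and cohort tables are plain tab-separated text; positions are
1-based, dosages are expected effect-allele counts in [0, 2], and the dosage of
a panel variant counts copies of ``allele1``.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: strand-ambiguous (palindromic) allele pairs: A/T and C/G
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

SCORE_COLUMNS = [
    "rsID",
    "chr_name",
    "chr_position",
    "effect_allele",
    "other_allele",
    "effect_weight",
]

QC_FLAG_NAMES = ("sex_discordant", "related", "het_miss_outlier")


def is_palindromic(a1: str, a2: str) -> bool:
    """True if the allele pair is strand-ambiguous (A/T or C/G)."""
    return (a1, a2) in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class ScoringVariant:
    """One row of a PRS definition: a variant, its effect allele and weight.

    ``flip_dosage`` is set by allele harmonization when the published effect
    allele is the panel's ``allele2``: the effect-allele dosage is then
    ``2 - d``.  It is never serialized; written files always carry the
    published alleles and weight.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    weight: float
    flip_dosage: bool = False

    def __post_init__(self):
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"variant {self.variant_id}: effect_allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"variant {self.variant_id}: other_allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"variant {self.variant_id}: effect and other allele are equal")
        if not math.isfinite(self.weight):
            raise ValidationError(f"variant {self.variant_id}: non-finite weight")
        if self.position < 1:
            raise ValidationError(f"variant {self.variant_id}: position must be 1-based (>= 1)")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class ScoreFile:
    """A PRS definition: an ordered set of weighted variants."""

    score_id: str
    trait_label: str
    variants: list[ScoringVariant]

    def __post_init__(self):
        seen: set[str] = set()
        dups = []
        for v in self.variants:
            if v.variant_id in seen:
                dups.append(v.variant_id)
            seen.add(v.variant_id)
        if dups:
            raise ValidationError(f"score {self.score_id}: duplicate variant ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def subset(self, keep: list[ScoringVariant]) -> "ScoreFile":
        return ScoreFile(self.score_id, self.trait_label, list(keep))


@dataclass
class DosagePanel:
    """Individuals x variants dosage matrix with per-variant metadata.

    ``dosages`` has one row per variant and one column per individual, and the
    value counts copies of that variant's ``allele1``.  ``true_maf`` is
    generator-side metadata (the allele frequency each variant was simulated
    at); it is not read from or written to disk.
    """

    sample_ids: list[str]
    variants: pd.DataFrame  # variant_id, chromosome, position, allele1, allele2, info_score
    dosages: np.ndarray
    true_maf: np.ndarray | None = None

    _id_index: dict = field(default_factory=dict, repr=False)
    _pos_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n_var = len(self.variants)
        if self.dosages.shape != (n_var, len(self.sample_ids)):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n_var} variants x {len(self.sample_ids)} individuals"
            )
        ids = self.variants["variant_id"]
        if ids.duplicated().any():
            raise ValidationError(f"duplicate variant ids in panel: {sorted(ids[ids.duplicated()])}")
        if self.dosages.size and (np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2):
            raise ValidationError("dosages outside [0, 2]")
        info = self.variants["info_score"].to_numpy(dtype=float)
        if n_var and ((info < 0) | (info > 1)).any():
            raise ValidationError("info scores outside [0, 1]")
        self._id_index = {vid: i for i, vid in enumerate(ids)}
        self._pos_index = {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.variants["chromosome"], self.variants["position"]))
        }

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def index_of(self, variant_id: str, chromosome: str | None = None, position: int | None = None):
        """Row index of a variant: primary key variant_id, fallback chrom:pos."""
        i = self._id_index.get(variant_id)
        if i is None and chromosome is not None and position is not None:
            i = self._pos_index.get((chromosome, int(position)))
        return i


@dataclass
class CohortTable:
    """Per-individual outcome, covariates and sample-QC flags.

    Backed by a DataFrame with columns ``sample_id``, ``outcome`` (0/1),
    ``age``, ``sex`` (female/male), ``array``, ``pc1``..``pc5`` and
    ``qc_flags`` (';'-joined subset of sex_discordant / related /
    het_miss_outlier, empty string when clean).
    """

    df: pd.DataFrame

    REQUIRED = ["sample_id", "outcome", "age", "sex", "array", "pc1", "pc2", "pc3", "pc4", "pc5", "qc_flags"]

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        out = self.df["outcome"]
        if out.isna().any():
            bad = self.df.loc[out.isna(), "sample_id"].tolist()
            raise ValidationError(f"missing outcome for samples: {bad[:5]}")
        if not set(out.unique()) <= {0, 1}:
            raise ValidationError("outcome must be 0/1")
        if self.df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in cohort")
        flags = self.df["qc_flags"].fillna("")
        for entry in flags:
            for f in str(entry).split(";"):
                if f and f not in QC_FLAG_NAMES:
                    raise ValidationError(f"unknown qc flag {f!r}")
        self.df = self.df.assign(qc_flags=flags.astype(str).replace("nan", ""))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def outcome(self) -> np.ndarray:
        return self.df["outcome"].to_numpy(dtype=int)

    def flagged_mask(self) -> np.ndarray:
        return (self.df["qc_flags"].str.len() > 0).to_numpy()


# ---------------------------------------------------------------------------
# scoring files


def read_score_file(path, score_id: str | None = None, trait_label: str = "") -> ScoreFile:
    """Parse a PGS Catalog-layout scoring file.

    ``#`` metadata lines are skipped (``# key=value`` lines for ``score_id``
    and ``trait_label`` are honoured); allele strings are upper-cased; CRLF
    and trailing blank lines are tolerated.
    """
    meta = {}
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            stripped = ln.lstrip("#").strip()
            if "=" in stripped:
                k, _, v = stripped.partition("=")
                meta[k.strip()] = v.strip()
        elif ln.strip():
            body.append(ln)
    if not body:
        raise FormatError(f"{path}: no header line found")
    df = pd.read_csv(_io.StringIO("\n".join(body)), sep="\t", dtype=str)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    variants = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        ea = str(row.effect_allele).upper()
        oa = str(row.other_allele).upper()
        try:
            variants.append(
                ScoringVariant(
                    variant_id=str(row.rsID),
                    chromosome=str(row.chr_name),
                    position=int(row.chr_position),
                    effect_allele=ea,
                    other_allele=oa,
                    weight=float(row.effect_weight),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    sid = score_id or meta.get("score_id") or str(path)
    try:
        return ScoreFile(sid, trait_label or meta.get("trait_label", ""), variants)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_score_file(score: ScoreFile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# score_id={score.score_id}\n")
        fh.write(f"# trait_label={score.trait_label}\n")
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for v in score.variants:
            fh.write(
                f"{v.variant_id}\t{v.chromosome}\t{v.position}\t"
                f"{v.effect_allele}\t{v.other_allele}\t{v.weight!r}\n"
            )


# ---------------------------------------------------------------------------
# dosage panels

PANEL_META_COLUMNS = ["variant_id", "chromosome", "position", "allele1", "allele2", "info_score"]


def read_dosage_panel(path) -> DosagePanel:
    """Read a tab-separated dosage panel (rows = variants, columns = individuals)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chromosome": str, "variant_id": str})
    missing = [c for c in PANEL_META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    sample_ids = [c for c in df.columns if c not in PANEL_META_COLUMNS]
    meta = df[PANEL_META_COLUMNS].copy()
    meta["position"] = meta["position"].astype(int)
    meta["allele1"] = meta["allele1"].str.upper()
    meta["allele2"] = meta["allele2"].str.upper()
    dosages = df[sample_ids].to_numpy(dtype=float) if sample_ids else np.empty((len(df), 0))
    # record-level range check with variant and sample named
    if dosages.size:
        bad = np.argwhere((dosages < 0) | (dosages > 2))
        if len(bad):
            i, j = bad[0]
            raise FormatError(
                f"{path}: dosage {dosages[i, j]} outside [0, 2] for variant "
                f"{meta['variant_id'].iloc[i]}, sample {sample_ids[j]}"
            )
    try:
        return DosagePanel(sample_ids=sample_ids, variants=meta.reset_index(drop=True), dosages=dosages)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_dosage_panel(panel: DosagePanel, path) -> None:
    df = panel.variants.copy()
    dos = pd.DataFrame(panel.dosages, columns=panel.sample_ids)
    pd.concat([df.reset_index(drop=True), dos.reset_index(drop=True)], axis=1).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cohort tables


def read_cohort(path) -> CohortTable:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"sample_id": str, "sex": str, "array": str, "qc_flags": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in CohortTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df["qc_flags"] = df["qc_flags"].fillna("")
    try:
        if df["outcome"].isna().any():
            raise ValidationError(
                f"missing outcome for samples: {df.loc[df['outcome'].isna(), 'sample_id'].tolist()[:5]}"
            )
        df["outcome"] = df["outcome"].astype(int)
        return CohortTable(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_cohort(cohort: CohortTable, path) -> None:
    cohort.df.to_csv(path, sep="\t", index=False)
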