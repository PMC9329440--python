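"""Synthetic cohorts, genotype panels and paired scoring files.

The generator emulates the statistical structure an inter-PRS agreement
analysis assumes, without any external data:

* **LD-block-structured dosages.**  Each block of variants shares a latent
  AR(1) Gaussian process per haplotype; thresholding each latent value at the
  variant's allele-frequency quantile yields the allele, and the two
  haplotypes sum to a hard genotype in {0,1,2} (Hardy-Weinberg by
  construction).  Within-block latent correlation decays geometrically with
  distance; blocks are independent.  Dichotomization attenuates correlation,
  so the dosage-scale R^2 between neighbours is materially below the latent
  correlation (latent 0.995 gives dosage R^2 around 0.85).
* **Two weight sets with controlled overlap.**  Score B shares a configurable
  fraction of score A's variants; shared effect sizes are drawn jointly with
  a configurable correlation.  Allele-swapped entries (effect/other exchanged
  with sign-flipped weight) and strand-flipped entries can be planted to
  exercise harmonization.
* **A logistic disease model** on the standardized true score A plus age and
  sex, with the intercept solved by 1-D root finding so the marginal case
  fraction hits a target prevalence; alternatively a quantitative trait
  thresholded at a quantile (hypertension-style "SBP >= 140" ascertainment).

Randomness comes from a single master seed; panel, score and cohort draws use
deterministically spawned substreams, so identical configurations reproduce
bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigurationError
from .io import COMPLEMENT, CohortTable, DosagePanel, ScoreFile, ScoringVariant

#: non-palindromic ordered allele pairs (strand-resolvable)
_SAFE_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and COMPLEMENT[a] != b
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class DiseaseModel:
    """Log-odds coefficients of the outcome model.

    ``intercept=None`` means: solve for the intercept that achieves the
    configured target prevalence on the realized linear predictor.
    Age enters standardized ((age - 55) / 8.66, the SD of Uniform(40, 70));
    sex as an indicator for male.
    """

    intercept: float | None = None
    beta_prs: float = 0.45
    beta_age: float = 0.1
    beta_sex: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the breast-cancer pair setting: a 313-variant earlier
    score of which 72% of variants are shared with the newer score
    (225 of 313), shared weights correlated at 0.9 so the induced inter-score
    correlation is near 0.65, and a rarer binary outcome.
    """

    n_individuals: int = 20_000
    n_blocks: int = 80
    block_size: int = 8
    within_block_corr: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_snps_a: int = 313
    n_snps_b: int = 313
    shared_fraction: float = 0.72
    weight_corr: float = 0.9
    weight_sd: float = 0.05
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    prevalence_target: float = 0.05
    outcome_mode: str = "logistic"  # or "threshold" (quantitative trait binarized)
    sex_mode: str = "both"  # or "female_only"
    qc_flag_rates: dict = field(
        default_factory=lambda: {"sex_discordant": 0.002, "related": 0.03, "het_miss_outlier": 0.002}
    )
    info_range: tuple[float, float] = (0.5, 1.0)
    dosage_noise: float = 0.0  # uniform jitter amplitude toward imputed-style dosages
    # planted pathologies, for QC/harmonization fixtures (all default off)
    n_plant_ambiguous: int = 0
    n_plant_rare: int = 0
    n_plant_low_info: int = 0
    n_allele_swaps: int = 0
    n_strand_flips: int = 0
    trait_label: str = "synthetic_trait"
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_blocks < 1 or self.block_size < 1:
            raise ConfigurationError("n_individuals, n_blocks and block_size must be positive")
        if not (0 <= self.within_block_corr < 1):
            raise ConfigurationError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.005 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0.005 < lo <= hi <= 0.5")
        if not (0 <= self.shared_fraction <= 1):
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if not (-1 <= self.weight_corr <= 1):
            raise ConfigurationError("weight_corr must lie in [-1, 1]")
        if not (0 < self.prevalence_target < 1):
            raise ConfigurationError("prevalence_target must lie in (0, 1)")
        if self.outcome_mode not in ("logistic", "threshold"):
            raise ConfigurationError(f"unknown outcome_mode {self.outcome_mode!r}")
        if self.sex_mode not in ("both", "female_only"):
            raise ConfigurationError(f"unknown sex_mode {self.sex_mode!r}")
        n_var = self.n_blocks * self.block_size
        planted = self.n_plant_ambiguous + self.n_plant_rare + self.n_plant_low_info
        if planted > n_var:
            raise ConfigurationError("more planted variants than panel variants")
        if self.n_snps_a > n_var:
            raise ConfigurationError("n_snps_a exceeds panel variant count")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def _streams(self):
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {name: np.random.default_rng(ss) for name, ss in zip(("panel", "scores", "cohort"), children)}


def _block_haplotypes(rng, n: int, m: int, rho: float, thresholds: np.ndarray) -> np.ndarray:
    """One haplotype per individual for one block: latent AR(1), thresholded."""
    z = rng.standard_normal((n, m))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    s = np.sqrt(1.0 - rho * rho)
    for k in range(1, m):
        x[:, k] = rho * x[:, k - 1] + s * z[:, k]
    return (x < thresholds).astype(np.int8)


def generate_panel(config: SimConfig) -> DosagePanel:
    """Simulate an LD-block-structured dosage panel.

    Variants are laid out on chromosomes 1..22 with blocks 10 Mb apart (far
    beyond any proxy-search window) and 5 kb spacing within a block.  Planted
    pathological variants occupy the first rows: strand-ambiguous pairs at
    MAF ~ 0.495, rare variants at MAF ~ 0.003, and low-info variants with
    info score in (0.30, 0.40]; these three sets are disjoint by construction.
    """
    rng = config._streams()["panel"]
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m)
    info = rng.uniform(*config.info_range, size=m)
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    alleles = [_SAFE_PAIRS[i] for i in pair_idx]

    k = 0
    for _ in range(config.n_plant_ambiguous):
        alleles[k] = _PALINDROMIC[rng.integers(0, 4)]
        maf[k] = rng.uniform(0.496, 0.499)
        info[k] = max(info[k], 0.6)
        k += 1
    for _ in range(config.n_plant_rare):
        maf[k] = rng.uniform(0.002, 0.003)  # comfortably below the 0.005 rule
        info[k] = max(info[k], 0.6)
        k += 1
    for _ in range(config.n_plant_low_info):
        info[k] = rng.uniform(0.31, 0.40)
        maf[k] = min(max(maf[k], 0.05), 0.45)
        k += 1

    thresholds = norm.ppf(maf)
    dosage = np.empty((n, m), dtype=np.float64)
    for b in range(config.n_blocks):
        sl = slice(b * config.block_size, (b + 1) * config.block_size)
        th = thresholds[sl]
        hap1 = _block_haplotypes(rng, n, config.block_size, config.within_block_corr, th)
        hap2 = _block_haplotypes(rng, n, config.block_size, config.within_block_corr, th)
        dosage[:, sl] = hap1 + hap2
    if config.dosage_noise > 0:
        dosage += rng.uniform(-config.dosage_noise, config.dosage_noise, size=dosage.shape)
        np.clip(dosage, 0.0, 2.0, out=dosage)

    # planted ambiguous/rare variants must *realize* the MAF their rule needs,
    # not just target it, so their dosage columns are laid down with an exact
    # allele count (in a random sample order)
    for i in range(config.n_plant_ambiguous + config.n_plant_rare):
        n_alt = int(round(2 * n * maf[i]))
        twos = max(0, n_alt - n)
        ones = n_alt - 2 * twos
        col = np.zeros(n)
        col[:twos] = 2.0
        col[twos : twos + ones] = 1.0
        dosage[:, i] = rng.permutation(col)

    chrom = [str((b % 22) + 1) for b in range(config.n_blocks) for _ in range(config.block_size)]
    pos = [
        (b // 22) * 10_000_000 + j * 5_000 + 1
        for b in range(config.n_blocks)
        for j in range(config.block_size)
    ]
    meta = pd.DataFrame(
        {
            "variant_id": [f"rs{100000 + i}" for i in range(m)],
            "chromosome": chrom,
            "position": pos,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
            "info_score": info,
        }
    )
    return DosagePanel(
        sample_ids=[f"ind{i:06d}" for i in range(n)],
        variants=meta,
        dosages=dosage.T,
        true_maf=maf,
    )


def generate_score_pair(panel: DosagePanel, config: SimConfig) -> tuple[ScoreFile, ScoreFile]:
    """Two scoring files over the panel with controlled variant overlap.

    Score B carries ``round(shared_fraction * n_snps_a)`` of A's variants;
    shared weights are drawn bivariate-normal with correlation
    ``weight_corr``.  Planted allele swaps rewrite a B entry against the
    opposite allele (alleles exchanged, weight negated — the same score,
    published differently); planted strand flips complement both alleles of a
    non-palindromic B entry.
    """
    rng = config._streams()["scores"]
    m = panel.n_variants
    n_shared = int(round(config.shared_fraction * config.n_snps_a))
    n_extra_b = config.n_snps_b - n_shared
    if n_extra_b < 0:
        raise ConfigurationError("n_snps_b smaller than the implied shared variant count")
    if config.n_snps_a + n_extra_b > m:
        raise ConfigurationError(
            f"panel has {m} variants; need {config.n_snps_a} + {n_extra_b} distinct"
        )

    idx_a = np.sort(rng.choice(m, size=config.n_snps_a, replace=False))
    shared = np.sort(rng.choice(config.n_snps_a, size=n_shared, replace=False))
    remaining = np.setdiff1d(np.arange(m), idx_a)
    idx_b_extra = np.sort(rng.choice(len(remaining), size=n_extra_b, replace=False))
    idx_b = np.concatenate([idx_a[shared], remaining[idx_b_extra]])

    w_a = rng.normal(0.0, config.weight_sd, size=config.n_snps_a)
    noise = rng.normal(0.0, config.weight_sd, size=n_shared)
    w_b_shared = config.weight_corr * w_a[shared] + np.sqrt(1 - config.weight_corr**2) * noise
    w_b_extra = rng.normal(0.0, config.weight_sd, size=n_extra_b)
    w_b = np.concatenate([w_b_shared, w_b_extra])

    def entries(indices, weights):
        out = []
        meta = panel.variants
        for i, w in zip(indices, weights):
            out.append(
                ScoringVariant(
                    variant_id=meta["variant_id"].iat[i],
                    chromosome=meta["chromosome"].iat[i],
                    position=int(meta["position"].iat[i]),
                    effect_allele=meta["allele1"].iat[i],
                    other_allele=meta["allele2"].iat[i],
                    weight=float(w),
                )
            )
        return out

    va = entries(idx_a, w_a)
    vb = entries(idx_b, w_b)

    # plant harmonization work in score B
    swappable = rng.permutation(len(vb))
    n_swapped = 0
    n_flipped = 0
    for j in swappable:
        v = vb[j]
        if n_swapped < config.n_allele_swaps:
            vb[j] = replace(
                v, effect_allele=v.other_allele, other_allele=v.effect_allele, weight=-v.weight
            )
            n_swapped += 1
        elif n_flipped < config.n_strand_flips:
            if (v.other_allele, v.effect_allele) == (
                COMPLEMENT[v.effect_allele],
                COMPLEMENT[v.other_allele],
            ):
                continue  # palindromic: a strand flip would be unresolvable
            vb[j] = replace(
                v,
                effect_allele=COMPLEMENT[v.effect_allele],
                other_allele=COMPLEMENT[v.other_allele],
            )
            n_flipped += 1
        else:
            break

    score_a = ScoreFile("PRS-A", config.trait_label, va)
    score_b = ScoreFile("PRS-B", config.trait_label, vb)
    return score_a, score_b


def analytic_score_correlation(
    score_a: ScoreFile, score_b: ScoreFile, panel: DosagePanel
) -> float:
    """Expected Pearson correlation of the two raw scores under variant independence.

    Uses the generator's per-variant allele frequencies (``panel.true_maf``)
    and the Hardy-Weinberg dosage variance 2f(1-f).  Only meaningful when the
    panel was simulated with ``within_block_corr == 0``; with LD the true
    correlation also has cross-variant terms.
    """
    if panel.true_maf is None:
        raise ConfigurationError("panel carries no generator allele frequencies")
    var = 2.0 * panel.true_maf * (1.0 - panel.true_maf)

    def mass(score):
        w = {}
        for v in score.variants:
            i = panel.index_of(v.variant_id)
            w[i] = v.weight
        return w

    wa, wb = mass(score_a), mass(score_b)
    num = sum(wa[i] * wb[i] * var[i] for i in wa.keys() & wb.keys())
    den_a = sum(w * w * var[i] for i, w in wa.items())
    den_b = sum(w * w * var[i] for i, w in wb.items())
    return float(num / np.sqrt(den_a * den_b))


def solve_intercept(linear_predictor: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(expit(c + lp)) == prevalence, by 1-D root finding."""

    def f(c):
        return float(expit(c + linear_predictor).mean()) - prevalence

    lo, hi = -30.0, 30.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def generate_cohort(
    panel: DosagePanel, scores: tuple[ScoreFile, ScoreFile], config: SimConfig
) -> CohortTable:
    """Simulate covariates, the disease outcome and sample-QC flags.

    The genetic liability is the standardized true score A computed directly
    from the generating weights (no QC), so the disease model is exactly the
    configured logistic model.  In ``threshold`` mode a Gaussian quantitative
    trait is formed from the same linear predictor plus unit noise and
    binarized at the (1 - prevalence_target) quantile.
    """
    from .engine import compute_prs, standardize  # local import to avoid a cycle

    rng = config._streams()["cohort"]
    n = panel.n_individuals
    dm = config.disease_model

    age = rng.uniform(40.0, 70.0, size=n)
    age_z = (age - 55.0) / 8.66
    if config.sex_mode == "female_only":
        sex = np.zeros(n, dtype=int)
        sex_label = np.array(["female"] * n, dtype=object)
    else:
        sex = rng.integers(0, 2, size=n)
        sex_label = np.where(sex == 1, "male", "female").astype(object)
    array = np.where(rng.random(n) < 0.1, "bileve", "axiom").astype(object)
    pcs = rng.standard_normal((n, 5))

    prs_z = standardize(compute_prs(scores[0], panel)).standardized
    lp = dm.beta_prs * prs_z + dm.beta_age * age_z + dm.beta_sex * sex

    if config.outcome_mode == "logistic":
        intercept = dm.intercept if dm.intercept is not None else solve_intercept(lp, config.prevalence_target)
        p = expit(intercept + lp)
        outcome = (rng.random(n) < p).astype(int)
    else:
        trait = lp + rng.standard_normal(n)
        cut = np.quantile(trait, 1.0 - config.prevalence_target)
        outcome = (trait >= cut).astype(int)

    flags = []
    draws = {name: rng.random(n) for name in ("sex_discordant", "related", "het_miss_outlier")}
    rates = config.qc_flag_rates
    for i in range(n):
        hit = [name for name in draws if draws[name][i] < rates.get(name, 0.0)]
        flags.append(";".join(hit))

    df = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "outcome": outcome,
            "age": np.round(age, 2),
            "sex": sex_label,
            "array": array,
            **{f"pc{k + 1}": pcs[:, k] for k in range(5)},
            "qc_flags": flags,
        }
    )
    return CohortTable(df)


def generate_all(config: SimConfig):
    """Panel, score pair and cohort from one configuration."""
    panel = generate_panel(config)
    scores = generate_score_pair(panel, config)
    cohort = generate_cohort(panel, scores, config)
    return panel, scores, cohort
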