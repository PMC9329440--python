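"""Agreement statistics for a pair of polygenic risk scores.

Implements the full between-score comparison surface: Pearson correlation of
the continuous scores, the 7x7 percentile cross-classification with
column/row/cell percentages, top-k% concordance, odds ratios at upper
cut-points versus the middle quintile, crude and multivariable-adjusted AUC,
continuous and categorical net reclassification improvement (NRI), and
percentile-bootstrap confidence intervals.

Logistic models are maximum-likelihood fits (Newton/IRLS via statsmodels)
with Wald standard errors; non-convergence and separation raise explicit
errors.  The AUC is the rank-based Mann-Whitney estimator with ties counted
one half.  Continuous NRI follows Pencina's convention: exact ties in
predicted risk contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .engine import BIN_LABELS, ScoreVector, assign_bins, percentile_ranks
from .errors import FitError, ValidationError
from .io import CohortTable

N_BINS = len(BIN_LABELS)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, as printed tables use (2.25 -> 2.3 at 1 digit)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# cross-classification


@dataclass
class CrossTab:
    """7x7 cross-classification of risk bins (rows = score A, cols = score B)."""

    counts: np.ndarray
    col_pct: np.ndarray
    row_pct: np.ndarray
    cell_pct: np.ndarray
    labels: tuple = BIN_LABELS

    @classmethod
    def from_counts(cls, counts) -> "CrossTab":
        counts = np.asarray(counts, dtype=int)
        if counts.shape != (N_BINS, N_BINS):
            raise ValidationError(f"expected a {N_BINS}x{N_BINS} count matrix, got {counts.shape}")
        total = counts.sum()
        col_sums = counts.sum(axis=0, keepdims=True)
        row_sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            col_pct = np.where(col_sums > 0, 100.0 * counts / col_sums, 0.0)
            row_pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
            cell_pct = 100.0 * counts / total if total else np.zeros_like(counts, dtype=float)
        return cls(counts=counts, col_pct=col_pct, row_pct=row_pct, cell_pct=cell_pct)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def check(self) -> None:
        for j in range(N_BINS):
            if self.counts[:, j].sum() and abs(self.col_pct[:, j].sum() - 100) > 0.1:
                raise ValidationError("column percentages do not sum to 100")
        for i in range(N_BINS):
            if self.counts[i].sum() and abs(self.row_pct[i].sum() - 100) > 0.1:
                raise ValidationError("row percentages do not sum to 100")
        if self.n and abs(self.cell_pct.sum() - 100) > 0.1:
            raise ValidationError("cell percentages do not sum to 100")


def cross_classify(a: ScoreVector, b: ScoreVector) -> CrossTab:
    """Count individuals by (bin of score A, bin of score B)."""
    a = a if a.bin is not None else assign_bins(a)
    b = b if b.bin is not None else assign_bins(b)
    if a.sample_ids != b.sample_ids:
        raise ValidationError("score vectors cover different individuals")
    ia, ib = a.bin_index, b.bin_index
    counts = np.zeros((N_BINS, N_BINS), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    return CrossTab.from_counts(counts)


# ---------------------------------------------------------------------------
# correlation and tail concordance


def pearson_r(a: ScoreVector, b: ScoreVector) -> float:
    """Pearson correlation of the two continuous scores."""
    if len(a) != len(b):
        raise ValidationError("score vectors differ in length")
    return float(np.corrcoef(a.raw, b.raw)[0, 1])


def _percentiles_of(x) -> np.ndarray:
    if isinstance(x, ScoreVector):
        return x.percentile if x.percentile is not None else percentile_ranks(x.raw)
    return percentile_ranks(np.asarray(x, dtype=float))


def topk_concordance(a, b, k_pct: float) -> float:
    """Fraction of score A's top-k% individuals also in score B's top k%.

    Accepts ``ScoreVector``s or plain value arrays (ranked internally).
    """
    if not (0 < k_pct <= 50):
        raise ValidationError("k_pct must lie in (0, 50]")
    pa = _percentiles_of(a)
    pb = _percentiles_of(b)
    top_a = pa >= 100.0 - k_pct
    if not top_a.any():
        raise ValidationError("no individuals in the top-k% stratum")
    return float((pb[top_a] >= 100.0 - k_pct).mean())


# ---------------------------------------------------------------------------
# logistic models, ORs and AUC


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    llf: float
    fitted: np.ndarray

    def wald_ci(self, name: str, z: float = 1.959963984540054):
        b, se = self.params[name], self.bse[name]
        return b - z * se, b + z * se


def fit_logistic(outcome, design) -> LogisticFit:
    """ML logistic fit (Newton/IRLS, Wald SEs); explicit failure on
    separation or non-convergence."""
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise FitError("outcome must contain both classes")
    X = design.astype(float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge in 100 iterations")
    if not np.isfinite(res.bse).all():
        raise FitError("logistic fit produced non-finite standard errors (separation?)")
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(res.params)
    bse = res.bse if isinstance(res.bse, pd.Series) else pd.Series(res.bse)
    return LogisticFit(params=params, bse=bse, llf=float(res.llf), fitted=np.asarray(res.predict(X)))


def build_covariate_design(cohort: CohortTable, include_age_sex: bool = True) -> pd.DataFrame:
    """Adjustment design: intercept, genotyping-array dummies, PC1-5, and
    optionally age and sex.  Constant columns (e.g. sex in a female-only
    population, a single array) are dropped automatically."""
    df = cohort.df
    out = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    if include_age_sex:
        out["age"] = df["age"].to_numpy(dtype=float)
        sex = (df["sex"] == "male").astype(float)
        if sex.nunique() > 1:
            out["sex_male"] = sex.to_numpy()
    arr = pd.get_dummies(df["array"], prefix="array", drop_first=True, dtype=float)
    for c in arr.columns:
        if arr[c].nunique() > 1:
            out[c] = arr[c].to_numpy()
    for k in range(1, 6):
        out[f"pc{k}"] = df[f"pc{k}"].to_numpy(dtype=float)
    return out


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_lo: float
    ci_hi: float
    coef: float
    se: float
    n_top: int
    n_ref: int


def or_at_cutpoints(
    v: ScoreVector, cohort: CohortTable, cutpoints=(1.0, 5.0)
) -> dict[float, OddsRatioResult]:
    """Adjusted odds ratio of the outcome for each top-k% group versus the
    middle quintile (percentile 40-60) of the same score."""
    if v.sample_ids != cohort.sample_ids:
        raise ValidationError("score vector and cohort cover different individuals")
    pct = v.percentile if v.percentile is not None else percentile_ranks(v.raw)
    y = cohort.outcome
    ref = (pct >= 40.0) & (pct < 60.0)
    out: dict[float, OddsRatioResult] = {}
    for k in cutpoints:
        top = pct >= 100.0 - k
        if not top.any():
            raise FitError(f"cut-point {k}%: empty top group")
        if y[ref].sum() == 0:
            raise FitError(f"cut-point {k}%: no cases in the middle-quintile reference group")
        if y[ref].sum() == ref.sum():
            raise FitError(f"cut-point {k}%: no controls in the middle-quintile reference group")
        mask = top | ref
        sub = CohortTable(cohort.df.loc[mask].reset_index(drop=True))
        design = build_covariate_design(sub, include_age_sex=True)
        design.insert(1, "top_bin", top[mask].astype(float))
        fit = fit_logistic(y[mask], design)
        lo, hi = fit.wald_ci("top_bin")
        out[k] = OddsRatioResult(
            odds_ratio=float(np.exp(fit.params["top_bin"])),
            ci_lo=float(np.exp(lo)),
            ci_hi=float(np.exp(hi)),
            coef=float(fit.params["top_bin"]),
            se=float(fit.bse["top_bin"]),
            n_top=int(top.sum()),
            n_ref=int(ref.sum()),
        )
    return out


def auc(predicted_risk, outcome) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    p = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC needs both outcome classes")
    ranks = rankdata(p, method="average")
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fitted_risk(v: ScoreVector, cohort: CohortTable, include_age_sex: bool) -> np.ndarray:
    """Predicted probabilities from a logistic model of the outcome on the
    standardized score plus adjustment covariates (crude: array + PCs;
    multivariable: also age and sex)."""
    if v.sample_ids != cohort.sample_ids:
        raise ValidationError("score vector and cohort cover different individuals")
    z = v.standardized
    if z is None:
        raw = v.raw
        sd = raw.std(ddof=0)
        if sd == 0:
            raise ValidationError("constant score, cannot fit risk model")
        z = (raw - raw.mean()) / sd
    design = build_covariate_design(cohort, include_age_sex=include_age_sex)
    design.insert(1, "prs", z)
    return fit_logistic(cohort.outcome, design).fitted


# ---------------------------------------------------------------------------
# net reclassification improvement


def nri_continuous(p_old, p_new, outcome) -> float:
    """Continuous NRI; exact ties in predicted risk contribute zero."""
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if not (len(p_old) == len(p_new) == len(y)):
        raise ValidationError("inputs differ in length")
    up = p_new > p_old
    down = p_new < p_old
    case = y == 1
    ctrl = ~case
    if case.sum() == 0 or ctrl.sum() == 0:
        raise ValidationError("NRI needs both outcome classes")
    nri_case = (up[case].mean() - down[case].mean())
    nri_ctrl = (down[ctrl].mean() - up[ctrl].mean())
    return float(nri_case + nri_ctrl)


def _as_bin_index(bins) -> np.ndarray:
    bins = np.asarray(bins)
    if bins.dtype.kind in "iu":
        return bins.astype(int)
    lookup = {lab: i for i, lab in enumerate(BIN_LABELS)}
    try:
        return np.array([lookup[b] for b in bins], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"unknown bin label {exc.args[0]!r}") from exc


def nri_categorical(bins_old, bins_new, outcome) -> float:
    """Categorical NRI over the seven percentile risk bins: movement to any
    higher (lower) bin counts as up (down)."""
    old = _as_bin_index(bins_old)
    new = _as_bin_index(bins_new)
    return nri_continuous(old, new, outcome)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_ci(statistic, data, n_boot: int = 1000, seed=None, alpha: float = 0.05):
    """Percentile bootstrap CI: resample individuals with replacement.

    ``data`` is an array or a tuple of equal-length arrays resampled jointly;
    ``statistic`` receives the resampled array(s) and returns a scalar.
    """
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValidationError("bootstrap arrays differ in length")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic(*(a[idx] for a in arrays))
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# full report


@dataclass
class ConcordanceReport:
    """Every agreement statistic for one PRS pair."""

    pearson_r: float
    crosstab: CrossTab
    topk_concordance: dict[float, float]
    or_table: dict[str, dict[float, OddsRatioResult]]
    auc: dict[str, dict[str, tuple[float, float, float]]]  # score -> {crude|multi: (value, lo, hi)}
    nri_continuous: tuple[float, float, float]
    nri_categorical: tuple[float, float, float]
    n_boot: int
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "topk_concordance": {str(k): v for k, v in self.topk_concordance.items()},
            "or": {
                sid: {
                    str(k): {"or": r.odds_ratio, "ci": [r.ci_lo, r.ci_hi]}
                    for k, r in table.items()
                }
                for sid, table in self.or_table.items()
            },
            "auc": {
                sid: {kind: {"value": v, "ci": [lo, hi]} for kind, (v, lo, hi) in d.items()}
                for sid, d in self.auc.items()
            },
            "nri_continuous": {
                "value": self.nri_continuous[0],
                "ci": list(self.nri_continuous[1:]),
            },
            "nri_categorical": {
                "value": self.nri_categorical[0],
                "ci": list(self.nri_categorical[1:]),
            },
            "n_boot": self.n_boot,
            "crosstab_counts": self.crosstab.counts.tolist(),
        }


def concordance_report(
    a: ScoreVector,
    b: ScoreVector,
    cohort: CohortTable,
    k_list=(1.0, 5.0),
    cutpoints=(1.0, 5.0),
    n_boot: int = 1000,
    seed=None,
) -> ConcordanceReport:
    """Assemble the full pair report.

    Bootstrap CIs (AUC and NRI) resample individuals with replacement and
    recompute the statistic from the fitted per-individual risks; Wald CIs
    are used for the ORs.  Score B's multivariable model is the "updated"
    model for the NRI.
    """
    a = a if a.bin is not None else assign_bins(a)
    b = b if b.bin is not None else assign_bins(b)
    y = cohort.outcome
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = ss.generate_state(8)

    report_auc: dict[str, dict[str, tuple[float, float, float]]] = {}
    risks_multi: dict[str, np.ndarray] = {}
    for i, v in enumerate((a, b)):
        sid = v.score_id or ("A" if v is a else "B")
        entry = {}
        for j, kind in enumerate(("crude", "multi")):
            p = fitted_risk(v, cohort, include_age_sex=(kind == "multi"))
            value = auc(p, y)
            lo, hi = bootstrap_ci(
                lambda pp, yy: auc(pp, yy), (p, y), n_boot=n_boot, seed=int(seeds[2 * i + j])
            )
            entry[kind] = (value, lo, hi)
            if kind == "multi":
                risks_multi[sid] = p
        report_auc[sid] = entry

    sid_a = a.score_id or "A"
    sid_b = b.score_id or "B"
    p_old, p_new = risks_multi[sid_a], risks_multi[sid_b]
    nri_c = nri_continuous(p_old, p_new, y)
    nri_c_ci = bootstrap_ci(nri_continuous, (p_old, p_new, y), n_boot=n_boot, seed=int(seeds[4]))
    ia, ib = a.bin_index, b.bin_index
    nri_k = nri_categorical(ia, ib, y)
    nri_k_ci = bootstrap_ci(nri_categorical, (ia, ib, y), n_boot=n_boot, seed=int(seeds[5]))

    return ConcordanceReport(
        pearson_r=pearson_r(a, b),
        crosstab=cross_classify(a, b),
        topk_concordance={float(k): topk_concordance(a, b, k) for k in k_list},
        or_table={
            sid_a: or_at_cutpoints(a, cohort, cutpoints),
            sid_b: or_at_cutpoints(b, cohort, cutpoints),
        },
        auc=report_auc,
        nri_continuous=(nri_c, *nri_c_ci),
        nri_categorical=(nri_k, *nri_k_ci),
        n_boot=n_boot,
        n=len(cohort),
    )
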