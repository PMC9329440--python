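"""End-to-end orchestration: simulate or load, QC, score, overlap, concord.

A run is described by a single YAML mapping (``RunConfig``): either paths to
a scoring-file pair, dosage panel and cohort table, or an inline simulation
configuration — never both.  All thresholds default to the standard analysis
values (ambiguous MAF 0.49, rare MAF 0.005, info 0.4, proxy R^2 0.8, 1000
bootstrap replications).  Identical configuration and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import simulate
from .engine import BIN_LABELS, assign_bins, compute_prs, standardize
from .errors import ConfigurationError, PipelineError
from .io import (
    read_cohort,
    read_dosage_panel,
    read_score_file,
    write_cohort,
    write_dosage_panel,
    write_score_file,
)
from .ld import overlap
from .qc import QcThresholds, apply_sample_qc, apply_variant_qc, harmonize_alleles
from .stats import ConcordanceReport, CrossTab, concordance_report, round_half_up

log = logging.getLogger("prsconcord")


@dataclass
class RunConfig:
    """Full pipeline configuration; exactly one of (input paths, sim) is set."""

    score_a: str | None = None
    score_b: str | None = None
    panel: str | None = None
    cohort: str | None = None
    sim: simulate.SimConfig | None = None
    thresholds: QcThresholds = field(default_factory=QcThresholds)
    r2_threshold: float = 0.8
    window: int = 500_000
    n_boot: int = 1000
    outdir: str = "prsconcord_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        have_paths = any(x is not None for x in (self.score_a, self.score_b, self.panel, self.cohort))
        if have_paths and self.sim is not None:
            raise ConfigurationError("supply either input paths or a simulation config, not both")
        if not have_paths and self.sim is None:
            raise ConfigurationError("supply input paths or a simulation config")
        if have_paths and None in (self.score_a, self.score_b, self.panel, self.cohort):
            raise ConfigurationError("input-path mode needs score_a, score_b, panel and cohort")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        thr_raw = raw.pop("thresholds", None)
        sim = None
        if sim_raw is not None:
            dm_raw = sim_raw.pop("disease_model", None)
            if dm_raw is not None:
                sim_raw["disease_model"] = simulate.DiseaseModel(**dm_raw)
            for key in ("maf_range", "info_range"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            sim = simulate.SimConfig(**sim_raw)
        thresholds = QcThresholds(**thr_raw) if thr_raw else QcThresholds()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, thresholds=thresholds, **raw)


def render_crosstab(t: CrossTab) -> str:
    """Render the 7x7 table in the published layout, percentages half-up to
    1 decimal.

    Each cell is ``n (p_row, p_col, p_cell)``: the share of the row score's
    bin classified into the column bin, the share of the column bin, and the
    share of everyone — the order the printed reclassification tables use.
    """
    header = "A\\B\t" + "\t".join(t.labels)
    lines = [header]
    for i, lab in enumerate(t.labels):
        cells = []
        for j in range(len(t.labels)):
            cells.append(
                f"{t.counts[i, j]} ({round_half_up(t.row_pct[i, j]):.1f}, "
                f"{round_half_up(t.col_pct[i, j]):.1f}, {round_half_up(t.cell_pct[i, j]):.1f})"
            )
        lines.append(lab + "\t" + "\t".join(cells))
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> ConcordanceReport:
    """Execute the full analysis and write every artifact under ``outdir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.sim is not None:
        log.info("simulating data (seed=%d)", config.sim.seed)
        try:
            panel, (score_a, score_b), cohort = simulate.generate_all(config.sim)
        except Exception as exc:
            raise PipelineError(f"stage 'simulate' failed: {exc}") from exc
        write_dosage_panel(panel, outdir / "panel.tsv")
        write_score_file(score_a, outdir / "score_a.tsv")
        write_score_file(score_b, outdir / "score_b.tsv")
        write_cohort(cohort, outdir / "cohort.tsv")
    else:
        try:
            score_a = read_score_file(config.score_a)
            score_b = read_score_file(config.score_b)
            panel = read_dosage_panel(config.panel)
            cohort = read_cohort(config.cohort)
        except Exception as exc:
            raise PipelineError(f"stage 'load' failed: {exc}") from exc

    reports = []
    try:
        cohort_qc, rep = apply_sample_qc(cohort)
        reports.append(rep)
        log.info("sample QC: %d -> %d individuals", rep.n_input, rep.retained)
        keep = set(cohort_qc.sample_ids)
        col_idx = [i for i, s in enumerate(panel.sample_ids) if s in keep]
        panel = dataclasses.replace(
            panel,
            sample_ids=[panel.sample_ids[i] for i in col_idx],
            dosages=panel.dosages[:, col_idx],
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'sample_qc' failed: {exc}") from exc

    scored = []
    try:
        for score in (score_a, score_b):
            s1, rep1 = apply_variant_qc(score, panel, config.thresholds)
            s2, rep2 = harmonize_alleles(s1, panel)
            reports.extend([rep1, rep2])
            log.info(
                "%s: variant QC %d -> %d, harmonized %d (flipped %d)",
                score.score_id, rep1.n_input, rep1.retained, rep2.retained, rep2.flipped,
            )
            v = assign_bins(standardize(compute_prs(s2, panel)))
            scored.append((s2, v))
    except Exception as exc:
        raise PipelineError(f"stage 'score' failed: {exc}") from exc

    (qc_a, vec_a), (qc_b, vec_b) = scored
    try:
        ld_result = overlap(qc_a, qc_b, panel, config.r2_threshold, config.window)
        log.info("overlap: %s", ld_result.summary().replace("\n", " "))
    except Exception as exc:
        raise PipelineError(f"stage 'overlap' failed: {exc}") from exc

    try:
        report = concordance_report(
            vec_a, vec_b, cohort_qc, n_boot=config.n_boot, seed=config.seed
        )
    except Exception as exc:
        raise PipelineError(f"stage 'concord' failed: {exc}") from exc

    with open(outdir / "qc_report.txt", "w") as fh:
        for rep in reports:
            fh.write(rep.summary() + "\n\n")
    for name, vec in (("score_a_values.tsv", vec_a), ("score_b_values.tsv", vec_b)):
        with open(outdir / name, "w") as fh:
            fh.write("sample_id\traw\tstandardized\tpercentile\tbin\n")
            for i, sid in enumerate(vec.sample_ids):
                fh.write(
                    f"{sid}\t{vec.raw[i]!r}\t{vec.standardized[i]!r}\t"
                    f"{vec.percentile[i]!r}\t{vec.bin[i]}\n"
                )
    with open(outdir / "overlap.tsv", "w") as fh:
        fh.write("variant_a\tvariant_b\tr2\n")
        for va, vb, r2 in ld_result.pairs:
            fh.write(f"{va}\t{vb}\t{r2:.6f}\n")
        fh.write("# " + ld_result.summary().replace("\n", "\t") + "\n")
    with open(outdir / "crosstab.txt", "w") as fh:
        fh.write(render_crosstab(report.crosstab) + "\n")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", outdir)
    return report
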