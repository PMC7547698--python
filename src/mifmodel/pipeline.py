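"""Pipeline orchestration, run configuration and file I/O.

Ties the stages together in order: simulate-cohort -> fit -> compare ->
recover -> analyze.  Every stage reads and writes tidy CSV tables in a
single artifact directory, each file carrying a provenance header line
(`# config_hash=... seed=...`), so a rerun with the same configuration
and master seed produces byte-identical outputs.  Stage seeds are
derived deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cohort_stats, model_variants
from .estimation import SearchConfig, cohort_variances, fit_cohort
from .model_core import PARAM_NAMES, PerformanceMatrix
from .recovery import recovery_experiment
from .synthetic_cohort import (
    CohortConfig,
    generate_cohort,
    participants_frame,
    pms_frame,
)
from .mif_task import trials_to_frame

logger = logging.getLogger(__name__)

STAGES = ("simulate-cohort", "fit", "compare", "recover", "analyze")


class PipelineDependencyError(RuntimeError):
    """A requested stage is missing the outputs of an upstream stage."""


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a pipeline run."""

    seed: int = 0
    outdir: str = "mifmodel_run"
    stages: tuple = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    recovery_n: int = 27
    recovery_pm_mode: str = "noise_free"

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        return json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["cohort"] = CohortConfig(**{
            **raw.get("cohort", {}),
            "alpha_bounds": tuple(raw.get("cohort", {}).get("alpha_bounds", (0.05, 4.0))),
            "beta_bounds": tuple(raw.get("cohort", {}).get("beta_bounds", (0.1, 100.0))),
        })
        search = dict(raw.get("search", {}))
        if "ranges" in search:
            search["ranges"] = {k: tuple(v) for k, v in search["ranges"].items()}
        raw["search"] = SearchConfig(**search)
        raw["stages"] = tuple(raw.get("stages", STAGES))
        return cls(**raw)

    def config_hash(self) -> str:
        # outdir is deployment detail, not provenance: two runs of the
        # same scientific configuration hash identically
        raw = json.loads(self.to_json())
        raw.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(raw, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(config: RunConfig, stage: str) -> int:
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence(config.seed).spawn(len(STAGES))[idx]
    return int(ss.generate_state(1)[0] % (2**31))


def write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    header = f"# config_hash={config.config_hash()} seed={config.seed}\n"
    path.write_text(header + df.to_csv(index=False))


def read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise PipelineDependencyError(
            f"missing {path.name}; run the upstream stage first"
        )
    return pd.read_csv(path, comment="#")


def _pms_from_table(df: pd.DataFrame):
    """Rebuild per-subject PerformanceMatrix objects from pms.csv."""
    from .model_core import INCENTIVES

    subjects, pms = [], []
    for sid, sub in df.groupby("subject_id", sort=False):
        grid = sub.pivot(index="incentive_chf", columns="session",
                         values="success_rate")
        grid = grid.reindex(index=list(INCENTIVES), columns=[1, 2, 3, 4])
        subjects.append(sid)
        pms.append(PerformanceMatrix(grid.to_numpy()))
    return subjects, pms


def _fits_frame(subjects, fits) -> pd.DataFrame:
    rows = []
    for sid, f in zip(subjects, fits):
        row = {"subject_id": sid, "variant": f.variant}
        row.update({nm: getattr(f.params, nm) for nm in PARAM_NAMES})
        row.update({"chi2": f.chi2, "df": f.df, "p_fit": f.p_fit})
        rows.append(row)
    return pd.DataFrame(rows)


def stage_simulate_cohort(config: RunConfig, outdir: Path) -> None:
    cohort_cfg = dataclasses.replace(
        config.cohort, seed=_stage_seed(config, "simulate-cohort")
    )
    cohort = generate_cohort(cohort_cfg, with_trials=True)
    write_table(participants_frame(cohort), outdir / "participants.csv", config)
    trials = pd.concat(
        [trials_to_frame(p.trials, p.subject_id) for p in cohort],
        ignore_index=True,
    )
    write_table(trials, outdir / "trials.csv", config)
    write_table(pms_frame(cohort), outdir / "pms.csv", config)


def stage_fit(config: RunConfig, outdir: Path) -> None:
    subjects, pms = _pms_from_table(read_table(outdir / "pms.csv"))
    sigma2 = cohort_variances(pms)
    cfg = dataclasses.replace(config.search, seed=_stage_seed(config, "fit"))
    fits = fit_cohort(pms, sigma2, cfg, variant="full")
    for sid, f in zip(subjects, fits):
        logger.info("fit %s: best chi2=%.4f (seed %d, budget %d)",
                    sid, f.chi2, cfg.seed, cfg.n_samples)
    write_table(_fits_frame(subjects, fits), outdir / "fits.csv", config)


def stage_compare(config: RunConfig, outdir: Path) -> None:
    subjects, pms = _pms_from_table(read_table(outdir / "pms.csv"))
    fits_df = read_table(outdir / "fits.csv")
    if not set(fits_df.subject_id) >= set(subjects):
        raise PipelineDependencyError("fits.csv does not cover the cohort")
    sigma2 = cohort_variances(pms)
    fit_seed = _stage_seed(config, "fit")
    cfg = dataclasses.replace(config.search, seed=fit_seed)
    full = fit_cohort(pms, sigma2, cfg, variant="full")
    results, variant_rows = [], []
    for offset, variant in enumerate(("reduced", "fix_spr", "fix_end"), start=1):
        vcfg = dataclasses.replace(
            config.search, seed=(fit_seed + offset) % (2**31)
        )
        alt = model_variants.fit_variant(pms, sigma2, vcfg, variant,
                                         full_fits=full)
        variant_rows.append(_fits_frame(subjects, alt))
        results.append(model_variants.compare_models(full, alt))
    write_table(model_variants.comparison_frame(results),
                outdir / "comparison.csv", config)
    write_table(pd.concat(variant_rows, ignore_index=True),
                outdir / "variant_fits.csv", config)
    (outdir / "comparison.txt").write_text(
        "\n".join(r.summary() for r in results) + "\n"
    )


def stage_recover(config: RunConfig, outdir: Path) -> None:
    res = recovery_experiment(
        n=config.recovery_n,
        config=config.search,
        pm_mode=config.recovery_pm_mode,
        seed=_stage_seed(config, "recover"),
    )
    write_table(res.report_frame(), outdir / "recovery.csv", config)
    write_table(res.scatter_frame(), outdir / "recovery_scatter.csv", config)


METABOLITE_COLS = ("glu", "gln", "gaba", "gln_glu", "gaba_gln")


def stage_analyze(config: RunConfig, outdir: Path) -> None:
    participants = read_table(outdir / "participants.csv")
    fits = read_table(outdir / "fits.csv")
    pms_df = read_table(outdir / "pms.csv")
    success = (
        pms_df.groupby("subject_id", sort=False)["success_rate"]
        .mean()
        .rename("success_rate")
        .reset_index()
    )
    table = participants[
        ["subject_id", "group", "effort_perception", *METABOLITE_COLS]
    ].merge(
        fits[["subject_id", *PARAM_NAMES]], on="subject_id"
    ).merge(success, on="subject_id")

    reports = []

    def attempt(label, fn):
        # small or degenerate cohorts legitimately fail some analyses
        # (empty design cells, constant columns); record, do not abort
        try:
            out = fn()
            reports.extend(out if isinstance(out, list) else [out])
        except ValueError as err:
            logger.warning("analysis %s skipped: %s", label, err)
            reports.append(
                cohort_stats.StatReport(label, "-", float("nan"),
                                        float("nan"), len(table),
                                        f"skipped: {err}")
            )

    attempt(
        "correlation_screen",
        lambda: cohort_stats.correlation_screen(
            table, METABOLITE_COLS, ("success_rate", "effort_perception")
        ),
    )
    for nm in PARAM_NAMES:
        attempt(
            f"group_compare[{nm}]",
            lambda nm=nm: cohort_stats.group_compare(
                table[nm], table["group"], analysis=f"group_compare[{nm}]"
            ),
        )
        attempt(
            f"regression[{nm}]",
            lambda nm=nm: cohort_stats.ratio_regressions(table, "gln_glu", nm),
        )
    for outcome in ("success_rate", "b", "eps_spr"):
        attempt(
            f"anova[{outcome}]",
            lambda outcome=outcome: cohort_stats.interaction_anova(
                table, outcome,
                rank_flag=not cohort_stats.is_normal(table[outcome]),
            ),
        )
    write_table(cohort_stats.reports_frame(reports), outdir / "stats.csv",
                config)

    _, pms = _pms_from_table(pms_df)
    explained, cum = cohort_stats.pm_pca(pms)
    pca = pd.DataFrame(
        {"component": np.arange(1, 13), "explained": explained,
         "cumulative": cum}
    )
    write_table(pca, outdir / "pca.csv", config)


_STAGE_FUNCS = {
    "simulate-cohort": stage_simulate_cohort,
    "fit": stage_fit,
    "compare": stage_compare,
    "recover": stage_recover,
    "analyze": stage_analyze,
}


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages in order; returns the artifact directory.

    The merged configuration is echoed to ``config.json`` for
    provenance, and a plain-text log records seeds, budgets and
    per-stage timings.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json() + "\n")
    log_lines = [f"config_hash={config.config_hash()} master_seed={config.seed}"]
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](config, outdir)
        dt = time.perf_counter() - t0
        line = (f"stage={stage} seed={_stage_seed(config, stage)} "
                f"budget={config.search.n_samples} elapsed_s={dt:.2f}")
        logger.info(line)
        log_lines.append(line)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir
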