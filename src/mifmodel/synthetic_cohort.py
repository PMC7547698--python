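"""Synthetic study generator.

Builds a complete synthetic cohort for the MIF-task pipeline: group
assignment (isolation / competition), an accumbal metabolite panel
(glutamate, glutamine, GABA and the Gln/Glu and GABA/Gln ratios), an
effort-perception score, latent model parameters, and simulated
trial-level task data.  Every downstream stage (fitting, model
comparison, statistics) can therefore run with no external data.

The generator encodes, as configurable couplings, the qualitative effect
structure the pipeline is meant to detect:

* endurance stamina (eps_end) increases with the Gln/Glu ratio (the
  primary coupling), sprint stamina (eps_spr) weakly so;
* effort perception decreases with Gln/Glu;
* competition lowers the effort-cost baseline b, with the effect
  concentrated in low-Gln/Glu subjects (a group x ratio interaction);
* competition lowers sprint stamina;
* Glu and Gln share a latent factor, inducing their positive
  correlation.

Stamina parameters and effort perception are generated through a
logistic link: a Gaussian linear predictor in the standardised Gln/Glu
ratio is passed through a sigmoid, which keeps values in (0, 1) without
clamping and makes the design rank correlation analytic (for a bivariate
normal pair with Pearson correlation r, the Spearman correlation is
(6/pi)*asin(r/2); monotone transforms preserve it).  alpha and beta are
drawn on their natural scales and clamped to the estimation search
ranges; clamp events are logged.

Metabolite concentration scales are invented fixture values in arbitrary
units (no absolute concentrations are modelled); only the ratios drive
couplings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .mif_task import build_schedule, simulate_trials, summarize
from .model_core import ModelParameters, PerformanceMatrix

logger = logging.getLogger(__name__)

GROUPS = ("isolation", "competition")


@dataclass(frozen=True)
class MetabolitePanel:
    """Metabolite concentrations (arbitrary units) and derived ratios."""

    glu: float
    gln: float
    gaba: float

    def __post_init__(self) -> None:
        if min(self.glu, self.gln, self.gaba) <= 0:
            raise ValueError("metabolite concentrations must be positive")

    @property
    def gln_glu(self) -> float:
        return self.gln / self.glu

    @property
    def gaba_gln(self) -> float:
        return self.gaba / self.gln


@dataclass(frozen=True)
class ParticipantRecord:
    """One synthetic subject with latent truth and realised task data."""

    subject_id: str
    group: str
    metabolites: MetabolitePanel
    effort_perception: float
    true_params: ModelParameters
    trials: Optional[tuple] = None
    pms: Optional[PerformanceMatrix] = None


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings: sizes, metabolite scales, couplings, noise.

    Coupling coefficients act on the Gln/Glu ratio standardised by the
    design (delta-method) ratio mean and SD, on the logit scale for the
    stamina parameters and effort perception, and on the natural scale
    for b.  Group effects are shifts of the competition group relative
    to isolation.
    """

    n_isolation: int = 15
    n_competition: int = 12
    seed: int = 0

    # metabolite panel (arbitrary concentration units)
    glu_mean: float = 9.0
    glu_sd: float = 1.0
    gln_mean: float = 3.0
    gln_sd: float = 0.5
    gaba_mean: float = 1.5
    gaba_sd: float = 0.4
    glu_gln_factor_loading: float = 0.8  # shared latent factor for Glu/Gln
    gaba_factor_loading: float = 0.3
    ratio_mean: float = 3.0 / 9.0  # design mean of Gln/Glu
    ratio_sd: float = 0.0427  # design (delta-method) SD of Gln/Glu

    # utility curvature: log-normal, no couplings
    log_alpha_mean: float = np.log(0.25)
    log_alpha_sd: float = 1.1

    # sigmoidal steepness: group-specific normals
    beta_mean_iso: float = 16.1
    beta_sd_iso: float = 13.9
    beta_mean_comp: float = 7.5
    beta_sd_comp: float = 8.0

    # effort-cost baseline: natural scale
    b_mean_iso: float = 0.356
    b_sd: float = 0.5
    b_group_shift: float = -1.17  # competition main effect
    b_group_ratio_interaction: float = 0.9  # competition x standardised ratio

    # stamina (logit scale)
    end_logit_iso: float = 3.5
    end_logit_comp: float = 2.7
    end_ratio_coupling: float = 1.0
    end_logit_sd: float = 1.0
    spr_logit_iso: float = 3.0
    spr_logit_comp: float = 0.6
    spr_ratio_coupling: float = 0.5
    spr_logit_sd: float = 1.2

    # effort perception (logit scale; fraction of MVC perceived required)
    percept_logit_mean: float = 0.0
    percept_ratio_coupling: float = -0.8
    percept_logit_sd: float = 0.8

    # clamp bounds for alpha/beta (match the estimation search ranges)
    alpha_bounds: tuple = (0.05, 4.0)
    beta_bounds: tuple = (0.1, 100.0)

    def __post_init__(self) -> None:
        if self.n_isolation < 2 or self.n_competition < 2:
            raise ValueError("each group needs at least 2 subjects")
        for nm in ("glu_sd", "gln_sd", "gaba_sd", "b_sd", "end_logit_sd",
                   "spr_logit_sd", "percept_logit_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    def design_rank_correlation(self, parameter: str) -> float:
        """Analytic Spearman correlation between the Gln/Glu ratio and a
        generated quantity, implied by the configured coupling and noise
        (bivariate-normal rank identity rho_s = (6/pi)*asin(r/2))."""
        k, s = {
            "eps_end": (self.end_ratio_coupling, self.end_logit_sd),
            "eps_spr": (self.spr_ratio_coupling, self.spr_logit_sd),
            "effort_perception": (self.percept_ratio_coupling, self.percept_logit_sd),
        }[parameter]
        denom = np.hypot(k, s)
        r = k / denom if denom > 0 else 0.0
        return float(6.0 / np.pi * np.arcsin(r / 2.0))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def effort_perception_model(
    gln_glu: float, config: CohortConfig, rng: np.random.Generator
) -> float:
    """Effort-perception score for one subject.

    A monotone-decreasing deterministic component in the standardised
    Gln/Glu ratio plus Gaussian noise, passed through a sigmoid so the
    score (perceived fraction of MVC required for success) stays in
    (0, 1).  With zero noise the score is strictly decreasing in the
    ratio; with zero coupling its mean is constant.
    """
    if gln_glu <= 0:
        raise ValueError("gln_glu ratio must be positive")
    z = (gln_glu - config.ratio_mean) / config.ratio_sd
    eta = (
        config.percept_logit_mean
        + config.percept_ratio_coupling * z
        + rng.normal(0.0, config.percept_logit_sd)
    )
    return float(_sigmoid(eta))


def _draw_metabolites(config: CohortConfig, rng: np.random.Generator) -> MetabolitePanel:
    lam = config.glu_gln_factor_loading
    lam_g = config.gaba_factor_loading
    shared = rng.normal()
    glu = config.glu_mean + config.glu_sd * (
        lam * shared + np.sqrt(1 - lam**2) * rng.normal()
    )
    gln = config.gln_mean + config.gln_sd * (
        lam * shared + np.sqrt(1 - lam**2) * rng.normal()
    )
    gaba = config.gaba_mean + config.gaba_sd * (
        lam_g * shared + np.sqrt(1 - lam_g**2) * rng.normal()
    )
    # truncate at a small positive floor (effectively never triggered at
    # the default scales)
    glu, gln, gaba = (max(v, 1e-3) for v in (glu, gln, gaba))
    return MetabolitePanel(glu=float(glu), gln=float(gln), gaba=float(gaba))


def _clamp(value: float, bounds: tuple, name: str) -> float:
    lo, hi = bounds
    if value < lo or value > hi:
        logger.debug("clamped %s=%.4g to [%g, %g]", name, value, lo, hi)
        return float(np.clip(value, lo, hi))
    return float(value)


def _draw_subject(
    subject_id: str,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    with_trials: bool,
) -> ParticipantRecord:
    comp = 1.0 if group == "competition" else 0.0
    panel = _draw_metabolites(config, rng)
    z = (panel.gln_glu - config.ratio_mean) / config.ratio_sd

    alpha = _clamp(
        float(np.exp(rng.normal(config.log_alpha_mean, config.log_alpha_sd))),
        config.alpha_bounds,
        "alpha",
    )
    if comp:
        beta_raw = rng.normal(config.beta_mean_comp, config.beta_sd_comp)
    else:
        beta_raw = rng.normal(config.beta_mean_iso, config.beta_sd_iso)
    beta = _clamp(float(beta_raw), config.beta_bounds, "beta")
    b = float(
        config.b_mean_iso
        + comp * (config.b_group_shift + config.b_group_ratio_interaction * z)
        + rng.normal(0.0, config.b_sd)
    )
    spr_logit0 = config.spr_logit_comp if comp else config.spr_logit_iso
    eps_spr = float(
        _sigmoid(
            spr_logit0
            + config.spr_ratio_coupling * z
            + rng.normal(0.0, config.spr_logit_sd)
        )
    )
    end_logit0 = config.end_logit_comp if comp else config.end_logit_iso
    eps_end = float(
        _sigmoid(
            end_logit0
            + config.end_ratio_coupling * z
            + rng.normal(0.0, config.end_logit_sd)
        )
    )
    percept = effort_perception_model(panel.gln_glu, config, rng)
    params = ModelParameters(alpha, beta, b, eps_spr, eps_end)

    trials = pms = None
    if with_trials:
        sched_seed = int(rng.integers(2**31))
        trial_seed = int(rng.integers(2**31))
        trials = simulate_trials(params, build_schedule(sched_seed), trial_seed)
        pms = summarize(trials)
    return ParticipantRecord(
        subject_id=subject_id,
        group=group,
        metabolites=panel,
        effort_perception=percept,
        true_params=params,
        trials=trials,
        pms=pms,
    )


def generate_cohort(config: CohortConfig, with_trials: bool = True) -> list:
    """Generate the full synthetic cohort, bit-identically per seed.

    Subjects are produced isolation-first (defaults 15 isolation, 12
    competition), each from an independent child seed of the master
    seed.  ``with_trials=False`` skips the 80-trial simulation (and
    leaves ``trials``/``pms`` unset) for analyses that only need the
    latent structure.
    """
    n_total = config.n_isolation + config.n_competition
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    cohort = []
    for i, ss in enumerate(children):
        group = "isolation" if i < config.n_isolation else "competition"
        rng = np.random.default_rng(ss)
        cohort.append(
            _draw_subject(f"S{i + 1:03d}", group, config, rng, with_trials)
        )
    return cohort


def participants_frame(cohort) -> pd.DataFrame:
    """Tidy participants table (metabolites, ratios, latent truth)."""
    rows = []
    for p in cohort:
        rows.append(
            {
                "subject_id": p.subject_id,
                "group": p.group,
                "glu": p.metabolites.glu,
                "gln": p.metabolites.gln,
                "gaba": p.metabolites.gaba,
                "gln_glu": p.metabolites.gln_glu,
                "gaba_gln": p.metabolites.gaba_gln,
                "effort_perception": p.effort_perception,
                "alpha": p.true_params.alpha,
                "beta": p.true_params.beta,
                "b": p.true_params.b,
                "eps_spr": p.true_params.eps_spr,
                "eps_end": p.true_params.eps_end,
            }
        )
    return pd.DataFrame(rows)


def pms_frame(cohort) -> pd.DataFrame:
    """Long-format per-cell success-rate table for the whole cohort."""
    from .model_core import INCENTIVES

    rows = []
    for p in cohort:
        if p.pms is None:
            raise ValueError(f"{p.subject_id} has no realised PMs")
        for i, x in enumerate(INCENTIVES):
            for s in range(4):
                rows.append(
                    {
                        "subject_id": p.subject_id,
                        "incentive_chf": x,
                        "session": s + 1,
                        "success_rate": p.pms.values[i, s],
                    }
                )
    return pd.DataFrame(rows)
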