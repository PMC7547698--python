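"""Nested model variants and the cohort-level model comparison.

Three alternatives to the full 5-parameter model are fitted with the
identical search procedure, each with 4 free parameters (df = 12 - 4 = 8):

* ``reduced`` -- a single energy-loss rate: eps_end = eps_spr**2, so the
  session energies are (1, eps_spr, eps_spr**2, eps_spr**3);
* ``fix_spr`` / ``fix_end`` -- one stamina parameter pinned to its
  average population value (the cohort mean of the full-model
  estimates), the rest refitted jointly.

Models are compared by their mean per-subject chi2 and a paired
two-sided t test on the per-subject chi2 differences; the alternative's
mean chi2 is also converted to an upper-tail fit probability at df 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    CohortVariances,
    FitResult,
    SearchConfig,
    chi2_upper_tail,
    fit_cohort,
)
from .model_core import PerformanceMatrix


@dataclass(frozen=True)
class ComparisonResult:
    """Paired full-vs-alternative fit comparison over a cohort."""

    variant: str
    per_subject_chi2: np.ndarray  # (n, 2): columns (full, alternative)
    mean_chi2_full: float
    mean_chi2_alt: float
    paired_t: float
    paired_p: float
    alt_df: int
    alt_p_fit: float  # upper tail of mean_chi2_alt at alt_df

    def summary(self) -> str:
        return (
            f"{self.variant}: mean chi2 = {self.mean_chi2_alt:.3f} "
            f"(= chi2_{self.alt_df}, {self.alt_p_fit:.2f}) vs full mean "
            f"chi2 = {self.mean_chi2_full:.3f}; paired t = "
            f"{self.paired_t:.3f}, p = {self.paired_p:.3f}"
        )


def fit_variant(
    pms: Sequence[PerformanceMatrix],
    sigma2: CohortVariances,
    config: SearchConfig,
    variant: str,
    fixed_value: Optional[float] = None,
    full_fits: Optional[Sequence[FitResult]] = None,
) -> list:
    """Fit a 4-parameter variant to every subject.

    For ``fix_spr``/``fix_end`` the pinned value defaults to the cohort
    mean of the full-model estimates, which must then be supplied via
    ``full_fits``.
    """
    if variant not in ("reduced", "fix_spr", "fix_end"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant.startswith("fix_") and fixed_value is None:
        if full_fits is None:
            raise ValueError(
                "fix_* variants need fixed_value or full_fits to average"
            )
        attr = "eps_spr" if variant == "fix_spr" else "eps_end"
        fixed_value = float(np.mean([getattr(f.params, attr) for f in full_fits]))
    return fit_cohort(pms, sigma2, config, variant=variant, fixed_value=fixed_value)


def compare_models(
    full: Sequence[FitResult], alt: Sequence[FitResult]
) -> ComparisonResult:
    """Paired comparison of per-subject chi2 between full and alternative."""
    if len(full) != len(alt):
        raise ValueError("fit lists must cover the same subjects")
    chi2_full = np.array([f.chi2 for f in full])
    chi2_alt = np.array([f.chi2 for f in alt])
    diff = chi2_full - chi2_alt
    if np.allclose(diff, 0):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(chi2_full, chi2_alt)
        t, p = float(res.statistic), float(res.pvalue)
    alt_df = alt[0].df
    mean_alt = float(chi2_alt.mean())
    return ComparisonResult(
        variant=alt[0].variant,
        per_subject_chi2=np.stack([chi2_full, chi2_alt], axis=1),
        mean_chi2_full=float(chi2_full.mean()),
        mean_chi2_alt=mean_alt,
        paired_t=t,
        paired_p=p,
        alt_df=alt_df,
        alt_p_fit=chi2_upper_tail(mean_alt, alt_df),
    )


def comparison_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy table of comparison statistics, one row per alternative."""
    return pd.DataFrame(
        [
            {
                "variant": r.variant,
                "mean_chi2_full": r.mean_chi2_full,
                "mean_chi2_alt": r.mean_chi2_alt,
                "alt_df": r.alt_df,
                "alt_p_fit": r.alt_p_fit,
                "paired_t": r.paired_t,
                "paired_p": r.paired_p,
                "n": r.per_subject_chi2.shape[0],
            }
            for r in results
        ]
    )
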