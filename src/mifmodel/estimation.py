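"""Chi-square goodness of fit and the stochastic parameter search.

Per-subject fit quality is a weighted sum of squared residuals over the
12 performance measures,

    chi2 = sum_i (PM_i_exp - PM_i_mod)**2 / sigma_i**2,

where sigma_i**2 is the cross-participant variance of PM_i in the cohort
(floored at 1e-4 to guard degenerate cohorts).  A chi-square test with
df = 12 - (number of free parameters) evaluates the fit: 12 - 5 = 7 for
the full model, 12 - 4 = 8 for the reduced and fixed-parameter variants.

Estimation is a Monte-Carlo-like stochastic search in two phases:

* broad phase -- independent draws from per-parameter sampling
  distributions (log-uniform for alpha and beta, uniform for b and the
  stamina fractions).  Draws are generated from a single uniform block so
  that enlarging the budget extends, rather than reshuffles, the
  candidate stream;
* refinement phase -- Gaussian perturbations (in the sampling transform
  space) around the current elite set, with a geometrically decaying
  scale, re-merged with the pool after each batch.

The search returns the best parameter set plus a top-K archive (default
K = 4000) sorted by chi2, with ties broken by draw order; it is fully
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model_core import (
    ModelParameters,
    PARAM_NAMES,
    PerformanceMatrix,
    predict_performance_batch,
)

N_PM = 12
VARIANCE_FLOOR = 1e-4

#: Model variants and their free parameters.
VARIANTS = ("full", "reduced", "fix_spr", "fix_end")

#: Sampling distribution per parameter: (low, high, scale).
#: "log" draws log-uniformly, "lin" uniformly, on [low, high].
DEFAULT_RANGES: Dict[str, Tuple[float, float, str]] = {
    "alpha": (0.05, 4.0, "log"),
    "beta": (0.1, 100.0, "log"),
    "b": (-3.0, 3.0, "lin"),
    "eps_spr": (0.01, 0.999, "lin"),
    "eps_end": (0.01, 0.999, "lin"),
}


@dataclass(frozen=True)
class CohortVariances:
    """Cross-participant variance of each of the 12 PMs (floored)."""

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2, dtype=float)
        if s.shape != (N_PM,):
            raise ValueError(f"expected 12 variances, got shape {s.shape}")
        if np.any(s <= 0):
            raise ValueError("variances must be positive (apply the floor)")
        object.__setattr__(self, "sigma2", s)


@dataclass(frozen=True)
class SearchConfig:
    """Budget and sampling ranges of the stochastic search.

    n_samples is the total candidate count; a refine_fraction of it is
    spent on the elite-perturbation phase, the rest on broad sampling.
    """

    n_samples: int = 200_000
    refine_fraction: float = 0.25
    top_k: int = 4000
    seed: int = 0
    ranges: Dict[str, Tuple[float, float, str]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    n_refine_batches: int = 10
    polish: bool = True
    n_polish_starts: int = 3

    def __post_init__(self) -> None:
        if not self.n_samples >= self.top_k >= 1:
            raise ValueError("need n_samples >= top_k >= 1")
        if not 0 <= self.refine_fraction < 1:
            raise ValueError("refine_fraction must be in [0, 1)")

    @property
    def n_refine(self) -> int:
        return int(self.n_samples * self.refine_fraction)

    @property
    def n_broad(self) -> int:
        return self.n_samples - self.n_refine


@dataclass(frozen=True)
class FitResult:
    """Best-fitting parameters with fit statistics and top-K archive."""

    params: ModelParameters
    chi2: float
    df: int
    p_fit: float
    variant: str = "full"
    archive_params: Optional[np.ndarray] = None  # (top_k, 5)
    archive_chi2: Optional[np.ndarray] = None  # (top_k,)


def cohort_variances(pms: Sequence[PerformanceMatrix]) -> CohortVariances:
    """Sample variance (ddof=1) of each PM across subjects, floored."""
    if len(pms) < 2:
        raise ValueError("need at least 2 subjects to estimate variances")
    mat = np.stack([p.flat() for p in pms])
    s2 = mat.var(axis=0, ddof=1)
    return CohortVariances(np.maximum(s2, VARIANCE_FLOOR))


def chi_square_gof(
    pm_exp: PerformanceMatrix, pm_mod: PerformanceMatrix, sigma2: CohortVariances
) -> float:
    """Weighted sum of squared PM residuals; zero iff exact match."""
    d = pm_exp.flat() - pm_mod.flat()
    return float(np.sum(d * d / sigma2.sigma2))


def chi2_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability P(X > x) of the chi-square distribution."""
    if not (isinstance(df, (int, np.integer)) and df > 0):
        raise ValueError("df must be a positive integer")
    if x < 0:
        raise ValueError("chi-square value must be >= 0")
    return float(stats.chi2.sf(x, df))


def chi2_critical(df: int, tail: float) -> float:
    """Value x with upper-tail probability `tail` at `df` degrees of freedom."""
    if not (isinstance(df, (int, np.integer)) and df > 0):
        raise ValueError("df must be a positive integer")
    if not 0 < tail < 1:
        raise ValueError("tail must be in (0, 1)")
    return float(stats.chi2.isf(tail, df))


# ----------------------------------------------------------------------
# sampling-space transforms
# ----------------------------------------------------------------------


def _to_transform(values: np.ndarray, rng_spec) -> np.ndarray:
    low, high, scale = rng_spec
    if scale == "log":
        return np.log(values)
    return values


def _from_uniform(u: np.ndarray, rng_spec) -> np.ndarray:
    """Map U(0,1) draws to the configured distribution."""
    low, high, scale = rng_spec
    if scale == "log":
        return np.exp(np.log(low) + u * (np.log(high) - np.log(low)))
    return low + u * (high - low)


def _transform_bounds(rng_spec):
    low, high, scale = rng_spec
    if scale == "log":
        return np.log(low), np.log(high)
    return low, high


def draw_parameter_sets(
    n: int,
    rng: np.random.Generator,
    ranges: Dict[str, Tuple[float, float, str]],
    names: Sequence[str],
) -> np.ndarray:
    """Draw an (n, len(names)) parameter matrix from the configured
    distributions.  A single uniform block is drawn row-major so the
    first rows are identical for any larger n under the same generator
    state (budget-prefix property).
    """
    u = rng.random((n, len(names)))
    cols = [_from_uniform(u[:, j], ranges[nm]) for j, nm in enumerate(names)]
    return np.stack(cols, axis=1)


def _free_names(variant: str) -> Tuple[str, ...]:
    if variant == "full":
        return PARAM_NAMES
    if variant == "reduced":
        return ("alpha", "beta", "b", "eps_spr")
    if variant == "fix_spr":
        return ("alpha", "beta", "b", "eps_end")
    if variant == "fix_end":
        return ("alpha", "beta", "b", "eps_spr")
    raise ValueError(f"unknown model variant {variant!r}")


def _expand(mat: np.ndarray, variant: str, fixed_value: Optional[float]) -> dict:
    """Map the free-parameter matrix to full keyword columns."""
    names = _free_names(variant)
    cols = {nm: mat[:, j] for j, nm in enumerate(names)}
    n = mat.shape[0]
    if variant == "full":
        pass
    elif variant == "reduced":
        cols["eps_end"] = cols["eps_spr"] ** 2
    elif variant == "fix_spr":
        cols["eps_spr"] = np.full(n, fixed_value)
    elif variant == "fix_end":
        cols["eps_end"] = np.full(n, fixed_value)
    return cols


def _evaluate(mat, variant, fixed_value, pm_exp_flat, inv_sigma2):
    cols = _expand(mat, variant, fixed_value)
    pred = predict_performance_batch(
        cols["alpha"], cols["beta"], cols["b"], cols["eps_spr"], cols["eps_end"]
    )
    d = pred - pm_exp_flat[None, :]
    return np.einsum("ij,ij,j->i", d, d, inv_sigma2)


def _polish(
    starts_t: np.ndarray,
    names,
    ranges,
    variant,
    fixed_value,
    pm_flat,
    inv_s2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic Nelder-Mead finish from a few stochastic starts.

    Runs in the sampling transform space (log for log-scaled
    parameters) with out-of-range excursions clipped and penalised.
    Returns polished parameter rows (natural scale) and their chi2.
    """
    from scipy import optimize

    lo = np.array([_transform_bounds(ranges[nm])[0] for nm in names])
    hi = np.array([_transform_bounds(ranges[nm])[1] for nm in names])
    is_log = np.array([ranges[nm][2] == "log" for nm in names])

    def natural(row_t):
        row = np.where(is_log, np.exp(row_t), row_t)
        return row

    def objective(row_t):
        clipped = np.clip(row_t, lo, hi)
        penalty = 1e6 * float(np.sum((row_t - clipped) ** 2))
        row = natural(clipped)
        c2 = _evaluate(row[None, :], variant, fixed_value, pm_flat, inv_s2)
        return float(c2[0]) + penalty

    rows, chis = [], []
    for start in starts_t:
        res = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-14},
        )
        row = natural(np.clip(res.x, lo, hi))
        rows.append(row)
        chis.append(
            float(_evaluate(row[None, :], variant, fixed_value, pm_flat, inv_s2)[0])
        )
    return np.stack(rows), np.array(chis)


def stochastic_search(
    pm_exp: PerformanceMatrix,
    sigma2: CohortVariances,
    config: SearchConfig,
    variant: str = "full",
    fixed_value: Optional[float] = None,
) -> FitResult:
    """Fit one subject's 12 PMs by two-phase stochastic search.

    Parameters
    ----------
    pm_exp : PerformanceMatrix
        The subject's observed 12 performance measures.
    sigma2 : CohortVariances
        Cross-participant PM variances weighting the chi2 objective.
    config : SearchConfig
        Budget, archive size, seed and sampling ranges.
    variant : str
        "full" (5 free parameters, df 7), "reduced" (single-stamina,
        eps_end = eps_spr**2), or "fix_spr"/"fix_end" (one stamina pinned
        to `fixed_value`); all non-full variants have 4 free parameters
        and df 8.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    if variant.startswith("fix_") and fixed_value is None:
        raise ValueError(f"variant {variant!r} requires a fixed_value")
    names = _free_names(variant)
    rng = np.random.default_rng(config.seed)
    pm_flat = pm_exp.flat()
    inv_s2 = 1.0 / sigma2.sigma2

    pool_params = draw_parameter_sets(config.n_broad, rng, config.ranges, names)
    pool_chi2 = _evaluate(pool_params, variant, fixed_value, pm_flat, inv_s2)

    n_refine = config.n_refine
    if n_refine > 0:
        lo = np.array([_transform_bounds(config.ranges[nm])[0] for nm in names])
        hi = np.array([_transform_bounds(config.ranges[nm])[1] for nm in names])
        width = hi - lo
        batch = n_refine // config.n_refine_batches
        # elite pool shrinks geometrically from broad (exploration) to a
        # tight neighbourhood of the incumbent (exploitation)
        elite_sizes = np.geomspace(
            max(100, config.n_broad // 100), 50, config.n_refine_batches
        ).astype(int)
        # stable order keeps tie-breaks at draw order under the seed
        order = np.argsort(pool_chi2, kind="stable")[: elite_sizes[0]]
        elite_t = np.stack(
            [
                _to_transform(pool_params[order][:, j], config.ranges[nm])
                for j, nm in enumerate(names)
            ],
            axis=1,
        )
        elite_chi2 = pool_chi2[order]
        extra_p, extra_c = [], []
        for k in range(config.n_refine_batches):
            m = batch if k < config.n_refine_batches - 1 else n_refine - batch * k
            # perturbations follow the full elite covariance (cross-entropy
            # style) so curved, correlated ridges are tracked; a small
            # diagonal jitter keeps the proposal full-rank
            cov = np.cov(elite_t, rowvar=False, ddof=0)
            cov = np.atleast_2d(cov) + np.diag((1e-12 * width) ** 2)
            chol = np.linalg.cholesky(cov)
            parents = elite_t[rng.integers(0, elite_t.shape[0], m)]
            cand_t = parents + rng.normal(0.0, 1.0, (m, len(names))) @ chol.T
            cand_t = np.clip(cand_t, lo, hi)
            cand = np.stack(
                [
                    np.exp(cand_t[:, j])
                    if config.ranges[nm][2] == "log"
                    else cand_t[:, j]
                    for j, nm in enumerate(names)
                ],
                axis=1,
            )
            c2 = _evaluate(cand, variant, fixed_value, pm_flat, inv_s2)
            extra_p.append(cand)
            extra_c.append(c2)
            merged_t = np.vstack([elite_t, cand_t])
            merged_c = np.concatenate([elite_chi2, c2])
            n_elite = elite_sizes[min(k + 1, config.n_refine_batches - 1)]
            keep = np.argsort(merged_c, kind="stable")[:n_elite]
            elite_t, elite_chi2 = merged_t[keep], merged_c[keep]
        pool_params = np.vstack([pool_params] + extra_p)
        pool_chi2 = np.concatenate([pool_chi2] + extra_c)

    if config.polish and config.n_polish_starts > 0:
        lo = np.array([_transform_bounds(config.ranges[nm])[0] for nm in names])
        hi = np.array([_transform_bounds(config.ranges[nm])[1] for nm in names])
        width = hi - lo
        top = np.argsort(pool_chi2, kind="stable")[:200]
        cand_t = np.stack(
            [
                _to_transform(pool_params[top][:, j], config.ranges[nm])
                for j, nm in enumerate(names)
            ],
            axis=1,
        )
        # greedy farthest-point picks give diverse polish starts, so the
        # finish is robust to multimodal chi2 surfaces
        chosen = [0]
        norm = cand_t / width
        while len(chosen) < min(config.n_polish_starts, len(top)):
            d = np.min(
                np.linalg.norm(norm[:, None, :] - norm[None, chosen, :], axis=2),
                axis=1,
            )
            chosen.append(int(np.argmax(d)))
        polished, pol_chi2 = _polish(
            cand_t[chosen], names, config.ranges, variant, fixed_value,
            pm_flat, inv_s2,
        )
        pool_params = np.vstack([pool_params, polished])
        pool_chi2 = np.concatenate([pool_chi2, pol_chi2])

    top_k = min(config.top_k, pool_chi2.size)
    part = np.argpartition(pool_chi2, top_k - 1)[:top_k]
    order = part[np.argsort(pool_chi2[part], kind="stable")]
    # within equal chi2, argpartition may disturb draw order; restore it
    ties = pool_chi2[order]
    if ties.size > 1 and np.any(np.diff(ties) == 0):
        order = order[np.lexsort((order, ties))]
    arch_free = pool_params[order]
    arch_chi2 = pool_chi2[order]
    arch_cols = _expand(arch_free, variant, fixed_value)
    archive = np.stack([arch_cols[nm] for nm in PARAM_NAMES], axis=1)

    best = ModelParameters(**{nm: float(archive[0, j]) for j, nm in enumerate(PARAM_NAMES)})
    df = N_PM - len(names)
    best_chi2 = float(arch_chi2[0])
    return FitResult(
        params=best,
        chi2=best_chi2,
        df=df,
        p_fit=chi2_upper_tail(best_chi2, df),
        variant=variant,
        archive_params=archive,
        archive_chi2=arch_chi2,
    )


def fit_cohort(
    pms: Sequence[PerformanceMatrix],
    sigma2: CohortVariances,
    config: SearchConfig,
    variant: str = "full",
    fixed_value: Optional[float] = None,
) -> list:
    """Fit every subject, deriving independent per-subject seeds."""
    seeds = np.random.SeedSequence(config.seed).spawn(len(pms))
    out = []
    for pm, ss in zip(pms, seeds):
        sub_cfg = replace(config, seed=int(ss.generate_state(1)[0] % (2**31)))
        out.append(stochastic_search(pm, sigma2, sub_cfg, variant, fixed_value))
    return out


def search_stability(run_a: Sequence[FitResult], run_b: Sequence[FitResult]) -> dict:
    """Across-subject agreement of two independent-seed cohort fits.

    For each parameter, the Spearman correlation across subjects between
    the two runs' best estimates.  High values (the reliability bar is
    0.97) indicate a stable search.
    """
    if len(run_a) != len(run_b):
        raise ValueError("runs must cover the same subjects")
    a = np.stack([f.params.as_array() for f in run_a])
    b = np.stack([f.params.as_array() for f in run_b])
    return {
        nm: float(stats.spearmanr(a[:, j], b[:, j]).statistic)
        for j, nm in enumerate(PARAM_NAMES)
    }


def archive_agreement(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Within-subject diagnostic: Spearman correlation, per parameter,
    between two runs' top-K archives paired by chi2 rank.  Exposed as a
    diagnostic only; the cohort-level `search_stability` is the primary
    reliability statistic.
    """
    k = min(fit_a.archive_chi2.size, fit_b.archive_chi2.size)
    return {
        nm: float(
            stats.spearmanr(
                fit_a.archive_params[:k, j], fit_b.archive_params[:k, j]
            ).statistic
        )
        for j, nm in enumerate(PARAM_NAMES)
    }
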