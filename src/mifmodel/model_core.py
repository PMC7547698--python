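"""Core algebra of the effort-based performance model.

A participant in the monetary incentive force (MIF) task squeezes a hand
grip to a fixed force threshold to win a trial-specific monetary reward
(CHF 0.2, 0.5 or 1).  Trial success is modelled in three stages:

1. subjective utility of a trial,  ``u(x) = x**alpha - tau``, combining a
   power-law reward gain with an effort cost ``tau``;
2. effort cost ``tau = b + 2*(1 - E)``, rising as the session energy
   fraction ``E`` is depleted;
3. a sigmoidal performance function
   ``P(success) = 1 / (1 + exp(-u*beta))``.

Energy follows a discrete four-session schedule: sessions 1-2 form block
one and sessions 3-4 block two, separated by a rest break.  Sprint
stamina ``eps_spr`` is the fraction of energy retained across adjacent
sessions within a block; endurance stamina ``eps_end`` is the fraction
retained across the between-block break, so the four session energies are
``(1, eps_spr, eps_end, eps_spr*eps_end)``.  A reduced single-stamina
variant sets ``eps_end = eps_spr**2``, giving energies
``(1, eps_spr, eps_spr**2, eps_spr**3)``.

Composing the three stages over the 3 incentives x 4 sessions grid yields
the model-predicted 3x4 performance matrix of success probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit

#: Incentive levels of the MIF task, in CHF.
INCENTIVES = (0.2, 0.5, 1.0)

#: Number of task sessions (2 blocks x 2 sessions).
N_SESSIONS = 4

#: Canonical order of the five free parameters.
PARAM_NAMES = ("alpha", "beta", "b", "eps_spr", "eps_end")


@dataclass(frozen=True)
class ModelParameters:
    """The five per-subject parameters of the performance model.

    Attributes
    ----------
    alpha : float
        Utility curvature (> 0).  Values below 1 give concave valuation
        of monetary incentives.
    beta : float
        Sigmoidal steepness / inverse temperature (>= 0).  Higher beta
        means less random performance; beta = 0 is the degenerate flat
        model with P = 0.5 everywhere.
    b : float
        Effort-cost baseline, in utility units; lower values mean better
        initial performance.  Unbounded real.
    eps_spr : float
        Sprint stamina, the fraction of energy retained across adjacent
        sessions within a block; in (0, 1].
    eps_end : float
        Endurance stamina, the fraction of energy retained across the
        between-block break; in (0, 1].
    """

    alpha: float
    beta: float
    b: float
    eps_spr: float
    eps_end: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not self.beta >= 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("eps_spr", "eps_end"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def as_array(self) -> np.ndarray:
        """Return (alpha, beta, b, eps_spr, eps_end) as a float array."""
        return np.array([getattr(self, f.name) for f in fields(self)])

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        return cls(*(float(v) for v in np.asarray(arr)))


@dataclass(frozen=True)
class PerformanceMatrix:
    """Success rates over the 3 incentives x 4 sessions task grid.

    ``values[i, s]`` is the success rate (a proportion in [0, 1]) for
    incentive ``INCENTIVES[i]`` in session ``s + 1``.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(INCENTIVES), N_SESSIONS):
            raise ValueError(f"expected shape (3, 4), got {v.shape}")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("success rates must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def flat(self) -> np.ndarray:
        """The 12 performance measures as a flat vector (incentive-major)."""
        return self.values.ravel()

    @property
    def overall(self) -> float:
        """Grand mean success rate over all 12 cells."""
        return float(self.values.mean())


def effort_cost(b, E):
    """Effort cost ``tau = b + 2*(1 - E)``.

    Parameters
    ----------
    b : float or array
        Effort-cost baseline.
    E : float or array
        Session energy as a fraction of initial energy, in [0, 1].

    Returns
    -------
    float or ndarray
        The effort cost; equals ``b`` at full energy and ``b + 2`` at
        complete depletion.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0) or np.any(E > 1):
        raise ValueError("energy fraction E must lie in [0, 1]")
    out = np.asarray(b, dtype=float) + 2.0 * (1.0 - E)
    return out if out.ndim else float(out)


def utility(x, alpha, tau):
    """Subjective utility ``u(x) = x**alpha - tau`` of a trial.

    ``x`` is the monetary incentive in CHF and must be positive
    (fractional powers of non-positive values are undefined here).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("incentive x must be positive")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be > 0")
    out = x**alpha - np.asarray(tau, dtype=float)
    return out if out.ndim else float(out)


def success_probability(u, beta):
    """Sigmoidal performance function ``P = 1 / (1 + exp(-u*beta))``.

    Computed with :func:`scipy.special.expit`, which saturates exactly to
    0/1 for large ``|u*beta|`` instead of overflowing.  ``beta = 0``
    returns 0.5 regardless of utility.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0):
        raise ValueError("beta must be >= 0")
    out = expit(np.asarray(u, dtype=float) * beta)
    return out if out.ndim else float(out)


def session_energies(params: ModelParameters, reduced: bool = False) -> np.ndarray:
    """Energy fractions for the four sessions.

    Full model: ``(1, eps_spr, eps_end, eps_spr*eps_end)``.  Reduced
    single-stamina model: ``(1, eps_spr, eps_spr**2, eps_spr**3)``,
    ignoring ``eps_end``.
    """
    s, e = params.eps_spr, params.eps_end
    if reduced:
        return np.array([1.0, s, s**2, s**3])
    return np.array([1.0, s, e, s * e])


def predict_performance(
    params: ModelParameters,
    incentives=INCENTIVES,
    reduced: bool = False,
) -> PerformanceMatrix:
    """Model-predicted 3x4 performance matrix for one parameter set.

    Entry ``(i, s)`` is the success probability at incentive
    ``incentives[i]`` in session ``s + 1``, obtained by composing the
    energy schedule, the effort-cost function, the utility function and
    the sigmoidal performance function.
    """
    E = session_energies(params, reduced=reduced)
    tau = effort_cost(params.b, E)  # (4,)
    x = np.asarray(incentives, dtype=float)
    u = utility(x[:, None], params.alpha, tau[None, :])  # (3, 4)
    return PerformanceMatrix(success_probability(u, params.beta))


def predict_performance_batch(
    alpha, beta, b, eps_spr, eps_end, incentives=INCENTIVES, reduced: bool = False
) -> np.ndarray:
    """Vectorised model predictions for many candidate parameter sets.

    Each argument is a length-n array; returns an (n, 12) array of
    flattened performance matrices (incentive-major, matching
    :meth:`PerformanceMatrix.flat`).  This is the hot path of the
    stochastic search, so inputs are not validated beyond broadcasting.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    b = np.asarray(b, dtype=float)
    s = np.asarray(eps_spr, dtype=float)
    e = np.asarray(eps_end, dtype=float)
    if reduced:
        e = s**2
    ones = np.ones_like(s)
    E = np.stack([ones, s, e, s * e], axis=-1)  # (n, 4)
    tau = b[:, None] + 2.0 * (1.0 - E)  # (n, 4)
    x = np.asarray(incentives, dtype=float)
    gain = x[None, :] ** alpha[:, None]  # (n, 3)
    u = gain[:, :, None] - tau[:, None, :]  # (n, 3, 4)
    p = expit(u * beta[:, None, None])
    return p.reshape(p.shape[0], -1)
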