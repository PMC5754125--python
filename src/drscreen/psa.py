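"""Probabilistic sensitivity analysis and cost-effectiveness acceptability curves.

Parameter uncertainty is propagated by Monte Carlo: each transition
probability, utility and the disability weight gets a beta distribution
matched by method of moments to its point estimate and 95% CI (sd taken as
CI width / 3.92); the mortality relative risk gets a lognormal on the same
principle; the baseline state distribution gets a Dirichlet whose
concentration is fitted to the widest printed marginal CI; unit costs are
held fixed (the study reports no cost uncertainty). The paper names none of
these families — they are this package's (conventional) choices.

Each iteration draws one parameter set, runs both arms, and records the
incremental cost, QALYs and DALYs. A cost-effectiveness acceptability curve
reports, for each willingness-to-pay threshold, the fraction of iterations
with positive net monetary benefit.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import arm_outcomes, incremental_result
from .lifetable import LifeTable
from .markov import run_cohort
from .parameters import (
    InitialDistribution,
    ModelInputs,
    ParamCI,
    TransitionParams,
    UtilityParams,
)
from .states import Arm

logger = logging.getLogger(__name__)

_Z95 = 3.92  # width of a 95% interval in units of sd
_MAX_RETRIES = 100

DEFAULT_THRESHOLDS = np.arange(0.0, 2001.0, 10.0)
DEFAULT_ITERATIONS = 1000


class DegenerateDistributionError(ValueError):
    """CI width is zero; no spread to fit."""


class InfeasibleMomentsError(ValueError):
    """Implied variance is too large for a beta with the given mean."""


def fit_beta_from_ci(point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Beta shape pair (a, b) with mean ``point`` and sd ``(ci_high-ci_low)/3.92``."""
    if not (0.0 < point < 1.0):
        raise ValueError(f"point must be in (0, 1), got {point!r}")
    if ci_high == ci_low:
        raise DegenerateDistributionError(f"degenerate CI at {point!r}")
    if ci_high < ci_low:
        raise ValueError("ci_high must exceed ci_low")
    sd = (ci_high - ci_low) / _Z95
    var = sd * sd
    if var >= point * (1.0 - point):
        raise InfeasibleMomentsError(
            f"variance {var!r} >= mean*(1-mean) {point * (1 - point)!r}"
        )
    nu = point * (1.0 - point) / var - 1.0
    return point * nu, (1.0 - point) * nu


def fit_lognormal_from_ci(point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """(log-mean, log-sd) with median ``point`` and log-CI width 3.92 log-sd."""
    if point <= 0 or ci_low <= 0:
        raise ValueError("lognormal fit requires positive point and bounds")
    if ci_high == ci_low:
        raise DegenerateDistributionError(f"degenerate CI at {point!r}")
    return math.log(point), (math.log(ci_high) - math.log(ci_low)) / _Z95


def fit_dirichlet_from_cis(init: InitialDistribution) -> np.ndarray:
    """Dirichlet concentration ``alpha = p * nu`` for the baseline distribution.

    ``nu`` is fitted so the marginal sd of the category with the widest
    printed CI matches (width / 3.92); the other marginals follow.
    """
    points = np.array([getattr(init, f).point for f in init._FIELDS])
    widths = np.array([getattr(init, f).width for f in init._FIELDS])
    if np.all(widths == 0):
        raise DegenerateDistributionError("all CI widths are zero")
    i = int(np.argmax(widths))
    var = (widths[i] / _Z95) ** 2
    nu = points[i] * (1.0 - points[i]) / var - 1.0
    if nu <= 0:
        raise InfeasibleMomentsError("widest CI too wide for a Dirichlet fit")
    return points * nu


@dataclass(frozen=True)
class ParameterDistributions:
    """Sampling distributions for every varied parameter.

    Entries are ``("beta", (a, b))``, ``("lognormal", (mu, sigma))``,
    ``("dirichlet", alpha)`` or ``("fixed", value)``; zero-width CIs collapse
    to ``fixed`` pass-throughs.
    """

    transitions: dict
    rr_mortality: tuple
    utilities: dict
    disability_weight: tuple
    initial: tuple

    @classmethod
    def from_inputs(cls, inputs: ModelInputs) -> "ParameterDistributions":
        def prob_dist(p: ParamCI) -> tuple:
            if p.width == 0 or not (0.0 < p.point < 1.0):
                return ("fixed", p.point)
            return ("beta", fit_beta_from_ci(p.point, p.low, p.high))

        tp = inputs.transitions
        transitions = {name: prob_dist(getattr(tp, name)) for name in tp._PROB_FIELDS}
        rr = tp.rr_mortality
        rr_dist = (
            ("fixed", rr.point)
            if rr.width == 0
            else ("lognormal", fit_lognormal_from_ci(rr.point, rr.low, rr.high))
        )
        up = inputs.utilities
        utilities = {name: prob_dist(getattr(up, name)) for name in up._STATE_FIELDS}
        dw_dist = prob_dist(up.disability_weight)
        init = inputs.config.initial_distribution
        try:
            init_dist = ("dirichlet", fit_dirichlet_from_cis(init))
        except DegenerateDistributionError:
            init_dist = ("fixed", np.array([getattr(init, f).point for f in init._FIELDS]))
        return cls(transitions, rr_dist, utilities, dw_dist, init_dist)


def _draw(dist: tuple, rng: np.random.Generator) -> float:
    kind, params = dist
    if kind == "fixed":
        return params
    if kind == "beta":
        return float(rng.beta(*params))
    if kind == "lognormal":
        return float(rng.lognormal(*params))
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_parameter_set(
    dists: ParameterDistributions, rng: np.random.Generator
) -> tuple[TransitionParams, UtilityParams, InitialDistribution, float]:
    """One independent draw of every varied parameter.

    Returns sampled transition parameters, utilities, baseline distribution
    and disability weight; sampled values are stored as zero-width triples.
    """

    def triple(x: float) -> ParamCI:
        return ParamCI(x, x, x)

    tp_kwargs = {name: triple(_draw(d, rng)) for name, d in dists.transitions.items()}
    tp_kwargs["rr_mortality"] = triple(_draw(dists.rr_mortality, rng))
    tp = TransitionParams(**tp_kwargs)

    up_kwargs = {name: triple(_draw(d, rng)) for name, d in dists.utilities.items()}
    dw = _draw(dists.disability_weight, rng)
    up_kwargs["disability_weight"] = triple(dw)
    up = UtilityParams(**up_kwargs)

    kind, params = dists.initial
    probs = rng.dirichlet(params) if kind == "dirichlet" else params
    init = InitialDistribution(**{
        f: triple(float(p)) for f, p in zip(InitialDistribution._FIELDS, probs)
    })
    return tp, up, init, float(dw)


def _ranges_valid(tp: TransitionParams, up: UtilityParams, dw: float) -> bool:
    # range checks only: sampled utilities are drawn independently, so the
    # deterministic bundle's monotonicity requirement is not imposed here
    probs = [getattr(tp, n).point for n in tp._PROB_FIELDS]
    utils = [getattr(up, n).point for n in up._STATE_FIELDS]
    return (
        all(0.0 <= p <= 1.0 for p in probs)
        and tp.rr_mortality.point > 0
        and all(0.0 <= u <= 1.0 for u in utils)
        and 0.0 <= dw <= 1.0
    )


def run_psa(
    inputs: ModelInputs,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    lt: LifeTable | None = None,
) -> pd.DataFrame:
    """Monte Carlo over parameter uncertainty for one scenario.

    Returns a frame with columns ``iteration, delta_cost, delta_qaly,
    delta_daly``. Each iteration uses an independent counter-derived
    substream of ``seed``, so results do not depend on evaluation order.
    """
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1, got {n_iterations!r}")
    if lt is None:
        from .lifetable import bundled_life_table

        lt = bundled_life_table()
    dists = ParameterDistributions.from_inputs(inputs)
    cfg = inputs.config
    screening_cost = inputs.screening_visit_cost()
    treatment_cost = inputs.treatment_visit_cost()

    rows = []
    for i in range(n_iterations):
        rng = np.random.default_rng([seed, i])
        for attempt in range(_MAX_RETRIES):
            tp, up, init, dw = sample_parameter_set(dists, rng)
            if _ranges_valid(tp, up, dw):
                break
            logger.warning("iteration %d: invalid draw, resampling (attempt %d)", i, attempt + 1)
        else:
            raise RuntimeError(f"iteration {i}: no valid parameter draw in {_MAX_RETRIES} tries")
        cfg_i = dataclasses.replace(cfg, initial_distribution=init)
        res = incremental_result(
            arm_outcomes(run_cohort(cfg_i, tp, Arm.INTERVENTION, lt), cfg_i, up, screening_cost, treatment_cost),
            arm_outcomes(run_cohort(cfg_i, tp, Arm.COMPARATOR, lt), cfg_i, up, screening_cost, treatment_cost),
            dw,
            scenario=cfg.name,
        )
        rows.append(
            {
                "iteration": i,
                "delta_cost": res.cost_per_patient,
                "delta_qaly": res.incremental_qalys,
                "delta_daly": res.incremental_dalys_averted,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs.update({"scenario": cfg.name, "seed": seed})
    return out


def ceac(
    samples: pd.DataFrame,
    thresholds: np.ndarray | None = None,
    effect: str = "qaly",
) -> pd.DataFrame:
    """Probability of positive net monetary benefit at each threshold.

    ``effect`` is ``"qaly"`` or ``"daly"``. NMB rule: cost-effective when
    ``threshold * delta_effect - delta_cost > 0``.
    """
    if len(samples) == 0:
        raise ValueError("empty PSA sample set")
    if effect not in ("qaly", "daly"):
        raise ValueError(f"effect must be 'qaly' or 'daly', got {effect!r}")
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    d_eff = samples[f"delta_{effect}"].to_numpy()
    d_cost = samples["delta_cost"].to_numpy()
    nmb = thresholds[:, None] * d_eff[None, :] - d_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"threshold": thresholds, "probability": prob})


def probability_cost_effective(samples: pd.DataFrame, threshold: float, effect: str = "qaly") -> float:
    """CEAC evaluated at a single willingness-to-pay threshold."""
    return float(ceac(samples, np.array([threshold]), effect)["probability"].iloc[0])


def plot_ceac(curves: dict[str, pd.DataFrame], ax=None, title: str | None = None):
    """Plot CEACs (one labelled line per curve). Returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.plot(curve["threshold"], curve["probability"], label=label)
    ax.set_xlabel("willingness-to-pay threshold (US$)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
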