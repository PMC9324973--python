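"""Design power for extreme-tail recall studies.

The chain model: selecting the upper and lower q-tails of a genetic score
that explains r2_grs_bmi of BMI variance separates the groups by a
standardized BMI difference d_BMI; a metabolite for which BMI explains
r2_met_bmi of variance then differs by d_M = sqrt(r2_met_bmi) * d_BMI
standard deviations between groups. Power is that of a two-sided two-sample
t-test with noncentrality d_M * sqrt(n_per_group / 2), evaluated on the
noncentral t distribution, with a Monte Carlo simulator of the full chain as
an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .simulate import expected_tail_difference


def pooled_cohort_sd(sd_male: float, sd_female: float) -> float:
    """Sex-pooled full-cohort SD: sqrt((sd_M^2 + sd_F^2) / 2)."""
    return math.sqrt((sd_male**2 + sd_female**2) / 2.0)


def standardized_bmi_difference(mean_low: float, mean_high: float, sd_reference: float) -> float:
    """(mean_high - mean_low) / sd_reference.

    ``sd_reference`` should be the full-cohort (not within-group) SD; for
    sex-stratified cohort SDs use :func:`pooled_cohort_sd` first. Using the
    full-cohort SD is the documented default because the within-group SDs
    are shrunk by the tail selection itself.
    """
    if sd_reference <= 0:
        raise ValueError(f"sd_reference must be positive, got {sd_reference}")
    return (mean_high - mean_low) / sd_reference


@dataclass(frozen=True)
class DesignPowerSpec:
    """Design parameters for the recall power calculation.

    ``d_bmi`` may be given directly (e.g. from observed group means over the
    cohort SD) or derived from the recall fraction and the score's
    r2_grs_bmi via the closed-form tail difference.
    """

    n_per_group: int
    r2_met_bmi: float
    alpha: float = 0.05
    d_bmi: float | None = None
    q: float | None = None
    r2_grs_bmi: float | None = None

    def resolved_d_bmi(self) -> float:
        if self.d_bmi is not None:
            if self.d_bmi < 0:
                raise ValueError("d_bmi must be >= 0")
            return self.d_bmi
        if self.q is not None and self.r2_grs_bmi is not None:
            return expected_tail_difference(self.q, self.r2_grs_bmi)
        raise ValueError("supply d_bmi directly or both q and r2_grs_bmi")

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 <= self.r2_met_bmi <= 1.0:
            raise ValueError(f"r2_met_bmi must be in [0,1], got {self.r2_met_bmi}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        self.resolved_d_bmi()


def analytic_power(spec: DesignPowerSpec) -> float:
    """Two-sided two-sample t-test power under the chain model."""
    spec.validate()
    d_m = math.sqrt(spec.r2_met_bmi) * spec.resolved_d_bmi()
    n = spec.n_per_group
    ncp = d_m * math.sqrt(n / 2.0)
    df = 2 * n - 2
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    p = float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    if math.isnan(p):  # noncentral-t tails underflow at large ncp
        p = normal_approximation_power(spec)
    return p


def min_r2_for_power(target_power: float, spec: DesignPowerSpec, tol: float = 1e-6) -> float:
    """Smallest r2_met_bmi achieving ``target_power``, by monotone
    root-finding on the analytic power function (power(r2=0) = alpha)."""
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must be in (0,1), got {target_power}")

    def f(r2: float) -> float:
        return analytic_power(_with_r2(spec, r2)) - target_power

    if f(1.0) < 0:
        raise ValueError(f"target power {target_power} unreachable even at r2 = 1")
    if f(0.0) >= 0:
        return 0.0
    return float(optimize.brentq(f, 0.0, 1.0, xtol=tol))


def _with_r2(spec: DesignPowerSpec, r2: float) -> DesignPowerSpec:
    return DesignPowerSpec(
        n_per_group=spec.n_per_group,
        r2_met_bmi=r2,
        alpha=spec.alpha,
        d_bmi=spec.d_bmi,
        q=spec.q,
        r2_grs_bmi=spec.r2_grs_bmi,
    )


def simulate_power(
    spec: DesignPowerSpec,
    n_reps: int = 20000,
    seed: int = 0,
    chunk: int = 2000,
) -> dict:
    """Monte Carlo power of the full chain.

    Per replicate: BMI_z of the low/high groups centred at -+d_BMI/2 with
    unit SD; metabolite = sqrt(r2) * BMI_z + sqrt(1-r2) * noise; pooled
    two-sample t-test at ``alpha``. Returns the rejection fraction with an
    exact (Clopper-Pearson) 95% CI; seed-deterministic.
    """
    spec.validate()
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    d = spec.resolved_d_bmi()
    r2 = spec.r2_met_bmi
    n = spec.n_per_group
    rng = np.random.default_rng(seed)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, 2 * n - 2)
    a, b = math.sqrt(r2), math.sqrt(1.0 - r2)
    rejections = 0
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        bmi_low = rng.standard_normal((m, n)) - d / 2.0
        bmi_high = rng.standard_normal((m, n)) + d / 2.0
        met_low = a * bmi_low + b * rng.standard_normal((m, n))
        met_high = a * bmi_high + b * rng.standard_normal((m, n))
        diff = met_high.mean(axis=1) - met_low.mean(axis=1)
        ss = ((met_low - met_low.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (met_high - met_high.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        se = np.sqrt(ss / (2 * n - 2) * (2.0 / n))
        tvals = diff / se
        rejections += int((np.abs(tvals) > tcrit).sum())
        done += m
    ci = stats.binomtest(rejections, n_reps).proportion_ci(confidence_level=0.95, method="exact")
    return {
        "power": rejections / n_reps,
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "n_reps": n_reps,
        "rejections": rejections,
    }


def power_curve(spec: DesignPowerSpec, r2_grid: np.ndarray) -> "np.ndarray":
    """Analytic power over a grid of r2_met_bmi values (same design)."""
    return np.array([analytic_power(_with_r2(spec, float(r2))) for r2 in r2_grid])


def normal_approximation_power(spec: DesignPowerSpec) -> float:
    """Large-sample closed form Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z),
    used as a numerical cross-check for large groups."""
    spec.validate()
    ncp = math.sqrt(spec.r2_met_bmi) * spec.resolved_d_bmi() * math.sqrt(spec.n_per_group / 2.0)
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))
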