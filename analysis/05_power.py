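#!/usr/bin/env python
"""Design power of the extreme-tail recall study.

Evaluates the chain model (tail selection -> standardized BMI difference ->
metabolite difference scaled by sqrt(R^2)) on the realized group contrast,
writes a power curve, and cross-checks the closed form by Monte Carlo."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from rbgmet.power import (
    DesignPowerSpec,
    analytic_power,
    min_r2_for_power,
    power_curve,
    simulate_power,
    standardized_bmi_difference,
)


def main() -> None:
    s = common.get_study()
    pheno = s.phenotypes.data.set_index("sample_id")
    low = pheno.loc[s.groups.ids("low"), "bmi"]
    high = pheno.loc[s.groups.ids("high"), "bmi"]
    d = standardized_bmi_difference(low.mean(), high.mean(), pheno["bmi"].std())
    n = min(len(low), len(high))
    spec = DesignPowerSpec(n_per_group=n, r2_met_bmi=0.20, alpha=0.05, d_bmi=d)

    grid = np.round(np.arange(0.01, 0.41, 0.01), 2)
    curve = pd.DataFrame({"r2_met_bmi": grid, "power": power_curve(spec, grid)})
    out = common.results_dir() / "05_power_curve.tsv"
    curve.to_csv(out, sep="\t", index=False, float_format="%.4f")

    mc = simulate_power(spec, n_reps=20000, seed=common.SEED)
    print(f"realized standardized BMI tail difference: d = {d:.3f} (n = {n}/group)")
    print(f"power at R^2 = 0.20: {analytic_power(spec):.1%} analytic, "
          f"{mc['power']:.1%} Monte Carlo (95% CI {mc['ci_low']:.1%}-{mc['ci_high']:.1%})")
    print(f"minimum R^2 for 80% power: {min_r2_for_power(0.80, spec):.3f}")

    # the same calculation from a published-style group summary: a 2.78
    # kg/m^2 contrast over a sex-pooled cohort SD of sqrt((4.44^2+5.42^2)/2)
    from rbgmet.power import pooled_cohort_sd

    d_pub = standardized_bmi_difference(0.0, 2.78, pooled_cohort_sd(4.44, 5.42))
    spec_pub = DesignPowerSpec(n_per_group=375, r2_met_bmi=0.20, alpha=0.05, d_bmi=d_pub)
    print(f"\nfrom the published-style summary (d = {d_pub:.3f}): "
          f"power at R^2 = 0.20 = {analytic_power(spec_pub):.1%}, "
          f"minimum R^2 for 80% power = {min_r2_for_power(0.80, spec_pub):.3f}")
    print("(this cohort drew a below-average tail contrast; the design value sits ~2 SD higher)")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
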