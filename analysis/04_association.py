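#!/usr/bin/env python
"""Metabolome-wide association of recall group: the two primary models.

Fits the linear model on every transformed metabolite and the logistic
model on every presence/absence trait, BH-corrects per family, and reports
discoveries against the generator's planted truth."""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from rbgmet.association import run_associations, summarize_associations


def main() -> None:
    s = common.get_study()
    qc = common.get_qc()
    results = run_associations(qc.transformed, qc.presence_absence, qc.raw_filtered, s.groups)
    summary = summarize_associations(results, alpha=0.05)
    hits = summary["hits"]

    rd = common.results_dir()
    hits.to_csv(rd / "04_hits.tsv", sep="\t", index=False, float_format="%.4g")
    summary["volcano"].to_csv(rd / "04_volcano.tsv", sep="\t", index=False, float_format="%.4g")

    truth_hits = set(s.truth.index[s.truth["r2_met_bmi"].abs() > 0])
    found = set(hits["metabolite_id"])
    tp = len(found & truth_hits)
    print(f"tests: {len(results)} ({(results['model'] == 'model1').sum()} linear, {(results['model'] == 'model2').sum()} logistic)")
    print(f"discoveries at BH p < 0.05: {len(hits)} ({tp} true, {len(found) - tp} false)")
    m1 = hits[hits["model"] == "model1"]
    print(f"linear-model effect sizes: |beta| {np.abs(m1['effect']).min():.2f}-{np.abs(m1['effect']).max():.2f} SD units, "
          f"{(m1['effect'] < 0).sum()}/{len(m1)} negative")
    m2 = hits[hits["model"] == "model2"]
    if len(m2):
        r = m2.iloc[0]
        print(f"presence/absence discovery: {r['metabolite_id']} OR = {r['effect']:.2f} "
              f"({r['ci_low']:.2f}-{r['ci_high']:.2f}), BH p = {r['p_adjusted']:.3f}")
    print(f"\ntop of the discovery table:\n{hits.head(8).to_string(index=False, float_format=lambda v: f'{v:.3g}')}")
    print(f"\nwrote {rd / '04_hits.tsv'} and {rd / '04_volcano.tsv'}")


if __name__ == "__main__":
    main()
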