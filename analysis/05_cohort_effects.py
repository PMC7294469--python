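#!/usr/bin/env python
"""Cohort-level adaptation to uncertainty: sensory acuity, memory usage,
and the cost of wrong priors.

Twelve synthetic subjects (four per predictability cohort) behave with
their cohort's typical parameters; each is grid-fitted and reduced to a
sensory-acuity index (sa) and a long-term-memory-usage index (mi).  The
shuffled-prior study then swaps histories between sequences.  Takes a
few minutes.
"""

import json
from pathlib import Path

import pandas as pd

from foragesim.studies import cohort_effects_study, shuffled_prior_study

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohort = cohort_effects_study(seed=0)
rows = [
    {
        "level": s.level,
        "subject": s.index,
        "re_bits": s.re_bits,
        "fit_sw": s.fit.best_params.sw,
        "fit_se": s.fit.best_params.se,
        "fit_md": s.fit.best_params.md_label,
        "best_r": s.fit.best_r,
        "sa": s.sa,
        "mi": s.mi,
    }
    for s in cohort["subjects"]
]
pd.DataFrame(rows).to_csv(OUT / "cohort_effects.csv", index=False)

prior = shuffled_prior_study(seed=0)
summary = {
    "by_level": cohort["by_level"],
    "re_sa_correlation": cohort["re_sa_correlation"],
    "re_mi_correlation": cohort["re_mi_correlation"],
    "shuffled_prior_ratio_randomized": prior["randomized_mean"],
    "shuffled_prior_ratio_repeated": prior["repeated_mean"],
}
(OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

for level, m in cohort["by_level"].items():
    print(
        f"{level:6s}: RE {m['re_bits']:.2f} bits, sa {m['sa']:.3f}, mi {m['mi']:.3f}"
    )
print(
    f"Across subjects, sensory acuity rises with training-set entropy "
    f"(r = {cohort['re_sa_correlation']:.2f}) while long-term memory usage "
    f"falls (r = {cohort['re_mi_correlation']:.2f})."
)
print(
    f"Swapping priors between sequences costs nothing on randomized "
    f"placements (ratio {prior['randomized_mean']:.3f}) but inflates paths on "
    f"repeated ones (ratio {prior['repeated_mean']:.2f})."
)
print(f"-> {OUT / 'cohort_effects.csv'}, {OUT / 'cohort_summary.json'}")
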