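"""Score module perturbation across the synthetic cohort.

Standardizes expression, computes MPS for every module × sample, and
summarizes: how often each module is significantly perturbed, how cleanly
planted activation is labeled, and which modules the cohort-specificity
filter keeps. Writes results/mps_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from pcmkit import SyntheticCohortSpec, cohort_specific_modules, generate, score_cohort
from pcmkit.io import standardize

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    coh = generate(SyntheticCohortSpec(seed=seed))
    z = standardize(coh.expression)
    P = score_cohort(coh.catalog, z, Ne=10, n_rand=200, seed=seed + 100)

    summary = pd.DataFrame({
        "significant_fraction": P.significant.mean(axis=1),
        "mean_abs_mps": P.mps.abs().mean(axis=1),
        "n_plus": (P.mps > 0).sum(axis=1),
        "n_minus": (P.mps < 0).sum(axis=1),
    })
    summary["planted"] = summary.index.str.startswith("planted")
    summary.to_csv(RESULTS / "mps_summary.tsv", sep="\t")

    planted = summary[summary.planted]
    decoys = summary[~summary.planted]
    print("per-module significant fraction: planted "
          f"{planted.significant_fraction.mean():.3f} vs decoys "
          f"{decoys.significant_fraction.mean():.3f} (nominal null 0.01)")

    hits = 0
    for name in coh.truth.planted_names:
        act = coh.truth.activation.loc[name]
        row = P.mps.loc[name]
        hits += ((row[act.values == 1] > 0).mean()
                 + (row[act.values == -1] < 0).mean()) / 2
    print(f"mean correct polarity labeling of activated samples: "
          f"{hits / len(coh.truth.planted_names):.3f}")

    specific = cohort_specific_modules(P)
    print(f"cohort-specific filter keeps {len(specific)} modules "
          "(it selects constitutively perturbed, low-variance modules; "
          "subset-activated planted modules are bimodal across patients "
          "and are expected to fall outside it)")


if __name__ == "__main__":
    main()
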