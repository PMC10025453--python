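"""Cross-validated discovery of prognostic cancer modules.

Runs the full 3-fold protocol on the planted cohort (training-fold
standardization, boundary propagation, empirical-FDR gates, full-cohort
Cox check) and reports which planted effect levels are recovered and how
many decoys slip through. Writes results/pcm_decisions.tsv and
results/recovery_report.tsv.
"""

from pathlib import Path

import pandas as pd

from pcmkit import SyntheticCohortSpec, decisions_to_frame, discover_pcms, generate
from pcmkit.simulate import recoverability_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    coh = generate(SyntheticCohortSpec(seed=seed))
    decisions = discover_pcms(coh.expression, coh.catalog, coh.outcomes,
                              Ne=10, n_rand=200, n_null=500, seed=seed + 200)
    frame = decisions_to_frame(decisions)
    frame.to_csv(RESULTS / "pcm_decisions.tsv", sep="\t", index=False)

    rep = recoverability_report(coh.truth, decisions, coh.catalog)
    rep.per_module.to_csv(RESULTS / "recovery_report.tsv", sep="\t")

    pcms = frame[frame.is_pcm]
    print(f"{len(frame)} (module, arm-size) stratifications evaluated; "
          f"{pcms.module.nunique()} modules pass all gates")
    print(f"sensitivity {rep.sensitivity:.2f} over "
          f"{rep.n_planted} planted modules; decoy pass rate "
          f"{rep.decoy_pass_rate:.3f} over {rep.n_decoys} decoys")
    print(f"Spearman(planted log-HR, |Wald z|) = {rep.spearman_beta_z:.2f}")
    planted = frame[frame.module.str.startswith("planted")]
    print(planted[["module", "group_size", "test_fdr", "full_fdr",
                   "full_cox_p", "full_wald_z", "is_pcm"]].to_string(index=False))


if __name__ == "__main__":
    main()
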