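"""Group statistics on the extracted microstate parameters.

Reads results/run/metrics.tsv (from 02), runs per-parameter-and-state
one-way ANOVAs with FDR-corrected pooled-t post hocs and Cohen's d, scores
the questionnaire into its ten domains, and correlates the C-like state's
occurrence with the visual-thought domain. Writes statistics.tsv and
arsq_domains.tsv next to the metrics.
"""

import sys
from pathlib import Path

import pandas as pd

import mstates as ms
from mstates import io as msio

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "results" / "run"


def main(seed: int = 1) -> None:
    metrics = msio.read_metrics(RUN / "metrics.tsv")
    report = ms.group_comparison_report(metrics)
    report.to_csv(RUN / "statistics.tsv", sep="\t", index=False)

    match = pd.read_csv(RUN / "template_match.tsv", sep="\t")
    label = match.loc[match.planted_state == 2, "recovered_label"].iloc[0]
    panel = report[(report.parameter == "duration_ms")
                   & (report.state == label)]
    print(f"duration panel for the C-like state ({label}):")
    print(panel[["test", "group_a", "group_b", "statistic",
                 "p_raw", "p_fdr", "cohens_d"]].round(4).to_string(index=False))

    items = pd.read_csv(RUN / "questionnaire.tsv", sep="\t", index_col=0)
    domains = ms.arsq_domains(items)
    domains.to_csv(RUN / "arsq_domains.tsv", sep="\t")
    occ = (metrics[metrics.state == label]
           .set_index("subject_id")["occurrence_per_s"]
           .reindex(domains.index))
    r, p = ms.pearson_corr(occ.to_numpy(), domains["visual_thought"].to_numpy())
    print(f"\noccurrence({label}) vs visual-thought domain: "
          f"r = {r:.3f}, p = {p:.4f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
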