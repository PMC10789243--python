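"""Merge the CGEM and TargOpt rankings into a triage list with flags.

The two engines were run on different simulated evidence (expression
library vs target catalogue), so their drug vocabularies overlap only
where a pair is named by both; pairs surfaced by one engine only carry
the single_method_only flag and a worst-rank penalty.  A small demo
drug-drug-interaction blocklist and mechanism map exercise the
annotation flags.
"""

from pathlib import Path

import pandas as pd

from combopredict.prioritize import aggregate_ranks, annotate, predictions_frame

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cgem = pd.read_csv(BASE / "cgem_ranking.tsv", sep="\t").sort_values("rank")
    targopt = pd.read_csv(BASE / "targopt_ranking.tsv", sep="\t").sort_values("rank")
    preds = aggregate_ranks(
        list(zip(cgem.compound_a.astype(str), cgem.compound_b.astype(str)))[:100],
        list(zip(targopt.drug_a.astype(str), targopt.drug_b.astype(str))))
    preds = annotate(
        preds,
        ddi_blocklist=[("drugA", "drug003")],
        mechanism_map={"drug001": "PDE inhibitor", "drug002": "PDE inhibitor"})
    frame = predictions_frame(preds)
    frame.to_csv(BASE / "predictions.tsv", sep="\t", index=False,
                 float_format="%.10g")
    flag_col = frame["flags"].astype(str)
    flagged = frame[flag_col.str.contains("ddi_alert|same_mechanism")]
    print(f"aggregated {len(preds)} candidate pairs "
          f"({int(flag_col.str.contains('single_method_only').sum())} "
          "from a single method)")
    print(f"pairs with triage alerts: {len(flagged)}")
    print("top of list:")
    print(frame.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
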