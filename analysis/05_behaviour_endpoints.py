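"""Compute behavioural endpoints and per-group summary tables.

Applies the discrimination-index formula with the 3-s minimum-exploration
inclusion rule to the NOR groups and the 300-s maximal-latency censoring
rule to the hyponeophagia groups, then summarizes each group
(mean +/- SEM), the form consumed by downstream inferential statistics.
"""

from pathlib import Path

from combopredict.behaviour import (compute_endpoints, endpoints_frame,
                                    read_trials, summarize_groups)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    trials = read_trials(BASE / "inputs" / "trials.tsv")
    records = compute_endpoints(trials)
    endpoints_frame(records).to_csv(BASE / "endpoints.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    summary = summarize_groups(records)
    summary.to_csv(BASE / "endpoint_summary.tsv", sep="\t", index=False,
                   float_format="%.10g")
    n_excluded = sum(not r.included for r in records)
    n_censored = sum(r.censored for r in records)
    print(f"{len(records)} endpoints; {n_excluded} excluded by the 3-s rule; "
          f"{n_censored} censored at the 300-s maximum")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
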