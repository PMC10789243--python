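"""Generate the synthetic study inputs with planted ground truth.

Emits, under results/inputs/: a 50-compound x 978-gene z-score library
(GCT) with a disease signature reverse-engineered from the planted pair
cpd001+cpd002 under mild measurement noise (sigma=0.1), a 12-drug target
catalogue in which drugA+drugB jointly covers all five disease targets
with zero off-targets, and a six-group behavioural cohort (n=10/group).
"""

from pathlib import Path

import pandas as pd

from combopredict import sigio, synthetic as syn
from combopredict.behaviour import trials_frame

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    lib = syn.generate_library(m=50, n=978, seed=SEED)
    disease, truth = syn.plant_reversal(lib, ("cpd001", "cpd002"),
                                        n_up=50, n_down=50, sigma=0.1,
                                        seed=SEED)
    sigio.write_gct(lib, OUT / "library.gct")
    sigio.write_gmt(disease, OUT / "disease.gmt")
    print(f"library: {len(lib)} compounds x {len(lib.universe)} genes; "
          f"planted reversing pair {'+'.join(truth.planted_pair)} "
          f"(sigma={truth.noise_sigma})")

    cat = syn.generate_target_catalog(n_drugs=12, n_disease_targets=5,
                                      n_decoy_targets=6,
                                      planted_pair=("drugA", "drugB"),
                                      seed=SEED)
    rows = [(d, t, dirn) for d in sorted(cat.drug_targets)
            for t, dirn in sorted(cat.drug_targets[d])]
    pd.DataFrame(rows, columns=["drug_id", "target_id", "direction"]).to_csv(
        OUT / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(cat.disease_targets.items()),
                 columns=["target_id", "desired_direction"]).to_csv(
        OUT / "disease_targets.tsv", sep="\t", index=False)
    print(f"target catalogue: {len(cat.drug_targets)} drugs, "
          f"{len(cat.disease_targets)} disease targets; planted drugA+drugB")

    trials = syn.generate_behaviour_cohort(syn.default_behaviour_spec(),
                                           seed=SEED)
    trials_frame(trials).to_csv(OUT / "trials.tsv", sep="\t", index=False)
    print(f"behavioural cohort: {len(trials)} trials across 6 groups")


if __name__ == "__main__":
    main()
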