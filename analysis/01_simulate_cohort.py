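"""Simulate the training cohort for the signature analysis.

Generates a 300-sample, 55-gene expression cohort with five planted
prognostic genes (conditional hazard ratios 2 or 0.5 acting through the
above-cutpoint indicator), exponential baseline survival and ~70%
observed events, then writes the expression matrix, survival table,
candidate list and ground truth under results/cohort/.
"""

import json
from pathlib import Path

import numpy as np

from ezscore.io import write_expression, write_manifest, write_survival
from ezscore.simulate import PlantedGene, generate_cohort

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

PLANTED = [
    PlantedGene("G0000", np.log(2)),
    PlantedGene("G0001", np.log(0.5)),
    PlantedGene("G0002", np.log(2)),
    PlantedGene("G0003", np.log(0.5)),
    PlantedGene("G0004", np.log(2)),
]


def main() -> None:
    expr, surv, truth = generate_cohort(
        n_samples=300, n_genes=55, planted=PLANTED, seed=SEED, event_fraction=0.7
    )
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression(expr, OUT / "expression.tsv")
    write_survival(surv, OUT / "survival.csv")
    (OUT / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    (OUT / "candidates.txt").write_text("\n".join(expr.index) + "\n")
    write_manifest(OUT, {"step": "simulate", "seed": SEED, "n_samples": 300,
                         "n_genes": 55, "event_fraction": 0.7})
    print(f"cohort: {expr.shape[1]} samples x {expr.shape[0]} genes, "
          f"{surv.n_events} events ({surv.event.mean():.0%})")
    print(f"planted genes: {[g for g, _, _ in truth.planted]}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
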