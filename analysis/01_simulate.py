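#!/usr/bin/env python
"""Generate the study's synthetic perturbation library.

Writes a 200-compound, 5-replicate, 1,000-gene library with 20 planted
query-concordant compounds and one planted drug-target feature among 100
size-matched decoys per category, under results/bundle/.  The bundle is
fully determined by SEED; truth.json records the planted ground truth.
"""

from pathlib import Path

from chemoconnect import SimulationConfig
from chemoconnect.pipeline import cmd_simulate

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"

if __name__ == "__main__":
    cfg = SimulationConfig(seed=SEED)
    bundle = cmd_simulate(OUT, cfg, force=True)
    print(f"wrote bundle to {OUT}")
    print(f"  {cfg.n_compounds} compounds x {cfg.n_replicates} replicates, "
          f"{cfg.n_genes} genes")
    print(f"  planted compounds: {sorted(bundle.truth.planted_compounds)}")
    print(f"  query: {len(bundle.query.up)} up / {len(bundle.query.down)} down genes")
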