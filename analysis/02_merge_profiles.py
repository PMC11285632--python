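#!/usr/bin/env python
"""Merge replicate rank profiles into prototype ranked lists (PRLs).

Each compound's replicates are aggregated by greedy closest-pair Borda
merging under the normalized Spearman footrule, yielding one representative
ranking per compound in results/bundle/prl.tsv.
"""

from pathlib import Path

from chemoconnect.io import read_prl_matrix
from chemoconnect.pipeline import cmd_merge

BUNDLE = Path(__file__).resolve().parent.parent / "results" / "bundle"

if __name__ == "__main__":
    out = cmd_merge(BUNDLE / "profiles.tsv", BUNDLE, force=True)
    prls = read_prl_matrix(out)
    print(f"wrote {out}")
    print(f"  {len(prls)} prototype ranked lists, "
          f"{next(iter(prls.values())).ranking.universe.size} genes each")
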