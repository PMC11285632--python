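#!/usr/bin/env python
"""Chemogenomic enrichment of drug features over the compound ranking.

Tests every target / off-target / side-effect feature for concentration
among the most query-similar compounds (running-sum ES, 10,000-permutation
two-tailed p, BH adjustment within category).  The planted target feature
should be the top hit in its category; decoys should be null.
"""

import json
from pathlib import Path

from chemoconnect.pipeline import FEATURE_FILES, cmd_enrich

BUNDLE = Path(__file__).resolve().parent.parent / "results" / "bundle"
SEED = 1

if __name__ == "__main__":
    out = cmd_enrich(
        BUNDLE / "connectivity.tsv",
        {cat: BUNDLE / name for cat, name in FEATURE_FILES.items()},
        BUNDLE, n_perm=10_000, seed=SEED, force=True,
    )
    planted_id = json.loads((BUNDLE / "truth.json").read_text())["planted_feature_id"]
    print(f"wrote {out}")
    print("top feature per category (category, feature, ES, p, p_adj):")
    seen = set()
    for line in out.read_text().splitlines()[1:]:
        cat, fid, m, es, p, padj = line.split("\t")
        if cat not in seen:  # output is sorted by (category, p_adj)
            seen.add(cat)
            tag = " <- planted" if fid == planted_id else ""
            print(f"  {cat:12s} {fid:24s} ES={es} p={p} p_adj={padj}{tag}")
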