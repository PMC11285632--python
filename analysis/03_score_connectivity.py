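#!/usr/bin/env python
"""Score and rank compound connectivity with the query signature.

Each PRL is scored with the bidirectional KS running sum against the
query's up/down gene sets; compounds are ranked by descending connectivity.
With planted compounds present, they should dominate the head of
results/bundle/connectivity.tsv.
"""

import json
from pathlib import Path

from chemoconnect.pipeline import cmd_score

BUNDLE = Path(__file__).resolve().parent.parent / "results" / "bundle"

if __name__ == "__main__":
    out = cmd_score(BUNDLE / "prl.tsv", BUNDLE, query_list=BUNDLE / "query.tsv",
                    force=True)
    planted = set(json.loads((BUNDLE / "truth.json").read_text())["planted_compounds"])
    lines = out.read_text().splitlines()
    print(f"wrote {out}")
    print("top 10 compounds by connectivity score:")
    n_planted_top = 0
    for line in lines[1:11]:
        rank, cid, es_up, es_down, score = line.split("\t")
        tag = " (planted)" if cid in planted else ""
        n_planted_top += cid in planted
        print(f"  {rank:>3} {cid} score={score}{tag}")
    top_n = {l.split("\t")[1] for l in lines[1 : 1 + len(planted) + 5]}
    print(f"planted compounds in top {len(planted) + 5}: "
          f"{len(planted & top_n)}/{len(planted)}")
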