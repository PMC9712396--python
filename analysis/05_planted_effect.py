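"""Recover a planted between-subnetwork group effect.

Fifty replicate cohorts (n=300, 15% high-OCS prevalence) each carry a 0.3
reduction of the community-pair (1,2) between-coupling in the high-OCS
group. The subnetwork inference family (high-OCS contrast, covariate
adjusted, BH-FDR over 10 tests) should reject the targeted pair far more
often than any other. Writes per-pair rejection counts to results/tables/.
"""

from pathlib import Path

import pandas as pd

from ocsnet.experiments import planted_effect_rejections

ROOT = Path(__file__).resolve().parents[1]
SEED = 20_240_105

counts = planted_effect_rejections(n_cohorts=50, n_subjects=300, seed=SEED)
rows = [
    {"community_a": a, "community_b": b, "rejections": c, "n_cohorts": 50}
    for (a, b), c in sorted(counts.items())
]
out = ROOT / "results" / "tables"
out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(out / "planted_effect_rejections.tsv", sep="\t", index=False)

modal = max(counts, key=counts.get)
print("FDR rejections per community pair over 50 cohorts:")
for (a, b), c in sorted(counts.items()):
    mark = " <- planted target" if (a, b) == (1, 2) else ""
    print(f"  pair ({a},{b}): {c}{mark}")
print(f"modal rejection: pair {modal} "
      f"({'matches' if modal == (1, 2) else 'DOES NOT match'} the planted target)")
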