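"""Validate the community-detection stack against exact oracles.

Two checks: (1) the greedy modularity optimizer attains the exhaustive
maximum over all 4140 partitions of random 8-node graphs; (2) consensus
clustering recovers the planted 5-community structure (ARI = 1) on
high-contrast synthetic cohorts. Writes rates to results/tables/.
"""

from pathlib import Path

import pandas as pd

from ocsnet.experiments import consensus_recovery_rate, louvain_oracle_agreement

ROOT = Path(__file__).resolve().parents[1]
SEED = 20_240_103

oracle = louvain_oracle_agreement(n_graphs=50, seed=SEED)
recovery = consensus_recovery_rate(n_cohorts=20, n_subjects=20, n_nodes=60, seed=SEED)

out = ROOT / "results" / "tables"
out.mkdir(parents=True, exist_ok=True)
pd.DataFrame(
    {
        "check": ["exhaustive_partition_agreement", "planted_partition_recovery"],
        "rate": [oracle, recovery],
        "n": [50, 20],
    }
).to_csv(out / "partition_validation.tsv", sep="\t", index=False)
print(f"optimizer matches exhaustive 8-node maximum on {oracle:.0%} of 50 graphs")
print(f"consensus recovers planted 5-community structure on {recovery:.0%} of 20 cohorts")
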