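"""MAF-matched eQTL-enrichment Z test and the per-TF count null.

The observed SNP set's eQTL-significant count is compared against random SNP
sets matched to its minor-allele-frequency spectrum:
Z = (observed - null mean) / null sd, P = Phi(-|Z|).
"""

import numpy as np
import pandas as pd

from regvar.enrichment import SNPPool, eqtl_enrichment_z, tf_count_null, tf_null_to_frame

rng = np.random.default_rng(42)
n = 4000
pool_df = pd.DataFrame(
    {
        "snp_id": [f"p{i}" for i in range(n)],
        "maf": rng.uniform(0.02, 0.5, size=n),
        "eqtl_flag": rng.random(n) < 0.3,  # 30% base eQTL rate
        "tf": rng.choice(["TFA", "TFB", "TFC"], size=n),
    }
)

# plant a doubled eQTL rate inside a 132-SNP observed set
obs_idx = rng.choice(n, size=132, replace=False)
flags = pool_df["eqtl_flag"].to_numpy().copy()
flags[obs_idx] = rng.random(132) < 0.6
pool = SNPPool.from_frame(pool_df.assign(eqtl_flag=flags))

result = eqtl_enrichment_z(pool, pool_df["snp_id"].iloc[obs_idx], n_sims=10_000, seed=1)
print(
    f"observed {result.observed} eQTL SNPs vs null {result.null_mean:.1f} "
    f"+/- {result.null_sd:.1f}: Z = {result.z:.2f}, P = {result.p:.2e}"
)
# Z far above 3: the planted 2x enrichment is detected against the
# frequency-matched null.

tf_null = tf_count_null(
    pool_df, m=132, observed_counts={"TFA": 60, "TFB": 40, "TFC": 32}, n_sims=1000, seed=2
)
print("\nper-TF count null (1000 draws of 132 SNPs):")
print(tf_null_to_frame(tf_null).to_string(index=False))
# With equal TF shares the null mean is 44 per TF; the inflated TFA
# observation gets a small add-one empirical p, the others do not.
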