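"""Allele-specific expression tests and LD partner screening.

ASE: exact two-sided binomial test of ref/alt read counts against a 0.5
null; sites with p < 0.001 show allelic imbalance. LD: partners of an index
variant are variants within 1 Mb whose squared dosage correlation reaches 0.3.
"""

import numpy as np

from regvar.eqtl_ase import binomial_ase, ld_partners

for ref, alt in [(25, 25), (15, 1), (40, 10), (48, 2)]:
    p = binomial_ase(ref, alt)
    verdict = "imbalanced" if p < 0.001 else "balanced"
    print(f"ref {ref:>2} / alt {alt:>2}: binomial p = {p:.3e} -> {verdict}")
# 15 vs 1 sits just under the 0.001 rule (p = 34/65536); 25 vs 25 is the
# null mode and gives p = 1 exactly.

rng = np.random.default_rng(0)
index = rng.binomial(2, 0.3, size=500)
near_copy = np.where(rng.random(500) < 0.03, rng.binomial(2, 0.3, 500), index)
unrelated = rng.binomial(2, 0.3, size=500)
partners = ld_partners(
    ["rsIndex", "rsCopy", "rsRandom"],
    np.array([0, 5_000, 8_000]),
    np.array([index, near_copy, unrelated]),
    "rsIndex",
)
for r in partners:
    print(f"{r.snp_b}: r2 = {r.r2:.3f} at {r.distance_bp} bp")
print("(the independent variant falls below r2 = 0.3 and is not listed)")
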