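"""Score genotypes with a base linear phenotypic selection index.

Loads the bundled grasspea genotype means (days to maturity, biological
yield, seed yield), combines them into one index per genotype with explicit
economic weights, and prints the five best genotypes. A negative weight on
maturity rewards earliness.
"""

from metgge import IndexSpec, blpsi
from metgge.datasets import load_genotype_means

df = load_genotype_means().set_index("genotype")
spec = IndexSpec(["DTM", "BY", "SY"], weights=[-1.0, 50.0, 1.0])
index = blpsi(df[["DTM", "BY", "SY"]], spec)

top = index.sort_values(ascending=False).head(5)
print("top genotypes by index (-1*DTM + 50*BY + 1*SY):")
for geno, value in top.items():
    print(f"  {geno:<5}{df.loc[geno, 'name']:<16}{value:>10.2f}")
# High-index genotypes combine early maturity with high biomass and seed
# yield; the weights are the breeder's explicit trade-off, not a fit.
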