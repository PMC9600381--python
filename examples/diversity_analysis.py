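"""Producer abundance vs community diversity on simulated communities.

Rarefies samples to even depth, computes Shannon diversity and the
cumulative relative abundance of producer species (CPC), groups samples by
CPC quartiles, and tests the association with rank statistics.
"""

import numpy as np

from cobashare import community_stats as cst

rng = np.random.default_rng(3)
species = ["Corynebacterium_A", "Corynebacterium_B"] + [
    f"Species_{i}" for i in range(8)]
producers = {"Corynebacterium_A", "Corynebacterium_B"}

shannon, cpc = [], []
for k in range(80):
    evenness = (k + 1) / 81
    alpha = np.ones(10) * evenness + (1 - evenness) * np.eye(10)[4]
    rel = rng.dirichlet(alpha * 40 + 1e-3)
    rel[:2] += evenness * 0.05
    rel /= rel.sum()
    counts = rng.multinomial(40_000, rel)
    rare = cst.rarefy(counts, depth=20_000, seed=int(rng.integers(1 << 30)))
    p = rare / rare.sum()
    shannon.append(cst.shannon(p))
    cpc.append(cst.cpc_abundance(dict(zip(species, p)), producers))

rho = cst.rank_tests({"cpc": cpc, "shannon": shannon}, design="spearman")
print(f"Spearman rho (CPC abundance vs Shannon): {rho.statistic:.3f} "
      f"(p = {rho.pvalue:.2e})")

labels = cst.quartile_grouping(cpc)
groups = {}
for lab, h in zip(labels, shannon):
    groups.setdefault(lab, []).append(h)
print("samples per CPC quartile group:",
      {k: len(v) for k, v in sorted(groups.items())})
kw = cst.rank_tests(groups)
print(f"Kruskal-Wallis H = {kw.statistic:.2f}, p = {kw.pvalue:.2e}")
print("Dunn-Bonferroni pairwise (Low/Mid/High Shannon):")
print(kw.pairwise.to_string(index=False))

bc = cst.bray_curtis(np.array([
    rng.dirichlet(np.ones(10)) for _ in range(4)]))
print(f"\nsqrt-Bray-Curtis between 4 random communities (mean off-diagonal): "
      f"{bc[np.triu_indices(4, 1)].mean():.3f}")
# A positive rho with small p says diversity rises with producer abundance in
# these planted communities; the Dunn table localizes which quartile groups
# differ.
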