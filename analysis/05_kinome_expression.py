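#!/usr/bin/env python
"""Kinome expression: normalization, tiers, differential kinases, RTK ranking.

Normalizes the 487-kinase count matrix from 01 with median-of-ratios size
factors, log2-transforms, cuts the Chebyshev/complete-linkage dendrogram
into high/medium/low tiers, screens for kinases differentially expressed
in Chor-IN-1 vs the other four lines (p < 0.05, |FC| > 2), and ranks a
receptor-tyrosine-kinase subset.
"""

from pathlib import Path

from chorline import io as cio
from chorline import kinome
from chorline.simulate import DEFAULT_DOWN_GENES, DEFAULT_UP_GENES

DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"
OUT = DATA.parent.parent / "results" / "kinome"
OUT.mkdir(parents=True, exist_ok=True)

counts = cio.read_counts(DATA / "kinome_counts.tsv")
factors = kinome.size_factors(counts)
print("size factors:", ", ".join(f"{s}={f:.3f}" for s, f in factors.items()))

expr = kinome.normalize_log2(counts, factors)
cio.write_counts(expr.round(4), OUT / "expression_log2.tsv")

tiers = kinome.assign_tiers(expr)
tiers.tiers.to_csv(OUT / "tiers.tsv", sep="\t", header=True)
sizes = tiers.tiers.value_counts()
expressed = sizes.get("high", 0) + sizes.get("medium", 0)
print(f"tiers: {sizes.to_dict()}; {100 * expressed / len(expr):.0f}% of kinases "
      "in the medium or high tier")

diff = kinome.differential_one_vs_rest(expr, "Chor-IN-1")
diff.to_csv(OUT / "differential_Chor-IN-1.tsv", sep="\t")
hits = diff[diff["significant"]]
print(f"\ndifferential in Chor-IN-1 (p < 0.05, |FC| > 2): {len(hits)} kinases")
print(hits[["log2_fc", "p_value", "p_adj"]].round(4).to_string())
up = [g for g in DEFAULT_UP_GENES if diff.loc[g, "significant"] and diff.loc[g, "log2_fc"] > 0]
down = [g for g in DEFAULT_DOWN_GENES if diff.loc[g, "significant"] and diff.loc[g, "log2_fc"] < 0]
print(f"recovered up: {up}; down: {down}")

rtk_like = list(DEFAULT_DOWN_GENES) + ["ULK4", "NPR1"]
ranked = kinome.rank_genes(expr, rtk_like)
ranked.round(3).to_csv(OUT / "rtk_ranking.tsv", sep="\t")
print(f"\nRTK-style ranking (high to low): {', '.join(ranked.index)}")
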