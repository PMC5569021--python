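#!/usr/bin/env python
"""Variant filtering, somatic subtraction and cross-sample similarity.

Applies the exclusion cascade (synonymous / dbSNP MAF > 2% / DP < 20 /
ADV < 7) to the cell, tumor and normal call sets from 01, identifies the
tumor-unique (somatic) variants as (cell ∩ tumor) \\ normal, lists the
near-miss records in the normal sample, and writes the pairwise
similarity matrix.
"""

import json
from pathlib import Path

import pandas as pd

from chorline import io as cio
from chorline import variants

DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"
OUT = DATA.parent.parent / "results" / "variants"
OUT.mkdir(parents=True, exist_ok=True)

records, sets = {}, {}
for tag in ("cell", "tumor", "normal"):
    records[tag] = cio.read_variants_vcf(DATA / f"variants_{tag}.vcf")
    sets[tag], counts = variants.filter_variants(records[tag], sample_id=tag)
    print(f"{tag}: {len(sets[tag])}/{len(records[tag])} retained; exclusions {counts}")

truth = json.load(open(DATA / "variants_truth.json"))

somatic = variants.somatic_subtract(sets["cell"], sets["tumor"], sets["normal"])
somatic_recs = [r for r in records["cell"] if r.key() in somatic.keys]
cio.write_variants_tsv(somatic_recs, OUT / "somatic.tsv")
genes = sorted(r.gene for r in somatic_recs)
print(f"\nsomatic (tumor-unique) variants: {len(somatic)} in genes {', '.join(genes)}")

# variants found only in the normal sample would be rescue candidates
normal_only = [r for r in records["normal"]
               if truth["|".join(map(str, r.key()))]["label"] == "normal_only"]
nm = variants.near_misses(normal_only)
print(f"normal-only records failing exactly one rule by a small margin: {len(nm)}")

for metric in ("jaccard", "overlap", "containment_a"):
    mat = variants.similarity_matrix(list(sets.values()), metric)
    df = pd.DataFrame(mat.values, index=mat.sample_ids, columns=mat.sample_ids)
    df.to_csv(OUT / f"similarity_{metric}.csv")
    print(f"\n{metric} similarity:\n{df.round(3).to_string()}")
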