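#!/usr/bin/env python
"""Generate the synthetic study inputs for all downstream analyses.

Writes, under scratch/data/: per-interval panel coverage for the five
chordoma cell lines (plus the Chor-IN-1 primary tumor and its normal
tissue counterpart), cell/tumor/normal variant calls, STR profiles,
the 487-kinase count matrix, a Ct table and a growth curve.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from chorline import io as cio
from chorline.quant import DEFAULT_REFERENCE_GENES
from chorline.simulate import (
    DEFAULT_CELL_LINES,
    DEFAULT_DOWN_GENES,
    DEFAULT_UP_GENES,
    VariantScenario,
    cell_line_scenarios,
    chor_in_1_scenario,
    default_kinome_scenario,
    default_str_profile,
    gen_counts,
    gen_coverage,
    gen_ct_table,
    gen_growth,
    gen_str_profiles,
    gen_variant_sets,
    make_panel,
    stream_rng,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# --- panel coverage: five cell lines + Chor-IN-1 tumor/normal -------------
panel = make_panel(spacing=500_000)
print(f"panel: {len(panel)} intervals at 500 kb spacing, 500 bp targets")
for name, scen in cell_line_scenarios(seed=SEED).items():
    cio.write_coverage(gen_coverage(scen, panel, name), OUT / f"coverage_{name}.bed")
# the primary tumor shares the cell line's event profile (independent noise);
# the normal tissue counterpart is flat diploid
tumor_scen = cell_line_scenarios(seed=SEED + 1)["Chor-IN-1"]
cio.write_coverage(gen_coverage(tumor_scen, panel, "Chor-IN-1-tumor"),
                   OUT / "coverage_tumor.bed")
from chorline.simulate import CnvScenario  # noqa: E402
cio.write_coverage(gen_coverage(CnvScenario(seed=SEED + 2), panel, "normal"),
                   OUT / "coverage_normal.bed")
print("coverage tracks written for", ", ".join(DEFAULT_CELL_LINES), "+ tumor/normal")

# --- variants --------------------------------------------------------------
cell, tumor, normal, truth = gen_variant_sets(VariantScenario(
    n_germline=100, n_tumor_only=4, n_normal_only=9,
    fraction_synonymous=0.1, fraction_common=0.05, seed=SEED))
for tag, recs in (("cell", cell), ("tumor", tumor), ("normal", normal)):
    cio.write_variants_vcf(recs, OUT / f"variants_{tag}.vcf")
with open(OUT / "variants_truth.json", "w") as fh:
    json.dump({"|".join(map(str, k)): v for k, v in sorted(truth.items())}, fh, indent=1)
print(f"variants: {len(cell)} cell, {len(tumor)} tumor, {len(normal)} normal")

# --- STR profiles ----------------------------------------------------------
base = default_str_profile("Chor-IN-1")
profiles = [base,
            gen_str_profiles(base, 0, seed=SEED, sample_id="Chor-IN-1-tumor"),
            gen_str_profiles(base, 2, seed=SEED, sample_id="related-line"),
            gen_str_profiles(base, 24, seed=SEED, sample_id="unrelated-line")]
cio.write_str_profiles(profiles, OUT / "str_profiles.csv")
print("STR profiles:", ", ".join(p.sample_id for p in profiles))

# --- kinome counts ---------------------------------------------------------
counts, ktruth = gen_counts(default_kinome_scenario(seed=SEED))
cio.write_counts(counts, OUT / "kinome_counts.tsv")
print(f"kinome counts: {counts.shape[0]} genes x {counts.shape[1]} samples; "
      f"shifted up {DEFAULT_UP_GENES}, down {DEFAULT_DOWN_GENES} in Chor-IN-1")

# --- Ct table --------------------------------------------------------------
rng = stream_rng(SEED, "analysis-ct")
genes = list(DEFAULT_UP_GENES + DEFAULT_DOWN_GENES)
expr = pd.DataFrame(2.0 ** rng.uniform(-2, 3, size=(len(DEFAULT_CELL_LINES), len(genes))),
                    index=list(DEFAULT_CELL_LINES), columns=genes)
for ref in DEFAULT_REFERENCE_GENES:
    expr[ref] = 1.0
gen_ct_table(expr, ref_genes=DEFAULT_REFERENCE_GENES, replicate_sd=0.05,
             seed=SEED).to_csv(OUT / "ct_table.csv", index=False)
print("Ct table written (duplicate reactions, 3 reference genes)")

# --- growth curve ----------------------------------------------------------
t, n = gen_growth(13_000, 168.0, np.arange(9) * 24.0, cv=0.05, seed=SEED)
pd.DataFrame({"time_hr": t, "count": n}).to_csv(OUT / "growth.csv", index=False)
print("growth curve written: 9 daily counts, true doubling time 168 h")
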