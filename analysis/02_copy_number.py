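#!/usr/bin/env python
"""Copy-number profiles, cross-line consensus and NGS-vs-aCGH comparison.

Reads the coverage tracks from 01, calls per-interval gains/losses with
the +/-0.2 log2 cutoffs, summarizes chromosome arms, builds the five-line
consensus profile, and checks that an aCGH-style two-channel profile of
the same genome is concordant with the coverage-based one.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from chorline import cnv
from chorline import io as cio
from chorline.simulate import DEFAULT_CELL_LINES, cell_line_scenarios, stream_rng

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
SCRATCH = ROOT / "scratch" / "cnv"   # per-interval tracks (bulky, regenerable)
OUT = ROOT / "results" / "cnv"      # summary tables
SCRATCH.mkdir(parents=True, exist_ok=True)
OUT.mkdir(parents=True, exist_ok=True)

profiles = {}
for name in DEFAULT_CELL_LINES:
    track = cio.read_coverage(DATA / f"coverage_{name}.bed", sample_id=name)
    profiles[name] = cnv.compute_log2_profile(track)
    cio.write_profile(profiles[name], SCRATCH / f"profile_{name}.tsv")

# Chor-IN-1 arm summary: the monosomies and the trisomy show up as arm calls
arms = pd.DataFrame(cnv.arm_summary(profiles["Chor-IN-1"]))
arms.to_csv(OUT / "chor_in_1_arm_summary.tsv", sep="\t", index=False)
aberrant = arms[arms["state"] != "balanced"]
print("Chor-IN-1 aberrant arms:")
print(aberrant.to_string(index=False))

# tumor vs cell line: profiles should be near-superimposable
tumor = cnv.compute_log2_profile(
    cio.read_coverage(DATA / "coverage_tumor.bed", sample_id="tumor"))
report = cnv.compare_profiles(profiles["Chor-IN-1"], tumor)
print(f"\ncell line vs tumor concordance: {report.concordance:.4f} "
      f"over {report.n_compared} intervals")

# five-line consensus: chr7 gain shared by 4/5 lines -> 80%
consensus = cnv.call_consensus(list(profiles.values()))
cio.write_consensus(consensus, SCRATCH / "consensus.tsv")
chr7p = [i for i, iv in enumerate(consensus.intervals)
         if iv.chrom == "chr7" and iv.midpoint < 59_900_000]
print(f"consensus gain on chr7p (shared trisomy, 4/5 lines): "
      f"{np.median(consensus.gain_pct[chr7p]):.0f}%")

# aCGH cross-check on Chor-IN-1: intensities proportional to copy number
scen = cell_line_scenarios(seed=9)["Chor-IN-1"]
rng = stream_rng(9, "acgh")
panel = profiles["Chor-IN-1"].intervals
cn = np.array([scen.copy_number_at(iv.chrom, iv.midpoint) for iv in panel])
ch2 = rng.lognormal(0, 0.02, size=len(panel))
ch1 = ch2 * (cn / 2) * rng.lognormal(0, 0.02, size=len(panel))
acgh = cnv.acgh_log2(panel, ch1, ch2, sample_id="Chor-IN-1-acgh")
cio.write_profile(acgh, SCRATCH / "profile_Chor-IN-1_acgh.tsv")
xcheck = cnv.compare_profiles(profiles["Chor-IN-1"], acgh)
print(f"NGS vs aCGH concordance: {xcheck.concordance:.4f} "
      f"(the two methods should be superimposable)")
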