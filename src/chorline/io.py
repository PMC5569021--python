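"""Readers and writers for the plain-text dialects used across the pipeline.

Genomic interval inputs are BED-like (0-based half-open); variant files
are minimal single-sample VCF with DP/ADV/MAF/GENE/EFF INFO keys (1-based
positions, as in the VariantRecord type). All writers round-trip through
their readers.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CnvProfile, ConsensusProfile, CoverageTrack, GenomicInterval
from .strs import StrProfile
from .variants import VariantRecord


class ParseError(ValueError):
    """Malformed input file; message carries the path and line number."""


def _fail(path, lineno, msg):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ------------------------------------------------------------- coverage BED

def read_coverage(path: str | os.PathLike, sample_id: str | None = None) -> CoverageTrack:
    """BED-like TSV: chrom, start, end, depth[, id]. '#' lines are comments."""
    intervals, depths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("# sample="):
                sample_id = sample_id or line.split("=", 1)[1]
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "need >= 4 tab-separated columns")
            chrom, start_s, end_s, depth_s = fields[:4]
            try:
                start, end, depth = int(start_s), int(end_s), float(depth_s)
            except ValueError:
                _fail(path, lineno, "non-numeric start/end/depth")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            if depth < 0:
                _fail(path, lineno, "negative depth")
            intervals.append(GenomicInterval(chrom, start, end,
                                             id=fields[4] if len(fields) > 4 else None))
            depths.append(depth)
    return CoverageTrack(sample_id or Path(path).stem, intervals, np.array(depths))


def write_coverage(track: CoverageTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample={track.sample_id}\n")
        for iv, depth in zip(track.intervals, track.depths):
            ident = iv.id or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{depth:.6g}\t{ident}\n")


# ------------------------------------------------------------- aCGH probes

def read_acgh(path: str | os.PathLike):
    """Probe TSV: probe_id, chrom, start, end, ch1, ch2 (header row)."""
    df = pd.read_csv(path, sep="\t")
    required = ["probe_id", "chrom", "start", "end", "ch1", "ch2"]
    if list(df.columns[:6]) != required:
        raise ParseError(f"{path}: expected columns {required}")
    probes = [GenomicInterval(r.chrom, int(r.start), int(r.end), id=str(r.probe_id))
              for r in df.itertuples()]
    return probes, df["ch1"].to_numpy(float), df["ch2"].to_numpy(float)


def write_acgh(probes, ch1, ch2, path) -> None:
    pd.DataFrame({
        "probe_id": [p.id for p in probes],
        "chrom": [p.chrom for p in probes],
        "start": [p.start for p in probes],
        "end": [p.end for p in probes],
        "ch1": ch1, "ch2": ch2,
    }).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------- CNV profiles

def write_profile(profile: CnvProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample={profile.sample_id}\n")
        fh.write("chrom\tstart\tend\tlog2_ratio\tcall\n")
        for iv, ratio, call in zip(profile.intervals, profile.log2_ratio, profile.calls):
            r = "NA" if np.isnan(ratio) else f"{ratio:.6g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r}\t{call}\n")


def read_profile(path) -> CnvProfile:
    sample_id = Path(path).stem
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sample="):
            sample_id = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    intervals = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce").to_numpy(float)
    return CnvProfile(sample_id, intervals, ratios, df["call"].to_numpy(object))


def write_consensus(consensus: ConsensusProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_samples={consensus.n_samples}\n")
        fh.write("chrom\tstart\tend\tgain_pct\tloss_pct\n")
        for iv, g, l in zip(consensus.intervals, consensus.gain_pct, consensus.loss_pct):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g:.6g}\t{l:.6g}\n")


def read_consensus_reference(path) -> ConsensusProfile:
    """Read a consensus percentage profile (e.g. a clinical-cohort export).

    Percentages outside [0, 100] are rejected. The sample count is taken
    from a '# n_samples=K' header line (0 when absent).
    """
    n_samples = 0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# n_samples="):
            n_samples = int(first.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    intervals = [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]
    return ConsensusProfile(intervals, df["gain_pct"].to_numpy(float),
                            df["loss_pct"].to_numpy(float), n_samples)


# ------------------------------------------------------------- variants

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=ADV,Number=1,Type=Integer,Description="Variant-allele read depth">
##INFO=<ID=MAF,Number=1,Type=Float,Description="dbSNP minor allele frequency">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(records: list[VariantRecord], path) -> None:
    from .cnv import CHROM_SIZES

    head, columns = _VCF_HEADER.rsplit("#CHROM", 1)
    contigs = "".join(f"##contig=<ID={c},length={n}>\n"
                      for c, n in CHROM_SIZES.items())
    with open(path, "w") as fh:
        fh.write(head + contigs + "#CHROM" + columns)
        for rec in sorted(records, key=lambda r: r.key()):
            info = [f"DP={rec.dp}", f"ADV={rec.adv}"]
            if rec.maf is not None:
                info.append(f"MAF={rec.maf:g}")
            if rec.gene:
                info.append(f"GENE={rec.gene}")
            info.append(f"EFF={rec.effect}")
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                     + ";".join(info) + "\n")


def read_variants_vcf(path) -> list[VariantRecord]:
    """Minimal single-sample VCF; comma-separated ALT (multi-allelic) rejected."""
    from cyvcf2 import VCF

    records = []
    for v in VCF(str(path)):
        if len(v.ALT) != 1:
            raise ParseError(f"{path}: multi-allelic record at {v.CHROM}:{v.POS}"
                             " — pre-split required")
        maf = v.INFO.get("MAF")
        if maf is not None:
            maf = float(f"{float(maf):.6g}")  # htslib stores INFO floats as float32
        records.append(VariantRecord(
            chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0],
            gene=v.INFO.get("GENE"), effect=v.INFO.get("EFF") or "other",
            dp=int(v.INFO.get("DP") or 0), adv=int(v.INFO.get("ADV") or 0),
            maf=maf))
    return records


def write_variants_tsv(records: list[VariantRecord], path) -> None:
    pd.DataFrame([{
        "chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
        "gene": r.gene or "", "effect": r.effect, "dp": r.dp, "adv": r.adv,
        "maf": "" if r.maf is None else r.maf,
    } for r in sorted(records, key=lambda r: r.key())]).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for r in df.itertuples():
        maf = None if r.maf in ("", None) else float(r.maf)
        gene = r.gene or None
        records.append(VariantRecord(r.chrom, int(r.pos), r.ref, r.alt,
                                     gene=gene, effect=r.effect,
                                     dp=int(r.dp), adv=int(r.adv), maf=maf))
    return records


# ------------------------------------------------------------- STR CSV

def write_str_profiles(profiles: list[StrProfile], path) -> None:
    """CSV with loci as rows, samples as columns, alleles comma-joined."""
    loci = sorted({locus for p in profiles for locus in p.loci})
    df = pd.DataFrame(index=loci)
    for p in profiles:
        df[p.sample_id] = [",".join(sorted(p.loci.get(locus, frozenset())))
                           for locus in loci]
    df.index.name = "locus"
    df.to_csv(path)


def read_str_profiles(path) -> list[StrProfile]:
    df = pd.read_csv(path, index_col="locus", keep_default_na=False, dtype=str)
    return [StrProfile(sample, {locus: cell for locus, cell in df[sample].items() if cell})
            for sample in df.columns]


# ------------------------------------------------------------- matrices etc.

def read_counts(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate gene or sample ids")
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep)


def read_ct(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample", "gene", "replicate", "ct"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: Ct CSV needs columns {sorted(required)}")
    return df


def read_growth(path):
    df = pd.read_csv(path)
    if not {"time_hr", "count"} <= set(df.columns):
        raise ParseError(f"{path}: growth CSV needs columns time_hr, count")
    return df["time_hr"].to_numpy(float), df["count"].to_numpy(float)
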