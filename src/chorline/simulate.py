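"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is parameterized by a scenario object plus a single seed,
returns machine-readable ground truth alongside the data, and is
bit-reproducible for a fixed (scenario, seed). The shipped default CNV
scenario encodes the copy-number events characteristic of the Chor-IN-1
chordoma cell line: monosomy of chr2q and chr3q, a chr8q21.3
microdeletion, a chr11q13.1 amplification, a chr13q21.31-qter duplication,
trisomy 7 and a biallelic (copy number 0) deletion of chr9p21.

Coverage noise model
--------------------
An interval's depth is the mean per-base coverage of the reads overlapping
it. The count of such reads is the natural Poisson quantity: for an
interval of length L at expected depth d the generator draws
reads ~ Poisson(d * L / read_length) and reports depth = reads *
read_length / L (negative-binomial optional, for overdispersion). At the
default 100x with 500-bp targets this gives a log2-ratio spread of about
0.065, consistent with targeted panels where +/-0.2 cutoffs separate
single-copy events cleanly. Copy number 0 produces exact zeros unless a
contamination floor (default 0, modeling normal-cell impurity) is set.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import CHROM_SIZES, CoverageTrack, GenomicInterval
from .strs import AMELOGENIN, PANEL_LOCI, StrProfile
from .variants import NONSYNONYMOUS, SYNONYMOUS, VariantRecord


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent substream of one global seed, keyed by stream name.

    Adding a generator call with a new stream name never perturbs the
    draws of existing streams.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())]))


# ---------------------------------------------------------------- coverage

@dataclass(frozen=True)
class CnvEvent:
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if not self.start < self.end:
            raise ValueError("event start must be < end")


@dataclass
class CnvScenario:
    """Integer copy-number events on a diploid baseline plus a noise model."""

    events: list[CnvEvent] = field(default_factory=list)
    baseline_cn: int = 2
    base_depth: float = 100.0
    noise_model: str = "poisson"        # {none, poisson, negative_binomial}
    dispersion: float = 0.0             # NB only; var = m + dispersion*m^2
    contamination: float = 0.0          # fraction of baseline cells mixed in
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.noise_model not in ("none", "poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "negative_binomial" and self.dispersion <= 0:
            raise ValueError("negative_binomial requires dispersion > 0")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must lie in [0, 1]")
        by_chrom: dict[str, list[CnvEvent]] = {}
        for ev in self.events:
            size = CHROM_SIZES.get(ev.chrom)
            if size is not None and ev.end > size:
                raise ValueError(f"event exceeds {ev.chrom} bounds: {ev}")
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if a.end > b.start:
                    raise ValueError(f"overlapping events on {chrom}: {a} / {b}")

    def copy_number_at(self, chrom: str, pos: int) -> int:
        for ev in self.events:
            if ev.chrom == chrom and ev.start <= pos < ev.end:
                return ev.copy_number
        return self.baseline_cn


def chor_in_1_scenario(**overrides) -> CnvScenario:
    """The default scenario: Chor-IN-1's characteristic alterations."""
    events = [
        CnvEvent("chr2", 93_300_000, 243_199_373, 1),    # monosomy 2q
        CnvEvent("chr3", 91_000_000, 198_022_430, 1),    # monosomy 3q
        CnvEvent("chr7", 0, 159_138_663, 3),             # trisomy 7
        CnvEvent("chr8", 87_200_000, 93_300_000, 1),     # 8q21.3 microdeletion
        CnvEvent("chr9", 19_900_000, 25_600_000, 0),     # biallelic 9p21 loss
        CnvEvent("chr11", 63_400_000, 65_400_000, 4),    # 11q13.1 amplification
        CnvEvent("chr13", 63_300_000, 115_169_878, 3),   # 13q21.31-qter duplication
    ]
    return CnvScenario(events=events, **overrides)


def cell_line_scenarios(**overrides) -> dict[str, CnvScenario]:
    """Scenarios for a five-line chordoma panel sharing recurrent events.

    All lines but JHC7 share monosomy 1p, trisomy 7 and the biallelic
    9p21 deletion; chr22 monosomy is shared by Chor-IN-1, U-CH1 and
    MUG-Chor1; Chor-IN-1 additionally carries its specific alterations.
    """
    shared = [
        CnvEvent("chr1", 0, 125_000_000, 1),
        CnvEvent("chr7", 0, 159_138_663, 3),
        CnvEvent("chr9", 19_900_000, 25_600_000, 0),
    ]
    chr22_loss = CnvEvent("chr22", 0, 51_304_566, 1)
    scen = {
        "Chor-IN-1": shared + [
            CnvEvent("chr2", 93_300_000, 243_199_373, 1),
            CnvEvent("chr3", 91_000_000, 198_022_430, 1),
            CnvEvent("chr8", 87_200_000, 93_300_000, 1),
            CnvEvent("chr11", 63_400_000, 65_400_000, 4),
            CnvEvent("chr13", 63_300_000, 115_169_878, 3),
            chr22_loss,
        ],
        "U-CH1": shared + [CnvEvent("chrX", 0, 155_270_560, 3), chr22_loss],
        "U-CH2": shared + [CnvEvent("chr6", 117_000_000, 171_115_067, 3)],
        "MUG-Chor1": shared + [chr22_loss],
        "JHC7": [CnvEvent("chr7", 61_000_000, 159_138_663, 3),  # partial 7q only
                 CnvEvent("chr6", 167_000_000, 171_115_067, 3)],
    }
    return {name: CnvScenario(events=evs, **overrides) for name, evs in scen.items()}


def make_panel(interval_length: int = 500, spacing: int = 100_000,
               chroms: list[str] | None = None) -> list[GenomicInterval]:
    """Evenly spaced targeted-panel intervals across the genome."""
    chroms = chroms or [c for c in CHROM_SIZES if c not in ("chrY",)]
    panel = []
    for chrom in chroms:
        size = CHROM_SIZES[chrom]
        for start in range(0, size - interval_length, spacing):
            panel.append(GenomicInterval(chrom, start, start + interval_length,
                                         id=f"{chrom}:{start}"))
    return panel


def gen_coverage(scenario: CnvScenario, panel: list[GenomicInterval],
                 sample_id: str = "sample") -> CoverageTrack:
    """Simulate per-interval panel coverage under a copy-number scenario.

    Expected depth of an interval is base_depth * cn / baseline_cn where
    cn is the event copy number at the interval midpoint (baseline
    elsewhere), blended with the baseline according to the contamination
    fraction. See the module docstring for the noise model.
    """
    if not panel:
        raise ValueError("empty panel")
    prev: GenomicInterval | None = None
    for iv in panel:
        if prev is not None and prev.chrom == iv.chrom and prev.end > iv.start:
            raise ValueError("panel intervals must be sorted and non-overlapping")
        prev = iv

    rng = stream_rng(scenario.seed, f"coverage:{sample_id}")
    cn = np.array([scenario.copy_number_at(iv.chrom, iv.midpoint) for iv in panel],
                  dtype=float)
    f = scenario.contamination
    cn_eff = (1.0 - f) * cn + f * scenario.baseline_cn
    exp_depth = scenario.base_depth * cn_eff / scenario.baseline_cn
    lengths = np.array([iv.length for iv in panel], dtype=float)
    mean_reads = exp_depth * lengths / scenario.read_length

    if scenario.noise_model == "none":
        depths = exp_depth
    elif scenario.noise_model == "poisson":
        depths = rng.poisson(mean_reads) * scenario.read_length / lengths
    else:
        r = 1.0 / scenario.dispersion
        p = r / (r + np.maximum(mean_reads, 1e-12))
        reads = np.where(mean_reads > 0, rng.negative_binomial(r, p), 0)
        depths = reads * scenario.read_length / lengths
    return CoverageTrack(sample_id, list(panel), depths)


# ---------------------------------------------------------------- variants

DEFAULT_TUMOR_ONLY_GENES = ("MUC1", "KEL", "TECTA", "SART3")


@dataclass
class VariantScenario:
    """Germline-dominated variant structure with a few tumor-unique calls."""

    n_germline: int = 100
    n_tumor_only: int = 4
    n_normal_only: int = 0
    mean_dp: float = 100.0
    het_fraction: float = 0.5        # expected variant-allele fraction
    fraction_synonymous: float = 0.0  # exact quota applied to germline records
    fraction_common: float = 0.0      # exact quota of dbSNP MAF > 2% germline records
    tumor_only_genes: tuple[str, ...] = DEFAULT_TUMOR_ONLY_GENES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_germline", "n_tumor_only", "n_normal_only"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_synonymous", "fraction_common"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _draw_keys(rng: np.random.Generator, n: int) -> list[tuple[str, int, str, str]]:
    bases = np.array(list("ACGT"))
    keys: set[tuple[str, int, str, str]] = set()
    chroms = list(CHROM_SIZES)
    while len(keys) < n:
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(1, CHROM_SIZES[chrom]))
        ref, alt = rng.choice(bases, size=2, replace=False)
        keys.add((chrom, pos, str(ref), str(alt)))
    return sorted(keys)


def gen_variant_sets(scenario: VariantScenario):
    """Per-sample variant records for cell line, tumor and normal tissue.

    Germline variants appear in all three samples; tumor-only variants in
    the cell line and tumor but not the normal; normal-only variants only
    in the normal. Depths are redrawn per sample (DP ~ Poisson(mean_dp),
    ADV ~ Binomial(DP, het_fraction)); annotation quotas (synonymous
    effect, common dbSNP frequency) are exact counts over the germline
    records, so downstream filter counts are deterministic given the seed.

    Returns
    -------
    (cell_records, tumor_records, normal_records, truth) where truth maps
    each variant key to {"label": germline|tumor_only|normal_only,
    "gene": symbol}.
    """
    s = scenario
    rng = stream_rng(s.seed, "variants")
    total = s.n_germline + s.n_tumor_only + s.n_normal_only
    keys = _draw_keys(rng, total)
    rng.shuffle(keys)
    germ = keys[:s.n_germline]
    tumor_only = keys[s.n_germline:s.n_germline + s.n_tumor_only]
    normal_only = keys[s.n_germline + s.n_tumor_only:]

    n_syn = round(s.fraction_synonymous * s.n_germline)
    n_common = round(s.fraction_common * s.n_germline)
    order = rng.permutation(s.n_germline)
    syn_idx = set(order[:n_syn])
    common_idx = set(rng.permutation(s.n_germline)[:n_common])

    truth: dict[tuple, dict] = {}
    annot: dict[tuple, dict] = {}
    for i, key in enumerate(germ):
        gene = f"GENE{i + 1:04d}"
        annot[key] = {
            "gene": gene,
            "effect": SYNONYMOUS if i in syn_idx else NONSYNONYMOUS,
            "maf": 0.05 if i in common_idx else None,
        }
        truth[key] = {"label": "germline", "gene": gene}
    for i, key in enumerate(tumor_only):
        gene = (s.tumor_only_genes[i] if i < len(s.tumor_only_genes)
                else f"SOM{i + 1:03d}")
        annot[key] = {"gene": gene, "effect": NONSYNONYMOUS, "maf": None}
        truth[key] = {"label": "tumor_only", "gene": gene}
    for i, key in enumerate(normal_only):
        gene = f"NRM{i + 1:03d}"
        annot[key] = {"gene": gene, "effect": NONSYNONYMOUS, "maf": None}
        truth[key] = {"label": "normal_only", "gene": gene}

    def records_for(sample_keys, stream):
        sub = stream_rng(s.seed, stream)
        recs = []
        for key in sample_keys:
            dp = max(int(sub.poisson(s.mean_dp)), 1)
            adv = int(sub.binomial(dp, s.het_fraction))
            a = annot[key]
            recs.append(VariantRecord(*key, gene=a["gene"], effect=a["effect"],
                                      dp=dp, adv=adv, maf=a["maf"]))
        return recs

    cell = records_for(sorted(germ + tumor_only), "depths:cell")
    tumor = records_for(sorted(germ + tumor_only), "depths:tumor")
    normal = records_for(sorted(germ + normal_only), "depths:normal")
    return cell, tumor, normal, truth


# ---------------------------------------------------------------- counts

DEFAULT_CELL_LINES = ("Chor-IN-1", "U-CH1", "U-CH2", "MUG-Chor1", "JHC7")
DEFAULT_UP_GENES = ("ULK4", "NPR1", "CDKL4")
DEFAULT_DOWN_GENES = ("FGFR3", "KDR", "WNK2")


@dataclass
class CountScenario:
    """Negative-binomial kinome counts with per-sample scale factors."""

    n_genes: int = 487
    sample_ids: tuple[str, ...] = DEFAULT_CELL_LINES
    gene_means: np.ndarray | None = None        # drawn log-uniform if None
    scale_factors: np.ndarray | None = None     # unit if None
    dispersion: float = 0.05
    differential: list[tuple[str, str, float]] = field(default_factory=list)
    mean_range: tuple[float, float] = (50.0, 5000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.gene_means is not None:
            self.gene_means = np.asarray(self.gene_means, dtype=float)
            if np.any(self.gene_means < 0):
                raise ValueError("gene means must be >= 0")
            if len(self.gene_means) != self.n_genes:
                raise ValueError("gene_means length must equal n_genes")
        if self.scale_factors is not None:
            self.scale_factors = np.asarray(self.scale_factors, dtype=float)
            if np.any(self.scale_factors <= 0):
                raise ValueError("scale factors must be positive")
        if self.differential and len(self.sample_ids) < 2:
            raise ValueError("differential specs need >= 2 samples")


def default_kinome_scenario(seed: int = 0, shift: float = 3.0) -> CountScenario:
    """487-kinase panel over five chordoma lines with six one-sample shifts."""
    diff = [(g, "Chor-IN-1", shift) for g in DEFAULT_UP_GENES]
    diff += [(g, "Chor-IN-1", -shift) for g in DEFAULT_DOWN_GENES]
    return CountScenario(differential=diff, seed=seed)


def _kinome_gene_ids(n_genes: int, named: tuple[str, ...]) -> list[str]:
    generic = [f"KIN{i + 1:04d}" for i in range(n_genes - len(named))]
    return sorted(list(named) + generic)


def gen_counts(scenario: CountScenario):
    """Simulate a genes x samples count matrix plus ground truth.

    Expected count for gene g in sample j is mean_g * factor_j *
    2^shift(g, j). Dispersion 0 is the Poisson limit; otherwise counts are
    negative binomial with var = m + dispersion * m^2.

    Returns (counts DataFrame, truth dict with gene_means, scale_factors
    and the differential spec).
    """
    s = scenario
    rng = stream_rng(s.seed, "counts")
    named = tuple(g for g, _, _ in s.differential)
    genes = _kinome_gene_ids(s.n_genes, tuple(dict.fromkeys(named)))
    means = s.gene_means
    if means is None:
        lo, hi = s.mean_range
        means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=s.n_genes))
    factors = s.scale_factors if s.scale_factors is not None \
        else np.ones(len(s.sample_ids))
    if len(factors) != len(s.sample_ids):
        raise ValueError("scale_factors length must match sample_ids")

    shift = pd.DataFrame(0.0, index=genes, columns=list(s.sample_ids))
    for gene, sample, sh in s.differential:
        if gene not in shift.index or sample not in shift.columns:
            raise ValueError(f"differential spec refers to unknown {gene}/{sample}")
        shift.loc[gene, sample] = sh

    mean_mat = (np.outer(means, factors)) * (2.0 ** shift.values)
    if s.dispersion == 0:
        counts = rng.poisson(mean_mat)
    else:
        r = 1.0 / s.dispersion
        p = r / (r + np.maximum(mean_mat, 1e-12))
        counts = np.where(mean_mat > 0, rng.negative_binomial(r, p), 0)
    df = pd.DataFrame(counts, index=genes, columns=list(s.sample_ids))
    truth = {"gene_means": pd.Series(means, index=genes),
             "scale_factors": pd.Series(factors, index=list(s.sample_ids)),
             "differential": list(s.differential)}
    return df, truth


# ---------------------------------------------------------------- STR

def default_str_profile(sample_id: str = "Chor-IN-1") -> StrProfile:
    """A plausible fully heterozygous 16-locus male profile (synthetic)."""
    alleles = {
        "D3S1358": {"15", "17"}, "TH01": {"6", "9.3"}, "D21S11": {"28", "30"},
        "D18S51": {"13", "16"}, "PentaE": {"7", "12"}, "D5S818": {"11", "12"},
        "D13S317": {"8", "11"}, "D7S820": {"9", "10"}, "D16S539": {"11", "13"},
        "CSF1PO": {"10", "12"}, "PentaD": {"9", "13"}, "vWA": {"16", "18"},
        "D8S1179": {"12", "14"}, "TPOX": {"8", "11"}, "FGA": {"21", "24"},
        AMELOGENIN: {"X", "Y"},
    }
    return StrProfile(sample_id, alleles)


def gen_str_profiles(base: StrProfile, n_mutated_alleles: int, seed: int = 0,
                     sample_id: str | None = None) -> StrProfile:
    """Derive a profile differing from base in exactly n allele slots.

    Each mutated slot's allele is replaced by a designation previously
    unused at that locus (numeric loci get a fresh designation; amelogenin
    can only flip between X and Y, so a heterozygous X/Y amelogenin offers
    no mutable slot). Raises when n exceeds the feasible slots.
    """
    if n_mutated_alleles < 0:
        raise ValueError("n_mutated_alleles must be >= 0")
    rng = stream_rng(seed, f"str:{base.sample_id}")
    slots = []
    for locus in sorted(base.loci):
        used = base.loci[locus]
        if locus == AMELOGENIN:
            unused = {"X", "Y"} - used
            if unused:
                slots.extend((locus, a) for a in sorted(used)[:len(unused)])
        else:
            slots.extend((locus, a) for a in sorted(used))
    if n_mutated_alleles > len(slots):
        raise ValueError(
            f"cannot mutate {n_mutated_alleles} alleles: only {len(slots)} mutable slots")

    chosen_idx = rng.choice(len(slots), size=n_mutated_alleles, replace=False)
    chosen = [slots[i] for i in sorted(chosen_idx)]
    new_loci = {locus: set(a for a in alleles) for locus, alleles in base.loci.items()}
    fresh: dict[str, int] = {}
    for locus, allele in chosen:
        new_loci[locus].discard(allele)
        if locus == AMELOGENIN:
            new_loci[locus] |= {"X", "Y"} - base.loci[locus]
        else:
            numeric = [float(a) for a in base.loci[locus] if a.replace(".", "").isdigit()]
            start = int(max(numeric, default=0)) + 1 + fresh.get(locus, 0)
            fresh[locus] = fresh.get(locus, 0) + 1
            new_loci[locus].add(str(start))
    return StrProfile(sample_id or f"{base.sample_id}_mut{n_mutated_alleles}", new_loci)


# ---------------------------------------------------------------- growth / Ct

def gen_growth(n0: float, doubling_time_hr: float, times_hr, cv: float = 0.0,
               seed: int = 0):
    """Exponential growth counts N(t) = n0 * 2^(t / DT) with CV-scaled noise.

    Noise is multiplicative lognormal with coefficient of variation cv
    (cv = 0 reproduces the exact exponential). Returns (times, counts).
    """
    if n0 <= 0 or doubling_time_hr <= 0:
        raise ValueError("n0 and doubling_time_hr must be positive")
    times = np.asarray(times_hr, dtype=float)
    if len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 2 points")
    expected = n0 * 2.0 ** (times / doubling_time_hr)
    if cv > 0:
        rng = stream_rng(seed, "growth")
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=len(times))
        expected = expected * noise
    return times, expected


def gen_ct_table(true_expression: pd.DataFrame,
                 ref_genes=("GUSB", "PPIA", "18S"),
                 base_ct: float = 30.0,
                 replicate_sd: float = 0.0,
                 sample_offsets: pd.Series | None = None,
                 n_replicates: int = 2,
                 seed: int = 0) -> pd.DataFrame:
    """Long-format Ct table from a samples x genes expression matrix.

    Ct(sample, gene) = base_ct + offset(sample) - log2(expression), assayed
    in duplicate (n_replicates) with optional Gaussian replicate noise.
    Per-sample offsets model loading differences and cancel in the ddCt.
    """
    if (true_expression.values <= 0).any():
        raise ValueError("expression levels must be positive")
    missing = set(ref_genes) - set(true_expression.columns)
    if missing:
        raise ValueError(f"reference genes absent from expression matrix: {sorted(missing)}")
    rng = stream_rng(seed, "ct")
    offsets = sample_offsets if sample_offsets is not None \
        else pd.Series(0.0, index=true_expression.index)
    rows = []
    for sample in true_expression.index:
        for gene in true_expression.columns:
            ct0 = base_ct + offsets.loc[sample] - np.log2(true_expression.loc[sample, gene])
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
                rows.append({"sample": sample, "gene": gene,
                             "replicate": rep, "ct": ct0 + noise})
    return pd.DataFrame(rows)
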