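"""Variant filtering, somatic subtraction and cross-sample similarity.

The filtering cascade keeps a called variant only when it is
non-synonymous, not a common polymorphism (population minor allele
frequency <= 2% when a dbSNP frequency is known; unknown frequencies are
retained), and adequately covered (total depth DP >= 20 and variant-allele
depth ADV >= 7). Somatic variants of a cell line are the variants shared
by the cell line and its tumor of origin minus those found in the
patient's normal tissue. Pairwise sample similarity is set-based on the
(chrom, pos, ref, alt) identity key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

#: Filter cutoffs, strict as printed: DP < 20 excludes, ADV < 7 excludes,
#: MAF > 0.02 excludes (records exactly at a boundary pass).
MIN_DP = 20
MIN_ADV = 7
MAX_MAF = 0.02

RULES = ("synonymous", "common_maf", "low_dp", "low_adv")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    """One called SNV/InDel with depth and population-frequency annotations.

    pos is 1-based (VCF convention). maf=None means the variant is not
    reported in dbSNP.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    effect: str = "other"
    dp: int = 0
    adv: int = 0
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if "," in self.alt:
            raise ValueError("multi-allelic records must be pre-split")
        if self.adv > self.dp:
            raise ValueError(f"malformed record: ADV {self.adv} > DP {self.dp}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError("maf must lie in [0, 1]")

    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    """A sample's filtered variants, keyed by (chrom, pos, ref, alt)."""

    sample_id: str
    keys: set[VariantKey] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys


def _failed_rules(rec: VariantRecord) -> list[str]:
    failed = []
    if rec.effect == SYNONYMOUS:
        failed.append("synonymous")
    if rec.maf is not None and rec.maf > MAX_MAF:
        failed.append("common_maf")
    if rec.dp < MIN_DP:
        failed.append("low_dp")
    if rec.adv < MIN_ADV:
        failed.append("low_adv")
    return failed


def filter_variants(
    records: list[VariantRecord], sample_id: str = "sample"
) -> tuple[VariantSet, dict[str, int]]:
    """Apply the exclusion cascade; return the retained set and per-rule counts.

    A record tripping several rules is counted under each. Idempotent:
    re-filtering retained records excludes nothing further.
    """
    counts = dict.fromkeys(RULES, 0)
    retained: set[VariantKey] = set()
    for rec in records:
        failed = _failed_rules(rec)
        if failed:
            for rule in failed:
                counts[rule] += 1
        else:
            retained.add(rec.key())
    return VariantSet(sample_id, retained), counts


def near_misses(
    records: list[VariantRecord],
    dp_margin: int = 5,
    adv_margin: int = 3,
    maf_margin: float = 0.01,
) -> list[VariantRecord]:
    """Records excluded by exactly one rule, failing it by at most a margin.

    Mirrors the manual rescue inspection of variants "called just below the
    filter threshold" in low-coverage regions. The synonymous rule is
    categorical and never near-missed; margins are this package's choice.
    """
    out = []
    for rec in records:
        failed = _failed_rules(rec)
        if len(failed) != 1:
            continue
        rule = failed[0]
        close = (
            (rule == "low_dp" and rec.dp >= MIN_DP - dp_margin)
            or (rule == "low_adv" and rec.adv >= MIN_ADV - adv_margin)
            or (rule == "common_maf" and rec.maf is not None
                and rec.maf <= MAX_MAF + maf_margin)
        )
        if close:
            out.append(rec)
    return out


def somatic_subtract(
    cell: VariantSet, tumor: VariantSet, normal: VariantSet
) -> VariantSet:
    """(cell ∩ tumor) \\ normal — tumor-derived variants absent from germline."""
    return VariantSet(f"{cell.sample_id}_somatic",
                      (cell.keys & tumor.keys) - normal.keys)


def concordance(a: VariantSet, b: VariantSet, metric: str = "jaccard") -> float:
    """Set similarity of two variant sets in [0, 1].

    jaccard = |A∩B|/|A∪B|; overlap = |A∩B|/min(|A|,|B|);
    containment_a = |A∩B|/|A|. Two empty sets score 1.0 by convention.
    """
    if metric not in ("jaccard", "overlap", "containment_a"):
        raise ValueError(f"unknown metric {metric!r}")
    if not a.keys and not b.keys:
        return 1.0
    inter = len(a.keys & b.keys)
    if metric == "jaccard":
        return inter / len(a.keys | b.keys)
    if metric == "overlap":
        smaller = min(len(a.keys), len(b.keys))
        return inter / smaller if smaller else 0.0
    return inter / len(a.keys) if a.keys else 0.0


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match sample count")


def similarity_matrix(sets: list[VariantSet], metric: str = "jaccard") -> SimilarityMatrix:
    """All-pairs concordance; symmetric with unit diagonal."""
    if len(sets) < 2:
        raise ValueError("need at least two variant sets")
    ids = [s.sample_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    n = len(sets)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = concordance(sets[i], sets[j], metric)
    return SimilarityMatrix(ids, mat, metric)
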