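"""STR fingerprint scoring for cell-line authentication.

Profiles cover the 15 polymorphic STR loci of the PowerPlex 16 panel plus
the amelogenin sex marker. Identity between a query and a reference is
scored with the standard percent-match formulas used for cell-line
authentication: Tanabe (non-empty intersection counted twice over the sum
of both allele counts) or either Masters variant (intersection over one
profile's allele count). Amelogenin is excluded from scoring by default —
it is a sex marker, not a polymorphic STR. The conventional >= 80%
threshold flags an authenticated match.
"""

from __future__ import annotations

from dataclasses import dataclass

AMELOGENIN = "AMEL"

#: PowerPlex 16 HS loci: 15 STRs + amelogenin.
PANEL_LOCI = (
    "D3S1358", "TH01", "D21S11", "D18S51", "PentaE",
    "D5S818", "D13S317", "D7S820", "D16S539", "CSF1PO",
    "PentaD", "vWA", "D8S1179", "TPOX", "FGA", AMELOGENIN,
)


@dataclass
class StrProfile:
    """Locus -> allele set for one sample (1-2 designations per locus).

    Homozygous loci recorded with a repeated designation are canonicalized
    to a single one. Amelogenin alleles are restricted to {X, Y}.
    """

    sample_id: str
    loci: dict[str, frozenset[str]]

    def __init__(self, sample_id: str, loci: dict[str, object]):
        self.sample_id = sample_id
        canon: dict[str, frozenset[str]] = {}
        for locus, alleles in loci.items():
            if isinstance(alleles, str):
                alleles = [a.strip() for a in alleles.split(",") if a.strip()]
            aset = frozenset(str(a) for a in alleles)
            if not aset:
                continue  # untyped locus
            if len(aset) > 2:
                raise ValueError(f"{locus}: more than 2 alleles ({sorted(aset)})")
            if locus == AMELOGENIN and not aset <= {"X", "Y"}:
                raise ValueError(f"amelogenin alleles must be X/Y, got {sorted(aset)}")
            canon[locus] = aset
        self.loci = canon

    def typed_loci(self) -> set[str]:
        return set(self.loci)


@dataclass
class MatchResult:
    sample_id: str
    score_pct: float
    is_match: bool


def match_score(
    query: StrProfile,
    reference: StrProfile,
    algorithm: str = "tanabe",
    include_amelogenin: bool = False,
) -> float:
    """Percent identity between two STR profiles over loci typed in both.

    tanabe        = 100 * 2*shared / (n_query + n_reference)
    masters_query = 100 * shared / n_query
    masters_ref   = 100 * shared / n_reference

    where shared counts alleles present in both profiles at each common
    locus and n_* count each profile's alleles over those loci (homozygous
    loci contribute one designation).
    """
    if algorithm not in ("tanabe", "masters_query", "masters_ref"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    common = query.typed_loci() & reference.typed_loci()
    if not include_amelogenin:
        common.discard(AMELOGENIN)
    if not common:
        raise ValueError("profiles share no typed loci")

    shared = n_q = n_r = 0
    for locus in common:
        q, r = query.loci[locus], reference.loci[locus]
        shared += len(q & r)
        n_q += len(q)
        n_r += len(r)
    if algorithm == "tanabe":
        return 100.0 * 2 * shared / (n_q + n_r)
    if algorithm == "masters_query":
        return 100.0 * shared / n_q
    return 100.0 * shared / n_r


def best_matches(
    query: StrProfile,
    database: list[StrProfile],
    algorithm: str = "tanabe",
    threshold_pct: float = 80.0,
    include_amelogenin: bool = False,
) -> list[MatchResult]:
    """Score the query against every database profile, best first.

    Ties are broken by sample_id lexicographic order; entries at or above
    threshold_pct are flagged as matches. An empty database yields an
    empty result.
    """
    results = [
        MatchResult(ref.sample_id,
                    match_score(query, ref, algorithm, include_amelogenin), False)
        for ref in database
    ]
    results.sort(key=lambda m: (-m.score_pct, m.sample_id))
    for m in results:
        m.is_match = m.score_pct >= threshold_pct
    return results
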