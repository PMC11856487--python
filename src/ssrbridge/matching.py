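"""Assign multilocus SSR profiles to reference clonal genotypes.

Phylloxera lineages are parthenogenetic: a genotype IS the combination of
SSR alleles across the panel, so assignment is exact identity of unordered
allele pairs at every compared locus (after calibration to historic allele
names).  ND loci are excluded from comparison; a query must still score a
minimum number of loci for the assignment to mean anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .panel import AlleleProfile, ReferencePanel


class MatchError(ValueError):
    pass


@dataclass
class CandidateMatch:
    genotype: str
    loci_compared: int
    loci_matching: int
    mismatched_loci: list[str] = field(default_factory=list)

    @property
    def full_match(self) -> bool:
        return self.loci_compared > 0 and self.loci_matching == self.loci_compared


@dataclass
class MatchResult:
    query: str
    candidates: list[CandidateMatch]
    verdict: str  # unique_match | ambiguous | no_match

    @property
    def best(self) -> CandidateMatch:
        return self.candidates[0]


def _pairs_equal(a, b, fuzzy: float) -> bool:
    return all(abs(x - y) <= fuzzy for x, y in zip(sorted(a), sorted(b)))


def match_profile(
    query: AlleleProfile,
    panel: ReferencePanel,
    min_loci: int = 4,
    fuzzy: float = 0.0,
) -> MatchResult:
    """Rank reference genotypes by allele-pair identity with the query.

    A locus matches when the unordered allele pairs are identical (within
    ``fuzzy`` bp per allele for uncalibrated queries).  Candidates are
    ranked by loci matching, then loci compared; the verdict is
    ``unique_match`` iff exactly one candidate matches at all compared loci.
    """
    scored = query.typed_loci()
    candidates: list[CandidateMatch] = []
    for genotype, ref in panel:
        compared = 0
        matching = 0
        mismatched: list[str] = []
        for locus in scored:
            ref_pair = ref.calls.get(locus)
            if ref_pair is None:
                continue
            compared += 1
            if _pairs_equal(query.calls[locus], ref_pair, fuzzy):
                matching += 1
            else:
                mismatched.append(locus)
        candidates.append(CandidateMatch(genotype, compared, matching, mismatched))
    if not candidates:
        raise MatchError("reference panel is empty")
    if all(c.loci_compared < min_loci for c in candidates):
        raise MatchError(
            f"insufficient loci: query scores fewer than {min_loci} against every reference"
        )
    candidates.sort(key=lambda c: (-c.loci_matching, -c.loci_compared, c.genotype))
    full = [c for c in candidates if c.full_match and c.loci_compared >= min_loci]
    if len(full) == 1:
        verdict = "unique_match"
    elif len(full) > 1:
        verdict = "ambiguous"
    else:
        verdict = "no_match"
    return MatchResult(query=query.sample_id, candidates=candidates, verdict=verdict)
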