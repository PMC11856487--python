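"""Tandem-repeat detection and primer-based amplicon extraction.

``find_repeat`` is a desk-scale tandem-run scanner: it reports the maximal
pure tandem run (motif length 1-6) covering the most bases, with ties broken
by shorter motif and then leftmost start.  ``extract_amplicon`` locates the
forward primer and the reverse-complemented reverse primer in a sequence,
allowing a bounded number of substitutions, and returns the amplified
fragment whose length is the sequence-level (HTS) allele size.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import reverse_complement


class RepeatError(ValueError):
    pass


def canonical_rotation(motif: str) -> str:
    """Lexicographically least rotation of a motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


@dataclass(frozen=True)
class RepeatAnnotation:
    """A pure tandem run: canonical motif, 0-based half-open span, copy number."""

    motif: str
    start: int
    end: int
    copies: float
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.end - self.start != round(self.copies * len(self.motif)):
            raise RepeatError("span length inconsistent with copies x motif length")
        if not 0 < self.purity <= 1:
            raise RepeatError("purity must be in (0, 1]")
        if self.motif != canonical_rotation(self.motif):
            raise RepeatError("motif must be its own canonical rotation")


def _run_length(seq: str, start: int, m: int) -> int:
    """Length in bases of the pure tandem run of period m starting at start."""
    end = start + m
    n = len(seq)
    while end < n and seq[end] == seq[end - m]:
        end += 1
    return end - start


def find_repeat(
    seq: str, max_motif_len: int = 6, min_copies: int = 3, min_length: int = 6
) -> RepeatAnnotation:
    """Longest maximal pure tandem run over motif lengths 1..max_motif_len.

    Ties go to the shorter motif, then the leftmost start.  A run must reach
    ``min_copies`` copies and ``min_length`` bases.  Raises ``RepeatError``
    if no qualifying run exists.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2:
        raise RepeatError("sequence too short")
    best: tuple[int, int, int] | None = None  # (-length, motif_len, start)
    for m in range(1, min(max_motif_len, n // 2) + 1):
        for start in range(n - 2 * m + 1):
            # maximal run: must not be extendable one base to the left
            if start > 0 and seq[start - 1] == seq[start - 1 + m]:
                continue
            length = _run_length(seq, start, m)
            if length < 2 * m:
                continue
            if length / m < min_copies or length < min_length:
                continue
            cand = (-length, m, start)
            if best is None or cand < best:
                best = cand
    if best is None:
        raise RepeatError("no repeat found")
    length, m, start = -best[0], best[1], best[2]
    return RepeatAnnotation(
        motif=canonical_rotation(seq[start : start + m]),
        start=start,
        end=start + length,
        copies=length / m,
        purity=1.0,
    )


@dataclass(frozen=True)
class PrimerSite:
    """Location of one primer footprint: 0-based half-open span and the
    positions (within the primer) of mismatched bases."""

    start: int
    end: int
    mismatches: tuple[int, ...]


@dataclass(frozen=True)
class AmpliconHit:
    sequence: str
    length: int
    forward_site: PrimerSite
    reverse_site: PrimerSite


def _scan_primer(seq: str, primer: str, max_mismatches: int) -> list[PrimerSite]:
    hits = []
    k = len(primer)
    for i in range(len(seq) - k + 1):
        mm = [j for j in range(k) if seq[i + j] != primer[j]]
        if len(mm) <= max_mismatches:
            hits.append(PrimerSite(start=i, end=i + k, mismatches=tuple(mm)))
    return hits


def extract_amplicon(seq: str, locus, max_mismatches: int = 2) -> AmpliconHit:
    """Locate both primer sites (substitutions only) and cut the amplicon.

    The amplicon spans the forward-primer start through the reverse-primer
    end inclusive of both footprints; its length is the sequence-level
    allele size.  Errors if either primer is absent or ambiguous.
    """
    seq = seq.upper()
    fwd = locus.forward_primer.upper()
    rev = reverse_complement(locus.reverse_primer.upper())
    if len(seq) < len(fwd) + len(rev):
        raise RepeatError(f"{locus.name}: sequence shorter than combined primers")
    fwd_hits = _scan_primer(seq, fwd, max_mismatches)
    if not fwd_hits:
        raise RepeatError(f"{locus.name}: primer site not located (forward)")
    if len(fwd_hits) > 1:
        raise RepeatError(
            f"{locus.name}: multiple forward primer sites at "
            f"{[h.start for h in fwd_hits]}"
        )
    rev_hits = [h for h in _scan_primer(seq, rev, max_mismatches) if h.start >= fwd_hits[0].end]
    if not rev_hits:
        raise RepeatError(f"{locus.name}: primer site not located (reverse)")
    if len(rev_hits) > 1:
        raise RepeatError(
            f"{locus.name}: multiple reverse primer sites at "
            f"{[h.start for h in rev_hits]}"
        )
    f, r = fwd_hits[0], rev_hits[0]
    amplicon = seq[f.start : r.end]
    return AmpliconHit(
        sequence=amplicon, length=len(amplicon), forward_site=f, reverse_site=r
    )
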