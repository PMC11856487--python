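"""Decompose allele-length differences into repeat vs. flanking components.

An observed allele sequence is globally aligned to the original reference
clone; every indel is left-normalized (shifted to its leftmost equivalent
position, as in variant normalization) and classified by the reference
region it falls in: forward-primer footprint, 5' flank, repeat run,
3' flank, or reverse-primer footprint.  The signed region deltas always sum
exactly to the total length difference, which is what lets a fragment-size
discrepancy between genotyping platforms be attributed base-by-base.

Primer-footprint indels are special: PCR overwrites the primer-binding
sequence with the primer itself, so they are length-neutral on amplified
platforms (polyacrylamide, capillary) but fully visible to direct
sequencing - the mechanism behind amplified-vs-sequenced size discrepancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .repeats import RepeatAnnotation

REGIONS = ("fwd_primer", "flank5", "repeat", "flank3", "rev_primer")


class DecomposeError(ValueError):
    pass


@dataclass(frozen=True)
class IndelEvent:
    """One insertion (+length) or deletion (-length) at a left-normalized
    0-based reference position, classified by region."""

    position: int
    length: int
    region: str
    ambiguous: bool = False  # left-normalized position sits on a region boundary

    def __post_init__(self) -> None:
        if self.length == 0:
            raise DecomposeError("indel length must be non-zero")
        if self.region not in REGIONS:
            raise DecomposeError(f"unknown region {self.region!r}")


@dataclass
class Decomposition:
    delta_total: int
    delta_repeat: int
    delta_flank5: int
    delta_flank3: int
    delta_primers: int
    events: list[IndelEvent] = field(default_factory=list)
    substitutions: int = 0

    def __post_init__(self) -> None:
        if (
            self.delta_total
            != self.delta_repeat + self.delta_flank5 + self.delta_flank3 + self.delta_primers
        ):
            raise DecomposeError("region deltas do not conserve total length change")


# ---------------------------------------------------------------------------
# alignment

_DEFAULT_SCORES = dict(match=2.0, mismatch=-3.0, gap_open=-6.0, gap_extend=-1.0)


def _matrix(match: float, mismatch: float):
    """ACGTN substitution matrix; N pairs with anything at zero score."""
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            else:
                m[a, b] = match if a == b else mismatch
    return m


def align_global(
    obs: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
):
    """Global alignment of obs against ref with affine gaps.

    A gap of length L costs ``gap_open + (L-1) * gap_extend``.  Ambiguous N
    bases match anything at zero score.  Returns a Bio.Align.Alignment with
    ref as target and obs as query.
    """
    if not obs or not ref:
        raise DecomposeError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(match, mismatch)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner.align(ref.upper(), obs.upper())[0]


def _raw_events(alignment) -> tuple[list[tuple[int, int, str]], int]:
    """Extract (ref_position, signed_length, inserted_seq) events and count
    substitutions from an alignment (ref = target, obs = query)."""
    ref = str(alignment.target)
    obs = str(alignment.query)
    events: list[tuple[int, int, str]] = []
    subs = 0
    ref_aln, obs_aln = alignment[0], alignment[1]
    rpos = 0
    i = 0
    n = len(ref_aln)
    while i < n:
        if ref_aln[i] == "-":  # insertion in obs
            j = i
            ins = []
            while j < n and ref_aln[j] == "-":
                ins.append(obs_aln[j])
                j += 1
            events.append((rpos, j - i, "".join(ins)))
            i = j
        elif obs_aln[i] == "-":  # deletion from ref
            j = i
            start = rpos
            while j < n and obs_aln[j] == "-" and ref_aln[j] != "-":
                rpos += 1
                j += 1
            events.append((start, -(j - i), ""))
            i = j
        else:
            if ref_aln[i] != obs_aln[i] and "N" not in (ref_aln[i], obs_aln[i]):
                subs += 1
            rpos += 1
            i += 1
    return events, subs


def _left_normalize(
    events: list[tuple[int, int, str]], ref: str
) -> list[tuple[int, int, str]]:
    """Shift every indel to its leftmost equivalent position."""
    out = []
    for pos, length, ins in events:
        if length < 0:  # deletion of ref[pos : pos - length]
            i, j = pos, pos - length
            while i > 0 and ref[i - 1] == ref[j - 1]:
                i -= 1
                j -= 1
            out.append((i, length, ""))
        else:  # insertion of ins before ref[pos]
            s = ins
            p = pos
            while p > 0 and s and s[-1] == ref[p - 1]:
                s = ref[p - 1] + s[:-1]
                p -= 1
            out.append((p, length, s))
    return sorted(out, key=lambda e: (e[0], -e[1]))


@dataclass(frozen=True)
class LocusLayout:
    """Region boundaries on the reference: primer footprints and repeat span
    (0-based half-open)."""

    fwd_primer: tuple[int, int]
    repeat: tuple[int, int]
    rev_primer: tuple[int, int]

    def region_of(self, pos: int) -> tuple[str, bool]:
        """Region containing a reference position, plus a boundary flag."""
        f0, f1 = self.fwd_primer
        rs, re = self.repeat
        r0, r1 = self.rev_primer
        bounds = {f0, f1, rs, re, r0, r1}
        if pos < f1:
            region = "fwd_primer"
        elif pos < rs:
            region = "flank5"
        elif pos < re:
            region = "repeat"
        elif pos < r0:
            region = "flank3"
        else:
            region = "rev_primer"
        return region, pos in bounds


def layout_from_annotation(
    repeat: RepeatAnnotation, fwd_primer: tuple[int, int], rev_primer: tuple[int, int]
) -> LocusLayout:
    if not (fwd_primer[1] <= repeat.start and repeat.end <= rev_primer[0]):
        raise DecomposeError("repeat coordinates overlap primer coordinates")
    return LocusLayout(
        fwd_primer=fwd_primer, repeat=(repeat.start, repeat.end), rev_primer=rev_primer
    )


def decompose(alignment, layout: LocusLayout) -> Decomposition:
    """Classify every indel of an alignment by reference region.

    Indels are left-normalized first; an indel is assigned to the region
    containing its leftmost base (flagged ambiguous when that position is a
    region boundary, where a flank indel of motif length is indistinguishable
    from a repeat-unit change).
    """
    ref = str(alignment.target)
    raw, subs = _raw_events(alignment)
    norm = _left_normalize(raw, ref)
    deltas = {r: 0 for r in REGIONS}
    events: list[IndelEvent] = []
    for pos, length, _ins in norm:
        region, on_boundary = layout.region_of(pos)
        deltas[region] += length
        events.append(
            IndelEvent(position=pos, length=length, region=region, ambiguous=on_boundary)
        )
    return Decomposition(
        delta_total=sum(deltas.values()),
        delta_repeat=deltas["repeat"],
        delta_flank5=deltas["flank5"],
        delta_flank3=deltas["flank3"],
        delta_primers=deltas["fwd_primer"] + deltas["rev_primer"],
        events=events,
        substitutions=subs,
    )


def decompose_pair(obs: str, ref: str, layout: LocusLayout, **scores) -> Decomposition:
    """Align obs to ref and decompose in one step."""
    return decompose(align_global(obs, ref, **scores), layout)


# ---------------------------------------------------------------------------
# primer-site diagnostics and platform size arithmetic


@dataclass(frozen=True)
class PrimerMismatch:
    primer: str  # "forward" | "reverse"
    position_in_primer: int
    ref_base: str
    obs_base: str
    kind: str  # "substitution" | "insertion" | "deletion"
    consequence: str


def primer_site_report(obs: str, ref: str, layout: LocusLayout) -> list[PrimerMismatch]:
    """Substitutions and indels inside primer footprints of obs vs ref.

    Indels in a primer footprint are length-neutral under PCR (the primer
    overwrites the template), unlike flanking indels; substitutions risk
    amplification efficiency but never shift fragment length.
    """
    alignment = align_global(obs, ref)
    ref_aln, obs_aln = alignment[0], alignment[1]
    records: list[PrimerMismatch] = []
    spans = {"forward": layout.fwd_primer, "reverse": layout.rev_primer}
    rpos = 0
    for r, o in zip(ref_aln, obs_aln):
        for name, (s, e) in spans.items():
            if not (s <= rpos < e or (r == "-" and s < rpos <= e)):
                continue
            in_primer = rpos - s
            if r == "-":
                records.append(
                    PrimerMismatch(name, in_primer, "-", o, "insertion",
                                   "length-neutral under amplification")
                )
            elif o == "-":
                records.append(
                    PrimerMismatch(name, in_primer, r, "-", "deletion",
                                   "length-neutral under amplification")
                )
            elif r != o and "N" not in (r, o):
                records.append(
                    PrimerMismatch(name, in_primer, r, o, "substitution",
                                   "efficiency risk, length-neutral")
                )
        if r != "-":
            rpos += 1
    return records


def expected_platform_lengths(dec: Decomposition) -> tuple[int, int]:
    """(amplified length delta, sequenced length delta) implied by a
    decomposition.  Sequencing sees every indel; PCR amplification restores
    primer-footprint indels, so the amplified delta omits them."""
    sequenced = dec.delta_total
    amplified = dec.delta_total - dec.delta_primers
    return amplified, sequenced
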