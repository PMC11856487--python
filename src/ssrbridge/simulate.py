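"""Synthetic SSR data with known truth for every pipeline stage.

The generators emulate the study's data shapes end to end: tandem-repeat
alleles embedded in unique flanking sequence (optionally with planted
flanking/primer indels mirroring the observed per-locus patterns), raw
capillary peak tables (amplicon + tail + per-locus whole-bp offset + small
Gaussian jitter, with stutter satellite ladders at homopolymer loci and
optional cross-dye pull-up peaks), and paired 150 bp reads with
geometric-step stutter noise and random strand orientation.

Default noise conditions: jitter SD 0.15 bp (the within-allele spread seen
in replicate capillary sizings), offsets within +/-3 bp (the adjustment
range needed against historic names), read stutter per the default
StutterModel, read length 150, coverage measured as spanning-read depth per
allele.  The full truth is serializable so downstream stages can be scored
without re-simulation; a fixed seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord

from .genotyper import StutterModel
from .panel import DYES, AlleleProfile, LocusSpec, PeakRecord, ReferencePanel

_TAILS = {"FAM": 18, "VIC": 16, "NED": 17, "PET": 15}

#: planted indel patterns mirroring the observed per-locus flanking variants:
#: (region, offset_within_region, signed_length)
PATTERNS: dict[str, list[tuple[str, int, int]]] = {
    "dvit1_like": [("fwd_primer", 7, -1), ("flank3", 5, -1)],
    "dvit2_like": [("flank5", 3, -1), ("flank5", 8, -1), ("flank5", 13, -1)],
    "dvit3_like": [("flank5", 6, -1)],
    "dvit6_like": [("flank5", 4, 2), ("flank5", 11, -1)],
}


@dataclass(frozen=True)
class SimAllele:
    repeat_copies: int
    sequence: str  # full allele: flank5 + repeat + flank3 (indels applied)
    sequenced_length: int  # bp seen by direct sequencing
    amplified_length: int  # bp seen by PCR platforms (primer indels restored)
    tract_length: int  # repeat tract bp after any planted repeat indels
    tract_start: int  # 0-based start of the tract within sequence


@dataclass
class SimLocus:
    spec: LocusSpec
    flank5: str  # includes forward primer at the 5' end
    flank3: str  # includes reverse-primer site at the 3' end
    reference_copies: int
    reference: str
    planted: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SimTruth:
    loci: dict[str, SimLocus]
    strains: dict[str, dict[str, tuple[SimAllele, SimAllele]]]
    capillary_offsets: dict[str, int] = field(default_factory=dict)
    jitter_sd: float = 0.15

    def historic_panel(self) -> ReferencePanel:
        """Reference profiles carrying the true amplified lengths as names."""
        profiles = {}
        for strain, loci in self.strains.items():
            prof = AlleleProfile(sample_id=strain, platform="polyacrylamide")
            for lname, (a, b) in loci.items():
                prof.calls[lname] = tuple(sorted((a.amplified_length, b.amplified_length)))
            profiles[strain] = prof
        return ReferencePanel(profiles=profiles)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "jitter_sd": self.jitter_sd,
            "capillary_offsets": self.capillary_offsets,
            "loci": {
                n: {
                    "flank5": l.flank5,
                    "flank3": l.flank3,
                    "reference_copies": l.reference_copies,
                    "reference": l.reference,
                    "planted": l.planted,
                    "motif": l.spec.motif,
                }
                for n, l in self.loci.items()
            },
            "strains": {
                s: {
                    n: [
                        {
                            "repeat_copies": a.repeat_copies,
                            "sequence": a.sequence,
                            "sequenced_length": a.sequenced_length,
                            "amplified_length": a.amplified_length,
                            "tract_length": a.tract_length,
                            "tract_start": a.tract_start,
                        }
                        for a in pair
                    ]
                    for n, pair in loci.items()
                }
                for s, loci in self.strains.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _unique_flanks(
    rng: random.Random, motif: str, f5_len: int, f3_len: int
) -> tuple[str, str]:
    """Flanks free of the repeat motif at their repeat-facing ends so the
    planted tract is the maximal run and anchors are unambiguous."""
    while True:
        f5 = _random_seq(rng, f5_len)
        f3 = _random_seq(rng, f3_len)
        double = motif * 2
        # a run of period m extends left iff the base before the tract equals
        # motif[-1], and right iff the base after equals motif[0]
        if (
            double not in f5[-20:]
            and double not in f3[:20]
            and f5[-1] != motif[-1]
            and f3[0] != motif[0]
        ):
            return f5, f3


def _apply_pattern(
    flank5: str, flank3: str, fwd_len: int, pattern: Sequence[tuple[str, int, int]],
    rng: random.Random,
) -> tuple[str, str, int]:
    """Apply planted indels to the flanks; returns new flanks and the total
    primer-footprint delta (needed for amplified-length bookkeeping).

    Offsets are interpreted within the named region: fwd_primer from the
    flank5 start, flank5 from the primer end, flank3/rev_primer from the
    flank3 start/end.  Deletions remove bases; insertions add random bases.
    """
    f5, f3 = flank5, flank3
    primer_delta = 0
    # apply right-to-left so earlier offsets stay valid
    for region, off, length in sorted(pattern, key=lambda p: -p[1]):
        if region == "fwd_primer":
            pos = off
        elif region == "flank5":
            pos = fwd_len + off
        elif region == "flank3":
            pos = off
        else:  # rev_primer
            pos = len(f3) - 20 + off
        target = f5 if region in ("fwd_primer", "flank5") else f3
        if length < 0:
            new = target[:pos] + target[pos - length :]
        else:
            new = target[:pos] + _random_seq(rng, length) + target[pos:]
        if region in ("fwd_primer", "flank5"):
            f5 = new
        else:
            f3 = new
        if region in ("fwd_primer", "rev_primer"):
            primer_delta += length
    return f5, f3, primer_delta


def simulate_panel(
    seed: int,
    n_loci: int = 8,
    motif_lengths: Sequence[int] | None = None,
    flank_len: int = 60,
    n_strains: int = 3,
    copies_range: tuple[int, int] = (8, 16),
    planted: Mapping[str, Sequence[tuple[str, int, int]]] | None = None,
) -> tuple[list[LocusSpec], dict[str, str], SimTruth]:
    """Generate a marker panel, reference sequences, and strain alleles.

    Each locus is a pure tandem repeat inside unique flanks whose outermost
    20 bp are the primer footprints.  ``planted`` maps locus name (L1,
    L2, ...) to an indel pattern applied to every strain allele (the
    reference keeps the unmutated flanks, mirroring discrepancies against
    an original clone).  Returns (panel, {name: reference seq}, truth).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if flank_len < 25:
        raise ValueError("flank too short to host primers")
    rng = random.Random(seed)
    motif_lengths = list(motif_lengths or [2, 2, 2, 2, 1, 3, 2, 2])
    bases = "ACGT"
    loci: dict[str, SimLocus] = {}
    panel: list[LocusSpec] = []
    references: dict[str, str] = {}
    strains: dict[str, dict[str, tuple[SimAllele, SimAllele]]] = {
        f"S{i+1}": {} for i in range(n_strains)
    }
    for i in range(n_loci):
        name = f"L{i+1}"
        mlen = motif_lengths[i % len(motif_lengths)]
        motif = "".join(rng.choice(bases) for _ in range(mlen))
        if mlen > 1 and len(set(motif)) == 1:
            motif = motif[:-1] + ("A" if motif[0] != "A" else "C")
        # loci sharing a dye are staggered in size so their expected ranges
        # never overlap in one capillary lane (real poolplex panel design);
        # 80 bp exceeds the widest allele range for motifs up to 3 bp
        f5_len = flank_len + 80 * (i // len(DYES))
        f5, f3 = _unique_flanks(rng, motif, f5_len, flank_len)
        ref_copies = rng.randint(*copies_range)
        dye = DYES[i % len(DYES)]
        reference = f5 + motif * ref_copies + f3
        spec = LocusSpec(
            name=name,
            forward_primer=f5[:20],
            reverse_primer=reverse_complement(f3[-20:]),
            tail_length=_TAILS[dye],
            motif=motif,
            dye=dye,
            size_range=(
                len(f5) + len(f3) + mlen * max(1, copies_range[0] - 6),
                len(f5) + len(f3) + mlen * (copies_range[1] + 6) + 4,
            ),
            mix_group=f"MM{i % 4 + 1}",
        )
        pattern = list((planted or {}).get(name, []))
        sim_locus = SimLocus(
            spec=spec,
            flank5=f5,
            flank3=f3,
            reference_copies=ref_copies,
            reference=reference,
            planted=pattern,
        )
        loci[name] = sim_locus
        panel.append(spec)
        references[name] = reference

        mf5, mf3, primer_delta = _apply_pattern(f5, f3, 20, pattern, rng) if pattern else (f5, f3, 0)
        for strain in strains:
            alleles = []
            for _ in range(2):
                copies = rng.randint(*copies_range)
                seq = mf5 + motif * copies + mf3
                alleles.append(
                    SimAllele(
                        repeat_copies=copies,
                        sequence=seq,
                        sequenced_length=len(seq),
                        amplified_length=len(seq) - primer_delta,
                        tract_length=copies * mlen,
                        tract_start=len(mf5),
                    )
                )
            alleles.sort(key=lambda a: a.repeat_copies)
            strains[strain][name] = (alleles[0], alleles[1])
    truth = SimTruth(loci=loci, strains=strains)
    return panel, references, truth


def write_references_fasta(references: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="synthetic reference")
        for name, seq in references.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# capillary simulation


def simulate_capillary_run(
    truth: SimTruth,
    offsets: Mapping[str, int],
    jitter_sd: float = 0.15,
    seed: int = 0,
    stutter_ladder: bool = True,
    ladder_decay: float = 0.4,
    pullup: bool = False,
) -> list[PeakRecord]:
    """Raw peak records for every strain allele.

    Peak size = amplified length + tail + per-locus offset + N(0, jitter).
    Homopolymer loci grow satellite peaks at -1 and -2 bp with heights
    decaying by ``ladder_decay`` per step; optional pull-up peaks copy a
    tall peak's size into another dye at ~1/20 height.
    """
    for lname, off in offsets.items():
        if abs(off) > 3:
            raise ValueError(f"{lname}: |offset| must be <= 3 bp")
    if jitter_sd > 0.5:
        raise ValueError("jitter_sd must be <= 0.5 bp")
    rng = random.Random(seed)
    truth.capillary_offsets = dict(offsets)
    truth.jitter_sd = jitter_sd
    peaks: list[PeakRecord] = []
    for strain, loci in truth.strains.items():
        for lname, pair in loci.items():
            locus = truth.loci[lname]
            spec = locus.spec
            offset = offsets.get(lname, 0)
            unique_alleles = {a.amplified_length: a for a in pair}.values()
            for allele in unique_alleles:
                # alleles of one sample amplify to comparable heights (<2x
                # apart), well separated from 0.4-decay stutter satellites
                h = rng.uniform(1500.0, 2800.0)
                size = (
                    allele.amplified_length
                    + spec.tail_length
                    + offset
                    + rng.gauss(0.0, jitter_sd)
                )
                peaks.append(PeakRecord(strain, spec.dye, round(size, 2), round(h, 1)))
                if stutter_ladder and spec.is_homopolymer:
                    for step in (1, 2):
                        peaks.append(
                            PeakRecord(
                                strain,
                                spec.dye,
                                round(size - step, 2),
                                round(h * ladder_decay**step, 1),
                            )
                        )
                if pullup and h > 2000:
                    other = rng.choice([d for d in DYES if d != spec.dye])
                    peaks.append(
                        PeakRecord(
                            strain,
                            other,
                            round(size + rng.uniform(-0.3, 0.3), 2),
                            round(h / 20.0, 1),
                        )
                    )
    return peaks


# ---------------------------------------------------------------------------
# read simulation


def _stutter_tract(
    tract: int, motif_len: int, model: StutterModel, rng: random.Random
) -> int:
    if rng.random() >= model.p_stutter:
        return tract
    # geometric magnitude in motif units: P(m) = step * (1-step)^(m-1)
    m = 1
    while rng.random() >= model.step:
        m += 1
    delta = m * motif_len * (-1 if rng.random() < model.p_down else 1)
    return max(0, tract + delta)


def simulate_reads(
    truth: SimTruth,
    coverage: int = 40,
    stutter: StutterModel | None = None,
    seed: int = 0,
    read_len: int = 150,
    loci: Sequence[str] | None = None,
    strains: Sequence[str] | None = None,
) -> dict[tuple[str, str], list[SeqRecord]]:
    """Paired 150 bp reads per (strain, locus) with per-read stutter noise.

    ``coverage`` is the target spanning-read depth per allele (reads whose
    span covers the whole repeat tract plus both 15-mer anchors).  Strand
    orientation is Bernoulli(0.5); qualities are constant Q30.  Amplicons
    shorter than the read length fall back to single whole-molecule reads.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    model = stutter or StutterModel()
    rng = random.Random(seed)
    out: dict[tuple[str, str], list[SeqRecord]] = {}
    for strain, locus_map in truth.strains.items():
        if strains is not None and strain not in strains:
            continue
        for lname, pair in locus_map.items():
            if loci is not None and lname not in loci:
                continue
            mlen = len(truth.loci[lname].spec.motif)
            records: list[SeqRecord] = []
            n = 0
            for allele in pair:  # both chromosomes; a homozygote gets 2x depth
                L = len(allele.sequence)
                # the spanning window: tract plus both 15-mer anchors
                w0 = allele.tract_start - 15
                w1 = allele.tract_start + allele.tract_length + 15
                if L <= read_len:
                    n_reads = coverage  # whole-molecule reads all span
                else:
                    # a read starting at s spans iff s <= w0 and s+read_len >= w1;
                    # scale the uniform placement count so the expected number
                    # of spanning reads hits the target depth
                    total_positions = L - read_len + 1
                    span_starts = min(w0, L - read_len) - max(0, w1 - read_len) + 1
                    if span_starts <= 0:
                        n_reads = coverage  # spanning impossible; still emit reads
                    else:
                        n_reads = max(
                            1, round(coverage * total_positions / span_starts)
                        )
                motif = truth.loci[lname].spec.motif
                for _ in range(n_reads):
                    tract = _stutter_tract(allele.tract_length, mlen, model, rng)
                    mutated = (
                        allele.sequence[: allele.tract_start]
                        + (motif * (tract // mlen + 1))[:tract]
                        + allele.sequence[allele.tract_start + allele.tract_length :]
                    )
                    if len(mutated) <= read_len:
                        frag = mutated
                    else:
                        start = rng.randrange(0, len(mutated) - read_len + 1)
                        frag = mutated[start : start + read_len]
                    if rng.random() < 0.5:
                        frag = reverse_complement(frag)
                    n += 1
                    rec = SeqRecord(
                        Seq(frag),
                        id=f"{strain}_{lname}_r{n}",
                        description="",
                    )
                    rec.letter_annotations["phred_quality"] = [30] * len(frag)
                    records.append(rec)
            out[(strain, lname)] = records
    return out


def write_reads_fastq(
    reads: Mapping[tuple[str, str], Sequence[SeqRecord]], path: str | Path
) -> None:
    records = [r for recs in reads.values() for r in recs]
    SeqIO.write(records, str(path), "fastq")
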