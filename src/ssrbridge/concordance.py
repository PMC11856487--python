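"""Cross-platform allele-size concordance statistics.

For each locus and ordered platform pair, every genotype's allele pairs are
sorted ascending and paired positionally; homozygotes contribute two
observations and ND genotypes are skipped.  The per-locus statistic is the
observation-weighted mean signed difference (B - A) in bp, rounded to one
decimal half away from zero at presentation only.  Grand statistics per
platform pair are the unweighted mean and sample SD over the *rounded*
per-locus means, matching how the published summary row was computed from
its own per-locus table.

Loci without measured polyacrylamide data (DVSSR3/DVSSR4, whose platform-1
entries are published expected sizes) are N/A for comparisons against the
polyacrylamide platform; their allele accounting is taken over the
capillary-vs-sequencing comparison instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from ._round import round_half_away, tenths
from .decompose import Decomposition, expected_platform_lengths
from .panel import (
    HISTORIC_SCORING_CORRECTIONS,
    LOCUS_ORDER,
    AlleleProfile,
    LocusSpec,
    panel_by_name,
)

PAIR_LABELS = {
    ("polyacrylamide", "capillary"): "Platforms 1 and 2",
    ("polyacrylamide", "hts"): "Platforms 1 and 3",
    ("capillary", "hts"): "Platforms 2 and 3",
}
DEFAULT_PAIRS = tuple(PAIR_LABELS)


@dataclass
class PlatformPairStats:
    locus: str
    platforms: tuple[str, str]
    n_obs: int
    n_unique: int
    mean_diff: float  # bp, rounded to 1 decimal
    sd_diff: float  # bp, rounded to 1 decimal
    mean_raw: float  # unrounded mean (for downstream arithmetic)

    def __post_init__(self) -> None:
        if not self.n_obs >= self.n_unique >= 1:
            raise ValueError("need n_obs >= n_unique >= 1")


@dataclass
class ExplanationEntry:
    locus: str
    platforms: tuple[str, str]
    discrepancy: float  # observed mean difference, bp
    attributed: float  # bp accounted for by indels / scoring corrections
    residual: float
    verdict: str  # explained | partial | unexplained | undetermined


def pair_alleles(
    profile_a: AlleleProfile, profile_b: AlleleProfile, locus: str
) -> list[float]:
    """Signed allele-size differences (B - A) for one genotype at one locus.

    Pairs are sorted ascending and paired positionally; homozygotes give two
    observations; ND on either side gives none.
    """
    a = profile_a.calls.get(locus)
    b = profile_b.calls.get(locus)
    if a is None or b is None:
        return []
    return [y - x for x, y in zip(sorted(a), sorted(b))]


def locus_stats(
    diffs: Sequence[float],
    locus: str,
    platforms: tuple[str, str],
    n_unique: int,
) -> PlatformPairStats:
    """Observation-weighted mean/SD of signed differences for one locus.

    Differences are exact multiples of 0.1 bp, so the mean is computed in
    integer tenths and rounded half away from zero only for presentation.
    """
    if not diffs:
        raise ValueError(f"{locus}: zero comparisons")
    t = [tenths(d) for d in diffs]
    mean = Fraction(sum(t), len(t))  # in tenths
    mean_raw = float(mean) / 10.0
    mean_rounded = round_half_away(Fraction(mean, 10), 1)
    if len(t) > 1:
        mu = sum(t) / len(t)
        sd = math.sqrt(sum((x - mu) ** 2 for x in t) / (len(t) - 1)) / 10.0
    else:
        sd = 0.0
    return PlatformPairStats(
        locus=locus,
        platforms=platforms,
        n_obs=len(t),
        n_unique=n_unique,
        mean_diff=mean_rounded,
        sd_diff=round_half_away(sd, 1),
        mean_raw=mean_raw,
    )


def grand_stats(stats: Sequence[PlatformPairStats]) -> tuple[float, float]:
    """Unweighted mean and sample SD over rounded per-locus means (1 dp)."""
    if len(stats) < 2:
        raise ValueError("grand statistics need at least two loci")
    t = [tenths(s.mean_diff) for s in stats]
    mean = round_half_away(Fraction(sum(t), 10 * len(t)), 1)
    mu = sum(t) / len(t)
    sd = math.sqrt(sum((x - mu) ** 2 for x in t) / (len(t) - 1)) / 10.0
    return mean, round_half_away(sd, 1)


@dataclass
class ConcordanceTable:
    per_locus: dict[tuple[tuple[str, str], str], PlatformPairStats]
    grand: dict[tuple[str, str], tuple[float, float]]
    allele_counts: dict[str, int]
    non_historic: set[str] = field(default_factory=set)

    def stat(self, platform_a: str, platform_b: str, locus: str) -> PlatformPairStats | None:
        return self.per_locus.get(((platform_a, platform_b), locus))

    @property
    def total_alleles(self) -> int:
        return sum(self.allele_counts.values())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        loci = sorted({k[1] for k in self.per_locus}, key=_locus_sort_key)
        for locus in loci:
            row: dict[str, object] = {
                "Locus": locus,
                "Alleles (n)": self.allele_counts.get(locus, 0),
            }
            for pair, label in PAIR_LABELS.items():
                s = self.per_locus.get((pair, locus))
                if s is not None:
                    row[label] = f"{s.mean_diff:+.1f} bp"
                elif "polyacrylamide" in pair and locus in self.non_historic:
                    row[label] = "N/A"
                else:
                    row[label] = "ND"
            rows.append(row)
        grand_row: dict[str, object] = {
            "Locus": "Av",
            "Alleles (n)": self.total_alleles,
        }
        for pair, label in PAIR_LABELS.items():
            if pair in self.grand:
                m, sd = self.grand[pair]
                grand_row[label] = f"{m:+.1f} bp (±{sd:.1f})"
            else:
                grand_row[label] = "ND"
        rows.append(grand_row)
        return pd.DataFrame(rows)


def _locus_sort_key(name: str) -> tuple[int, str]:
    try:
        return (LOCUS_ORDER.index(name), name)
    except ValueError:
        return (len(LOCUS_ORDER), name)


def _unique_count(
    profiles_a: Mapping[str, AlleleProfile],
    profiles_b: Mapping[str, AlleleProfile],
    locus: str,
) -> int:
    """Distinct platform-A allele identities (nearest integer) entering >=1
    comparison at this locus."""
    seen: set[int] = set()
    for genotype, pa in profiles_a.items():
        pb = profiles_b.get(genotype)
        if pb is None:
            continue
        a, b = pa.calls.get(locus), pb.calls.get(locus)
        if a is None or b is None:
            continue
        seen.update(int(round_half_away(x)) for x in a)
    return len(seen)


def build_concordance(
    by_platform: Mapping[str, Mapping[str, AlleleProfile]],
    panel: Sequence[LocusSpec],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> ConcordanceTable:
    """Compute per-locus and grand discrepancy statistics across platforms.

    ``by_platform`` maps platform name -> genotype -> profile.  Platform
    pairs involving polyacrylamide are skipped for loci without measured
    historic data.
    """
    loci = panel_by_name(panel)
    per_locus: dict[tuple[tuple[str, str], str], PlatformPairStats] = {}
    grand: dict[tuple[str, str], tuple[float, float]] = {}
    for pair in pairs:
        pa_name, pb_name = pair
        profs_a = by_platform.get(pa_name, {})
        profs_b = by_platform.get(pb_name, {})
        stats_for_pair: list[PlatformPairStats] = []
        for lname, locus in loci.items():
            if "polyacrylamide" in pair and not locus.historic_platform1:
                continue
            diffs: list[float] = []
            for genotype, prof_a in profs_a.items():
                prof_b = profs_b.get(genotype)
                if prof_b is not None:
                    diffs.extend(pair_alleles(prof_a, prof_b, lname))
            if not diffs:
                continue
            n_unique = _unique_count(profs_a, profs_b, lname)
            s = locus_stats(diffs, lname, pair, n_unique)
            per_locus[(pair, lname)] = s
            stats_for_pair.append(s)
        if len(stats_for_pair) >= 2:
            grand[pair] = grand_stats(stats_for_pair)

    # allele accounting: historic loci are counted over the platform-1
    # comparison, the remaining loci over capillary-vs-sequencing
    allele_counts: dict[str, int] = {}
    for lname, locus in loci.items():
        if locus.historic_platform1:
            pair = ("polyacrylamide", "capillary")
        else:
            pair = ("capillary", "hts")
        a, b = by_platform.get(pair[0], {}), by_platform.get(pair[1], {})
        n = _unique_count(a, b, lname)
        if n:
            allele_counts[lname] = n
    return ConcordanceTable(
        per_locus=per_locus,
        grand=grand,
        allele_counts=allele_counts,
        non_historic={l.name for l in panel if not l.historic_platform1},
    )


# ---------------------------------------------------------------------------
# explanation ledger


def _expected_delta(
    platform: str, dec: Decomposition | None, scoring_correction: int
) -> float:
    """Expected allele-size shift of a platform relative to the historic
    (clone-anchored) allele name."""
    if platform == "polyacrylamide":
        return 0.0
    if dec is None:
        return float(scoring_correction)
    amplified, sequenced = expected_platform_lengths(dec)
    shift = sequenced if platform == "hts" else amplified
    return float(shift + scoring_correction)


def explain(
    table: ConcordanceTable,
    decompositions: Mapping[str, Decomposition | None],
    scoring_corrections: Mapping[str, int] | None = None,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
) -> list[ExplanationEntry]:
    """Attribute each locus's platform discrepancy to sequence evidence.

    ``decompositions`` maps locus -> consistent across-strain decomposition
    of observed alleles against the original clone (None when alleles could
    not be sequenced).  ``scoring_corrections`` maps locus -> bp by which the
    historic name is known to be mis-scored relative to the true sequence.

    Verdicts: |residual| < 0.5 bp -> explained; some attribution but a
    >=0.5 bp residual -> partial; no sequence data -> undetermined; no
    attribution and a residual -> unexplained.
    """
    scoring = dict(HISTORIC_SCORING_CORRECTIONS if scoring_corrections is None else scoring_corrections)
    entries: list[ExplanationEntry] = []
    for pair in pairs:
        for (p, lname), s in table.per_locus.items():
            if p != pair:
                continue
            dec = decompositions.get(lname)
            corr = scoring.get(lname, 0)
            if dec is None and corr == 0:
                # alleles could not be sequenced and no documented correction
                entries.append(
                    ExplanationEntry(lname, pair, s.mean_diff, 0.0, s.mean_diff, "undetermined")
                )
                continue
            attributed = _expected_delta(pair[1], dec, corr) - _expected_delta(pair[0], dec, corr)
            residual = round(s.mean_diff - attributed, 10)
            if abs(residual) < 0.5:
                verdict = "explained"
            elif attributed != 0:
                verdict = "partial"
            else:
                verdict = "unexplained"
            entries.append(
                ExplanationEntry(lname, pair, s.mean_diff, attributed, residual, verdict)
            )
    return entries
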