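"""Capillary fragment-size calibration against historic allele names.

Raw capillary sizes include the universal primer tail and sit a systematic
whole-bp offset away from the historic polyacrylamide allele names.  The
calibration pipeline is: subtract the tail, estimate a per-locus integer
offset from control samples of known genotype (the historic sizes minus the
tail-subtracted observations, homozygotes counted twice, half-integers
rounded away from zero), and snap calibrated sizes to named allele bins
within a +/-1 bp tolerance.

Bins follow fragment-analysis practice: each bin has a float *center*
(the mean calibrated size of the control observations carrying that allele)
and an integer *name* (the historic allele).  The name may sit off the
center - e.g. the DVSSR4 allele migrating at 251 bp keeps its historic name
"250" - and loci whose alleles shift by unequal sub-bp amounts (Dvit3's two
alleles differ by 1.9 bp in shift) still close exactly on their controls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._round import round_half_away
from .panel import (
    AlleleProfile,
    LocusSpec,
    PeakRecord,
    ReferencePanel,
    panel_by_name,
)


class CalibrationError(ValueError):
    pass


@dataclass
class AlleleBin:
    """A named allele bin: integer historic name + calibrated-space center."""

    name: int
    center: float


@dataclass
class LocusCalibration:
    tail_length: int
    offset: int
    bins: list[AlleleBin] = field(default_factory=list)
    uncalibrated: bool = False

    def __post_init__(self) -> None:
        if abs(self.offset) > 5:
            raise CalibrationError(f"|offset| {self.offset} exceeds 5 bp")


@dataclass
class CalibrationModel:
    loci: dict[str, LocusCalibration]
    tolerance: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise CalibrationError("tolerance must be > 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tolerance": self.tolerance,
            "loci": {
                name: {
                    "tail_length": lc.tail_length,
                    "offset": lc.offset,
                    "uncalibrated": lc.uncalibrated,
                    "bins": [{"name": b.name, "center": b.center} for b in lc.bins],
                }
                for name, lc in self.loci.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        loci = {
            name: LocusCalibration(
                tail_length=d["tail_length"],
                offset=d["offset"],
                uncalibrated=d.get("uncalibrated", False),
                bins=[AlleleBin(b["name"], b["center"]) for b in d["bins"]],
            )
            for name, d in payload["loci"].items()
        }
        return cls(loci=loci, tolerance=payload.get("tolerance", 1.0))


@dataclass
class AlleleCall:
    sample_id: str
    locus: str
    called: tuple[int, int] | None
    raw: tuple[float, float] | None
    flags: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------


def subtract_tail(raw_size: float, locus: LocusSpec) -> float:
    """Remove the universal-tail length from a raw fragment size."""
    out = raw_size - locus.tail_length
    if out <= 0:
        raise CalibrationError(
            f"{locus.name}: size {raw_size} not larger than tail {locus.tail_length}"
        )
    return out


def assign_locus(
    peak: PeakRecord, panel: Sequence[LocusSpec]
) -> LocusSpec | None:
    """Candidate locus for a peak by dye and tail-subtracted size range."""
    for locus in panel:
        lo, hi = locus.size_range
        if peak.dye == locus.dye and lo <= peak.raw_size - locus.tail_length <= hi:
            return locus
    return None


@dataclass
class ArtifactConfig:
    """Thresholds for capillary artifact removal (conservative defaults;
    none of these are published values)."""

    pullup_window: float = 0.5  # bp; size proximity for cross-dye pull-up
    pullup_ratio: float = 10.0  # min height ratio of the causative peak
    stutter_min: float = 0.5  # bp; satellite window below a retained peak
    stutter_max: float = 2.5
    stutter_ratio: float = 2.0  # min height ratio of the retained parent
    min_relative_height: float = 0.2  # secondary-allele height floor


def filter_artifacts(
    peaks: Sequence[PeakRecord],
    panel: Sequence[LocusSpec],
    config: ArtifactConfig | None = None,
) -> dict[tuple[str, str], list[PeakRecord]]:
    """Remove pull-up and homopolymer stutter peaks; keep <=2 peaks per locus.

    Pull-up: a peak within ``pullup_window`` bp of a >=``pullup_ratio``-times
    taller peak in a *different* dye of the same sample.  Stutter: at
    homopolymer loci, a peak 1-2 bp below a >=2x-taller retained peak.
    After removal, peaks under ``min_relative_height`` of the locus maximum
    are dropped (distant low stutter products), and the two tallest
    survivors are kept.

    Returns ``{(sample_id, locus_name): [peaks]}``.
    """
    config = config or ArtifactConfig()
    by_sample: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample_id, []).append(p)

    out: dict[tuple[str, str], list[PeakRecord]] = {}
    for sample, sample_peaks in by_sample.items():
        # cross-dye pull-up first: compares peaks across loci
        surviving = []
        for p in sample_peaks:
            pulled = any(
                q.dye != p.dye
                and abs(q.raw_size - p.raw_size) <= config.pullup_window
                and q.height >= config.pullup_ratio * p.height
                for q in sample_peaks
            )
            if not pulled:
                surviving.append(p)

        by_locus: dict[str, list[PeakRecord]] = {}
        for p in surviving:
            locus = assign_locus(p, panel)
            if locus is not None:
                by_locus.setdefault(locus.name, []).append(p)

        loci = panel_by_name(panel)
        for lname, lpeaks in by_locus.items():
            locus = loci[lname]
            lpeaks = sorted(lpeaks, key=lambda p: -p.height)
            retained: list[PeakRecord] = []
            for p in lpeaks:
                is_stutter = locus.is_homopolymer and any(
                    config.stutter_min <= q.raw_size - p.raw_size <= config.stutter_max
                    and q.height >= config.stutter_ratio * p.height
                    for q in retained
                )
                if not is_stutter:
                    retained.append(p)
            if retained:
                floor_h = config.min_relative_height * retained[0].height
                retained = [p for p in retained if p.height >= floor_h]
            out[(sample, lname)] = retained[:2]
    return out


# ---------------------------------------------------------------------------


def calibrate_from_profiles(
    observed: Mapping[str, AlleleProfile],
    control_truth: ReferencePanel,
    panel: Sequence[LocusSpec],
    tolerance: float = 1.0,
) -> CalibrationModel:
    """Estimate offsets and bins from tail-subtracted control profiles.

    For each locus, pair each control's observed alleles against its historic
    genotype (both sorted ascending, homozygote observations counted twice).
    The locus offset is the integer nearest the mean of
    (historic - observed), half-integers away from zero; bin centers are the
    mean calibrated observation per historic allele name.
    """
    loci = panel_by_name(panel)
    model_loci: dict[str, LocusCalibration] = {}
    for lname, locus in loci.items():
        diffs: list[float] = []
        per_allele: dict[int, list[float]] = {}
        for sample, truth_prof in control_truth:
            obs_prof = observed.get(sample)
            if obs_prof is None:
                continue
            truth = truth_prof.calls.get(lname)
            obs = obs_prof.calls.get(lname)
            if truth is None or obs is None:
                continue
            for h, o in zip(sorted(truth), sorted(obs)):
                diffs.append(h - o)
                per_allele.setdefault(int(h), []).append(o)
        if not diffs:
            warnings.warn(f"{lname}: no control observations; offset left at 0")
            model_loci[lname] = LocusCalibration(
                tail_length=locus.tail_length, offset=0, uncalibrated=True
            )
            continue
        offset = int(round_half_away(sum(diffs) / len(diffs)))
        bins = [
            AlleleBin(name=name, center=sum(obs) / len(obs) + offset)
            for name, obs in sorted(per_allele.items())
        ]
        model_loci[lname] = LocusCalibration(
            tail_length=locus.tail_length, offset=offset, bins=bins
        )
    return CalibrationModel(loci=model_loci, tolerance=tolerance)


def estimate_offsets(
    control_peaks: Sequence[PeakRecord],
    control_truth: ReferencePanel,
    panel: Sequence[LocusSpec],
    tolerance: float = 1.0,
    config: ArtifactConfig | None = None,
) -> CalibrationModel:
    """Estimate a CalibrationModel from raw control peak data.

    Filters artifacts, assigns peaks to loci, subtracts tails, and delegates
    to :func:`calibrate_from_profiles`.
    """
    filtered = filter_artifacts(control_peaks, panel, config)
    loci = panel_by_name(panel)
    profiles: dict[str, AlleleProfile] = {}
    for (sample, lname), peaks in filtered.items():
        prof = profiles.setdefault(
            sample, AlleleProfile(sample_id=sample, platform="capillary")
        )
        if not peaks:
            prof.calls[lname] = None
            continue
        sizes = sorted(subtract_tail(p.raw_size, loci[lname]) for p in peaks)
        if len(sizes) == 1:
            sizes = [sizes[0], sizes[0]]
        prof.calls[lname] = (sizes[0], sizes[1])
    return calibrate_from_profiles(profiles, control_truth, panel, tolerance)


def _call_size(
    size: float, cal: LocusCalibration, tolerance: float
) -> tuple[int, set[str]]:
    """Snap one calibrated size to a named bin (or a provisional bin)."""
    flags: set[str] = set()
    best: AlleleBin | None = None
    best_d: float | None = None
    for b in cal.bins:
        d = abs(size - b.center)
        if best_d is None or d < best_d - 1e-9:
            best, best_d = b, d
            flags.discard("bin_tie")
        elif best is not None and abs(d - best_d) <= 1e-9:
            # equidistant bins: take the lower-sized name and flag
            flags.add("bin_tie")
            if b.name < best.name:
                best = b
    if best is not None and best_d is not None and best_d <= tolerance:
        return best.name, flags
    flags.add("off_bin")
    flags.add("provisional_bin")
    return int(round_half_away(size)), flags


def call_alleles(
    filtered_peaks: Mapping[tuple[str, str], Sequence[PeakRecord]],
    model: CalibrationModel,
    panel: Sequence[LocusSpec],
) -> list[AlleleCall]:
    """Call named alleles from artifact-filtered peaks.

    Calibrated size = tail-subtracted size + locus offset; each retained peak
    snaps to the nearest bin within tolerance, otherwise to a provisional bin
    named by its rounded calibrated size.  One surviving peak gives a
    homozygote, zero gives ND.
    """
    loci = panel_by_name(panel)
    calls: list[AlleleCall] = []
    for (sample, lname), peaks in sorted(filtered_peaks.items()):
        if len(peaks) > 2:
            raise CalibrationError(
                f"{sample}/{lname}: multi-peak locus; inspect artifacts"
            )
        cal = model.loci.get(lname)
        if cal is None:
            continue
        if not peaks:
            calls.append(AlleleCall(sample, lname, None, None, {"nd"}))
            continue
        locus = loci[lname]
        raw = sorted(subtract_tail(p.raw_size, locus) for p in peaks)
        if len(raw) == 1:
            raw = [raw[0], raw[0]]
        named: list[int] = []
        flags: set[str] = set()
        for r in raw:
            n, f = _call_size(r + cal.offset, cal, model.tolerance)
            named.append(n)
            flags |= f
        if cal.uncalibrated:
            flags.add("uncalibrated")
        named.sort()
        calls.append(
            AlleleCall(sample, lname, (named[0], named[1]), (raw[0], raw[1]), flags)
        )
    return calls


def calibrate_profile(
    profile: AlleleProfile, model: CalibrationModel
) -> AlleleProfile:
    """Apply a calibration model to a tail-subtracted float profile,
    producing integer historic allele names (used for genotype matching)."""
    out = AlleleProfile(sample_id=profile.sample_id, platform=profile.platform)
    for lname, pair in profile.calls.items():
        cal = model.loci.get(lname)
        if pair is None or cal is None:
            out.calls[lname] = None
            continue
        named = []
        for a in pair:
            n, flags = _call_size(a + cal.offset, cal, model.tolerance)
            named.append(n)
            if "provisional_bin" in flags:
                out.notes[lname] = f"provisional bin {n}"
        out.calls[lname] = (min(named), max(named))
    return out
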