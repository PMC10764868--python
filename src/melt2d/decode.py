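"""Decode (channel, Tm) peak calls into per-locus genotypes.

Each detected peak is matched to the unique panel coordinate in the same
channel within the panel's Tm tolerance; the presence/absence pattern of the
two allele coordinates of a locus then determines its genotype class:
wild-only, both, mutant-only or neither (no call). Because the bundled panel
assigns wild alleles to FAM, mutant alleles to Alexa568 and splits HEX at
48 C, the channel and temperature of a peak jointly identify the allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from . import genotypes as gt
from .meltcall import PeakCall, call_peaks
from .panel import Allele, AlleleCoordinate, Channel, Panel, HEX_SPLIT_C
from .simulate import MeltTrace

__all__ = [
    "AlleleEvidence",
    "PeakAssignment",
    "SampleGenotypeCall",
    "assign_peaks",
    "call_genotypes",
    "hex_threshold_check",
    "enumerate_genotype_classes",
    "genotype_sample",
]


@dataclass(frozen=True)
class AlleleEvidence:
    """A peak matched to one allele coordinate."""

    locus_id: str
    allele: Allele
    matched_peak: PeakCall
    delta_tm: float


@dataclass
class PeakAssignment:
    evidence: list[AlleleEvidence]
    unassigned: list[PeakCall]
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class SampleGenotypeCall:
    """Decoded genotypes for one sample with QC annotations."""

    sample_id: str
    calls: dict[str, str]
    unassigned_peaks: list[PeakCall] = field(default_factory=list)
    qc_flags: list[str] = field(default_factory=list)

    @property
    def passed_qc(self) -> bool:
        return not self.qc_flags


def assign_peaks(
    panel: Panel, peaks: Iterable[PeakCall] | Mapping[Channel, Sequence[PeakCall]]
) -> PeakAssignment:
    """Match one sample's peaks to panel coordinates.

    Each peak is assigned to the nearest coordinate in its own channel within
    ``panel.tolerance_c``, or left unassigned. When two peaks compete for one
    coordinate the closer wins; the loser is unassigned and the sample is
    QC-flagged. (In a validated panel the +/- tolerance windows are disjoint,
    so a peak can never sit within tolerance of two coordinates.)
    """
    if isinstance(peaks, Mapping):
        flat = [p for ch in peaks for p in peaks[ch]]
    else:
        flat = list(peaks)
    best: dict[tuple[str, Allele], AlleleEvidence] = {}
    unassigned: list[PeakCall] = []
    flags: list[str] = []
    for peak in flat:
        candidates = [
            (abs(peak.tm_c - c.tm_c), c)
            for c in panel.coordinates_in(peak.channel)
            if abs(peak.tm_c - c.tm_c) <= panel.tolerance_c
        ]
        if not candidates:
            unassigned.append(peak)
            continue
        delta, coord = min(candidates, key=lambda dc: dc[0])
        key = (coord.locus_id, coord.allele)
        ev = AlleleEvidence(coord.locus_id, coord.allele, peak, delta)
        if key in best:
            flags.append(
                f"{coord.locus_id}/{coord.allele.value}: two {peak.channel.value} peaks "
                f"within tolerance of {coord.tm_c} C"
            )
            if delta < best[key].delta_tm:
                unassigned.append(best[key].matched_peak)
                best[key] = ev
            else:
                unassigned.append(peak)
        else:
            best[key] = ev
    evidence = sorted(best.values(), key=lambda e: (e.locus_id, e.allele.value))
    return PeakAssignment(evidence=evidence, unassigned=unassigned, qc_flags=flags)


def call_genotypes(
    panel: Panel, assignment: PeakAssignment, sample_id: str = "sample"
) -> SampleGenotypeCall:
    """Turn allele evidence into per-locus genotype classes.

    Diploid loci: wild only -> WW, both -> WM, mutant only -> MM, neither ->
    no_call. Mitochondrial loci: wild only -> wild homoplasmic, mutant only
    -> mutant homoplasmic, both -> heteroplasmic (QC-flagged: a physically
    possible state the assay's validation cohort never showed), neither ->
    no_call. Every no_call is QC-flagged since a working multiplex emits at
    least one allele peak per locus.
    """
    present: dict[str, set[Allele]] = {l: set() for l in panel.locus_ids}
    for ev in assignment.evidence:
        present[ev.locus_id].add(ev.allele)
    calls: dict[str, str] = {}
    flags = list(assignment.qc_flags)
    for locus in panel.loci:
        cls = gt.class_from_alleles(present[locus.locus_id], locus.ploidy)
        calls[locus.locus_id] = cls
        if cls == gt.NO_CALL:
            flags.append(f"{locus.locus_id}: no allele peak detected")
        elif cls == gt.HETEROPLASMIC:
            flags.append(f"{locus.locus_id}: heteroplasmic pattern (both mitochondrial peaks)")
    for peak in assignment.unassigned:
        flags.append(
            f"unassigned {peak.channel.value} peak at {peak.tm_c:.1f} C"
        )
    return SampleGenotypeCall(
        sample_id=sample_id,
        calls=calls,
        unassigned_peaks=list(assignment.unassigned),
        qc_flags=flags,
    )


def hex_threshold_check(
    panel: Panel, assignment: PeakAssignment
) -> list[str]:
    """Verify assigned HEX peaks obey the 48 C wild/mutant split.

    Wild-type tag-probe duplexes in the HEX channel melt below 48 C and
    mutant ones above it; a breach is possible only with a mis-specified
    panel and is returned as a list of discrepancy messages (empty = pass).
    """
    issues = []
    for ev in assignment.evidence:
        if ev.matched_peak.channel != Channel.HEX:
            continue
        tm = ev.matched_peak.tm_c
        if ev.allele == Allele.WILD and not tm < HEX_SPLIT_C:
            issues.append(
                f"{ev.locus_id}: HEX peak at {tm:.1f} C assigned to a wild allele"
            )
        if ev.allele == Allele.MUTANT and not tm > HEX_SPLIT_C:
            issues.append(
                f"{ev.locus_id}: HEX peak at {tm:.1f} C assigned to a mutant allele"
            )
    return issues


def enumerate_genotype_classes(panel: Panel) -> list[tuple[str, str]]:
    """All (locus, genotype class) pairs the assay can report: 3 per locus."""
    return [
        (locus.locus_id, cls)
        for locus in panel.loci
        for cls in gt.classes_for(locus.ploidy)
    ]


def genotype_sample(
    panel: Panel,
    traces: Mapping[Channel, MeltTrace] | Iterable[MeltTrace],
    sample_id: Optional[str] = None,
    **peak_params,
) -> SampleGenotypeCall:
    """Full per-sample pipeline: peak-call each channel, assign, decode."""
    trace_list = list(traces.values()) if isinstance(traces, Mapping) else list(traces)
    if not trace_list:
        raise ValueError("no traces supplied")
    sid = sample_id or trace_list[0].sample_id
    peaks: list[PeakCall] = []
    for trace in trace_list:
        peaks.extend(call_peaks(trace, **peak_params))
    assignment = assign_peaks(panel, peaks)
    call = call_genotypes(panel, assignment, sample_id=sid)
    call.qc_flags.extend(hex_threshold_check(panel, assignment))
    return call
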