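"""Panel definition for two-dimensional (channel x Tm) melting-curve genotyping.

A panel places every allele of every assayed locus at one coordinate in a
two-dimensional space spanned by fluorophore channel and melting temperature.
Allele-specific forward primers carry a 5' "tag" homologous (with deliberate
mismatches) to one of three base-quenching probes; the tag-probe duplex melts
at a calibrated Tm, so each allele appears as one negative-derivative peak at
its (channel, Tm) coordinate.

The bundled ``deafness9`` panel covers nine hereditary hearing-loss hotspot
mutations in GJB2, SLC26A4, GJB3 and MT-RNR1, read out in the FAM, HEX and
Alexa568 channels.
"""

from __future__ import annotations

import re
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "Allele",
    "Channel",
    "Ploidy",
    "AlleleCoordinate",
    "OligoRecord",
    "Probe",
    "Locus",
    "Panel",
    "PanelConfigError",
    "ValidationReport",
    "MismatchProfile",
    "ARMSCheck",
    "load_panel",
    "bundled_panel_path",
    "load_bundled_panel",
    "validate_channel_rules",
    "tag_probe_mismatches",
    "check_arms_design",
]

# Acquisition window of the melt ramp, degrees C.
TM_MIN = 30.0
TM_MAX = 70.0

# HEX channel decision boundary: wild-type tag-probe duplexes melt below
# 48 C, mutant ones above it.
HEX_SPLIT_C = 48.0

_DNA_RE = re.compile(r"^[ACGTacgt]+$")


class Channel(str, Enum):
    FAM = "FAM"
    HEX = "HEX"
    ALEXA568 = "Alexa568"


class Allele(str, Enum):
    WILD = "wild"
    MUTANT = "mutant"


class Ploidy(str, Enum):
    DIPLOID = "diploid"
    MITOCHONDRIAL = "mitochondrial"


class PanelConfigError(ValueError):
    """Raised when a panel config file violates the schema or its invariants."""


class AlleleCoordinate(BaseModel):
    """One allele's position in (channel, Tm) space."""

    locus_id: str
    allele: Allele
    channel: Channel
    tm_c: float = Field(ge=TM_MIN, le=TM_MAX)


class Probe(BaseModel):
    """A base-quenching probe defining one fluorescence channel."""

    channel: Channel
    label: str
    sequence: str

    @field_validator("sequence")
    @classmethod
    def _dna(cls, v: str) -> str:
        if not _DNA_RE.match(v):
            raise ValueError("probe sequence must contain only A/C/G/T")
        return v.lower()


class OligoRecord(BaseModel):
    """Tagged allele-specific forward primer plus its reverse primer.

    ``tag_sequence`` is the lowercase 5' extension homologous to the channel
    probe; ``specific_primer`` is the 3' allele-discriminating part whose
    terminal base matches only one allele (ARMS design).
    """

    locus_id: str
    allele: Allele
    channel: Channel
    tag_sequence: str
    specific_primer: str
    reverse_primer: str

    @field_validator("tag_sequence", "specific_primer", "reverse_primer")
    @classmethod
    def _dna(cls, v: str) -> str:
        if not _DNA_RE.match(v):
            raise ValueError("sequence must contain only A/C/G/T")
        return v


class Locus(BaseModel):
    gene: str
    locus_id: str
    ploidy: Ploidy


class Panel(BaseModel):
    """A validated 2D-PCR assay definition.

    Invariants enforced at construction: unique locus ids, exactly one probe
    per channel, at most one coordinate per (locus, allele), every coordinate
    and oligo referring to a declared locus, and tag lengths equal to their
    channel probe length.
    """

    name: str = "panel"
    description: str = ""
    tolerance_c: float = Field(default=1.0, gt=0.0)
    loci: list[Locus]
    probes: list[Probe]
    coordinates: list[AlleleCoordinate]
    oligos: list[OligoRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_invariants(self) -> "Panel":
        locus_ids = [l.locus_id for l in self.loci]
        if len(set(locus_ids)) != len(locus_ids):
            raise ValueError("loci: duplicate locus_id")
        known = set(locus_ids)

        channels = [p.channel for p in self.probes]
        if len(set(channels)) != len(channels):
            raise ValueError("probes: more than one probe for a channel")

        seen: set[tuple[str, Allele]] = set()
        for c in self.coordinates:
            if c.locus_id not in known:
                raise ValueError(f"coordinates: unknown locus_id {c.locus_id!r}")
            key = (c.locus_id, c.allele)
            if key in seen:
                raise ValueError(
                    f"coordinates: duplicate coordinate for ({c.locus_id}, {c.allele.value})"
                )
            seen.add(key)

        probe_len = {p.channel: len(p.sequence) for p in self.probes}
        for o in self.oligos:
            if o.locus_id not in known:
                raise ValueError(f"oligos: unknown locus_id {o.locus_id!r}")
            if o.channel in probe_len and len(o.tag_sequence) != probe_len[o.channel]:
                raise ValueError(
                    f"oligos: tag length {len(o.tag_sequence)} for ({o.locus_id}, "
                    f"{o.allele.value}) differs from {o.channel.value} probe length "
                    f"{probe_len[o.channel]}"
                )
        return self

    # -- convenience lookups -------------------------------------------------

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus(self, locus_id: str) -> Locus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def probe(self, channel: Channel | str) -> Probe:
        channel = Channel(channel)
        for p in self.probes:
            if p.channel == channel:
                return p
        raise KeyError(channel)

    def coordinate(self, locus_id: str, allele: Allele | str) -> AlleleCoordinate:
        allele = Allele(allele)
        for c in self.coordinates:
            if c.locus_id == locus_id and c.allele == allele:
                return c
        raise KeyError((locus_id, allele))

    def coordinates_in(self, channel: Channel | str) -> list[AlleleCoordinate]:
        channel = Channel(channel)
        return [c for c in self.coordinates if c.channel == channel]

    def genes(self) -> dict[str, list[str]]:
        """Map gene name -> locus ids, preserving panel order."""
        out: dict[str, list[str]] = {}
        for l in self.loci:
            out.setdefault(l.gene, []).append(l.locus_id)
        return out


# ---------------------------------------------------------------------------
# loading


def load_panel(config_path: str | Path) -> Panel:
    """Load and validate a panel from a YAML (or JSON) config file.

    Raises :class:`PanelConfigError` naming the offending field on any schema
    violation, including duplicate (locus, allele) coordinates.
    """
    path = Path(config_path)
    if not path.exists():
        raise PanelConfigError(f"panel config not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise PanelConfigError(f"panel config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelConfigError("panel config must be a mapping at top level")
    try:
        return Panel.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        )
        raise PanelConfigError(f"invalid panel config {path.name}: {details}") from exc


def bundled_panel_path() -> Path:
    """Filesystem path of the bundled nine-locus deafness panel."""
    return Path(str(resources.files("melt2d").joinpath("panels/deafness9.yaml")))


def load_bundled_panel() -> Panel:
    return load_panel(bundled_panel_path())


# ---------------------------------------------------------------------------
# channel-rule validation


class ValidationReport(BaseModel):
    """Outcome of the panel channel-rule checks.

    ``violations`` lists human-readable rule breaches with locus ids;
    ``min_gap_c`` gives the minimum within-channel Tm separation.
    """

    passed: bool
    violations: list[str]
    min_gap_c: dict[str, float]

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def validate_channel_rules(panel: Panel) -> ValidationReport:
    """Check the panel's channel semantics and Tm spacing.

    Rules (bundled-panel conventions made explicit and checkable):

    * every FAM coordinate is a wild allele;
    * every Alexa568 coordinate is a mutant allele;
    * HEX wild coordinates melt below 48 C, HEX mutant ones above it;
    * within each channel any two coordinates are separated by more than
      twice the matching tolerance, so +/- tolerance windows are disjoint.
    """
    violations: list[str] = []
    for c in panel.coordinates:
        if c.channel == Channel.FAM and c.allele != Allele.WILD:
            violations.append(f"{c.locus_id}: FAM coordinate is not a wild allele")
        if c.channel == Channel.ALEXA568 and c.allele != Allele.MUTANT:
            violations.append(f"{c.locus_id}: Alexa568 coordinate is not a mutant allele")
        if c.channel == Channel.HEX:
            if c.allele == Allele.WILD and not c.tm_c < HEX_SPLIT_C:
                violations.append(
                    f"{c.locus_id}: HEX wild coordinate at {c.tm_c} C is not below "
                    f"{HEX_SPLIT_C} C"
                )
            if c.allele == Allele.MUTANT and not c.tm_c > HEX_SPLIT_C:
                violations.append(
                    f"{c.locus_id}: HEX mutant coordinate at {c.tm_c} C is not above "
                    f"{HEX_SPLIT_C} C"
                )

    min_gap: dict[str, float] = {}
    for channel in Channel:
        tms = sorted(c.tm_c for c in panel.coordinates_in(channel))
        if len(tms) < 2:
            continue
        gap = min(b - a for a, b in zip(tms, tms[1:]))
        min_gap[channel.value] = round(gap, 6)
        if gap <= 2.0 * panel.tolerance_c:
            violations.append(
                f"{channel.value}: minimum Tm gap {gap:.2f} C does not exceed twice "
                f"the tolerance ({panel.tolerance_c} C)"
            )
    return ValidationReport(passed=not violations, violations=violations, min_gap_c=min_gap)


# ---------------------------------------------------------------------------
# sequence-design checks


class MismatchProfile(BaseModel):
    count: int
    positions: list[int]  # 1-based, 5'->3'


def tag_probe_mismatches(tag: str, probe: str) -> MismatchProfile:
    """Compare a primer tag against its channel probe, case-insensitively.

    The deliberate tag-probe mismatches tune the duplex Tm: fewer mismatches,
    higher Tm. Returns the mismatch count and 1-based positions.
    """
    for name, seq in (("tag", tag), ("probe", probe)):
        if not seq or not _DNA_RE.match(seq):
            raise ValueError(f"{name} must be a non-empty A/C/G/T string")
    if len(tag) != len(probe):
        raise ValueError(
            f"tag length {len(tag)} differs from probe length {len(probe)}"
        )
    positions = [
        i + 1 for i, (a, b) in enumerate(zip(tag.lower(), probe.lower())) if a != b
    ]
    return MismatchProfile(count=len(positions), positions=positions)


class ARMSCheck(BaseModel):
    """Result of the allele-specific (ARMS) primer design check.

    ``three_prime_ok`` reports whether the 3'-terminal base is the declared
    allele-discriminating base. When a template is supplied,
    ``artificial_mismatch_ok`` reports whether exactly the declared artificial
    mismatches fall in the allowed window near the 3' end; otherwise None.
    Positions are counted 1-based from the 3' terminus.
    """

    three_prime_ok: bool
    three_prime_base: str
    expected_3prime_base: str
    artificial_mismatch_ok: Optional[bool] = None
    observed_mismatch_positions: list[int] = Field(default_factory=list)
    notes: list[str] = Field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.three_prime_ok and self.artificial_mismatch_ok is not False


def check_arms_design(
    oligo: OligoRecord,
    expected_3prime_base: str,
    mismatch_positions_allowed: tuple[int, int] = (3, 6),
    template: Optional[str] = None,
    declared_mismatch_positions: Iterable[int] = (),
) -> ARMSCheck:
    """Check the ARMS design rules on an allele-specific primer.

    The primer's 3'-terminal base must equal ``expected_3prime_base`` (the
    allele-discriminating base). When ``template`` (the target strand context,
    3'-aligned with the primer) is supplied, the primer is compared to it and
    every declared artificial mismatch must (a) actually mismatch the template
    and (b) sit within ``mismatch_positions_allowed`` bases of the 3' end;
    undeclared mismatches other than the terminal base itself fail the check.
    """
    primer = oligo.specific_primer
    if not primer:
        raise ValueError("oligo has an empty specific primer")
    base = primer[-1].upper()
    expected = expected_3prime_base.upper()
    if expected not in "ACGT":
        raise ValueError("expected_3prime_base must be one of A/C/G/T")
    check = ARMSCheck(
        three_prime_ok=(base == expected),
        three_prime_base=base,
        expected_3prime_base=expected,
    )
    if not check.three_prime_ok:
        check.notes.append(
            f"3' terminal base {base} does not match expected {expected}"
        )

    if template is None:
        return check

    if len(template) < len(primer):
        raise ValueError("template shorter than primer")
    lo, hi = mismatch_positions_allowed
    ref = template[-len(primer):]
    observed = [
        len(primer) - i
        for i in range(len(primer))
        if primer[i].upper() != ref[i].upper()
    ]
    observed.sort()
    check.observed_mismatch_positions = observed
    declared = sorted(set(int(p) for p in declared_mismatch_positions))
    ok = True
    for p in declared:
        if p not in observed:
            ok = False
            check.notes.append(f"declared artificial mismatch at 3' position {p} "
                               "does not mismatch the template")
        elif not lo <= p <= hi:
            ok = False
            check.notes.append(f"artificial mismatch at 3' position {p} outside "
                               f"allowed window {lo}-{hi}")
    for p in observed:
        if p == 1 or p in declared:
            continue  # terminal base discriminates the allele; not "artificial"
        ok = False
        check.notes.append(f"undeclared mismatch against template at 3' position {p}")
    check.artificial_mismatch_ok = ok
    return check
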