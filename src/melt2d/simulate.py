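"""Synthetic three-channel melting curves and cohorts.

Each present allele is rendered as a two-state duplex dissociation: a
sigmoidal fluorescence step centred at the allele's calibrated Tm, so that
the negative derivative -dF/dT peaks at the Tm. Traces are the sum of the
per-allele steps, a linear baseline, and additive Gaussian noise on the
default 30-70 C acquisition grid.

The cohort generators produce per-sample genotype tables: a deterministic
fixture replaying the published 116-patient hearing-loss cohort, and a
Hardy-Weinberg sampler parameterised by per-locus mutant allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import genotypes as gt
from .panel import Allele, Channel, Panel, Ploidy

__all__ = [
    "GRID_MIN_C",
    "GRID_MAX_C",
    "GRID_STEP_C",
    "DEFAULT_WIDTH_C",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BASELINE_SLOPE",
    "DEFAULT_BASELINE_INTERCEPT",
    "DuplexComponent",
    "MeltTrace",
    "SampleGenotype",
    "CohortGenotypes",
    "SimulationParams",
    "default_grid",
    "render_channel",
    "simulate_sample",
    "fixture_cohort",
    "sample_cohort",
    "FIXTURE_ALLELE_FREQUENCIES",
]

GRID_MIN_C = 30.0
GRID_MAX_C = 70.0
GRID_STEP_C = 0.1

DEFAULT_WIDTH_C = 0.5
DEFAULT_NOISE_SD = 0.005
DEFAULT_BASELINE_SLOPE = -0.002  # fluorescence units per degree C
DEFAULT_BASELINE_INTERCEPT = 1.0


def default_grid() -> np.ndarray:
    """Uniform 30-70 C acquisition grid at 0.1 C steps (401 points)."""
    n = int(round((GRID_MAX_C - GRID_MIN_C) / GRID_STEP_C)) + 1
    return np.linspace(GRID_MIN_C, GRID_MAX_C, n)


@dataclass(frozen=True)
class DuplexComponent:
    """A two-state duplex: melts at ``tm_c`` over a transition of ``width_c``."""

    tm_c: float
    amplitude: float = 1.0
    width_c: float = DEFAULT_WIDTH_C

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.width_c <= 0:
            raise ValueError("width must be positive")


@dataclass
class MeltTrace:
    """One sample's fluorescence-vs-temperature signal in one channel."""

    sample_id: str
    channel: Channel
    temperatures: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 2:
            raise ValueError("temperature grid must be a 1-D array of >= 2 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.fluorescence.shape != self.temperatures.shape:
            raise ValueError("fluorescence and temperature lengths differ")


@dataclass
class SampleGenotype:
    """Ground-truth genotype classes for one sample, one entry per locus."""

    sample_id: str
    calls: dict[str, str]

    def require_loci(self, panel: Panel) -> None:
        missing = [l for l in panel.locus_ids if l not in self.calls]
        if missing:
            raise ValueError(f"sample {self.sample_id}: missing loci {missing}")
        extra = [l for l in self.calls if l not in panel.locus_ids]
        if extra:
            raise ValueError(f"sample {self.sample_id}: unknown loci {extra}")


@dataclass
class CohortGenotypes:
    samples: list[SampleGenotype]
    provenance: str = "fixture"  # "fixture" | "sampled"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)


@dataclass
class SimulationParams:
    """Noise/shape parameters for trace rendering.

    ``channel_scale`` rescales whole channels, emulating unequal probe
    amounts in the reaction mix; defaults to 1.0 everywhere.
    """

    width_c: float = DEFAULT_WIDTH_C
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_slope: float = DEFAULT_BASELINE_SLOPE
    baseline_intercept: float = DEFAULT_BASELINE_INTERCEPT
    channel_scale: dict[str, float] = field(default_factory=dict)

    def scale(self, channel: Channel) -> float:
        return float(self.channel_scale.get(channel.value, 1.0))


def render_channel(
    components: Sequence[DuplexComponent],
    grid: Optional[np.ndarray] = None,
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    noise_sd: float = 0.0,
    seed: Optional[int | np.random.Generator] = None,
    sample_id: str = "sample",
    channel: Channel | str = Channel.FAM,
) -> MeltTrace:
    """Render one channel's melt trace as a sum of two-state transitions.

    F(T) = sum_i amplitude_i * sigmoid((tm_i - T) / width_i)
           + intercept + slope * (T - T_min) + N(0, noise_sd).

    With no noise or baseline, the negative derivative of each isolated
    component peaks at its Tm (to within one grid step).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    f = np.full_like(t, baseline_intercept)
    f += baseline_slope * (t - t[0])
    for comp in components:
        x = (comp.tm_c - t) / comp.width_c
        f += comp.amplitude / (1.0 + np.exp(-x))
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        f += rng.normal(0.0, noise_sd, size=t.shape)
    return MeltTrace(sample_id=sample_id, channel=Channel(channel), temperatures=t, fluorescence=f)


def components_for_sample(
    panel: Panel, genotype: SampleGenotype, params: Optional[SimulationParams] = None
) -> dict[Channel, list[DuplexComponent]]:
    """Per-channel duplex components implied by a sample's genotype.

    Each present allele contributes one component at its (channel, Tm)
    coordinate; heterozygous/heteroplasmic alleles at half amplitude.
    """
    params = params or SimulationParams()
    genotype.require_loci(panel)
    out: dict[Channel, list[DuplexComponent]] = {ch: [] for ch in Channel}
    for locus_id in panel.locus_ids:
        for allele, dose in gt.allele_dosage(genotype.calls[locus_id]).items():
            coord = panel.coordinate(locus_id, allele)
            out[coord.channel].append(
                DuplexComponent(
                    tm_c=coord.tm_c,
                    amplitude=dose * params.scale(coord.channel),
                    width_c=params.width_c,
                )
            )
    return out


def simulate_sample(
    panel: Panel,
    genotype: SampleGenotype,
    params: Optional[SimulationParams] = None,
    seed: Optional[int | np.random.Generator] = None,
    grid: Optional[np.ndarray] = None,
) -> dict[Channel, MeltTrace]:
    """Simulate the three channel traces for one genotyped sample."""
    params = params or SimulationParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = components_for_sample(panel, genotype, params)
    return {
        ch: render_channel(
            comps[ch],
            grid=grid,
            baseline_slope=params.baseline_slope,
            baseline_intercept=params.baseline_intercept,
            noise_sd=params.noise_sd,
            seed=rng,
            sample_id=genotype.sample_id,
            channel=ch,
        )
        for ch in Channel
    }


def simulate_cohort(
    panel: Panel,
    cohort: CohortGenotypes,
    params: Optional[SimulationParams] = None,
    seed: Optional[int] = None,
    grid: Optional[np.ndarray] = None,
) -> dict[str, dict[Channel, MeltTrace]]:
    """Simulate traces for every sample in a cohort (one shared RNG stream)."""
    rng = np.random.default_rng(seed)
    return {
        s.sample_id: simulate_sample(panel, s, params=params, seed=rng, grid=grid)
        for s in cohort
    }


# ---------------------------------------------------------------------------
# cohorts


#: Observed mutant allele frequencies in the 116-patient cohort (fractions).
FIXTURE_ALLELE_FREQUENCIES: dict[str, float] = {
    "c.235delC": 37 / 232,
    "c.176-191del16": 6 / 232,
    "c.299_300delAT": 14 / 232,
    "c.919-2A>G": 17 / 232,
    "c.2168A>G": 5 / 232,
    "c.1229C>T": 0.0,
    "c.538C>T": 0.0,
    "m.1494C>T": 0.0,
    "m.1555A>G": 2 / 116,
}

_FIXTURE_LOCI = list(FIXTURE_ALLELE_FREQUENCIES)

# (count, {locus: class}) blocks reproducing the published 116-patient cohort:
# GJB2 34 (10x c.235delC hom, 1x c.176-191del16 hom, 2x c.299_300delAT hom,
# 6+3+1 compound het, 8+3 single het); SLC26A4 15 (3 hom, 4 compound het,
# 7+1 single het); MT-RNR1 2 homoplasmic m.1555A>G, one of them in a sample
# that also carries the c.919-2A>G/c.2168A>G compound het, so distinct
# carriers number 50 of 116.
_FIXTURE_BLOCKS: list[tuple[int, dict[str, str]]] = [
    (10, {"c.235delC": gt.MM}),
    (1, {"c.176-191del16": gt.MM}),
    (2, {"c.299_300delAT": gt.MM}),
    (6, {"c.235delC": gt.WM, "c.299_300delAT": gt.WM}),
    (3, {"c.235delC": gt.WM, "c.176-191del16": gt.WM}),
    (1, {"c.176-191del16": gt.WM, "c.299_300delAT": gt.WM}),
    (8, {"c.235delC": gt.WM}),
    (3, {"c.299_300delAT": gt.WM}),
    (3, {"c.919-2A>G": gt.MM}),
    (1, {"c.919-2A>G": gt.WM, "c.2168A>G": gt.WM, "m.1555A>G": gt.MUTANT_HOMOPLASMIC}),
    (3, {"c.919-2A>G": gt.WM, "c.2168A>G": gt.WM}),
    (7, {"c.919-2A>G": gt.WM}),
    (1, {"c.2168A>G": gt.WM}),
    (1, {"m.1555A>G": gt.MUTANT_HOMOPLASMIC}),
    (66, {}),
]


def _wild_calls(loci: Iterable[str], ploidy_of: Mapping[str, Ploidy]) -> dict[str, str]:
    return {l: gt.WILD_CLASS[ploidy_of[l]] for l in loci}


def fixture_cohort(panel: Optional[Panel] = None) -> CohortGenotypes:
    """The deterministic 116-sample cohort replaying the published genotypes.

    Every count in the published genotype and allele-frequency tables is
    reproduced exactly, including the single sample carrying both the
    SLC26A4 compound heterozygote and the homoplasmic m.1555A>G variant.
    """
    if panel is None:
        from .panel import load_bundled_panel

        panel = load_bundled_panel()
    ploidy_of = {l.locus_id: l.ploidy for l in panel.loci}
    loci = panel.locus_ids
    unknown = [l for b in _FIXTURE_BLOCKS for l in b[1] if l not in ploidy_of]
    if unknown:
        raise ValueError(f"fixture loci not in panel: {sorted(set(unknown))}")
    samples: list[SampleGenotype] = []
    i = 0
    for count, overrides in _FIXTURE_BLOCKS:
        for _ in range(count):
            i += 1
            calls = _wild_calls(loci, ploidy_of)
            calls.update(overrides)
            samples.append(SampleGenotype(sample_id=f"S{i:03d}", calls=calls))
    return CohortGenotypes(samples=samples, provenance="fixture", seed=None)


def sample_cohort(
    panel: Panel,
    n: int,
    allele_frequencies: Mapping[str, float],
    seed: Optional[int] = None,
) -> CohortGenotypes:
    """Draw a random cohort under Hardy-Weinberg equilibrium.

    Diploid loci are two independent Bernoulli(f) allele draws; mitochondrial
    loci a single Bernoulli(f) draw between the two homoplasmic states
    (heteroplasmy is representable downstream but not sampled). Loci are
    independent. Frequencies default to 0 for loci not listed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    for locus, f in allele_frequencies.items():
        if locus not in panel.locus_ids:
            raise ValueError(f"unknown locus in allele_frequencies: {locus!r}")
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"allele frequency for {locus} outside [0, 1]: {f}")
    rng = np.random.default_rng(seed)
    ploidy_of = {l.locus_id: l.ploidy for l in panel.loci}
    samples = []
    for i in range(n):
        calls: dict[str, str] = {}
        for locus in panel.locus_ids:
            f = float(allele_frequencies.get(locus, 0.0))
            if ploidy_of[locus] == Ploidy.DIPLOID:
                n_mut = int(rng.random() < f) + int(rng.random() < f)
                calls[locus] = (gt.WW, gt.WM, gt.MM)[n_mut]
            else:
                calls[locus] = gt.MUTANT_HOMOPLASMIC if rng.random() < f else gt.WILD_HOMOPLASMIC
        samples.append(SampleGenotype(sample_id=f"R{i + 1:05d}", calls=calls))
    return CohortGenotypes(samples=samples, provenance="sampled", seed=seed)
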