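"""Cohort-level accounting and statistics for hotspot-mutation screening.

Aggregates per-sample genotypes into the standard epidemiological outputs:
per-gene genotype categories (homozygous, compound heterozygous, single-site
heterozygous, homoplasmic) with positivity rates, per-site mutant allele
frequencies (diploid denominator 2n, mitochondrial denominator n), overall
carrier rate with cross-gene deduplication, Pearson chi-square comparisons
against published regional rates, and Cohen's kappa for method concordance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from scipy.stats import chi2_contingency, norm

from . import genotypes as gt
from .panel import Panel, Ploidy
from .simulate import CohortGenotypes, SampleGenotype

__all__ = [
    "GeneSummary",
    "SiteStats",
    "CohortSummary",
    "RegionComparison",
    "summarize_cohort",
    "chi_square_2x2",
    "compare_with_region",
    "cohens_kappa",
]


def _pct(k: int, n: int) -> Optional[float]:
    return round(100.0 * k / n, 1) if n else None


@dataclass
class GeneSummary:
    """Genotype-category counts for one gene."""

    gene: str
    positive: int = 0
    homozygous: int = 0
    compound_het: int = 0
    single_het: int = 0
    homoplasmic: int = 0
    other: int = 0  # patterns outside the four standard categories
    genotype_counts: Counter = field(default_factory=Counter)

    def positive_pct(self, n: int) -> Optional[float]:
        return _pct(self.positive, n)


@dataclass
class SiteStats:
    """Per-site carrier counts and mutant allele frequency."""

    locus_id: str
    gene: str
    ploidy: Ploidy
    het: int = 0
    hom: int = 0
    het_with_other_site: int = 0

    @property
    def mutant_alleles(self) -> int:
        # mitochondrial "hom" is a homoplasmic carrier counted once against
        # a haploid denominator; diploid homozygotes carry two alleles
        return self.het + (2 if self.ploidy == Ploidy.DIPLOID else 1) * self.hom

    def denominator(self, n_samples: int) -> int:
        return (2 if self.ploidy == Ploidy.DIPLOID else 1) * n_samples

    def frequency_pct(self, n_samples: int) -> Optional[float]:
        d = self.denominator(n_samples)
        return round(100.0 * self.mutant_alleles / d, 1) if d else None


@dataclass
class CohortSummary:
    n_samples: int
    genes: dict[str, GeneSummary]
    sites: dict[str, SiteStats]
    overall_carriers: int

    @property
    def overall_carrier_pct(self) -> Optional[float]:
        return _pct(self.overall_carriers, self.n_samples)

    def gene_positive_pct(self, gene: str) -> Optional[float]:
        return self.genes[gene].positive_pct(self.n_samples)

    def site_frequency_pct(self, locus_id: str) -> Optional[float]:
        return self.sites[locus_id].frequency_pct(self.n_samples)


GenotypeLike = Union[CohortGenotypes, Iterable]


def _iter_calls(genotypes: GenotypeLike) -> list[tuple[str, Mapping[str, str]]]:
    items = genotypes.samples if isinstance(genotypes, CohortGenotypes) else list(genotypes)
    out = []
    for s in items:
        out.append((s.sample_id, s.calls))
    return out


def summarize_cohort(panel: Panel, genotypes: GenotypeLike) -> CohortSummary:
    """Aggregate a fully-called cohort into gene and site summaries.

    Counting rules: gene positivity is the number of samples with at least
    one mutant allele in that gene; a compound heterozygote carries two
    different heterozygous sites within one gene; heterozygotes of different
    genes are counted separately per site; overall carriers deduplicate
    samples across genes; diploid mutant allele counts are het + 2 x hom over
    a 2n denominator, mitochondrial ones carrier counts over n.

    Raises on unknown loci and on ``no_call``/``conflict`` entries (the
    cohort must be QC-complete before summarising).
    """
    samples = _iter_calls(genotypes)
    ploidy_of = {l.locus_id: l.ploidy for l in panel.loci}
    gene_of = {l.locus_id: l.gene for l in panel.loci}
    genes = {g: GeneSummary(gene=g) for g in panel.genes()}
    sites = {
        l.locus_id: SiteStats(locus_id=l.locus_id, gene=l.gene, ploidy=l.ploidy)
        for l in panel.loci
    }
    carriers = 0
    for sample_id, calls in samples:
        unknown = [l for l in calls if l not in ploidy_of]
        if unknown:
            raise ValueError(f"sample {sample_id}: unknown loci {unknown}")
        bad = [l for l, c in calls.items() if c in (gt.NO_CALL, gt.CONFLICT)]
        if bad:
            raise ValueError(
                f"sample {sample_id}: unresolved calls at {bad}; "
                "summaries require a fully-called cohort"
            )
        mutant_sites: dict[str, list[tuple[str, str]]] = {g: [] for g in genes}
        for locus, cls in calls.items():
            if cls in gt.MUTANT_BEARING:
                mutant_sites[gene_of[locus]].append((locus, cls))
            if cls == gt.WM or cls == gt.HETEROPLASMIC:
                sites[locus].het += 1
            elif cls == gt.MM or cls == gt.MUTANT_HOMOPLASMIC:
                sites[locus].hom += 1
        if any(mutant_sites.values()):
            carriers += 1
        # heterozygotes carrying a second mutant site anywhere in the panel
        all_mut = [l for l, c in calls.items() if c in gt.MUTANT_BEARING]
        for locus, cls in calls.items():
            if cls == gt.WM and len(all_mut) > 1:
                sites[locus].het_with_other_site += 1
        for g, found in mutant_sites.items():
            if not found:
                continue
            summary = genes[g]
            summary.positive += 1
            classes = [c for _, c in found]
            loci = [l for l, _ in found]
            if all(c == gt.MUTANT_HOMOPLASMIC for c in classes):
                summary.homoplasmic += 1
                summary.genotype_counts[" + ".join(loci)] += 1
            elif len(found) == 1 and classes[0] == gt.MM:
                summary.homozygous += 1
                summary.genotype_counts[f"{loci[0]}/{loci[0]}"] += 1
            elif len(found) == 1 and classes[0] == gt.WM:
                summary.single_het += 1
                summary.genotype_counts[f"{loci[0]}/wt"] += 1
            elif len(found) >= 2 and all(c == gt.WM for c in classes):
                summary.compound_het += 1
                summary.genotype_counts["/".join(loci)] += 1
            else:
                summary.other += 1
                summary.genotype_counts[" + ".join(f"{l}({c})" for l, c in found)] += 1
    return CohortSummary(
        n_samples=len(samples), genes=genes, sites=sites, overall_carriers=carriers
    )


# ---------------------------------------------------------------------------
# statistics


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("all margins of the 2x2 table must be positive")
    stat, p, dof, _ = chi2_contingency(np.array([[a, b], [c, d]]), correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class RegionComparison:
    """A local-vs-published-rate 2x2 chi-square comparison."""

    site: str
    basis: str  # "allele" | "carrier"
    local_k: int
    local_n: int
    external_rate_percent: float
    external_n: int
    external_basis_n: int
    external_k: int
    chi_square: float
    df: int
    p_value: float

    @property
    def local_rate_percent(self) -> float:
        return round(100.0 * self.local_k / self.local_n, 1)


def compare_with_region(
    local_k: int,
    local_n: int,
    external_rate_percent: float,
    external_n: int,
    basis: str = "allele",
    site: str = "",
    diploid: bool = True,
) -> RegionComparison:
    """Chi-square a local count against a published external rate.

    ``external_n`` is a patient count; for allele-based comparisons at
    diploid loci the external denominator doubles to 2n alleles. The external
    numerator is the published rate applied to that denominator and rounded
    to the nearest integer.
    """
    if basis not in ("allele", "carrier"):
        raise ValueError("basis must be 'allele' or 'carrier'")
    if not 0.0 <= external_rate_percent <= 100.0:
        raise ValueError("external_rate_percent must be in [0, 100]")
    if external_n <= 0:
        raise ValueError("external_n must be positive")
    basis_n = external_n * 2 if (basis == "allele" and diploid) else external_n
    external_k = int(round(external_rate_percent * basis_n / 100.0))
    stat, dof, p = chi_square_2x2(
        local_k, local_n - local_k, external_k, basis_n - external_k
    )
    return RegionComparison(
        site=site,
        basis=basis,
        local_k=local_k,
        local_n=local_n,
        external_rate_percent=external_rate_percent,
        external_n=external_n,
        external_basis_n=basis_n,
        external_k=external_k,
        chi_square=stat,
        df=dof,
        p_value=p,
    )


def cohens_kappa(
    calls_a: Mapping, calls_b: Mapping
) -> tuple[float, float]:
    """Cohen's kappa between two categorical call sets over the same keys.

    Keys are typically (sample_id, locus_id) pairs pooled over a cohort.
    Returns (kappa, two-sided p-value) where p tests kappa = 0 using the
    large-sample standard error under independence. Total observed agreement
    yields kappa = 1 even in the degenerate single-category case.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("call sets must cover identical keys")
    keys = list(calls_a)
    n = len(keys)
    if n == 0:
        raise ValueError("call sets are empty")
    pairs = [(calls_a[k], calls_b[k]) for k in keys]
    po = sum(a == b for a, b in pairs) / n
    cats = sorted({c for pair in pairs for c in pair})
    pa = Counter(a for a, _ in pairs)
    pb = Counter(b for _, b in pairs)
    pe = sum((pa[c] / n) * (pb[c] / n) for c in cats)
    if po == 1.0:
        kappa = 1.0
    elif pe == 1.0:
        kappa = 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen large-sample variance of kappa under the null of chance
    # agreement; degenerate tables get p = 0 when agreement is total.
    if pe == 1.0:
        return kappa, 0.0 if po == 1.0 else 1.0
    var0 = (
        pe
        + pe * pe
        - sum((pa[c] / n) * (pb[c] / n) * (pa[c] / n + pb[c] / n) for c in cats)
    ) / (n * (1.0 - pe) ** 2)
    if var0 <= 0:
        return kappa, 0.0
    z = kappa / math.sqrt(var0)
    p = 2.0 * float(norm.sf(abs(z)))
    return kappa, p
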