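"""Per-locus genotype class labels and their text notation.

Diploid loci take one of three classes: homozygous wild (``WW``),
heterozygous (``WM``), homozygous mutant (``MM``). Mitochondrial loci are
haploid-like populations of genome copies, so their classes are
``wild_homoplasmic``, ``mutant_homoplasmic`` and ``heteroplasmic``.

Text notation in genotype tables follows the slash style used for hearing
loss variants ("c.235delC/wt", "c.235delC/c.235delC", "wt/wt"); homoplasmic
mitochondrial genotypes are written as the bare variant ("m.1555A>G") or
"wt", and heteroplasmy as "m.1555A>G/wt".
"""

from __future__ import annotations

from .panel import Allele, Ploidy

WW = "WW"
WM = "WM"
MM = "MM"
WILD_HOMOPLASMIC = "wild_homoplasmic"
MUTANT_HOMOPLASMIC = "mutant_homoplasmic"
HETEROPLASMIC = "heteroplasmic"
NO_CALL = "no_call"
CONFLICT = "conflict"

DIPLOID_CLASSES = (WW, WM, MM)
MITO_CLASSES = (WILD_HOMOPLASMIC, MUTANT_HOMOPLASMIC, HETEROPLASMIC)

#: classes in which the locus carries at least one mutant allele
MUTANT_BEARING = frozenset({WM, MM, MUTANT_HOMOPLASMIC, HETEROPLASMIC})

#: wild-type class per ploidy
WILD_CLASS = {Ploidy.DIPLOID: WW, Ploidy.MITOCHONDRIAL: WILD_HOMOPLASMIC}


def classes_for(ploidy: Ploidy) -> tuple[str, str, str]:
    return DIPLOID_CLASSES if ploidy == Ploidy.DIPLOID else MITO_CLASSES


def allele_dosage(genotype_class: str) -> dict[Allele, float]:
    """Relative amount of each allele present in a genotype class.

    Both alleles of a heterozygote (or both mitochondrial subpopulations of a
    heteroplasmy) contribute half the template each; homozygous/homoplasmic
    states contribute a full dose of a single allele.
    """
    table = {
        WW: {Allele.WILD: 1.0},
        WM: {Allele.WILD: 0.5, Allele.MUTANT: 0.5},
        MM: {Allele.MUTANT: 1.0},
        WILD_HOMOPLASMIC: {Allele.WILD: 1.0},
        MUTANT_HOMOPLASMIC: {Allele.MUTANT: 1.0},
        HETEROPLASMIC: {Allele.WILD: 0.5, Allele.MUTANT: 0.5},
    }
    try:
        return dict(table[genotype_class])
    except KeyError:
        raise ValueError(f"unknown genotype class {genotype_class!r}") from None


def class_from_alleles(present: set[Allele], ploidy: Ploidy) -> str:
    """Genotype class implied by the set of alleles observed at a locus."""
    if not present:
        return NO_CALL
    if ploidy == Ploidy.DIPLOID:
        if present == {Allele.WILD}:
            return WW
        if present == {Allele.MUTANT}:
            return MM
        return WM
    if present == {Allele.WILD}:
        return WILD_HOMOPLASMIC
    if present == {Allele.MUTANT}:
        return MUTANT_HOMOPLASMIC
    return HETEROPLASMIC


def to_notation(locus_id: str, genotype_class: str) -> str:
    """Render a genotype class in slash notation for genotype tables."""
    table = {
        WW: "wt/wt",
        WM: f"{locus_id}/wt",
        MM: f"{locus_id}/{locus_id}",
        WILD_HOMOPLASMIC: "wt",
        MUTANT_HOMOPLASMIC: locus_id,
        HETEROPLASMIC: f"{locus_id}/wt",
        NO_CALL: NO_CALL,
        CONFLICT: CONFLICT,
    }
    try:
        return table[genotype_class]
    except KeyError:
        raise ValueError(f"unknown genotype class {genotype_class!r}") from None


def from_notation(locus_id: str, text: str, ploidy: Ploidy) -> str:
    """Parse slash notation back into a genotype class."""
    text = text.strip()
    if text in (NO_CALL, CONFLICT):
        return text
    for cls in classes_for(ploidy):
        if to_notation(locus_id, cls) == text:
            return cls
    raise ValueError(f"cannot parse genotype {text!r} for locus {locus_id}")
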