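"""File formats: melt-curve CSV, genotype TSV, summary tables.

Melt traces travel as long-format CSV (``sample_id, channel, temperature,
fluorescence``), one row per acquisition point; a column map adapts
instrument exports with different headers. Genotypes travel as TSV with one
column per locus in slash notation plus a QC column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from . import genotypes as gt
from .cohortstats import CohortSummary, RegionComparison
from .decode import SampleGenotypeCall
from .panel import Channel, Panel
from .simulate import CohortGenotypes, MeltTrace, SampleGenotype

__all__ = [
    "MELT_COLUMNS",
    "read_melt_csv",
    "write_melt_csv",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "summary_gene_table",
    "summary_site_table",
    "summary_to_dict",
    "write_summary",
    "write_comparisons_tsv",
]

MELT_COLUMNS = ("sample_id", "channel", "temperature", "fluorescence")

TraceSet = Union[Iterable[MeltTrace], Mapping[str, Mapping[Channel, MeltTrace]]]


def _flatten(traces: TraceSet) -> list[MeltTrace]:
    if isinstance(traces, Mapping):
        return [t for per_sample in traces.values() for t in per_sample.values()]
    return list(traces)


def write_melt_csv(traces: TraceSet, path: str | Path) -> None:
    """Write melt traces as long-format CSV."""
    frames = []
    for t in _flatten(traces):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": t.sample_id,
                    "channel": t.channel.value,
                    "temperature": t.temperatures,
                    "fluorescence": t.fluorescence,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=MELT_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_melt_csv(
    path: str | Path, column_map: Optional[Mapping[str, str]] = None
) -> list[MeltTrace]:
    """Read melt traces from CSV, grouping rows by (sample, channel).

    ``column_map`` maps the canonical names (``sample_id``, ``channel``,
    ``temperature``, ``fluorescence``) to the file's actual headers. Rows may
    appear in any order; each trace is sorted by temperature. Missing columns
    and non-numeric cells raise with the column / row identified.
    """
    df = pd.read_csv(path, dtype=str)
    colmap = {k: (column_map or {}).get(k, k) for k in MELT_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise ValueError(f"melt CSV {path}: missing column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[list(MELT_COLUMNS)]
    for col in ("temperature", "fluorescence"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            # +2: one for the header line, one for 0- vs 1-based
            raise ValueError(
                f"melt CSV {path}: non-numeric {col!r} value "
                f"{df.loc[bad[0], col]!r} at line {bad[0] + 2}"
            )
        if converted.isna().any():
            raise ValueError(f"melt CSV {path}: empty {col!r} cell")
        df[col] = converted
    traces = []
    for (sample_id, channel), grp in df.groupby(["sample_id", "channel"], sort=True):
        grp = grp.sort_values("temperature")
        traces.append(
            MeltTrace(
                sample_id=str(sample_id),
                channel=Channel(channel),
                temperatures=grp["temperature"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# genotype tables


def write_genotype_tsv(
    samples: Union[CohortGenotypes, Iterable[Union[SampleGenotype, SampleGenotypeCall]]],
    panel: Panel,
    path: str | Path,
) -> None:
    """Write per-sample genotypes as TSV: sample_id, one locus column, QC."""
    items = samples.samples if isinstance(samples, CohortGenotypes) else list(samples)
    rows = []
    for s in items:
        row = {"sample_id": s.sample_id}
        for locus in panel.locus_ids:
            row[locus] = gt.to_notation(locus, s.calls[locus])
        flags = getattr(s, "qc_flags", None)
        row["qc"] = "; ".join(flags) if flags else "pass"
        rows.append(row)
    pd.DataFrame(rows, columns=["sample_id", *panel.locus_ids, "qc"]).to_csv(
        path, sep="\t", index=False
    )


def read_genotype_tsv(path: str | Path, panel: Panel) -> CohortGenotypes:
    """Read a genotype TSV back into a cohort of per-locus classes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", *panel.locus_ids) if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV {path}: missing column(s) {missing}")
    ploidy_of = {l.locus_id: l.ploidy for l in panel.loci}
    samples = []
    for _, row in df.iterrows():
        calls = {
            locus: gt.from_notation(locus, row[locus], ploidy_of[locus])
            for locus in panel.locus_ids
        }
        samples.append(SampleGenotype(sample_id=str(row["sample_id"]), calls=calls))
    return CohortGenotypes(samples=samples, provenance="fixture", seed=None)


# ---------------------------------------------------------------------------
# summaries


def summary_gene_table(summary: CohortSummary) -> pd.DataFrame:
    """Gene-level genotype-category table (one row per gene/category/genotype)."""
    rows = []
    n = summary.n_samples
    for gene, gs in summary.genes.items():
        rows.append(
            {"gene": gene, "category": "total", "genotype": "", "n": gs.positive,
             "percent": gs.positive_pct(n)}
        )
        for cat, count in (
            ("homozygous", gs.homozygous),
            ("compound_heterozygous", gs.compound_het),
            ("heterozygous", gs.single_het),
            ("homoplasmic", gs.homoplasmic),
            ("other", gs.other),
        ):
            if count == 0:
                continue
            rows.append(
                {"gene": gene, "category": cat, "genotype": "", "n": count,
                 "percent": _pct(count, n)}
            )
        for label, count in sorted(gs.genotype_counts.items()):
            rows.append(
                {"gene": gene, "category": "genotype", "genotype": label, "n": count,
                 "percent": None}
            )
    rows.append(
        {"gene": "ALL", "category": "carriers", "genotype": "", "n": summary.overall_carriers,
         "percent": summary.overall_carrier_pct}
    )
    return pd.DataFrame(rows, columns=["gene", "category", "genotype", "n", "percent"])


def summary_site_table(summary: CohortSummary) -> pd.DataFrame:
    """Per-site allele-frequency table (heterozygotes counted per site)."""
    rows = []
    for locus, st in summary.sites.items():
        rows.append(
            {
                "gene": st.gene,
                "locus_id": locus,
                "heterozygous": st.het,
                "homozygous": st.hom,
                "mutant_alleles": st.mutant_alleles,
                "denominator": st.denominator(summary.n_samples),
                "allele_frequency_percent": st.frequency_pct(summary.n_samples),
            }
        )
    return pd.DataFrame(rows)


def summary_to_dict(summary: CohortSummary) -> dict:
    n = summary.n_samples
    return {
        "n_samples": n,
        "overall_carriers": summary.overall_carriers,
        "overall_carrier_percent": summary.overall_carrier_pct,
        "genes": {
            g: {
                "positive": gs.positive,
                "positive_percent": gs.positive_pct(n),
                "homozygous": gs.homozygous,
                "compound_heterozygous": gs.compound_het,
                "heterozygous": gs.single_het,
                "homoplasmic": gs.homoplasmic,
                "other": gs.other,
                "genotypes": dict(sorted(gs.genotype_counts.items())),
            }
            for g, gs in summary.genes.items()
        },
        "sites": {
            locus: {
                "gene": st.gene,
                "heterozygous": st.het,
                "homozygous": st.hom,
                "mutant_alleles": st.mutant_alleles,
                "denominator": st.denominator(n),
                "allele_frequency_percent": st.frequency_pct(n),
                "het_with_other_site": st.het_with_other_site,
            }
            for locus, st in summary.sites.items()
        },
    }


def write_summary(summary: CohortSummary, out_prefix: str | Path) -> list[Path]:
    """Write gene TSV, site TSV and JSON summaries; returns paths written."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = [
        Path(f"{prefix}.genes.tsv"),
        Path(f"{prefix}.sites.tsv"),
        Path(f"{prefix}.json"),
    ]
    summary_gene_table(summary).to_csv(paths[0], sep="\t", index=False)
    summary_site_table(summary).to_csv(paths[1], sep="\t", index=False)
    paths[2].write_text(json.dumps(summary_to_dict(summary), indent=2) + "\n")
    return paths


def _format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def write_comparisons_tsv(
    comparisons: Iterable[RegionComparison], path: str | Path
) -> None:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "site": c.site,
                "basis": c.basis,
                "local_k": c.local_k,
                "local_n": c.local_n,
                "local_rate_percent": c.local_rate_percent,
                "external_rate_percent": c.external_rate_percent,
                "external_n_patients": c.external_n,
                "external_denominator": c.external_basis_n,
                "external_k": c.external_k,
                "chi_square": round(c.chi_square, 2),
                "df": c.df,
                "p_value": _format_p(c.p_value),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _pct(k: int, n: int) -> Optional[float]:
    return round(100.0 * k / n, 1) if n else None
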