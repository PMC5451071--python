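"""Cohort-level summaries: responder table, SI magnitudes, immunogenicity
plot coordinates, HLA allele-frequency tabulation, and a JSON report.

The immunogenicity view plots, per compound, the percentage of responding
donors against the mean stimulation index of the responders — compounds in
the upper right carry a higher T cell response risk. The HLA section
tabulates cohort allele frequencies at a class II locus (DRB1 by default)
and compares them to a user-supplied reference population by Pearson
correlation, a standard representativeness check for donor panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .assay_model import MISSING, OTHER, AlleleFrequencyTable, HLAGenotype
from .precursor_frequency import CohortFrequencySummary, FrequencyEstimate, cohort_frequency_summary
from .response_stats import DonorCompoundCall, calls_to_frame, responder_frequency

__all__ = [
    "CompoundSummary",
    "HLAFrequencyComparison",
    "magnitude_table",
    "immunogenicity_plot_table",
    "hla_allele_frequencies",
    "population_correlation",
    "build_report",
]


@dataclass(frozen=True)
class CompoundSummary:
    """One compound's cohort summary (means over all 26 donors unless noted)."""

    compound: str
    pct_responders: float
    mean_si_prolif_d6: float | None
    mean_si_prolif_d8: float | None
    mean_si_elispot: float | None
    mean_si_responders: float | None  # over responders' positive readouts only
    mean_freq_per_million: float | None
    sem_freq_per_million: float | None


@dataclass(frozen=True)
class HLAFrequencyComparison:
    """Pearson comparison of cohort vs reference allele frequencies at one locus."""

    locus: str
    alleles: tuple[str, ...]
    cohort_frequencies: tuple[float, ...]
    reference_frequencies: tuple[float, ...]
    pearson_r: float | None
    p_value: float | None
    flags: tuple[str, ...] = ()


def magnitude_table(calls: Iterable[DonorCompoundCall]) -> pd.DataFrame:
    """Mean SI per (compound, readout) over all donors (responders or not)."""
    frame = calls_to_frame(calls)
    table = (
        frame.pivot_table(index="compound", columns="readout", values="si", aggfunc="mean")
        .sort_index()
    )
    table.columns.name = None
    return table


def immunogenicity_plot_table(
    calls: Iterable[DonorCompoundCall],
    responder_si: Literal["positive_only", "all_readouts"] = "positive_only",
) -> pd.DataFrame:
    """Per-compound (pct_responders, mean SI of responders) coordinates.

    ``positive_only`` (default) averages SI over the positive readouts of
    responding donors; ``all_readouts`` averages over every readout of
    responding donors. Compounds without responders get NaN for the mean SI.
    """
    calls = list(calls)
    frame = calls_to_frame(calls)
    rows = []
    for compound in sorted(frame["compound"].unique()):
        pct = responder_frequency(calls, compound)
        sub = frame[(frame["compound"] == compound) & frame["responder"]]
        if responder_si == "positive_only":
            sub = sub[sub["positive"]]
        elif responder_si != "all_readouts":
            raise ValueError(f"unknown responder_si mode {responder_si!r}")
        mean_si = float(sub["si"].mean()) if len(sub) else math.nan
        rows.append((compound, pct, mean_si))
    return pd.DataFrame(rows, columns=["compound", "pct_responders", "mean_si_responders"])


def hla_allele_frequencies(
    genotypes: Iterable[HLAGenotype],
    locus: str,
    homozygote_convention: Literal["homozygous", "single"] = "homozygous",
) -> AlleleFrequencyTable:
    """Allele (chromosome) frequencies of a cohort at one locus.

    A genotype with a MISSING second allele contributes two chromosomes of
    the first allele under the ``homozygous`` convention (standard
    typing-report semantics) and one chromosome under ``single`` (treating
    the blank as a typing failure).
    """
    if homozygote_convention not in ("homozygous", "single"):
        raise ValueError(f"unknown convention {homozygote_convention!r}")
    counts: dict[str, int] = {}
    total = 0
    seen = False
    for g in genotypes:
        if g.locus != locus:
            continue
        seen = True
        counts[g.allele_1] = counts.get(g.allele_1, 0) + 1
        total += 1
        if g.allele_2 != MISSING:
            counts[g.allele_2] = counts.get(g.allele_2, 0) + 1
            total += 1
        elif homozygote_convention == "homozygous":
            counts[g.allele_1] += 1
            total += 1
    if not seen:
        raise ValueError(f"no genotypes at locus {locus}")
    return AlleleFrequencyTable(
        locus=locus,
        frequencies={a: counts[a] / total for a in sorted(counts)},
    )


def population_correlation(
    cohort: AlleleFrequencyTable, reference: AlleleFrequencyTable
) -> HLAFrequencyComparison:
    """Pearson correlation of cohort vs reference allele frequencies.

    Paired over the union of alleles of both tables (the OTHER remainder
    bucket excluded); an allele absent from one table enters as frequency 0.
    Zero variance in either vector leaves r undefined (None, flagged).
    """
    alleles = sorted(set(cohort.alleles()) | set(reference.alleles()))
    if len(alleles) < 3:
        raise ValueError("need at least 3 alleles in the union for a correlation")
    x = np.array([cohort.frequencies.get(a, 0.0) for a in alleles])
    y = np.array([reference.frequencies.get(a, 0.0) for a in alleles])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return HLAFrequencyComparison(
            locus=cohort.locus,
            alleles=tuple(alleles),
            cohort_frequencies=tuple(map(float, x)),
            reference_frequencies=tuple(map(float, y)),
            pearson_r=None,
            p_value=None,
            flags=("zero_variance",),
        )
    r, p = stats.pearsonr(x, y)
    return HLAFrequencyComparison(
        locus=cohort.locus,
        alleles=tuple(alleles),
        cohort_frequencies=tuple(map(float, x)),
        reference_frequencies=tuple(map(float, y)),
        pearson_r=float(r),
        p_value=float(p),
    )


def _none_if_nan(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def build_report(
    calls: Iterable[DonorCompoundCall],
    frequencies: Iterable[FrequencyEstimate] | None = None,
    hla_comparison: HLAFrequencyComparison | None = None,
) -> dict:
    """Assemble the machine-readable cohort summary (JSON-serialisable dict).

    Contains one :class:`CompoundSummary` per compound plus plot-ready
    tables: SI magnitudes per readout, per-donor frequency estimates with
    cohort mean ± SEM, responder percentages, and the percent-responders vs
    mean-responder-SI coordinates. The HLA section appears only when a
    comparison is supplied. Deterministic given its inputs.
    """
    calls = list(calls)
    mag = magnitude_table(calls)
    plot = immunogenicity_plot_table(calls).set_index("compound")
    freq_list = list(frequencies) if frequencies is not None else []
    freq_summaries: dict[str, CohortFrequencySummary] = {}
    for compound in sorted({e.compound for e in freq_list}):
        freq_summaries[compound] = cohort_frequency_summary(freq_list, compound)

    compounds = []
    for compound in sorted({c.compound for c in calls}):
        fsum = freq_summaries.get(compound)
        row = mag.loc[compound] if compound in mag.index else pd.Series(dtype=float)
        compounds.append(
            CompoundSummary(
                compound=compound,
                pct_responders=float(plot.loc[compound, "pct_responders"]),
                mean_si_prolif_d6=_none_if_nan(row.get("prolif_d6", math.nan)),
                mean_si_prolif_d8=_none_if_nan(row.get("prolif_d8", math.nan)),
                mean_si_elispot=_none_if_nan(row.get("elispot", math.nan)),
                mean_si_responders=_none_if_nan(plot.loc[compound, "mean_si_responders"]),
                mean_freq_per_million=fsum.mean_per_million if fsum else None,
                sem_freq_per_million=fsum.sem_per_million if fsum else None,
            )
        )

    report: dict = {
        "n_donors": len({c.donor_id for c in calls}),
        "compounds": [asdict(c) for c in compounds],
        "plot_tables": {
            "si_magnitude": {
                "index": list(mag.index),
                "columns": list(mag.columns),
                "values": [[_none_if_nan(v) for v in row] for row in mag.to_numpy()],
            },
            "immunogenicity": [
                {
                    "compound": idx,
                    "pct_responders": float(r["pct_responders"]),
                    "mean_si_responders": _none_if_nan(r["mean_si_responders"]),
                }
                for idx, r in plot.iterrows()
            ],
            "frequencies": [asdict(e) for e in freq_list],
        },
    }
    if hla_comparison is not None:
        d = asdict(hla_comparison)
        d["alleles"] = list(d["alleles"])
        d["cohort_frequencies"] = list(d["cohort_frequencies"])
        d["reference_frequencies"] = list(d["reference_frequencies"])
        d["flags"] = list(d["flags"])
        report["hla"] = d
    return report
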