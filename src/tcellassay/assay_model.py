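"""Domain types, validation and I/O for well-level T cell assay data.

The atomic record is one measured well: a donor's CD4+ T cells co-cultured
with irradiated autologous PBMCs and a test compound, read out either as
proliferation (counts per minute of tritiated-thymidine incorporation, cpm)
or as IL-2 ELISpot spots per well (spw). Untreated control wells are stored
as ordinary rows whose compound is the reserved token ``BASELINE`` so that a
whole cohort travels in a single CSV.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

#: Reserved compound token for untreated control wells.
BASELINE = "BASELINE"

#: Reserved allele token for an absent second allele in an HLA genotype.
MISSING = "MISSING"

#: Reserved allele label for the remainder bucket of a frequency table.
OTHER = "OTHER"


class ReadoutKind(str, enum.Enum):
    """The three assay readouts.

    Proliferation is measured in sextuplicate at day six and day eight
    (values are cpm, non-negative reals); IL-2 secretion is measured in
    triplicate by ELISpot (values are spots/well, non-negative integers).
    """

    PROLIF_D6 = "prolif_d6"
    PROLIF_D8 = "prolif_d8"
    ELISPOT = "elispot"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_proliferation(self) -> bool:
        return self in (ReadoutKind.PROLIF_D6, ReadoutKind.PROLIF_D8)


#: Assay design defaults: replicate wells per readout.
DEFAULT_REPLICATES = {
    ReadoutKind.PROLIF_D6: 6,
    ReadoutKind.PROLIF_D8: 6,
    ReadoutKind.ELISPOT: 3,
}

#: Assay design defaults: CD4+ T cells seeded per well.
DEFAULT_CELLS_PER_WELL = {
    ReadoutKind.PROLIF_D6: 100_000,
    ReadoutKind.PROLIF_D8: 100_000,
    ReadoutKind.ELISPOT: 500_000,
}

#: Required columns of the wells CSV, in canonical order.
WELL_COLUMNS = ["donor_id", "compound", "readout", "replicate", "value", "cells_per_well"]


class WellDataError(ValueError):
    """Raised when a wells table violates the format contract."""


class HLADataError(ValueError):
    """Raised when an HLA genotype table is malformed."""


class CohortValidationError(ValueError):
    """Raised in strict mode when a cohort fails design validation."""


@dataclass(frozen=True)
class AssayWell:
    """One measured well."""

    donor_id: str
    compound: str
    readout: ReadoutKind
    replicate: int
    value: float
    cells_per_well: int

    def __post_init__(self) -> None:
        if not isinstance(self.readout, ReadoutKind):
            object.__setattr__(self, "readout", ReadoutKind(self.readout))
        if self.replicate < 1:
            raise WellDataError(f"replicate must be a positive integer, got {self.replicate}")
        if not np.isfinite(self.value) or self.value < 0:
            raise WellDataError(f"value must be a non-negative real, got {self.value}")
        if self.cells_per_well < 1:
            raise WellDataError(f"cells_per_well must be positive, got {self.cells_per_well}")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the analysis.

    ``si_cutoff`` and ``alpha`` are applied as strict inequalities
    (SI > cutoff, p < alpha); ``well_score_multiplier`` is the per-well
    positivity threshold relative to the baseline mean used in limiting
    dilution scoring; ``zero_negative_substitute`` replaces a raw negative
    well count of zero so the log in the frequency formula stays finite.
    """

    si_cutoff: float = 2.0
    alpha: float = 0.05
    well_score_multiplier: float = 2.0
    zero_negative_substitute: float = 0.1

    def __post_init__(self) -> None:
        for name in ("si_cutoff", "alpha", "well_score_multiplier", "zero_negative_substitute"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


ALLELE_PATTERN = re.compile(r"^\*\d{2}:\d{2}$")


@dataclass(frozen=True)
class HLAGenotype:
    """A donor's two alleles at one HLA locus (4-digit resolution).

    ``allele_2`` is :data:`MISSING` when the typing report lists a single
    allele ("-" in the table layout); whether that means homozygosity or a
    typing failure is decided downstream by the counting convention.
    """

    donor_id: str
    locus: str
    allele_1: str
    allele_2: str = MISSING

    def __post_init__(self) -> None:
        if not ALLELE_PATTERN.match(self.allele_1):
            raise HLADataError(f"malformed allele {self.allele_1!r} for donor {self.donor_id}")
        if self.allele_2 != MISSING and not ALLELE_PATTERN.match(self.allele_2):
            raise HLADataError(f"malformed allele {self.allele_2!r} for donor {self.donor_id}")


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Allele → frequency map at one locus.

    Frequencies lie in [0, 1] and sum to at most 1; an explicit
    :data:`OTHER` bucket may absorb the remainder.
    """

    locus: str
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frequency of {allele} out of [0,1]: {f}")
        if sum(self.frequencies.values()) > 1.0 + 1e-9:
            raise ValueError(f"frequencies at locus {self.locus} sum to more than 1")

    def alleles(self) -> list[str]:
        """Real alleles in the table (the OTHER bucket excluded)."""
        return [a for a in self.frequencies if a != OTHER]


WellsLike = Union[pd.DataFrame, Iterable[AssayWell]]


def wells_to_frame(wells: WellsLike) -> pd.DataFrame:
    """Coerce a wells collection to the canonical DataFrame layout."""
    if isinstance(wells, pd.DataFrame):
        missing = [c for c in WELL_COLUMNS if c not in wells.columns]
        if missing:
            raise WellDataError(f"wells table missing columns: {missing}")
        return wells
    rows = [
        (w.donor_id, w.compound, w.readout.value, w.replicate, w.value, w.cells_per_well)
        for w in wells
    ]
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def frame_to_wells(frame: pd.DataFrame) -> list[AssayWell]:
    return [
        AssayWell(
            donor_id=str(r.donor_id),
            compound=str(r.compound),
            readout=ReadoutKind(r.readout),
            replicate=int(r.replicate),
            value=float(r.value),
            cells_per_well=int(r.cells_per_well),
        )
        for r in frame.itertuples(index=False)
    ]


def read_wells(path: Union[str, Path]) -> pd.DataFrame:
    """Read a wells CSV, validating every row.

    The file must carry the six required columns (comma-separated, UTF-8,
    "." decimal, header required). Errors name the offending CSV row
    (header = row 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={"donor_id": str, "compound": str, "readout": str})
    missing = [c for c in WELL_COLUMNS if c not in frame.columns]
    if missing:
        raise WellDataError(f"{path.name}: missing required column(s): {missing}")
    frame = frame[WELL_COLUMNS].copy()

    def _row(i: int) -> int:
        # CSV row number: +1 for the header, +1 for 1-based counting
        return int(i) + 2

    valid_readouts = {r.value for r in ReadoutKind}
    for i, ro in frame["readout"].items():
        if ro not in valid_readouts:
            raise WellDataError(f"{path.name} row {_row(i)}: unknown readout {ro!r}")

    for col in ("replicate", "value", "cells_per_well"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna()]
        if len(bad):
            raise WellDataError(
                f"{path.name} row {_row(bad[0])}: non-numeric {col} "
                f"{frame.loc[bad[0], col]!r}"
            )
        frame[col] = numeric

    neg = frame.index[frame["value"] < 0]
    if len(neg):
        raise WellDataError(
            f"{path.name} row {_row(neg[0])}: negative value {frame.loc[neg[0], 'value']}"
        )
    for col, low in (("replicate", 1), ("cells_per_well", 1)):
        bad = frame.index[frame[col] < low]
        if len(bad):
            raise WellDataError(
                f"{path.name} row {_row(bad[0])}: {col} must be >= {low}, "
                f"got {frame.loc[bad[0], col]}"
            )
    frame["replicate"] = frame["replicate"].astype(int)
    frame["cells_per_well"] = frame["cells_per_well"].astype(int)
    frame["value"] = frame["value"].astype(float)

    dup = frame.duplicated(subset=["donor_id", "compound", "readout", "replicate"])
    if dup.any():
        i = frame.index[dup][0]
        raise WellDataError(
            f"{path.name} row {_row(i)}: duplicate replicate index "
            f"{frame.loc[i, 'replicate']} within "
            f"({frame.loc[i, 'donor_id']}, {frame.loc[i, 'compound']}, {frame.loc[i, 'readout']})"
        )
    return frame


def write_wells(wells: WellsLike, path: Union[str, Path]) -> None:
    """Write a wells table as CSV in the canonical column order."""
    frame = wells_to_frame(wells)
    frame.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Report-only output of :func:`validate_cohort`.

    ``flags`` lists human-readable deviations from the expected assay
    design; an empty list means the cohort conforms.
    """

    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def __iter__(self):
        return iter(self.flags)


def validate_cohort(
    wells: WellsLike,
    expected_replicates: dict[ReadoutKind, int] | None = None,
    strict: bool = False,
) -> ValidationReport:
    """Check a cohort against the assay design.

    Reports, per (donor, compound, readout): replicate count versus the
    expected design (default 6/6/3), presence of matching BASELINE wells,
    and cells_per_well consistency within (donor, readout). In strict mode
    any flag (including non-integer ELISpot values) raises
    :class:`CohortValidationError`; otherwise the report is purely
    informational. The function is pure: identical inputs give identical
    reports.
    """
    frame = wells_to_frame(wells)
    expected = expected_replicates or DEFAULT_REPLICATES
    flags: list[str] = []

    counts = frame.groupby(["donor_id", "compound", "readout"], sort=True).size()
    for (donor, compound, readout), n in counts.items():
        want = expected.get(ReadoutKind(readout))
        if want is not None and n != want:
            flags.append(
                f"({donor}, {compound}, {readout}): expected {want} replicates, found {n}"
            )

    treated = frame[frame["compound"] != BASELINE]
    baseline_keys = set(
        map(tuple, frame.loc[frame["compound"] == BASELINE, ["donor_id", "readout"]].values)
    )
    for donor, readout in sorted(set(map(tuple, treated[["donor_id", "readout"]].values))):
        if (donor, readout) not in baseline_keys:
            flags.append(f"({donor}, {readout}): treated wells without BASELINE wells")

    cpw = frame.groupby(["donor_id", "readout"])["cells_per_well"].nunique()
    for (donor, readout), n in cpw.items():
        if n > 1:
            flags.append(f"({donor}, {readout}): cells_per_well not constant")

    if strict:
        spots = frame.loc[frame["readout"] == ReadoutKind.ELISPOT.value, "value"]
        frac = spots[np.abs(spots - np.round(spots)) > 1e-9]
        if len(frac):
            flags.append(f"{len(frac)} elispot value(s) are not integers")
        if flags:
            raise CohortValidationError("; ".join(flags))
    return ValidationReport(flags=flags)


def _parse_allele(cell: object) -> str | None:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip()
    if text in ("-", "", "nan"):
        return None
    return text


def read_hla_table(path: Union[str, Path]) -> list[HLAGenotype]:
    """Read an HLA typing table (donor rows, paired locus-allele columns).

    The layout mirrors a standard typing report: a ``donor`` column followed
    by ``LOCUS-1``/``LOCUS-2`` column pairs (e.g. ``DRB1-1``, ``DRB1-2``).
    A "-" entry denotes an absent allele; a genotype is emitted for every
    (donor, locus) whose first allele is present, with ``allele_2`` set to
    :data:`MISSING` when absent. Malformed allele strings raise
    :class:`HLADataError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if frame.empty and len(frame.columns) == 0:
        return []
    donor_col = frame.columns[0]
    loci: dict[str, tuple[str, str | None]] = {}
    for col in frame.columns[1:]:
        m = re.match(r"^(.*)-([12])$", col)
        if not m:
            raise HLADataError(f"{path.name}: column {col!r} is not a LOCUS-1/LOCUS-2 pair")
        locus, idx = m.group(1), m.group(2)
        first, second = loci.get(locus, (None, None))
        loci[locus] = (col, second) if idx == "1" else (first, col)

    genotypes: list[HLAGenotype] = []
    for _, row in frame.iterrows():
        donor = str(row[donor_col]).strip()
        for locus, (c1, c2) in loci.items():
            a1 = _parse_allele(row[c1]) if c1 else None
            a2 = _parse_allele(row[c2]) if c2 else None
            if a1 is None and a2 is None:
                continue
            if a1 is None:
                a1, a2 = a2, None
            genotypes.append(
                HLAGenotype(
                    donor_id=donor,
                    locus=locus,
                    allele_1=a1,
                    allele_2=a2 if a2 is not None else MISSING,
                )
            )
    return genotypes


def read_allele_frequencies(
    path: Union[str, Path], locus: str | None = None
) -> AlleleFrequencyTable:
    """Read a reference allele-frequency CSV (columns: locus, allele, frequency)."""
    frame = pd.read_csv(path, dtype={"locus": str, "allele": str})
    if locus is None:
        unique = frame["locus"].unique()
        if len(unique) != 1:
            raise ValueError(f"table holds several loci {list(unique)}; pass locus=")
        locus = str(unique[0])
    sub = frame[frame["locus"] == locus]
    return AlleleFrequencyTable(
        locus=locus,
        frequencies={str(a): float(f) for a, f in zip(sub["allele"], sub["frequency"])},
    )
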