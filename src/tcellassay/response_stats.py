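"""Stimulation indices, the two-sample test, and responder classification.

A readout is called positive for a (donor, compound) when the stimulation
index SI = mean(treated)/mean(baseline) strictly exceeds the cutoff (default
2) AND the two-tailed unpaired Student t-test of treated versus baseline
wells gives p strictly below alpha (default 0.05). A donor is a responder to
a compound when at least one available readout — proliferation day 6,
proliferation day 8, or IL-2 ELISpot — is positive (OR combination). No
multiple-testing correction is applied across compounds or readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assay_model import BASELINE, ReadoutKind, Thresholds, WellsLike, wells_to_frame

__all__ = [
    "ReadoutSummary",
    "DonorCompoundCall",
    "stimulation_index",
    "two_tailed_unpaired_t",
    "readout_call",
    "classify_donor",
    "classify_cohort",
    "calls_to_frame",
    "responder_frequency",
]


@dataclass(frozen=True)
class ReadoutSummary:
    """SI, p-value and positivity of one (donor, compound, readout)."""

    donor_id: str
    compound: str
    readout: ReadoutKind
    si: float
    p_value: float
    n_treated: int
    n_baseline: int
    positive: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DonorCompoundCall:
    """Donor-level responder call: OR over the available readout summaries."""

    donor_id: str
    compound: str
    readouts: tuple[ReadoutSummary, ...]
    responder: bool


def stimulation_index(
    treated: Sequence[float],
    baseline: Sequence[float],
    baseline_floor: float | None = None,
) -> float:
    """SI = mean(treated) / mean(baseline).

    The ratio of replicate means (well-defined when replicate counts differ).
    A non-positive baseline mean raises unless ``baseline_floor`` is given,
    in which case the floor (in measurement units) replaces the denominator.
    """
    treated = np.asarray(treated, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if treated.size == 0 or baseline.size == 0:
        raise ValueError("treated and baseline must both be non-empty")
    denom = baseline.mean()
    if denom <= 0:
        if baseline_floor is None:
            raise ValueError(f"baseline mean must be positive, got {denom}")
        denom = baseline_floor
    return float(treated.mean() / denom)


def two_tailed_unpaired_t(
    treated: Sequence[float], baseline: Sequence[float]
) -> float:
    """Two-tailed p of the classical equal-variance Student t-test.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)) with pooled variance and
    df = n1 + n2 - 2. Degenerate limit convention when the pooled variance
    is zero: p = 1 for equal means, p = 0 for unequal means.
    """
    treated = np.asarray(treated, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if treated.size < 2 or baseline.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = treated.var(ddof=1) * (treated.size - 1) + baseline.var(ddof=1) * (
        baseline.size - 1
    )
    if pooled == 0.0:
        return 1.0 if treated.mean() == baseline.mean() else 0.0
    with warnings.catch_warnings():
        # near-identical groups trip scipy's precision-loss warning; the
        # exact zero-variance case is already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated, baseline, equal_var=True)
    return float(res.pvalue)


def readout_call(
    treated: Sequence[float],
    baseline: Sequence[float],
    thresholds: Thresholds = Thresholds(),
    *,
    donor_id: str = "",
    compound: str = "",
    readout: ReadoutKind | str = ReadoutKind.PROLIF_D6,
    baseline_floor: float | None = None,
) -> ReadoutSummary:
    """Dual-criterion positivity of one readout (strict inequalities)."""
    flags: list[str] = []
    baseline_arr = np.asarray(baseline, dtype=float)
    if baseline_arr.mean() <= 0 and baseline_floor is not None:
        flags.append("baseline_floor_applied")
    si = stimulation_index(treated, baseline, baseline_floor=baseline_floor)
    p = two_tailed_unpaired_t(treated, baseline)
    if p == 0.0:
        flags.append("zero_variance_unequal_means")
    positive = (si > thresholds.si_cutoff) and (p < thresholds.alpha)
    return ReadoutSummary(
        donor_id=donor_id,
        compound=compound,
        readout=ReadoutKind(readout),
        si=si,
        p_value=p,
        n_treated=len(np.atleast_1d(np.asarray(treated))),
        n_baseline=len(baseline_arr),
        positive=positive,
        flags=tuple(flags),
    )


def classify_donor(summaries: Iterable[ReadoutSummary]) -> DonorCompoundCall:
    """OR-combine 1-3 readout summaries of one (donor, compound)."""
    summaries = tuple(summaries)
    if not summaries:
        raise ValueError("classify_donor needs at least one readout summary")
    donor_ids = {s.donor_id for s in summaries}
    compounds = {s.compound for s in summaries}
    if len(donor_ids) > 1 or len(compounds) > 1:
        raise ValueError("summaries must belong to a single (donor, compound)")
    return DonorCompoundCall(
        donor_id=summaries[0].donor_id,
        compound=summaries[0].compound,
        readouts=summaries,
        responder=any(s.positive for s in summaries),
    )


def classify_cohort(
    wells: WellsLike,
    thresholds: Thresholds = Thresholds(),
    baseline_floor: float | None = None,
) -> list[DonorCompoundCall]:
    """Classify every (donor, compound) in a wells table.

    Each treated group is compared against the BASELINE wells of the same
    (donor, readout) — day-matched for the two proliferation time points.
    Missing readouts are tolerated (the OR runs over what is available).
    """
    frame = wells_to_frame(wells)
    baselines: dict[tuple[str, str], np.ndarray] = {
        (donor, readout): grp["value"].to_numpy()
        for (donor, readout), grp in frame[frame["compound"] == BASELINE].groupby(
            ["donor_id", "readout"]
        )
    }
    calls: list[DonorCompoundCall] = []
    treated = frame[frame["compound"] != BASELINE]
    for (donor, compound), grp in treated.groupby(["donor_id", "compound"], sort=True):
        summaries = []
        for readout, sub in grp.groupby("readout", sort=True):
            key = (donor, readout)
            if key not in baselines:
                raise ValueError(f"no BASELINE wells for ({donor}, {readout})")
            summaries.append(
                readout_call(
                    sub["value"].to_numpy(),
                    baselines[key],
                    thresholds,
                    donor_id=str(donor),
                    compound=str(compound),
                    readout=readout,
                    baseline_floor=baseline_floor,
                )
            )
        calls.append(classify_donor(summaries))
    return calls


def calls_to_frame(calls: Iterable[DonorCompoundCall]) -> pd.DataFrame:
    """Flatten calls to one row per (donor, compound, readout).

    The donor-level ``responder`` flag is repeated on every row of that
    (donor, compound).
    """
    rows = [
        (
            c.donor_id,
            c.compound,
            s.readout.value,
            s.si,
            s.p_value,
            s.positive,
            c.responder,
        )
        for c in calls
        for s in c.readouts
    ]
    return pd.DataFrame(
        rows,
        columns=["donor_id", "compound", "readout", "si", "p_value", "positive", "responder"],
    )


def responder_frequency(calls: Iterable[DonorCompoundCall], compound: str | None = None) -> float:
    """Percentage of donors responding, to one decimal place.

    ``calls`` may span several compounds if ``compound`` names which one to
    summarise; each donor must appear once for that compound.
    """
    selected = [c for c in calls if compound is None or c.compound == compound]
    if not selected:
        raise ValueError("no calls to summarise")
    donors = [c.donor_id for c in selected]
    if len(set(donors)) != len(donors):
        raise ValueError("multiple calls per donor; pass compound= to disambiguate")
    n_resp = sum(c.responder for c in selected)
    return round(100.0 * n_resp / len(selected), 1)
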