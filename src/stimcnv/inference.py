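"""Statistical procedures for cohort, Southern, growth-curve and dose data.

The central procedure is the viability-normalised cohort rate test: the
background per-allele CNV rate is estimated from the untreated cohort on a
per-starting-allele basis (recovered alleles divided by viability), under the
conservative assumption that cells lost during the assay window did not
undergo CNV. The expected number of events in the treated cohort is that rate
times the treated starting-allele count, and observed vs expected are compared
by a two-cell goodness-of-fit χ² with 1 degree of freedom.

The remaining operations are the quantitative readouts used around the
cohort assay: percentage of alleles deviating from the parental copy number,
probe-site correction of Southern band intensities, 9-point growth-curve
smoothing, maximum specific growth rate (max of the first derivative of the
smoothed OD curve), dose-response AUC and GI50, and competition composition
change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError, ParameterError, UndefinedTestError
from .population import GrowthCurve

__all__ = [
    "CohortCounts",
    "CohortTest",
    "BandTable",
    "MaxGrowthRate",
    "DoseResponse",
    "cohort_rate_test",
    "percent_deviating",
    "probe_correct",
    "percent_low_copy",
    "smooth_curve",
    "max_growth_rate",
    "dose_response",
    "competition_change",
]


@dataclass(frozen=True)
class CohortCounts:
    """Event and allele counts for one cohort arm with its viability."""

    events: int
    alleles_assayed: int
    viability: float

    def __post_init__(self) -> None:
        if not 0 <= self.events <= self.alleles_assayed:
            raise ParameterError("require 0 <= events <= alleles_assayed")
        if not 0.0 < self.viability <= 1.0:
            raise DomainError("viability must lie in (0, 1]")

    @property
    def rate_per_starting_allele(self) -> float:
        """Events per starting-cohort allele (lost cells assumed event-free)."""
        return self.events / (self.alleles_assayed / self.viability)


@dataclass(frozen=True)
class CohortTest:
    """Result of the viability-normalised χ² cohort rate test."""

    background_rate: float  # events per starting allele, untreated arm
    n_treated: float  # starting-allele count of the treated arm
    expected: float  # E
    observed: int  # O
    chi2: float
    df: int
    p_value: float
    fold: float  # raw per-recovered-allele rate ratio treated/untreated


@dataclass(frozen=True)
class BandTable:
    """Quantified Southern bands: one row per allele copy-number class."""

    table: pd.DataFrame  # copy_number, intensity, probe_sites

    def __post_init__(self) -> None:
        t = self.table
        required = {"copy_number", "intensity", "probe_sites"}
        if not required.issubset(t.columns):
            raise InputError(f"band table needs columns {sorted(required)}")
        if len(t) == 0:
            raise InputError("band table must be non-empty")
        if t["copy_number"].duplicated().any():
            raise InputError("copy numbers must be distinct")
        if (t["copy_number"] < 0).any():
            raise InputError("copy numbers must be >= 0")
        if (t["intensity"] < 0).any():
            raise InputError("intensities must be >= 0")
        if (t["probe_sites"] < 1).any():
            raise InputError("probe_sites must be >= 1")

    @classmethod
    def from_records(cls, records) -> "BandTable":
        return cls(pd.DataFrame(records, columns=["copy_number", "intensity", "probe_sites"]))


@dataclass(frozen=True)
class MaxGrowthRate:
    """Maximum dOD/dt (per hour) of a smoothed growth curve, and its time."""

    rate: float
    time: float
    nonpositive: bool  # flagged when the curve never grows


@dataclass(frozen=True)
class DoseResponse:
    """Final OD by concentration with derived AUC and GI50 (mM)."""

    concentrations: np.ndarray
    od: np.ndarray
    auc: float
    gi50: float
    censored: bool  # True when OD never falls to 50% of the zero-dose OD


# ---------------------------------------------------------------------------
# Cohort inference
# ---------------------------------------------------------------------------


def cohort_rate_test(treated: CohortCounts, untreated: CohortCounts) -> CohortTest:
    """Viability-normalised expected-event χ² test between two cohort arms.

    Background rate r = events_u / (alleles_u / v_u); treated starting
    alleles N_t = alleles_t / v_t; E = r·N_t; O = events_t. Two-cell
    goodness of fit: χ² = (O−E)²/E + ((N_t−O)−(N_t−E))²/(N_t−E), df = 1.
    The fold stimulation is the raw per-recovered-allele rate ratio
    (events_t/alleles_t)/(events_u/alleles_u); viability enters the test but
    not the fold, which matches how the per-cohort percentages are reported.
    """
    r = untreated.rate_per_starting_allele
    n_t = treated.alleles_assayed / treated.viability
    expected = r * n_t
    if expected <= 0:
        raise UndefinedTestError(
            "expected event count is zero (no untreated events); χ² undefined"
        )
    observed = treated.events
    if n_t - expected <= 0:
        raise UndefinedTestError("expected non-event count is zero; χ² undefined")
    chi2 = (observed - expected) ** 2 / expected + (
        (n_t - observed) - (n_t - expected)
    ) ** 2 / (n_t - expected)
    p = float(stats.chi2.sf(chi2, df=1))
    fold = (treated.events / treated.alleles_assayed) / (
        untreated.events / untreated.alleles_assayed
    )
    return CohortTest(
        background_rate=r,
        n_treated=n_t,
        expected=expected,
        observed=observed,
        chi2=float(chi2),
        df=1,
        p_value=max(p, np.finfo(float).tiny),
        fold=fold,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent_deviating(
    data: Union[tuple[int, int], Sequence[int], BandTable],
    parental_copy: Optional[int] = None,
    rounding: str = "nearest",
) -> float:
    """Percentage of alleles deviating from the parental copy number.

    ``data`` may be a ``(events, alleles_assayed)`` count pair, a sequence of
    per-allele copy numbers (cohort mode; requires ``parental_copy``), or a
    :class:`BandTable` (band mode: probe-corrected intensity-weighted
    fraction). ``rounding='nearest'`` rounds half up to an integer percent,
    ``'none'`` returns the raw percentage.
    """
    if rounding not in ("nearest", "none"):
        raise DomainError("rounding must be 'nearest' or 'none'")
    if isinstance(data, BandTable):
        if parental_copy is None:
            raise DomainError("band mode requires parental_copy")
        fractions = probe_correct(data)
        frac = float(fractions[fractions.index != parental_copy].sum())
    elif isinstance(data, tuple) and len(data) == 2:
        events, alleles = data
        if alleles <= 0:
            raise DomainError("alleles_assayed must be > 0")
        if not 0 <= events <= alleles:
            raise DomainError("require 0 <= events <= alleles")
        frac = events / alleles
    else:
        copies = np.asarray(data)
        if copies.size == 0:
            raise DomainError("empty allele list")
        if parental_copy is None:
            raise DomainError("cohort mode requires parental_copy")
        frac = float((copies != parental_copy).mean())
    pct = 100.0 * frac
    return float(_round_half_up(pct)) if rounding == "nearest" else pct


def probe_correct(table: BandTable) -> pd.Series:
    """Molar abundance fractions from band intensities.

    Each band's intensity is divided by its number of probe-binding sites
    (amplified alleles bind proportionally more probe), then renormalised to
    sum to 1. Indexed by copy number.
    """
    t = table.table
    if not (t["intensity"] > 0).any():
        raise DomainError("all band intensities are zero")
    corrected = t["intensity"] / t["probe_sites"]
    fractions = corrected / corrected.sum()
    out = pd.Series(fractions.values, index=t["copy_number"].values, name="fraction")
    out.index.name = "copy_number"
    return out


def percent_low_copy(table: BandTable, max_copies: int = 3, rounding: str = "none") -> float:
    """Probe-corrected abundance percentage at copy numbers <= ``max_copies``."""
    fractions = probe_correct(table)
    pct = 100.0 * float(fractions[fractions.index <= max_copies].sum())
    return float(_round_half_up(pct)) if rounding == "nearest" else pct


# ---------------------------------------------------------------------------
# Growth-curve kinetics
# ---------------------------------------------------------------------------


def smooth_curve(curve: GrowthCurve, window: int = 9) -> GrowthCurve:
    """Centred moving average of the OD series; truncated windows at edges."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be a positive odd integer")
    if window > len(curve):
        raise ParameterError("window longer than the series")
    smoothed = (
        pd.Series(curve.od).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return GrowthCurve(times=curve.times, od=smoothed)


def max_growth_rate(curve: GrowthCurve, window: int = 9) -> MaxGrowthRate:
    """Maximum of the first derivative of the smoothed OD curve, per hour.

    Central finite differences on the smoothed curve; a non-growing or
    shrinking curve is reported with its (non-positive) maximum and flagged.
    """
    if len(curve) < window + 2:
        raise DomainError(f"need at least window+2 = {window + 2} points")
    sm = smooth_curve(curve, window)
    deriv = np.gradient(sm.od, sm.times)
    i = int(np.argmax(deriv))
    rate = float(deriv[i])
    return MaxGrowthRate(rate=rate, time=float(sm.times[i]), nonpositive=rate <= 0)


def dose_response(
    concentrations: Sequence[float], od: Sequence[float]
) -> DoseResponse:
    """AUC and GI50 from final OD across a concentration series.

    AUC is the trapezoid over concentration. GI50 is the concentration at
    which OD falls to 50% of the zero-dose OD, by linear interpolation
    between the flanking grid points; a curve that never crosses is
    right-censored at the maximum concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    vals = np.asarray(od, dtype=float)
    if conc.shape != vals.shape or conc.ndim != 1:
        raise InputError("concentrations and od must be 1-d of equal length")
    if len(conc) < 2:
        raise DomainError("need at least 2 concentrations")
    if not np.all(np.diff(conc) > 0):
        raise InputError("concentrations must be strictly increasing")
    if conc[0] != 0:
        raise DomainError("a zero-concentration reference is required")
    auc = float(np.trapezoid(vals, conc))
    target = 0.5 * vals[0]
    below = np.flatnonzero(vals <= target)
    below = below[below > 0]
    if len(below) == 0:
        return DoseResponse(conc, vals, auc, gi50=float(conc[-1]), censored=True)
    i = int(below[0])
    if vals[i] == target:
        gi50 = float(conc[i])
    else:
        gi50 = float(
            conc[i - 1]
            + (target - vals[i - 1]) * (conc[i] - conc[i - 1]) / (vals[i] - vals[i - 1])
        )
    return DoseResponse(conc, vals, auc, gi50=gi50, censored=False)


def competition_change(
    before: Sequence[float], after: Sequence[float], focal: int = 0, tol: float = 1.0
) -> float:
    """Percentage-point change of the focal marker between two share vectors.

    Both vectors must sum to 100 within ``tol`` percent.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    for name, v in (("before", b), ("after", a)):
        if abs(v.sum() - 100.0) > tol:
            raise InputError(f"{name} shares sum to {v.sum():.3f}, not 100 ± {tol}")
    return float(a[focal] - b[focal])
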