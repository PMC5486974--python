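"""Agent-based simulator of budding-yeast populations carrying tandem arrays.

Reproduces the four experiment designs of the stimulated-CNV study at desk
scale:

* **MEP cohort** — a fixed cohort of mother cells (daughters inviable in
  β-estradiol) grown for a wall-clock window with or without copper; the
  recovered founders' allele copy numbers measure the CNV rate free of
  selection.
* **Batch outgrowth** — exponential expansion for a set number of population
  doublings with per-division CNV and fitness-weighted selection, yielding a
  Southern-blot-like allele copy-number distribution.
* **Competition** — two marked populations outgrown together; composition
  before/after in percent.
* **Growth curves** — OD_660 time series under logistic capacity, from which
  maximum growth rates and dose responses are derived.

Copper toxicity is a Hill function of concentration with half-inhibition
shifted up by ``k_copy`` mM per array copy, so higher copy number confers
resistance. Division slows with inhibition (division time 1/(mu_max·(1−I)))
and cells suffer a per-division death probability that rises steeply with
inhibition; both are calibrated to the printed phenotypes (≈12 divisions per
24 h without copper vs ≈8 with 1 mM for the high-copy diploid; 0.3 mM slows
and 0.75 mM fully inhibits growth of 3-copy cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    ActivityParams,
    EnvironmentCondition,
    Genotype,
    LocusConfig,
    RateParams,
    SwitchScheme,
    WILD_TYPE,
    enumerate_switch_outcomes,
    locus_activity,
    sample_cnv_event,
    stimulated_cnv_rate,
)
from .errors import ConfigurationError, DomainError, ParameterError, StateError

__all__ = [
    "Cell",
    "FitnessParams",
    "SimParams",
    "ModelParams",
    "CohortResult",
    "BatchResult",
    "CompetitionResult",
    "GrowthCurve",
    "inhibition",
    "death_probability",
    "step_division",
    "run_mep_cohort",
    "run_batch_culture",
    "run_competition",
    "simulate_growth_curve",
]


@dataclass
class Cell:
    """One agent: per-allele copy numbers plus bookkeeping."""

    alleles: list[int]
    divisions: int = 0
    is_founder: bool = True
    marker: str = ""
    alive: bool = True

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.alleles):
            raise ParameterError("allele copy numbers must be >= 0")
        if self.divisions < 0:
            raise ParameterError("divisions must be >= 0")

    @property
    def total_copies(self) -> int:
        return int(sum(self.alleles))


@dataclass(frozen=True)
class FitnessParams:
    """Copper fitness model.

    ``mu_max`` divisions/hour; inhibition I = c^h / (c^h + (K0 + k_copy·n)^h)
    with n the cell's total array copies. The per-division death probability
    is ``p_death · I^death_h / (I^death_h + death_threshold^death_h)`` — a
    graded hazard with half-maximum at ``death_threshold`` — plus a small
    copper-independent ``p_death_base`` (replicative attrition over the assay
    window).
    """

    mu_max: float = 0.5
    K0: float = 0.385
    k_copy: float = 0.0383
    hill_h: float = 2.0
    death_threshold: float = 0.6
    death_h: float = 4.0
    p_death: float = 0.95
    p_death_base: float = 0.01

    def __post_init__(self) -> None:
        if self.mu_max <= 0:
            raise ParameterError("mu_max must be > 0")
        if self.K0 < 0 or self.k_copy < 0:
            raise ParameterError("K0 and k_copy must be >= 0")
        if self.hill_h < 1:
            raise ParameterError("hill_h must be >= 1")
        if not 0.0 < self.death_threshold <= 1.0:
            raise ParameterError("death_threshold must lie in (0, 1]")
        if self.death_h < 1:
            raise ParameterError("death_h must be >= 1")
        for name in ("p_death", "p_death_base"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Simulation plumbing: MEP leakiness, population cap, OD mapping."""

    p_esc: float = 0.0  # MEP escape probability for daughters
    population_cap: int = 100_000  # random down-sampling above this
    od_blank: float = 0.05
    od_capacity: float = 1.2  # OD_660 at saturation above blank
    inoculum_od: float = 0.0012  # 1:1000 dilution of a saturated preculture
    od_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_esc <= 1.0:
            raise ParameterError("p_esc must lie in [0, 1]")
        if self.population_cap < 1:
            raise ParameterError("population_cap must be >= 1")
        if self.od_capacity <= 0 or self.inoculum_od <= 0:
            raise ParameterError("od_capacity and inoculum_od must be > 0")
        if self.od_blank < 0 or self.od_noise_sd < 0:
            raise ParameterError("od_blank and od_noise_sd must be >= 0")


@dataclass(frozen=True)
class ModelParams:
    """Bundle of all model parameter blocks used by the simulators."""

    activity: ActivityParams = field(default_factory=ActivityParams)
    rate: RateParams = field(default_factory=RateParams)
    switch: SwitchScheme = field(default_factory=SwitchScheme)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    sim: SimParams = field(default_factory=SimParams)


@dataclass
class CohortResult:
    """Recovered-founder allele table with viability and division counts."""

    allele_table: pd.DataFrame  # cell_id, allele_index, copy_number, viable
    n_start: int
    n_recovered: int
    mean_divisions: float
    sd_divisions: float

    @property
    def viability(self) -> float:
        """Fraction of the starting cohort recovered; NaN for an empty cohort."""
        if self.n_start == 0:
            return float("nan")
        return self.n_recovered / self.n_start

    def to_counts(self, parental: Sequence[int], events: str = "cnv"):
        """Collapse to (events, alleles, viability) for the cohort rate test.

        ``parental`` gives the parental copy number of each allele index.
        ``events='cnv'`` counts any deviation from parental; ``'amplification'``
        counts gains only.
        """
        from .inference import CohortCounts

        if events not in ("cnv", "amplification"):
            raise DomainError("events must be 'cnv' or 'amplification'")
        tab = self.allele_table
        n_events = 0
        for idx, par in enumerate(parental):
            col = tab[tab["allele_index"] == idx]["copy_number"]
            if events == "cnv":
                n_events += int((col != par).sum())
            else:
                n_events += int((col > par).sum())
        return CohortCounts(
            events=n_events, alleles_assayed=len(tab), viability=self.viability
        )


@dataclass
class BatchResult:
    """Allele copy-number frequency distribution after batch outgrowth."""

    distribution: pd.Series  # index copy_number, values abundance fractions
    generations: float
    population_size: int
    extinct: bool


@dataclass
class CompetitionResult:
    """Marker shares (percent) at inoculation and saturation."""

    before: dict[str, float]
    after: dict[str, float]
    focal: str

    @property
    def change(self) -> float:
        """Percentage-point change of the focal marker's share."""
        return self.after[self.focal] - self.before[self.focal]


@dataclass(frozen=True)
class GrowthCurve:
    """Uniformly-sampled OD_660 time series (times in hours)."""

    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        o = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", o)
        if t.shape != o.shape or t.ndim != 1:
            raise ParameterError("times and od must be 1-d arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(o < 0):
            raise ParameterError("od readings must be >= 0")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Fitness primitives
# ---------------------------------------------------------------------------


def inhibition(copies, copper_mM: float, p: FitnessParams = FitnessParams()):
    """Growth inhibition I in [0, 1]; 0 without copper, decreasing in copies.

    Accepts scalar or array ``copies``.
    """
    copies = np.asarray(copies, dtype=float)
    if np.any(copies < 0):
        raise DomainError("copies must be >= 0")
    if copper_mM < 0:
        raise DomainError("copper_mM must be >= 0")
    if copper_mM == 0:
        out = np.zeros_like(copies)
        return float(out) if out.ndim == 0 else out
    ch = copper_mM**p.hill_h
    K = (p.K0 + p.k_copy * copies) ** p.hill_h
    out = ch / (ch + K)
    return float(out) if out.ndim == 0 else out


def death_probability(I, p: FitnessParams = FitnessParams()):
    """Per-division death probability at inhibition level I (scalar or array)."""
    I = np.asarray(I, dtype=float)
    Ih = I**p.death_h
    tox = p.p_death * Ih / (Ih + p.death_threshold**p.death_h)
    out = 1.0 - (1.0 - p.p_death_base) * (1.0 - tox)
    return float(out) if out.ndim == 0 else out


def _net_growth_rate(copies, copper_mM: float, p: FitnessParams):
    """Net exponential growth rate per hour (division minus death)."""
    I = np.asarray(inhibition(copies, copper_mM, p), dtype=float)
    mu = p.mu_max * (1.0 - I)
    pd_ = np.asarray(death_probability(I, p), dtype=float)
    # each division multiplies lineage size by 2*(1-p_death)
    with np.errstate(divide="ignore"):
        factor = np.where(pd_ < 1.0, 1.0 + np.log2(np.maximum(1.0 - pd_, 1e-300)), -np.inf)
    return mu * factor


# ---------------------------------------------------------------------------
# Division step and MEP cohort
# ---------------------------------------------------------------------------


def step_division(
    cell: Cell,
    env: EnvironmentCondition,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    model: ModelParams = ModelParams(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, Optional[Cell]]:
    """Advance one cell through one division.

    Returns ``(division_time_hours, daughter_or_None)`` and mutates the
    mother in place. Each allele is independently subjected to a CNV draw;
    a mutated allele segregates to mother or daughter with probability ½
    (sister-chromatid ambiguity). Under β-estradiol the daughter is inviable
    except with escape probability ``p_esc``. The mother dies (``alive``
    set False) with the graded per-division death probability. An inhibition
    level of 1 means no division (+inf time).
    """
    if not cell.alive:
        raise StateError("cannot divide a dead cell")
    if rng is None:
        rng = np.random.default_rng()
    fp = model.fitness
    I = inhibition(cell.total_copies, env.copper_mM, fp)
    if I >= 1.0:
        return math.inf, None
    dt = 1.0 / (fp.mu_max * (1.0 - I))

    act = locus_activity(env, locus, genotype, model.activity)
    daughter_alleles = list(cell.alleles)
    for i, copies in enumerate(cell.alleles):
        if copies < 1:
            continue
        ev = sample_cnv_event(
            copies,
            act,
            model.switch,
            rng,
            genotype=genotype,
            rate_params=model.rate,
            min_copies=locus.min_copies,
        )
        if ev is not None:
            if rng.random() < 0.5:
                cell.alleles[i] = copies + ev.delta
            else:
                daughter_alleles[i] = copies + ev.delta
    cell.divisions += 1

    daughter: Optional[Cell] = None
    if not env.estradiol or rng.random() < model.sim.p_esc:
        daughter = Cell(
            alleles=daughter_alleles,
            divisions=0,
            is_founder=False,
            marker=cell.marker,
        )
    if rng.random() < death_probability(I, fp):
        cell.alive = False
    return dt, daughter


def run_mep_cohort(
    n_start: int,
    env: EnvironmentCondition,
    hours: float,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    model: ModelParams = ModelParams(),
    rng: Optional[np.random.Generator] = None,
) -> CohortResult:
    """Simulate a defined cohort of founder (mother) cells for a time window.

    Only founders are tracked: the cohort assay is run in β-estradiol where
    daughters are inviable, and the readout plates only the starting cohort.
    Returns the allele table of surviving founders.
    """
    if n_start < 0:
        raise DomainError("n_start must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    divisions = []
    n_recovered = 0
    for cid in range(n_start):
        cell = Cell(alleles=list(_parental_alleles(locus)), marker="cohort")
        t = 0.0
        while cell.alive:
            I = inhibition(cell.total_copies, env.copper_mM, model.fitness)
            if I >= 1.0:
                break
            dt = 1.0 / (model.fitness.mu_max * (1.0 - I))
            if t + dt > hours:
                break
            dt, _ = step_division(cell, env, locus, genotype, model, rng)
            t += dt
        if cell.alive:
            n_recovered += 1
            divisions.append(cell.divisions)
            for idx, c in enumerate(cell.alleles):
                rows.append((cid, idx, c, True))
    table = pd.DataFrame(
        rows, columns=["cell_id", "allele_index", "copy_number", "viable"]
    )
    mean_div = float(np.mean(divisions)) if divisions else float("nan")
    sd_div = float(np.std(divisions, ddof=1)) if len(divisions) > 1 else float("nan")
    return CohortResult(
        allele_table=table,
        n_start=n_start,
        n_recovered=n_recovered,
        mean_divisions=mean_div,
        sd_divisions=sd_div,
    )


def _parental_alleles(locus: LocusConfig, ploidy: int = 2) -> tuple[int, ...]:
    """Diploid parental allele pair (the cohort strains are MEP diploids)."""
    return (locus.copies,) * ploidy


# ---------------------------------------------------------------------------
# Batch culture and competition (vectorised, haploid one-allele populations)
# ---------------------------------------------------------------------------


def _evolve_population(
    copies: np.ndarray,
    markers: Optional[np.ndarray],
    env: EnvironmentCondition,
    generations: float,
    locus: LocusConfig,
    genotype: Genotype,
    model: ModelParams,
    rng: np.random.Generator,
    max_hours: float = 1000.0,
):
    """Shared engine for batch outgrowth and competition.

    Discrete time steps; each live cell divides within a step with
    probability 1−exp(−mu·(1−I)·dt); dividing mothers draw one CNV event per
    allele assigned to mother or daughter with probability ½ and die with the
    per-division death probability. Stops after ``generations`` population
    doublings (of cumulative biomass) or at extinction. Populations above the
    cap are randomly down-sampled (tracked by a scale factor).
    """
    fp, sp = model.fitness, model.sim
    act = locus_activity(env, locus, genotype, model.activity)
    rate = stimulated_cnv_rate(act, genotype, model.rate)
    dist = enumerate_switch_outcomes(model.switch)
    deltas = np.array([o.delta for o in dist.outcomes])
    probs = np.array([o.probability for o in dist.outcomes])
    dt = 0.25 / fp.mu_max
    scale = 1.0
    n0 = float(len(copies))
    t = 0.0
    doublings = 0.0
    while doublings < generations and len(copies) > 0 and t < max_hours:
        I = np.asarray(inhibition(copies, env.copper_mM, fp), dtype=float)
        p_div = -np.expm1(-fp.mu_max * (1.0 - I) * dt)
        div = rng.random(len(copies)) < p_div
        n_div = int(div.sum())
        if n_div:
            mothers_idx = np.flatnonzero(div)
            d_copies = copies[mothers_idx].copy()
            # one CNV opportunity per allele per division
            ev = rng.random(n_div) < rate
            ev &= copies[mothers_idx] > 1  # single copies cannot recombine
            if ev.any():
                n_ev = int(ev.sum())
                draw = deltas[rng.choice(len(deltas), size=n_ev, p=probs)]
                to_mother = rng.random(n_ev) < 0.5
                # clipping at the contraction floor; a fully-clipped event
                # leaves the copy number unchanged (suppressed)
                m_targets = mothers_idx[ev][to_mother]  # global indices
                copies[m_targets] = np.maximum(
                    copies[m_targets] + draw[to_mother], locus.min_copies
                )
                d_targets = np.flatnonzero(ev)[~to_mother]  # mother-local
                d_copies[d_targets] = np.maximum(
                    d_copies[d_targets] + draw[~to_mother], locus.min_copies
                )
            # mother death at division
            p_dead = np.asarray(death_probability(I[mothers_idx], fp), dtype=float)
            dead = rng.random(n_div) < p_dead
            alive_mask = np.ones(len(copies), dtype=bool)
            alive_mask[mothers_idx[dead]] = False
            new_copies = np.concatenate([copies[alive_mask], d_copies])
            if markers is not None:
                d_markers = markers[mothers_idx]
                markers = np.concatenate([markers[alive_mask], d_markers])
            copies = new_copies
        t += dt
        if len(copies) == 0:
            break
        doublings = math.log2(max(len(copies) * scale, 1e-300) / n0)
        if len(copies) > sp.population_cap:
            keep = rng.choice(len(copies), size=sp.population_cap, replace=False)
            scale *= len(copies) / sp.population_cap
            copies = copies[keep]
            if markers is not None:
                markers = markers[keep]
    return copies, markers, doublings, scale


def run_batch_culture(
    founder_alleles: Sequence[int],
    env: EnvironmentCondition,
    generations: float,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    model: ModelParams = ModelParams(),
    rng: Optional[np.random.Generator] = None,
) -> BatchResult:
    """Expand a (haploid) population for a number of doublings with CNV and
    selection; return the Southern-like allele copy-number distribution."""
    if generations < 1:
        raise DomainError("generations must be >= 1")
    if len(founder_alleles) == 0:
        raise DomainError("founder population must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    copies = np.asarray(founder_alleles, dtype=int).copy()
    copies, _, doublings, _ = _evolve_population(
        copies, None, env, generations, locus, genotype, model, rng
    )
    extinct = len(copies) == 0
    if extinct:
        distribution = pd.Series(dtype=float, name="fraction")
    else:
        distribution = (
            pd.Series(copies).value_counts(normalize=True).sort_index().rename("fraction")
        )
        distribution.index.name = "copy_number"
    return BatchResult(
        distribution=distribution,
        generations=doublings,
        population_size=len(copies),
        extinct=extinct,
    )


def run_competition(
    pop_a: tuple[str, Sequence[int]],
    pop_b: tuple[str, Sequence[int]],
    env: EnvironmentCondition,
    generations: float,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    model: ModelParams = ModelParams(),
    rng: Optional[np.random.Generator] = None,
) -> CompetitionResult:
    """Outgrow two marked populations in direct competition.

    Returns marker shares (summing to 100%) at inoculation and saturation;
    the first population is the focal marker.
    """
    (marker_a, alleles_a), (marker_b, alleles_b) = pop_a, pop_b
    if marker_a == marker_b:
        raise ConfigurationError("competition populations must carry distinct markers")
    if len(alleles_a) == 0 or len(alleles_b) == 0:
        raise DomainError("both competition populations must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    copies = np.concatenate(
        [np.asarray(alleles_a, dtype=int), np.asarray(alleles_b, dtype=int)]
    )
    markers = np.array([marker_a] * len(alleles_a) + [marker_b] * len(alleles_b))
    before = {
        marker_a: 100.0 * len(alleles_a) / len(copies),
        marker_b: 100.0 * len(alleles_b) / len(copies),
    }
    copies, markers, _, _ = _evolve_population(
        copies, markers, env, generations, locus, genotype, model, rng
    )
    if len(copies) == 0:
        after = {marker_a: float("nan"), marker_b: float("nan")}
    else:
        after = {
            m: 100.0 * float((markers == m).sum()) / len(markers)
            for m in (marker_a, marker_b)
        }
    return CompetitionResult(before=before, after=after, focal=marker_a)


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def simulate_growth_curve(
    founder_alleles: Sequence[int],
    env: EnvironmentCondition,
    hours: float,
    dt: float,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    model: ModelParams = ModelParams(),
    rng: Optional[np.random.Generator] = None,
) -> GrowthCurve:
    """OD_660 time series for a culture seeded from ``founder_alleles``.

    Biomass is tracked per copy-number class and integrated under logistic
    capacity: dB_i/dt = r_i·B_i·(1 − B/C) for net growth rate r_i > 0 (cells
    with net death decline exponentially without the capacity factor). OD is
    blank + biomass plus additive Gaussian measurement noise. CNV during the
    curve is not modelled; the curve reflects the seeded composition.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    if hours < 0:
        raise DomainError("hours must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    sp = model.sim
    times = np.arange(0.0, hours + dt / 2, dt)
    if len(founder_alleles) == 0:
        od = np.full_like(times, sp.od_blank)
    else:
        classes, counts = np.unique(np.asarray(founder_alleles, dtype=int), return_counts=True)
        B = sp.inoculum_od * counts / counts.sum()
        rates = _net_growth_rate(classes, env.copper_mM, model.fitness)
        C = sp.od_capacity
        h = min(dt, 0.02)  # Euler substep
        od = np.empty_like(times)
        t = 0.0
        j = 0
        od[j] = sp.od_blank + B.sum()
        while j + 1 < len(times):
            t_next = times[j + 1]
            while t < t_next - 1e-12:
                step = min(h, t_next - t)
                total = B.sum()
                cap = max(1.0 - total / C, 0.0)
                growth = np.where(rates > 0, rates * cap, rates)
                B = np.maximum(B * (1.0 + growth * step), 0.0)
                t += step
            j += 1
            od[j] = sp.od_blank + B.sum()
    if sp.od_noise_sd > 0:
        od = od + rng.normal(0.0, sp.od_noise_sd, size=od.shape)
    return GrowthCurve(times=times, od=np.maximum(od, 0.0))
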