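"""Mechanistic model of transcription-stimulated copy number variation (CNV).

Tandem gene arrays such as the budding-yeast *CUP1* locus sit next to a
replication fork stalling (RFS) site. When the promoter embedded in each
repeat is induced by an environmental cue, the promoter fires bidirectionally
and a cryptic unstable transcript (CUT) runs through the RFS site.
Transcription across a stalled fork promotes fork collapse; the collapsed fork
restarts by break-induced replication (BIR), which template-switches readily
between repeat copies and thereby changes the copy number of the array. High
H3K56 acetylation (deposited by Rtt109, removed by the Hst3/Hst4 deacetylases,
globally raised by nicotinamide) lowers the processivity of BIR forks and is
required for the stimulated pathway.

This module encodes that mechanism as three composable pieces:

1. :func:`locus_activity` — maps an environment + locus + genotype onto a
   transcription/chromatin state (sense activity, antisense/CUT activity
   through the RFS, H3K56ac level).
2. :func:`stimulated_cnv_rate` — per-allele per-division CNV probability as a
   saturating function of antisense transcription drive, gated by a Hill
   function of H3K56ac. With acetylation absent (rtt109Δ) the rate collapses
   exactly to the basal fork-instability term.
3. :func:`enumerate_switch_outcomes` / :func:`sample_cnv_event` — the
   template-switch outcome scheme. Two successive ±1 template switches with
   zero-net paths scored as contractions reproduce the 3:1
   contraction:amplification bias of the mechanism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, ParameterError

__all__ = [
    "Genotype",
    "EnvironmentCondition",
    "LocusConfig",
    "LocusActivityState",
    "ActivityParams",
    "RateParams",
    "SwitchScheme",
    "SwitchOutcome",
    "SwitchOutcomeDistribution",
    "CNVEvent",
    "hill",
    "locus_activity",
    "stimulated_cnv_rate",
    "enumerate_switch_outcomes",
    "sample_cnv_event",
    "WILD_TYPE",
    "GENOTYPES",
]

PROMOTER_KINDS = ("copper_inducible", "galactose_inducible", "formaldehyde_inducible")
OUTCOME_CLASSES = ("contraction", "neutral", "amplification")


def hill(x: float, K: float, h: float) -> float:
    """Saturating Hill response x^h / (x^h + K^h); exactly 0 at x = 0."""
    if x <= 0.0:
        return 0.0
    xh = x**h
    return xh / (xh + K**h)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Genotype:
    """Genetic background of a strain, reduced to the traits the model reads.

    Parameters
    ----------
    name:
        Strain label, e.g. ``"wild_type"`` or ``"rtt109"``.
    h3k56ac_capable:
        False for rtt109Δ (no H3K56 acetyltransferase): closes the acetylation
        channel and abolishes stimulated CNV.
    hdac_active:
        False for hst3Δ hst4Δ: H3K56ac is constitutively maximal.
    fork_stability_modifier:
        Multiplier on the basal CNV rate; > 1 for mutants with elevated basal
        fork instability (mrc1Δ, pol32Δ).
    cut_degradation:
        False for rrp6Δ. Affects only reported CUT abundance in synthetic
        expression outputs, never the CNV rate.
    """

    name: str
    h3k56ac_capable: bool = True
    hdac_active: bool = True
    fork_stability_modifier: float = 1.0
    cut_degradation: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ParameterError("Genotype.name must be non-empty")
        if self.fork_stability_modifier < 0:
            raise ParameterError("fork_stability_modifier must be >= 0")


WILD_TYPE = Genotype("wild_type")

#: Common laboratory backgrounds used in the stimulated-CNV experiments.
GENOTYPES = {
    "wild_type": WILD_TYPE,
    "rtt109": Genotype("rtt109", h3k56ac_capable=False),
    "hst3_hst4": Genotype("hst3_hst4", hdac_active=False),
    "mrc1": Genotype("mrc1", fork_stability_modifier=10.0),
    "pol32": Genotype("pol32", fork_stability_modifier=10.0),
    "rrp6": Genotype("rrp6", cut_degradation=False),
}


@dataclass(frozen=True)
class EnvironmentCondition:
    """Growth environment (concentrations in mM unless noted)."""

    copper_mM: float = 0.0
    nicotinamide_mM: float = 0.0
    galactose_frac: float = 0.0  # fraction of carbon supplied as galactose
    formaldehyde_mM: float = 0.0
    estradiol: bool = False
    ascorbate_mM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("copper_mM", "nicotinamide_mM", "formaldehyde_mM", "ascorbate_mM"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.galactose_frac <= 1.0:
            raise ParameterError("galactose_frac must lie in [0, 1]")


@dataclass(frozen=True)
class LocusConfig:
    """A tandem gene array and its promoter type.

    ``min_copies`` is the contraction floor: 1 by default (a single-copy
    allele has no nonallelic homologous template), 0 to allow whole-array
    loss as seen for pol32Δ.
    """

    locus_id: str
    copies: int = 13
    promoter_kind: str = "copper_inducible"
    has_rfs: bool = True
    min_copies: int = 1

    def __post_init__(self) -> None:
        if not self.locus_id:
            raise ParameterError("locus_id must be non-empty")
        if self.copies < 1:
            raise ParameterError("copies must be >= 1")
        if self.min_copies < 0:
            raise ParameterError("min_copies must be >= 0")
        if self.copies < self.min_copies:
            raise ParameterError("copies must be >= min_copies")
        if self.promoter_kind not in PROMOTER_KINDS:
            raise ConfigurationError(
                f"unknown promoter_kind {self.promoter_kind!r}; "
                f"expected one of {PROMOTER_KINDS}"
            )


@dataclass(frozen=True)
class LocusActivityState:
    """Transcriptional and chromatin state of one array.

    ``t_sense``/``t_anti`` are sense and antisense (CUT-through-RFS)
    transcription activities in [0, 1]; ``h3k56ac`` is the acetylation level A
    in [0, 1].
    """

    t_sense: float
    t_anti: float
    h3k56ac: float

    def __post_init__(self) -> None:
        for name in ("t_sense", "t_anti", "h3k56ac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class ActivityParams:
    """Environment → locus activity map.

    Hill constants are in the units of the driving variable (mM for copper,
    nicotinamide and formaldehyde; carbon fraction for galactose).
    ``antisense_floor`` is the baseline CUT activity of the uninduced copper
    promoter; ``basal_acetylation`` is the steady-state H3K56ac level with
    active Hst3/Hst4; nicotinamide ramps acetylation linearly up to full
    inhibition at ``nic_full_mM`` (5 mM, the concentration used throughout
    the experiments).
    """

    copper_K: float = 0.3
    copper_h: float = 2.0
    galactose_K: float = 0.2
    galactose_h: float = 2.0
    formaldehyde_K: float = 0.7
    formaldehyde_h: float = 6.0
    nic_K: float = 1.0
    nic_h: float = 2.0
    nic_full_mM: float = 5.0
    antisense_floor: float = 0.01
    basal_acetylation: float = 0.4

    def __post_init__(self) -> None:
        for name in ("copper_K", "galactose_K", "formaldehyde_K", "nic_K", "nic_full_mM"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("copper_h", "galactose_h", "formaldehyde_h", "nic_h"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 0.0 <= self.antisense_floor < 1.0:
            raise ParameterError("antisense_floor must lie in [0, 1)")
        if not 0.0 < self.basal_acetylation < 1.0:
            raise ParameterError("basal_acetylation must lie in (0, 1)")


@dataclass(frozen=True)
class RateParams:
    """Parameters of the per-allele per-division CNV rate law.

    rate = fork_stability_modifier * b
           + r_max * (1 - exp(-kappa * t_anti * H(A)))

    with H(A) = A^ac_h / (A^ac_h + ac_K^ac_h). ``b`` is the basal
    (unstimulated) probability per allele per division, ``r_max`` the ceiling
    of the stimulated term, ``kappa`` the saturation steepness of the
    transcription drive, and (``ac_K``, ``ac_h``) the Hill constant/exponent
    of the acetylation gate.
    """

    b: float = 0.0015
    r_max: float = 0.05
    kappa: float = 8.0
    ac_K: float = 0.3
    ac_h: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ParameterError("b must lie in [0, 1]")
        if not 0.0 <= self.r_max <= 1.0:
            raise ParameterError("r_max must lie in [0, 1]")
        if self.b + self.r_max > 1.0:
            raise ParameterError("b + r_max must be <= 1")
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if not 0.0 < self.ac_K <= 1.0:
            raise ParameterError("ac_K must lie in (0, 1]")
        if self.ac_h < 1:
            raise ParameterError("ac_h must be >= 1")


@dataclass(frozen=True)
class SwitchScheme:
    """Template-switch outcome scheme.

    ``n_switches`` successive template switches, each independently forward
    (towards the array end; copy loss, ``delta_forward`` < 0) with probability
    ``p_forward`` or backward (re-replication; copy gain, ``delta_backward``
    > 0). Paths with zero net copy-number change are scored as
    ``zero_net_class`` — ``contraction`` under the default scheme, because a
    fork that switched forward and back has resolved by an error-prone route
    biased against amplification.
    """

    p_forward: float = 0.5
    delta_forward: int = -1
    delta_backward: int = 1
    n_switches: int = 2
    zero_net_class: str = "contraction"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_forward <= 1.0:
            raise ParameterError("p_forward must lie in [0, 1]")
        if not self.delta_forward < 0 < self.delta_backward:
            raise ParameterError("require delta_forward < 0 < delta_backward")
        if self.n_switches < 1:
            raise ParameterError("n_switches must be >= 1")
        if self.zero_net_class not in OUTCOME_CLASSES:
            raise ParameterError(
                f"zero_net_class must be one of {OUTCOME_CLASSES}, "
                f"got {self.zero_net_class!r}"
            )


@dataclass(frozen=True)
class SwitchOutcome:
    """One ordered template-switch path and its net effect."""

    path: tuple[str, ...]  # elements 'F' (forward) / 'B' (backward)
    delta: int
    probability: float
    outcome_class: str


@dataclass(frozen=True)
class SwitchOutcomeDistribution:
    """Exhaustive distribution over switch paths.

    ``class_counts`` counts paths per outcome class; ``class_probs`` sums path
    probabilities per class (identical to counts/2^n when p_forward = 1/2).
    """

    scheme: SwitchScheme
    outcomes: tuple[SwitchOutcome, ...]
    class_counts: dict[str, int] = field(default_factory=dict)
    class_probs: dict[str, float] = field(default_factory=dict)

    def contraction_amplification_ratio(self, weighted: bool = False) -> float:
        """Contraction:amplification ratio, by path count or by probability."""
        if weighted:
            num = self.class_probs.get("contraction", 0.0)
            den = self.class_probs.get("amplification", 0.0)
        else:
            num = self.class_counts.get("contraction", 0)
            den = self.class_counts.get("amplification", 0)
        if den == 0:
            return float("inf") if num else float("nan")
        return num / den

    def delta_probabilities(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for o in self.outcomes:
            out[o.delta] = out.get(o.delta, 0.0) + o.probability
        return out


@dataclass(frozen=True)
class CNVEvent:
    """A realised copy-number change: signed delta, class, and switch path."""

    delta: int
    outcome_class: str
    path: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.outcome_class not in OUTCOME_CLASSES:
            raise ParameterError(f"bad outcome_class {self.outcome_class!r}")
        if self.delta > 0 and self.outcome_class != "amplification":
            raise ParameterError("positive delta must be an amplification")
        if self.delta < 0 and self.outcome_class != "contraction":
            raise ParameterError("negative delta must be a contraction")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def locus_activity(
    env: EnvironmentCondition,
    locus: LocusConfig,
    genotype: Genotype = WILD_TYPE,
    params: ActivityParams = ActivityParams(),
) -> LocusActivityState:
    """Map environment, locus and genotype onto a locus activity state.

    Copper-inducible loci respond to copper with a Hill curve in both sense
    and antisense directions; nicotinamide additionally raises the antisense
    CUT (loss of promoter directionality) without inducing the sense mRNA.
    Galactose- and formaldehyde-inducible loci fire symmetrically
    (bidirectional promoter), are silent without their inducer, and do not
    respond to nicotinamide. H3K56ac is 0 without Rtt109, 1 with inactive
    HDACs (hst3Δ hst4Δ or full nicotinamide inhibition), basal otherwise.
    """
    p = params
    kind = locus.promoter_kind
    if kind == "copper_inducible":
        induced = hill(env.copper_mM, p.copper_K, p.copper_h)
        nic_drive = hill(env.nicotinamide_mM, p.nic_K, p.nic_h)
        # independent routes to antisense firing: promoter induction and
        # HDAC-inhibition-driven loss of directionality
        drive = 1.0 - (1.0 - induced) * (1.0 - nic_drive)
        t_sense = induced
        t_anti = p.antisense_floor + (1.0 - p.antisense_floor) * drive
    elif kind == "galactose_inducible":
        t = hill(env.galactose_frac, p.galactose_K, p.galactose_h)
        t_sense = t_anti = t
    elif kind == "formaldehyde_inducible":
        t = hill(env.formaldehyde_mM, p.formaldehyde_K, p.formaldehyde_h)
        t_sense = t_anti = t
    else:  # pragma: no cover - LocusConfig already validates
        raise ConfigurationError(f"unknown promoter_kind {kind!r}")

    if not genotype.h3k56ac_capable:
        ac = 0.0
    elif not genotype.hdac_active:
        ac = 1.0
    else:
        a0 = p.basal_acetylation
        ac = a0 + (1.0 - a0) * min(env.nicotinamide_mM / p.nic_full_mM, 1.0)
    return LocusActivityState(t_sense=t_sense, t_anti=t_anti, h3k56ac=ac)


def stimulated_cnv_rate(
    act: LocusActivityState,
    genotype: Genotype = WILD_TYPE,
    params: RateParams = RateParams(),
) -> float:
    """Per-allele per-division CNV probability.

    Promoter activity (antisense transcription through the RFS site) and
    H3K56ac contribute through a product inside a saturating exponential, so
    either channel alone saturates the stimulated term at high drive while
    the loss of either (silent promoter, or rtt109Δ) removes stimulation
    entirely. Without H3K56ac capability the rate is exactly
    ``fork_stability_modifier * b``.
    """
    base = genotype.fork_stability_modifier * params.b
    if not genotype.h3k56ac_capable:
        rate = base
    else:
        gate = hill(act.h3k56ac, params.ac_K, params.ac_h)
        rate = base + params.r_max * (-np.expm1(-params.kappa * act.t_anti * gate))
    if not 0.0 <= rate <= 1.0:
        raise ParameterError(
            f"CNV rate {rate!r} outside [0, 1]; check fork_stability_modifier, "
            "b and r_max"
        )
    return float(rate)


def _classify(delta: int, zero_net_class: str) -> str:
    if delta > 0:
        return "amplification"
    if delta < 0:
        return "contraction"
    return zero_net_class


@lru_cache(maxsize=64)
def enumerate_switch_outcomes(scheme: SwitchScheme) -> SwitchOutcomeDistribution:
    """Exhaustively enumerate the 2^n ordered template-switch paths.

    Each path is weighted by its Bernoulli probability; the net delta is the
    sum of per-switch deltas, and the class follows the sign of the net delta
    (``zero_net_class`` for net zero). Under the default scheme the four
    paths {FF: −2, FB: 0, BF: 0, BB: +2} give 3 contraction paths per
    amplification path.
    """
    outcomes = []
    counts = dict.fromkeys(OUTCOME_CLASSES, 0)
    probs = dict.fromkeys(OUTCOME_CLASSES, 0.0)
    for path in itertools.product("FB", repeat=scheme.n_switches):
        n_fwd = path.count("F")
        n_bwd = scheme.n_switches - n_fwd
        prob = scheme.p_forward**n_fwd * (1.0 - scheme.p_forward) ** n_bwd
        delta = n_fwd * scheme.delta_forward + n_bwd * scheme.delta_backward
        cls = _classify(delta, scheme.zero_net_class)
        outcomes.append(SwitchOutcome(tuple(path), delta, prob, cls))
        counts[cls] += 1
        probs[cls] += prob
    counts = {k: v for k, v in counts.items() if v}
    probs = {k: v for k, v in probs.items() if v}
    return SwitchOutcomeDistribution(scheme, tuple(outcomes), counts, probs)


def sample_cnv_event(
    copies: int,
    act: LocusActivityState,
    scheme: SwitchScheme = SwitchScheme(),
    rng: Optional[np.random.Generator] = None,
    *,
    genotype: Genotype = WILD_TYPE,
    rate_params: RateParams = RateParams(),
    min_copies: int = 1,
) -> Optional[CNVEvent]:
    """Draw a CNV event (or no event) for one allele at one division.

    With probability :func:`stimulated_cnv_rate` an outcome path is drawn
    from :func:`enumerate_switch_outcomes`; the net delta is clipped so the
    allele never falls below ``min_copies``. A single-copy allele has no
    nonallelic homologous template, so ``copies == 1`` always returns
    no-event. Events whose contraction is clipped all the way to zero are
    suppressed.
    """
    if copies < 1:
        raise DomainError(f"copies must be >= 1, got {copies}")
    if rng is None:
        rng = np.random.default_rng()
    if copies == 1:
        return None
    rate = stimulated_cnv_rate(act, genotype, rate_params)
    if rng.random() >= rate:
        return None
    dist = enumerate_switch_outcomes(scheme)
    idx = rng.choice(len(dist.outcomes), p=[o.probability for o in dist.outcomes])
    outcome = dist.outcomes[idx]
    delta = outcome.delta
    if delta < 0:
        delta = max(delta, min_copies - copies)
        if delta == 0:
            return None  # clipped away entirely
    cls = _classify(delta, scheme.zero_net_class) if delta != outcome.delta else outcome.outcome_class
    return CNVEvent(delta=delta, outcome_class=cls, path=outcome.path)


def apply_event(copies: int, event: Optional[CNVEvent]) -> int:
    """Copy number after an event (identity for no-event)."""
    return copies if event is None else copies + event.delta
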