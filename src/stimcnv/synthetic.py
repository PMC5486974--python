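"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed), returns its outputs
together with a :class:`GroundTruth` record sufficient to regenerate them,
and emits the same formats the real-data paths read, so tests exercise the
parsers too.

Defaults mirror the study conditions: diploid cohorts with 13/14-copy
parental alleles and 89%/40% viabilities, 72-hour growth curves sampled
every 15 minutes, and genome fixtures with a planted γH2A gene set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .core_model import SwitchScheme, enumerate_switch_outcomes
from .errors import DomainError, ParameterError
from .inference import BandTable
from .population import GrowthCurve

__all__ = [
    "GroundTruth",
    "gen_cohort_dataset",
    "gen_growth_curves",
    "gen_genome_fixture",
    "gen_band_table",
]


@dataclass(frozen=True)
class GroundTruth:
    """Provenance record of a synthetic dataset: generator, parameters,
    planted quantities and seed — enough to regenerate it deterministically."""

    generator: str
    params: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Cohort tables (shape of the mother-enrichment allele copy-number data)
# ---------------------------------------------------------------------------


def gen_cohort_dataset(
    n_cells: int = 200,
    basal_rate: float = 0.027,
    stimulated_rate: float = 0.27,
    viabilities: tuple[float, float] = (0.40, 0.89),
    parental_copies: tuple[int, ...] = (13, 14),
    scheme: SwitchScheme = SwitchScheme(),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Treated and untreated cohort allele tables with known event rates.

    ``basal_rate``/``stimulated_rate`` are per-allele probabilities of a
    detectable (non-zero) CNV event over the assay window; deltas are drawn
    from the template-switch scheme conditioned on a net change, so the
    contraction bias of the mechanism is present in the tables. Viabilities
    ``(treated, untreated)`` set how many of ``n_cells`` starting cells are
    recovered per arm. Same seed ⇒ identical tables.
    """
    for name, r in (("basal_rate", basal_rate), ("stimulated_rate", stimulated_rate)):
        if not 0.0 <= r <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1]")
    v_treated, v_untreated = viabilities
    rng = np.random.default_rng(seed)
    dist = enumerate_switch_outcomes(scheme)
    nonzero = [(o.delta, o.probability) for o in dist.outcomes if o.delta != 0]
    if not nonzero:
        raise DomainError("switch scheme has no net-change outcome")
    deltas = np.array([d for d, _ in nonzero])
    probs = np.array([p for _, p in nonzero])
    probs = probs / probs.sum()

    def one_arm(rate: float, viability: float) -> pd.DataFrame:
        n_rec = int(round(n_cells * viability))
        rows = []
        for cid in range(n_rec):
            for idx, par in enumerate(parental_copies):
                c = par
                if par > 1 and rng.random() < rate:
                    d = int(deltas[rng.choice(len(deltas), p=probs)])
                    c = max(par + d, 1)
                    if c == par:  # fully clipped contraction: redraw as -1
                        c = par - 1
                rows.append((cid, idx, c, True))
        return pd.DataFrame(
            rows, columns=["cell_id", "allele_index", "copy_number", "viable"]
        )

    treated = one_arm(stimulated_rate, v_treated)
    untreated = one_arm(basal_rate, v_untreated)
    truth = GroundTruth(
        generator="gen_cohort_dataset",
        params=dict(
            n_cells=n_cells,
            viabilities=list(viabilities),
            parental_copies=list(parental_copies),
            scheme=dataclasses.asdict(scheme),
        ),
        planted=dict(
            basal_rate=basal_rate,
            stimulated_rate=stimulated_rate,
            fold=(stimulated_rate / basal_rate) if basal_rate > 0 else float("inf"),
        ),
        seed=seed,
    )
    return treated, untreated, truth


# ---------------------------------------------------------------------------
# Growth curves (shape of the raw plate-reader data)
# ---------------------------------------------------------------------------


def gen_growth_curves(
    mu: float = 0.35,
    capacity: float = 1.2,
    noise_sd: float = 0.005,
    dt: float = 0.25,
    hours: float = 72.0,
    n_replicates: int = 1,
    blank: float = 0.05,
    t_mid: float = 24.0,
    seed: int = 0,
) -> tuple[list[GrowthCurve], GroundTruth]:
    """Logistic OD curves with additive measurement noise.

    ``mu`` is the logistic growth rate (per hour; plate cultures in synthetic
    medium double roughly every 2 hours), ``capacity`` the saturation OD
    above blank and ``t_mid`` the inflection time. The planted maximum of
    dOD/dt is mu·capacity/4. ``hours = 0`` yields a single-point curve, which
    downstream kinetics reject.
    """
    if mu <= 0 or capacity <= 0:
        raise ParameterError("mu and capacity must be > 0")
    if dt <= 0:
        raise DomainError("dt must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, hours + dt / 2, dt)
    curves = []
    for _ in range(n_replicates):
        od = blank + capacity / (1.0 + np.exp(-mu * (times - t_mid)))
        if noise_sd > 0:
            od = od + rng.normal(0.0, noise_sd, size=od.shape)
        curves.append(GrowthCurve(times=times, od=np.maximum(od, 0.0)))
    truth = GroundTruth(
        generator="gen_growth_curves",
        params=dict(
            mu=mu, capacity=capacity, noise_sd=noise_sd, dt=dt, hours=hours,
            n_replicates=n_replicates, blank=blank, t_mid=t_mid,
        ),
        planted=dict(max_growth_rate=mu * capacity / 4.0),
        seed=seed,
    )
    return curves, truth


# ---------------------------------------------------------------------------
# Genome fixtures (genes + peaks + expression with planted γH2A structure)
# ---------------------------------------------------------------------------


def gen_genome_fixture(
    n_genes: int = 100,
    n_gh2a: int = 10,
    shift_log2: float = -2.0,
    n_datasets: int = 3,
    expr_sd: float = 0.8,
    outdir: Optional[Union[str, Path]] = None,
    seed: int = 0,
):
    """Gene annotation, peak calls and expression counts with planted truth.

    Genes are laid out head-to-tail with >= 1.2 kb spacing on two
    chromosomes; each planted γH2A gene receives a >= 2-fold peak inside its
    1-kb upstream window, and non-γH2A genes receive occasional sub-threshold
    decoy peaks. Expression counts are drawn so that γH2A genes sit
    ``shift_log2`` log2 units below the rest in every dataset.

    Returns ``(genes, peaks, expression, truth)`` where genes/peaks are the
    in-memory object lists and expression is a tidy counts table. With
    ``outdir`` set, also writes genes.gff3, peaks.bed, expression.tsv and
    truth.json there.
    """
    from .genomics import GeneModel, GenomicInterval, PeakCall

    if not 0 <= n_gh2a <= n_genes:
        raise ParameterError("require 0 <= n_gh2a <= n_genes")
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        chrom = "chrI" if i < (n_genes + 1) // 2 else "chrII"
        local = i if i < (n_genes + 1) // 2 else i - (n_genes + 1) // 2
        # spacing leaves > 2 kb between consecutive CDS ends and starts so
        # two 1-kb upstream windows can never share a gap
        start = 2000 + local * 5000 + int(rng.integers(0, 300))
        length = int(rng.integers(500, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"GENE{i:04d}", GenomicInterval(chrom, start, start + length, strand))
        )
    gh2a_ids = sorted(
        genes[int(i)].gene_id for i in rng.choice(n_genes, size=n_gh2a, replace=False)
    )
    gh2a_set = set(gh2a_ids)

    from .genomics import upstream_window

    peaks = []
    for g in genes:
        win = upstream_window(g, 1000)
        if g.gene_id in gh2a_set:
            width = int(rng.integers(200, 500))
            lo = int(rng.integers(win.start, max(win.end - width, win.start) + 1))
            peaks.append(
                PeakCall(
                    GenomicInterval(win.chrom, lo, lo + width),
                    float(rng.uniform(2.5, 8.0)),
                )
            )
        elif rng.random() < 0.1:  # sub-threshold decoy in the window
            width = int(rng.integers(200, 400))
            lo = int(rng.integers(win.start, max(win.end - width, win.start) + 1))
            peaks.append(
                PeakCall(
                    GenomicInterval(win.chrom, lo, lo + width),
                    float(rng.uniform(1.1, 1.9)),
                )
            )

    datasets = [f"dataset_{d:02d}" for d in range(n_datasets)]
    rows = []
    for g in genes:
        base = float(rng.normal(9.0, expr_sd))
        if g.gene_id in gh2a_set:
            base += shift_log2
        length_kb = (g.cds.end - g.cds.start) / 1000.0
        for ds in datasets:
            value = base + float(rng.normal(0.0, expr_sd / 2))
            count = max(int(round(2.0**value * length_kb)), 0)
            rows.append((g.gene_id, ds, count, g.cds.end - g.cds.start))
    expression = pd.DataFrame(rows, columns=["gene_id", "dataset", "count", "cds_length"])

    truth = GroundTruth(
        generator="gen_genome_fixture",
        params=dict(
            n_genes=n_genes, n_gh2a=n_gh2a, shift_log2=shift_log2,
            n_datasets=n_datasets, expr_sd=expr_sd,
        ),
        planted=dict(gh2a_genes=gh2a_ids, shift_log2=shift_log2),
        seed=seed,
    )

    if outdir is not None:
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_genes_gff3(genes, outdir / "genes.gff3")
        _io.write_peaks_bed(peaks, outdir / "peaks.bed")
        _io.write_table(expression, outdir / "expression.tsv")
        truth.to_json(outdir / "truth.json")
    return genes, peaks, expression, truth


# ---------------------------------------------------------------------------
# Southern band tables
# ---------------------------------------------------------------------------


def gen_band_table(
    allele_distribution: Mapping[int, float],
    intensity_scale: float = 1000.0,
    noise_sd: float = 0.0,
    probe_sites_per_copy: Union[Callable[[int], int], int, None] = None,
    seed: int = 0,
) -> tuple[BandTable, GroundTruth]:
    """Southern band quantification table from a known molar allele mixture.

    ``allele_distribution`` maps copy number to molar fraction (normalised
    internally). Band intensity is fraction × probe sites × scale with
    multiplicative Gaussian noise of SD ``noise_sd``. By default each copy
    binds one probe site per repeat unit (probe sites = copy number, floor 1),
    which is what the probe-site correction inverts.
    """
    if not allele_distribution:
        raise DomainError("allele_distribution must be non-empty")
    fracs = np.array(list(allele_distribution.values()), dtype=float)
    if (fracs < 0).any() or fracs.sum() <= 0:
        raise DomainError("allele fractions must be >= 0 with positive sum")
    fracs = fracs / fracs.sum()
    copies = np.array(list(allele_distribution.keys()), dtype=int)
    if probe_sites_per_copy is None:
        sites = np.maximum(copies, 1)
    elif callable(probe_sites_per_copy):
        sites = np.array([probe_sites_per_copy(int(c)) for c in copies], dtype=int)
    else:
        sites = np.full_like(copies, int(probe_sites_per_copy))
    rng = np.random.default_rng(seed)
    intensity = fracs * sites * intensity_scale
    if noise_sd > 0:
        intensity = np.maximum(
            intensity * (1.0 + rng.normal(0.0, noise_sd, size=len(intensity))), 0.0
        )
    table = BandTable(
        pd.DataFrame(
            {"copy_number": copies, "intensity": intensity, "probe_sites": sites}
        )
    )
    truth = GroundTruth(
        generator="gen_band_table",
        params=dict(
            intensity_scale=intensity_scale,
            noise_sd=noise_sd,
            probe_sites="per_copy" if probe_sites_per_copy is None else "custom",
        ),
        planted=dict(
            molar_fractions={int(c): float(f) for c, f in zip(copies, fracs)}
        ),
        seed=seed,
    )
    return table, truth
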