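"""Synthetic genomes, mutation catalogues and evolution outcomes with known
ground truth.

Everything the pipeline consumes can be generated here, seeded and fully
reproducible:

* circular genomes with controllable GC content and planted G_nT motifs in
  chosen replichore orientations;
* mutation catalogues in which each leading-strand T site draws an
  independent Poisson count with mean ``baseline_rate x fold(context)`` —
  exactly the sampling model under which the estimator's Garwood intervals
  are exact;
* evolution-experiment replicates with competing mutational targets and
  day-censored emergence times.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .evolution_stats import FOCAL, OTHER, EvolutionOutcome
from .genome_io import Genome, ReplichoreModel, leading_strand_at, reverse_complement
from .motif_scanner import ContextKey, ContextScheme, iter_t_sites
from .rate_estimator import MutationEvent
from .rate_model import RateTable, predict_fold

__all__ = [
    "PlantedMotif",
    "PlantedTruth",
    "SyntheticSpec",
    "EvolutionTarget",
    "generate_genome",
    "simulate_mutations",
    "simulate_key_counts",
    "simulate_evolution",
    "MutationGroundTruth",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
# 5' dinucleotide may not end in G (tract maximality)
_MOTIF_RE = re.compile(r"^([ACGT][ACT])(G+)T([ACGT]{0,2})$")


@dataclass(frozen=True)
class PlantedMotif:
    """A motif string to write at a plus-strand start position.

    ``leading=True`` writes it so it reads 5'->3' on the leading strand at
    that position (the potent orientation); ``leading=False`` plants it in
    lagging orientation.
    """

    position: int
    motif_string: str
    leading: bool = True


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one planted motif: where its mutable T landed."""

    t_pos: int
    strand: str
    key: ContextKey
    replication: str


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic genome."""

    genome_length: int
    gc_fraction: float = 0.5
    oriC: int = 0
    ter: Optional[int] = None  # default: genome_length // 2
    planted_motifs: Sequence[PlantedMotif] = field(default_factory=tuple)
    seed: int = 0
    baseline_rate: Optional[float] = None
    rate_table: Optional[RateTable] = None

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.ter is None:
            self.ter = self.genome_length // 2
        if self.baseline_rate is not None and self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    @property
    def model(self) -> ReplichoreModel:
        return ReplichoreModel(self.oriC, self.ter, self.genome_length)


def _parse_motif(motif_string: str) -> tuple[str, int, str, Optional[str]]:
    m = _MOTIF_RE.match(motif_string)
    if m is None:
        raise ValueError(
            f"bad motif string {motif_string!r}: need 5' dinucleotide (not "
            "ending in G, first base also non-G), a G tract, T, and 0-2 3' bases"
        )
    dinuc, gs, tail = m.groups()
    tp1 = tail[0] if tail else "N"
    tp2 = tail[1] if len(tail) > 1 else None
    return dinuc, len(gs), tp1, tp2


def generate_genome(spec: SyntheticSpec) -> tuple[Genome, list[PlantedTruth]]:
    """A random circular genome with the requested GC content and planted
    motifs.

    Background bases are i.i.d. with P(G) = P(C) = gc/2. Planted motif
    strings overwrite the background in the requested orientation; overlaps
    between planted motifs are an error. Motifs arising by chance in the
    background are legal and expected — ground truth covers only the planted
    ones. Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    bases = np.array(list("ACGT"))
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(bases, size=spec.genome_length, p=probs)
    model = spec.model

    occupied: set[int] = set()
    truths: list[PlantedTruth] = []
    for pm in spec.planted_motifs:
        dinuc, n, tp1, tp2 = _parse_motif(pm.motif_string)
        if tp1 == "N":
            raise ValueError(
                f"planted motif {pm.motif_string!r} must include at least one 3' base"
            )
        L = len(pm.motif_string)
        span = range(pm.position, pm.position + L)
        if pm.position < 0 or pm.position + L > spec.genome_length:
            raise ValueError(f"planted motif at {pm.position} exceeds genome")
        if any(i in occupied for i in span):
            raise ValueError(f"planted motifs overlap at position {pm.position}")
        occupied.update(span)

        lead = leading_strand_at(model, pm.position)
        read_strand = lead if pm.leading else ("-" if lead == "+" else "+")
        i_t = 2 + n  # index of the mutable T within the motif string
        if read_strand == "+":
            content = pm.motif_string
            t_pos = pm.position + i_t
        else:
            content = reverse_complement(pm.motif_string)
            t_pos = pm.position + (L - 1 - i_t)
        for j, ch in enumerate(content):
            arr[pm.position + j] = ch
        truths.append(
            PlantedTruth(
                t_pos=t_pos,
                strand=read_strand,
                key=ContextKey(dinuc, n, tp1, tp2),
                replication="leading" if pm.leading else "lagging",
            )
        )
    genome = Genome(name=f"synthetic_{spec.seed}", sequence="".join(arr), circular=True)
    return genome, truths


@dataclass
class MutationGroundTruth:
    """Exact per-context bookkeeping for a simulated catalogue."""

    key_sites: dict[ContextKey, int]
    key_events: dict[ContextKey, int]
    key_folds: dict[ContextKey, float]
    baseline_sites: int
    baseline_events: int
    baseline_rate: float


def simulate_mutations(
    genome: Genome,
    model: Optional[ReplichoreModel],
    table: RateTable,
    baseline_rate: float,
    seed: int,
    missing_fold: float = 1.0,
    scheme: ContextScheme = ContextScheme(),
) -> tuple[list[MutationEvent], MutationGroundTruth]:
    """Draw per-site Poisson T->G counts over every leading-strand T site.

    Baseline sites use fold 1; keyed sites use the table's forecast, or
    ``missing_fold`` (recorded in the ground truth) when the key is absent.
    Events are emitted in plus-strand ref/alt convention (T->G on '+' arcs,
    A->C on '-' arcs) with per-site multiplicities as counts.
    """
    if baseline_rate < 0:
        raise ValueError("baseline_rate must be >= 0")
    rng = np.random.default_rng(seed)
    positions: list[int] = []
    strands: list[str] = []
    keys: list[Optional[ContextKey]] = []
    means: list[float] = []
    key_sites: dict[ContextKey, int] = {}
    key_folds: dict[ContextKey, float] = {}
    baseline_sites = 0
    for pos, strand, _n, key, is_base in iter_t_sites(genome, model, scheme):
        if is_base:
            fold = 1.0
            baseline_sites += 1
        else:
            key_sites[key] = key_sites.get(key, 0) + 1
            fold = predict_fold(table, key)
            if fold is None:
                fold = missing_fold
            key_folds[key] = fold
        positions.append(pos)
        strands.append(strand)
        keys.append(key)
        means.append(baseline_rate * fold)
    counts = rng.poisson(np.asarray(means)) if means else np.array([], dtype=int)
    events: list[MutationEvent] = []
    key_events: dict[ContextKey, int] = {}
    baseline_events = 0
    for pos, strand, key, c in zip(positions, strands, keys, counts):
        if c == 0:
            continue
        if key is None:
            baseline_events += int(c)
        else:
            key_events[key] = key_events.get(key, 0) + int(c)
        ref, alt = ("T", "G") if strand == "+" else ("A", "C")
        events.append(MutationEvent(pos=pos, ref=ref, alt=alt, count=int(c)))
    truth = MutationGroundTruth(
        key_sites=key_sites,
        key_events=key_events,
        key_folds=key_folds,
        baseline_sites=baseline_sites,
        baseline_events=baseline_events,
        baseline_rate=baseline_rate,
    )
    return events, truth


def simulate_key_counts(
    key_sites: dict[ContextKey, int],
    key_folds: dict[ContextKey, float],
    baseline_sites: int,
    baseline_rate: float,
    rng: np.random.Generator,
) -> tuple[dict[ContextKey, int], int]:
    """Aggregated form of :func:`simulate_mutations`.

    A sum of independent per-site Poisson counts is Poisson with the summed
    mean, so drawing one count per context (mean = baseline_rate x fold x
    sites) is distributionally identical to the site-level simulation and is
    used for replicate-heavy calibration runs.
    """
    key_counts = {
        k: int(rng.poisson(baseline_rate * key_folds[k] * s))
        for k, s in key_sites.items()
    }
    baseline_count = int(rng.poisson(baseline_rate * baseline_sites))
    return key_counts, baseline_count


@dataclass(frozen=True)
class EvolutionTarget:
    """A mutational route to the selected phenotype."""

    label: str
    relative_rate: float
    in_focal_gene: bool = True

    def __post_init__(self) -> None:
        if not self.relative_rate > 0:
            raise ValueError("relative_rate must be > 0")


def simulate_evolution(
    targets: Sequence[EvolutionTarget],
    daily_hazard: float,
    n_replicates: int,
    horizon: int,
    seed: int,
) -> list[EvolutionOutcome]:
    """Simulate day-censored emergence of the selected phenotype.

    ``daily_hazard`` is the per-day emergence probability contributed by one
    unit of relative rate; target i contributes h_i = daily_hazard *
    relative_rate_i and a replicate emerges on a given day with probability
    1 - prod(1 - h_i). Conditional on emergence the winning target is drawn
    with probability proportional to its relative rate (first motile zone
    per plate; clonal interference not modelled). Replicates that do not
    emerge within ``horizon`` days are censored.
    """
    if not targets:
        raise ValueError("need at least one target")
    if not 0 < daily_hazard < 1:
        raise ValueError("daily_hazard must be in (0, 1)")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rates = np.array([t.relative_rate for t in targets], dtype=float)
    per_target = daily_hazard * rates
    if np.any(per_target >= 1):
        raise ValueError("daily_hazard * relative_rate must be < 1 for every target")
    p_day = 1.0 - np.prod(1.0 - per_target)
    rng = np.random.default_rng(seed)
    days = rng.geometric(p_day, size=n_replicates)
    winners = rng.choice(len(targets), size=n_replicates, p=rates / rates.sum())
    out: list[EvolutionOutcome] = []
    for i, (day, w) in enumerate(zip(days, winners)):
        if day > horizon:
            out.append(EvolutionOutcome(replicate_id=f"rep_{i}", emergence_day=None))
        else:
            locus = FOCAL if targets[w].in_focal_gene else OTHER
            out.append(
                EvolutionOutcome(replicate_id=f"rep_{i}", emergence_day=int(day), locus=locus)
            )
    return out
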