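"""Per-context relative T->G mutation-rate estimation from a catalogue.

Given a catalogue of inferred independent mutation events and a site census,
the relative rate of a context is

    (mutations_in_context / sites_in_context)
    -------------------------------------------
    (baseline_mutations  / baseline_sites)

where the baseline is the genomic T->G rate at T positions with no
immediately-preceding G. Confidence intervals treat the per-context mutation
count as Poisson (exact Garwood bounds from chi-square quantiles) and the
baseline rate as fixed — appropriate when baseline counts dwarf per-context
counts, as in genome-scale catalogues with >1e5 baseline events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from scipy.stats import chi2

from .genome_io import Genome, ReplichoreModel, leading_strand_at
from .motif_scanner import ContextKey, ContextScheme, _SiteReader, _site_at

__all__ = [
    "MutationEvent",
    "MutationTally",
    "RateEstimate",
    "read_mutations_tsv",
    "read_mutations_vcf",
    "classify_mutations",
    "poisson_ci",
    "estimate_relative_rates",
    "write_rate_estimates",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class MutationEvent:
    """One observed substitution in plus-strand convention.

    ``count`` carries multiplicity: recurrent independent events at one site
    are legitimate and counted as many times.
    """

    pos: int
    ref: str
    alt: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"bases must be A/C/G/T, got {self.ref}->{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class MutationTally:
    """Leading-orientation T->G counts per ContextKey plus baseline, with
    tallies of discarded events."""

    key_counts: dict[ContextKey, int]
    baseline_count: int
    ignored_non_tg: int
    ignored_undefined: int

    @property
    def total_retained(self) -> int:
        return self.baseline_count + sum(self.key_counts.values())


def read_mutations_tsv(path: Union[str, Path]) -> list[MutationEvent]:
    """Read a catalogue TSV with columns pos (1-based), ref, alt[, count]."""
    events = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("pos", "ref", "alt"):
            if need not in idx:
                raise ValueError(f"mutation TSV missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            count = int(f[idx["count"]]) if "count" in idx else 1
            events.append(
                MutationEvent(
                    pos=int(f[idx["pos"]]) - 1,
                    ref=f[idx["ref"]].upper(),
                    alt=f[idx["alt"]].upper(),
                    count=count,
                )
            )
    return events


def read_mutations_vcf(path: Union[str, Path]) -> list[MutationEvent]:
    """Read a minimal single-sample-free VCF (CHROM/POS/REF/ALT; INFO
    ignored). Multi-allelic records must be split upstream; non-SNV records
    are rejected."""
    import pysam

    events = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"VCF record at POS {rec.pos} is not a bi-allelic SNV; "
                    "split multi-allelics upstream"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"VCF record at POS {rec.pos} is not a SNV")
            events.append(MutationEvent(pos=rec.pos - 1, ref=ref, alt=alt))
    return events


def classify_mutations(
    events: Iterable[MutationEvent],
    genome: Genome,
    model: Optional[ReplichoreModel],
    scheme: ContextScheme = ContextScheme(),
) -> MutationTally:
    """Map events to leading orientation and tally T->G counts per context.

    A plus-strand A->C inside a minus-leading arc is a leading-orientation
    T->G and is retained; events that are not T->G in leading orientation
    are ignored (tallied). Retained events at sites whose context window is
    undefined (N, replichore boundary, linear end) are tallied separately.
    An event whose ref base disagrees with the genome is a hard error.
    """
    reader = _SiteReader(genome, model)
    key_counts: dict[ContextKey, int] = {}
    baseline = 0
    non_tg = 0
    undefined = 0
    for ev in events:
        if not 0 <= ev.pos < genome.length:
            raise ValueError(f"event position {ev.pos} outside genome")
        g_ref = genome.sequence[ev.pos]
        if g_ref != ev.ref:
            raise ValueError(
                f"event at position {ev.pos} (1-based {ev.pos + 1}) has ref "
                f"{ev.ref!r} but genome has {g_ref!r}"
            )
        strand = leading_strand_at(model, ev.pos)
        if strand == "+":
            lead_ref, lead_alt = ev.ref, ev.alt
        else:
            lead_ref, lead_alt = _COMP[ev.ref], _COMP[ev.alt]
        if (lead_ref, lead_alt) != ("T", "G"):
            non_tg += ev.count
            continue
        site = _site_at(reader, ev.pos, strand, strand, scheme.down)
        if site is None:
            undefined += ev.count
            continue
        n, dinuc, tp1, tp2, is_baseline = site
        if is_baseline:
            baseline += ev.count
        else:
            key = ContextKey(dinuc, n, tp1, tp2)
            key_counts[key] = key_counts.get(key, 0) + ev.count
    return MutationTally(
        key_counts=key_counts,
        baseline_count=baseline,
        ignored_non_tg=non_tg,
        ignored_undefined=undefined,
    )


def poisson_ci(count: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) central confidence interval for a Poisson mean.

    lo is the mean whose upper-tail probability at ``count`` equals
    (1-confidence)/2 (0 for count = 0); hi is defined symmetrically. Both
    are chi-square quantiles: lo = chi2.ppf(a/2, 2k)/2,
    hi = chi2.ppf(1-a/2, 2k+2)/2.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0 <= confidence < 1:
        raise ValueError("confidence must be in [0, 1)")
    alpha = 1.0 - confidence
    lo = 0.0 if count == 0 else 0.5 * chi2.ppf(alpha / 2.0, 2 * count)
    hi = 0.5 * chi2.ppf(1.0 - alpha / 2.0, 2 * (count + 1))
    return lo, hi


@dataclass(frozen=True)
class RateEstimate:
    """Relative-rate estimate for one context (``key=None`` = baseline)."""

    key: Optional[ContextKey]
    mutation_count: int
    site_count: int
    relative_rate: float
    ci_low: float
    ci_high: float

    @property
    def is_baseline(self) -> bool:
        return self.key is None


def estimate_relative_rates(
    mutation_counts: Mapping[ContextKey, int],
    site_counts: Mapping[ContextKey, int],
    baseline_counts: tuple[int, int],
    confidence: float = 0.95,
) -> list[RateEstimate]:
    """Relative rates with Poisson CIs for every key with a positive census.

    ``baseline_counts`` is (baseline_mutations, baseline_sites). CI bounds
    are ``poisson_ci(m_key)`` scaled by 1/(s_key * baseline_per_site_rate);
    baseline uncertainty is ignored (treated as fixed). Keys with zero sites
    are omitted unless they carry mutations, which is an error. The returned
    list starts with the baseline's own estimate (exactly 1 by construction).
    """
    m_base, s_base = baseline_counts
    if m_base <= 0 or s_base <= 0:
        raise ValueError("baseline mutation and site counts must be positive")
    base_rate = m_base / s_base
    orphans = [k for k, m in mutation_counts.items() if m > 0 and site_counts.get(k, 0) == 0]
    if orphans:
        raise ValueError(
            f"keys with mutations but zero census sites: {[str(k) for k in orphans]}"
        )
    out: list[RateEstimate] = []
    b_lo, b_hi = poisson_ci(m_base, confidence)
    scale_base = 1.0 / (s_base * base_rate)
    out.append(
        RateEstimate(
            key=None,
            mutation_count=m_base,
            site_count=s_base,
            relative_rate=1.0,
            ci_low=b_lo * scale_base,
            ci_high=b_hi * scale_base,
        )
    )
    for key in sorted(site_counts, key=str):
        s = site_counts[key]
        if s <= 0:
            continue
        m = mutation_counts.get(key, 0)
        rate = (m / s) / base_rate
        lo, hi = poisson_ci(m, confidence)
        scale = 1.0 / (s * base_rate)
        out.append(
            RateEstimate(
                key=key,
                mutation_count=m,
                site_count=s,
                relative_rate=rate,
                ci_low=lo * scale,
                ci_high=hi * scale,
            )
        )
    return out


def write_rate_estimates(estimates: Iterable[RateEstimate], path: Union[str, Path]) -> None:
    """Write estimates in the rate-table TSV dialect (plus count columns) so
    an estimated table can feed the forecaster directly."""
    with open(path, "w") as fh:
        fh.write(
            "five_prime_dinuc\tn\tthree_prime_1\tthree_prime_2\tfold_change\t"
            "ci_low\tci_high\tmutation_count\tsite_count\n"
        )
        for est in estimates:
            if est.key is None:
                continue  # the baseline (rate 1 by definition) has no key row
            k = est.key
            fh.write(
                f"{k.five_prime_dinuc}\t{k.n}\t{k.three_prime_1}\t"
                f"{k.three_prime_2 or '.'}\t{est.relative_rate:g}\t"
                f"{est.ci_low:g}\t{est.ci_high:g}\t{est.mutation_count}\t{est.site_count}\n"
            )
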