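"""G_nT motif scanning, T-site censuses and coding-effect annotation.

A G_nT motif is a maximal homopolymeric tract of n guanines immediately
followed by a thymine, read 5'->3' in leading-strand orientation; the T is the
mutational hotspot, mutating T->G so the tract extends by one (GGGT -> GGGG).
The motif's potency is modulated by its flanks: the dinucleotide 5' of the G
tract and one or two nucleotides 3' of the mutable T. Those flanks plus the
tract length form the :class:`ContextKey` under which rates are tabulated.

All scanning is done per replichore: a context window that would cross the
oriC/ter boundary (where the leading strand flips) or contain an N, or run off
the end of a linear genome, is undefined and the site is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio.Seq import Seq

from .genome_io import (
    CDSRecord,
    Genome,
    ReplichoreModel,
    leading_strand_at,
    reverse_complement,
)

__all__ = [
    "ContextKey",
    "ContextScheme",
    "GntMotif",
    "TSiteCensus",
    "CodingEffect",
    "scan_gnt",
    "census_t_sites",
    "coding_effect",
    "substitution_effects",
    "write_motif_tsv",
    "write_motif_bed",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class ContextKey:
    """The partition a T site falls into: 5' dinucleotide, G-tract length,
    first 3' base, and optionally the +2 base (``None`` = marginal over +2).
    """

    five_prime_dinuc: str
    n: int
    three_prime_1: str
    three_prime_2: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.five_prime_dinuc) != 2 or not set(self.five_prime_dinuc) <= set("ACGT"):
            raise ValueError(f"bad 5' dinucleotide {self.five_prime_dinuc!r}")
        if self.five_prime_dinuc[1] == "G" and self.n >= 1:
            raise ValueError(
                "5' dinucleotide may not end in G for n >= 1 (G tracts are maximal)"
            )
        if self.n < 0:
            raise ValueError("tract length n must be >= 0")
        if self.three_prime_1 not in "ACGT":
            raise ValueError(f"bad 3' base {self.three_prime_1!r}")
        if self.three_prime_2 is not None and self.three_prime_2 not in "ACGT":
            raise ValueError(f"bad +2 base {self.three_prime_2!r}")

    @property
    def motif_string(self) -> str:
        tail = self.three_prime_2 or ""
        return f"{self.five_prime_dinuc}{'G' * self.n}T{self.three_prime_1}{tail}"

    def marginal(self) -> "ContextKey":
        """The same key marginalised over the +2 position."""
        if self.three_prime_2 is None:
            return self
        return ContextKey(self.five_prime_dinuc, self.n, self.three_prime_1, None)

    def __str__(self) -> str:
        tp2 = self.three_prime_2 or "."
        return f"{self.five_prime_dinuc}.G{self.n}T.{self.three_prime_1}{tp2}"


@dataclass(frozen=True)
class ContextScheme:
    """How sites are keyed: whether the +2 base is part of the key."""

    include_plus_two: bool = False

    @property
    def down(self) -> int:
        return 2 if self.include_plus_two else 1


@dataclass(frozen=True)
class GntMotif:
    """One G_nT motif: the mutable T, its tract and flanks, in leading (or,
    when requested, lagging) orientation.

    ``t_pos`` is the plus-strand coordinate of the mutable T; ``strand`` is
    the strand on which the motif reads 5'->3'.
    """

    t_pos: int
    strand: str
    n: int
    five_prime_dinuc: str
    three_prime_1: str
    three_prime_2: Optional[str]
    motif_string: str
    replication: str = "leading"

    @property
    def key(self) -> ContextKey:
        return ContextKey(self.five_prime_dinuc, self.n, self.three_prime_1, self.three_prime_2)

    @property
    def ref_alt_plus(self) -> tuple[str, str]:
        """The substitution in plus-strand (VCF) convention."""
        return ("T", "G") if self.strand == "+" else ("A", "C")


@dataclass
class TSiteCensus:
    """Leading-strand T sites per context plus the no-preceding-G baseline.

    ``baseline_sites`` counts T sites whose immediately-5' base (in leading
    orientation) is defined and is not G; ``key_sites`` keys every T with a
    fully defined motif window by its ContextKey, for every tract length
    n >= 1.
    """

    key_sites: dict[ContextKey, int]
    baseline_sites: int

    @property
    def total_defined(self) -> int:
        return self.baseline_sites + sum(self.key_sites.values())


@dataclass(frozen=True)
class CodingEffect:
    """Codon-level consequence of a single-base substitution."""

    gene_id: Optional[str]
    codon_index: Optional[int]
    codon_position: Optional[int]
    ref_codon: Optional[str]
    alt_codon: Optional[str]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    effect: str

    @classmethod
    def intergenic(cls) -> "CodingEffect":
        return cls(None, None, None, None, None, None, None, "intergenic")


class _SiteReader:
    """Leading-orientation base access with same-arc and N/edge checks."""

    def __init__(self, genome: Genome, model: Optional[ReplichoreModel]):
        self.seq = genome.sequence
        self.L = genome.length
        self.circular = genome.circular
        self.model = model

    def lead_strand(self, pos: int) -> str:
        return leading_strand_at(self.model, pos)

    def base(self, pos: int, strand: str, offset: int, arc_strand: str) -> Optional[str]:
        """Base at leading-orientation ``offset`` from ``pos`` read on
        ``strand``; None when undefined (off a linear end, outside the
        replichore arc of the focal site, or N).

        ``arc_strand`` is the leading strand at the focal site: all window
        positions must lie on the same arc.
        """
        p = pos + offset if strand == "+" else pos - offset
        if self.circular:
            p %= self.L
        elif not 0 <= p < self.L:
            return None
        if self.model is not None and leading_strand_at(self.model, p) != arc_strand:
            return None
        b = self.seq[p]
        if b == "N":
            return None
        return b if strand == "+" else _COMP[b]


def _site_at(
    reader: _SiteReader, pos: int, read_strand: str, arc_strand: str, down: int
):
    """Classify position ``pos`` read on ``read_strand``.

    Returns ``(n, dinuc, tp1, tp2, baseline)`` for a T site, or None when the
    site is not a (defined) T site. ``baseline`` is True for n = 0 sites; for
    those only the -1 base and the 3' window need be defined. For n >= 1 the
    full window (tract, dinucleotide, 3' bases) must be defined; an
    interrupted window means the site is undefined and None is returned.
    """
    if reader.base(pos, read_strand, 0, arc_strand) != "T":
        return None
    # count the maximal 5' G run
    n = 0
    while True:
        b = reader.base(pos, read_strand, -(n + 1), arc_strand)
        if b == "G":
            n += 1
        else:
            break
    if n == 0:
        if b is None:  # -1 base undefined
            return None
        tp1 = reader.base(pos, read_strand, 1, arc_strand)
        if tp1 is None:
            return None
        tp2 = reader.base(pos, read_strand, 2, arc_strand) if down >= 2 else None
        if down >= 2 and tp2 is None:
            return None
        return (0, None, tp1, tp2, True)
    # n >= 1: maximality base b at -(n+1) must be defined (and is not G)
    if b is None:
        return None
    b2 = reader.base(pos, read_strand, -(n + 2), arc_strand)
    if b2 is None:
        return None
    tp1 = reader.base(pos, read_strand, 1, arc_strand)
    if tp1 is None:
        return None
    tp2 = None
    if down >= 2:
        tp2 = reader.base(pos, read_strand, 2, arc_strand)
        if tp2 is None:
            return None
    return (n, b2 + b, tp1, tp2, False)


def iter_t_sites(
    genome: Genome,
    model: Optional[ReplichoreModel],
    scheme: ContextScheme = ContextScheme(),
) -> Iterator[tuple[int, str, int, Optional[ContextKey], bool]]:
    """Yield every defined leading-strand T site as
    ``(pos, strand, n, key_or_None, is_baseline)``.

    Baseline sites (no immediately-5' G) yield ``key=None``; keyed sites
    yield their ContextKey at the scheme's resolution.
    """
    reader = _SiteReader(genome, model)
    for pos in range(genome.length):
        strand = reader.lead_strand(pos)
        site = _site_at(reader, pos, strand, strand, scheme.down)
        if site is None:
            continue
        n, dinuc, tp1, tp2, baseline = site
        if baseline:
            yield pos, strand, 0, None, True
        else:
            yield pos, strand, n, ContextKey(dinuc, n, tp1, tp2), False


def scan_gnt(
    genome: Genome,
    model: Optional[ReplichoreModel],
    n_min: int = 3,
    n_max: int = 5,
    leading_only: bool = True,
    scheme: ContextScheme = ContextScheme(include_plus_two=True),
) -> list[GntMotif]:
    """Find every G_nT motif with maximal tract length in [n_min, n_max].

    Motifs are read 5'->3' in leading-strand orientation; with
    ``leading_only=False`` the lagging orientation of each replichore is
    scanned too and motifs carry a ``replication`` label. Motifs whose
    context window contains an N, crosses the replichore boundary, or runs
    off a linear genome end are dropped. Sorted by ``t_pos``.
    """
    if not 1 <= n_min <= n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    reader = _SiteReader(genome, model)
    out: list[GntMotif] = []
    for pos in range(genome.length):
        arc = reader.lead_strand(pos)
        orientations = [(arc, "leading")]
        if not leading_only:
            orientations.append(("-" if arc == "+" else "+", "lagging"))
        for read_strand, label in orientations:
            site = _site_at(reader, pos, read_strand, arc, scheme.down)
            if site is None:
                continue
            n, dinuc, tp1, tp2, baseline = site
            if baseline or not n_min <= n <= n_max:
                continue
            motif_string = dinuc + "G" * n + "T" + tp1 + (tp2 or "")
            out.append(
                GntMotif(
                    t_pos=pos,
                    strand=read_strand,
                    n=n,
                    five_prime_dinuc=dinuc,
                    three_prime_1=tp1,
                    three_prime_2=tp2,
                    motif_string=motif_string,
                    replication=label,
                )
            )
    out.sort(key=lambda m: (m.t_pos, m.replication))
    return out


def census_t_sites(
    genome: Genome,
    model: Optional[ReplichoreModel],
    scheme: ContextScheme = ContextScheme(),
) -> TSiteCensus:
    """Count every leading-strand T site by ContextKey, plus the baseline.

    The baseline counts T sites with no immediately-preceding G — the
    denominator for the "no preceding Gs" genomic T->G rate against which
    motif fold changes are expressed.
    """
    key_sites: dict[ContextKey, int] = {}
    baseline = 0
    for _pos, _strand, _n, key, is_base in iter_t_sites(genome, model, scheme):
        if is_base:
            baseline += 1
        else:
            key_sites[key] = key_sites.get(key, 0) + 1
    return TSiteCensus(key_sites=key_sites, baseline_sites=baseline)


# --- coding effects ---------------------------------------------------------

_STOP = "*"


def _classify(ref_aa: str, alt_aa: str) -> str:
    if ref_aa == _STOP and alt_aa != _STOP:
        return "stop_lost"
    if ref_aa != _STOP and alt_aa == _STOP:
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def substitution_effects(
    pos: int,
    ref: str,
    alt: str,
    cds_list: Iterable[CDSRecord],
    genome: Genome,
) -> list[CodingEffect]:
    """Codon-level effects of a plus-strand substitution ``ref``->``alt``.

    One record per overlapping CDS; a single intergenic record when the
    position falls in none. Translation uses the bacterial/standard genetic
    code (NCBI table 11) without start-codon special-casing. CDS whose coding
    span is not a whole number of codons are skipped with a warning.
    """
    if genome.sequence[pos] != ref:
        raise ValueError(
            f"reference base mismatch at position {pos}: genome has "
            f"{genome.sequence[pos]!r}, substitution says {ref!r}"
        )
    effects: list[CodingEffect] = []
    for cds in cds_list:
        if pos not in cds:
            continue
        if cds.strand == "+":
            frame_start = cds.start + cds.phase
            offset = pos - frame_start
            span = cds.end - frame_start
        else:
            frame_start = cds.end - 1 - cds.phase
            offset = frame_start - pos
            span = frame_start - cds.start + 1
        if span % 3 != 0:
            warnings.warn(
                f"CDS {cds.gene_id!r}: coding span {span} not divisible by 3; skipped",
                stacklevel=2,
            )
            continue
        if offset < 0:
            # inside the phase-trimmed overhang: no complete codon
            continue
        codon_index = offset // 3
        codon_position = offset % 3 + 1
        if cds.strand == "+":
            c0 = frame_start + 3 * codon_index
            ref_codon = genome.sequence[c0 : c0 + 3]
        else:
            c0 = frame_start - 3 * codon_index
            ref_codon = reverse_complement(genome.sequence[c0 - 2 : c0 + 1])
        alt_base = alt if cds.strand == "+" else _COMP[alt]
        i = codon_position - 1
        alt_codon = ref_codon[:i] + alt_base + ref_codon[i + 1 :]
        ref_aa = str(Seq(ref_codon).translate(table=11))
        alt_aa = str(Seq(alt_codon).translate(table=11))
        effects.append(
            CodingEffect(
                gene_id=cds.gene_id,
                codon_index=codon_index,
                codon_position=codon_position,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                effect=_classify(ref_aa, alt_aa),
            )
        )
    if not effects:
        effects.append(CodingEffect.intergenic())
    return effects


def coding_effect(
    t_pos: int,
    leading_strand: str,
    cds_list: Iterable[CDSRecord],
    genome: Genome,
) -> list[CodingEffect]:
    """Effects of the hotspot T->G substitution at ``t_pos``.

    ``leading_strand`` is the orientation in which the motif reads 5'->3':
    '+' means a plus-strand T->G, '-' means the plus strand carries the
    complementary A->C.
    """
    if leading_strand == "+":
        ref, alt = "T", "G"
    elif leading_strand == "-":
        ref, alt = "A", "C"
    else:
        raise ValueError("leading_strand must be '+' or '-'")
    return substitution_effects(t_pos, ref, alt, cds_list, genome)


# --- report writers ---------------------------------------------------------


def write_motif_tsv(
    motifs: Iterable[GntMotif],
    path: Union[str, Path],
    folds: Optional[dict[int, Optional[float]]] = None,
    effects: Optional[dict[int, str]] = None,
) -> None:
    """One motif per row, 1-based position; optional fold-change and coding
    effect columns keyed by t_pos."""
    with open(path, "w") as fh:
        fh.write(
            "pos\tstrand\treplication\tn\tfive_prime_dinuc\tthree_prime_1\t"
            "three_prime_2\tmotif_string\tref\talt\tfold_change\teffect\n"
        )
        for m in motifs:
            ref, alt = m.ref_alt_plus
            fold = (folds or {}).get(m.t_pos)
            eff = (effects or {}).get(m.t_pos, "")
            fold_s = "" if fold is None else f"{fold:g}"
            fh.write(
                f"{m.t_pos + 1}\t{m.strand}\t{m.replication}\t{m.n}\t"
                f"{m.five_prime_dinuc}\t{m.three_prime_1}\t{m.three_prime_2 or '.'}\t"
                f"{m.motif_string}\t{ref}\t{alt}\t{fold_s}\t{eff}\n"
            )


def write_motif_bed(
    motifs: Iterable[GntMotif],
    path: Union[str, Path],
    chrom: str,
    folds: Optional[dict[int, Optional[float]]] = None,
    score_cap: int = 1000,
) -> None:
    """BED6: the mutable T as a 1-bp interval, score = capped fold change."""
    with open(path, "w") as fh:
        for m in motifs:
            fold = (folds or {}).get(m.t_pos)
            score = 0 if fold is None else min(score_cap, int(round(fold)))
            fh.write(
                f"{chrom}\t{m.t_pos}\t{m.t_pos + 1}\t{m.motif_string}\t{score}\t{m.strand}\n"
            )
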