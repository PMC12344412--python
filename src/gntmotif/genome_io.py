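"""Genome and annotation I/O plus the replichore strand model.

A circular bacterial chromosome is replicated bidirectionally from a single
origin (*oriC*) to a terminus (*ter*), splitting it into two replichores. On
the replichore where the fork travels toward increasing plus-strand
coordinates, the plus strand is synthesised continuously and is the *leading*
strand; on the other replichore the minus strand is leading. Hotspot activity
of G_nT motifs depends on being read 5'->3' on the leading strand, so every
context extraction in this package is performed in leading-strand orientation.

Coordinates are 0-based half-open internally; file formats (FASTA, GFF3, VCF,
TSV reports) use their native 1-based inclusive conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "ReplichoreModel",
    "CDSRecord",
    "reverse_complement",
    "read_genome",
    "write_genome",
    "read_cds",
    "write_cds",
    "read_replichore_config",
    "leading_strand_at",
    "leading_context",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class Genome:
    """A single chromosome: upper-case DNA over {A,C,G,T,N}.

    ``circular`` controls whether context windows may wrap around the
    sequence ends.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("genome name must be non-empty")
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"genome contains unsupported characters {sorted(bad)}; "
                "only A/C/G/T/N are accepted (IUPAC ambiguity codes other "
                "than N must be resolved or masked to N upstream)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReplichoreModel:
    """Origin/terminus coordinates defining the two replichores.

    The half-open circular arc [oriC, ter) (walking in the direction of
    increasing coordinates, wrapping past the end) is the replichore on which
    the plus strand is the leading strand; the complementary arc [ter, oriC)
    has the minus strand leading. The boundary positions oriC and ter belong
    to the increasing-coordinate arc, so the partition is deterministic.
    """

    oriC: int
    ter: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        for label, v in (("oriC", self.oriC), ("ter", self.ter)):
            if not 0 <= v < self.genome_length:
                raise ValueError(f"{label}={v} outside [0, {self.genome_length})")
        if self.oriC == self.ter:
            raise ValueError("oriC and ter must differ")


@dataclass(frozen=True)
class CDSRecord:
    """One single-segment CDS feature, 0-based half-open, non-wrapping."""

    gene_id: str
    start: int
    end: int
    strand: str
    phase: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"CDS {self.gene_id}: need 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.gene_id}: strand must be + or -")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"CDS {self.gene_id}: phase must be 0, 1 or 2")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_genome(
    fasta_source: Union[str, Path], record: Optional[str] = None, circular: bool = True
) -> Genome:
    """Read a genome from FASTA.

    By default the first record is used; pass ``record`` to select a record
    by id from a multi-record file. Sequences are upper-cased; ambiguity
    codes other than N are rejected.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_source}")
    if record is None:
        chosen = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record not in by_id:
            raise ValueError(f"record {record!r} not found in {fasta_source}")
        chosen = by_id[record]
    return Genome(name=chosen.id, sequence=str(chosen.seq).upper(), circular=circular)


def write_genome(genome: Genome, fasta_path: Union[str, Path]) -> None:
    """Write a genome to a single-record FASTA file."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")


def _gff_attr(attributes: dict, *keys: str) -> Optional[str]:
    for key in keys:
        if key in attributes and attributes[key]:
            return attributes[key][0]
    return None


def read_cds(gff3_source: Union[str, Path], genome: Genome) -> list[CDSRecord]:
    """Read single-segment CDS features from a GFF3 file.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Multi-segment CDS (several CDS lines sharing one ID, i.e. joined parts)
    are skipped with a warning: codon arithmetic across segments is out of
    scope. Features extending beyond the genome raise.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        id_spec=None,
    )
    by_id: dict[str, list] = {}
    anonymous = []
    for feat in db.features_of_type("CDS"):
        fid = _gff_attr(dict(feat.attributes), "ID", "Parent", "gene_id", "locus_tag")
        if fid is None:
            anonymous.append(feat)
        else:
            by_id.setdefault(fid, []).append(feat)

    records: list[CDSRecord] = []
    counter = 0
    for fid, feats in by_id.items():
        if len(feats) > 1:
            warnings.warn(
                f"CDS {fid!r} has {len(feats)} segments; multi-segment CDS are "
                "skipped",
                stacklevel=2,
            )
            continue
        records.append(_feature_to_record(feats[0], fid, genome))
    for feat in anonymous:
        counter += 1
        records.append(_feature_to_record(feat, f"cds_{counter}", genome))
    records.sort(key=lambda r: (r.start, r.gene_id))
    return records


def _feature_to_record(feat, gene_id: str, genome: Genome) -> CDSRecord:
    start = feat.start - 1  # GFF3 is 1-based inclusive
    end = feat.end
    if end > genome.length:
        raise ValueError(
            f"CDS {gene_id!r} end {end} exceeds genome length {genome.length}"
        )
    frame = feat.frame
    phase = int(frame) if frame not in (None, ".", "") else 0
    strand = feat.strand if feat.strand in "+-" else "+"
    return CDSRecord(gene_id=gene_id, start=start, end=end, strand=strand, phase=phase)


def write_cds(
    records: Iterable[CDSRecord], gff3_path: Union[str, Path], seqid: str = "genome"
) -> None:
    """Write CDS records as GFF3 (1-based inclusive coordinates)."""
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(
                f"{seqid}\tgntmotif\tCDS\t{rec.start + 1}\t{rec.end}\t.\t"
                f"{rec.strand}\t{rec.phase}\tID={rec.gene_id}\n"
            )


def read_replichore_config(path: Union[str, Path]) -> tuple[ReplichoreModel, bool]:
    """Read oriC/ter/genome_length (and a circular flag) from TOML or YAML.

    oriC and ter must be supplied explicitly — they are never inferred.
    Returns ``(model, circular)``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib

        cfg = tomllib.loads(text)
    else:
        import yaml

        cfg = yaml.safe_load(text)
    missing = [k for k in ("oriC", "ter", "genome_length") if k not in cfg]
    if missing:
        raise ValueError(f"replichore config missing required keys: {missing}")
    model = ReplichoreModel(
        oriC=int(cfg["oriC"]), ter=int(cfg["ter"]), genome_length=int(cfg["genome_length"])
    )
    return model, bool(cfg.get("circular", True))


def leading_strand_at(model: Optional[ReplichoreModel], pos: int) -> str:
    """Which strand is leading at plus-strand coordinate ``pos``.

    '+' on the arc traversed from oriC toward ter in increasing-coordinate
    direction (with wraparound), '-' on the complementary arc. ``model=None``
    is the uniform convention used for bare test sequences: every position is
    treated as plus-strand leading.
    """
    if model is None:
        if pos < 0:
            raise IndexError(f"position {pos} out of range")
        return "+"
    if not 0 <= pos < model.genome_length:
        raise IndexError(f"position {pos} outside [0, {model.genome_length})")
    if model.oriC < model.ter:
        return "+" if model.oriC <= pos < model.ter else "-"
    return "+" if (pos >= model.oriC or pos < model.ter) else "-"


def leading_context(
    genome: Genome,
    model: Optional[ReplichoreModel],
    pos: int,
    up: int,
    down: int,
) -> str:
    """The (up + 1 + down)-mer centred on ``pos``, read 5'->3' on the leading
    strand.

    On a '-' leading arc this is the reverse complement of the plus-strand
    window [pos - down, pos + up]. Circular genomes wrap; on a linear genome a
    window that leaves the sequence raises.
    """
    if not 0 <= pos < genome.length:
        raise IndexError(f"position {pos} outside [0, {genome.length})")
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    strand = leading_strand_at(model, pos)
    if strand == "+":
        lo, hi = pos - up, pos + down
    else:
        lo, hi = pos - down, pos + up
    if genome.circular:
        L = genome.length
        window = "".join(genome.sequence[i % L] for i in range(lo, hi + 1))
    else:
        if lo < 0 or hi >= genome.length:
            raise IndexError(
                f"window [{lo}, {hi}] exceeds linear genome of length {genome.length}"
            )
        window = genome.sequence[lo : hi + 1]
    return window if strand == "+" else reverse_complement(window)
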