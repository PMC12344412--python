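"""Context -> fold-change rate tables and genome-wide hotspot forecasting.

Fold changes are dimensionless multipliers of the baseline genomic T->G rate
(the rate at T positions with no immediately preceding G). Because flank
effects are strongly non-independent — the contribution of one motif
component depends on the others — a missing key is never interpolated from
marginals: lookups fall back from a +2-resolved key to the +2-marginal key
and otherwise return an explicit missing marker (``None``).

The packaged default table carries only the handful of context fold changes
published as text for the Salmonella analysis (e.g. GA.G4T.C = 1112-fold,
95% CI 1004-1185; AC.G4T.A = 5.6-fold, CI 2.668-10.23); a full table must be
supplied as TSV for genome-wide work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .genome_io import CDSRecord, Genome, ReplichoreModel
from .motif_scanner import (
    ContextKey,
    ContextScheme,
    GntMotif,
    coding_effect,
    scan_gnt,
)

__all__ = [
    "RateEntry",
    "RateTable",
    "load_rate_table",
    "default_rate_table",
    "write_rate_table",
    "predict_fold",
    "forecast_genome",
    "ForecastReport",
]

_NONSYN = {"missense", "stop_gained", "stop_lost"}


@dataclass(frozen=True)
class RateEntry:
    fold_change: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be > 0, got {self.fold_change}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.fold_change <= self.ci_high:
                raise ValueError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"fold_change {self.fold_change}"
                )


@dataclass
class RateTable:
    """Map from ContextKey to fold change (with optional 95% CI).

    ``baseline_rate`` (expected T->G events per baseline site over the
    exposure of interest) is only needed to simulate absolute counts.
    """

    entries: dict[ContextKey, RateEntry] = field(default_factory=dict)
    baseline_rate: Optional[float] = None

    def add(self, key: ContextKey, entry: RateEntry) -> None:
        if key in self.entries:
            raise ValueError(f"duplicate rate-table key {key}")
        self.entries[key] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: ContextKey) -> bool:
        return key in self.entries


def _parse_opt(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in (".", "", "NA", "nan"):
        return None
    return float(s)


def load_rate_table(tsv_source: Union[str, Path], baseline_rate: Optional[float] = None) -> RateTable:
    """Load a rate table from TSV.

    Columns: five_prime_dinuc, n, three_prime_1, three_prime_2 (literal "."
    marks an entry marginal over the +2 position), fold_change, ci_low,
    ci_high ("." for absent bounds). Duplicate keys and non-positive fold
    changes are errors.
    """
    df = pd.read_csv(tsv_source, sep="\t", dtype=str, comment="#")
    required = {"five_prime_dinuc", "n", "three_prime_1", "three_prime_2", "fold_change"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"rate table missing columns: {sorted(missing)}")
    table = RateTable(baseline_rate=baseline_rate)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            tp2 = None if str(row.three_prime_2).strip() == "." else str(row.three_prime_2).strip()
            key = ContextKey(
                str(row.five_prime_dinuc).strip(),
                int(row.n),
                str(row.three_prime_1).strip(),
                tp2,
            )
            entry = RateEntry(
                fold_change=float(row.fold_change),
                ci_low=_parse_opt(getattr(row, "ci_low", None)),
                ci_high=_parse_opt(getattr(row, "ci_high", None)),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed rate-table row {row_no}: {exc}") from exc
        table.add(key, entry)
    return table


def default_rate_table() -> RateTable:
    """The packaged table of published Salmonella context fold changes."""
    with resources.as_file(
        resources.files("gntmotif.data").joinpath("context_rates.tsv")
    ) as path:
        return load_rate_table(path)


def write_rate_table(table: RateTable, path: Union[str, Path]) -> None:
    """Write a rate table in the TSV dialect ``load_rate_table`` reads."""
    with open(path, "w") as fh:
        fh.write("five_prime_dinuc\tn\tthree_prime_1\tthree_prime_2\tfold_change\tci_low\tci_high\n")
        for key in sorted(table.entries, key=str):
            e = table.entries[key]
            lo = "." if e.ci_low is None else f"{e.ci_low:g}"
            hi = "." if e.ci_high is None else f"{e.ci_high:g}"
            fh.write(
                f"{key.five_prime_dinuc}\t{key.n}\t{key.three_prime_1}\t"
                f"{key.three_prime_2 or '.'}\t{e.fold_change:g}\t{lo}\t{hi}\n"
            )


def predict_fold(table: RateTable, key: ContextKey) -> Optional[float]:
    """Forecast the fold change for a context key.

    Exact (+2-resolved) lookup first, then the +2-marginal entry; ``None``
    when neither exists — never a silent default, and never interpolation,
    because flank effects are contingent on one another.
    """
    entry = table.entries.get(key)
    if entry is None and key.three_prime_2 is not None:
        entry = table.entries.get(key.marginal())
    return None if entry is None else entry.fold_change


@dataclass
class ForecastReport:
    """Genome-wide hotspot forecast: per-motif rows plus summary counts."""

    motifs: pd.DataFrame
    fold_threshold: float
    n_motifs: int
    n_above_threshold: int
    genes_nonsynonymous_above: set[str]
    missing_keys: list[ContextKey]

    @property
    def summary(self) -> dict:
        return {
            "fold_threshold": self.fold_threshold,
            "n_motifs": self.n_motifs,
            "n_above_threshold": self.n_above_threshold,
            "n_genes_nonsynonymous_above": len(self.genes_nonsynonymous_above),
            "n_missing_keys": len(self.missing_keys),
        }


def forecast_genome(
    genome: Genome,
    model: Optional[ReplichoreModel],
    cds_list: Iterable[CDSRecord],
    table: RateTable,
    n_min: int = 3,
    n_max: int = 5,
    fold_threshold: float = 100.0,
    scheme: ContextScheme = ContextScheme(include_plus_two=True),
) -> ForecastReport:
    """Scan, forecast and annotate every leading-strand G_nT motif.

    Summary counts report motifs with forecast fold change above
    ``fold_threshold`` and the genes carrying at least one above-threshold
    motif whose T->G substitution is nonsynonymous (missense or
    stop-affecting). Motifs whose key is absent from the table are reported
    with a missing fold (and collected in ``missing_keys``), never defaulted.
    """
    cds_list = list(cds_list)
    motifs = scan_gnt(genome, model, n_min=n_min, n_max=n_max, leading_only=True, scheme=scheme)
    rows = []
    missing: list[ContextKey] = []
    genes_nonsyn: set[str] = set()
    n_above = 0
    for m in motifs:
        fold = predict_fold(table, m.key)
        if fold is None:
            missing.append(m.key)
        effects = coding_effect(m.t_pos, m.strand, cds_list, genome)
        above = fold is not None and fold > fold_threshold
        if above:
            n_above += 1
            for eff in effects:
                if eff.effect in _NONSYN and eff.gene_id is not None:
                    genes_nonsyn.add(eff.gene_id)
        ref, alt = m.ref_alt_plus
        rows.append(
            {
                "pos": m.t_pos + 1,
                "strand": m.strand,
                "n": m.n,
                "five_prime_dinuc": m.five_prime_dinuc,
                "three_prime_1": m.three_prime_1,
                "three_prime_2": m.three_prime_2,
                "motif_string": m.motif_string,
                "ref": ref,
                "alt": alt,
                "fold_change": fold,
                "above_threshold": above,
                "effects": ",".join(
                    e.effect if e.gene_id is None else f"{e.gene_id}:{e.effect}"
                    for e in effects
                ),
            }
        )
    if missing:
        uniq = sorted({str(k) for k in missing})
        warnings.warn(
            f"{len(missing)} motifs had no rate-table entry "
            f"({len(uniq)} distinct keys): {', '.join(uniq[:10])}"
            + ("..." if len(uniq) > 10 else ""),
            stacklevel=2,
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pos", "strand", "n", "five_prime_dinuc", "three_prime_1",
            "three_prime_2", "motif_string", "ref", "alt", "fold_change",
            "above_threshold", "effects",
        ],
    )
    return ForecastReport(
        motifs=df,
        fold_threshold=fold_threshold,
        n_motifs=len(motifs),
        n_above_threshold=n_above,
        genes_nonsynonymous_above=genes_nonsyn,
        missing_keys=missing,
    )
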