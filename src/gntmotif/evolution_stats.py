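"""Statistics for hotspot-potency experiments.

An evolution experiment scores, per independent replicate, whether motility
was restored via the focal hotspot T->G mutation or via some other mutation,
and on which day the motile phenotype emerged (censored as "9+" beyond the
monitoring horizon). The analyses here are the ones those data call for:

* exact 2x2 comparisons of hotspot potency (Fisher's test; fold changes as
  conditional-MLE odds ratios with exact CIs),
* ordinary least squares of hotspot potency on G-tract length,
* Spearman rank correlation between rate estimates from different datasets
  (exact permutation p at small n),
* a censored-geometric waiting-time fit giving a mean emergence day and the
  proportion of sequenced replicates mutated at the focal locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

__all__ = [
    "PotencyCount",
    "EvolutionOutcome",
    "FisherResult",
    "fisher_exact_2x2",
    "potency_fold_changes",
    "tract_length_regression",
    "SpearmanResult",
    "spearman_rho",
    "EmergenceSummary",
    "emergence_summary",
    "read_outcomes_tsv",
    "write_outcomes_tsv",
]

FOCAL = "focal_gene"
OTHER = "other"


@dataclass(frozen=True)
class PotencyCount:
    """Replicate counts for one motif variant: hotspot vs other routes to
    the selected phenotype."""

    label: str
    hotspot_hits: int
    other_hits: int

    def __post_init__(self) -> None:
        if self.hotspot_hits < 0 or self.other_hits < 0:
            raise ValueError("counts must be non-negative")
        if self.hotspot_hits + self.other_hits == 0:
            raise ValueError(f"variant {self.label!r} has zero total replicates")

    @property
    def total(self) -> int:
        return self.hotspot_hits + self.other_hits

    @property
    def proportion(self) -> float:
        return self.hotspot_hits / self.total


@dataclass(frozen=True)
class EvolutionOutcome:
    """One replicate: emergence day (None = censored beyond the horizon,
    i.e. "9+" for an 8-day experiment) and, for sequenced replicates, the
    mutated locus."""

    replicate_id: str
    emergence_day: Optional[int]
    locus: Optional[str] = None

    @property
    def censored(self) -> bool:
        return self.emergence_day is None


class FisherResult(NamedTuple):
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, confidence: float = 0.95
) -> FisherResult:
    """Fisher's exact test on [[a, b], [c, d]].

    Two-sided p sums all hypergeometric outcomes no more probable than the
    observed one; the odds ratio is the conditional maximum-likelihood
    estimate with its exact conditional CI.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("cell counts must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("degenerate margin: every row and column sum must be > 0")
    table = [[a, b], [c, d]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    res = _scipy_odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=confidence)
    return FisherResult(p_value=float(p), odds_ratio=float(res.statistic),
                        ci_low=float(ci.low), ci_high=float(ci.high))


def potency_fold_changes(
    counts: Sequence[PotencyCount],
    reference_label: str,
    confidence: float = 0.95,
) -> dict[str, FisherResult]:
    """Fold change in hotspot potency of each variant relative to a
    reference variant, as conditional-MLE odds ratios with exact CIs.

    The reference maps to an odds ratio of exactly 1.
    """
    by_label = {c.label: c for c in counts}
    if reference_label not in by_label:
        raise ValueError(f"reference {reference_label!r} not among counts")
    ref = by_label[reference_label]
    out: dict[str, FisherResult] = {}
    for c in counts:
        if c.label == reference_label:
            out[c.label] = FisherResult(1.0, 1.0, 1.0, 1.0)
            continue
        out[c.label] = fisher_exact_2x2(
            c.hotspot_hits, c.other_hits, ref.hotspot_hits, ref.other_hits,
            confidence=confidence,
        )
    return out


def tract_length_regression(
    groups: Sequence[tuple[int, int, int]]
) -> tuple[float, float, float]:
    """OLS of hotspot-hit proportion on G-tract length.

    ``groups`` are (n, hits, total) tuples — one per variant or per pooled
    tract-length group, as the caller prefers. Returns (slope, intercept,
    r_squared). Requires >= 2 distinct tract lengths.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    xs, ys = [], []
    for n, hits, total in groups:
        if total <= 0 or not 0 <= hits <= total:
            raise ValueError(f"bad group (n={n}, hits={hits}, total={total})")
        xs.append(float(n))
        ys.append(hits / total)
    if len(set(xs)) < 2:
        raise ValueError("slope undefined: need >= 2 distinct tract lengths")
    res = stats.linregress(xs, ys)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    exact: bool


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def spearman_rho(x: Sequence[float], y: Sequence[float], exact_max_n: int = 8) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p is exact — enumerated over all rank permutations — for
    n <= ``exact_max_n``, and the usual t-approximation above (flagged by
    ``exact=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        tol = 1e-12
        hits = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_corr(rx, np.asarray(perm))) >= abs(rho) - tol:
                hits += 1
        return SpearmanResult(rho=rho, p_value=hits / total, exact=True)
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho=rho, p_value=min(1.0, p), exact=False)


@dataclass(frozen=True)
class EmergenceSummary:
    """Censored-geometric fit of emergence times plus the focal-locus
    proportion among sequenced (uncensored) replicates."""

    daily_hazard: float
    mean_emergence_day: float
    locus_proportion: Optional[float]
    n_total: int
    n_censored: int


def emergence_summary(
    outcomes: Sequence[EvolutionOutcome], horizon: int
) -> EmergenceSummary:
    """Fit a constant daily emergence hazard by maximum likelihood.

    Uncensored replicates emerging on day d contribute a geometric term
    (1-h)^(d-1) h; replicates censored at the horizon contribute the
    survival term (1-h)^horizon. The MLE has the closed form
    h = n_uncensored / (sum of uncensored days + n_censored * horizon);
    the mean waiting time is 1/h. ``locus_proportion`` is the share of
    uncensored replicates with a known locus that mutated the focal gene
    (None when no loci are known).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not outcomes:
        raise ValueError("no outcomes")
    unc_days = []
    n_cens = 0
    focal = 0
    located = 0
    for o in outcomes:
        if o.censored:
            n_cens += 1
            continue
        if not 1 <= o.emergence_day <= horizon:
            raise ValueError(
                f"replicate {o.replicate_id}: emergence day {o.emergence_day} "
                f"outside 1..{horizon} (censor beyond the horizon)"
            )
        unc_days.append(o.emergence_day)
        if o.locus is not None:
            located += 1
            if o.locus == FOCAL:
                focal += 1
    if not unc_days:
        raise ValueError("all outcomes censored: hazard not estimable")
    hazard = len(unc_days) / (sum(unc_days) + n_cens * horizon)
    return EmergenceSummary(
        daily_hazard=hazard,
        mean_emergence_day=1.0 / hazard,
        locus_proportion=(focal / located) if located else None,
        n_total=len(outcomes),
        n_censored=n_cens,
    )


def write_outcomes_tsv(
    outcomes: Iterable[EvolutionOutcome], path: Union[str, Path], horizon: int
) -> None:
    with open(path, "w") as fh:
        fh.write("replicate_id\temergence_day\tlocus\n")
        for o in outcomes:
            day = f"{horizon + 1}+" if o.censored else str(o.emergence_day)
            fh.write(f"{o.replicate_id}\t{day}\t{o.locus or '.'}\n")


def read_outcomes_tsv(path: Union[str, Path]) -> list[EvolutionOutcome]:
    """Read outcomes; an emergence_day ending in '+' marks censoring."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for need in ("replicate_id", "emergence_day"):
            if need not in idx:
                raise ValueError(f"outcomes TSV missing column {need!r}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            day_s = f[idx["emergence_day"]]
            day = None if day_s.endswith("+") else int(day_s)
            locus = f[idx["locus"]] if "locus" in idx else "."
            out.append(
                EvolutionOutcome(
                    replicate_id=f[idx["replicate_id"]],
                    emergence_day=day,
                    locus=None if locus in (".", "") else locus,
                )
            )
    return out
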