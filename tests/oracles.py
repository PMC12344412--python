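"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation: regex/string scanning over explicit leading-strand arc
sequences, sliding-window censuses, full-translation protein diffs,
CDF bisection for Poisson bounds, and exhaustive hypergeometric enumeration
for 2x2 exact tests.
"""

from __future__ import annotations

import re

import numpy as np
from scipy.optimize import brentq
from scipy.stats import hypergeom, poisson

from gntmotif import Genome, ReplichoreModel, reverse_complement

# --- explicit leading-strand arc sequences ----------------------------------


def arc_leading_strings(genome: Genome, model: ReplichoreModel | None):
    """Each replichore arc as its explicit leading-strand 5'->3' string.

    Returns a list of (string, coord_map, strand) where coord_map[i] is the
    plus-strand genome coordinate of string position i.
    """
    seq = genome.sequence
    L = genome.length
    if model is None:
        return [(seq, list(range(L)), "+")]

    def circ_range(start, stop):
        i = start
        out = []
        while i != stop:
            out.append(i)
            i = (i + 1) % L
        return out

    fwd = circ_range(model.oriC, model.ter)  # '+' leading arc
    rev = circ_range(model.ter, model.oriC)  # '-' leading arc
    fwd_str = "".join(seq[i] for i in fwd)
    rev_plus = "".join(seq[i] for i in rev)
    rev_str = reverse_complement(rev_plus)
    rev_map = list(reversed(rev))  # string position i <-> genome coord
    return [(fwd_str, fwd, "+"), (rev_str, rev_map, "-")]


def regex_scan_oracle(
    genome: Genome,
    model: ReplichoreModel | None,
    n_min: int,
    n_max: int,
    include_plus_two: bool = True,
):
    """Set of (t_pos, strand, n, dinuc, tp1, tp2) found by regex over the
    explicit leading-strand arc strings."""
    down = 2 if include_plus_two else 1
    pat = re.compile(
        rf"(?=([ACGT][ACT])(G{{{n_min},{n_max}}})T([ACGT]{{{down}}}))"
    )
    found = set()
    for s, coord_map, strand in arc_leading_strings(genome, model):
        for m in pat.finditer(s):
            dinuc, gs, tail = m.group(1), m.group(2), m.group(3)
            # the G run must not extend past n_max: the char after the last G
            # is T by construction, and the char before the run is non-G via
            # [ACT]; regex backtracking could match a sub-run of a longer
            # tract only if preceded by G, excluded by the dinucleotide class
            i_t = m.start() + 2 + len(gs)
            tp1 = tail[0]
            tp2 = tail[1] if down == 2 else None
            found.add((coord_map[i_t], strand, len(gs), dinuc, tp1, tp2))
    return found


def census_oracle(
    genome: Genome, model: ReplichoreModel | None, include_plus_two: bool = False
):
    """Sliding-window census of leading-strand T sites over arc strings.

    Returns (key_counts, baseline) with keys as (dinuc, n, tp1, tp2) tuples.
    """
    down = 2 if include_plus_two else 1
    key_counts: dict[tuple, int] = {}
    baseline = 0
    for s, _coord_map, _strand in arc_leading_strings(genome, model):
        for i, ch in enumerate(s):
            if ch != "T":
                continue
            n = 0
            while i - n - 1 >= 0 and s[i - n - 1] == "G":
                n += 1
            tail = s[i + 1 : i + 1 + down]
            if len(tail) < down or "N" in tail:
                continue
            tp1 = tail[0]
            tp2 = tail[1] if down == 2 else None
            if n == 0:
                if i - 1 >= 0 and s[i - 1] not in "GN":
                    baseline += 1
                continue
            if i - n - 2 < 0:
                continue
            dinuc = s[i - n - 2 : i - n]
            if "N" in dinuc:
                continue
            key = (dinuc, n, tp1, tp2)
            key_counts[key] = key_counts.get(key, 0) + 1
    return key_counts, baseline


# --- coding effects ---------------------------------------------------------

_CODE11 = None


def _table11():
    global _CODE11
    if _CODE11 is None:
        from Bio.Data.CodonTable import unambiguous_dna_by_id

        tab = unambiguous_dna_by_id[11]
        code = dict(tab.forward_table)
        for stop in tab.stop_codons:
            code[stop] = "*"
        _CODE11 = code
    return _CODE11


def translation_diff_oracle(genome_seq: str, cds, pos: int, alt: str):
    """Translate the whole CDS before and after a plus-strand substitution
    and classify the protein difference."""
    code = _table11()
    mutant = genome_seq[:pos] + alt + genome_seq[pos + 1 :]

    def protein(seq):
        sub = seq[cds.start : cds.end]
        if cds.strand == "-":
            sub = reverse_complement(sub)
        sub = sub[cds.phase :]
        return "".join(code[sub[i : i + 3]] for i in range(0, len(sub) - len(sub) % 3, 3))

    p_ref = protein(genome_seq)
    p_alt = protein(mutant)
    assert len(p_ref) == len(p_alt)
    diffs = [(i, r, a) for i, (r, a) in enumerate(zip(p_ref, p_alt)) if r != a]
    if not diffs:
        return "synonymous", None
    assert len(diffs) == 1
    i, r, a = diffs[0]
    if r == "*" and a != "*":
        return "stop_lost", i
    if r != "*" and a == "*":
        return "stop_gained", i
    return "missense", i


# --- Poisson CI by CDF bisection --------------------------------------------


def poisson_ci_bisection(count: int, confidence: float = 0.95):
    """Central Poisson interval found by root-finding on the tail equations."""
    alpha = 1.0 - confidence
    if count == 0:
        lo = 0.0
    else:
        # P(X >= count | mean=lo) = alpha/2
        f = lambda mu: poisson.sf(count - 1, mu) - alpha / 2.0
        lo = brentq(f, 1e-12, max(10.0, 10.0 * count), xtol=1e-12, rtol=1e-14)
    # P(X <= count | mean=hi) = alpha/2
    g = lambda mu: poisson.cdf(count, mu) - alpha / 2.0
    hi = brentq(g, 1e-12, max(20.0, 10.0 * count + 20.0), xtol=1e-12, rtol=1e-14)
    return lo, hi


# --- exact 2x2 enumeration --------------------------------------------------


def fisher_enumeration_oracle(a: int, b: int, c: int, d: int):
    """Two-sided p (probability-ordering rule) and conditional-MLE odds
    ratio by exhaustive enumeration of the conditional distribution."""
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - N)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, col1, row1)
    p_obs = hypergeom.pmf(a, N, col1, row1)
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-10)].sum())

    # conditional MLE of the odds ratio: solve E_psi[X] = a over the
    # noncentral hypergeometric family
    if a == lo:
        or_cmle = 0.0
    elif a == hi:
        or_cmle = np.inf
    else:
        log_binoms = (
            np.log([float(_comb(row1, k)) for k in support])
            + np.log([float(_comb(N - row1, col1 - k)) for k in support])
        )

        def mean_minus_a(log_psi):
            w = log_binoms + support * log_psi
            w -= w.max()
            w = np.exp(w)
            return float((support * w).sum() / w.sum()) - a

        or_cmle = np.exp(brentq(mean_minus_a, -50, 50, xtol=1e-13))
    return min(1.0, p_two), or_cmle


def _comb(n, k):
    import math

    return math.comb(n, k)


# --- censored-geometric likelihood grid -------------------------------------


def hazard_grid_oracle(unc_days, n_censored: int, horizon: int, grid_size: int = 200001):
    """Grid-search MLE of the daily hazard for day-censored waiting times."""
    hs = np.linspace(1e-9, 1 - 1e-9, grid_size)
    n_unc = len(unc_days)
    loglik = (
        n_unc * np.log(hs)
        + (sum(d - 1 for d in unc_days)) * np.log1p(-hs)
        + n_censored * horizon * np.log1p(-hs)
    )
    return float(hs[np.argmax(loglik)])
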