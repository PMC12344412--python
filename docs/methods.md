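# Methods

## The motif and its coordinate model

A `G_nT` motif is a *maximal* run of `n` guanines immediately followed by a
thymine, read 5′→3′ in leading-strand orientation; maximality means the
base 5′ of the run is not G, so every tract has exactly one motif and one
mutable T. The motif's context is keyed by `(5′ dinucleotide, n, +1 base,
optional +2 base)` — the components experimentally shown to modulate the
T→G rate. Keys never include N and a key's dinucleotide cannot end in G.

Coordinates are 0-based half-open internally and 1-based inclusive in all
file I/O. The replichore model takes *user-supplied* `oriC`/`ter`
coordinates (no GC-skew inference): the circular arc `[oriC, ter)` walked
in increasing-coordinate direction has the plus strand leading, the
complementary arc the minus strand; the boundary positions themselves
belong to the increasing-coordinate arc so the partition is deterministic.
Scanning, censusing and event classification all require a site's whole
context window to lie within one replichore arc and contain no N; a window
that crosses the oriC/ter boundary, contains an N, or runs off a linear
sequence end makes the site *undefined* and it is excluded everywhere
(scan, census and classification use the same rule, so numerators and
denominators always match).

**Baseline definition.** The baseline T→G rate is measured at T sites with
no immediately-preceding G (tract length 0). A baseline site only needs its
−1 base and its 3′ window (+1, plus +2 when the scheme resolves the +2
position) to be defined; keyed sites (n ≥ 1) need the full window including
the 5′ dinucleotide. Each T in a poly-T run is its own site.

## Forecasting

Rate tables map context keys to fold changes over the baseline. Lookup is
exact-key first (+2-resolved), then the +2-marginal entry, and otherwise an
explicit missing marker — never interpolation, because the motif components
interact non-additively (the effect of one flank is contingent on the
others). The packaged default table carries only fold changes published as
text (GA·G₄T·C = 1112 [1004–1185]; AC·G₄T·A = 5.6 [2.668–10.23];
TC·G₄T·G = 129; GA·G₄T·C with +2 = A/G → 360/2700); genome-wide forecasting
needs a full user-supplied table in the same TSV dialect. The forecast
report counts motifs above a fold threshold (default 100) and genes with at
least one above-threshold motif whose T→G substitution is nonsynonymous
(missense, stop_gained or stop_lost), translating with NCBI table 11;
start-codon special-casing is ignored (internal codons dominate in
practice) and multi-segment CDS are skipped.

## Estimation

For context *k* with `m_k` catalogued events over `s_k` census sites and a
baseline of `m_0` events over `s_0` sites,

    rate_k = (m_k / s_k) / (m_0 / s_0)

Events are mapped to leading orientation first (a plus-strand A→C inside a
minus-leading arc is a leading-orientation T→G); non-T→G events and events
at undefined sites are tallied and excluded. Event multiplicity is honoured:
the catalogue rows are inferred *independent mutation events*, so recurrent
hits at one site are real counts, not polymorphisms.

Confidence intervals treat `m_k` as Poisson and use the exact central
(Garwood) interval, `lo = χ²(α/2, 2m)/2`, `hi = χ²(1−α/2, 2m+2)/2`, scaled
by `1/(s_k · m_0/s_0)`. Baseline uncertainty is deliberately ignored: in
the intended use the baseline aggregates >10⁵ events, so its relative error
is negligible next to per-context Poisson noise. This is a documented
approximation — with a small baseline the intervals are anticonservative.
Keys with zero census sites are omitted (an event at such a key is an
error); keys with sites but no events report rate 0 with an exact upper
bound.

## Experiment statistics

* **Fisher 2×2**: two-sided p by the probability-ordering rule; the odds
  ratio is the conditional MLE of the noncentral hypergeometric parameter,
  with the exact conditional CI (scipy's implementations stand behind this
  surface; the test suite checks both against full enumeration).
* **Tract-length regression**: OLS of hotspot-hit proportion on tract
  length, on per-variant or pooled points as the caller supplies them.
* **Spearman**: average-rank rho; p is exact by enumeration of all rank
  permutations for n ≤ 8 (flagged `exact`), t-approximate above.
* **Emergence times**: daily monitoring with censoring at the horizon
  ("9+") is modelled as a censored geometric waiting time with constant
  daily hazard h; the MLE is closed-form,
  `h = n_unc / (Σ uncensored days + n_cens · horizon)`, and the reported
  mean emergence day is `1/h`. The estimator behind the original
  experiment's reported means is not specified beyond "a Poisson
  distribution", so this fit is the package's explicit model choice — the
  standard one for day-resolution monitoring — and exact agreement with
  externally reported means is not asserted anywhere.

## Synthetic data

The generators define the study conditions under which everything is
validated:

* **Genomes**: i.i.d. background with P(G)=P(C)=GC/2; planted motif strings
  written in a chosen replichore orientation, non-overlapping, with ground
  truth for each planted T. Background motifs arise by chance and are
  expected; ground truth covers planted ones only.
* **Mutation catalogues**: every leading-strand T site draws an independent
  Poisson count with mean `baseline_rate × fold(context)` (fold 1 at
  baseline sites; table lookups for keyed sites, a configurable
  `missing_fold`, default 1, elsewhere). This is exactly the sampling model
  the estimator assumes, which makes recovery tests clean. A
  distribution-identical aggregated sampler (one Poisson per context, by
  superposition) supports replicate-heavy calibration runs.
* **Evolution**: `daily_hazard` is the per-day emergence probability per
  unit of relative rate; target i contributes `h·r_i` and a replicate
  emerges each day with probability `1 − Π(1 − h·r_i)`, so adding a second
  hotspot accelerates emergence. The winner is drawn ∝ relative rate (one
  winner per replicate: the first motile zone is passaged, clonal
  interference is not modelled). Days beyond the horizon are censored.

What the simulators do **not** emulate: real base composition and repeat
structure, replication-distance rate gradients along the replichore,
lagging-strand mutagenesis, selection, and multi-genome weighted site
censuses. Passing recovery tests therefore demonstrates correctness of the
counting, orientation and interval machinery under the stated sampling
model, not fidelity of that model to any particular organism.

## Numerical and design choices

* Exposure for the recovery studies (200 kb genome, baseline rate 0.06 per
  site, planted-copy numbers chosen to put expected per-context counts at
  roughly 40–550 with a baseline expectation ≈ 2200) was fixed a priori in
  the regime where exact Poisson intervals attain near-nominal coverage;
  at small expected counts the Garwood interval is markedly conservative
  and no implementation could show ~95% empirical coverage.
* Garwood-oracle comparisons use CDF bisection (`brentq` at 1e-12) and
  agree to better than 1e-10 relative over counts up to 10⁴.
* Fisher p-values are compared to enumeration with an absolute 1e-9
  tolerance; conditional-MLE odds ratios at 1e-5 relative (the CMLE is a
  numeric root of `E_ψ[X] = a`; 0 and ∞ at the support edges).
* The Spearman exact/approximate cut-over at n = 8 keeps enumeration ≤
  40320 permutations.
* Ties in the replichore partition break by assigning `oriC` and `ter` to
  the increasing-coordinate arc.
* The scanner reports a motif only when its maximal tract length lies in
  `[n_min, n_max]`; a longer run is not re-segmented.

## Known limitations

* Single-chromosome replichore model; no plasmids, no multi-segment CDS,
  no start-codon translation rules.
* The forecaster is a lookup, not a fitted flank-effect model; contexts
  missing from the table stay missing.
* Baseline uncertainty excluded from estimator CIs (see above).
* Genome-scale reference counts (1924 motifs, ≥1238 genes) require external
  inputs (reference chromosome, deposited oriC/ter convention, full
  supplementary rate tables) that are not redistributable with the package.
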