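# Methods

## Problem and model

A 1D ¹H-NMR spectrum of a mixture is, to a good approximation, the sum
of its components' spectra. Identification therefore reduces to asking,
for each reference metabolite, how many of its characteristic peak
positions appear in the query. `nmrmatch` works entirely on peak
*coordinates* (chemical shift in ppm); peak heights are used only to
denoise the query and for display, never for scoring, because relative
intensities vary with concentration and acquisition conditions while
positions are far more stable.

All coordinates are canonicalized to 0.01 ppm — roughly the
reproducibility of peak positions across curated reference libraries —
using round-half-away-from-zero, chosen over banker's rounding so the
canonical coordinate of a value like 1.005 is the same on every platform
and the matching results are exactly reproducible. Internally a
canonical coordinate is the integer `round(ppm × 100)` ("centi-ppm"), so
exact equality and tolerance windows are integer arithmetic; a slack of
1e−9 on `tolerance × 100` keeps the inclusive window inclusive at its
float boundary (in binary, |2.01 − 2.00| slightly exceeds 0.01).

## Scoring

A candidate with `matched` of its `total` library peaks found in the
query scores

    f2:  score = matched / (total + 1)        (default)
    f1:  score = matched / total              (comparison baseline)

`f2` is a strictly increasing function of `matched` at fixed `total`,
bounded in [0, 1), and — its design point — strictly prefers the
peak-richer candidate among metabolites with equal matched fraction. At
self-query on a duplicate-free library this makes the true record the
unique top hit: any competitor matching `c ≤ min(T, t)` of its `T` peaks
against a `t`-peak query scores at most `min(T, t)/(T + 1) < t/(t + 1)`
unless its peak set is identical. `f1` ties every fully matched subset
at 1.0 and is retained only for head-to-head comparisons.

A metabolite is reported when it matches at least one query peak *and*
scores at least the confidence threshold `r` (inclusive ≥, default 0.5).
Thresholding happens at full precision; the two-decimal rounding seen in
output tables is display-only.

## Search strategies

* **MH1** scores every record passing the metadata filter at zero
  tolerance and reports those above threshold, ranked by descending
  score.
* **MH2** is MH1 with an inclusive matching window [q − τ, q + τ] around
  each library peak q. Each library peak counts at most once no matter
  how many query peaks fall inside its window, which keeps
  `matched ≤ total` and the score well-defined. With τ = 0 the code path
  is shared with MH1, so the two are bit-identical by construction.
* **MH3** greedily emits the current best candidate (ties: larger total
  peak count, then lexicographic id) and removes the query coordinates
  it matched before re-scoring the rest. The loop stops when the best
  remaining candidate scores below `r` or matches nothing — a guard that
  terminates cleanly on residual noise peaks no candidate can claim —
  or when query peaks, candidates, or the output cap run out. Removal
  can only lower later scores, so MH3's emitted set is always a subset
  of MH1's at equal τ and `r`, and the matched coordinate sets of its
  output are pairwise disjoint. With τ > 0, removal consumes every query
  peak inside each matched window; this mode is experimental and is
  gated behind an explicit opt-in flag.

Ranking ties (equal full-precision score) in MH1/MH2 are broken by more
matched peaks, then lexicographic id — a deterministic convention chosen
by this package.

## Query preparation

Full spectra (two-column ppm/intensity ASCII, either axis direction) are
denoised by dropping points with intensity below the user threshold η
(inclusive: points at exactly η survive) and reduced to peaks as the
local maxima of the surviving intensity sequence; a plateau of equal
maximal values yields one peak at the plateau's central ppm. This is the
simplest deterministic rule consistent with threshold-based peak
identification; no baseline correction, apodization or phasing is
attempted — inputs are assumed processed. Externally picked peak lists
are canonicalized and de-duplicated (larger height kept).

## Synthetic data

The generator emulates the structural features of curated ¹H libraries
that drive search behaviour, not any specific database's content:

* `generate_library(k, peak_count_range, ppm_range, overlap_rate, seed)`
  draws per-record peak counts uniformly in `peak_count_range` (defaults
  to (1, 66), the count range of the smaller of the two widely used
  curated libraries; the larger spans 1–181) and places each peak, with
  probability `overlap_rate`, on a coordinate already used by an earlier
  record — reproducing the cross-metabolite peak sharing real libraries
  show — otherwise on a fresh grid point. `overlap_rate = 0` yields
  pairwise disjoint records, the regime where every method is provably
  exact. Default `overlap_rate = 0.25` gives visible sharing without
  exhausting the 0.01 ppm grid. Heights are uniform in [1, 100];
  metadata fields are drawn uniformly from their legal values.
* `make_mixture` pools n records sampled uniformly without replacement;
  the pooled peak list is the canonical union.
* `apply_noise` implements two noise channels: uniform random removal of
  `floor(fraction × count)` peaks with fraction ≤ 0.5 (floor guarantees
  at least one peak survives, keeping records searchable), then a
  ±magnitude ppm shift per surviving peak with an independent random
  sign, magnitude ∈ {0.01, …, 0.05}. The per-peak independent sign is a
  choice — a per-metabolite sign would model field-calibration offsets
  instead — and is the harsher condition for tolerance search.
* `render_spectrum` sums Lorentzian lines (the natural NMR lineshape; no
  result here depends on the choice) with optional Gaussian baseline
  noise, for exercising the peak picker end to end.

What the synthetic model does *not* capture: J-coupling multiplets,
pH-dependent shift drift, baseline and phase artefacts, solvent peaks,
and the strongly non-uniform coordinate density of real libraries.
Passing benchmarks therefore demonstrates the correctness and direction
of the machinery (equivalences, exclusivity, monotone degradation,
tolerance recovery), not absolute identification rates on real data.

## Evaluation

Against a known mixture, keeping the first N ranked predictions gives a
confusion matrix with `tn = k − tp − fp − fn` (k = library size;
cut-offs beyond the ranking length use the ranking length). Sensitivity,
specificity and accuracy follow the usual definitions, with 0/0 reported
as undefined rather than raised. Sweeping N = 1…max traces a ROC curve
(false-positive rate vs sensitivity); the area is the trapezoidal
integral anchored at (0, 0) and extended horizontally to (1, last
sensitivity), and the optimal cut-off is the accuracy argmax with ties
resolved to the smallest N. Rank metrics report the percentage of truth
members within a cap (default 100) and their average rank; when none is
identified the average rank is reported as the cap — the pessimistic
convention for an empty hit list.

Two experiment drivers:

* `recovery_experiment`: per mixture size n, pool random mixtures and
  report the mean percentage of members found anywhere in the output
  (`pct_all`) and within the first n ranks (`pct_topn`). Searches run at
  `r = 0` by default so "anywhere" means any rank; raising
  `score_threshold` switches to the stricter above-threshold notion.
* `noise_experiment`: per noise condition, either noise-and-search every
  record individually (`single` mode) or noise members before pooling
  (`pooled` mode, default pool of 50), counting a metabolite as
  identified within the first `within_first` (default 50) results.
  When MH2 is among the methods its tolerance is set to the condition's
  shift magnitude — the regime the window is designed for.
  `couple_levels=True` applies common random numbers across the
  conditions of one sweep (nested removal sets, shared shift signs),
  which sharpens paired comparisons along the sweep without changing any
  per-condition expectation; the default draws independently.

Experiment defaults are desk scale — libraries of ~100 records, tens of
runs per condition — chosen so the full benchmark suite runs in well
under a minute while keeping Monte-Carlo noise far from the effect sizes
being asserted.

## Numerical and degenerate-input conventions

* Empty query after denoising → error at search time; an empty peak list
  from picking is not itself an error (the downstream caller decides).
* Empty post-filter library → configuration error; `filter_records` may
  return an empty view to make that diagnosis possible.
* Duplicate coordinates within a record or query collapse to the taller
  peak, with a warning at parse time.
* MH1 rejects any nonzero tolerance at configuration time.
* The significance score rejects `matched > total` as a logic error
  rather than clamping.

## Known limitations

* Coordinate-only matching cannot distinguish co-resonant metabolites;
  on heavily overlapping libraries MH3's exclusivity deliberately
  sacrifices such metabolites (false negatives) for precision.
* The 0.01 ppm grid makes tolerance meaningful only in multiples of
  0.005 and the shift-noise model only at grid magnitudes.
* No concentration estimation or residual re-fitting: once a peak is
  assigned, its intensity is not decomposed among co-located candidates.
* The peak picker is a threshold/local-maximum rule; shoulders of
  unresolved multiplets below the threshold are lost by design.
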