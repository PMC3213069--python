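"""Benchmark machinery: confusion statistics, ROC/AUC, recovery and rank
metrics, and the experiment drivers that exercise the search methods on
synthetic libraries.

The evaluation unit is a ranked result list against a known mixture.  A
cut-off N keeps the first N predictions; counting hits and misses at
that cut-off against the library of k candidates gives a confusion
matrix, and sweeping N traces a ROC curve whose area summarizes ranking
quality independently of any single cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .library import ReferenceLibrary
from .matching import SearchConfig, search
from .spectra import PeakList
from .synthetic import (
    SHIFT_MAGNITUDES,
    MixtureTruth,
    NoiseSpec,
    apply_noise,
    make_mixture,
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts at one cut-off against a library of ``library_size`` candidates.

    True negatives are defined by difference: tn = k − tp − fp − fn, so
    the four cells always sum to the library size.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    library_size: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.tp + self.fp + self.fn + self.tn != self.library_size:
            raise ValidationError("confusion cells must sum to the library size")


@dataclass(frozen=True)
class EvalStats:
    """Sensitivity, specificity and accuracy; ``None`` marks a statistic
    whose denominator is zero (undefined, not an error)."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


@dataclass(frozen=True)
class RocCurve:
    """ROC points (false-positive rate, sensitivity) over cut-offs 1…N."""

    cutoffs: tuple[int, ...]
    points: tuple[tuple[float, float], ...]
    accuracies: tuple[float, ...]
    auc: float
    optimal_cutoff: int
    best_accuracy: float


def confusion_at_cutoff(
    ranked: Sequence[str], truth: MixtureTruth | Iterable[str], cutoff: int, k: int
) -> ConfusionMatrix:
    """Confusion matrix when the first *cutoff* predictions are kept.

    If the ranking is shorter than the cut-off, the effective cut-off is
    the ranking length.
    """
    if cutoff < 1:
        raise ConfigurationError(f"cutoff must be >= 1, got {cutoff}")
    truth_ids = set(truth.member_ids if isinstance(truth, MixtureTruth) else truth)
    top = list(ranked[:cutoff])
    tp = sum(1 for mid in top if mid in truth_ids)
    fp = len(top) - tp
    fn = len(truth_ids) - tp
    tn = k - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, library_size=k)


def stats(cm: ConfusionMatrix) -> EvalStats:
    """sensitivity = tp/(tp+fn); specificity = tn/(tn+fp); accuracy = (tp+tn)/k."""
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    acc = (cm.tp + cm.tn) / cm.library_size if cm.library_size > 0 else None
    return EvalStats(sensitivity=sens, specificity=spec, accuracy=acc)


def roc_and_auc(
    ranked: Sequence[str],
    truth: MixtureTruth | Iterable[str],
    k: int,
    max_cutoff: int | None = None,
) -> RocCurve:
    """ROC curve and area over cut-offs 1…max_cutoff.

    The curve plots sensitivity against the false-positive rate
    (1 − specificity).  The area is the trapezoidal integral of the
    curve anchored at (0, 0) and extended horizontally to (1, last
    sensitivity).  The optimal cut-off is the accuracy argmax, smallest
    N on ties.
    """
    truth_ids = set(truth.member_ids if isinstance(truth, MixtureTruth) else truth)
    if not truth_ids:
        raise ValidationError("empty truth: AUC is undefined")
    if max_cutoff is None:
        max_cutoff = max(1, len(ranked))
    if max_cutoff < 1:
        raise ConfigurationError(f"max_cutoff must be >= 1, got {max_cutoff}")

    cutoffs, points, accs = [], [], []
    for n in range(1, max_cutoff + 1):
        cm = confusion_at_cutoff(ranked, truth_ids, n, k)
        st = stats(cm)
        sens = st.sensitivity  # defined: truth is non-empty
        # fp + tn = k - |truth|; if the truth covers the whole library the
        # false-positive rate is vacuously 0.
        fpr = 1.0 - st.specificity if st.specificity is not None else 0.0
        cutoffs.append(n)
        points.append((fpr, sens))
        accs.append(st.accuracy)

    xs = np.array([0.0] + [p[0] for p in points] + [1.0])
    ys = np.array([0.0] + [p[1] for p in points] + [points[-1][1]])
    auc = float(np.trapezoid(ys, xs))
    best_i = int(np.argmax(accs))  # argmax returns the first (smallest N) tie
    return RocCurve(
        cutoffs=tuple(cutoffs),
        points=tuple(points),
        accuracies=tuple(accs),
        auc=auc,
        optimal_cutoff=cutoffs[best_i],
        best_accuracy=accs[best_i],
    )


def rank_metrics(
    ranked: Sequence[str], truth: MixtureTruth | Iterable[str], cap: int = 100
) -> tuple[float, float]:
    """Percent of truth members within the top *cap* results, and their
    average rank.

    When no member is identified the average rank is reported as *cap*
    (the pessimistic convention for an empty hit list).
    """
    if cap < 1:
        raise ConfigurationError(f"cap must be >= 1, got {cap}")
    truth_ids = set(truth.member_ids if isinstance(truth, MixtureTruth) else truth)
    if not truth_ids:
        raise ValidationError("empty truth: rank metrics are undefined")
    hit_ranks = [i for i, mid in enumerate(ranked[:cap], start=1) if mid in truth_ids]
    pct = 100.0 * len(hit_ranks) / len(truth_ids)
    avg_rank = float(np.mean(hit_ranks)) if hit_ranks else float(cap)
    return pct, avg_rank


# ---------------------------------------------------------------------------
# Experiment drivers (desk scale by default: k ≈ 100 records, tens of runs)
# ---------------------------------------------------------------------------


def _child_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def recovery_experiment(
    lib: ReferenceLibrary,
    n_range: Iterable[int] = range(1, 11),
    runs: int = 25,
    methods: Sequence[str] = ("MH1", "MH3"),
    seed: int | None = None,
    score_threshold: float = 0.0,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Mean percent of mixture members recovered, by mixture size and method.

    For each n in *n_range*, *runs* random n-member mixtures are pooled
    (no noise) and searched.  Two recovery notions are reported per
    method: ``pct_all`` counts a member found anywhere in the emitted
    list, ``pct_topn`` only within the first n ranks.  With the default
    ``score_threshold=0`` "anywhere" means at any rank; raise it to
    require the confidence threshold as well.
    """
    if runs < 1:
        raise ConfigurationError(f"runs must be >= 1, got {runs}")
    n_range = list(n_range)
    rows = []
    seeds = _child_seeds(seed, len(n_range) * runs)
    si = 0
    for n in n_range:
        hits_all = {m: 0 for m in methods}
        hits_top = {m: 0 for m in methods}
        for _ in range(runs):
            mixture = make_mixture(lib, n, seed=seeds[si])
            si += 1
            sample = mixture.to_peaklist()
            for method in methods:
                cfg = SearchConfig(
                    method=method,
                    r=score_threshold,
                    tolerance=tolerance if method != "MH1" else 0.0,
                    max_results=len(lib),
                    allow_mh3_tolerance=True,
                )
                ids = [m.metabolite_id for m in search(sample, lib, cfg)]
                top = set(ids[:n])
                found = set(ids)
                hits_all[method] += sum(1 for mid in mixture.member_ids if mid in found)
                hits_top[method] += sum(1 for mid in mixture.member_ids if mid in top)
        denom = runs * n
        for method in methods:
            rows.append(
                {
                    "n": n,
                    "method": method,
                    "pct_all": 100.0 * hits_all[method] / denom,
                    "pct_topn": 100.0 * hits_top[method] / denom,
                    "runs": runs,
                }
            )
    return pd.DataFrame(rows, columns=["n", "method", "pct_all", "pct_topn", "runs"])


def removal_grid(fractions: Iterable[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)) -> list[NoiseSpec]:
    """Noise conditions sweeping peak removal at zero shift."""
    return [NoiseSpec(remove_fraction=f) for f in fractions]


def shift_grid(magnitudes: Iterable[float] = SHIFT_MAGNITUDES[1:]) -> list[NoiseSpec]:
    """Noise conditions sweeping shift perturbation with no removal."""
    return [NoiseSpec(shift_magnitude=m) for m in magnitudes]


def _noised_coupled(peaks, frac, magnitude, perm, signs):
    """Removal/shift with pre-drawn permutation and signs, so different
    noise levels of one sweep share randomness (common random numbers:
    removed sets are nested across fractions, signs are identical)."""
    n = len(peaks)
    n_remove = int(math.floor(frac * n))
    keep = sorted(perm[n_remove:])
    survivors = [peaks[i] for i in keep]
    kept_signs = [signs[i] for i in keep]
    if magnitude > 0:
        from .library import Peak, canonicalize_ppm

        survivors = [
            Peak(canonicalize_ppm(p.ppm + s * magnitude), p.height)
            for p, s in zip(survivors, kept_signs)
        ]
    from .library import dedupe_peaks

    return dedupe_peaks(survivors)


def noise_experiment(
    lib: ReferenceLibrary,
    noise_grid: Sequence[NoiseSpec],
    mode: str = "single",
    methods: Sequence[str] = ("MH1", "MH3"),
    runs: int = 5,
    pool_size: int = 50,
    within_first: int = 50,
    seed: int | None = None,
    couple_levels: bool = False,
) -> pd.DataFrame:
    """Mean percent of metabolites identified under each noise condition.

    Two modes:

    ``single``
        Every library record is noised and searched on its own, *runs*
        times; a record counts as identified when it appears within the
        first *within_first* results.  MH2, when requested, runs with its
        tolerance set to the condition's shift magnitude (the regime it
        was designed for).
    ``pooled``
        *runs* mixtures of *pool_size* members are built per condition;
        each member's peaks are noised before pooling, and a member
        counts as identified within the first *within_first* results.

    ``couple_levels=True`` re-uses one removal permutation and one sign
    vector per (record, repetition) across all grid conditions — common
    random numbers, which sharpens paired comparisons along a sweep
    without changing any per-condition expectation.
    """
    if mode not in ("single", "pooled"):
        raise ConfigurationError(f"mode must be 'single' or 'pooled', got {mode!r}")
    if runs < 1 or within_first < 1:
        raise ConfigurationError("runs and within_first must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []

    def _cfg(method, spec):
        return SearchConfig(
            method=method,
            r=0.0,
            tolerance=spec.shift_magnitude if method == "MH2" else 0.0,
            max_results=within_first,
        )

    if mode == "single":
        if couple_levels:
            # one permutation + sign vector per (record, rep), shared by levels
            draws = {}
            for rec in lib:
                for rep in range(runs):
                    perm = rng.permutation(rec.total)
                    signs = rng.choice((-1.0, 1.0), size=rec.total)
                    draws[(rec.id, rep)] = (perm, signs)
        for spec in noise_grid:
            hits = {m: 0 for m in methods}
            trials = 0
            for rec in lib:
                for rep in range(runs):
                    if couple_levels:
                        perm, signs = draws[(rec.id, rep)]
                        noised = _noised_coupled(
                            rec.peaks, spec.remove_fraction, spec.shift_magnitude, perm, signs
                        )
                    else:
                        noised = apply_noise(rec.peaks, spec, rng=rng)
                    sample = PeakList(noised)
                    trials += 1
                    for method in methods:
                        ids = [m.metabolite_id for m in search(sample, lib, _cfg(method, spec))]
                        hits[method] += rec.id in ids
            for method in methods:
                rows.append(
                    {
                        "remove_fraction": spec.remove_fraction,
                        "shift_magnitude": spec.shift_magnitude,
                        "mode": mode,
                        "method": method,
                        "pct_identified": 100.0 * hits[method] / trials,
                        "runs": runs,
                    }
                )
    else:  # pooled
        from .library import dedupe_peaks

        for spec in noise_grid:
            hits = {m: 0 for m in methods}
            trials = 0
            for _ in range(runs):
                mixture = make_mixture(lib, pool_size, seed=int(rng.integers(2**31 - 1)))
                pooled = []
                for mid in mixture.member_ids:
                    pooled.extend(apply_noise(lib.get(mid).peaks, spec, rng=rng))
                sample = PeakList(dedupe_peaks(pooled))
                trials += len(mixture.member_ids)
                for method in methods:
                    ids = set(
                        m.metabolite_id for m in search(sample, lib, _cfg(method, spec))
                    )
                    hits[method] += sum(1 for mid in mixture.member_ids if mid in ids)
            for method in methods:
                rows.append(
                    {
                        "remove_fraction": spec.remove_fraction,
                        "shift_magnitude": spec.shift_magnitude,
                        "mode": mode,
                        "method": method,
                        "pct_identified": 100.0 * hits[method] / trials,
                        "runs": runs,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "remove_fraction", "shift_magnitude", "mode", "method", "pct_identified", "runs",
        ],
    )


def plot_recovery(df: pd.DataFrame, ax=None):
    """Line plot of recovery vs mixture size (one line per method/metric)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, sub in df.groupby("method"):
        ax.plot(sub["n"], sub["pct_all"], marker="o", label=f"{method} ALL")
        ax.plot(sub["n"], sub["pct_topn"], marker="s", linestyle="--", label=f"{method} TOPN")
    ax.set_xlabel("metabolites in mixture (n)")
    ax.set_ylabel("% recovered")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax


def plot_noise(df: pd.DataFrame, x: str = "remove_fraction", ax=None):
    """Line plot of identification vs a noise axis (one line per method)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, sub in df.groupby("method"):
        ax.plot(sub[x], sub["pct_identified"], marker="o", label=method)
    ax.set_xlabel(x)
    ax.set_ylabel("% identified")
    ax.set_ylim(0, 105)
    ax.legend()
    return ax
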