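"""Diagnostic-performance and inter-reader agreement statistics.

Per-segment verdicts from CTA readings are compared against a catheter
angiography reference on a 2x2 table per stratum (the three anatomical
regions plus overall).  Segments not depicted by the reference or rated in
any non-assessable category are excluded before any statistic, and the
exclusions are accounted for explicitly.  Percentages are rounded half
away from zero to integer percent (one decimal for non-assessable
fractions), matching how such tables are conventionally printed.

Because segments cluster within patients, paired modality comparisons use
a seedable cluster bootstrap of the difference in proportions (patients
resampled with replacement); a GEE variant with robust variance is offered
for cross-checking, but the bootstrap is the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from mpcpr.errors import DataError, UsageError
from mpcpr.stenosis import VERDICT_SIGNIFICANT, is_na

OVERALL = "overall"
STAT_NAMES = ("sensitivity", "specificity", "accuracy", "ppv", "npv")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(num: int, den: int, decimals: int = 0) -> float | None:
    """Printed-style percentage, or None when not calculable (den == 0)."""
    if den == 0:
        return None
    p = 100.0 * num / den
    if decimals == 0:
        return float(round_half_away(p))
    f = 10.0 ** decimals
    return round_half_away(p * f) / f


@dataclass
class ConfusionCounts:
    """2x2 counts for one stratum, with explicit exclusion accounting."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    excluded_na: int = 0
    stratum: str = OVERALL

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def offered(self) -> int:
        return self.total + self.excluded_na


def tabulate(
    ratings: Mapping[Hashable, str],
    reference: Mapping[Hashable, bool | None],
    groups: Mapping[Hashable, str] | None = None,
) -> dict[str, ConfusionCounts]:
    """Cross-tabulate rated verdicts against the reference standard.

    ``ratings`` maps segment keys to verdicts (a sequence of ``(key,
    verdict)`` pairs is also accepted and checked for duplicate keys).
    ``reference`` maps each segment key to True (significant), False, or
    None (not depicted by the reference).  Segments absent from the
    reference, depicted as None, or rated in any ``na_*`` category are
    counted in ``excluded_na``.  Returns counts per region stratum plus
    ``"overall"``.
    """
    if not isinstance(ratings, Mapping):
        pairs = list(ratings)
        keys = [k for k, _ in pairs]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise DataError(f"duplicate segment key {dup!r} in ratings")
        ratings = dict(pairs)
    strata: dict[str, ConfusionCounts] = {OVERALL: ConfusionCounts(stratum=OVERALL)}
    if groups:
        for g in dict.fromkeys(groups.values()):
            strata[g] = ConfusionCounts(stratum=g)

    def targets(key):
        yield strata[OVERALL]
        if groups and key in groups:
            yield strata[groups[key]]

    for key, verdict in ratings.items():
        ref = reference.get(key, None)
        if ref is None or is_na(verdict):
            for c in targets(key):
                c.excluded_na += 1
            continue
        pos = verdict == VERDICT_SIGNIFICANT
        for c in targets(key):
            if pos and ref:
                c.tp += 1
            elif pos and not ref:
                c.fp += 1
            elif not pos and ref:
                c.fn += 1
            else:
                c.tn += 1
    return strata


def perf_stats(c: ConfusionCounts) -> dict[str, tuple[float | None, int, int]]:
    """The five statistics as (integer percent, numerator, denominator).

    A zero denominator yields a ``None`` percent (not calculable), never a
    division failure.
    """
    pairs = {
        "sensitivity": (c.tp, c.tp + c.fn),
        "specificity": (c.tn, c.tn + c.fp),
        "accuracy": (c.tp + c.tn, c.total),
        "ppv": (c.tp, c.tp + c.fp),
        "npv": (c.tn, c.tn + c.fn),
    }
    return {k: (percent(n, d), n, d) for k, (n, d) in pairs.items()}


def perf_table(counts: Mapping[str, ConfusionCounts]) -> pd.DataFrame:
    """Long-format diagnostic-performance table across strata."""
    rows = []
    for stratum, c in counts.items():
        for stat, (p, n, d) in perf_stats(c).items():
            rows.append({"stratum": stratum, "statistic": stat,
                         "percent": p, "numerator": n, "denominator": d,
                         "excluded_na": c.excluded_na})
    return pd.DataFrame(rows)


def agreement(
    r1: Mapping[Hashable, str],
    r2: Mapping[Hashable, str],
) -> tuple[float | None, int, int]:
    """Absolute inter-reader agreement as (percent, numerator, denominator).

    Segments either reader rated non-assessable are excluded, so the
    denominator generally differs between readers/modalities.
    """
    keys = [k for k in r1 if k in r2 and not is_na(r1[k]) and not is_na(r2[k])]
    den = len(keys)
    num = sum(1 for k in keys if r1[k] == r2[k])
    return percent(num, den), num, den


# ---------------------------------------------------------------------------
# clustered paired comparison
# ---------------------------------------------------------------------------

def compare_clustered(
    outcomes_a: Sequence[int],
    outcomes_b: Sequence[int],
    clusters: Sequence[Hashable],
    reps: int = 10000,
    seed: int | None = None,
    method: str = "bootstrap",
) -> float:
    """Two-sided p-value for a paired difference in clustered proportions.

    ``outcomes_a``/``outcomes_b`` are per-segment 0/1 correctness
    indicators of the two modalities on the same segments; ``clusters``
    are patient identifiers.  The contract implementation resamples
    patients with replacement and reports the two-sided bootstrap tail
    probability of the difference in proportions; ``method="gee"`` fits a
    GEE with exchangeable working correlation and robust variance instead.
    """
    a = np.asarray(outcomes_a, dtype=float)
    b = np.asarray(outcomes_b, dtype=float)
    cl = np.asarray(clusters)
    if not (len(a) == len(b) == len(cl)):
        raise UsageError("outcomes_a, outcomes_b and clusters must have equal length")
    uniq, inv = np.unique(cl, return_inverse=True)
    if len(uniq) < 2:
        raise UsageError("need at least 2 clusters (no between-cluster variance)")
    if method == "gee":
        return _compare_gee(a, b, inv)
    if method != "bootstrap":
        raise UsageError(f"unknown method {method!r}")
    k = len(uniq)
    n_i = np.bincount(inv, minlength=k).astype(float)
    diff_i = np.bincount(inv, weights=a - b, minlength=k)
    # canonical cluster order: the p-value depends only on the multiset of
    # per-cluster summaries, not on how patients happen to be labelled
    order = np.lexsort((diff_i, n_i))
    n_i, diff_i = n_i[order], diff_i[order]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, k, size=(reps, k))
    boot = diff_i[idx].sum(axis=1) / n_i[idx].sum(axis=1)
    p_lo = float(np.mean(boot <= 0.0))
    p_hi = float(np.mean(boot >= 0.0))
    return min(1.0, 2.0 * min(p_lo, p_hi))


def _compare_gee(a: np.ndarray, b: np.ndarray, inv: np.ndarray) -> float:
    import statsmodels.api as sm

    y = np.concatenate([a, b])
    modality = np.concatenate([np.ones_like(a), np.zeros_like(b)])
    groups = np.concatenate([inv, inv])
    X = sm.add_constant(modality)
    model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit()
    return float(res.pvalues[1])


# ---------------------------------------------------------------------------
# published reader-study regression fixtures
# ---------------------------------------------------------------------------

def load_reader_study_tables() -> dict[str, pd.DataFrame]:
    """Published two-reader peripheral-CTA reader-study tables.

    Returns the diagnostic-performance cells (``"performance"``: region x
    reader x modality x statistic with printed percent and
    numerator/denominator), the inter-reader agreement cells
    (``"agreement"``) and the non-assessable segment fractions
    (``"nonassessable"``).  Cells whose printed percent is inconsistent
    with their own printed count pair are flagged ``discrepant``.
    """
    out = {}
    for key, fname in (
        ("performance", "reader_study_performance.csv"),
        ("agreement", "reader_study_agreement.csv"),
        ("nonassessable", "reader_study_nonassessable.csv"),
    ):
        with resources.files("mpcpr.data").joinpath(fname).open() as fh:
            out[key] = pd.read_csv(fh)
    return out


def counts_from_sens_spec(sens_num: int, sens_den: int,
                          spec_num: int, spec_den: int,
                          stratum: str = OVERALL) -> ConfusionCounts:
    """Reconstruct a 2x2 from printed sensitivity and specificity pairs."""
    return ConfusionCounts(
        tp=sens_num, fn=sens_den - sens_num,
        tn=spec_num, fp=spec_den - spec_num,
        stratum=stratum,
    )
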