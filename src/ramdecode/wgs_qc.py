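"""WGS dataset validation metrics.

Quality control of whole-genome-sequence genotypes against independently
derived truth sets: genotype call rate under a minimum read-depth rule,
accuracy against consensus reference-SNP genotypes (with a >97% per-animal
pass gate), per-animal concordance against bead-array genotypes, a
through-origin regression of mean read depth on the amount of sequence
collected, and read-depth distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "call_rate",
    "genotype_accuracy",
    "concordance_by_animal",
    "depth_regression",
    "depth_histogram",
    "ACCURACY_GATE_PCT",
]

#: Per-animal accuracy must strictly exceed this percentage to pass.
ACCURACY_GATE_PCT = 97.0


class UndefinedRateError(ValueError):
    """A rate was requested over zero comparable items."""


def call_rate(depths=None, calls=None, min_depth: int = 3) -> float:
    """Fraction of attempted genotype sites that were scored.

    A site is scored iff its read depth is at least ``min_depth``; when
    depths are unavailable, iff its call is non-missing.  Either ``depths``
    (array-like of per-site read depths, NaN allowed meaning zero) or
    ``calls`` (array-like where None/NaN is missing) must be given.
    """
    if depths is not None:
        d = np.asarray(pd.Series(list(depths), dtype=float))
        if d.size == 0:
            raise UndefinedRateError("no sites attempted")
        scored = np.count_nonzero(np.nan_to_num(d, nan=0.0) >= min_depth)
        return scored / d.size
    if calls is not None:
        c = list(calls)
        if not c:
            raise UndefinedRateError("no sites attempted")
        scored = sum(1 for x in c
                     if x is not None and not (isinstance(x, float) and np.isnan(x)))
        return scored / len(c)
    raise ValueError("either depths or calls required")


def _is_full_call(g) -> bool:
    """True for a complete genotype call (no missing allele)."""
    if g is None or (isinstance(g, float) and np.isnan(g)):
        return False
    if isinstance(g, (tuple, list)):
        return all(a is not None and a not in (".", "") for a in g)
    return True


def _normalise(g):
    if isinstance(g, (tuple, list)):
        return tuple(sorted(str(a).lower() for a in g))
    return (str(g).lower(),)


def genotype_accuracy(test: Mapping, truth: Mapping) -> tuple[int, int, float]:
    """Compare test genotypes to truth genotypes over shared keys.

    Both arguments map (animal, site) -> genotype, where a genotype is an
    unordered allele tuple (A/B == B/A).  Cells missing (or half-missing) in
    either table are excluded.  Returns (errors, compared, percent) with
    percent = 100 * (1 - errors / compared).
    """
    shared = set(test) & set(truth)
    errors = compared = 0
    for key in shared:
        a, b = test[key], truth[key]
        if not (_is_full_call(a) and _is_full_call(b)):
            continue
        compared += 1
        if _normalise(a) != _normalise(b):
            errors += 1
    if compared == 0:
        raise UndefinedRateError("zero comparable genotype cells")
    return errors, compared, 100.0 * (1.0 - errors / compared)


def concordance_by_animal(
    test: Mapping, truth: Mapping,
    pooling: str = "animal",
) -> tuple[pd.Series, float]:
    """Per-animal genotype concordance plus a pooled figure.

    Keys are (animal, site) pairs.  The pooled percentage is the unweighted
    mean of per-animal concordances (``pooling='animal'``), or the per-site
    pooled fraction over all cells (``pooling='site'``).
    """
    shared = set(test) & set(truth)
    per_animal: dict[str, list[int]] = {}
    for key in shared:
        a, b = test[key], truth[key]
        if not (_is_full_call(a) and _is_full_call(b)):
            continue
        per_animal.setdefault(key[0], []).append(
            int(_normalise(a) == _normalise(b)))
    if not per_animal:
        raise UndefinedRateError("no overlapping scored cells")
    series = pd.Series(
        {animal: 100.0 * float(np.mean(v)) for animal, v in per_animal.items()}
    ).sort_index()
    if pooling == "animal":
        pooled = float(series.mean())
    elif pooling == "site":
        total = sum(len(v) for v in per_animal.values())
        hits = sum(sum(v) for v in per_animal.values())
        pooled = 100.0 * hits / total
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return series, pooled


def depth_regression(pairs: Sequence[tuple[float, float]]) -> dict:
    """Least-squares proportional fit of mean depth on data volume.

    ``pairs`` are (GB collected, mean read depth) per animal.  The intercept
    is fixed at zero (depth is directly proportional to yield); returns the
    slope, its standard error, and the uncentred R².
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("at least two (GB, depth) pairs required")
    x, y = arr[:, 0], arr[:, 1]
    if np.all(x == 0):
        raise ValueError("all data volumes are zero")
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    n = len(x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum(y ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    se = float(np.sqrt(ss_res / (n - 1) / sxx)) if n > 1 else float("nan")
    return {"slope": slope, "se": se, "r_squared": r2, "n": n}


def depth_histogram(depths: pd.DataFrame, bins: int = 40) -> dict:
    """Distribution summary of read depths.

    ``depths`` is an animals × sites frame.  Summary statistics (mean, min,
    max, SD) are computed over per-animal mean depths — matching how panel
    coverage is reported — while the mode is taken from the pooled per-cell
    depth histogram.
    """
    if depths is None or depths.size == 0 or depths.isna().all().all():
        raise ValueError("no depths present")
    per_animal = depths.mean(axis=1, skipna=True)
    pooled = depths.values[~np.isnan(depths.values)]
    hist, edges = np.histogram(pooled, bins=bins)
    mode = float((edges[int(np.argmax(hist))] + edges[int(np.argmax(hist)) + 1]) / 2)
    return {
        "per_animal_mean": per_animal,
        "mean": float(per_animal.mean()),
        "min": float(per_animal.min()),
        "max": float(per_animal.max()),
        "sd": float(per_animal.std(ddof=1)) if len(per_animal) > 1 else 0.0,
        "mode": mode,
    }


@dataclass
class QCReport:
    """Per-animal and panel-level WGS validation report."""

    per_animal: pd.DataFrame  # animal, call_rate_pct, accuracy_pct, concordance_pct, mean_depth, passed
    panel: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pct_cols = [c for c in self.per_animal.columns if c.endswith("_pct")]
        for c in pct_cols:
            vals = self.per_animal[c].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValueError(f"column {c} outside [0, 100]")

    @property
    def failed_animals(self) -> list[str]:
        df = self.per_animal
        return list(df.loc[~df["passed"], "animal"]) if "passed" in df else []


def build_report(
    wgs: Mapping, truth: Mapping,
    array: Optional[Mapping] = None,
    depths: Optional[pd.DataFrame] = None,
    min_depth: int = 3,
) -> QCReport:
    """Assemble the full QC report from genotype tables.

    ``wgs``/``truth``/``array`` map (animal, site) -> genotype tuple; the
    pass flag applies the strict >97% accuracy gate per animal.
    """
    animals = sorted({a for a, _ in wgs})
    rows = []
    for animal in animals:
        keys = [k for k in wgs if k[0] == animal]
        if depths is not None and animal in depths.index:
            cr = call_rate(depths=depths.loc[animal], min_depth=min_depth)
            mean_depth = float(depths.loc[animal].mean(skipna=True))
        else:
            cr = call_rate(calls=[wgs[k] for k in keys])
            mean_depth = float("nan")
        sub_test = {k: wgs[k] for k in keys}
        try:
            _, _, acc = genotype_accuracy(sub_test, truth)
        except UndefinedRateError:
            acc = float("nan")
        conc = float("nan")
        if array is not None:
            try:
                _, _, conc = genotype_accuracy(sub_test, array)
            except UndefinedRateError:
                pass
        rows.append((animal, 100.0 * cr, acc, conc, mean_depth,
                     bool(acc > ACCURACY_GATE_PCT)))
    per_animal = pd.DataFrame(
        rows, columns=["animal", "call_rate_pct", "accuracy_pct",
                       "concordance_pct", "mean_depth", "passed"])
    panel = {
        "n_animals": len(animals),
        "mean_accuracy_pct": float(per_animal["accuracy_pct"].mean()),
        "mean_call_rate_pct": float(per_animal["call_rate_pct"].mean()),
        "n_failed": int((~per_animal["passed"]).sum()),
    }
    if array is not None:
        try:
            _, pooled = concordance_by_animal(wgs, array)
            panel["pooled_concordance_pct"] = pooled
        except UndefinedRateError:
            pass
    return QCReport(per_animal, panel)
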