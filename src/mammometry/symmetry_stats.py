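"""Symmetry Index and manual-vs-automatic validation statistics.

The Symmetry Index (SI) condenses the seven bilateral breast measurements
into one value: for each measurement the left/right ratio
``min(L, R) / max(L, R)`` is formed, and the SI is 100 times the mean of
those ratios over the included measurements.  An SI of 100 means perfect
left-right agreement; the index is scale-invariant and symmetric in the
two sides.  The upper-breast-pole distance can be excluded from the index
via the ``included`` set, matching clinical practice of dropping it.

Method agreement between manual tape measurements and the automatic
pipeline is assessed with the Wilcoxon signed-rank test on per-patient
means of the left and right value (the "R + L" convention): zero
differences are dropped, tied absolute differences receive midranks, the
null distribution is enumerated exactly for up to 25 effective pairs and
approximated normally (with continuity and tie correction) above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import StatsError

if TYPE_CHECKING:  # pragma: no cover
    from .metrology import MeasurementTable

#: canonical order of the seven bilateral measurements
MEASUREMENT_NAMES = ("SN_N", "LBP_N", "UBP_N", "XI_N", "LABP_N",
                     "BREAST_WIDTH", "IMF_LENGTH")

EXACT_LIMIT = 25  # largest effective n for exact null enumeration


@dataclass(frozen=True)
class SymmetryResult:
    """Per-measurement left/right ratios and the scalar Symmetry Index."""

    per_measurement_ratio: dict[str, float]
    symmetry_index: float


@dataclass(frozen=True)
class PairedComparison:
    """One Wilcoxon signed-rank comparison between paired samples."""

    name: str
    n: int
    statistic: float
    p_two_tailed: float
    n_zero_dropped: int

    @property
    def defined(self) -> bool:
        return self.n - self.n_zero_dropped >= 1 and not math.isnan(self.p_two_tailed)


@dataclass(frozen=True)
class DescriptiveRow:
    """Descriptive statistics of one measurement under one method."""

    name: str
    method: str
    n: int
    minimum: float
    maximum: float
    median: float
    sd: float


# --------------------------------------------------------------- symmetry index


def symmetry_index(left: Mapping[str, float] | Sequence[float],
                   right: Mapping[str, float] | Sequence[float],
                   included: Iterable[str] = MEASUREMENT_NAMES) -> SymmetryResult:
    """Symmetry Index from the seven per-side measurement values.

    ``left`` and ``right`` are mappings from measurement name to value in
    cm (sequences are taken in the canonical :data:`MEASUREMENT_NAMES`
    order).  Only names in ``included`` contribute to the index; ratios
    are reported for every name present on both sides.
    """
    lmap = _as_map(left)
    rmap = _as_map(right)
    included = tuple(included)
    if not included:
        raise StatsError("empty inclusion set for the Symmetry Index")
    unknown = [n for n in included if n not in lmap or n not in rmap]
    if unknown:
        raise StatsError(f"included measurements missing from input: {unknown}")
    ratios: dict[str, float] = {}
    for name in lmap:
        if name not in rmap:
            continue
        lv, rv = float(lmap[name]), float(rmap[name])
        if lv <= 0 or rv <= 0:
            raise StatsError(f"nonpositive measurement value for {name}")
        ratios[name] = min(lv, rv) / max(lv, rv)
    si = 100.0 * float(np.mean([ratios[n] for n in included]))
    return SymmetryResult(per_measurement_ratio=ratios, symmetry_index=si)


def _as_map(values: Mapping[str, float] | Sequence[float]) -> dict[str, float]:
    if isinstance(values, Mapping):
        return dict(values)
    values = list(values)
    if len(values) != len(MEASUREMENT_NAMES):
        raise StatsError(
            f"expected {len(MEASUREMENT_NAMES)} values, got {len(values)}")
    return dict(zip(MEASUREMENT_NAMES, values))


# ------------------------------------------------------------ Wilcoxon signed rank


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         name: str = "") -> PairedComparison:
    """Two-tailed Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped (classic Wilcoxon reduction), tied
    absolute differences are midranked.  For an effective sample of at
    most :data:`EXACT_LIMIT` pairs the two-tailed p-value comes from exact
    enumeration of the null distribution of the positive-rank sum; larger
    samples use the normal approximation with continuity correction and a
    tie-corrected variance.  The reported statistic is the classic
    W = min(W+, W-).  When every difference is zero the test is undefined
    and the p-value is reported as NaN (not as 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired samples must be 1-D and of equal length")
    if len(x) < 2:
        raise StatsError("need at least 2 pairs")
    d = x - y
    nonzero = d != 0
    n_zero = int((~nonzero).sum())
    d = d[nonzero]
    n_eff = len(d)
    if n_eff == 0:
        return PairedComparison(name=name, n=len(x), statistic=math.nan,
                                p_two_tailed=math.nan, n_zero_dropped=n_zero)
    ranks = rankdata(np.abs(d))  # midranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n_eff <= EXACT_LIMIT:
        p = _exact_p_two_tailed(ranks, w_plus)
    else:
        p = _normal_p_two_tailed(ranks, w_plus)
    return PairedComparison(name=name, n=len(x), statistic=min(w_plus, w_minus),
                            p_two_tailed=p, n_zero_dropped=n_zero)


def exact_null_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum for given ranks.

    Returns ``(support, pmf)`` on the doubled-rank integer grid (doubling
    makes midranks exact).  Enumeration uses the subset-sum generating
    polynomial, equivalent to summing over all 2^n sign assignments.
    """
    r2 = np.rint(2 * np.asarray(ranks, dtype=float)).astype(np.int64)
    if not np.allclose(2 * np.asarray(ranks, float), r2):
        raise StatsError("midranks must be multiples of 0.5")
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    pmf = counts / counts.sum()
    return np.arange(total + 1) / 2.0, pmf


def _exact_p_two_tailed(ranks: np.ndarray, w_plus: float) -> float:
    support, pmf = exact_null_distribution(ranks)
    w = np.rint(2 * w_plus).astype(int)
    cdf = np.cumsum(pmf)
    p_le = float(cdf[w])
    p_ge = float(pmf[w:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p_two_tailed(ranks: np.ndarray, w_plus: float) -> float:
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1) / 24.0
           - float(((tie_counts ** 3 - tie_counts).sum())) / 48.0)
    if var <= 0:
        return math.nan
    dev = w_plus - mean
    cc = 0.5 * np.sign(dev)  # continuity correction toward the mean
    z = (dev - cc) / math.sqrt(var)
    return min(1.0, 2.0 * float(norm.sf(abs(z))))


# -------------------------------------------------------------- cohort summaries


def descriptive_table(tables: Iterable["MeasurementTable"],
                      symmetry: Mapping[str, Mapping[str, float]] | None = None,
                      ) -> list[DescriptiveRow]:
    """Descriptive statistics across scans, per measurement and method.

    For each scan the left and right values of a measurement are averaged
    first (the "R + L" convention); n, min, max, median and the sample
    standard deviation are then taken across scans.  ``symmetry`` may map
    method -> scan_id -> SI value to append per-method SI rows.
    """
    tables = list(tables)
    if not tables:
        raise StatsError("descriptive_table needs at least one scan")
    cells: dict[tuple[str, str], list[float]] = {}
    for table in tables:
        for name, method, mean_lr in table.per_patient_means():
            cells.setdefault((name, method), []).append(mean_lr)
    rows = [_describe(name, method, values)
            for (name, method), values in sorted(cells.items())]
    if symmetry:
        for method in sorted(symmetry):
            values = [float(v) for _, v in sorted(symmetry[method].items())]
            rows.append(_describe("SI", method, values))
    return rows


def _describe(name: str, method: str, values: Sequence[float]) -> DescriptiveRow:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return DescriptiveRow(name=name, method=method, n=len(arr),
                          minimum=float(arr.min()), maximum=float(arr.max()),
                          median=float(np.median(arr)), sd=sd)


def compare_methods(manual: Iterable["MeasurementTable"],
                    automatic: Iterable["MeasurementTable"],
                    si_included: Iterable[str] = MEASUREMENT_NAMES,
                    ) -> list[PairedComparison]:
    """Wilcoxon comparisons of manual vs automatic measurements plus the SI.

    One comparison per measurement name on per-patient left/right means,
    and one for the Symmetry Index: 8 rows.  Scans are paired by
    ``scan_id``; both cohorts must contain the same scans.
    """
    man = {t.scan_id: t for t in manual}
    aut = {t.scan_id: t for t in automatic}
    if set(man) != set(aut):
        raise StatsError(
            f"mismatched cohorts: manual scans {sorted(set(man) ^ set(aut))} unmatched")
    if not man:
        raise StatsError("empty cohorts")
    ids = sorted(man)
    rows: list[PairedComparison] = []
    for name in MEASUREMENT_NAMES:
        xs = [man[i].mean_left_right(name) for i in ids]
        ys = [aut[i].mean_left_right(name) for i in ids]
        rows.append(wilcoxon_signed_rank(xs, ys, name=name))
    si_m = [man[i].symmetry(included=si_included).symmetry_index for i in ids]
    si_a = [aut[i].symmetry(included=si_included).symmetry_index for i in ids]
    rows.append(wilcoxon_signed_rank(si_m, si_a, name="SI"))
    return rows
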