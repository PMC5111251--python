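"""Eubiotic/dysbiotic impact cumulation and Fisher exact contingency tests.

Each annotated differential genus contributes |Δg| to one quadrant of the
Cartesian impact plane (harmful/harmless on the x-axis, cumulated |Δg| on the
y-axis):

    Q1: harmless, Δg > 0    eubiotic
    Q2: harmful,  Δg > 0    dysbiotic
    Q3: harmful,  Δg < 0    eubiotic
    Q4: harmless, Δg < 0    dysbiotic

Per condition pair, the eubiotic frequency is the increase of harmless
abundances plus the (absolute) decrease of harmful ones (Q1+Q3), and vice
versa for the dysbiotic frequency (Q2+Q4). The pairs × {eubiotic, dysbiotic}
Condition × Impact table is then compared between conditions with Fisher's
exact test: one-sided ("the row condition is more associated with a harmless
composition than the column condition") or two-sided against a control
("conditions are equally likely to lead to a mostly harmless microbiome").

The Fisher p-values are computed from log-space hypergeometric probabilities
(log-gamma), so extreme associations (p ~ 1e-300) are resolved accurately;
p-values that underflow the double range are reported as 0 with a log note.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotate import DISCARDED, HARMFUL, HARMLESS, DifferentialGenus, GenusAnnotation

logger = logging.getLogger(__name__)

EUBIOTIC = "eubiotic"
DYSBIOTIC = "dysbiotic"

#: relative tolerance for "as extreme as observed" in the two-sided test,
#: guarding against log-space rounding of exact pmf ties (same convention as
#: R's fisher.test / scipy)
_TWO_SIDED_RELTOL = 1e-7

ALTERNATIVES = ("two_sided", "greater", "less")


def round_half_up(x: float) -> int:
    """Round a nonnegative value to the nearest integer, ties upward."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ImpactContribution:
    """One genus's signed contribution to a condition pair's impact."""

    condition_pair: str
    genus: str
    quadrant: int            # 1..4, see module docstring
    impact_class: str        # eubiotic | dysbiotic
    magnitude: float         # |delta| >= 0

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValueError("quadrant must be in 1..4")
        expected = EUBIOTIC if self.quadrant in (1, 3) else DYSBIOTIC
        if self.impact_class != expected:
            raise ValueError(
                f"quadrant {self.quadrant} implies {expected}, "
                f"got {self.impact_class}"
            )
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class ImpactContingency:
    """Condition × Impact table of cumulated integer frequencies."""

    table: pd.DataFrame  # index: condition pairs; columns: eubiotic, dysbiotic

    def __post_init__(self) -> None:
        if list(self.table.columns) != [EUBIOTIC, DYSBIOTIC]:
            raise ValueError("columns must be [eubiotic, dysbiotic]")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("contingency entries must be nonnegative")

    @property
    def pairs(self) -> list[str]:
        return list(self.table.index)

    def row(self, pair: str) -> tuple[int, int]:
        r = self.table.loc[pair]
        return int(r[EUBIOTIC]), int(r[DYSBIOTIC])

    def to_csv(self, dest) -> None:
        self.table.to_csv(dest, index_label="condition_pair")

    @classmethod
    def from_csv(cls, path) -> "ImpactContingency":
        df = pd.read_csv(path, index_col=0)
        df.columns = [c.strip().lower() for c in df.columns]
        if not {EUBIOTIC, DYSBIOTIC} <= set(df.columns):
            raise ValueError(
                f"contingency file {path!r} must have eubiotic and dysbiotic "
                f"columns, got {list(df.columns)}"
            )
        return cls(table=df[[EUBIOTIC, DYSBIOTIC]].astype(int))


def _quadrant(label: str, delta: float) -> int:
    if label == HARMLESS:
        return 1 if delta > 0 else 4
    return 2 if delta > 0 else 3


def cumulate_impact(
    diffs: Sequence[DifferentialGenus],
    annotations: Sequence[GenusAnnotation],
) -> tuple[ImpactContingency, list[ImpactContribution]]:
    """Cumulate |Δg| into per-pair eubiotic/dysbiotic frequencies.

    Discarded genera are excluded. Row totals are conserved: for each pair,
    eubiotic + dysbiotic equals the half-up-rounded Σ|Δg| over its
    non-discarded genera (the eubiotic entry is rounded half-up and the
    dysbiotic entry is the remainder, so the two rounded entries always sum
    to the rounded total).

    Raises
    ------
    ValueError
        If some differential genus lacks an annotation.
    """
    ann_index = {(a.condition_pair, a.genus): a for a in annotations}
    missing = [
        (d.condition_pair, d.genus)
        for d in diffs
        if (d.condition_pair, d.genus) not in ann_index
    ]
    if missing:
        raise ValueError(f"no annotation for: {missing[:10]}")

    contributions: list[ImpactContribution] = []
    eub: dict[str, float] = {}
    tot: dict[str, float] = {}
    pair_order: list[str] = []
    for d in diffs:
        if d.condition_pair not in tot:
            pair_order.append(d.condition_pair)
            tot[d.condition_pair] = 0.0
            eub[d.condition_pair] = 0.0
        ann = ann_index[(d.condition_pair, d.genus)]
        if ann.label == DISCARDED:
            continue
        q = _quadrant(ann.label, d.delta)
        impact_class = EUBIOTIC if q in (1, 3) else DYSBIOTIC
        mag = abs(d.delta)
        contributions.append(
            ImpactContribution(d.condition_pair, d.genus, q, impact_class, mag)
        )
        tot[d.condition_pair] += mag
        if impact_class == EUBIOTIC:
            eub[d.condition_pair] += mag

    rows = {}
    for pair in pair_order:
        if tot[pair] == 0.0:
            warnings.warn(f"condition pair {pair!r} has no usable genera")
        total_r = round_half_up(tot[pair])
        eub_r = round_half_up(eub[pair])
        rows[pair] = (eub_r, total_r - eub_r)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[EUBIOTIC, DYSBIOTIC]
    )
    return ImpactContingency(table=table), contributions


def cartesian_plane_data(
    contributions: Iterable[ImpactContribution],
) -> pd.DataFrame:
    """Per-pair quadrant sums of |Δg|, plot-ready.

    Columns: condition_pair, quadrant, label (harmless/harmful), direction
    (increase/decrease), impact_class, sum_abs_delta. Quadrants 1+3 sum to
    the pair's (unrounded) eubiotic frequency and 2+4 to the dysbiotic one.
    """
    meta = {
        1: (HARMLESS, "increase", EUBIOTIC),
        2: (HARMFUL, "increase", DYSBIOTIC),
        3: (HARMFUL, "decrease", EUBIOTIC),
        4: (HARMLESS, "decrease", DYSBIOTIC),
    }
    sums: dict[tuple[str, int], float] = {}
    pair_order: list[str] = []
    for c in contributions:
        if c.condition_pair not in pair_order:
            pair_order.append(c.condition_pair)
        sums[(c.condition_pair, c.quadrant)] = (
            sums.get((c.condition_pair, c.quadrant), 0.0) + c.magnitude
        )
    records = []
    for pair in pair_order:
        for q in (1, 2, 3, 4):
            label, direction, impact_class = meta[q]
            records.append(
                {
                    "condition_pair": pair,
                    "quadrant": q,
                    "label": label,
                    "direction": direction,
                    "impact_class": impact_class,
                    "sum_abs_delta": sums.get((pair, q), 0.0),
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Fisher exact test, log space

_lgamma_cache = gammaln(np.arange(2))


def _log_factorials(n: int) -> np.ndarray:
    """Cached log k! for k = 0..n."""
    global _lgamma_cache
    if n >= _lgamma_cache.size:
        _lgamma_cache = gammaln(np.arange(max(n + 1, 2 * _lgamma_cache.size)) + 1.0)
    return _lgamma_cache


def _as_counts(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("contingency entries must be nonnegative")
    if np.any(arr != np.floor(arr)):
        raise ValueError("contingency entries must be integers")
    a, b, c, d = (int(v) for v in arr.ravel())
    return a, b, c, d


def _log_hypergeom_pmf(
    support: np.ndarray, r1: int, r2: int, c1: int, n: int
) -> np.ndarray:
    lf = _log_factorials(n)
    c2 = n - c1
    return (
        lf[r1] + lf[r2] + lf[c1] + lf[c2] - lf[n]
        - lf[support] - lf[r1 - support] - lf[c1 - support]
        - lf[c2 - r1 + support]
    )


def _logsumexp(logs: np.ndarray) -> float:
    if logs.size == 0:
        return -np.inf
    m = float(np.max(logs))
    return m + math.log(np.sum(np.exp(logs - m)))


def fisher_exact(table, alternative: str = "two_sided") -> float:
    """Fisher's exact test p-value for a 2×2 table of nonnegative integers.

    The conditional distribution of the top-left cell given the margins is
    hypergeometric; its probabilities are evaluated in log space via cached
    log-factorials, so p-values remain accurate down to the double-precision
    floor (~1e-300). ``alternative`` is one of

    - ``"greater"``: P(X >= a), the top-left cell at least as large,
    - ``"less"``: P(X <= a),
    - ``"two_sided"``: total probability of tables as or less probable than
      the observed one.

    A table with a zero row or column margin is degenerate: the observed
    table is the only one possible and p = 1 (with a warning).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    a, b, c, d = _as_counts(table)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margin in 2x2 table; p = 1 by convention")
        return 1.0

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, r1, n - r1, c1, n)
    i = a - lo

    if alternative == "greater":
        logp = _logsumexp(logpmf[i:])
    elif alternative == "less":
        logp = _logsumexp(logpmf[: i + 1])
    else:
        cutoff = logpmf[i] + math.log1p(_TWO_SIDED_RELTOL)
        logp = _logsumexp(logpmf[logpmf <= cutoff])

    p = float(math.exp(logp)) if logp > -745.0 else 0.0
    if p == 0.0:
        logger.info(
            "fisher_exact: p-value underflows double precision "
            "(log p = %.3f); reported as 0", logp,
        )
    return min(p, 1.0)


def test_vs_control(pair_row, control_row) -> float:
    """Two-sided Fisher test of a condition pair's row against the control's.

    Rows are (eubiotic, dysbiotic) count pairs. Tests the null that the two
    conditions are equally likely to lead to a mostly harmless-composed
    microbiome.
    """
    return fisher_exact([list(pair_row), list(control_row)], "two_sided")


def pairwise_condition_tests(contingency: ImpactContingency) -> pd.DataFrame:
    """One-sided Fisher p-value matrix over all condition-pair rows.

    Entry (i, j) tests whether the row-i condition is more associated with a
    harmless (eubiotic-dominated) composition than the row-j condition:
    alternative = greater on the eubiotic column. The diagonal is 1.
    """
    pairs = contingency.pairs
    if len(pairs) < 2:
        raise ValueError("need at least 2 condition pairs to compare")
    out = pd.DataFrame(1.0, index=pairs, columns=pairs)
    for pi in pairs:
        for pj in pairs:
            if pi == pj:
                continue
            out.loc[pi, pj] = fisher_exact(
                [list(contingency.row(pi)), list(contingency.row(pj))],
                "greater",
            )
    return out


def bonferroni(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Optional Bonferroni correction over the off-diagonal comparisons."""
    m = pvalues.shape[0] * (pvalues.shape[1] - 1)
    adj = (pvalues * m).clip(upper=1.0)
    np.fill_diagonal(adj.values, 1.0)
    return adj
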