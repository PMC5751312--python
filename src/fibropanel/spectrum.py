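"""Mutation-type spectrum per gene and exact Fisher r×c comparison.

The spectrum counts *unique* deleterious mutations (one per variant, however
many populations carry it) in five classes: frameshift, nonsense, splicing
(core and near-splice collapsed), missense, and in-frame indels, together
with the subset already reported in fibrinogen-disorder databases.

The two-tailed Fisher exact test for a 2×k table follows the standard
probability-ordering convention: with both margins fixed, the p-value is the
total null (multivariate hypergeometric) probability of all tables whose
probability does not exceed that of the observed table.  Tables with total
count up to ``max_exact_total`` are enumerated exactly; larger tables fall
back to seeded Monte Carlo sampling with a reported standard error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from .model import ClassifiedVariant, Consequence, GENES

logger = logging.getLogger("fibropanel")

MUTATION_TYPES = ("frameshift", "nonsense", "splicing", "missense", "inframe_indel")

_TYPE_OF_CONSEQUENCE = {
    Consequence.FRAMESHIFT: "frameshift",
    Consequence.NONSENSE: "nonsense",
    Consequence.SPLICE_CORE: "splicing",
    Consequence.SPLICE_NEAR: "splicing",
    Consequence.MISSENSE: "missense",
    Consequence.INFRAME_INDEL: "inframe_indel",
}

# log-probability slack when comparing table probabilities (the comparison
# "at least as extreme" is made robust to floating-point noise, cf. the
# usual practice in exact-test implementations)
_LOG_EPS = 1e-9


@dataclass
class SpectrumTable:
    """Unique-mutation counts by class for one gene."""

    gene: str
    counts: dict[str, int] = field(default_factory=lambda: {t: 0 for t in MUTATION_TYPES})
    reported_in_db: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in MUTATION_TYPES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reported(self) -> int:
        return sum(self.reported_in_db.values())

    def as_row(self) -> list[int]:
        return [self.counts[t] for t in MUTATION_TYPES]


def spectrum_counts(classified: Sequence[ClassifiedVariant]) -> dict[str, SpectrumTable]:
    """Per-gene spectrum of unique deleterious mutations."""
    tables = {g: SpectrumTable(g) for g in GENES}
    seen: set[str] = set()
    for v in classified:
        if not v.deleterious or v.variant_id in seen:
            continue
        seen.add(v.variant_id)
        mtype = _TYPE_OF_CONSEQUENCE.get(v.record.consequence)
        if mtype is None:  # pragma: no cover - deleterious implies a known class
            continue
        tables[v.gene].counts[mtype] += 1
        if v.db.reported:
            tables[v.gene].reported_in_db[mtype] += 1
    return tables


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact" or "monte_carlo"
    standard_error: float = 0.0
    n_samples: int = 0


def _log_table_prob(x: np.ndarray, cols: np.ndarray, n: int, r1: int) -> np.ndarray:
    """Null log-probability of row-1 vector(s) ``x`` given fixed margins."""
    num = gammaln(cols + 1) - gammaln(x + 1) - gammaln(cols - x + 1)
    den = gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1)
    return num.sum(axis=-1) - den


def _exact_p(row1: np.ndarray, cols: np.ndarray) -> float:
    n, r1 = int(cols.sum()), int(row1.sum())
    log_obs = float(_log_table_prob(row1, cols, n, r1))
    den = float(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
    k = len(cols)
    suffix = np.concatenate([np.cumsum(cols[::-1])[::-1], [0]])  # sum of cols j..k-1
    total = 0.0

    def recurse(j: int, remaining: int, log_num: float) -> None:
        nonlocal total
        if j == k:
            log_p = log_num - den
            if log_p <= log_obs + _LOG_EPS:
                total += float(np.exp(log_p))
            return
        lo = max(0, remaining - int(suffix[j + 1]))
        hi = min(int(cols[j]), remaining)
        for x in range(lo, hi + 1):
            term = float(gammaln(cols[j] + 1) - gammaln(x + 1) - gammaln(cols[j] - x + 1))
            recurse(j + 1, remaining - x, log_num + term)

    recurse(0, r1, 0.0)
    return min(total, 1.0)


def fisher_exact_rxc(
    table_a: Sequence[int],
    table_b: Sequence[int],
    max_exact_total: int = 500,
    n_monte_carlo: int = 200_000,
    seed: Optional[int] = None,
) -> FisherResult:
    """Two-tailed Fisher exact test for a 2×k table of counts.

    ``table_a`` and ``table_b`` are the two rows (k ≤ 6 for the exact path).
    Columns with zero margin are dropped with a warning; an all-zero table
    is an error.  Row and column order do not affect the p-value.
    """
    a = np.asarray(table_a, dtype=np.int64)
    b = np.asarray(table_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("table_a and table_b must be 1-D sequences of equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    cols = a + b
    if cols.sum() == 0:
        raise ValueError("all-zero table")
    if (cols == 0).any():
        logger.warning("dropping %d zero-margin column(s)", int((cols == 0).sum()))
        keep = cols > 0
        a, b, cols = a[keep], b[keep], cols[keep]
    if a.sum() == 0 or b.sum() == 0:
        # one empty row: the observed table is the only table with its margins
        return FisherResult(1.0, "exact")

    n, r1 = int(cols.sum()), int(a.sum())
    if n <= max_exact_total:
        return FisherResult(_exact_p(a, cols), "exact")

    rng = np.random.default_rng(seed)
    samples = rng.multivariate_hypergeometric(cols, r1, size=n_monte_carlo)
    log_p = _log_table_prob(samples, cols, n, r1)
    log_obs = float(_log_table_prob(a, cols, n, r1))
    hits = log_p <= log_obs + _LOG_EPS
    p = float(hits.mean())
    se = float(np.sqrt(p * (1.0 - p) / n_monte_carlo))
    return FisherResult(max(p, 1.0 / n_monte_carlo), "monte_carlo", se, n_monte_carlo)


def compare_to_reference(
    spectrum: SpectrumTable,
    reference_counts: dict[str, int],
    **kwargs,
) -> FisherResult:
    """Fisher comparison of a gene's spectrum against a reference distribution
    (e.g. the class counts of a curated mutation database)."""
    row_a = [spectrum.counts[t] for t in MUTATION_TYPES]
    row_b = [int(reference_counts.get(t, 0)) for t in MUTATION_TYPES]
    return fisher_exact_rxc(row_a, row_b, **kwargs)
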