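"""Over-representation tests for regulator target sets.

Given a hit list of genes (e.g. the differentially expressed genes of a
two-group comparison), each regulator's target set is tested for significant
overlap with the list against a finite gene universe, and regulators are
ranked by adjusted p-value.

Notation: N = universe size, K = regulator targets in the universe,
n = hit-list size, k = overlap between targets and hit list. All tests are
one-sided for over-representation (upper tail); under-representation is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import InputError
from .rti import RTICollection, restrict_to_universe

ADJUSTMENT_METHODS = {
    "bonferroni": "bonferroni",
    "sidak": "sidak",
    "holm": "holm",
    "holm_sidak": "holm-sidak",
    "hochberg": "simes-hochberg",
    "simes_hommel": "hommel",
    "benjamini_hochberg": "fdr_bh",
    "benjamini_yekutieli": "fdr_by",
}


@dataclass(frozen=True)
class EnrichmentInput:
    gene_list: frozenset[str]
    universe: frozenset[str]
    rti: RTICollection

    def __post_init__(self):
        stray = self.gene_list - self.universe
        if stray:
            raise InputError(
                f"hit-list genes outside the universe: {sorted(stray)[:10]}"
            )
        if not self.universe:
            raise InputError("empty universe")


@dataclass(frozen=True)
class EnrichmentRow:
    regulator: str
    targets_in_universe: int  # K
    list_size: int            # n
    overlap: int              # k
    p_value: float
    p_adjusted: float
    test: str
    direction: str = "n/a"


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise InputError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > N or n > N:
        raise InputError(f"K={K} and n={n} must not exceed the universe N={N}")
    if min(k, K, n, N) < 0:
        raise InputError("negative count")


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) with X ~ Hypergeom(N, K, n)."""
    _check_counts(k, K, n, N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def fisher_exact_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided Fisher's exact test on [[k, n-k], [K-k, N-K-n+k]].

    Mathematically identical to the hypergeometric upper tail on the same
    margins; offered separately because the service exposes both.
    """
    _check_counts(k, K, n, N)
    # below the hypergeometric support minimum the upper tail is certain;
    # clamp so the 2x2 table stays consistent with its margins
    k_eff = max(k, K + n - N)
    table = np.array([[k_eff, n - k_eff], [K - k_eff, N - K - n + k_eff]])
    if (table < 0).any():
        raise InputError(f"inconsistent 2x2 table {table.tolist()}")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def binomial_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail binomial test with background hit rate p0 = K/N.

    Unlike the sampling-without-replacement tests, the binomial model does
    not bound the overlap by K, so only 0 <= k <= n is required.
    """
    if N <= 0:
        raise InputError("empty universe")
    if not (0 <= k <= n <= N) or K < 0 or K > N:
        raise InputError(f"invalid counts k={k}, K={K}, n={n}, N={N}")
    p0 = K / N
    if not 0 <= p0 <= 1:
        raise InputError(f"background rate {p0} outside [0, 1]")
    if n == 0:
        return 1.0
    return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)


TESTS = {
    "hypergeometric": hypergeometric_test,
    "fisher": fisher_exact_test,
    "binomial": binomial_test,
}


def adjust_pvalues(p_values, method: str = "benjamini_yekutieli") -> np.ndarray:
    """Multiple-testing adjustment; returns values in input order, clipped
    to [0, 1]. BH/BY apply the usual step-up monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InputError("p-values must lie in [0, 1]")
    if method not in ADJUSTMENT_METHODS:
        raise InputError(
            f"unknown adjustment {method!r}; choose from {sorted(ADJUSTMENT_METHODS)}"
        )
    adjusted = multipletests(p, method=ADJUSTMENT_METHODS[method])[1]
    return np.clip(adjusted, 0.0, 1.0)


def enrich(
    input: EnrichmentInput,
    test: str = "hypergeometric",
    adjust: str = "benjamini_yekutieli",
    min_targets: int = 2,
) -> list[EnrichmentRow]:
    """Test every regulator's target set for over-representation.

    Regulators with fewer than ``min_targets`` targets in the universe are
    not reported. Rows are sorted by (adjusted p, raw p, overlap descending,
    regulator name).
    """
    if test not in TESTS:
        raise InputError(f"unknown test {test!r}; choose from {sorted(TESTS)}")
    if min_targets < 1:
        raise InputError("min_targets must be >= 1")
    test_fn = TESTS[test]
    rti = restrict_to_universe(input.rti, set(input.universe))
    N = len(input.universe)
    n = len(input.gene_list)

    rows: list[tuple] = []
    for reg in rti.regulators:
        targets = rti.targets(reg)
        K = len(targets)
        if K < min_targets:
            continue
        k = len(targets & input.gene_list)
        rows.append((reg, K, k, test_fn(k, K, n, N)))

    adjusted = adjust_pvalues([r[3] for r in rows], adjust)
    out = [
        EnrichmentRow(reg, K, n, k, p, float(p_adj), test)
        for (reg, K, k, p), p_adj in zip(rows, adjusted)
    ]
    out.sort(key=lambda r: (r.p_adjusted, r.p_value, -r.overlap, r.regulator))
    return out
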