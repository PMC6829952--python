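"""Directional over/under-representation of categories among DE genes.

For each (rolled-up bin, contrast, direction) a 2x2 contingency drawn
without replacement is tested: a universe of N genes contains K members of
the bin; n genes are differentially expressed in the given direction; k of
those fall in the bin.  The two-tailed hypergeometric p-value is converted
to a signed Z-value via the standard normal quantile, positive for
over-representation (k > expected = n*K/N), so |Z| >= 1.96 corresponds to
p <= 0.05 exactly at the threshold.

The two-sided p uses minimum-likelihood summation (the convention of
Fisher's exact test): all outcomes whose point probability does not exceed
that of the observed table contribute.  Point probabilities are compared in
exact integer arithmetic, so ties are handled without floating-point
ambiguity; a relative tolerance of 1e-7 is applied to the comparison, as is
customary for this dialect.  A tail-doubling dialect is available behind
``twosided="double"``.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PipelineConfig
from .errors import ConfigError, InputError
from .io_formats import CategoryMap, ExpressionMatrix

#: numerator/denominator of the relative tolerance (1 + 1e-7) used when
#: comparing point probabilities for minimum-likelihood summation
_EPS_NUM = 10**7 + 1
_EPS_DEN = 10**7

Z_CAP_DEFAULT = 8.0

log = logging.getLogger(__name__)


def build_universe(matrix: ExpressionMatrix, category_map: CategoryMap, mode: str = "annotated") -> set[str]:
    """Gene universe for enrichment: annotated genes only, or all measured."""
    measured = set(matrix.gene_ids)
    if mode == "all_measured":
        universe = measured
    elif mode == "annotated":
        universe = measured & category_map.genes
    else:
        raise ConfigError(f"unknown universe mode {mode!r}")
    if not universe:
        raise ConfigError(
            "empty enrichment universe: no overlap between expression matrix "
            "and category map gene identifiers"
        )
    return universe


@lru_cache(maxsize=200_000)
def _support_weights(N: int, K: int, n: int) -> tuple[int, tuple[int, ...], tuple[int, ...]]:
    """Exact hypergeometric weights comb(K,j)*comb(N-K,n-j) over the support.

    Returns (total = comb(N, n), support js, weights); cached because the
    same (N, K, n) triple recurs across bins and contrasts.
    """
    lo = max(0, n + K - N)
    hi = min(n, K)
    js = tuple(range(lo, hi + 1))
    weights = tuple(comb(K, j) * comb(N - K, n - j) for j in js)
    return comb(N, n), js, weights


def hypergeom_two_tailed(N: int, K: int, n: int, k: int, method: str = "minlike") -> float:
    """Two-tailed hypergeometric p-value for observing k bin members among n draws.

    ``minlike``: sum of P(X = j) over all j with P(j) <= P(k)*(1 + 1e-7),
    evaluated in exact integer arithmetic.  ``double``: twice the smaller
    tail, clipped to 1.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v:
            raise InputError(f"{name} must be an integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N):
        raise InputError(f"need 0 <= K <= N and 0 <= n <= N, got N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(n, K)
    if not (lo <= k <= hi):
        raise InputError(f"k={k} outside support [{lo}, {hi}] for N={N}, K={K}, n={n}")
    total, js, weights = _support_weights(N, K, n)
    wk = weights[k - lo]
    if method == "minlike":
        included = sum(w for w in weights if w * _EPS_DEN <= wk * _EPS_NUM)
        p = included / total
    elif method == "double":
        lower = sum(weights[: k - lo + 1])
        upper = sum(weights[k - lo:])
        p = 2 * min(lower, upper) / total
    else:
        raise ConfigError(f"unknown two-sided dialect {method!r}")
    return min(p, 1.0)


def p_to_z(p: float, observed: float, expected: float, z_cap: float = Z_CAP_DEFAULT) -> float:
    """Signed Z from a two-tailed p: sign(observed - expected) * Phi^-1(1 - p/2).

    Zero when observed equals expected; |Z| clipped to ``z_cap`` (also the
    fallback when p underflows to 0).
    """
    if not (0.0 <= p <= 1.0):
        raise InputError(f"p-value {p} outside [0, 1]")
    if observed == expected:
        return 0.0
    sign = 1.0 if observed > expected else -1.0
    if p == 0.0:
        log.warning("p-value underflowed to 0; returning capped Z = %s", sign * z_cap)
        return sign * z_cap
    z = norm.ppf(1.0 - p / 2.0)
    return sign * float(np.clip(z, 0.0, z_cap))


def enrich_all(
    de_tables: dict,
    category_map: CategoryMap,
    universe: set[str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Enrichment table over all (bin, contrast, direction) cells.

    ``de_tables`` maps :class:`~germclock.de_calling.ContrastSpec` to a DE
    result frame with a ``call`` column.  Bins smaller than
    ``config.min_bin_size`` within the universe are skipped.  Ordering is
    deterministic: bincode (numeric path order), contrast name, direction.
    """
    cfg = config or PipelineConfig()
    membership = category_map.membership(rollup=cfg.rollup)
    N = len(universe)
    tested_bins = {
        code: members & universe
        for code, members in membership.items()
        if len(members & universe) >= cfg.min_bin_size
    }
    rows = []
    for contrast in de_tables:
        calls = de_tables[contrast]["call"]
        for direction in ("up", "down"):
            de_genes = set(calls.index[calls == direction]) & universe
            n = len(de_genes)
            for code in tested_bins:
                members = tested_bins[code]
                K = len(members)
                k = len(members & de_genes)
                expected = n * K / N
                p = hypergeom_two_tailed(N, K, n, k, method=cfg.twosided)
                z = p_to_z(p, k, expected, cfg.z_cap)
                rows.append(
                    {
                        "bincode": code,
                        "bin_name": category_map.bins.get(code, code),
                        "contrast": contrast.name,
                        "system": contrast.system,
                        "test_stage": contrast.test_stage,
                        "reference_stage": contrast.reference_stage,
                        "direction": direction,
                        "N": N,
                        "K": K,
                        "n": n,
                        "k": k,
                        "expected": expected,
                        "p": p,
                        "Z": z,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        table["_key"] = table["bincode"].map(lambda c: tuple(int(x) for x in c.split(".")))
        table = (
            table.sort_values(["_key", "contrast", "system", "direction"], kind="mergesort")
            .drop(columns="_key")
            .reset_index(drop=True)
        )
    return table
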