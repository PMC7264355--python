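"""Direction-switched hypergeometric enrichment ("two-sided" test).

For a kinase with n predicted substrate sites among N quantified sites, of
which M are NCPs and m of its substrates are NCPs, the enrichment ratio is

    E = (m/M) / (n/N)

and the p-value is the hypergeometric tail in the direction of the effect:
the upper tail sum_{m'=m}^{n} C(M,m')C(N-M,n-m')/C(N,n) when E >= 1 (ties to
the upper tail), the lower tail sum_{m'=0}^{m} otherwise.  Note the observed
term is included in both directions, so this is not a symmetric two-tailed
mass test.  A kinase is called circadian when p < 0.05 and E > 1, both
strict.  The same machinery serves generic term (gene-set) enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .rhythm import bh_qvalues

EXACT_N_MAX = 1000  # exact integer arithmetic below this, log-gamma above


@dataclass
class EnrichmentResult:
    unit_id: str  # kinase or term
    N: int  # all quantified sites (or background genes)
    n: int  # sites predicted for the kinase (term members in background)
    M: int  # NCPs (foreground genes)
    m: int  # NCPs predicted for the kinase (term members in foreground)
    e_ratio: float
    p: float
    q: float = float("nan")


def _validate(N: int, n: int, M: int, m: int) -> None:
    if not (0 <= m <= min(n, M) and n <= N and M <= N and N > 0):
        raise ValueError(f"invalid counts N={N}, n={n}, M={M}, m={m}")


def e_ratio(N: int, n: int, M: int, m: int) -> float:
    """(m/M) / (n/N); NaN-flagged when a denominator is zero."""
    _validate(N, n, M, m)
    if n == 0 or M == 0:
        return float("nan")
    return (m / M) / (n / N)


def _log_pmf(N: int, n: int, M: int, mp: int) -> float:
    return (
        _logcomb(M, mp)
        + _logcomb(N - M, n - mp)
        - _logcomb(N, n)
    )


def _logcomb(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def _tail(N: int, n: int, M: int, terms: Iterable[int]) -> float:
    terms = list(terms)
    if N <= EXACT_N_MAX:
        denom = math.comb(N, n)
        num = 0
        for mp in terms:
            if 0 <= mp <= M and 0 <= n - mp <= N - M:
                num += math.comb(M, mp) * math.comb(N - M, n - mp)
        return num / denom
    logs = [
        _log_pmf(N, n, M, mp)
        for mp in terms
        if 0 <= mp <= M and 0 <= n - mp <= N - M
    ]
    if not logs:
        return 0.0
    top = max(logs)
    return float(math.exp(top) * sum(math.exp(l - top) for l in logs))


def circadian_kinase_test(N: int, n: int, M: int, m: int) -> float:
    """Direction-switched hypergeometric p-value (see module docstring)."""
    _validate(N, n, M, m)
    if n == 0 or M == 0:
        return 1.0
    if e_ratio(N, n, M, m) >= 1.0:
        p = _tail(N, n, M, range(m, n + 1))
    else:
        p = _tail(N, n, M, range(0, m + 1))
    return min(max(p, 5e-324), 1.0)


def kinase_enrichment(
    predictions,  # Sequence[SsKsrPrediction] or DataFrame with kinase_id/site_id
    all_site_ids: Iterable[str],
    ncp_site_ids: Iterable[str],
) -> list[EnrichmentResult]:
    """Per-kinase NCP enrichment among predicted substrates.

    N = quantified sites, n = sites predicted for the kinase, M = NCPs,
    m = NCPs predicted for the kinase.  Predictions outside ``all_site_ids``
    are ignored; BH q-values are filled in across kinases.
    """
    universe = set(all_site_ids)
    ncps = set(ncp_site_ids) & universe
    if isinstance(predictions, pd.DataFrame):
        pairs = list(zip(predictions["kinase_id"], predictions["site_id"]))
    else:
        pairs = [(p.kinase_id, p.site_id) for p in predictions]
    per_kinase: dict[str, set[str]] = {}
    for k, s in pairs:
        if s in universe:
            per_kinase.setdefault(k, set()).add(s)
    N, M = len(universe), len(ncps)
    results = []
    for k in sorted(per_kinase):
        subs = per_kinase[k]
        n, m = len(subs), len(subs & ncps)
        results.append(
            EnrichmentResult(
                unit_id=k,
                N=N,
                n=n,
                M=M,
                m=m,
                e_ratio=e_ratio(N, n, M, m),
                p=circadian_kinase_test(N, n, M, m),
            )
        )
    if results:
        qs = bh_qvalues(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def classify_circadian_kinases(
    results: Sequence[EnrichmentResult], p_max: float = 0.05
) -> set[str]:
    """Kinases with p < p_max AND E-ratio > 1, both strict."""
    return {
        r.unit_id
        for r in results
        if r.p < p_max and np.isfinite(r.e_ratio) and r.e_ratio > 1.0
    }


def term_enrichment(
    annotation: Mapping[str, set[str]],
    foreground: set[str],
    background: set[str],
) -> list[EnrichmentResult]:
    """Gene-set enrichment with the same direction-switched test.

    N = |background|, M = |foreground|, n = |term in background|,
    m = |term in foreground|.  Terms disjoint from the background are skipped.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    N, M = len(background), len(foreground)
    results = []
    for term in sorted(annotation):
        in_bg = annotation[term] & background
        if not in_bg:
            continue
        n, m = len(in_bg), len(in_bg & foreground)
        results.append(
            EnrichmentResult(
                unit_id=term,
                N=N,
                n=n,
                M=M,
                m=m,
                e_ratio=e_ratio(N, n, M, m),
                p=circadian_kinase_test(N, n, M, m),
            )
        )
    if results:
        qs = bh_qvalues(np.array([r.p for r in results]))
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "N": r.N,
                "n": r.n,
                "M": r.M,
                "m": r.m,
                "e_ratio": r.e_ratio,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ],
        columns=["unit_id", "N", "n", "M", "m", "e_ratio", "p", "q"],
    )
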