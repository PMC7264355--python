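"""Summary-statistic arithmetic for pipeline reports.

Every percentage in a report is the plain ratio of two stage counts, rounded
half-up (the convention of printed tables, where 0.5955% prints as 0.60%).
Keeping these one-liners in a single module lets tests re-derive each
reported figure independently from the stage tables.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping


def pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    """100 * numerator/denominator, rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage of an empty denominator")
    v = Decimal(str(numerator)) / Decimal(str(denominator)) * 100
    return float(v.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def ncp_fraction(n_ncp: int, n_sites: int, decimals: int = 2) -> float:
    """Share of quantified p-sites whose occupancy series cycles."""
    return pct(n_ncp, n_sites, decimals)


def residue_shares(counts: Mapping[str, int], decimals: int = 2) -> dict[str, float]:
    """p-Ser/p-Thr/p-Tyr percentage shares of the site inventory."""
    total = sum(counts.values())
    return {res: pct(c, total, decimals) for res, c in counts.items()}


def multi_observation_fraction(obs_counts: Iterable[int], decimals: int = 2) -> float:
    """Fraction of features matched with >= 2 observations (e.g. spectral counts)."""
    counts = list(obs_counts)
    return pct(sum(c >= 2 for c in counts), len(counts), decimals)


def single_support_fraction(support_counts: Iterable[int], decimals: int = 2) -> float:
    """Fraction of proteins with exactly one supporting feature (peptide)."""
    counts = list(support_counts)
    return pct(sum(c == 1 for c in counts), len(counts), decimals)


def validated_fraction(n_validated: int, n_predicted: int, decimals: int = 0) -> float:
    """Share of predicted kinases confirmed by a validation annotation table."""
    return pct(n_validated, n_predicted, decimals)
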