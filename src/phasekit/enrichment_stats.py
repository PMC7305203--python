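"""Case/control enrichment statistics for 2x2 tables.

Individual-level contingency construction, a two-sided Fisher exact
test (sum of all tables at most as probable, log-space hypergeometric),
the Yates-corrected chi-square, minor-allele frequencies, and the
rounded frequency-ratio labels used in per-cohort report rows.

Conventions, stated once:

* Fisher two-sided p sums pmf(k) over the hypergeometric support for
  every k with pmf(k) <= pmf(a) * (1 + 1e-7); the relative tolerance
  absorbs floating-point ties.
* Yates statistic clamps to 0 when |ad - bc| <= N/2.
* Ratio labels round half away from zero; no printed ratio in scope
  sits at .5, so the choice is a documented convention, not inference.
* No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.special import erfc

from .errors import StatsError
from .io_formats import GenotypeCall

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "fisher_exact_two_sided",
    "chisq_yates",
    "frequency_ratio",
    "allele_frequency",
    "enrichment_report",
]

_PMF_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = cases positive, b = cases negative, c = controls
    positive, d = controls negative.  Margins are derived, never stored."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (
            self.a + self.b,
            self.c + self.d,
            self.a + self.c,
            self.b + self.d,
        )

    @classmethod
    def from_counts(cls, case_pos: int, case_n: int,
                    ctrl_pos: int, ctrl_n: int) -> "ContingencyTable2x2":
        if case_pos > case_n or ctrl_pos > ctrl_n:
            raise ValueError("positives exceed cohort size")
        return cls(case_pos, case_n - case_pos, ctrl_pos, ctrl_n - ctrl_pos)


@dataclass(frozen=True)
class EnrichmentResult:
    """One report row; rounding is applied only at formatting time."""

    population: str
    case_count: int
    case_n: int
    ctrl_count: int
    ctrl_n: int
    case_freq: float
    ctrl_freq: float
    ratio: float
    ratio_label: str
    fisher_p: float
    chisq_stat: Optional[float]
    chisq_p: Optional[float]


def _log_hypergeom_pmf(k: int, r1: int, c1: int, n: int) -> float:
    """log pmf of the hypergeometric count in cell a, margins fixed."""
    r2 = n - r1
    return (
        math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
        + math.lgamma(r2 + 1) - math.lgamma(c1 - k + 1)
        - math.lgamma(r2 - (c1 - k) + 1)
        - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
    )


def fisher_exact_two_sided(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum over the hypergeometric support
    (margins fixed) of pmf(k) for all k at most as probable as the
    observed table, with a relative tolerance of 1e-7 on the comparison.
    Degenerate margins give p = 1."""
    r1, _, c1, _ = t.margins
    n = t.n
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    k_lo = max(0, r1 + c1 - n)
    k_hi = min(r1, c1)
    log_obs = _log_hypergeom_pmf(t.a, r1, c1, n)
    cutoff = log_obs + math.log1p(_PMF_RTOL)
    p = 0.0
    for k in range(k_lo, k_hi + 1):
        lp = _log_hypergeom_pmf(k, r1, c1, n)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


def chisq_yates(t: ContingencyTable2x2) -> tuple[float, float]:
    """Yates-corrected chi-square statistic and its df=1 upper-tail p,
    via the complementary-error-function identity
    ``sf(x) = erfc(sqrt(x / 2))``.  Zero margins are an error, distinct
    from p = 1."""
    r1, r2, c1, c2 = t.margins
    if 0 in (r1, r2, c1, c2):
        raise StatsError("chi-square with Yates correction undefined: zero margin")
    n = t.n
    diff = abs(t.a * t.d - t.b * t.c)
    num = max(diff - n / 2.0, 0.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    p = float(erfc(math.sqrt(stat / 2.0)))
    return stat, p


def frequency_ratio(t: ContingencyTable2x2) -> tuple[float, str]:
    """Case/control positive-frequency ratio and its ``k:1`` label,
    rounded half away from zero.  ``c = 0`` yields an infinite sentinel
    labelled ``inf``."""
    r1, r2, _, _ = t.margins
    if r1 == 0:
        raise StatsError("no cases: frequency ratio undefined")
    if t.c == 0:
        return math.inf, "inf"
    ratio = (t.a / r1) / (t.c / r2)
    return ratio, f"{_round_half_away(ratio)}:1"


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def allele_frequency(calls: Sequence[GenotypeCall]) -> float:
    """Alt-allele frequency among called diploid individuals; missing
    calls drop out of the denominator."""
    alt = 0
    called = 0
    for call in calls:
        if call.is_missing:
            continue
        called += 1
        alt += call.alt_count()
    if called == 0:
        raise StatsError("no called individuals: allele frequency undefined")
    return alt / (2 * called)


def enrichment_report(
    case_count: int,
    case_n: int,
    ctrl_count: int,
    ctrl_n: int,
    population: str = "all",
) -> EnrichmentResult:
    """Assemble one report row from individual-level cohort counts."""
    t = ContingencyTable2x2.from_counts(case_count, case_n, ctrl_count, ctrl_n)
    case_freq = case_count / case_n if case_n else math.nan
    ctrl_freq = ctrl_count / ctrl_n if ctrl_n else math.nan

    if case_count == 0 and ctrl_count == 0:
        ratio, label = math.nan, "0:0"
    elif ctrl_count == 0:
        ratio, label = math.inf, "inf"
    else:
        ratio = case_freq / ctrl_freq
        label = f"{_round_half_away(ratio)}:1"

    fisher_p = fisher_exact_two_sided(t)
    try:
        chisq_stat, chisq_p = chisq_yates(t)
    except StatsError:
        chisq_stat = chisq_p = None
    return EnrichmentResult(
        population=population,
        case_count=case_count,
        case_n=case_n,
        ctrl_count=ctrl_count,
        ctrl_n=ctrl_n,
        case_freq=case_freq,
        ctrl_freq=ctrl_freq,
        ratio=ratio,
        ratio_label=label,
        fisher_p=fisher_p,
        chisq_stat=chisq_stat,
        chisq_p=chisq_p,
    )
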