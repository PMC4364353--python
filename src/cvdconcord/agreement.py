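"""Agreement statistics for paired binary risk classifications.

Implements the statistics used to compare two dichotomized risk scores on
the same patients: the 2x2 cross-tabulation, observed agreement with an
Agresti-Coull interval, specific agreement for the high and low categories
with Mackinnon delta-method intervals, Cohen's kappa with the
Fleiss-Cohen-Everitt asymptotic interval, and the paired relative increase
in eligible patients with a bootstrap interval.

Conventions
-----------
A :class:`TwoByTwoTable` stores ``a`` = both classifiers low, ``b`` =
column classifier high only, ``c`` = row classifier high only, ``d`` = both
high.  Kappa is invariant to transposition, and the specific-agreement
statistics depend only on the concordant diagonal and the total
discordance, so the orientation is purely cosmetic.

z for 95% intervals is the exact normal quantile 1.959964, whose difference
from 1.96 is far below printed rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
from scipy.stats import norm


class DegenerateTableError(Exception):
    """A statistic is undefined for this table (zero denominator)."""


class Estimate(NamedTuple):
    """A point estimate with a two-sided confidence interval."""

    value: float
    lower: float
    upper: float


@dataclass(frozen=True)
class TwoByTwoTable:
    """Paired binary classification counts.

    ``a``: both low; ``b``: column-classifier high only; ``c``:
    row-classifier high only; ``d``: both high.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.a, self.c, self.b, self.d)


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as statistical packages print."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cross_tabulate(
    flags_x: Sequence[bool], flags_y: Sequence[bool]
) -> TwoByTwoTable:
    """2x2 table from paired boolean sequences (x = rows, y = columns)."""
    if len(flags_x) != len(flags_y):
        raise ValueError(
            f"paired sequences differ in length: {len(flags_x)} vs {len(flags_y)}"
        )
    x = np.asarray(flags_x, dtype=bool)
    y = np.asarray(flags_y, dtype=bool)
    return TwoByTwoTable(
        a=int(np.sum(~x & ~y)),
        b=int(np.sum(~x & y)),
        c=int(np.sum(x & ~y)),
        d=int(np.sum(x & y)),
    )


def agresti_coull_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull confidence interval for a binomial proportion.

    Adds z^2/2 pseudo-successes and pseudo-failures before applying the
    Wald formula; bounds are clipped to [0, 1].
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    z = norm.ppf(1 - (1 - conf) / 2)
    n_tilde = n + z**2
    p_tilde = (x + z**2 / 2) / n_tilde
    half = z * np.sqrt(p_tilde * (1 - p_tilde) / n_tilde)
    return (max(p_tilde - half, 0.0), min(p_tilde + half, 1.0))


def observed_agreement(t: TwoByTwoTable, conf: float = 0.95) -> Estimate:
    """Proportion of concordant pairs, (a+d)/n, with an Agresti-Coull CI."""
    lo, hi = agresti_coull_ci(t.a + t.d, t.n, conf)
    return Estimate((t.a + t.d) / t.n, lo, hi)


def specific_agreement(
    t: TwoByTwoTable, which: Literal["high", "low"], conf: float = 0.95
) -> Estimate:
    """Specific (category-conditional) agreement with a delta-method CI.

    ``high``: 2d/(2d+b+c); ``low``: 2a/(2a+b+c).  The variance treats
    (concordant cell, total discordance) as two cells of a multinomial and
    propagates through the ratio — the delta method of Mackinnon (2000).
    """
    conc = t.d if which == "high" else t.a
    disc = t.b + t.c
    denom = 2 * conc + disc
    if denom == 0:
        raise DegenerateTableError(f"specific agreement ({which}) undefined: empty denominator")
    value = 2 * conc / denom
    n = t.n
    p_conc, p_disc = conc / n, disc / n
    q = 2 * p_conc + p_disc
    g_conc = 2 * p_disc / q**2
    g_disc = -2 * p_conc / q**2
    var = (
        g_conc**2 * p_conc * (1 - p_conc)
        + g_disc**2 * p_disc * (1 - p_disc)
        - 2 * g_conc * g_disc * p_conc * p_disc
    ) / n
    z = norm.ppf(1 - (1 - conf) / 2)
    half = z * np.sqrt(max(var, 0.0))
    return Estimate(value, max(value - half, 0.0), min(value + half, 1.0))


KappaBand = Literal["poor", "fair", "moderate", "substantial", "very_good"]


def kappa_band(kappa: float) -> KappaBand:
    """Verbal agreement band: <=0.20 poor, 0.21-0.40 fair, 0.41-0.60
    moderate, 0.61-0.80 substantial, >0.80 very good."""
    if kappa <= 0.20:
        return "poor"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "very_good"


def cohens_kappa(t: TwoByTwoTable, conf: float = 0.95) -> tuple[Estimate, KappaBand]:
    """Cohen's kappa with the Fleiss-Cohen-Everitt asymptotic CI.

    kappa = (p_o - p_e)/(1 - p_e), p_o the concordant fraction and p_e the
    chance agreement from the marginals.  The variance is the large-sample
    formula of Fleiss, Cohen & Everitt (1969), which reproduces the
    intervals printed by standard statistical software.
    """
    if t.n < 2:
        raise DegenerateTableError("kappa needs at least two observations")
    n = t.n
    p = np.array([[t.a, t.b], [t.c, t.d]], dtype=float) / n
    rows = p.sum(axis=1)
    cols = p.sum(axis=0)
    p_o = p[0, 0] + p[1, 1]
    p_e = float(rows @ cols)
    if p_e >= 1.0:
        raise DegenerateTableError("degenerate marginals: chance agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)

    one_minus_k = 1 - kappa
    term_a = sum(
        p[i, i] * (1 - (rows[i] + cols[i]) * one_minus_k) ** 2 for i in (0, 1)
    )
    term_b = one_minus_k**2 * sum(
        p[i, j] * (cols[i] + rows[j]) ** 2
        for i in (0, 1)
        for j in (0, 1)
        if i != j
    )
    term_c = (kappa - p_e * one_minus_k) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - p_e) ** 2)
    z = norm.ppf(1 - (1 - conf) / 2)
    half = z * np.sqrt(max(var, 0.0))
    est = Estimate(kappa, max(kappa - half, -1.0), min(kappa + half, 1.0))
    return est, kappa_band(kappa)


def cohens_kappa_bootstrap_ci(
    t: TwoByTwoTable,
    conf: float = 0.95,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile-bootstrap alternative to the asymptotic kappa interval."""
    rng = rng or np.random.default_rng()
    probs = np.array([t.a, t.b, t.c, t.d], dtype=float) / t.n
    counts = rng.multinomial(t.n, probs, size=n_boot)
    a, b, c, d = (counts[:, i] for i in range(4))
    p_o = (a + d) / t.n
    rows0, cols0 = (a + b) / t.n, (a + c) / t.n
    p_e = rows0 * cols0 + (1 - rows0) * (1 - cols0)
    valid = p_e < 1.0
    kappas = (p_o[valid] - p_e[valid]) / (1 - p_e[valid])
    alpha = (1 - conf) / 2
    return (float(np.quantile(kappas, alpha)), float(np.quantile(kappas, 1 - alpha)))


def relative_increase(
    count_new: int,
    count_ref: int,
    paired_flags: Optional[tuple[Sequence[bool], Sequence[bool]]] = None,
    conf: float = 0.95,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> Estimate:
    """Percent increase of one eligible count over another.

    Point estimate ``100 * (count_new - count_ref) / count_ref``.  When the
    per-patient flag pair is supplied, a paired patient-level bootstrap
    yields the percentile CI (the paired structure matters because the same
    people tend to be eligible under both rules); without it no interval is
    produced (NaN bounds).
    """
    if count_ref == 0:
        raise DegenerateTableError("relative increase undefined for a zero reference count")
    point = 100.0 * (count_new - count_ref) / count_ref
    if paired_flags is None:
        return Estimate(point, float("nan"), float("nan"))
    new_f = np.asarray(paired_flags[0], dtype=float)
    ref_f = np.asarray(paired_flags[1], dtype=float)
    if new_f.shape != ref_f.shape:
        raise ValueError("paired flag sequences differ in length")
    n = len(new_f)
    rng = rng or np.random.default_rng()
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_new = new_f[idx].sum(axis=1)
    boot_ref = ref_f[idx].sum(axis=1)
    valid = boot_ref > 0
    ratios = 100.0 * (boot_new[valid] - boot_ref[valid]) / boot_ref[valid]
    alpha = (1 - conf) / 2
    return Estimate(
        point, float(np.quantile(ratios, alpha)), float(np.quantile(ratios, 1 - alpha))
    )


@dataclass(frozen=True)
class AgreementSummary:
    """All agreement statistics for one 2x2 comparison."""

    table: TwoByTwoTable
    observed: Estimate
    agreement_high: Estimate
    agreement_low: Estimate
    kappa: Estimate
    kappa_band: KappaBand


def summarize_agreement(t: TwoByTwoTable, conf: float = 0.95) -> AgreementSummary:
    """Observed, specific, and chance-corrected agreement for one table."""
    kappa, band = cohens_kappa(t, conf)
    return AgreementSummary(
        table=t,
        observed=observed_agreement(t, conf),
        agreement_high=specific_agreement(t, "high", conf),
        agreement_low=specific_agreement(t, "low", conf),
        kappa=kappa,
        kappa_band=band,
    )
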