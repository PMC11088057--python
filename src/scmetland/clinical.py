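"""Immunoreactivity scoring and clinicopathological association tests.

Tumor sections are scored semi-quantitatively: staining intensity 0-3
times percent-positive grade 1-3 gives the immunoreactivity score (IRS,
attainable values 0,1,2,3,4,6,9); IRS >= 4 dichotomizes patients into
high vs low expressors. Each binary clinicopathological feature then
forms a 2x2 table against the expression class and is tested with a
two-sided Fisher's exact test using the point-probability convention:
the p-value sums the hypergeometric probabilities of every table with
the same margins whose point probability does not exceed the observed
one. The summation runs in log space via the exact hypergeometric pmf.
Other two-sided conventions (e.g. doubling the one-sided tail) give
different numbers; the point-probability convention is the one that
matches standard R/scipy behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import IhcCohort
from .errors import ValidationError

ALPHA_DEFAULT = 0.05

# relative slack when comparing log point probabilities; absorbs float
# round-off between tables that are exactly tied (R uses the same device)
_REL_TIE_EPS = 1e-7


def score_cohort(cohort: IhcCohort) -> pd.DataFrame:
    """Return the cohort table with derived IRS and high/low class.

    Derivation happens on cohort construction (IRS = intensity x grade,
    high iff IRS >= 4); this accessor re-validates and hands back the
    scored table.
    """
    return IhcCohort(cohort.table, cohort.feature_columns).table


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): rows feature yes/no, columns expression high/low."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not float(v).is_integer() or v < 0:
                raise ValidationError(f"contingency counts must be nonnegative integers, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def build_tables(
    cohort: IhcCohort,
    features: list[str] | tuple[str, ...] | None = None,
) -> dict[str, ContingencyTable2x2]:
    """Tally one 2x2 table (yes/no x high/low) per clinical feature."""
    if len(cohort) == 0:
        raise ValidationError("cohort is empty; no tables to build")
    features = list(features) if features is not None else list(cohort.feature_columns)
    tables: dict[str, ContingencyTable2x2] = {}
    for feat in features:
        if feat not in cohort.table.columns:
            raise ValidationError(f"feature {feat!r} not in cohort")
        col = cohort.table[feat]
        bad = set(col.unique()) - {"yes", "no"}
        if bad:
            raise ValidationError(f"feature {feat!r} is not binary: {sorted(bad)}")
        cls = cohort.table["expression_class"]
        tables[feat] = ContingencyTable2x2(
            a=int(((col == "yes") & (cls == "high")).sum()),
            b=int(((col == "yes") & (cls == "low")).sum()),
            c=int(((col == "no") & (cls == "high")).sum()),
            d=int(((col == "no") & (cls == "low")).sum()),
        )
    return tables


@dataclass
class AssociationResult:
    feature: str
    table: ContingencyTable2x2
    p_value: float
    odds_ratio: float
    significant: bool
    p_adjusted: float | None = None


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test; returns (p, odds ratio).

    With margins fixed, cell a follows a hypergeometric distribution;
    the two-sided p sums P(a') over every admissible a' whose point
    probability is no larger than the observed one (up to a 1e-7
    relative tie tolerance in log space). A degenerate table (any zero
    margin) is uninformative: p = 1 with a warning.

    The odds ratio is the sample OR ad/bc, with the Haldane 0.5
    correction applied to every cell when any cell is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        p = 1.0
    else:
        lo = max(0, c1 - r2)
        hi = min(r1, c1)
        support = np.arange(lo, hi + 1)
        # hypergeom(M=population, n=successes, N=draws), pmf at k
        logpmf = stats.hypergeom.logpmf(support, n, c1, r1)
        log_obs = stats.hypergeom.logpmf(a, n, c1, r1)
        keep = logpmf <= log_obs + _REL_TIE_EPS * abs(log_obs) + 1e-300
        p = float(np.exp(logpmf[keep]).sum())
        p = min(p, 1.0)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return p, float(odds)


def associate(
    cohort: IhcCohort,
    features: list[str] | tuple[str, ...] | None = None,
    alpha: float = ALPHA_DEFAULT,
    adjust: bool = False,
) -> list[AssociationResult]:
    """Fisher's exact association of every feature with the IRS class.

    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values across the
    tested features (the significance flag still uses the raw p, which
    is how such tables are conventionally presented).
    """
    tables = build_tables(cohort, features)
    results = []
    for feat, tab in tables.items():
        p, odds = fisher_exact_2x2(tab)
        results.append(AssociationResult(feat, tab, p, odds, p <= alpha))
    if adjust and results:
        padj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, q in zip(results, padj):
            r.p_adjusted = float(q)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Publication-style table: one row per feature with the 2x2 counts."""
    rows = []
    for r in results:
        t = r.table
        rows.append({
            "feature": r.feature,
            "yes_high": t.a, "yes_low": t.b, "no_high": t.c, "no_low": t.d,
            "odds_ratio": r.odds_ratio, "p_value": r.p_value,
            "p_adjusted": r.p_adjusted, "significant": r.significant,
        })
    return pd.DataFrame(rows)
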