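"""Fisher's exact enrichment of positive selection in NEMs.

At each significance level, genes with BUSTED p at or below the level are
"positively selected"; the 2x2 table NEM-status x selected over all records
is tested with the two-sided Fisher's exact test (summing hypergeometric
probabilities no larger than the observed table's).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import DataValidationError

DEFAULT_LEVELS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fisher's exact enrichment at one significance level.

    The odds ratio is the sample (cross-product) ratio ad/bc, reported as
    ``inf`` when only the bc denominator vanishes and NaN when the table is
    degenerate.
    """

    level: float
    nem_selected: int
    nem_not: int
    nonnem_selected: int
    nonnem_not: int
    odds_ratio: float
    p_two_sided: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "nem_selected": self.nem_selected,
            "nem_not": self.nem_not,
            "nonnem_selected": self.nonnem_selected,
            "nonnem_not": self.nonnem_not,
            "odds_ratio": self.odds_ratio,
            "p_two_sided": self.p_two_sided,
            "flags": list(self.flags),
        }


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 count table.

    Returns (sample odds ratio ad/bc, two-sided p).  Counts must be
    nonnegative with at least one positive margin.
    """
    (a, b), (c, d) = table
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise DataValidationError("counts must be nonnegative")
    if sum(counts) == 0:
        raise DataValidationError("all-zero table")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, p


def enrichment_test(records: pd.DataFrame, levels=DEFAULT_LEVELS) -> list[EnrichmentResult]:
    """Fisher enrichment of NEMs among selected genes at each level."""
    out = []
    for level in levels:
        if not (0.0 < level < 1.0):
            raise DataValidationError(f"level {level} outside (0, 1)")
        selected = records["busted_p"] <= level
        is_nem = records["nem_status"] == "NEM"
        a = int((is_nem & selected).sum())
        b = int((is_nem & ~selected).sum())
        c = int((~is_nem & selected).sum())
        d = int((~is_nem & ~selected).sum())
        flags: tuple[str, ...] = ()
        if a + c == 0:
            odds, p = math.nan, 1.0
            flags = ("no_selected_genes",)
        else:
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
        out.append(
            EnrichmentResult(
                level=level,
                nem_selected=a,
                nem_not=b,
                nonnem_selected=c,
                nonnem_not=d,
                odds_ratio=odds,
                p_two_sided=p,
                flags=flags,
            )
        )
    return out
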