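"""Chi-squared motif enrichment with Yates' continuity correction.

The baseline method (CT): for every motif, genes are dichotomized into
with / without at least one retained hit, cross-tabulated against the
positive / negative labels, and tested on the resulting 2x2 table. The
top 10 motifs per cluster are ranked by -log10 p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .scan import HitCountMatrix

#: minimum number of genes with hits for a motif to be testable
MIN_GENES_WITH_HITS = 5


@dataclass
class ContingencyTable:
    """2x2 table: hit presence (rows collapsed) vs positive/negative."""

    a: int  # positive genes with >= 1 hit
    b: int  # positive genes without
    c: int  # negative genes with >= 1 hit
    d: int  # negative genes without

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def build_contingency(matrix: HitCountMatrix, motif: str) -> ContingencyTable:
    """Presence/absence dichotomization of one motif's counts per gene."""
    if motif not in matrix.motifs:
        raise KeyError(f"motif {motif!r} absent from matrix")
    j = matrix.motifs.index(motif)
    present = matrix.counts[:, j] >= 1
    pos = matrix.label_array() == 1
    return ContingencyTable(
        a=int(np.sum(present & pos)),
        b=int(np.sum(~present & pos)),
        c=int(np.sum(present & ~pos)),
        d=int(np.sum(~present & ~pos)),
    )


def chi2_yates(table: ContingencyTable) -> tuple[float, float]:
    """Yates-corrected chi-squared statistic and upper-tail p (df = 1).

    chi2 = N * max(|ad - bc| - N/2, 0)^2 / ((a+b)(c+d)(a+c)(b+d)).
    Raises on a zero margin, where the test is inapplicable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-squared test inapplicable: zero margin")
    n = table.n
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p


def enrichment_table(
    matrix: HitCountMatrix, min_genes_with_hits: int = MIN_GENES_WITH_HITS
) -> pd.DataFrame:
    """Per-motif CT results; motifs failing eligibility are marked untested.

    Eligibility requires at least ``min_genes_with_hits`` genes with a
    hit of the motif (the test's validity requirement) and non-zero
    margins.
    """
    rows = []
    for motif in matrix.motifs:
        t = build_contingency(matrix, motif)
        tested = (t.a + t.c) >= min_genes_with_hits and min(t.margins()) > 0
        stat = p = neglog = np.nan
        if tested:
            stat, p = chi2_yates(t)
            neglog = -math.log10(p) if p > 0 else np.inf
        rows.append(
            {
                "motif": motif,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "chi2": stat,
                "p": p,
                "neglog10p": neglog,
                "tested": tested,
            }
        )
    df = pd.DataFrame(rows)
    # rank among tested motifs: descending -log10 p, then larger chi2,
    # then lexicographic motif id
    tested_df = df[df["tested"]].sort_values(
        ["neglog10p", "chi2", "motif"], ascending=[False, False, True]
    )
    df["rank"] = np.nan
    df.loc[tested_df.index, "rank"] = np.arange(1, len(tested_df) + 1)
    return df


def rank_ct(results: pd.DataFrame, k: int = 10) -> list[str]:
    """Top-k tested motifs by -log10 p (ties: larger chi2, then id)."""
    tested = results[results["tested"]]
    if len(tested) == 0:
        raise ValueError("no tested motifs to rank")
    ordered = tested.sort_values(
        ["neglog10p", "chi2", "motif"], ascending=[False, False, True]
    )
    return list(ordered["motif"].head(k))
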