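"""Chromosome representation of clock CpGs versus the training background.

For each chromosome, a 2x2 Fisher's exact test compares the clock's retained
CpGs against the non-selected CpGs of the training set::

              on chromosome   off chromosome
    selected        a               b
    non-selected    c               d

The two-sided p-value is the standard exact convention: the sum of
hypergeometric point probabilities not exceeding that of the observed table.
Unplaced scaffolds are pooled into one "unplaced" category.  No multiple-
testing correction is applied by default (per-chromosome results are
reported raw); Benjamini-Hochberg q-values are available behind a flag.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["chromosome_enrichment", "fisher_two_sided"]

UNPLACED = "unplaced"


def fisher_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(odds ratio, two-sided exact p) for the 2x2 table [[a, b], [c, d]]."""
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def chromosome_enrichment(
    selected: Iterable[str],
    background: Iterable[str],
    chrom_map: Mapping[str, str],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-chromosome over/under-representation of selected CpGs.

    Parameters
    ----------
    selected
        Site ids retained by the final clock; must be a subset of
        ``background``.
    background
        All site ids of the clock's training matrix.
    chrom_map
        Site id -> chromosome label; sites absent from the map are pooled
        as ``"unplaced"``.
    bh_correction
        Add a Benjamini-Hochberg ``q`` column.

    Returns one row per chromosome with the 2x2 counts, odds ratio,
    two-sided p and a direction flag ("over"/"under") given by the sign of
    observed minus expected selected count under proportional representation.
    """
    selected = set(selected)
    background = set(background)
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected sites not in background: {extra}")
    chrom_of = {s: chrom_map.get(s, UNPLACED) for s in background}
    frame = pd.DataFrame(
        {
            "chrom": [chrom_of[s] for s in background],
            "selected": [s in selected for s in background],
        }
    )
    n_sel = len(selected)
    n_bg_rest = len(background) - n_sel
    rows = []
    for chrom, sub in frame.groupby("chrom", sort=True):
        a = int(sub["selected"].sum())           # selected on chromosome
        b = n_sel - a                            # selected elsewhere
        c = int((~sub["selected"]).sum())        # non-selected on chromosome
        d = n_bg_rest - c
        odds, p = fisher_two_sided(a, b, c, d)
        expected = n_sel * len(sub) / len(background)
        rows.append(
            {
                "chromosome": chrom,
                "selected_on": a,
                "selected_off": b,
                "background_on": c,
                "background_off": d,
                "odds_ratio": odds,
                "p_value": p,
                "direction": "over" if a >= expected else "under",
            }
        )
    table = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
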