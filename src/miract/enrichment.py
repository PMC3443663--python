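"""Functional representation of target gene sets via the EASE score.

The EASE score is a conservative variant of the one-sided Fisher exact
enrichment test: the overlap between the hit list and a biological theme is
reduced by one (floored at zero) before computing the hypergeometric upper
tail, which penalises themes supported by a single gene.  Raw scores across
a theme collection are adjusted by Benjamini-Hochberg ("global FDR").

Theme collections are user-supplied GMT files; the default universe is the
expression matrix's gene complement (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import TargetSetCollection, write_table

# A theme collection is structurally identical to a target-set collection
# (named gene sets read from GMT), so the same container is reused.
ThemeCollection = TargetSetCollection


def _enrichment_p(overlap: int, n_universe: int, n_theme: int,
                  n_hits: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(min(stats.hypergeom.sf(overlap - 1, n_universe, n_theme,
                                        n_hits), 1.0))


def ease_score(hit_genes: Iterable[str], theme_genes: Iterable[str],
               universe: Iterable[str]) -> tuple[float, float, dict[str, int]]:
    """(ease_p, fisher_p, counts) for one theme against one hit list.

    ``fisher_p`` is the one-sided Fisher exact enrichment p; ``ease_p`` is
    the same computation with the overlap count reduced by one (floor 0).
    Empty hit lists give both p = 1.
    """
    hits = frozenset(hit_genes)
    theme = frozenset(theme_genes)
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    if not hits <= uni or not theme <= uni:
        raise ValueError("hit and theme genes must be contained in universe")
    overlap = len(hits & theme)
    counts = {
        "overlap": overlap,
        "n_hits": len(hits),
        "n_theme": len(theme),
        "n_universe": len(uni),
    }
    if not hits:
        return 1.0, 1.0, counts
    fisher_p = _enrichment_p(overlap, len(uni), len(theme), len(hits))
    ease_p = _enrichment_p(max(overlap - 1, 0), len(uni), len(theme),
                           len(hits))
    return ease_p, fisher_p, counts


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(hit_genes: Iterable[str], themes: ThemeCollection,
                     universe: Iterable[str]) -> pd.DataFrame:
    """Score every theme against one hit list; BH-adjust the EASE scores.

    Themes are restricted to the universe first; themes with no gene in the
    universe are dropped.
    """
    uni = frozenset(universe)
    hits = frozenset(hit_genes) & uni
    rows = []
    for theme_id in themes.mirna_ids:
        theme = frozenset(themes[theme_id]) & uni
        if not theme:
            continue
        ease_p, fisher_p, counts = ease_score(hits, theme, uni)
        rows.append({"theme": theme_id, **counts,
                     "fisher_p": fisher_p, "ease_p": ease_p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["bh_fdr"] = bh_adjust(df["ease_p"])
        df = df.sort_values(["ease_p", "theme"]).reset_index(drop=True)
    return df


def write_enrichment(df: pd.DataFrame, path: str | Path,
                     comments: Iterable[str] = ()) -> None:
    write_table(df, path, comments, index=False)
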