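"""Gene-panel bookkeeping, set overlap and chi-square enrichment.

The rapamycin-regulated panel was assembled from 1033 up- and 94
down-regulated genes found in lymphocytes (1127) plus 38 literature-derived
mTOR targets, for 1165 genes in all.  The screen's headline counts are
simple set arithmetic over that panel (shared and stage-specific signature
tiers), and enrichment against an external disease gene set is a Pearson
chi-square on the panel-vs-rest-of-genome 2x2 table.  The default gene
universe is 20,000 protein-coding genes (the printed percentages imply it:
1165 ~ 5.82%, 519 ~ 2.59%), configurable.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.stats import chi2_contingency

__all__ = ["PanelComposition", "panel_composition", "percent", "tier_counts",
           "overlap_and_enrichment", "load_gene_list", "packaged_gene_list",
           "DEFAULT_UNIVERSE"]

DEFAULT_UNIVERSE = 20_000


@dataclass(frozen=True)
class PanelComposition:
    n_up_lymphocyte: int
    n_down_lymphocyte: int
    n_literature: int

    @property
    def n_lymphocyte(self) -> int:
        return self.n_up_lymphocyte + self.n_down_lymphocyte

    @property
    def n_total(self) -> int:
        return self.n_lymphocyte + self.n_literature

    def fraction_of_genome(self, universe: int = DEFAULT_UNIVERSE,
                           decimals: int = 2) -> float:
        return percent(self.n_total, universe, decimals)


def panel_composition(n_up_lymphocyte: int = 1033, n_down_lymphocyte: int = 94,
                      n_literature: int = 38) -> PanelComposition:
    """Panel membership arithmetic (defaults are the study's panel)."""
    return PanelComposition(n_up_lymphocyte, n_down_lymphocyte, n_literature)


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded to the printed precision."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round(100.0 * numerator / denominator, decimals)


def tier_counts(shared_up: int, shared_down: int, stage_a_only: int,
                stage_b_only: int) -> dict:
    """Shared/stage-specific tier totals for the signature structure."""
    return {"shared": shared_up + shared_down,
            "stage_specific": stage_a_only + stage_b_only,
            "total": shared_up + shared_down + stage_a_only + stage_b_only}


def overlap_and_enrichment(panel: set, reference: set, universe_size: int,
                           altered_in_panel: int | None = None,
                           altered_in_rest: int | None = None) -> dict:
    """Overlap of two gene sets plus a 2x2 Pearson chi-square enrichment.

    Symbols are uppercase-normalised before intersection.  The 2x2 table is
    {panel vs rest-of-universe} x {altered/associated vs not}: by default the
    "altered/associated" margin is the reference set itself
    (``altered_in_panel`` = overlap size, ``altered_in_rest`` = reference
    genes outside the panel); both counts can be overridden, e.g. to compare
    the panel's differentially-expressed fraction against the genome-wide
    disease-associated fraction.  The statistic is reported both with and
    without the Yates continuity correction.
    """
    panel = {str(g).upper() for g in panel}
    reference = {str(g).upper() for g in reference}
    if universe_size <= 0:
        raise ValueError("empty universe")
    if universe_size < len(panel | reference):
        raise ValueError("universe smaller than the union of the gene sets")
    overlap = sorted(panel & reference)
    a = len(overlap) if altered_in_panel is None else int(altered_in_panel)
    rest = universe_size - len(panel)
    c = (len(reference) - len(overlap) if altered_in_rest is None
         else int(altered_in_rest))
    table = np.array([[a, len(panel) - a], [c, rest - c]], dtype=float)
    if np.any(table < 0):
        raise ValueError(f"inconsistent 2x2 table: {table.tolist()}")
    chi2_plain = chi2_contingency(table, correction=False)
    chi2_corr = chi2_contingency(table, correction=True)
    return {
        "overlap": overlap,
        "n_overlap": len(overlap),
        "table": table.astype(int).tolist(),
        "chi2": float(chi2_plain.statistic),
        "p_value": float(chi2_plain.pvalue),
        "chi2_continuity": float(chi2_corr.statistic),
        "p_value_continuity": float(chi2_corr.pvalue),
    }


def load_gene_list(path) -> set:
    """Read a one-symbol-per-line gene list, uppercase-normalised."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def packaged_gene_list(name: str) -> set:
    """Load one of the synthetic gene lists shipped with the package.

    Available: ``"mtor_panel_synthetic"`` (a 1165-symbol stand-in panel) and
    ``"apoe_regulated_synthetic"`` (a 154-symbol stand-in for an
    ApoE-allele-regulated list).  Both are synthetic: only the six genes in
    their intersection (A2M, B2M, GSN, LRP1, DDIT4, MAL) are real symbols;
    the rest are placeholder ids.
    """
    ref = resources.files("rapatest").joinpath("data", f"{name}.txt")
    return {line.strip().upper() for line in ref.read_text().splitlines()
            if line.strip()}
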