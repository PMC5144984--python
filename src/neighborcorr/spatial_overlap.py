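"""Tissue-expression overlap of gene pairs from in situ-style annotations.

Each gene carries a set of tissue terms (e.g. from RNA in situ hybridization
atlases).  The overlap of a pair is the Jaccard percentage — common tissues
over total unique tissues — which is then pushed through the same sliding
median and exponential decay fit used for expression correlation, yielding a
characteristic distance for spatial (tissue-level) coexpression.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .decay_model import DecayFit, SmoothedCurve, fit_exponential_decay, sliding_median
from .genome_pairs import PairTable

logger = logging.getLogger(__name__)

OVERLAP_BOUNDS = ((0.0, 200.0), (1e-15, np.inf), (-100.0, 100.0))


class TissueAnnotation:
    """Mapping gene_id -> set of case-normalized tissue terms."""

    def __init__(self, mapping: dict[str, set[str]]):
        clean: dict[str, set[str]] = {}
        for gene, terms in mapping.items():
            terms = {t.strip().lower() for t in terms if t.strip()}
            if terms:
                clean[gene] = terms
        self.mapping = clean

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping

    def get(self, gene: str) -> set[str] | None:
        return self.mapping.get(gene)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TissueAnnotation":
        """Read one (gene_id, tissue) assignment per row."""
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "tissue"} <= set(df.columns):
            raise ValueError(f"{path}: need columns gene_id, tissue")
        mapping: dict[str, set[str]] = {}
        for gene, tissue in zip(df["gene_id"].astype(str), df["tissue"].astype(str)):
            mapping.setdefault(gene, set()).add(tissue)
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (g, t) for g, terms in self.mapping.items() for t in sorted(terms)
        ]
        pd.DataFrame(rows, columns=["gene_id", "tissue"]).to_csv(
            path, sep="\t", index=False
        )


def tissue_overlap(a: set[str], b: set[str]) -> float:
    """Percentage overlap: 100 * |a & b| / |a | b|, in [0, 100]."""
    if not a or not b:
        raise ValueError("tissue sets must be non-empty")
    return 100.0 * len(a & b) / len(a | b)


def pair_overlaps(ann: TissueAnnotation, pairs: PairTable) -> pd.DataFrame:
    """Overlap for every pair with both genes annotated.

    Pairs with an unannotated member are skipped (count logged).  Returns a
    DataFrame with columns ``gene_a, gene_b, distance_bp, overlap``.
    """
    df = pairs.df
    keep = df["gene_a"].isin(ann.mapping) & df["gene_b"].isin(ann.mapping)
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.info("skipping %d pairs lacking tissue annotation", n_skipped)
    sub = df.loc[keep, ["gene_a", "gene_b", "distance_bp"]].reset_index(drop=True)
    sub["overlap"] = [
        tissue_overlap(ann.mapping[a], ann.mapping[b])
        for a, b in zip(sub["gene_a"], sub["gene_b"])
    ]
    return sub


def overlap_vs_distance(
    ann: TissueAnnotation,
    pairs: PairTable,
    window: int = 1000,
) -> tuple[SmoothedCurve, DecayFit]:
    """Tissue-overlap decay with distance: smooth then fit.

    Delegates to :func:`sliding_median` and :func:`fit_exponential_decay`
    with bounds widened to the percentage scale; the fit's ``dexp`` is in bp.
    """
    overlaps = pair_overlaps(ann, pairs)
    curve = sliding_median(
        overlaps, window=window, value_col="overlap", statistic_name="overlap"
    )
    fit = fit_exponential_decay(curve, bounds=OVERLAP_BOUNDS)
    return curve, fit
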