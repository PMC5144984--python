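"""Distance-controlled group comparisons (orientation and insulator strata).

Gene pairs grouped by strand orientation, or by whether an insulator binding
site lies between their TSSs, show different correlation distributions — but
the groups also have very different intergenic-distance distributions, and
distance itself drives correlation.  This module reproduces that dissection:
compare raw group correlation distributions, then control the distance
confound either by restricting all groups to a shared absolute distance
window (e.g. 30-40 kb) or by histogram-matching the distance distributions
via per-bin downsampling, and compare again.

Insulator binding intervals arrive as BED replicates; the replicate
intersection is used, and a pair is "flanked" by a factor when at least one
intersected site overlaps the open interval between the pair's TSSs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.stats

from .genome_pairs import GeneTable, PairTable

logger = logging.getLogger(__name__)

KS_MATCH_THRESHOLD = 0.05
DEFAULT_MIN_GROUP = 10


@dataclass
class IntervalSet:
    """Genomic intervals for one factor, 0-based half-open, BED-style.

    ``df`` columns: ``Chromosome, Start, End`` (pyranges convention), sorted
    by (Chromosome, Start).
    """

    factor: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"Chromosome", "Start", "End"} - set(self.df.columns)
        if missing:
            raise ValueError(f"interval set missing columns: {sorted(missing)}")
        if len(self.df) and ((self.df["Start"] < 0) | (self.df["Start"] >= self.df["End"])).any():
            raise ValueError("intervals must satisfy 0 <= start < end")
        self.df = (
            self.df[["Chromosome", "Start", "End"]]
            .sort_values(["Chromosome", "Start"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, factor: str) -> "IntervalSet":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["Chromosome", "Start", "End"],
            dtype={"Chromosome": str},
        )
        return cls(factor=factor, df=df)

    def to_bed(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class GroupComparison:
    """Per-group correlation/distance distributions after (optional) control.

    ``groups`` maps label -> DataFrame with at least ``rho`` and
    ``distance_bp`` columns.  ``sampled`` is True after histogram matching;
    ``distance_window`` records a (lo, hi) bp restriction when window mode
    was used.
    """

    groups: dict[str, pd.DataFrame]
    sampled: bool = False
    distance_window: tuple[float, float] | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def medians(self) -> dict[str, float]:
        return {g: float(df["rho"].median()) for g, df in self.groups.items()}

    def summary(self) -> pd.DataFrame:
        """Group sizes, medians, and KS distance of each group's distance
        distribution against the first (reference) group."""
        ref_label = self.labels[0]
        ref = self.groups[ref_label]["distance_bp"].to_numpy()
        rows = []
        for g, df in self.groups.items():
            ks = (
                0.0
                if g == ref_label
                else float(scipy.stats.ks_2samp(df["distance_bp"], ref).statistic)
            )
            rows.append(
                (
                    g,
                    len(df),
                    float(df["rho"].median()),
                    float(df["distance_bp"].median()),
                    ks,
                )
            )
        return pd.DataFrame(
            rows, columns=["group", "n", "median_rho", "median_distance", "ks_vs_reference"]
        )

    def median_cis(
        self, n_boot: int = 1000, seed: int = 0
    ) -> dict[str, tuple[float, float]]:
        """Percentile bootstrap 95% CI of each group's median rho."""
        rng = np.random.default_rng(seed)
        out = {}
        for g, df in self.groups.items():
            x = df["rho"].to_numpy()
            boots = np.median(
                x[rng.integers(0, x.size, size=(n_boot, x.size))], axis=1
            )
            lo, hi = np.percentile(boots, [2.5, 97.5])
            out[g] = (float(lo), float(hi))
        return out

    def to_long_tsv(self, path: str | Path, control_mode: str = "raw") -> None:
        frames = []
        for g, df in self.groups.items():
            sub = df[["gene_a", "gene_b", "distance_bp", "rho"]].copy()
            sub.insert(0, "group", g)
            sub.insert(1, "control_mode", control_mode)
            frames.append(sub)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# insulator intervals
# ---------------------------------------------------------------------------


def intersect_replicates(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Maximal intervals covered by both replicates (interval intersection)."""
    if rep1.factor != rep2.factor:
        raise ValueError(
            f"replicate factors differ: {rep1.factor!r} vs {rep2.factor!r}"
        )
    if not len(rep1) or not len(rep2):
        logger.warning("factor %s: a replicate is empty", rep1.factor)
        return IntervalSet(rep1.factor, rep1.df.iloc[0:0])
    a = pr.PyRanges(rep1.df).merge()
    b = pr.PyRanges(rep2.df).merge()
    inter = a.intersect(b).merge()
    out = inter.df if len(inter) else rep1.df.iloc[0:0]
    out = out.reset_index(drop=True).astype({"Chromosome": str})
    if not len(out):
        logger.warning("factor %s: replicates do not intersect", rep1.factor)
    return IntervalSet(rep1.factor, out)


def flag_flanked_pairs(
    pairs: PairTable,
    sites: dict[str, IntervalSet],
    genes: GeneTable,
    mode: str = "between",
) -> PairTable:
    """Flag pairs with an insulator site between their TSSs, per factor.

    ``mode='between'`` (default) flags a pair for factor F when at least one
    F interval overlaps the open genomic interval between the two TSSs.
    ``mode='outside'`` is the bracketing reading: sites on both distal sides
    of the pair and none between.
    """
    if mode not in ("between", "outside"):
        raise ValueError(f"unknown mode {mode!r}")
    tss = genes.df.set_index("gene_id")["tss"]
    df = pairs.df.copy()
    ta = tss.loc[df["gene_a"]].to_numpy(dtype=np.int64)
    tb = tss.loc[df["gene_b"]].to_numpy(dtype=np.int64)
    lo = np.minimum(ta, tb)
    hi = np.maximum(ta, tb)
    chroms = df["chromosome"].to_numpy()

    pair_chroms = set(df["chromosome"].unique())
    for factor, iset in sites.items():
        site_chroms = set(iset.df["Chromosome"].unique())
        if len(iset) and not (site_chroms & pair_chroms):
            raise ValueError(
                f"factor {factor}: no shared chromosome names; "
                f"sites use {sorted(site_chroms)[:4]}, pairs use "
                f"{sorted(pair_chroms)[:4]}"
            )

    for factor, iset in sites.items():
        between = np.zeros(len(df), dtype=bool)
        for chrom, sub in iset.df.groupby("Chromosome", sort=False):
            sel = np.flatnonzero(chroms == chrom)
            if not sel.size:
                continue
            # 1-based inclusive site coords: [Start+1, End]
            s1 = np.sort(sub["Start"].to_numpy(dtype=np.int64) + 1)
            order = np.argsort(sub["Start"].to_numpy(), kind="stable")
            e1 = np.maximum.accumulate(sub["End"].to_numpy(dtype=np.int64)[order])
            # site overlaps open (lo, hi) iff s1 < hi and e1 > lo
            cnt = np.searchsorted(s1, hi[sel], side="left")
            has = cnt > 0
            runmax = np.where(has, e1[np.maximum(cnt - 1, 0)], np.iinfo(np.int64).min)
            between[sel] = has & (runmax > lo[sel])
        if mode == "between":
            df[f"flank_{factor}"] = between
        else:
            left = np.zeros(len(df), dtype=bool)
            right = np.zeros(len(df), dtype=bool)
            for chrom, sub in iset.df.groupby("Chromosome", sort=False):
                sel = np.flatnonzero(chroms == chrom)
                if not sel.size:
                    continue
                starts = np.sort(sub["Start"].to_numpy(dtype=np.int64) + 1)
                ends = np.sort(sub["End"].to_numpy(dtype=np.int64))
                left[sel] = np.searchsorted(ends, lo[sel], side="left") > 0
                right[sel] = np.searchsorted(starts, hi[sel], side="right") < len(starts)
            df[f"flank_{factor}"] = left & right & ~between
    return PairTable(df, k=pairs.k)


def attach_pair_flags(corr: pd.DataFrame, pairs: PairTable) -> pd.DataFrame:
    """Merge per-factor flanking flags (and rank separation) onto a
    correlation table, keyed by (gene_a, gene_b)."""
    flag_cols = [c for c in pairs.df.columns if c.startswith("flank_")]
    keep = ["gene_a", "gene_b", "rank_separation"] + flag_cols
    return corr.merge(pairs.df[keep], on=["gene_a", "gene_b"], how="left")


# ---------------------------------------------------------------------------
# grouping and distance control
# ---------------------------------------------------------------------------


def orientation_groups(
    corr: pd.DataFrame, max_distance: float | None = None
) -> dict[str, pd.DataFrame]:
    """Split a correlation table by orientation class, optionally keeping
    only pairs closer than ``max_distance`` bp (raw Fig-style comparison)."""
    df = corr if max_distance is None else corr[corr["distance_bp"] < max_distance]
    return {
        o: sub.reset_index(drop=True)
        for o, sub in df.groupby("orientation", sort=True)
    }


def insulator_groups(
    corr_flagged: pd.DataFrame, factor: str, max_distance: float | None = None
) -> dict[str, pd.DataFrame]:
    """Split into flanked / not-flanked groups for one insulator factor."""
    col = f"flank_{factor}"
    if col not in corr_flagged.columns:
        raise KeyError(f"missing {col}; run flag_flanked_pairs + attach_pair_flags")
    df = (
        corr_flagged
        if max_distance is None
        else corr_flagged[corr_flagged["distance_bp"] < max_distance]
    )
    flagged = df[col].fillna(False).astype(bool)
    return {
        f"not_{factor}": df[~flagged].reset_index(drop=True),
        factor: df[flagged].reset_index(drop=True),
    }


def distance_window_subset(
    groups: dict[str, pd.DataFrame],
    lo: float,
    hi: float,
    min_pairs: int = DEFAULT_MIN_GROUP,
) -> GroupComparison:
    """Restrict every group to pairs with lo <= distance < hi.

    Errors if the window empties (or nearly empties) a group, naming it.
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi})")
    out = {}
    for g, df in groups.items():
        sub = df[(df["distance_bp"] >= lo) & (df["distance_bp"] < hi)]
        if len(sub) < min_pairs:
            raise ValueError(
                f"group {g!r} has {len(sub)} pairs in window [{lo}, {hi}) "
                f"(minimum {min_pairs})"
            )
        out[g] = sub.reset_index(drop=True)
    return GroupComparison(out, sampled=False, distance_window=(lo, hi))


def histogram_matched_sample(
    groups: dict[str, pd.DataFrame],
    bin_width: float = 1000.0,
    seed: int = 0,
    min_pairs: int = DEFAULT_MIN_GROUP,
) -> GroupComparison:
    """Downsample groups so their distance histograms coincide.

    Within every distance bin shared by all groups, each group is sampled
    down (without replacement) to the smallest per-group bin count.  The
    matching criterion — a two-sample Kolmogorov-Smirnov statistic <= 0.05
    between every pair of post-sampling distance distributions — is asserted
    and reported.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to match")
    rng = np.random.default_rng(seed)
    binned = {
        g: np.floor(df["distance_bp"].to_numpy() / bin_width).astype(np.int64)
        for g, df in groups.items()
    }
    shared = set.intersection(*(set(b) for b in binned.values()))
    if not shared:
        raise ValueError("groups have no shared distance bins")

    out: dict[str, list[pd.DataFrame]] = {g: [] for g in groups}
    for b in sorted(shared):
        take = min(int((binned[g] == b).sum()) for g in groups)
        for g, df in groups.items():
            members = np.flatnonzero(binned[g] == b)
            chosen = rng.choice(members, size=take, replace=False)
            out[g].append(df.iloc[np.sort(chosen)])
    matched = {
        g: pd.concat(parts, ignore_index=True) for g, parts in out.items()
    }
    for g, df in matched.items():
        if len(df) < min_pairs:
            raise ValueError(
                f"group {g!r} reduced to {len(df)} pairs after matching"
            )
    labels = list(matched)
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            ks = scipy.stats.ks_2samp(
                matched[gi]["distance_bp"], matched[gj]["distance_bp"]
            ).statistic
            if ks > KS_MATCH_THRESHOLD:
                logger.warning(
                    "post-matching KS(%s, %s) = %.3f exceeds %.2f",
                    gi,
                    gj,
                    ks,
                    KS_MATCH_THRESHOLD,
                )
    return GroupComparison(matched, sampled=True)
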