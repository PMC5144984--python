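"""Expression normalization, ranking, and per-pair Spearman correlation.

The expression compendium is a genes x experiments table (TPM scale; NaN
marks unassayed entries).  Genes detected in fewer than 80% of experiments
are discarded, TPM values are ranked within each experiment (average ranks
for ties), and the Spearman coefficient of a gene pair is the Pearson
correlation of the two rank vectors over the experiments where both genes
were assayed:

    rho = cov(rank_1, rank_2) / (sd(rank_1) * sd(rank_2))

The background (null) level of correlation is estimated by pairing each gene
with partners drawn at random from *other* chromosomes, summarizing with the
median, and attaching a percentile bootstrap 95% confidence interval of that
median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .genome_pairs import GeneTable, PairTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 10
CORR_COLUMNS = ["gene_a", "gene_b", "distance_bp", "orientation", "rho", "n_obs"]


class ExpressionMatrix:
    """Genes x experiments abundance table with NaN as the missing marker.

    ``df`` is indexed by gene_id with one column per experiment.  Values are
    non-negative where present (TPM scale after :func:`tpm_from_counts`).
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            raise ValueError("duplicate gene_ids in expression matrix")
        vals = df.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("expression values must be >= 0")
        self.df = df.astype(float)

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    @property
    def experiment_ids(self) -> pd.Index:
        return self.df.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", na_rep="NA")


class RankedMatrix:
    """Within-experiment ranks of an :class:`ExpressionMatrix`.

    Same shape as its source; missing entries stay NaN and do not consume
    ranks.  Ties receive average ranks.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index


@dataclass
class BackgroundEstimate:
    """Median cross-chromosome correlation with bootstrap 95% CI."""

    median_rho: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def tpm_from_counts(
    counts: pd.DataFrame, lengths: pd.Series | np.ndarray
) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    ``TPM_g = 1e6 * (counts_g / length_g) / sum_j (counts_j / length_j)``
    per experiment; ``lengths`` are effective gene lengths in bp aligned with
    the count matrix rows.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape[0] != counts.shape[0]:
        raise ValueError("lengths must align with count matrix rows")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    vals = counts.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("counts must be >= 0")

    rate = vals / lengths[:, None]
    total = np.nansum(rate, axis=0)
    dead = np.flatnonzero(total == 0)
    if dead.size:
        raise ValueError(
            f"experiments with zero total signal: {list(counts.columns[dead])}"
        )
    tpm = 1e6 * rate / total
    return ExpressionMatrix(pd.DataFrame(tpm, index=counts.index, columns=counts.columns))


def detection_filter(m: ExpressionMatrix, min_frac: float = 0.8) -> ExpressionMatrix:
    """Drop genes detected (value > 0, non-missing) in < ``min_frac`` of experiments."""
    if not 0 < min_frac <= 1:
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    vals = m.df.to_numpy()
    detected = np.nan_to_num(vals, nan=0.0) > 0
    frac = detected.sum(axis=1) / m.df.shape[1]
    keep = frac >= min_frac
    if not keep.any():
        raise ValueError("detection filter removed every gene")
    logger.info(
        "detection filter (>= %.0f%%): kept %d / %d genes",
        100 * min_frac,
        int(keep.sum()),
        len(keep),
    )
    return ExpressionMatrix(m.df.loc[keep])


def rank_by_experiment(m: ExpressionMatrix) -> RankedMatrix:
    """Rank values within each experiment; average ranks for ties, NaN passes through."""
    if m.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    vals = m.df.to_numpy(dtype=float)
    usable = (~np.isnan(vals)).sum(axis=0) >= 2
    if not usable.all():
        bad = list(m.df.columns[~usable])
        logger.warning("excluding experiments with < 2 assayed genes: %s", bad)
        vals = vals[:, usable]
    ranks = scipy.stats.rankdata(vals, axis=0, nan_policy="omit")
    return RankedMatrix(
        pd.DataFrame(ranks, index=m.df.index, columns=m.df.columns[usable])
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _masked_pearson(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson correlation over jointly observed columns.

    Returns (rho, n_obs); rho is NaN where either row is constant over the
    joint support or the support is < 2.
    """
    M = ~(np.isnan(A) | np.isnan(B))
    n = M.sum(axis=1)
    Az = np.where(M, A, 0.0)
    Bz = np.where(M, B, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = Az.sum(axis=1) / n
        mb = Bz.sum(axis=1) / n
        Ac = np.where(M, Az - ma[:, None], 0.0)
        Bc = np.where(M, Bz - mb[:, None], 0.0)
        cov = (Ac * Bc).sum(axis=1)
        va = (Ac * Ac).sum(axis=1)
        vb = (Bc * Bc).sum(axis=1)
        rho = cov / np.sqrt(va * vb)
    rho[(va == 0) | (vb == 0) | (n < 2)] = np.nan
    return rho, n


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation of two vectors via the ranked-Pearson identity.

    Ranks each vector (average ranks for ties) and evaluates
    ``cov(rx, ry) / (sd(rx) sd(ry))`` with the same masked-covariance
    machinery used for pair correlations; NaNs are handled
    pairwise-complete.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~(np.isnan(x) | np.isnan(y))
    rx = np.full(x.shape, np.nan)
    ry = np.full(y.shape, np.nan)
    rx[both] = scipy.stats.rankdata(x[both])
    ry[both] = scipy.stats.rankdata(y[both])
    rho, _ = _masked_pearson(rx[None, :], ry[None, :])
    return float(rho[0])


def pair_correlations(
    r: RankedMatrix,
    pairs: PairTable,
    min_obs: int = DEFAULT_MIN_OBS,
    chunk_size: int = 200_000,
) -> pd.DataFrame:
    """Spearman correlation (Pearson on ranks) for every neighbor pair.

    Pairs whose genes are absent from the ranked matrix, have fewer than
    ``min_obs`` jointly observed experiments, or have a constant rank vector
    are omitted (with a logged count).  Returns a DataFrame with columns
    ``gene_a, gene_b, distance_bp, orientation, rho, n_obs``.
    """
    if min_obs < 3:
        raise ValueError(f"min_obs must be >= 3, got {min_obs}")
    df = pairs.df
    idx = pd.Index(r.gene_ids)
    ia = idx.get_indexer(df["gene_a"])
    ib = idx.get_indexer(df["gene_b"])
    present = (ia >= 0) & (ib >= 0)
    n_absent = int((~present).sum())
    if n_absent:
        logger.info("omitting %d pairs with unmeasured genes", n_absent)

    sub = df.loc[present].reset_index(drop=True)
    ia, ib = ia[present], ib[present]
    R = r.df.to_numpy(dtype=float)

    rhos = np.empty(len(sub))
    nobs = np.empty(len(sub), dtype=int)
    if not np.isnan(R).any():
        # complete matrix: standardize rows once, rho is a dot product
        Z = R - R.mean(axis=1, keepdims=True)
        norms = np.sqrt((Z * Z).sum(axis=1))
        zero = norms == 0
        norms[zero] = 1.0
        Z /= norms[:, None]
        for lo in range(0, len(sub), chunk_size):
            hi = min(lo + chunk_size, len(sub))
            rhos[lo:hi] = np.einsum(
                "ij,ij->i", Z[ia[lo:hi]], Z[ib[lo:hi]]
            )
        nobs[:] = R.shape[1]
        rhos[zero[ia] | zero[ib]] = np.nan
    else:
        for lo in range(0, len(sub), chunk_size):
            hi = min(lo + chunk_size, len(sub))
            rho, n = _masked_pearson(R[ia[lo:hi]], R[ib[lo:hi]])
            rhos[lo:hi] = rho
            nobs[lo:hi] = n

    out = sub[["gene_a", "gene_b", "distance_bp", "orientation"]].copy()
    out["rho"] = rhos
    out["n_obs"] = nobs
    ok = (nobs >= min_obs) & ~np.isnan(rhos)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "omitting %d pairs (joint observations < %d or constant ranks)",
            n_dropped,
            min_obs,
        )
    return out.loc[ok].reset_index(drop=True)


def _bootstrap_medians(
    x: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Medians of ``n_boot`` with-replacement resamples of ``x`` (chunked)."""
    out = np.empty(n_boot)
    step = max(1, int(2e7) // max(x.size, 1))
    for lo in range(0, n_boot, step):
        hi = min(lo + step, n_boot)
        draws = rng.integers(0, x.size, size=(hi - lo, x.size))
        out[lo:hi] = np.median(x[draws], axis=1)
    return out


def background_correlation(
    r: RankedMatrix,
    genes: GeneTable,
    n_per_gene: int = 20,
    n_boot: int = 10_000,
    seed: int = 0,
    min_obs: int = DEFAULT_MIN_OBS,
) -> BackgroundEstimate:
    """Null correlation level from random cross-chromosome gene pairs.

    Each gene in the ranked matrix is paired with ``n_per_gene`` genes drawn
    without replacement from other chromosomes; the summary is the median
    correlation with a percentile bootstrap 95% CI of the median over
    ``n_boot`` resamples.  Fully reproducible from ``seed``.
    """
    gdf = genes.df.set_index("gene_id")
    ids = [g for g in r.gene_ids if g in gdf.index]
    chrom = gdf.loc[ids, "chromosome"].to_numpy()
    if len(set(chrom)) < 2:
        raise ValueError("background correlation needs >= 2 chromosomes")

    idx = pd.Index(r.gene_ids)
    pos = idx.get_indexer(ids)
    rng = np.random.default_rng(seed)

    src, dst = [], []
    all_pos = np.arange(len(ids))
    for i in range(len(ids)):
        eligible = all_pos[chrom != chrom[i]]
        take = min(n_per_gene, eligible.size)
        if take < n_per_gene:
            logger.warning(
                "gene %s: only %d cross-chromosome partners available", ids[i], take
            )
        partners = rng.choice(eligible, size=take, replace=False)
        src.append(np.full(take, i))
        dst.append(partners)
    ia = pos[np.concatenate(src)]
    ib = pos[np.concatenate(dst)]

    R = r.df.to_numpy(dtype=float)
    rho, n = _masked_pearson(R[ia], R[ib])
    rho = rho[(n >= min_obs) & ~np.isnan(rho)]

    med = float(np.median(rho))
    boot = _bootstrap_medians(rho, n_boot, rng)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return BackgroundEstimate(
        median_rho=med,
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=int(rho.size),
        n_boot=n_boot,
        seed=seed,
    )
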