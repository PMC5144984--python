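"""Synthetic genomes, expression compendia, tissue maps, and insulator sites.

Every generator here produces data with *known* ground truth so the whole
pipeline — pairing, correlation, smoothing, decay fitting, stratified
comparison — can be validated end to end without external downloads.

The expression model is a one-dimensional Ornstein-Uhlenbeck (first-order
autoregressive) Gaussian process along each chromosome: latent values of two
genes separated by ``d`` bp correlate as ``exp(-d / delta)``, so the
population pairwise correlation of the emitted expression is

    rho(d) = a * exp(-d / delta) + c_sim

with amplitude ``a`` (latent weight), shared baseline ``c_sim``, and
independent noise carrying the rest of the variance.  The AR(1)
construction ``z_{i+1} = phi_i z_i + sqrt(1 - phi_i^2) eps``,
``phi_i = exp(-gap_i / delta)``, is exact for the exponential kernel on a
line and runs in linear time.  Expression values are mapped to a TPM-like
scale through a strictly increasing exponential link, which cannot affect
rank-based statistics.

The baseline enters as a factor shared by the genes of a *chromosome*, not
genome-wide.  Spearman correlation ranks genes within each experiment, so a
factor loading equally on every gene is exactly invisible to it (within-
sample ranks are a fixed permutation; an all-pairs positive rank-correlation
floor is arithmetically impossible).  A chromosome-level factor moves one
chromosome's genes jointly relative to the rest, which ranking does see, and
gives every same-chromosome pair — the only pairs the decay analysis uses —
the intended distance-independent plateau ``c_sim``.

Confound switches reproduce the structures that make distance control
necessary: with ``orientation_confound`` divergent pairs preferentially sit
on small intergenic gaps; with ``insulator_confound`` binding sites are
preferentially placed in large gaps.  Neither has any direct effect on the
simulated expression — distance is the only real driver — so a correct
stratified analysis must see group differences vanish once distance is
controlled.

Rank (Spearman) correlation of a bivariate normal is (6/pi)*asin(rho/2),
about 4.5% below rho at these amplitudes; this attenuates the fitted
amplitude slightly but not the distance scale delta.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_corr import ExpressionMatrix
from .genome_pairs import GeneTable
from .spatial_overlap import TissueAnnotation
from .stratified import IntervalSet

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_expression",
    "simulate_tissue_annotations",
    "simulate_insulators",
    "write_dataset",
]

# distinct RNG streams per generator so the pieces are independently
# reproducible from one seed
_STREAM_GENOME = 1
_STREAM_EXPRESSION = 2
_STREAM_TISSUE = 3
_STREAM_INSULATOR = 4


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic dataset.

    Intergenic gaps are log-normal (``gap_log_mean``/``gap_log_sd`` on the
    natural-log scale; the defaults give a ~3 kb median gap with a heavy
    right tail).  ``delta`` is the correlation length of the expression
    process in bp, ``amplitude`` the decay amplitude at zero distance, and
    ``shared_baseline`` the distance-independent correlation floor shared
    genome-wide; ``amplitude + shared_baseline`` must stay below 1.
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 1000
    gap_log_mean: float = 8.0
    gap_log_sd: float = 1.5
    gene_length_log_mean: float = 7.2
    gene_length_log_sd: float = 0.5
    delta: float = 10_000.0
    amplitude: float = 0.3
    shared_baseline: float = 0.05
    n_experiments: int = 200
    orientation_confound: bool = False
    insulator_confound: bool = False
    n_tissues: int = 30
    tissue_set_size: float = 6.0
    delta_t: float = 20_000.0
    insulator_factors: tuple[str, ...] = ("insulatorA", "insulatorB")
    site_width: int = 200
    site_prob: float = 0.5
    replicate_jitter: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.amplitude < 1):
            raise ValueError("amplitude must be in [0, 1)")
        if not (0 <= self.shared_baseline < 1 - self.amplitude):
            raise ValueError("need amplitude + shared_baseline < 1")
        if self.delta <= 0 or self.delta_t <= 0:
            raise ValueError("correlation lengths must be positive")
        for name in ("n_chromosomes", "genes_per_chromosome", "n_experiments", "n_tissues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["insulator_factors"] = list(self.insulator_factors)
        return d


def _rng(cfg: SimulationConfig, stream: int, seed: int | None) -> np.random.Generator:
    return np.random.default_rng([seed if seed is not None else cfg.seed, stream])


def _gap_logit(cfg: SimulationConfig, gaps: np.ndarray) -> np.ndarray:
    """Squash log-gap size to (0, 1); ~0 for small gaps, ~1 for large."""
    z = (np.log(gaps) - cfg.gap_log_mean) / cfg.gap_log_sd
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(cfg: SimulationConfig, seed: int | None = None) -> GeneTable:
    """Multi-chromosome gene map with log-normal intergenic gaps.

    TSS positions are cumulative gap draws.  Strands are i.i.d. +/- unless
    ``orientation_confound`` is set, in which case each gene's strand is
    drawn conditional on the preceding gap so that divergent configurations
    concentrate on small gaps and convergent ones on large gaps — with no
    effect on expression.
    """
    rng = _rng(cfg, _STREAM_GENOME, seed)
    rows = []
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = cfg.genes_per_chromosome
        gaps = np.maximum(
            1, np.round(rng.lognormal(cfg.gap_log_mean, cfg.gap_log_sd, size=n))
        ).astype(np.int64)
        tss = 100_000 + np.cumsum(gaps)
        lengths = np.maximum(
            50,
            np.round(
                rng.lognormal(cfg.gene_length_log_mean, cfg.gene_length_log_sd, size=n)
            ),
        ).astype(np.int64)

        if cfg.orientation_confound:
            q = _gap_logit(cfg, np.diff(tss).astype(float))
            strands = np.empty(n, dtype="<U1")
            strands[0] = "+" if rng.random() < 0.5 else "-"
            u = rng.random(n - 1)
            for i in range(1, n):
                if strands[i - 1] == "-":
                    p_plus = 0.5 + 0.45 * (1.0 - q[i - 1])  # divergent if small gap
                else:
                    p_plus = 0.5 - 0.45 * q[i - 1]  # convergent if large gap
                strands[i] = "+" if u[i - 1] < p_plus else "-"
        else:
            strands = np.where(rng.random(n) < 0.5, "+", "-")

        start = np.where(strands == "+", tss, tss - lengths)
        end = np.where(strands == "+", tss + lengths, tss)
        for i in range(n):
            rows.append(
                (
                    f"g{ci + 1}_{i:05d}",
                    chrom,
                    int(start[i]),
                    int(end[i]),
                    strands[i],
                    int(tss[i]),
                    "protein_coding",
                )
            )
    return GeneTable(
        pd.DataFrame(
            rows,
            columns=["gene_id", "chromosome", "start", "end", "strand", "tss", "biotype"],
        )
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _ou_latent(
    tss_by_chrom: list[np.ndarray],
    delta: float,
    n_experiments: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean unit-variance OU field: corr(z_i, z_j) = exp(-d_ij/delta)
    within a chromosome, independent across chromosomes."""
    blocks = []
    for tss in tss_by_chrom:
        n = len(tss)
        eps = rng.standard_normal((n, n_experiments))
        z = np.empty_like(eps)
        z[0] = eps[0]
        phi = np.exp(-np.diff(tss).astype(float) / delta)
        w = np.sqrt(1.0 - phi**2)
        for i in range(1, n):
            z[i] = phi[i - 1] * z[i - 1] + w[i - 1] * eps[i]
        blocks.append(z)
    return np.vstack(blocks)


def simulate_expression(
    genes: GeneTable, cfg: SimulationConfig, seed: int | None = None
) -> ExpressionMatrix:
    """TPM-like expression whose pairwise correlation decays as
    ``a * exp(-d/delta) + c_sim`` with TSS distance.

    Per experiment the signal is ``sqrt(a) * z + sqrt(c_sim) * g_chrom +
    sqrt(1 - a - c_sim) * eta`` with ``z`` the chromosome-wise OU latent,
    ``g_chrom`` a factor shared by the genes of each chromosome, and ``eta``
    i.i.d. noise.  The Gaussian signal is mapped through ``exp`` and
    column-scaled to sum to 1e6 (a strictly increasing transform, invisible
    to ranks).  The baseline factor is per chromosome because a genome-wide
    equal-loading factor is cancelled by within-experiment ranking and would
    leave no plateau in the Spearman statistic.
    """
    rng = _rng(cfg, _STREAM_EXPRESSION, seed)
    df = genes.df
    tss_by_chrom = [
        sub["tss"].to_numpy() for _, sub in df.groupby("chromosome", sort=False)
    ]
    n_genes, n_exp = len(df), cfg.n_experiments

    a, c = cfg.amplitude, cfg.shared_baseline
    z = _ou_latent(tss_by_chrom, cfg.delta, n_exp, rng)
    g = np.vstack(
        [
            np.tile(rng.standard_normal(n_exp), (len(tss), 1))
            for tss in tss_by_chrom
        ]
    )  # one factor per chromosome, shared by its genes
    eta = rng.standard_normal((n_genes, n_exp))
    u = np.sqrt(a) * z + np.sqrt(c) * g + np.sqrt(1.0 - a - c) * eta

    x = np.exp(u)
    x *= 1e6 / x.sum(axis=0)
    cols = [f"exp{j:04d}" for j in range(n_exp)]
    return ExpressionMatrix(pd.DataFrame(x, index=df["gene_id"].to_numpy(), columns=cols))


# ---------------------------------------------------------------------------
# tissue annotations
# ---------------------------------------------------------------------------


def _expected_jaccard(r: np.ndarray, p: float) -> np.ndarray:
    """Large-set approximation of the expected Jaccard overlap of two genes
    whose per-tissue membership indicators correlate at ``r``.

    With stationary membership probability ``p`` and indicator correlation
    ``r``, ``P(both) = p^2 + r p (1-p)``, so
    ``E|A&B| / E|A|B| = (p + r(1-p)) / (2 - p - r(1-p))``.
    """
    x = p + r * (1.0 - p)
    return x / (2.0 - x)


def _calibrate_latent_length(delta_t: float, p: float) -> float:
    """Latent correlation length whose *overlap* curve fits at scale delta_t.

    The Jaccard map is monotone but convex in the indicator correlation, so
    the overlap decays somewhat faster than the latent process; this solves
    (via the closed-form overlap curve) for the latent length whose best-fit
    exponential has rate 1/delta_t.
    """
    import scipy.optimize

    d = np.linspace(0.0, 5.0 * delta_t, 200)

    def fitted_rate(delta_z: float) -> float:
        j = _expected_jaccard(np.exp(-d / delta_z), p)

        def resid(x: np.ndarray) -> np.ndarray:
            return x[0] * np.exp(-x[1] * d) + x[2] - j

        res = scipy.optimize.least_squares(
            resid,
            [j[0] - j[-1], 1.0 / delta_t, j[-1]],
            bounds=([0.0, 1e-12, -1.0], [2.0, np.inf, 1.0]),
        )
        return res.x[1]

    return float(
        scipy.optimize.brentq(
            lambda dz: fitted_rate(dz) - 1.0 / delta_t,
            delta_t,
            20.0 * delta_t,
            xtol=delta_t * 1e-4,
        )
    )


def simulate_tissue_annotations(
    genes: GeneTable, cfg: SimulationConfig, seed: int | None = None
) -> TissueAnnotation:
    """Tissue sets whose pairwise overlap decays with TSS distance.

    Per tissue term, membership is a stationary two-state Markov process
    along each chromosome: gene ``i+1`` inherits gene ``i``'s membership
    with probability ``exp(-gap / delta_z)`` and is otherwise re-drawn
    Bernoulli with the stationary rate ``tissue_set_size / n_tissues``.
    Membership indicators of two genes at distance ``d`` then correlate at
    exactly ``exp(-d / delta_z)``; ``delta_z`` is pre-calibrated so the
    best-fit exponential of the resulting Jaccard-overlap curve decays at
    ``delta_t``.  Genes at identical positions receive identical sets.
    """
    rng = _rng(cfg, _STREAM_TISSUE, seed)
    df = genes.df
    p = cfg.tissue_set_size / cfg.n_tissues
    if not 0 < p < 1:
        raise ValueError("tissue_set_size must be in (0, n_tissues)")
    delta_z = _calibrate_latent_length(cfg.delta_t, p)

    ids = df["gene_id"].to_numpy()
    n_t = cfg.n_tissues
    has = np.empty((len(ids), n_t), dtype=bool)
    row = 0
    for _, sub in df.groupby("chromosome", sort=False):
        tss = sub["tss"].to_numpy()
        n = len(tss)
        keep = rng.random((n - 1, n_t)) < np.exp(
            -np.diff(tss).astype(float) / delta_z
        )[:, None]
        fresh = rng.random((n, n_t)) < p
        has[row] = fresh[0]
        for i in range(1, n):
            has[row + i] = np.where(keep[i - 1], has[row + i - 1], fresh[i])
        row += n
    mapping = {
        ids[i]: {f"tissue{t:02d}" for t in np.flatnonzero(has[i])}
        for i in range(len(ids))
        if has[i].any()
    }
    return TissueAnnotation(mapping)


# ---------------------------------------------------------------------------
# insulator sites
# ---------------------------------------------------------------------------


def simulate_insulators(
    genes: GeneTable, cfg: SimulationConfig, seed: int | None = None
) -> dict[str, tuple[IntervalSet, IntervalSet]]:
    """Insulator binding sites as two jittered BED replicates per factor.

    A site may be placed in each intergenic gap: with ``insulator_confound``
    the placement probability grows with gap size (sites end up between
    distant pairs), otherwise it is constant.  Sites never influence the
    simulated expression.  Replicate coordinates are jittered independently
    by up to ``replicate_jitter`` bp at each end.
    """
    rng = _rng(cfg, _STREAM_INSULATOR, seed)
    df = genes.df
    out: dict[str, tuple[IntervalSet, IntervalSet]] = {}
    w = cfg.site_width
    for factor in cfg.insulator_factors:
        reps: list[list[tuple[str, int, int]]] = [[], []]
        for chrom, sub in df.groupby("chromosome", sort=False):
            tss = np.sort(sub["tss"].to_numpy())
            gaps = np.diff(tss)
            if cfg.insulator_confound:
                prob = cfg.site_prob * _gap_logit(cfg, np.maximum(gaps, 1).astype(float))
            else:
                prob = np.full(gaps.shape, cfg.site_prob * 0.5)
            place = rng.random(len(gaps)) < prob
            for i in np.flatnonzero(place):
                lo, hi = int(tss[i]), int(tss[i + 1])
                if hi - lo < w + 4:
                    continue
                s1 = int(rng.integers(lo + 1, hi - w))  # 1-based start
                start0, end0 = s1 - 1, s1 - 1 + w  # BED half-open
                for r in range(2):
                    js = int(rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
                    je = int(rng.integers(-cfg.replicate_jitter, cfg.replicate_jitter + 1))
                    if cfg.replicate_jitter == 0:
                        js = je = 0
                    a = max(0, start0 + js)
                    b = max(a + 1, end0 + je)
                    reps[r].append((chrom, a, b))
        sets = tuple(
            IntervalSet(
                factor,
                pd.DataFrame(rep, columns=["Chromosome", "Start", "End"]),
            )
            for rep in reps
        )
        out[factor] = sets  # type: ignore[assignment]
    return out


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_dataset(outdir: str | Path, cfg: SimulationConfig, seed: int | None = None) -> dict:
    """Emit a complete synthetic dataset in the formats the pipeline reads.

    Writes ``genes.tsv``, ``expression.tsv``, ``tissues.tsv``, two BED files
    per insulator factor, small ``operons.tsv`` / ``duplicates.tsv`` fixture
    lists (a same-operon adjacent pair, a cross-operon pair, a distant
    duplicated pair), and ``ground_truth.json`` recording the generating
    parameters.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = simulate_genome(cfg, seed)
    expr = simulate_expression(genes, cfg, seed)
    tissues = simulate_tissue_annotations(genes, cfg, seed)
    insulators = simulate_insulators(genes, cfg, seed)

    paths: dict[str, str] = {}
    genes.to_tsv(outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    expr.to_tsv(outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    tissues.to_tsv(outdir / "tissues.tsv")
    paths["tissues"] = str(outdir / "tissues.tsv")

    for factor, (r1, r2) in insulators.items():
        p1 = outdir / f"{factor}_rep1.bed"
        p2 = outdir / f"{factor}_rep2.bed"
        r1.to_bed(p1)
        r2.to_bed(p2)
        paths[f"{factor}_rep1"] = str(p1)
        paths[f"{factor}_rep2"] = str(p2)

    ids = genes.df["gene_id"].tolist()
    with open(outdir / "operons.tsv", "w") as fh:
        fh.write("\t".join(ids[0:2]) + "\n")  # adjacent same-operon pair
        fh.write("\t".join(ids[2:4]) + "\n")  # second operon -> cross-operon pair
    paths["operons"] = str(outdir / "operons.tsv")
    with open(outdir / "duplicates.tsv", "w") as fh:
        fh.write(f"{ids[0]}\t{ids[min(50, len(ids) - 1)]}\n")  # distant duplicates
    paths["duplicates"] = str(outdir / "duplicates.tsv")

    truth = {
        "config": cfg.to_dict(),
        "seed": seed if seed is not None else cfg.seed,
        "delta_bp": cfg.delta,
        "amplitude": cfg.amplitude,
        "shared_baseline": cfg.shared_baseline,
        "delta_t_bp": cfg.delta_t,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
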