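"""Gene annotation ingestion and neighbor-pair construction.

Genes are loaded from GFF3/GTF (via :mod:`gffutils`) or a simple TSV,
restricted to protein-coding biotypes, grouped by chromosome and sorted by
strand-aware TSS.  Every gene is then paired with its ``k`` nearest neighbors
on the same chromosome — "nearest" meaning rank separation in TSS-sorted
order, which is deterministic under coordinate ties and reproduces the
expected pair counts (about ``k`` pairs per gene).  Each unordered pair is
stored once, with ``gene_a`` the upstream-by-TSS member, together with its
TSS-to-TSS distance and relative-orientation class.  Pairs co-transcribed in
the same operon are removed, and pairs of duplicated genes can be flagged or
removed, so that trivial sources of expression correlation do not contaminate
the distance-decay signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand", "tss", "biotype"]
PAIR_COLUMNS = [
    "gene_a",
    "gene_b",
    "chromosome",
    "distance_bp",
    "rank_separation",
    "orientation",
    "is_operon_pair",
    "is_duplicate_pair",
]

#: biotype attribute values accepted as protein coding
PROTEIN_CODING = frozenset({"protein_coding", "protein-coding", "mrna"})


class AnnotationError(ValueError):
    """Raised when a gene annotation file cannot be interpreted."""


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5' end of the gene span."""
        return self.start if self.strand == "+" else self.end


@dataclass
class GenePair:
    """An unordered neighbor pair; ``gene_a`` is the upstream-by-TSS member."""

    gene_a: str
    gene_b: str
    chromosome: str
    distance_bp: int
    rank_separation: int
    orientation: str
    is_operon_pair: bool = False
    is_duplicate_pair: bool = False
    insulator_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError("a pair cannot contain the same gene twice")
        if self.distance_bp < 0 or self.rank_separation < 1:
            raise ValueError("invalid pair geometry")

    @classmethod
    def from_records(
        cls, a: GeneRecord, b: GeneRecord, rank_separation: int = 1
    ) -> "GenePair":
        if b.tss < a.tss or (b.tss == a.tss and b.gene_id < a.gene_id):
            a, b = b, a
        return cls(
            gene_a=a.gene_id,
            gene_b=b.gene_id,
            chromosome=a.chromosome,
            distance_bp=intergenic_distance(a, b),
            rank_separation=rank_separation,
            orientation=classify_orientation(a, b),
        )


class GeneTable:
    """Protein-coding genes grouped by chromosome, sorted by TSS.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``gene_id, chromosome, start, end, strand, tss, biotype``.  Sorting is
    stable on ``(chromosome, tss, gene_id)`` so downstream pairing is
    deterministic even under coordinate ties.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()[:5]
            raise ValueError(f"duplicate gene_ids in table: {dups} ...")
        self.df = (
            df[GENE_COLUMNS]
            .sort_values(["chromosome", "tss", "gene_id"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"GeneTable({len(self)} genes on "
            f"{self.df['chromosome'].nunique()} chromosomes)"
        )

    @classmethod
    def from_records(cls, records: Iterable[GeneRecord]) -> "GeneTable":
        rows = [
            (r.gene_id, r.chromosome, r.start, r.end, r.strand, r.tss, r.biotype)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=GENE_COLUMNS))

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chromosome"]))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class PairTable:
    """Unordered neighbor pairs with distances and orientation classes.

    ``df`` columns: ``gene_a, gene_b, chromosome, distance_bp,
    rank_separation, orientation, is_operon_pair, is_duplicate_pair`` plus one
    ``flank_<factor>`` column per insulator factor once flagged.  ``gene_a``
    is always the upstream-by-TSS member and every unordered pair appears
    exactly once.
    """

    df: pd.DataFrame
    k: int

    def __post_init__(self) -> None:
        missing = [c for c in PAIR_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"pair table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = 0) -> "PairTable":
        return cls(pd.read_csv(path, sep="\t"), k=k)


# ---------------------------------------------------------------------------
# annotation loading
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("biotype", "gene_biotype", "gene_type")


def _is_protein_coding(biotype: str) -> bool:
    return biotype.lower() in PROTEIN_CODING


def _load_gff(path: str | Path, fmt: str) -> pd.DataFrame:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"cannot parse {path} as {fmt}: {exc}") from exc

    rows = []
    for feat in db.features_of_type("gene"):
        biotype = ""
        for key in _BIOTYPE_KEYS:
            if key in feat.attributes:
                biotype = feat.attributes[key][0]
                break
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            raise AnnotationError(f"gene {gid}: missing or invalid strand")
        rows.append((gid, feat.seqid, feat.start, feat.end, feat.strand, biotype))
    return pd.DataFrame(
        rows, columns=["gene_id", "chromosome", "start", "end", "strand", "biotype"]
    )


def _load_tsv(path: str | Path, bed_coords: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "gene_id": str})
    except Exception as exc:
        raise AnnotationError(f"cannot parse {path} as TSV: {exc}") from exc
    required = ["gene_id", "chromosome", "start", "end", "strand", "biotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: TSV is missing columns {missing}")
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise AnnotationError(f"{path}: strand must be '+' or '-' for every gene")
    df = df.copy()
    if bed_coords:  # 0-based half-open -> 1-based inclusive
        df["start"] = df["start"] + 1
    return df[required]


def load_gene_annotation(path: str | Path, format: str = "gff3") -> GeneTable:
    """Load protein-coding genes from GFF3, GTF, or TSV/BED-like annotation.

    Parameters
    ----------
    path
        Annotation file.
    format
        One of ``gff3``, ``gtf``, ``tsv``, ``bed``.  ``tsv`` expects header
        columns ``gene_id, chromosome, start, end, strand, biotype`` with
        1-based inclusive coordinates; ``bed`` expects the same columns in
        0-based half-open convention.

    Returns
    -------
    GeneTable
        Only protein-coding genes, one record per ``gene_id`` (the longest
        span wins when a gene has several entries), grouped by chromosome and
        sorted by strand-aware TSS.
    """
    fmt = format.lower()
    if fmt in ("gff3", "gff", "gtf"):
        df = _load_gff(path, fmt)
    elif fmt in ("tsv", "bed"):
        df = _load_tsv(path, bed_coords=(fmt == "bed"))
    else:
        raise ValueError(f"unknown annotation format: {format!r}")

    df = df[df["biotype"].map(_is_protein_coding)].copy()
    if df.empty:
        raise AnnotationError(f"{path}: no protein-coding genes found")

    # collapse multiple entries per gene_id: keep the longest span
    n_before = len(df)
    df["span"] = df["end"] - df["start"]
    df = (
        df.sort_values(["gene_id", "span"], kind="stable")
        .drop_duplicates("gene_id", keep="last")
        .drop(columns="span")
    )
    if len(df) < n_before:
        logger.info("collapsed %d duplicate annotation entries", n_before - len(df))

    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return GeneTable(df)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """TSS-to-TSS distance in bp between two genes on the same chromosome.

    The distance runs from the 5' start of one gene to the 5' start of the
    other, so it is symmetric in its arguments and strand-aware.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"genes on different chromosomes: {a.chromosome} vs {b.chromosome}"
        )
    return abs(b.tss - a.tss)


def classify_orientation(a: GeneRecord, b: GeneRecord) -> str:
    """Relative orientation of a neighbor pair; ``a`` is the upstream member.

    ``divergent`` — promoters face away from each other (upstream gene on
    ``-``, downstream on ``+``); ``convergent`` — genes transcribe toward each
    other; ``parallel`` — both on the same strand.
    """
    if a.strand == b.strand:
        return "parallel"
    return "divergent" if a.strand == "-" else "convergent"


_ORIENTATION_LUT = {
    ("+", "+"): "parallel",
    ("-", "-"): "parallel",
    ("-", "+"): "divergent",
    ("+", "-"): "convergent",
}


def neighbor_pairs(genes: GeneTable, k: int = 100) -> PairTable:
    """Pair every gene with its ``k`` nearest neighbors on its chromosome.

    Nearest is defined by rank separation in the TSS-sorted order; a
    chromosome of ``n`` genes yields ``sum_{i=1..n-1} min(i, k)`` unordered
    pairs.  Distances are TSS-to-TSS.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    frames = []
    for chrom, sub in genes.df.groupby("chromosome", sort=False):
        n = len(sub)
        if n < 2:
            continue
        tss = sub["tss"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        strands = sub["strand"].to_numpy()
        for sep in range(1, min(k, n - 1) + 1):
            ia = np.arange(0, n - sep)
            ib = ia + sep
            frames.append(
                pd.DataFrame(
                    {
                        "gene_a": ids[ia],
                        "gene_b": ids[ib],
                        "chromosome": chrom,
                        "distance_bp": np.abs(tss[ib] - tss[ia]),
                        "rank_separation": sep,
                        "orientation": [
                            _ORIENTATION_LUT[(sa, sb)]
                            for sa, sb in zip(strands[ia], strands[ib])
                        ],
                    }
                )
            )
    if not frames:
        df = pd.DataFrame(columns=PAIR_COLUMNS)
    else:
        df = pd.concat(frames, ignore_index=True)
        df["is_operon_pair"] = False
        df["is_duplicate_pair"] = False
    return PairTable(df[PAIR_COLUMNS] if len(df) else df, k=k)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def load_operon_sets(path: str | Path) -> list[frozenset[str]]:
    """Read operons as one tab-separated line of gene_ids per operon."""
    sets = []
    with open(path) as fh:
        for line in fh:
            genes = [g for g in line.strip().split("\t") if g]
            if len(genes) >= 2:
                sets.append(frozenset(genes))
    return sets


def load_duplicate_pairs(path: str | Path) -> set[frozenset[str]]:
    """Read duplicated gene pairs from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {frozenset((str(a), str(b))) for a, b in zip(df[0], df[1])}


def apply_pair_filters(
    pairs: PairTable,
    operon_sets: Sequence[frozenset[str]] | None = None,
    duplicate_pairs: set[frozenset[str]] | None = None,
    known_genes: set[str] | None = None,
    drop_duplicates: bool = False,
) -> PairTable:
    """Remove same-operon pairs and flag (optionally remove) duplicate pairs.

    A pair is operonic iff both members share at least one operon set —
    membership in two *different* operons does not disqualify a pair.
    Duplicate pairs are flagged; set ``drop_duplicates`` to also remove them.
    Unknown gene_ids in the lists are warned about, never fatal.
    """
    df = pairs.df.copy()

    if known_genes is not None:
        listed: set[str] = set()
        for s in operon_sets or []:
            listed |= s
        for p in duplicate_pairs or set():
            listed |= set(p)
        unknown = listed - known_genes
        if unknown:
            logger.warning(
                "%d gene_ids in filter lists not present in gene table (e.g. %s)",
                len(unknown),
                sorted(unknown)[:3],
            )

    if operon_sets:
        membership: dict[str, set[int]] = {}
        for i, s in enumerate(operon_sets):
            for g in s:
                membership.setdefault(g, set()).add(i)
        empty: set[int] = set()

        def _same_operon(a: str, b: str) -> bool:
            return bool(membership.get(a, empty) & membership.get(b, empty))

        df["is_operon_pair"] = [
            _same_operon(a, b) for a, b in zip(df["gene_a"], df["gene_b"])
        ]
        n_removed = int(df["is_operon_pair"].sum())
        if n_removed:
            logger.info("removed %d same-operon pairs", n_removed)
        df = df[~df["is_operon_pair"]].reset_index(drop=True)

    if duplicate_pairs:
        df["is_duplicate_pair"] = [
            frozenset((a, b)) in duplicate_pairs
            for a, b in zip(df["gene_a"], df["gene_b"])
        ]
        logger.info("flagged %d duplicate pairs", int(df["is_duplicate_pair"].sum()))
        if drop_duplicates:
            df = df[~df["is_duplicate_pair"]].reset_index(drop=True)

    return PairTable(df.reset_index(drop=True), k=pairs.k)
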