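"""From raw reads to per-cell fragments, UMI counts and count matrices.

The demultiplexing contract: a read belongs to the nucleus identified by its
corrected ``(sample index, droplet barcode)`` pair.  Because the
deduplication key for ATAC fragments *includes* the cell key, identical
coordinates observed in two different nuclei are never merged — this is what
makes overloaded droplets resolvable.

Alignment on the toy references is exact-match: the first 25 nt of a read is
looked up in a k-mer index of both strands; the unique-25-mer reference
invariant guarantees at most one hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .barcode_model import (
    BarcodeCall,
    BarcodeWhitelist,
    CellKey,
    ReadLayout,
    ReadTruncatedError,
    STATUS_SPACER_FAIL,
    correct_barcode,
    extract_elements,
    resolve_cell_key,
)
from .io import iter_fastq_quads, revcomp
from .synthetic_data import ToyReference

__all__ = [
    "Alignment",
    "Fragment",
    "mock_align",
    "build_fragments",
    "dedup_fragments",
    "collapse_umis",
    "CountMatrix",
    "build_tile_matrix",
    "build_gene_matrix",
    "match_modalities",
    "demux_atac",
    "demux_rna",
]

TN5_SHIFT = (4, 5)  # +4 to fragment start, -5 to half-open end


@dataclass(frozen=True)
class Alignment:
    contig: str
    start: int  # leftmost genomic coordinate of the 25-mer match
    strand: str  # "+" or "-"
    five_prime: int  # genomic coordinate of the read's first base


@dataclass(frozen=True)
class Fragment:
    """One deduplicated ATAC fragment (0-based half-open)."""

    contig: str
    start: int
    end: int
    cell: CellKey
    dup_count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")
        if self.dup_count < 1:
            raise ValueError("dup_count must be >= 1")


def mock_align(seq: str, ref: ToyReference) -> Optional[Alignment]:
    """Exact-match alignment of a read's first ``ref.k`` bases, both strands.

    Returns ``None`` when the seed k-mer occurs on neither strand (e.g. a
    read carrying sequencing errors in its first bases, or random sequence).
    """
    k = ref.k
    if len(seq) < k:
        return None
    index = ref.kmer_index()
    kmer = seq[:k]
    hit = index.get(kmer)
    if hit is not None:
        contig, pos = hit
        return Alignment(contig, pos, "+", pos)
    hit = index.get(revcomp(kmer))
    if hit is not None:
        contig, pos = hit
        # the read's first base aligns to the last base of the rc match
        return Alignment(contig, pos, "-", pos + k - 1)
    return None


# ---------------------------------------------------------------------------
# fragments


PAIR_COLUMNS = ["contig", "left5", "right5", "sample", "droplet"]
FRAG_COLUMNS = ["contig", "start", "end", "sample", "droplet", "dup_count"]


def build_fragments(
    pairs: pd.DataFrame, shift: tuple[int, int] = TN5_SHIFT
) -> pd.DataFrame:
    """Turn aligned, properly oriented read pairs into deduplicated fragments.

    ``pairs`` has one row per read pair with the 5' insertion coordinates of
    the forward (``left5``) and reverse (``right5``) mate.  The fragment is
    ``[left5 + s5, right5 + 1 - s3)`` with the Tn5 offset ``(s5, s3) =
    (4, 5)`` by default, compensating the 9-bp target-site duplication.
    Duplicates (identical contig/start/end/cell) are collapsed with their
    count accumulated; output is sorted by (contig, start, end, cell).
    """
    s5, s3 = shift
    if len(pairs) == 0:
        return pd.DataFrame(columns=FRAG_COLUMNS)
    out = pairs.copy()
    out["start"] = out["left5"] + s5
    out["end"] = out["right5"] + 1 - s3
    if (out["start"] >= out["end"]).any():
        bad = int((out["start"] >= out["end"]).sum())
        raise ValueError(f"{bad} pairs collapse to empty fragments under shift")
    if "dup_count" not in out.columns:
        out["dup_count"] = 1
    return dedup_fragments(out[FRAG_COLUMNS])


def dedup_fragments(frags: pd.DataFrame) -> pd.DataFrame:
    """Collapse identical (contig, start, end, cell) rows; idempotent."""
    out = (
        frags.groupby(["contig", "start", "end", "sample", "droplet"],
                      as_index=False, sort=False)["dup_count"]
        .sum()
        .sort_values(["contig", "start", "end", "sample", "droplet"],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    return out[FRAG_COLUMNS]


def fragments_with_cell(frags: pd.DataFrame) -> pd.DataFrame:
    out = frags.copy()
    out["cell"] = out["sample"] + ":" + out["droplet"]
    return out


# ---------------------------------------------------------------------------
# UMI collapsing


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > 1:
                return False
    return mism == 1


def _directional_clusters(counts: dict[str, int]) -> int:
    """Number of molecules under the directional adjacency rule.

    UMI ``u`` merges into ``v`` when Hamming(u, v) == 1 and
    reads(v) >= 2 * reads(u) - 1.  Clusters are grown breadth-first from the
    most-supported UMIs.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    n_clusters = 0
    for root in order:
        if root in visited:
            continue
        n_clusters += 1
        queue = [root]
        visited.add(root)
        while queue:
            v = queue.pop()
            for u in order:
                if u in visited:
                    continue
                if _hamming1(u, v) and counts[v] >= 2 * counts[u] - 1:
                    visited.add(u)
                    queue.append(u)
    return n_clusters


def collapse_umis(records: pd.DataFrame, mode: str = "exact") -> pd.DataFrame:
    """Collapse UMI records to molecule counts per (cell, gene).

    ``records`` has columns cell, gene, umi and optionally ``reads`` (number
    of supporting reads; defaults to row multiplicity).  ``exact`` counts
    distinct UMI strings; ``directional`` additionally merges 1-mismatch
    neighbours whose read support is consistent with being an error of a
    better-supported UMI.  UMIs are never collapsed across genes.
    """
    if mode not in ("exact", "directional"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    if len(records) == 0:
        return pd.DataFrame(columns=["cell", "gene", "n_molecules", "n_reads"])
    rec = records.copy()
    if "reads" not in rec.columns:
        rec["reads"] = 1
    per_umi = rec.groupby(["cell", "gene", "umi"], as_index=False,
                          sort=False)["reads"].sum()
    if mode == "exact":
        out = per_umi.groupby(["cell", "gene"], sort=False).agg(
            n_molecules=("umi", "size"), n_reads=("reads", "sum")
        ).reset_index()
    else:
        rows = []
        for (cell, gene), grp in per_umi.groupby(["cell", "gene"], sort=False):
            counts = dict(zip(grp.umi, grp.reads))
            rows.append((cell, gene, _directional_clusters(counts),
                         int(grp.reads.sum())))
        out = pd.DataFrame(rows, columns=["cell", "gene", "n_molecules",
                                          "n_reads"])
    return out.sort_values(["cell", "gene"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Sparse features x cells matrix of non-negative integers."""

    matrix: sparse.csr_matrix
    features: list[str]
    cells: list[str]

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix)
        self.matrix.eliminate_zeros()
        if self.matrix.shape != (len(self.features), len(self.cells)):
            raise ValueError("matrix shape does not match feature/cell axes")

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, feature_col: str,
                    cell_col: str, value_col: str,
                    features: Optional[Sequence[str]] = None) -> "CountMatrix":
        if features is None:
            features = sorted(counts[feature_col].unique())
        cells = sorted(counts[cell_col].unique())
        fidx = {f: i for i, f in enumerate(features)}
        cidx = {c: i for i, c in enumerate(cells)}
        rows = counts[feature_col].map(fidx).to_numpy()
        cols = counts[cell_col].map(cidx).to_numpy()
        keep = ~pd.isna(rows)
        mat = sparse.coo_matrix(
            (counts[value_col].to_numpy()[keep],
             (rows[keep].astype(int), cols[keep].astype(int))),
            shape=(len(features), len(cells)),
        ).tocsr()
        return cls(matrix=mat, features=list(features), cells=cells)

    def cell_totals(self) -> pd.Series:
        return pd.Series(np.asarray(self.matrix.sum(axis=0)).ravel(),
                         index=self.cells)

    def feature_cell_counts(self) -> pd.Series:
        """Number of cells in which each feature is non-zero."""
        return pd.Series(np.asarray((self.matrix > 0).sum(axis=1)).ravel(),
                         index=self.features)

    def write(self, outdir, prefix: str) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(outdir / f"{prefix}_matrix.mtx"), self.matrix.tocoo())
        (outdir / f"{prefix}_features.tsv").write_text(
            "".join(f"{f}\n" for f in self.features))
        (outdir / f"{prefix}_barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in self.cells))

    @classmethod
    def read(cls, outdir, prefix: str) -> "CountMatrix":
        outdir = Path(outdir)
        mat = sparse.csr_matrix(spio.mmread(str(outdir / f"{prefix}_matrix.mtx")))
        features = (outdir / f"{prefix}_features.tsv").read_text().split()
        cells = (outdir / f"{prefix}_barcodes.tsv").read_text().split()
        return cls(matrix=mat, features=features, cells=cells)

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.matrix.T.tocsr(),
            obs=pd.DataFrame(index=self.cells),
            var=pd.DataFrame(index=self.features),
        )


def build_tile_matrix(fragments: pd.DataFrame, tile_size: int = 500
                      ) -> CountMatrix:
    """Insertion counts per cell in fixed-width genome tiles.

    Each fragment contributes its two Tn5 insertion sites — the ``start``
    and ``end - 1`` positions — and increments every tile they fall in (the
    same tile twice for short fragments).  Tiles are half-open and labelled
    ``contig:start-end``.
    """
    if len(fragments) == 0:
        return CountMatrix(sparse.csr_matrix((0, 0), dtype=np.int64), [], [])
    frags = fragments_with_cell(fragments)
    ins = pd.concat([
        frags.assign(pos=frags.start),
        frags.assign(pos=frags.end - 1),
    ], ignore_index=True)
    ins["tile_start"] = (ins.pos // tile_size) * tile_size
    ins["feature"] = (ins.contig + ":" + ins.tile_start.astype(str) + "-"
                      + (ins.tile_start + tile_size).astype(str))
    counts = ins.groupby(["feature", "cell"], as_index=False).size()
    counts = counts.rename(columns={"size": "count"})
    # order tiles genomically, not lexically
    uniq = counts[["feature"]].drop_duplicates().copy()
    parts = uniq.feature.str.rsplit(":", n=1, expand=True)
    uniq["contig"] = parts[0]
    uniq["start"] = parts[1].str.split("-").str[0].astype(int)
    features = uniq.sort_values(["contig", "start"]).feature.tolist()
    return CountMatrix.from_counts(counts, "feature", "cell", "count",
                                   features=features)


def build_gene_matrix(molecule_counts: pd.DataFrame, min_cells: int = 10
                      ) -> CountMatrix:
    """Genes x cells molecule-count matrix, dropping rarely seen features.

    Features present (non-zero) in fewer than ``min_cells`` cells are
    removed; ``min_cells=1`` keeps everything.
    """
    mat = CountMatrix.from_counts(molecule_counts, "gene", "cell", "n_molecules")
    presence = mat.feature_cell_counts()
    keep = presence[presence >= min_cells].index.tolist()
    if not keep:
        warnings.warn("gene matrix is empty after the min_cells filter",
                      stacklevel=2)
    keep_idx = [mat.features.index(f) for f in keep]
    return CountMatrix(matrix=mat.matrix[keep_idx, :], features=keep,
                       cells=mat.cells)


def match_modalities(atac_cells: Iterable, rna_cells: Iterable
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exact join of the two modalities on the cell key.

    Returns the joint table (cell, in_atac, in_rna, membership) and the
    counts of each membership class.  Raises when both sets are non-empty
    but share no sample label — that indicates mismatched sample maps.
    """
    a = {str(c) for c in atac_cells}
    r = {str(c) for c in rna_cells}
    if a and r:
        sa = {c.rpartition(":")[0] for c in a}
        sr = {c.rpartition(":")[0] for c in r}
        if not sa & sr:
            raise ValueError(
                "ATAC and RNA cell sets share no sample label; "
                "check the sample maps")
    cells = sorted(a | r)
    df = pd.DataFrame({
        "cell": cells,
        "in_atac": [c in a for c in cells],
        "in_rna": [c in r for c in cells],
    })
    df["membership"] = np.where(
        df.in_atac & df.in_rna, "both",
        np.where(df.in_atac, "atac_only", "rna_only"))
    counts = df.membership.value_counts().to_dict()
    for key in ("both", "atac_only", "rna_only"):
        counts.setdefault(key, 0)
    return df, counts


# ---------------------------------------------------------------------------
# demultiplexing drivers


@dataclass
class DemuxStats:
    """Per-stage read accounting for the conservation audit."""

    n_input: int = 0
    n_assigned: int = 0  # resolved to a cell key
    rejected: dict = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1

    def conserved(self) -> bool:
        return self.n_input == self.n_assigned + sum(self.rejected.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_assigned": self.n_assigned,
                "rejected": dict(sorted(self.rejected.items()))}


@dataclass
class AtacDemuxResult:
    fragments: pd.DataFrame  # deduplicated, sorted
    assignments: pd.DataFrame  # read_id, sample, droplet (barcode stage)
    stats: DemuxStats
    n_pairs_mapped: int = 0
    n_pairs_discordant: int = 0
    n_pairs_unmapped: int = 0


@dataclass
class RnaDemuxResult:
    records: pd.DataFrame  # cell, gene, umi, reads (pre-collapse)
    assignments: pd.DataFrame
    stats: DemuxStats
    n_intergenic: int = 0
    n_unmapped: int = 0


def _resolve_read(reads, layout, sample_wl, droplet_wl, sample_map,
                  max_dist_sample, max_dist_droplet, stats):
    """Shared barcode stage; returns (cell, elements) or (None, None)."""
    try:
        elements = extract_elements(reads, layout)
    except ReadTruncatedError:
        stats.reject("truncated")
        return None, None
    if layout.expected_spacer:
        spacer = elements.get("spacer", "")
        if spacer != layout.expected_spacer:
            stats.reject(STATUS_SPACER_FAIL)
            return None, None
    sample_call = correct_barcode(elements["sample_index"], sample_wl,
                                  max_dist_sample)
    if not sample_call.ok:
        stats.reject(f"sample_{sample_call.status}")
        return None, None
    droplet_call = correct_barcode(elements["droplet_barcode"], droplet_wl,
                                   max_dist_droplet)
    if not droplet_call.ok:
        stats.reject(f"droplet_{droplet_call.status}")
        return None, None
    cell = resolve_cell_key(sample_call, droplet_call, sample_map)
    return cell, elements


def demux_atac(
    fastq_paths: Mapping[str, object],
    ref: ToyReference,
    sample_whitelist: BarcodeWhitelist,
    droplet_whitelist: BarcodeWhitelist,
    sample_map: Mapping[str, str],
    layout: Optional[ReadLayout] = None,
    max_dist_sample: int = 1,
    max_dist_droplet: int = 1,
    shift: tuple[int, int] = TN5_SHIFT,
) -> AtacDemuxResult:
    """Demultiplex ATAC read quadruples into deduplicated fragments."""
    from .barcode_model import ATAC_LAYOUT

    layout = layout or ATAC_LAYOUT
    stats = DemuxStats()
    assign_rows = []
    pair_rows = []
    n_unmapped = n_discordant = n_mapped = 0
    for name, reads in iter_fastq_quads(fastq_paths):
        stats.n_input += 1
        cell, elements = _resolve_read(reads, layout, sample_whitelist,
                                       droplet_whitelist, sample_map,
                                       max_dist_sample, max_dist_droplet, stats)
        if cell is None:
            continue
        stats.n_assigned += 1
        assign_rows.append((name, cell.sample_label, cell.droplet_barcode))
        payload = elements["payload"]
        aln1 = mock_align(payload[0], ref)
        aln2 = mock_align(payload[1], ref)
        if aln1 is None or aln2 is None:
            n_unmapped += 1
            continue
        if aln1.contig != aln2.contig or aln1.strand == aln2.strand:
            n_discordant += 1
            continue
        fwd, rev = (aln1, aln2) if aln1.strand == "+" else (aln2, aln1)
        if fwd.five_prime >= rev.five_prime:
            n_discordant += 1
            continue
        n_mapped += 1
        pair_rows.append((fwd.contig, fwd.five_prime, rev.five_prime,
                          cell.sample_label, cell.droplet_barcode))
    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    fragments = build_fragments(pairs, shift=shift)
    assignments = pd.DataFrame(assign_rows,
                               columns=["read_id", "sample", "droplet"])
    return AtacDemuxResult(fragments=fragments, assignments=assignments,
                           stats=stats, n_pairs_mapped=n_mapped,
                           n_pairs_discordant=n_discordant,
                           n_pairs_unmapped=n_unmapped)


class _GeneLocator:
    """Position -> gene lookup over non-overlapping gene intervals."""

    def __init__(self, genes: pd.DataFrame):
        self._by_contig = {}
        for contig, grp in genes.groupby("contig"):
            grp = grp.sort_values("start")
            self._by_contig[contig] = (
                grp["start"].to_numpy(), grp["end"].to_numpy(),
                grp["name"].to_numpy(),
            )

    def locate(self, contig: str, pos: int) -> Optional[str]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, ends, names = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return str(names[i])
        return None


def demux_rna(
    fastq_paths: Mapping[str, object],
    ref: ToyReference,
    sample_whitelist: BarcodeWhitelist,
    droplet_whitelist: BarcodeWhitelist,
    sample_map: Mapping[str, str],
    layout: Optional[ReadLayout] = None,
    max_dist_sample: int = 2,
    max_dist_droplet: int = 1,
) -> RnaDemuxResult:
    """Demultiplex RNA read quadruples into per-(cell, gene, UMI) records."""
    from .barcode_model import RNA_LAYOUT

    layout = layout or RNA_LAYOUT
    stats = DemuxStats()
    locator = _GeneLocator(ref.genes)
    assign_rows = []
    rec_counts: dict[tuple[str, str, str], int] = {}
    n_unmapped = n_intergenic = 0
    for name, reads in iter_fastq_quads(fastq_paths):
        stats.n_input += 1
        cell, elements = _resolve_read(reads, layout, sample_whitelist,
                                       droplet_whitelist, sample_map,
                                       max_dist_sample, max_dist_droplet, stats)
        if cell is None:
            continue
        stats.n_assigned += 1
        assign_rows.append((name, cell.sample_label, cell.droplet_barcode))
        aln = mock_align(elements["payload"][0], ref)
        if aln is None:
            n_unmapped += 1
            continue
        gene = locator.locate(aln.contig, aln.five_prime)
        if gene is None:
            n_intergenic += 1
            continue
        key = (str(cell), gene, elements["umi"])
        rec_counts[key] = rec_counts.get(key, 0) + 1
    records = pd.DataFrame(
        [(c, g, u, n) for (c, g, u), n in rec_counts.items()],
        columns=["cell", "gene", "umi", "reads"],
    )
    assignments = pd.DataFrame(assign_rows,
                               columns=["read_id", "sample", "droplet"])
    return RnaDemuxResult(records=records, assignments=assignments,
                          stats=stats, n_intergenic=n_intergenic,
                          n_unmapped=n_unmapped)
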