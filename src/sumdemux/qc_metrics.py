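"""Per-cell QC metrics, knee-based cell calling and filter profiles.

All ATAC metrics are defined on Tn5 *insertion sites*: the ``start`` and
``end - 1`` positions of each deduplicated fragment.  The TSS enrichment
score follows the convention of the major snATAC toolkits: insertion density
within +/-50 bp of any TSS divided by the density in distal windows
1,901-2,000 bp on both sides of each TSS, with one pseudo-insertion added to
the flank count so cells with empty flanks get a finite score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "tss_enrichment",
    "fraction_in_peaks",
    "promoter_ratio",
    "AnnotationWindows",
    "compute_qc",
    "Threshold",
    "FilterProfile",
    "load_profile",
    "available_profiles",
    "apply_filters",
    "knee_call_cells",
    "KneeResult",
    "saturation",
]


# ---------------------------------------------------------------------------
# interval machinery


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping [start, end) intervals; returns sorted (n,2)."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = np.asarray(intervals, dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="mergesort")]
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.array(out, dtype=np.int64)


def _membership(positions: np.ndarray, merged: np.ndarray) -> np.ndarray:
    if len(merged) == 0 or len(positions) == 0:
        return np.zeros(len(positions), dtype=bool)
    idx = np.searchsorted(merged[:, 0], positions, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(positions), dtype=bool)
    res[ok] = positions[ok] < merged[idx[ok], 1]
    return res


def _insertions(fragments: pd.DataFrame) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for contig, grp in fragments.groupby("contig"):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy() - 1
        out[str(contig)] = np.concatenate([s, e])
    return out


class AnnotationWindows:
    """Precomputed merged windows around TSS sites and peaks.

    Building the merged interval sets once and reusing them across cells is
    what keeps the per-cell QC loop cheap.
    """

    def __init__(
        self,
        tss: Mapping[str, np.ndarray],
        peaks: Optional[Mapping[str, np.ndarray]] = None,
        center_halfwidth: int = 50,
        flank: tuple[int, int] = (1901, 2000),
        promoter: tuple[int, int] = (2000, 101),  # [TSS-2000, TSS+101)
    ):
        self.center: dict[str, np.ndarray] = {}
        self.flank: dict[str, np.ndarray] = {}
        self.promoters: dict[str, np.ndarray] = {}
        f0, f1 = flank
        for contig, sites in tss.items():
            t = np.asarray(sites, dtype=np.int64)
            self.center[contig] = merge_intervals(
                np.stack([t - center_halfwidth, t + center_halfwidth + 1], axis=1)
            )
            fl = np.concatenate([
                np.stack([t - f1, t - f0 + 1], axis=1),
                np.stack([t + f0, t + f1 + 1], axis=1),
            ])
            fl = np.clip(fl, 0, None)
            self.flank[contig] = merge_intervals(fl)
            self.promoters[contig] = merge_intervals(
                np.clip(np.stack([t - promoter[0], t + promoter[1]], axis=1), 0, None)
            )
        self.peaks: dict[str, np.ndarray] = {}
        if peaks is not None:
            for contig, iv in peaks.items():
                self.peaks[contig] = merge_intervals(np.asarray(iv))

    @staticmethod
    def _width(merged_by_contig: Mapping[str, np.ndarray]) -> int:
        return int(sum((m[:, 1] - m[:, 0]).sum() for m in merged_by_contig.values()))

    def tss_score(self, fragments: pd.DataFrame) -> float:
        if len(fragments) == 0:
            return 0.0
        cc = cf = 0
        for contig, pos in _insertions(fragments).items():
            cc += int(_membership(pos, self.center.get(contig,
                                                       np.empty((0, 2)))).sum())
            cf += int(_membership(pos, self.flank.get(contig,
                                                      np.empty((0, 2)))).sum())
        wc = self._width(self.center)
        wf = self._width(self.flank)
        if wc == 0 or wf == 0:
            raise ValueError("TSS windows are empty; at least one TSS required")
        return (cc / wc) / ((cf + 1) / wf)

    def _either_insertion_in(self, fragments: pd.DataFrame,
                             merged_by_contig: Mapping[str, np.ndarray]
                             ) -> tuple[int, float]:
        if len(fragments) == 0:
            return 0, 0.0
        n_in = 0
        for contig, grp in fragments.groupby("contig"):
            merged = merged_by_contig.get(str(contig), np.empty((0, 2)))
            s_in = _membership(grp["start"].to_numpy(), merged)
            e_in = _membership(grp["end"].to_numpy() - 1, merged)
            n_in += int((s_in | e_in).sum())
        return n_in, n_in / len(fragments)

    def fraction_in_peaks(self, fragments: pd.DataFrame) -> tuple[int, float]:
        return self._either_insertion_in(fragments, self.peaks)

    def promoter_ratio(self, fragments: pd.DataFrame) -> float:
        return self._either_insertion_in(fragments, self.promoters)[1]


def tss_enrichment(fragments: pd.DataFrame, tss: Mapping[str, np.ndarray],
                   center_halfwidth: int = 50,
                   flank: tuple[int, int] = (1901, 2000)) -> float:
    """TSS enrichment score of one cell's fragments (0 for empty cells)."""
    return AnnotationWindows(tss, center_halfwidth=center_halfwidth,
                             flank=flank).tss_score(fragments)


def fraction_in_peaks(fragments: pd.DataFrame,
                      peaks: Mapping[str, np.ndarray]) -> tuple[int, float]:
    """(n_fip, fip_fraction): fragments with either insertion inside a peak."""
    return AnnotationWindows({}, peaks=peaks).fraction_in_peaks(fragments)


def promoter_ratio(fragments: pd.DataFrame, tss: Mapping[str, np.ndarray],
                   promoter: tuple[int, int] = (2000, 101)) -> float:
    """Fraction of fragments with an insertion in [TSS-2000, TSS+101)."""
    return AnnotationWindows(tss, promoter=promoter).promoter_ratio(fragments)


# ---------------------------------------------------------------------------
# per-cell QC table


def compute_qc(
    fragments: Optional[pd.DataFrame],
    molecule_counts: Optional[pd.DataFrame],
    tss: Mapping[str, np.ndarray],
    peaks: Mapping[str, np.ndarray],
    gene_categories: Optional[Mapping[str, str]] = None,
    occupancy: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Assemble the per-cell QC table across both modalities.

    ``fragments`` is the deduplicated fragment table (with sample/droplet
    columns); ``molecule_counts`` the collapsed (cell, gene, n_molecules)
    table; ``occupancy`` maps droplet barcode -> distinct samples per droplet.
    Cells absent from a modality carry NaN in that modality's metrics.
    """
    windows = AnnotationWindows(tss, peaks=peaks)
    rows = []
    if fragments is not None and len(fragments):
        frags = fragments.copy()
        frags["cell"] = frags["sample"] + ":" + frags["droplet"]
        for cell, grp in frags.groupby("cell", sort=True):
            n_fip, fip = windows.fraction_in_peaks(grp)
            rows.append({
                "cell": cell,
                "n_fragments": len(grp),
                "n_fip": n_fip,
                "fip_fraction": fip,
                "tss_score": windows.tss_score(grp),
                "promoter_ratio": windows.promoter_ratio(grp),
            })
    atac_df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=["cell"])

    rna_df = pd.DataFrame(columns=["cell"])
    if molecule_counts is not None and len(molecule_counts):
        mc = molecule_counts.copy()
        if gene_categories:
            mc["category"] = mc["gene"].map(gene_categories).fillna("protein")
        else:
            mc["category"] = "protein"
        agg = mc.groupby("cell").agg(
            n_umi=("n_molecules", "sum"), n_genes=("gene", "nunique"))
        for cat, col in (("mito", "pct_mito"), ("ribo", "pct_ribo")):
            sub = mc[mc.category == cat].groupby("cell")["n_molecules"].sum()
            agg[col] = 100.0 * sub.reindex(agg.index).fillna(0) / agg["n_umi"]
        rna_df = agg.reset_index()

    qc = atac_df.merge(rna_df, on="cell", how="outer")
    if len(qc) == 0:
        return qc
    qc["sample"] = qc["cell"].str.rpartition(":")[0]
    qc["droplet"] = qc["cell"].str.rpartition(":")[2]
    if occupancy is not None:
        qc["droplet_occupancy"] = qc["droplet"].map(occupancy)
    else:
        occ = qc.groupby("droplet")["sample"].nunique()
        qc["droplet_occupancy"] = qc["droplet"].map(occ)
    return qc.sort_values("cell", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# filter profiles


@dataclass(frozen=True)
class Threshold:
    value: float
    inclusive: bool = True

    def passes_min(self, x) -> pd.Series:
        return (x >= self.value) if self.inclusive else (x > self.value)

    def passes_max(self, x) -> pd.Series:
        return (x <= self.value) if self.inclusive else (x < self.value)


# threshold name -> (QC column, direction)
_ATAC_RULES = {
    "min_fragments": ("n_fragments", "min"),
    "min_tss": ("tss_score", "min"),
    "min_promoter_ratio": ("promoter_ratio", "min"),
    "min_fip_fraction": ("fip_fraction", "min"),
    "max_nuclei_per_droplet": ("droplet_occupancy", "max"),
}
_RNA_RULES = {
    "min_genes": ("n_genes", "min"),
    "min_umis": ("n_umi", "min"),
    "max_pct_mito": ("pct_mito", "max"),
    "max_nuclei_per_droplet": ("droplet_occupancy", "max"),
}


@dataclass
class FilterProfile:
    """A named set of per-modality QC thresholds; unset thresholds are inert."""

    name: str
    atac: dict[str, Threshold] = field(default_factory=dict)
    rna: dict[str, Threshold] = field(default_factory=dict)
    umi_range: Optional[tuple[Threshold, Threshold]] = None

    def __post_init__(self) -> None:
        unknown = set(self.atac) - set(_ATAC_RULES)
        unknown |= set(self.rna) - set(_RNA_RULES)
        if unknown:
            raise ValueError(f"unknown threshold name(s): {sorted(unknown)}")
        for t in list(self.atac.values()) + list(self.rna.values()):
            if t.value < 0:
                raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_dict(cls, name: str, doc: Mapping) -> "FilterProfile":
        def conv(side: Mapping) -> dict[str, Threshold]:
            return {k: Threshold(**v) for k, v in side.items() if k != "umi_range"}

        umi_range = None
        rna = doc.get("rna") or {}
        if "umi_range" in rna:
            umi_range = (Threshold(**rna["umi_range"]["min"]),
                         Threshold(**rna["umi_range"]["max"]))
        return cls(name=name, atac=conv(doc.get("atac") or {}),
                   rna=conv(rna), umi_range=umi_range)


def _profile_doc() -> dict:
    text = (resources.files("sumdemux") / "data" / "profiles.yaml").read_text()
    return yaml.safe_load(text)


def available_profiles() -> list[str]:
    return sorted(_profile_doc())


def load_profile(name: str, overrides: Optional[Mapping] = None) -> FilterProfile:
    """Load a named preset, optionally overriding individual thresholds."""
    doc = _profile_doc()
    if name not in doc:
        raise KeyError(f"unknown profile {name!r}; "
                       f"available: {available_profiles()}")
    merged = doc[name]
    if overrides:
        merged = {side: {**(merged.get(side) or {}),
                         **(overrides.get(side) or {})}
                  for side in ("atac", "rna")}
    return FilterProfile.from_dict(name, merged)


def apply_filters(qc: pd.DataFrame, profile: FilterProfile
                  ) -> tuple[pd.DataFrame, dict]:
    """Set pass/fail flags on the QC table and summarize rejection reasons.

    A cell missing the metric a threshold applies to (NaN) fails that
    threshold.  ``pass_joint`` requires both modality flags.
    """
    out = qc.copy()
    summary: dict[str, int] = {}

    def run(rules, thresholds, flag_col):
        ok = pd.Series(True, index=out.index)
        for tname, thr in thresholds.items():
            col, direction = rules[tname]
            x = out[col] if col in out.columns else pd.Series(np.nan,
                                                              index=out.index)
            good = thr.passes_min(x) if direction == "min" else thr.passes_max(x)
            good = good.fillna(False)
            summary[f"fail_{flag_col[5:]}_{tname}"] = int((~good).sum())
            ok &= good
        out[flag_col] = ok

    run(_ATAC_RULES, profile.atac, "pass_atac")
    run(_RNA_RULES, profile.rna, "pass_rna")
    if profile.umi_range is not None:
        lo, hi = profile.umi_range
        x = out["n_umi"] if "n_umi" in out.columns else pd.Series(
            np.nan, index=out.index)
        good = (lo.passes_min(x) & hi.passes_max(x)).fillna(False)
        summary["fail_rna_umi_range"] = int((~good).sum())
        out["pass_rna"] &= good
    out["pass_joint"] = out["pass_atac"] & out["pass_rna"]
    summary["n_cells"] = len(out)
    summary["n_pass_atac"] = int(out["pass_atac"].sum())
    summary["n_pass_rna"] = int(out["pass_rna"].sum())
    summary["n_pass_joint"] = int(out["pass_joint"].sum())
    return out, summary


# ---------------------------------------------------------------------------
# knee-based cell calling


@dataclass
class KneeResult:
    retained: list[str]
    knee_rank: int  # 1-based rank of the knee barcode; 0 on fallback
    fallback: bool


def knee_call_cells(totals: pd.Series, window: int = 5,
                    fallback_min_count: int = 1) -> KneeResult:
    """Call cells from a barcode rank-vs-count curve.

    Barcodes are sorted by count (descending); on the log10(rank) vs
    log10(count) curve, smoothed by a centred rolling median, the knee is the
    point of maximum perpendicular distance to the chord joining the curve's
    endpoints.  Barcodes at or above the knee are retained.  A flat curve has
    no knee; the call falls back to a minimum-count threshold with a warning.

    The retained set is invariant under global count rescaling (a shift in
    log space) and under permutation of barcode labels.
    """
    totals = totals[totals > 0]
    if len(totals) < 50:
        raise ValueError("need at least 50 barcodes with a positive count")
    ranked = totals.sort_values(ascending=False, kind="mergesort")
    y = np.log10(ranked.to_numpy(dtype=float))
    x = np.log10(np.arange(1, len(y) + 1, dtype=float))
    y_s = pd.Series(y).rolling(window, center=True, min_periods=1).median() \
        .to_numpy()

    p0 = np.array([x[0], y_s[0]])
    p1 = np.array([x[-1], y_s[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0 or np.ptp(y_s) < 1e-12:
        warnings.warn("flat barcode-rank curve: no knee, falling back to "
                      f"count >= {fallback_min_count}", stacklevel=2)
        kept = ranked[ranked >= fallback_min_count]
        return KneeResult(retained=list(kept.index), knee_rank=0, fallback=True)
    d = np.abs(chord[0] * (y_s - p0[1]) - chord[1] * (x - p0[0])) / norm
    knee = int(np.argmax(d))
    if d[knee] < 1e-12:
        warnings.warn("degenerate barcode-rank curve: no knee, falling back "
                      f"to count >= {fallback_min_count}", stacklevel=2)
        kept = ranked[ranked >= fallback_min_count]
        return KneeResult(retained=list(kept.index), knee_rank=0, fallback=True)
    return KneeResult(retained=list(ranked.index[: knee + 1]),
                      knee_rank=knee + 1, fallback=False)


def saturation(total_reads: int, unique_items: int) -> float:
    """Sequencing saturation: 1 - unique molecules / total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if unique_items > total_reads or unique_items < 0:
        raise ValueError("unique_items must be in [0, total_reads]")
    return 1.0 - unique_items / total_reads
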