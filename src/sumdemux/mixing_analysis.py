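"""Barnyard species-mixing analysis, droplet occupancy and hopping diagnostics.

In a two-species mixing experiment, two nuclei that end up with the same
(sample index, droplet barcode) pair are indistinguishable — a *collision*.
Only cross-species collisions are observable: a "cell" whose reads split
across both genomes.  A cell is a singlet of species *s* when strictly more
than 90% (ATAC fragments) or 80% (RNA UMIs) of its reads align to *s*;
everything else is a collision.  The headline collision rate is the raw
cross-species fraction, uncorrected for invisible same-species collisions
(an optional x2 correction for equal species proportions is provided but off
by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SINGLET_THRESHOLDS",
    "classify_species",
    "collision_rate",
    "droplet_occupancy",
    "OccupancyTable",
    "hopping_diagnostic",
    "HoppingReport",
]

# strict (>) singlet thresholds per modality
SINGLET_THRESHOLDS = {"ATAC": 0.9, "RNA": 0.8}


def classify_species(counts: pd.DataFrame, modality: str,
                     threshold: Optional[float] = None) -> pd.DataFrame:
    """Classify cells as species singlets or collisions from per-species counts.

    ``counts`` has columns cell, species, count (reads/fragments/UMIs per
    genome).  A cell is a singlet of species ``s`` iff its fraction on ``s``
    is *strictly* greater than the threshold (0.9 for ATAC, 0.8 for RNA);
    otherwise it is a collision.  Cells with zero total count are excluded
    and reported in the ``n_excluded`` attribute of the result.
    """
    if threshold is None:
        if modality not in SINGLET_THRESHOLDS:
            raise ValueError(f"unknown modality {modality!r}")
        threshold = SINGLET_THRESHOLDS[modality]
    wide = counts.pivot_table(index="cell", columns="species", values="count",
                              aggfunc="sum", fill_value=0)
    totals = wide.sum(axis=1)
    n_excluded = int((totals == 0).sum())
    wide = wide[totals > 0]
    totals = totals[totals > 0]
    frac = wide.div(totals, axis=0)
    call = pd.Series("collision", index=frac.index, dtype=object)
    for sp in frac.columns:
        call[frac[sp] > threshold] = f"{sp}_singlet"
    out = frac.add_prefix("frac_")
    out["total"] = totals
    out["call"] = call
    out = out.reset_index()
    out.attrs["n_excluded"] = n_excluded
    out.attrs["modality"] = modality
    return out


def collision_rate(calls: pd.DataFrame, corrected: bool = False) -> float:
    """Observed cross-species collision fraction among classified cells.

    With ``corrected=True`` the value is doubled — the inferred total
    multiplet rate under equal species proportions, where half of the
    collisions are invisible same-species pairings.
    """
    if len(calls) == 0:
        raise ValueError("no classified cells")
    rate = float((calls["call"] == "collision").mean())
    return min(1.0, 2.0 * rate) if corrected else rate


@dataclass
class OccupancyTable:
    """Distinct-sample count per droplet among called cells.

    Same-sample co-encapsulation is invisible by construction: two nuclei of
    one sample in one droplet share a cell key.  Occupancy here is therefore
    a lower bound on the true number of nuclei per droplet.
    """

    per_droplet: pd.Series  # droplet barcode -> n distinct samples
    histogram: pd.Series  # occupancy -> n droplets

    def occupancy_of(self, droplet: str) -> int:
        return int(self.per_droplet.get(droplet, 0))


def droplet_occupancy(cells) -> OccupancyTable:
    """Occupancy table from called cells (iterable of CellKey or 'S:bc')."""
    pairs = []
    for c in cells:
        text = str(c)
        sample, _, bc = text.rpartition(":")
        pairs.append((sample, bc))
    if not pairs:
        per = pd.Series(dtype=int)
        return OccupancyTable(per_droplet=per,
                              histogram=pd.Series(dtype=int))
    df = pd.DataFrame(pairs, columns=["sample", "droplet"]).drop_duplicates()
    per = df.groupby("droplet")["sample"].nunique().sort_index()
    hist = per.value_counts().sort_index()
    return OccupancyTable(per_droplet=per, histogram=hist)


@dataclass
class HoppingReport:
    score: float  # NaN when undefined
    baseline: float  # expected random-coincidence score
    n_multi_droplets: int
    n_tuples: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.score)


def hopping_diagnostic(fragments: pd.DataFrame,
                       genome_sizes: Optional[Mapping[str, int]] = None
                       ) -> HoppingReport:
    """Quantify within-droplet barcode hopping from coordinate coincidences.

    Within droplets hosting >= 2 sample labels, the score is the fraction of
    distinct fragment coordinate tuples (contig, start, end) that occur under
    two or more sample labels of the *same* droplet.  Under the
    coordinate-preserving hopping mechanism, each hopped fragment produces
    exactly such a coincidence, so the score estimates the per-fragment
    hopping probability directly.

    The random-coincidence baseline is the first-order expectation of the
    score if all coincidences were chance: cross-sample fragment pairs within
    a droplet collide when they independently draw the same start position
    (~1/G on a genome of size G) and the same length (sum of squared length
    frequencies).  Returns NaN score when no multi-sample droplet exists.
    """
    if len(fragments) == 0:
        return HoppingReport(float("nan"), float("nan"), 0, 0)
    frags = fragments.copy()
    n_samples = frags.groupby("droplet")["sample"].transform("nunique")
    multi = frags[n_samples >= 2]
    n_multi_droplets = multi["droplet"].nunique()
    if n_multi_droplets == 0:
        return HoppingReport(float("nan"), float("nan"), 0, 0)

    tuples = multi.drop_duplicates(["droplet", "contig", "start", "end",
                                    "sample"])
    per_tuple = tuples.groupby(["droplet", "contig", "start", "end"])["sample"] \
        .nunique()
    n_tuples = len(per_tuple)
    score = float((per_tuple >= 2).mean())

    # analytic chance-coincidence baseline
    lengths = (multi["end"] - multi["start"]).to_numpy()
    vals, cnt = np.unique(lengths, return_counts=True)
    p_len = ((cnt / cnt.sum()) ** 2).sum()
    if genome_sizes:
        g_total = float(sum(genome_sizes.values()))
    else:
        # fall back to the observed coordinate span per contig
        g_total = float(sum(
            multi[multi.contig == c]["end"].max() for c in multi.contig.unique()
        ))
    p_pair = p_len / max(g_total, 1.0)
    cross_pairs = 0.0
    for _, grp in multi.groupby("droplet"):
        sizes = grp.groupby("sample").size().to_numpy(dtype=float)
        tot = sizes.sum()
        cross_pairs += (tot * tot - (sizes * sizes).sum()) / 2.0
    baseline = float(min(1.0, cross_pairs * p_pair / max(n_tuples, 1)))
    return HoppingReport(score=score, baseline=baseline,
                         n_multi_droplets=int(n_multi_droplets),
                         n_tuples=int(n_tuples))


def species_counts_from_fragments(fragments: pd.DataFrame,
                                  species_of_contig: Mapping[str, str]
                                  ) -> pd.DataFrame:
    """Per-cell unique-fragment counts per species (ATAC barnyard input)."""
    frags = fragments.copy()
    frags["cell"] = frags["sample"] + ":" + frags["droplet"]
    frags["species"] = frags["contig"].map(dict(species_of_contig))
    out = (frags.groupby(["cell", "species"]).size().rename("count")
           .reset_index())
    return out


def species_counts_from_molecules(molecule_counts: pd.DataFrame,
                                  species_of_gene: Mapping[str, str]
                                  ) -> pd.DataFrame:
    """Per-cell molecule counts per species (RNA barnyard input)."""
    mc = molecule_counts.copy()
    mc["species"] = mc["gene"].map(dict(species_of_gene))
    out = (mc.groupby(["cell", "species"])["n_molecules"].sum().rename("count")
           .reset_index())
    return out
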