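"""Ground-truthed simulator for overloaded-droplet single-nucleus multiome runs.

The simulator emulates the experimental design this package demultiplexes:
nuclei from ``n_samples`` bulk-indexed samples (each sample either a single
species or an equal two-species mixture, as in a barnyard experiment) are
overloaded onto droplets uniformly at random, so many droplets carry several
nuclei.  Each nucleus emits ATAC fragments and RNA molecules; reads carry the
sample index and droplet barcode according to the configured read layouts.
Three noise processes are modelled on top:

* **ambient reads** — reads carrying a real droplet barcode but no nucleus
  context (free-floating material);
* **per-base substitution sequencing error**, applied after the ground truth
  is recorded;
* **Tn5 barcode hopping** — an ATAC fragment re-emitted, coordinates
  preserved, under a *different* sample index present in the same droplet
  (the carry-over-oligo mechanism; only possible in multi-sample droplets).

Everything is driven by a single seed and two runs with equal configuration
are byte-identical, including the gzipped FASTQ output.  Toy reference
genomes are built so that every 25-mer is unique within and across species,
which makes exact-match alignment of read ends unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .barcode_model import (
    ATAC_LAYOUT,
    RNA_LAYOUT,
    BarcodeWhitelist,
    CellKey,
    ReadLayout,
)
from .io import FastqQuadWriter, read_bed, read_fasta, revcomp, write_bed, write_fasta

__all__ = [
    "ToyReference",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "make_toy_reference",
    "simulate_experiment",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# toy reference


@dataclass
class ToyReference:
    """Two small single-contig genomes with TSS / peak / gene annotations.

    Coordinates are 0-based half-open.  The unique-25-mer invariant (within
    and across species) guarantees that the mock exact-match aligner is
    unambiguous.
    """

    contigs: dict[str, str]  # contig name -> sequence
    species_of_contig: dict[str, str]
    tss: dict[str, np.ndarray]  # contig -> sorted TSS positions
    peaks: dict[str, np.ndarray]  # contig -> (n, 2) sorted non-overlapping
    genes: pd.DataFrame  # contig, start, end, name, category
    k: int = 25

    _kmer_index: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.species_of_contig.values()))

    def contig_for(self, species: str) -> str:
        for contig, sp in self.species_of_contig.items():
            if sp == species:
                return contig
        raise KeyError(species)

    def kmer_index(self) -> dict[str, tuple[str, int]]:
        """Forward-strand k-mer -> (contig, position). Built lazily, cached."""
        if self._kmer_index is None:
            index: dict[str, tuple[str, int]] = {}
            k = self.k
            for contig, seq in self.contigs.items():
                for i in range(len(seq) - k + 1):
                    index[seq[i : i + k]] = (contig, i)
            self._kmer_index = index
        return self._kmer_index

    def validate(self) -> None:
        k = self.k
        seen: set[str] = set()
        for contig, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in seen:
                    raise ValueError(f"repeated {k}-mer at {contig}:{i}")
                seen.add(kmer)
        for contig in self.contigs:
            size = len(self.contigs[contig])
            p = self.peaks[contig]
            if len(p) and (p[:, 0].min() < 0 or p[:, 1].max() > size):
                raise ValueError(f"peak out of bounds on {contig}")
            if len(p) > 1 and (p[1:, 0] < p[:-1, 1]).any():
                raise ValueError(f"overlapping peaks on {contig}")
        g = self.genes
        for _, row in g.iterrows():
            if row.start < 0 or row.end > len(self.contigs[row.contig]):
                raise ValueError(f"gene {row['name']} out of bounds")

    # -- persistence --------------------------------------------------------

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.contigs, outdir / "reference.fa")
        tss_rows = []
        for contig, positions in self.tss.items():
            for p in positions:
                tss_rows.append((contig, int(p), int(p) + 1))
        write_bed(pd.DataFrame(tss_rows, columns=["contig", "start", "end"]),
                  outdir / "tss.bed", ["contig", "start", "end"])
        peak_rows = [
            (contig, int(a), int(b))
            for contig, arr in self.peaks.items()
            for a, b in arr
        ]
        write_bed(pd.DataFrame(peak_rows, columns=["contig", "start", "end"]),
                  outdir / "peaks.bed", ["contig", "start", "end"])
        self.genes.to_csv(outdir / "genes.bed", sep="\t", header=False, index=False,
                          columns=["contig", "start", "end", "name", "category"])
        species_map = pd.DataFrame(
            sorted(self.species_of_contig.items()), columns=["contig", "species"]
        )
        species_map.to_csv(outdir / "species.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, refdir, k: int = 25) -> "ToyReference":
        refdir = Path(refdir)
        contigs = read_fasta(refdir / "reference.fa")
        species = pd.read_csv(refdir / "species.tsv", sep="\t")
        species_of_contig = dict(zip(species.contig, species.species))
        tss_df = read_bed(refdir / "tss.bed", ["contig", "start", "end"])
        peaks_df = read_bed(refdir / "peaks.bed", ["contig", "start", "end"])
        genes = read_bed(refdir / "genes.bed",
                         ["contig", "start", "end", "name", "category"])
        tss = {
            c: np.sort(tss_df.loc[tss_df.contig == c, "start"].to_numpy())
            for c in contigs
        }
        peaks = {}
        for c in contigs:
            sub = peaks_df[peaks_df.contig == c].sort_values("start")
            peaks[c] = sub[["start", "end"]].to_numpy().reshape(-1, 2)
        return cls(contigs=contigs, species_of_contig=species_of_contig,
                   tss=tss, peaks=peaks, genes=genes, k=k)


def _random_genome(rng: np.random.Generator, size: int, k: int,
                   forbidden: set[str], max_retries: int) -> str:
    """Random sequence whose k-mers are unique and disjoint from `forbidden`."""
    for _ in range(max_retries):
        seq = "".join(_BASES[rng.integers(0, 4, size=size)])
        kmers = set()
        ok = True
        for i in range(size - k + 1):
            km = seq[i : i + k]
            if km in kmers or km in forbidden:
                ok = False
                break
            kmers.add(km)
        if ok:
            forbidden |= kmers
            return seq
    raise RuntimeError(f"could not build a genome with unique {k}-mers "
                       f"after {max_retries} attempts")


def make_toy_reference(
    seed: int,
    species: Sequence[str] = ("human", "mouse"),
    size: int = 100_000,
    n_genes: int = 20,
    gene_length: int = 1_200,
    n_peaks: int = 40,
    peak_length: int = 400,
    promoter_peak_fraction: float = 0.5,
    n_mito_like: int = 2,
    n_ribo_like: int = 2,
    k: int = 25,
    max_retries: int = 10,
) -> ToyReference:
    """Build a two-species toy reference with TSS, peaks and labelled genes.

    Genes are laid out on a jittered grid with a 3 kb margin so that each
    promoter and its distal flanking windows fit inside the contig.  Half of
    the peaks (by default) sit on promoters, the rest in intergenic space at
    least 2.5 kb from any TSS.  A subset of genes is flagged
    mitochondrial-like / ribosomal-like for the percentage QC metrics.
    """
    if size < 10_000:
        raise ValueError("genome size must be >= 10 kb")
    margin = 3_000
    slot = (size - 2 * margin) // n_genes
    if slot < gene_length + 500:
        raise ValueError(
            f"cannot fit {n_genes} genes of {gene_length} bp into {size} bp"
        )
    rng = np.random.default_rng(seed)
    forbidden: set[str] = set()
    contigs: dict[str, str] = {}
    species_of_contig: dict[str, str] = {}
    tss: dict[str, np.ndarray] = {}
    peaks: dict[str, np.ndarray] = {}
    gene_rows = []

    for sp in species:
        contig = f"{sp}_chr1"
        contigs[contig] = _random_genome(rng, size, k, forbidden, max_retries)
        species_of_contig[contig] = sp

        starts = np.array(
            [margin + i * slot + rng.integers(0, slot - gene_length)
             for i in range(n_genes)]
        )
        tss[contig] = starts.copy()
        for i, s in enumerate(starts):
            if i < n_mito_like:
                cat = "mito"
            elif i < n_mito_like + n_ribo_like:
                cat = "ribo"
            else:
                cat = "protein"
            gene_rows.append((contig, int(s), int(s + gene_length),
                              f"{sp}_g{i + 1}", cat))

        n_prom = int(round(n_peaks * promoter_peak_fraction))
        prom_genes = rng.choice(n_genes, size=min(n_prom, n_genes), replace=False)
        intervals = [
            (int(starts[g]) - peak_length // 4,
             int(starts[g]) - peak_length // 4 + peak_length)
            for g in sorted(prom_genes)
        ]
        n_distal = n_peaks - len(intervals)
        placed = 0
        tries = 0
        while placed < n_distal:
            tries += 1
            if tries > 200 * n_peaks:
                raise ValueError(
                    f"cannot fit {n_peaks} peaks of {peak_length} bp into "
                    f"{size} bp (genome too small or too many peaks)"
                )
            a = int(rng.integers(500, size - 500 - peak_length))
            b = a + peak_length
            if np.min(np.abs(starts - (a + b) // 2)) < 2_500:
                continue
            if any(a < e and s < b for s, e in intervals):
                continue
            intervals.append((a, b))
            placed += 1
        peaks[contig] = np.array(sorted(intervals), dtype=np.int64).reshape(-1, 2)

    genes = pd.DataFrame(
        gene_rows, columns=["contig", "start", "end", "name", "category"]
    )
    ref = ToyReference(contigs=contigs, species_of_contig=species_of_contig,
                       tss=tss, peaks=peaks, genes=genes, k=k)
    ref.validate()
    return ref


# ---------------------------------------------------------------------------
# simulation configuration


@dataclass
class SimConfig:
    """Parameters of one simulated run.

    Defaults describe a small barnyard experiment: 4 equally mixed
    human/mouse samples of 250 nuclei each, overloaded onto 2,000 droplets
    (mean occupancy 0.5 nuclei per droplet).  Per-nucleus depths are
    negative-binomial; ambient fractions default to 0.10 (ATAC) and 0.30
    (RNA), matching the unassigned-read shares typical of this assay class.
    """

    n_samples: int = 4
    nuclei_per_sample: int = 250
    species_of_sample: Optional[dict[str, str]] = None  # label -> species|"mixed"
    mixed_fraction: float = 0.5  # P(first species) within a "mixed" sample
    n_droplets: int = 2_000
    fragments_per_nucleus_mean: float = 100.0
    fragments_per_nucleus_dispersion: float = 10.0  # NB size parameter r
    frac_fragments_in_peaks: float = 0.4
    umis_per_nucleus_mean: float = 50.0
    umis_per_nucleus_dispersion: float = 10.0
    ambient_fraction_atac: float = 0.10
    ambient_fraction_rna: float = 0.30
    seq_error_rate: float = 0.002
    hopping_rate: float = 0.0
    atac_dup_mean: float = 1.3  # mean reads per unique fragment (>= 1)
    rna_reads_per_umi_mean: float = 1.3
    subnucleosomal_fraction: float = 0.6
    rna_indices_per_sample: int = 2
    modalities: tuple[str, ...] = ("ATAC", "RNA")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_fragments_in_peaks", "ambient_fraction_atac",
                     "ambient_fraction_rna", "seq_error_rate", "hopping_rate",
                     "subnucleosomal_fraction", "mixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.atac_dup_mean < 1 or self.rna_reads_per_umi_mean < 1:
            raise ValueError("mean reads per item must be >= 1")
        if self.n_samples < 1 or self.n_droplets < 1:
            raise ValueError("n_samples and n_droplets must be positive")

    @property
    def sample_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    def resolved_species_of_sample(self) -> dict[str, str]:
        if self.species_of_sample is None:
            return {s: "mixed" for s in self.sample_labels}
        missing = set(self.sample_labels) - set(self.species_of_sample)
        if missing:
            raise ValueError(f"species_of_sample missing labels: {sorted(missing)}")
        return dict(self.species_of_sample)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "modalities" in d:
            d["modalities"] = tuple(d["modalities"])
        return cls(**d)


def _negative_binomial(rng, mean: float, r: float, size: int) -> np.ndarray:
    # NB with mean m and size r: p = r / (r + m)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruth:
    """Per-read, per-nucleus, per-droplet truth tables for one simulation."""

    nuclei: pd.DataFrame  # nucleus_id, sample, species, droplet, depths
    reads: pd.DataFrame  # read_id, modality, origin, sample, droplet, nucleus_id, origin_sample
    fragments: pd.DataFrame  # contig,start,end,cell,dup_count,hopped reads included
    molecules: pd.DataFrame  # cell, gene, umi, reads
    droplets: pd.DataFrame  # droplet, n_nuclei, n_samples_distinct

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.nuclei.to_csv(outdir / "truth_nuclei.tsv", sep="\t", index=False)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        self.fragments.to_csv(outdir / "truth_fragments.tsv", sep="\t", index=False)
        self.molecules.to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
        self.droplets.to_csv(outdir / "truth_droplets.tsv", sep="\t", index=False)

    def cell_fragment_counts(self) -> pd.Series:
        """Unique (deduplicated) fragment count per cell, nucleus origin only."""
        frag = self.fragments
        real = frag[~frag.hopped]
        dedup = real.drop_duplicates(["cell", "contig", "start", "end"])
        return dedup.groupby("cell").size()

    def cell_molecule_counts(self) -> pd.Series:
        mol = self.molecules.drop_duplicates(["cell", "gene", "umi"])
        return mol.groupby("cell").size()


@dataclass
class SimResult:
    config: SimConfig
    reference: ToyReference
    truth: GroundTruth
    fastq_paths: dict[str, dict[str, Path]]  # modality -> {R1,R2,I1,I2: path}
    whitelists: dict[str, BarcodeWhitelist]  # "ATAC_sample","RNA_sample","droplet"
    sample_maps: dict[str, dict[str, str]]  # modality -> index seq -> label
    layouts: dict[str, ReadLayout]


# ---------------------------------------------------------------------------
# simulation


def _fragment_lengths(rng, n: int, sub_fraction: float) -> np.ndarray:
    """Raw genomic fragment lengths: sub-nucleosomal + mono-nucleosomal bands."""
    is_sub = rng.random(n) < sub_fraction
    sub = np.clip(np.round(rng.normal(105, 15, size=n)), 60, 140)
    nuc = np.clip(np.round(rng.normal(300, 25, size=n)), 250, 350)
    return np.where(is_sub, sub, nuc).astype(np.int64)


def _apply_errors(rng, seqs: list[str], rate: float) -> list[str]:
    """Per-base substitution errors; substitutions always change the base."""
    if rate <= 0 or not seqs:
        return seqs
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    n_err = rng.binomial(lengths, rate)
    out = seqs
    hit = np.nonzero(n_err)[0]
    if len(hit) == 0:
        return out
    out = list(seqs)
    for i in hit:
        s = list(out[i])
        pos = rng.choice(len(s), size=min(n_err[i], len(s)), replace=False)
        for p in pos:
            cur = s[p]
            alternatives = [b for b in "ACGT" if b != cur]
            s[p] = alternatives[rng.integers(0, 3)]
        out[i] = "".join(s)
    return out


def build_default_whitelists(cfg: SimConfig, rng: np.random.Generator
                             ) -> tuple[dict[str, BarcodeWhitelist],
                                        dict[str, dict[str, str]]]:
    """Random whitelists sized for the run, plus index -> sample maps.

    Pairwise Hamming separation is chosen so correction at the default
    mismatch tolerances is always unambiguous: ATAC sample indices (d=1)
    and droplet barcodes (d=1) at min distance 3, RNA sample indices (d=2)
    at min distance 5.
    """
    from .barcode_model import random_whitelist

    atac_wl = random_whitelist(cfg.n_samples, 11, 3, rng,
                               label="atac_sample", modality="ATAC")
    rna_wl = random_whitelist(cfg.n_samples * cfg.rna_indices_per_sample, 11, 5,
                              rng, label="rna_sample", modality="RNA")
    droplet_wl = random_whitelist(cfg.n_droplets, 16, 3, rng,
                                  label="droplet", modality="droplet")
    labels = cfg.sample_labels
    atac_map = {seq: labels[i] for i, seq in enumerate(atac_wl.entries)}
    rna_map = {
        seq: labels[i // cfg.rna_indices_per_sample]
        for i, seq in enumerate(rna_wl.entries)
    }
    whitelists = {"ATAC_sample": atac_wl, "RNA_sample": rna_wl,
                  "droplet": droplet_wl}
    sample_maps = {"ATAC": atac_map, "RNA": rna_map}
    return whitelists, sample_maps


def simulate_experiment(
    cfg: SimConfig,
    ref: ToyReference,
    outdir,
    layouts: Optional[dict[str, ReadLayout]] = None,
    whitelists: Optional[dict[str, BarcodeWhitelist]] = None,
    sample_maps: Optional[dict[str, dict[str, str]]] = None,
) -> SimResult:
    """Simulate one run: write FASTQ quadruples and return the ground truth.

    The generation order is: nucleus reads, hopped copies, ambient reads —
    all deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layouts = dict(layouts or {"ATAC": ATAC_LAYOUT, "RNA": RNA_LAYOUT})
    if whitelists is None or sample_maps is None:
        whitelists, sample_maps = build_default_whitelists(cfg, rng)
    if len(whitelists["droplet"]) < cfg.n_droplets:
        raise ValueError("droplet whitelist smaller than n_droplets")
    if len(set(sample_maps["ATAC"].values())) < cfg.n_samples:
        raise ValueError("ATAC sample map covers fewer labels than n_samples")

    species_of_sample = cfg.resolved_species_of_sample()
    species_list = list(ref.species)
    if any(v == "mixed" for v in species_of_sample.values()) and len(species_list) < 2:
        raise ValueError("mixed samples require a two-species reference")

    labels = cfg.sample_labels
    atac_index_of_sample = {v: k for k, v in sample_maps["ATAC"].items()}
    rna_indices_of_sample: dict[str, list[str]] = {}
    for seq, label in sample_maps["RNA"].items():
        rna_indices_of_sample.setdefault(label, []).append(seq)

    droplet_entries = whitelists["droplet"].entries[: cfg.n_droplets]

    # ---- nuclei ----------------------------------------------------------
    n_nuclei = cfg.n_samples * cfg.nuclei_per_sample
    sample_of_nucleus = np.repeat(np.arange(cfg.n_samples), cfg.nuclei_per_sample)
    droplet_of_nucleus = rng.integers(0, cfg.n_droplets, size=n_nuclei)
    species_idx = np.empty(n_nuclei, dtype=np.int64)
    for i in range(n_nuclei):
        spec = species_of_sample[labels[sample_of_nucleus[i]]]
        if spec == "mixed":
            species_idx[i] = 0 if rng.random() < cfg.mixed_fraction else 1
        else:
            species_idx[i] = species_list.index(spec)

    nuclei = pd.DataFrame({
        "nucleus_id": np.arange(n_nuclei),
        "sample": [labels[s] for s in sample_of_nucleus],
        "species": [species_list[s] for s in species_idx],
        "droplet": [droplet_entries[d] for d in droplet_of_nucleus],
    })

    droplets = (
        nuclei.groupby("droplet")
        .agg(n_nuclei=("nucleus_id", "size"),
             n_samples_distinct=("sample", "nunique"))
        .reset_index()
    )
    samples_in_droplet: dict[int, list[str]] = {}
    for d, grp in nuclei.assign(di=droplet_of_nucleus).groupby("di"):
        samples_in_droplet[int(d)] = sorted(grp["sample"].unique())

    # ---- ATAC ------------------------------------------------------------
    atac_reads: list[dict[str, str]] = []
    atac_truth_rows: list[tuple] = []
    frag_rows: list[tuple] = []
    mol_rows: list[tuple] = []
    rna_reads: list[dict[str, str]] = []
    rna_truth_rows: list[tuple] = []
    n_frag_per_nuc = np.zeros(n_nuclei, dtype=np.int64)
    n_umi_per_nuc = np.zeros(n_nuclei, dtype=np.int64)

    do_atac = "ATAC" in cfg.modalities
    do_rna = "RNA" in cfg.modalities

    merged_peaks = {c: ref.peaks[c] for c in ref.contigs}

    if do_atac:
        frag_counts = _negative_binomial(
            rng, cfg.fragments_per_nucleus_mean,
            cfg.fragments_per_nucleus_dispersion, n_nuclei)
        n_frag_per_nuc = frag_counts
        for nid in range(n_nuclei):
            n = int(frag_counts[nid])
            if n == 0:
                continue
            sample = labels[sample_of_nucleus[nid]]
            droplet_bc = droplet_entries[droplet_of_nucleus[nid]]
            contig = ref.contig_for(species_list[species_idx[nid]])
            genome = ref.contigs[contig]
            size = len(genome)
            peaks = merged_peaks[contig]
            lengths = _fragment_lengths(rng, n, cfg.subnucleosomal_fraction)
            in_peak = rng.random(n) < cfg.frac_fragments_in_peaks
            starts = np.empty(n, dtype=np.int64)  # shifted fragment starts
            for j in range(n):
                L = int(lengths[j])
                if in_peak[j] and len(peaks):
                    pk = peaks[rng.integers(0, len(peaks))]
                    p = int(rng.integers(pk[0], pk[1]))  # start insertion in peak
                    p = min(max(p, 4), size - L + 4 - 1)
                    starts[j] = p
                else:
                    while True:
                        g = int(rng.integers(0, size - L))
                        s, e = g + 4, g + L - 5  # shifted, half-open
                        # keep background clear of peaks so FiP matches config
                        i1 = np.searchsorted(peaks[:, 0], s, side="right") - 1
                        i2 = np.searchsorted(peaks[:, 0], e - 1, side="right") - 1
                        hit = (i1 >= 0 and s < peaks[i1, 1]) or \
                              (i2 >= 0 and e - 1 < peaks[i2, 1])
                        if not hit:
                            starts[j] = s
                            break
            dups = 1 + rng.poisson(cfg.atac_dup_mean - 1.0, size=n)
            di = int(droplet_of_nucleus[nid])
            multi = [s for s in samples_in_droplet[di] if s != sample]
            for j in range(n):
                s = int(starts[j])
                L = int(lengths[j])
                gstart, gend = s - 4, s - 4 + L  # raw genomic fragment
                end = gend - 5  # shifted half-open end
                r1 = genome[gstart : gstart + 55]
                r2 = revcomp(genome[gend - 55 : gend])
                frag_rows.append((contig, s, end, sample, droplet_bc,
                                  int(dups[j]), False, ""))
                for _ in range(int(dups[j])):
                    atac_reads.append({
                        "R1": r1, "R2": r2,
                        "I1": atac_index_of_sample[sample],
                        "I2": droplet_bc,
                    })
                    atac_truth_rows.append(("nucleus", sample, droplet_bc, nid, ""))
                if multi and cfg.hopping_rate > 0 and rng.random() < cfg.hopping_rate:
                    dest = multi[rng.integers(0, len(multi))]
                    frag_rows.append((contig, s, end, dest, droplet_bc,
                                      1, True, sample))
                    atac_reads.append({
                        "R1": r1, "R2": r2,
                        "I1": atac_index_of_sample[dest],
                        "I2": droplet_bc,
                    })
                    atac_truth_rows.append(("hopped", dest, droplet_bc, nid, sample))

        # ambient ATAC reads
        n_real = len(atac_reads)
        f = cfg.ambient_fraction_atac
        n_amb = int(round(f / (1.0 - f) * n_real)) if f < 1 else 0
        contig_names = list(ref.contigs)
        weights = np.array([len(ref.contigs[c]) for c in contig_names], dtype=float)
        weights /= weights.sum()
        for _ in range(n_amb):
            contig = contig_names[rng.choice(len(contig_names), p=weights)]
            genome = ref.contigs[contig]
            L = int(_fragment_lengths(rng, 1, cfg.subnucleosomal_fraction)[0])
            g = int(rng.integers(0, len(genome) - L))
            sample = labels[rng.integers(0, cfg.n_samples)]
            droplet_bc = droplet_entries[rng.integers(0, cfg.n_droplets)]
            atac_reads.append({
                "R1": genome[g : g + 55],
                "R2": revcomp(genome[g + L - 55 : g + L]),
                "I1": atac_index_of_sample[sample],
                "I2": droplet_bc,
            })
            atac_truth_rows.append(("ambient", sample, droplet_bc, -1, ""))

    # ---- RNA -------------------------------------------------------------
    if do_rna:
        genes_by_contig = {}
        for c in ref.contigs:
            sub = ref.genes[ref.genes.contig == c]
            genes_by_contig[c] = (sub["start"].to_numpy(),
                                  sub["end"].to_numpy(),
                                  sub["name"].to_numpy())
        umi_len = layouts["RNA"].umi_length
        umi_counts = _negative_binomial(
            rng, cfg.umis_per_nucleus_mean,
            cfg.umis_per_nucleus_dispersion, n_nuclei)
        n_umi_per_nuc = umi_counts
        p_dup = 1.0 / cfg.rna_reads_per_umi_mean
        for nid in range(n_nuclei):
            n = int(umi_counts[nid])
            if n == 0:
                continue
            sample = labels[sample_of_nucleus[nid]]
            droplet_bc = droplet_entries[droplet_of_nucleus[nid]]
            contig = ref.contig_for(species_list[species_idx[nid]])
            genome = ref.contigs[contig]
            gstarts, gends, gnames = genes_by_contig[contig]
            idx_choices = rna_indices_of_sample[sample]
            gene_ids = rng.integers(0, len(gnames), size=n)
            reads_per = rng.geometric(p_dup, size=n)
            for j in range(n):
                gi = int(gene_ids[j])
                offset = int(rng.integers(gstarts[gi], gends[gi] - 95))
                umi = "".join(_BASES[rng.integers(0, 4, size=umi_len)])
                index_seq = idx_choices[rng.integers(0, len(idx_choices))]
                r1 = genome[offset : offset + 95]
                cell = f"{sample}:{droplet_bc}"
                mol_rows.append((cell, str(gnames[gi]), umi, int(reads_per[j])))
                for _ in range(int(reads_per[j])):
                    rna_reads.append({
                        "R1": r1,
                        "R2": index_seq + umi,
                        "I1": "ACGTAC",
                        "I2": droplet_bc,
                    })
                    rna_truth_rows.append(("nucleus", sample, droplet_bc, nid, ""))

        n_real = len(rna_reads)
        f = cfg.ambient_fraction_rna
        n_amb = int(round(f / (1.0 - f) * n_real)) if f < 1 else 0
        all_rna_indices = list(sample_maps["RNA"])
        contig_names = list(ref.contigs)
        for _ in range(n_amb):
            contig = contig_names[rng.integers(0, len(contig_names))]
            genome = ref.contigs[contig]
            gstarts, gends, _ = genes_by_contig[contig]
            gi = int(rng.integers(0, len(gstarts)))
            offset = int(rng.integers(gstarts[gi], gends[gi] - 95))
            umi = "".join(_BASES[rng.integers(0, 4, size=umi_len)])
            index_seq = all_rna_indices[rng.integers(0, len(all_rna_indices))]
            droplet_bc = droplet_entries[rng.integers(0, cfg.n_droplets)]
            rna_reads.append({
                "R1": genome[offset : offset + 95],
                "R2": index_seq + umi,
                "I1": "ACGTAC",
                "I2": droplet_bc,
            })
            rna_truth_rows.append(
                ("ambient", sample_maps["RNA"][index_seq], droplet_bc, -1, ""))

    # ---- sequencing errors, applied after truth is recorded --------------
    for reads in (atac_reads, rna_reads):
        if not reads or cfg.seq_error_rate <= 0:
            continue
        for src in ("R1", "R2", "I1", "I2"):
            seqs = _apply_errors(rng, [r[src] for r in reads], cfg.seq_error_rate)
            for r, s in zip(reads, seqs):
                r[src] = s

    # ---- write FASTQ -----------------------------------------------------
    fastq_paths: dict[str, dict[str, Path]] = {}
    truth_read_frames = []
    if do_atac:
        with FastqQuadWriter(outdir / "fastq", "atac") as w:
            for i, r in enumerate(atac_reads):
                w.write(f"A{i:08d}", r)
            fastq_paths["ATAC"] = w.paths
        truth_read_frames.append(pd.DataFrame(
            atac_truth_rows,
            columns=["origin", "sample", "droplet", "nucleus_id", "origin_sample"],
        ).assign(modality="ATAC",
                 read_id=[f"A{i:08d}" for i in range(len(atac_truth_rows))]))
    if do_rna:
        with FastqQuadWriter(outdir / "fastq", "rna") as w:
            for i, r in enumerate(rna_reads):
                w.write(f"R{i:08d}", r)
            fastq_paths["RNA"] = w.paths
        truth_read_frames.append(pd.DataFrame(
            rna_truth_rows,
            columns=["origin", "sample", "droplet", "nucleus_id", "origin_sample"],
        ).assign(modality="RNA",
                 read_id=[f"R{i:08d}" for i in range(len(rna_truth_rows))]))

    reads_df = (pd.concat(truth_read_frames, ignore_index=True)
                if truth_read_frames else
                pd.DataFrame(columns=["origin", "sample", "droplet",
                                      "nucleus_id", "origin_sample",
                                      "modality", "read_id"]))

    fragments_df = pd.DataFrame(
        frag_rows,
        columns=["contig", "start", "end", "sample", "droplet", "dup_count",
                 "hopped", "origin_sample"],
    )
    if len(fragments_df):
        fragments_df["cell"] = (fragments_df["sample"] + ":"
                                + fragments_df["droplet"])
    else:
        fragments_df["cell"] = pd.Series(dtype=str)

    molecules_df = pd.DataFrame(mol_rows, columns=["cell", "gene", "umi", "reads"])

    nuclei = nuclei.assign(
        n_fragments=n_frag_per_nuc, n_umis=n_umi_per_nuc,
        cell=nuclei["sample"] + ":" + nuclei["droplet"],
    )

    truth = GroundTruth(nuclei=nuclei, reads=reads_df, fragments=fragments_df,
                        molecules=molecules_df, droplets=droplets)
    truth.write(outdir / "truth")

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    whitelists["ATAC_sample"].to_file(outdir / "whitelist_atac_sample.txt")
    whitelists["RNA_sample"].to_file(outdir / "whitelist_rna_sample.txt")
    whitelists["droplet"].to_file(outdir / "whitelist_droplet.txt")
    from .barcode_model import write_sample_map

    write_sample_map(sample_maps["ATAC"], outdir / "sample_map_atac.tsv")
    write_sample_map(sample_maps["RNA"], outdir / "sample_map_rna.tsv")
    with open(outdir / "layouts.yaml", "w") as fh:
        yaml.safe_dump({m: l.to_dict() for m, l in layouts.items()}, fh,
                       sort_keys=True)

    return SimResult(config=cfg, reference=ref, truth=truth,
                     fastq_paths=fastq_paths, whitelists=whitelists,
                     sample_maps=sample_maps, layouts=layouts)
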