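"""Alignment, fragment building, UMI collapsing, matrices and the
modality join — including the simulator-truth exactness oracle."""

import numpy as np
import pandas as pd
import pytest

import sumdemux as sd
from sumdemux.demux_core import (
    PAIR_COLUMNS,
    build_fragments,
    build_gene_matrix,
    build_tile_matrix,
    collapse_umis,
    dedup_fragments,
    match_modalities,
    mock_align,
)
from sumdemux.io import revcomp


class TestMockAlign:
    def test_forward_hit(self, ref_small):
        contig = next(iter(ref_small.contigs))
        read = ref_small.contigs[contig][5_000:5_055]
        aln = mock_align(read, ref_small)
        assert (aln.contig, aln.start, aln.strand) == (contig, 5_000, "+")
        assert aln.five_prime == 5_000

    def test_reverse_hit_symmetric_fragment_coordinates(self, ref_small):
        """A reverse-complemented read reports the 5' position of its first
        base, so forward/reverse mates of one fragment reconstruct the same
        interval."""
        contig = next(iter(ref_small.contigs))
        frag = ref_small.contigs[contig][5_000:5_200]
        fwd = mock_align(frag[:55], ref_small)
        rev = mock_align(revcomp(frag)[:55], ref_small)
        assert rev.strand == "-" and rev.contig == contig
        assert fwd.five_prime == 5_000
        assert rev.five_prime == 5_199  # last base of the fragment

    def test_absent_sequence_unmapped(self, ref_small, rng):
        # brute-force confirm the random 55-mer is on neither strand
        while True:
            read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 55)])
            present = any(read[:25] in seq or revcomp(read[:25]) in seq
                          for seq in ref_small.contigs.values())
            if not present:
                break
        assert mock_align(read, ref_small) is None


def _pairs(rows):
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


class TestBuildFragments:
    def test_identical_pairs_collapse_with_count(self):
        pairs = _pairs([("c", 100, 299, "S1", "bc")] * 3)
        frags = build_fragments(pairs)
        assert len(frags) == 1
        row = frags.iloc[0]
        assert (row.start, row.end, row.dup_count) == (104, 295, 3)

    def test_cell_aware_dedup_keeps_cells_apart(self):
        pairs = _pairs([("c", 100, 299, "S1", "bc1"),
                        ("c", 100, 299, "S1", "bc2")])
        assert len(build_fragments(pairs)) == 2

    def test_shift_disabled(self):
        frags = build_fragments(_pairs([("c", 100, 299, "S1", "bc")]),
                                shift=(0, 0))
        assert (frags.iloc[0].start, frags.iloc[0].end) == (100, 300)

    def test_dedup_idempotent(self, demux_noiseless):
        atac, _ = demux_noiseless
        again = dedup_fragments(atac.fragments)
        pd.testing.assert_frame_equal(again, atac.fragments)

    def test_noiseless_fragments_equal_truth(self, sim_noiseless,
                                             demux_noiseless):
        """End-to-end oracle: at zero noise the demultiplexed fragment set
        equals the simulator's ground-truth fragment set exactly."""
        atac, _ = demux_noiseless
        truth = (sim_noiseless.truth.fragments
                 .groupby(["contig", "start", "end", "sample", "droplet"],
                          as_index=False)["dup_count"].sum()
                 .sort_values(["contig", "start", "end", "sample", "droplet"],
                              kind="mergesort").reset_index(drop=True))
        got = atac.fragments.reset_index(drop=True)
        pd.testing.assert_frame_equal(got[truth.columns], truth,
                                      check_dtype=False)


class TestCollapseUmis:
    records = pd.DataFrame({
        "cell": ["c"] * 6, "gene": ["g"] * 6,
        "umi": ["AAAA"] * 5 + ["AAAT"],
    })

    def test_exact_counts_distinct_umis(self):
        out = collapse_umis(self.records, "exact")
        assert out.n_molecules.tolist() == [2]
        assert out.n_reads.tolist() == [6]

    def test_directional_merges_error_umi(self):
        # 5 reads of AAAA vs 1 of AAAT: 5 >= 2*1-1, Hamming 1 -> one molecule
        out = collapse_umis(self.records, "directional")
        assert out.n_molecules.tolist() == [1]

    def test_directional_keeps_balanced_pair(self):
        rec = pd.DataFrame({"cell": ["c"] * 4, "gene": ["g"] * 4,
                            "umi": ["AAAA", "AAAA", "AAAT", "AAAT"]})
        assert collapse_umis(rec, "directional").n_molecules.tolist() == [2]

    def test_directional_matches_network_oracle(self, rng):
        """Cross-check the cluster count against an explicit directed-graph
        enumeration on random small UMI sets."""
        from sumdemux.demux_core import _directional_clusters, _hamming1

        for _ in range(30):
            umis = {"".join(np.array(list("ACGT"))[rng.integers(0, 4, 3)]):
                    int(rng.integers(1, 20)) for _ in range(6)}
            got = _directional_clusters(umis)
            # oracle: count nodes unreachable from any other node via
            # allowed merge edges walked from stronger nodes first
            order = sorted(umis, key=lambda u: (-umis[u], u))
            absorbed = set()
            for v in order:
                if v in absorbed:
                    continue
                stack = [v]
                while stack:
                    x = stack.pop()
                    for u in order:
                        if u not in absorbed and u != v and _hamming1(u, x) \
                                and umis[x] >= 2 * umis[u] - 1:
                            absorbed.add(u)
                            stack.append(u)
            assert got == len(umis) - len(absorbed)

    def test_no_cross_gene_collapse(self):
        rec = pd.DataFrame({"cell": ["c"] * 2, "gene": ["g1", "g2"],
                            "umi": ["AAAA", "AAAA"]})
        out = collapse_umis(rec, "exact")
        assert out.n_molecules.sum() == 2

    def test_noiseless_molecules_equal_truth(self, sim_noiseless,
                                             demux_noiseless):
        _, rna = demux_noiseless
        got = collapse_umis(rna.records, "exact") \
            .groupby("cell")["n_molecules"].sum().sort_index()
        truth = sim_noiseless.truth.cell_molecule_counts().sort_index()
        assert got.astype(int).equals(truth.astype(int))


class TestTileMatrix:
    def test_insertions_straddle_tiles(self):
        frags = pd.DataFrame([("c", 100, 600, "S1", "b", 1)],
                             columns=["contig", "start", "end", "sample",
                                      "droplet", "dup_count"])
        mat = build_tile_matrix(frags, tile_size=500)
        assert mat.features == ["c:0-500", "c:500-1000"]
        assert mat.matrix.toarray().ravel().tolist() == [1, 1]

    def test_short_fragment_double_counts_one_tile(self):
        frags = pd.DataFrame([("c", 0, 10, "S1", "b", 1)],
                             columns=["contig", "start", "end", "sample",
                                      "droplet", "dup_count"])
        mat = build_tile_matrix(frags, tile_size=500)
        assert mat.features == ["c:0-500"]
        assert mat.matrix.toarray().ravel().tolist() == [2]

    def test_total_mass_is_twice_fragment_count(self, demux_noiseless):
        atac, _ = demux_noiseless
        mat = build_tile_matrix(atac.fragments)
        assert mat.matrix.sum() == 2 * len(atac.fragments)

    def test_mtx_roundtrip(self, demux_noiseless, tmp_path):
        atac, _ = demux_noiseless
        mat = build_tile_matrix(atac.fragments.head(500))
        mat.write(tmp_path, "tiles")
        back = sd.CountMatrix.read(tmp_path, "tiles")
        assert back.features == mat.features and back.cells == mat.cells
        assert (back.matrix != mat.matrix).nnz == 0


class TestGeneMatrix:
    @staticmethod
    def _counts(n_cells_per_gene):
        rows = []
        for gene, n in n_cells_per_gene.items():
            for i in range(n):
                rows.append((f"S1:bc{i}", gene, 1))
        return pd.DataFrame(rows, columns=["cell", "gene", "n_molecules"])

    def test_rare_feature_dropped(self):
        counts = self._counts({"g_common": 10, "g_rare": 9})
        mat = build_gene_matrix(counts, min_cells=10)
        assert mat.features == ["g_common"]

    def test_min_cells_one_keeps_everything(self):
        counts = self._counts({"a": 1, "b": 3})
        assert build_gene_matrix(counts, min_cells=1).features == ["a", "b"]

    def test_empty_result_warns(self):
        counts = self._counts({"a": 1})
        with pytest.warns(UserWarning, match="empty"):
            build_gene_matrix(counts, min_cells=5)

    def test_retained_features_match_census(self, demux_noiseless):
        _, rna = demux_noiseless
        molecules = collapse_umis(rna.records, "exact")
        mat = build_gene_matrix(molecules, min_cells=10)
        census = molecules.groupby("gene")["cell"].nunique()
        assert set(mat.features) == set(census[census >= 10].index)


class TestMatchModalities:
    def test_membership_counts(self):
        df, counts = match_modalities({"M0:bc1"}, {"M0:bc1", "M0:bc2"})
        assert counts == {"both": 1, "rna_only": 1, "atac_only": 0}
        assert df.loc[df.cell == "M0:bc1", "membership"].item() == "both"

    def test_empty_atac_side(self):
        _, counts = match_modalities(set(), {"M0:bc1"})
        assert counts["both"] == 0 and counts["rna_only"] == 1

    def test_disjoint_sample_vocabularies_error(self):
        with pytest.raises(ValueError, match="sample"):
            match_modalities({"A:bc1"}, {"B:bc1"})

    def test_noiseless_join_matches_truth(self, sim_noiseless,
                                          demux_noiseless):
        atac, rna = demux_noiseless
        molecules = collapse_umis(rna.records, "exact")
        a_cells = set(atac.fragments["sample"] + ":" + atac.fragments.droplet)
        r_cells = set(molecules.cell)
        _, counts = match_modalities(a_cells, r_cells)
        nuc = sim_noiseless.truth.nuclei
        both_truth = nuc.groupby("cell").agg(
            f=("n_fragments", "sum"), u=("n_umis", "sum"))
        expected = int(((both_truth.f > 0) & (both_truth.u > 0)).sum())
        assert counts["both"] == expected


class TestConservation:
    def test_stats_account_for_every_read(self, demux_noiseless):
        for res in demux_noiseless:
            assert res.stats.conserved()
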