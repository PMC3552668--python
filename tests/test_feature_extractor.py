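"""Feature extraction: word statistics, track summaries, block structure."""

import numpy as np
import pytest

from cgimethpred import Contig, GenomicInterval, NumericTrack, word_counts
from cgimethpred.feature_extractor import (
    TETRAMERS,
    conformation_features,
    conserved_element_features,
    extract_all,
    feature_columns,
    gene_function_features,
    histone_features,
    nucleosome_features,
    tetramer_features,
    tetramer_zscore,
    tfbs_features,
)
from cgimethpred.genomic_io import (
    DEFAULT_DINUCLEOTIDE_PROPERTIES,
    TrackManifest,
)
from cgimethpred.island_finder import CpGIsland

from oracles import naive_tetramer_stats, naive_word_counts


def _island(start, end, chrom="c", iid=None):
    return CpGIsland(
        id=iid or f"{chrom}:{start}-{end}",
        interval=GenomicInterval(chrom, start, end),
        length=end - start,
        gc_content=0.6,
        obs_exp_cpg=1.0,
    )


class TestWordCounts:
    def test_hand_enumeration(self):
        wc = word_counts("ACGTACGT")
        assert wc.count("ACGT") == 2
        assert wc.count("CGTA") == 1
        assert wc.valid_windows[4] == 5

    def test_homopolymer(self):
        wc = word_counts("AAAA")
        assert wc.count("AAAA") == 1
        assert sum(wc.counts[4].values()) == 1

    def test_windows_containing_n_skipped(self):
        wc = word_counts("ACNGT")
        assert wc.valid_windows[4] == 0
        assert wc.valid_windows[2] == 2  # AC and GT
        assert wc.count("AC") == 1

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_naive_counting(self, rng, k):
        seq = "".join(rng.choice(list("ACGTN"), size=500,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        wc = word_counts(seq)
        naive, valid = naive_word_counts(seq, k)
        assert wc.counts[k] == naive
        assert wc.valid_windows[k] == valid


class TestTetramerFeatures:
    def test_hand_evaluated_zscore(self):
        # E(ACGT) = O(ACG) O(CGT) / O(CG) = 2*2/2 = 2 = O(ACGT); sigma = 0
        wc = word_counts("ACGTACGT")
        assert tetramer_zscore(wc, "ACGT") == 0.0

    def test_frequencies_sum_to_one(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        feats = tetramer_features(seq)
        total = sum(feats[f"freq_{t}"] for t in TETRAMERS)
        assert total == pytest.approx(1.0)
        assert all(0 <= feats[f"freq_{t}"] <= 1 for t in TETRAMERS)

    def test_matches_bruteforce_oracle(self, rng):
        """Production z-scores agree with the naive implementation to 1e-9."""
        for _ in range(30):
            length = int(rng.integers(200, 2001))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            feats = tetramer_features(seq)
            freqs, zs = naive_tetramer_stats(seq)
            for t in TETRAMERS:
                assert feats[f"freq_{t}"] == pytest.approx(freqs[t], abs=1e-9)
                assert feats[f"z_{t}"] == pytest.approx(zs[t], abs=1e-9)

    def test_zscores_standardized_on_long_iid_sequence(self, rng):
        """On a long uniform sequence the 256 z-scores are approximately
        standard normal (the Markov model is correct there)."""
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        feats = tetramer_features(seq)
        z = np.array([feats[f"z_{t}"] for t in TETRAMERS])
        assert abs(z.mean()) < 0.15
        assert abs(z.std() - 1.0) < 0.15

    def test_degenerate_missing_dimer_gives_zero(self):
        wc = word_counts("AAAAAAAA")
        assert tetramer_zscore(wc, "ACGT") == 0.0  # O(CG) = 0

    def test_sigma_zero_mismatch_capped(self):
        # E = 2*2/2 = 2, sigma = 0, observed 3 != 2 -> +z_cap
        from cgimethpred import WordCounts

        wc = WordCounts(
            counts={4: {"ACGT": 3}, 3: {"ACG": 2, "CGT": 2}, 2: {"CG": 2}},
            valid_windows={4: 3, 3: 4, 2: 5},
        )
        assert tetramer_zscore(wc, "ACGT", z_cap=10.0) == 10.0
        wc.counts[4]["ACGT"] = 1
        assert tetramer_zscore(wc, "ACGT", z_cap=10.0) == -10.0


class TestIntervalFeatures:
    def _manifest(self, groups):
        return TrackManifest(tfbs_groups=groups)

    def test_count_and_average_score(self):
        sites = [
            GenomicInterval("c", 100, 110, score=400.0),
            GenomicInterval("c", 200, 210, score=600.0),
        ]
        m = self._manifest({"G1": sites})
        feats = tfbs_features(_island(150, 250), 100, m, contig_length=10_000)
        assert feats["tfbs_G1_count"] == 2
        assert feats["tfbs_G1_avgscore"] == pytest.approx(500.0)

    def test_empty_group_is_zero_zero(self):
        m = self._manifest({"G1": []})
        feats = tfbs_features(_island(150, 250), 100, m, contig_length=10_000)
        assert feats["tfbs_G1_count"] == 0
        assert feats["tfbs_G1_avgscore"] == 0

    def test_half_open_overlap_at_window_end(self):
        # site starting exactly at window end is not counted
        site = GenomicInterval("c", 350, 360, score=100.0)
        m = self._manifest({"G1": [site]})
        feats = tfbs_features(_island(150, 250), 100, m, contig_length=10_000)
        assert feats["tfbs_G1_count"] == 0

    def test_flank_extends_reach(self):
        element = GenomicInterval("c", 100, 120, score=7.0)
        m = TrackManifest(conserved_elements=[element])
        isl = _island(600, 900)
        near = conserved_element_features(isl, 0, m, 10_000)
        far = conserved_element_features(isl, 2000, m, 10_000)
        assert near["conserved_element_count"] == 0
        assert far["conserved_element_count"] == 1
        assert far["conserved_element_avgscore"] == pytest.approx(7.0)


class TestConformationFeatures:
    def test_homopolymer_takes_table_value(self):
        tables = DEFAULT_DINUCLEOTIDE_PROPERTIES
        feats = conformation_features("AAAA", tables)
        for prop, table in tables.items():
            assert feats[f"conformation_{prop}"] == pytest.approx(table["AA"])

    def test_alternating_mean(self):
        tables = {p: dict(t) for p, t in DEFAULT_DINUCLEOTIDE_PROPERTIES.items()}
        tables["twist"]["AC"] = 34.4
        tables["twist"]["CA"] = 34.5
        feats = conformation_features("ACAC", tables)
        assert feats["conformation_twist"] == pytest.approx(
            (34.4 + 34.5 + 34.4) / 3
        )

    def test_homogeneous_table_constant_output(self, rng):
        tables = {
            p: {d: 2.5 for d in DEFAULT_DINUCLEOTIDE_PROPERTIES["twist"]}
            for p in DEFAULT_DINUCLEOTIDE_PROPERTIES
        }
        seq = "".join(rng.choice(list("ACGT"), size=100))
        feats = conformation_features(seq, tables)
        assert all(v == pytest.approx(2.5) for v in feats.values())


class TestTrackFeatures:
    def test_constant_occupancy(self):
        manifest = TrackManifest(
            nucleosome_nt_track=NumericTrack({"c": [(0, 1000, 0.8)]}),
            nucleosome_fragment_track=NumericTrack({"c": [(0, 1000, 1.5)]}),
        )
        feats = nucleosome_features(_island(200, 400), manifest)
        assert feats["nucleosome_nt_mean"] == pytest.approx(0.8)
        assert feats["nucleosome_nt_sd"] == pytest.approx(0.0)
        assert feats["nucleosome_frag_mean"] == pytest.approx(1.5)
        assert feats["nucleosome_frag_sd"] == pytest.approx(0.0)

    def test_two_level_histone_track(self):
        # tags 5 over half the island, 0 over the other half
        track = NumericTrack({"c": [(0, 100, 5.0)]})
        feats = histone_features(_island(0, 200), {"H3K4me3": track}, "hm")
        assert feats["hm_H3K4me3_mean"] == pytest.approx(2.5)
        assert feats["hm_H3K4me3_sd"] == pytest.approx(2.5)

    def test_absent_mark_is_zero(self):
        feats = histone_features(
            _island(0, 200), {"H3K9ac": NumericTrack()}, "ha"
        )
        assert feats["ha_H3K9ac_mean"] == 0.0
        assert feats["ha_H3K9ac_sd"] == 0.0


class TestGeneFunctionFeatures:
    def test_no_nearby_genes(self):
        m = TrackManifest(genes=[], oncogene_process_genes={"X"})
        assert gene_function_features(_island(0, 300), m) == {
            "gene_function_oncogene": 0.0,
            "gene_function_tsg": 0.0,
        }

    def test_promoter_interval_arithmetic(self):
        # + strand TSS=1000 -> promoter [0, 1200) overlaps island [1150,1400)
        m = TrackManifest(
            genes=[("G1", "c", 1000, "+")],
            oncogene_process_genes={"G1"},
            tsg_process_genes=set(),
        )
        feats = gene_function_features(_island(1150, 1400), m)
        assert feats["gene_function_oncogene"] == 1.0
        assert feats["gene_function_tsg"] == 0.0

    def test_minus_strand_promoter(self):
        # - strand TSS=1000 -> promoter [800, 2000)
        m = TrackManifest(
            genes=[("G1", "c", 1000, "-")],
            oncogene_process_genes={"G1"},
            tsg_process_genes={"G1"},
        )
        inside = gene_function_features(_island(1900, 2200), m)
        outside = gene_function_features(_island(2000, 2300), m)
        assert inside == {"gene_function_oncogene": 1.0,
                          "gene_function_tsg": 1.0}
        assert outside == {"gene_function_oncogene": 0.0,
                           "gene_function_tsg": 0.0}


class TestExtractAll:
    def test_default_manifest_dimensionalities(self, cv_bundle):
        genome = cv_bundle.load_genome()
        manifest = cv_bundle.load_manifest()
        islands = cv_bundle.load_planted_islands()[:5]
        matrix = extract_all(islands, genome, manifest)
        assert matrix.data.shape == (5, 841)
        assert matrix.category_counts() == {
            "general": 3, "tetramer_freq": 256, "tetramer_z": 256,
            "tfbs": 230, "conserved_element": 2, "conformation": 6,
            "nucleosome": 4, "gene_function": 2,
            "histone_methylation": 46, "histone_acetylation": 36,
        }

    def test_reduced_manifest_block_arithmetic(self):
        manifest = TrackManifest(
            tfbs_groups={"G1": []},
            histone_methylation_tracks={"H3K4me3": NumericTrack()},
            histone_acetylation_tracks={"H3K9ac": NumericTrack()},
        )
        names, cats = feature_columns(manifest)
        # 3 + 512 + 2 + 2 + 6 + 4 + 2 + 2 + 2
        assert len(names) == 535
        assert len(cats) == 535

    def test_empty_island_list_keeps_header(self, cv_bundle):
        genome = cv_bundle.load_genome()
        manifest = cv_bundle.load_manifest()
        matrix = extract_all([], genome, manifest)
        assert matrix.data.shape == (0, 841)

    def test_translation_invariance(self, rng):
        """Shifting all coordinates and tracks by a constant offset leaves
        every feature unchanged."""
        offset = 1000
        isl_seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2],
                                     size=300))
        pad = "".join(rng.choice(list("AT"), size=500))
        genome0 = {"c": Contig("c", pad + isl_seq + pad)}
        genome1 = {"c": Contig("c", "A" * offset + pad + isl_seq + pad)}

        def manifest(shift):
            return TrackManifest(
                tfbs_groups={"G1": [
                    GenomicInterval("c", 400 + shift, 420 + shift, score=5.0)
                ]},
                conserved_elements=[
                    GenomicInterval("c", 600 + shift, 640 + shift, score=2.0)
                ],
                histone_methylation_tracks={"m": NumericTrack(
                    {"c": [(450 + shift, 900 + shift, 3.0)]}
                )},
                histone_acetylation_tracks={"a": NumericTrack(
                    {"c": [(500 + shift, 700 + shift, 1.0)]}
                )},
                nucleosome_nt_track=NumericTrack(
                    {"c": [(300 + shift, 1100 + shift, 0.4)]}
                ),
                nucleosome_fragment_track=NumericTrack(
                    {"c": [(354 + shift, 800 + shift, 1.2)]}
                ),
                genes=[("G", "c", 520 + shift, "+")],
                oncogene_process_genes={"G"},
            )

        def one_matrix(genome, shift):
            isl = _island(500 + shift, 800 + shift, iid="i")
            return extract_all([isl], genome, manifest(shift), flank_bp=200)

        m0 = one_matrix(genome0, 0)
        m1 = one_matrix(genome1, offset)
        np.testing.assert_allclose(
            m0.data.to_numpy(), m1.data.to_numpy(), rtol=0, atol=1e-12
        )
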