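"""Six-frame search, HCAA-to-codon projection and the 64x20 matrix."""

import numpy as np
import pytest

from tinygenome import FormatError, ParameterError
from tinygenome._codons import CODONS, STANDARD_CODE, revcomp
from tinygenome.hcaa import (
    HCAAPosition,
    consensus_column_map,
    consensus_sequence,
    identify_hcaa,
)
from tinygenome.search import (
    CodonObservation,
    CodonObservationMatrix,
    FrameTranslation,
    TranslatedHit,
    accumulate,
    map_hcaa_to_codons,
    six_frame_translate,
    translated_search,
)
from tinygenome.simulate import SimConfig, generate_marker_families, generate_target_genome

RNG = np.random.default_rng(2024)


def random_dna(n, rng=RNG, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestSixFrameTranslate:
    def test_forward_frame0(self):
        frames = six_frame_translate("ATGTGA")
        fwd0 = next(f for f in frames if f.strand == "+" and f.frame == 0)
        assert fwd0.protein == "M*"

    def test_reverse_strand(self):
        frames = six_frame_translate("TCACAT")
        rev0 = next(f for f in frames if f.strand == "-" and f.frame == 0)
        assert rev0.protein == "M*"

    def test_empty_sequence_gives_empty_frames(self):
        frames = six_frame_translate("")
        assert len(frames) == 6 and all(f.protein == "" for f in frames)

    def test_n_codons_become_x_and_partial_codons_dropped(self):
        fwd0 = six_frame_translate("ATNGGGC")[0]
        assert fwd0.protein == "XG"

    def test_coordinate_round_trip_on_random_sequence(self):
        genome = random_dna(3000)
        for ft in six_frame_translate(genome):
            for i in range(len(ft.protein)):
                s, e = ft.codon_span(i)
                codon = genome[s:e]
                if ft.strand == "-":
                    codon = revcomp(codon)
                expected = STANDARD_CODE.get(codon, "X")
                assert ft.protein[i] == expected


def plant_gene(protein, strand="+", pad=300, rng=RNG, gc=0.5):
    """Encode a protein in random DNA; return genome and its truth span."""
    cds = "".join(
        str(rng.choice([c for c in CODONS if STANDARD_CODE[c] == aa]))
        for aa in protein
    )
    left = random_dna(pad, rng, gc)
    insert = cds if strand == "+" else revcomp(cds)
    genome = left + insert + random_dna(pad, rng, gc)
    return genome, (pad, pad + len(cds))


class TestTranslatedSearch:
    def test_exact_match_hits_planted_coordinates(self):
        rng = np.random.default_rng(7)
        query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        genome, span = plant_gene(query, "+", rng=rng)
        (hit,) = translated_search(genome, query)
        assert hit.span == span
        assert hit.strand == "+"
        assert "-" not in hit.aligned_query + hit.aligned_subject
        assert hit.aligned_query == query

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_minus_strand_diverged_gene_recovered(self, strand):
        rng = np.random.default_rng(21)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        protein = "".join(rng.choice(aas, size=100))
        # 20% residue substitutions between query and planted gene
        mutated = list(protein)
        for i in rng.choice(100, size=20, replace=False):
            mutated[i] = str(rng.choice([a for a in aas if a != mutated[i]]))
        genome, span = plant_gene("".join(mutated), strand, rng=rng)
        hits = translated_search(genome, protein)
        assert hits, "diverged planted gene must still be found"
        best = max(hits, key=lambda h: h.score)
        assert best.strand == strand
        overlap = min(best.span[1], span[1]) - max(best.span[0], span[0])
        assert overlap / (span[1] - span[0]) >= 0.9

    def test_no_hits_in_random_sequence_above_calibrated_null(self):
        rng = np.random.default_rng(4)
        query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        genome = random_dna(4000, rng)
        # empirical null: max score over shuffled queries, plus margin
        null_scores = []
        for _ in range(100):
            shuffled = "".join(rng.permutation(list(query)))
            hits = translated_search(genome, shuffled, score_threshold=0)
            null_scores.append(max((h.score for h in hits), default=0.0))
        threshold = max(null_scores) + 5
        assert translated_search(genome, query, score_threshold=threshold) == []

    def test_short_query_rejected(self):
        with pytest.raises(ParameterError):
            translated_search("ACGT" * 100, "MKV")

    def test_bad_query_letters_rejected(self):
        with pytest.raises(FormatError):
            translated_search("ACGT" * 100, "M1V" * 20)

    def test_hit_span_is_whole_codons(self, small_standard_sim):
        _, families, _, genome, _ = small_standard_sim
        for fam in families[:2]:
            for h in translated_search(genome, consensus_sequence(fam),
                                       family_id=fam.family_id):
                assert (h.span[1] - h.span[0]) % 3 == 0
                assert h.n_subject_residues * 3 == h.span[1] - h.span[0]


class TestMapHcaaToCodons:
    def test_gapless_mapping_arithmetic(self):
        rng = np.random.default_rng(3)
        query = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        genome, (g0, _) = plant_gene(query, "+", rng=rng)
        (hit,) = translated_search(genome, query)
        hcaa = [HCAAPosition("query", i, query[i], 1.0) for i in (0, 17, 59)]
        colmap = {i: i for i in range(len(query))}
        obs = map_hcaa_to_codons(hit, hcaa, colmap, genome)
        assert len(obs) == 3
        for o, i in zip(obs, (0, 17, 59)):
            start = g0 + 3 * (i - hit.query_start)
            assert o.genome_start == start
            assert o.codon == genome[start:start + 3]
            assert STANDARD_CODE[o.codon] == query[i]

    def test_column_opposite_subject_gap_emits_nothing(self):
        ft = FrameTranslation("c", "+", 0, "MKVWDE", 18)
        hit = TranslatedHit(
            family_id="f", query_id="q", contig="c", strand="+", frame=0,
            span=(0, 18), score=50.0,
            aligned_query="MKQVWDE", aligned_subject="MK-VWDE",
            query_start=0, subject_start=0, _frame_translation=ft,
        )
        hcaa = [HCAAPosition("f", 2, "Q", 1.0)]  # aligned to the subject gap
        assert map_hcaa_to_codons(hit, hcaa, {i: i for i in range(7)},
                                  "ATGAAAGTTTGGGATGAA") == []

    def test_family_mismatch_rejected(self):
        ft = FrameTranslation("c", "+", 0, "M", 3)
        hit = TranslatedHit("f", "q", "c", "+", 0, (0, 3), 1.0, "M", "M", 0, 0, ft)
        with pytest.raises(ParameterError):
            map_hcaa_to_codons(hit, [HCAAPosition("other", 0, "M", 1.0)],
                               {0: 0}, "ATG")

    def test_uga_trp_truth_sites_observed_as_tga_w(self, small_uga_sim):
        from tinygenome.pipeline import run_code_inference

        cfg, families, truth_cols, genome, truth = small_uga_sim
        observations = []
        for fam in families:
            hcaa = identify_hcaa(fam, 0.90)
            colmap = consensus_column_map(fam)
            for hit in translated_search(genome, consensus_sequence(fam),
                                         family_id=fam.family_id):
                observations.extend(map_hcaa_to_codons(hit, hcaa, colmap, genome))
        got_tga_w = {(o.family_id, o.genome_start)
                     for o in observations if o.codon == "TGA" and o.consensus_aa == "W"}
        expected = {(s.family_id, s.start)
                    for s in truth.tga_sites if s.at_conserved_column}
        assert expected <= got_tga_w

    def test_strand_symmetry_of_codon_observations(self, small_standard_sim):
        _, families, _, genome, _ = small_standard_sim
        def observe(g):
            out = []
            for fam in families:
                hcaa = identify_hcaa(fam, 0.90)
                colmap = consensus_column_map(fam)
                for hit in translated_search(g, consensus_sequence(fam),
                                             family_id=fam.family_id):
                    out.extend(map_hcaa_to_codons(hit, hcaa, colmap, g))
            return sorted((o.family_id, o.column, o.codon, o.consensus_aa)
                          for o in out)
        assert observe(genome) == observe(revcomp(genome))


class TestAccumulate:
    def test_empty_input_zero_matrix(self):
        m = accumulate([])
        assert m.total_sites == 0
        assert (m.counts.values == 0).all()

    def test_small_count_example(self):
        obs = [
            CodonObservation("f", 0, "W", "TGG", "c", 0, "+"),
            CodonObservation("f", 1, "W", "TGG", "c", 3, "+"),
            CodonObservation("f", 2, "W", "TGA", "c", 6, "+"),
        ]
        m = accumulate(obs)
        assert m.counts.loc["TGG", "W"] == 2
        assert m.counts.loc["TGA", "W"] == 1
        assert m.total_sites == 3

    def test_duplicate_positions_count_once(self):
        o = CodonObservation("f", 0, "W", "TGG", "c", 0, "+")
        assert accumulate([o, o]).total_sites == 1

    def test_ambiguous_codons_dropped(self):
        obs = [CodonObservation("f", 0, "W", "TGN", "c", 0, "+")]
        assert accumulate(obs).total_sites == 0

    def test_count_conservation(self, small_standard_sim):
        from tinygenome.pipeline import run_code_inference

        _, families, _, genome, _ = small_standard_sim
        matrix, _, _ = run_code_inference(genome, families)
        assert matrix.total_sites == int(matrix.counts.values.sum())
        assert matrix.total_sites > 0

    def test_zero_divergence_one_observation_per_hcaa_column_per_gene(self):
        cfg = SimConfig(seed=8, n_families=3, n_ref_taxa=20, family_length=100,
                        divergence=0.0)
        fams, tc = generate_marker_families(cfg)
        genome, truth = generate_target_genome(fams, cfg, tc)
        for fam in fams:
            hcaa = identify_hcaa(fam, 0.90)
            colmap = consensus_column_map(fam)
            obs = []
            for hit in translated_search(genome, consensus_sequence(fam),
                                         family_id=fam.family_id):
                obs.extend(map_hcaa_to_codons(hit, hcaa, colmap, genome))
            m = accumulate(obs)
            assert m.total_sites == len(hcaa)

    def test_standard_code_rows_argmax_to_table11(self, small_standard_sim):
        from tinygenome.pipeline import run_code_inference

        _, families, _, genome, _ = small_standard_sim
        matrix, _, _ = run_code_inference(genome, families)
        for codon in CODONS:
            row = matrix.counts.loc[codon]
            if row.sum() >= 20:
                assert row.idxmax() == STANDARD_CODE[codon]

    def test_tsv_round_trip(self, tmp_path):
        obs = [CodonObservation("f", 0, "K", "AAA", "c", 0, "+")]
        m = accumulate(obs)
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        assert CodonObservationMatrix.from_tsv(p) == m
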