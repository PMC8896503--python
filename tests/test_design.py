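"""Probe-design module: tiling, variant enumeration, probe assembly,
manifest construction."""

import numpy as np
import pytest

from cascade_pbm import design as d
from cascade_pbm.seq import random_dna, revcomp


def brute_force_offsets(L, tile_len=26, step=5):
    """Independent enumeration of tile offsets, including the terminal rule."""
    offs = []
    off = 0
    while off + tile_len <= L:
        offs.append(off)
        off += step
    if offs[-1] + tile_len < L:
        offs.append(L - tile_len)
    return offs


class TestTiling:
    @pytest.mark.parametrize(
        "length,n_tiles", [(166, 29), (26, 1), (40, 4), (31, 2), (27, 2)]
    )
    def test_tile_counts(self, length, n_tiles, rng):
        assert len(d.tile_region(random_dna(length, rng))) == n_tiles

    def test_terminal_tile_offsets(self, rng):
        tiles = d.tile_region(random_dna(40, rng))
        assert [t.start for t in tiles] == [0, 5, 10, 14]
        assert [t.tile_index for t in tiles] == [0, 1, 2, 3]

    def test_tiles_match_sequence(self, rng):
        seq = random_dna(63, rng)
        for t in d.tile_region(seq):
            assert t.target_seq == seq[t.start : t.end]

    def test_coverage_and_overlap(self, rng):
        for L in rng.integers(26, 300, size=20):
            seq = random_dna(int(L), rng)
            tiles = d.tile_region(seq)
            covered = set()
            for t in tiles:
                covered.update(range(t.start, t.end))
            assert covered == set(range(int(L)))
            for a, b in zip(tiles, tiles[1:-1]):
                # regular (non-terminal) neighbours overlap by tile_len - step
                assert a.end - b.start == 26 - 5

    def test_short_region_rejected(self):
        with pytest.raises(ValueError, match="shorter than tile"):
            d.tile_region("ACGT")

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="invalid base"):
            d.tile_region("ACGTN" * 6)

    def test_bad_step_rejected(self, rng):
        with pytest.raises(ValueError, match="step"):
            d.tile_region(random_dna(30, rng), step=0)


class TestEnumerateSv:
    def test_26mer_count(self, rng):
        assert len(d.enumerate_sv(random_dna(26, rng))) == 79

    def test_single_base(self):
        variants = d.enumerate_sv("A")
        assert [v.target_seq for v in variants] == ["A", "C", "G", "T"]
        assert variants[0].sv_position is None
        assert [(v.sv_position, v.sv_base) for v in variants[1:]] == [
            (0, "C"), (0, "G"), (0, "T"),
        ]

    def test_all_distinct_and_single_mismatch(self, rng):
        seq = random_dna(26, rng)
        variants = d.enumerate_sv(seq)
        seqs = [v.target_seq for v in variants]
        assert len(set(seqs)) == len(seqs)
        for v in variants[1:]:
            diffs = [i for i, (a, b) in enumerate(zip(seq, v.target_seq)) if a != b]
            assert diffs == [v.sv_position]
            assert v.target_seq[v.sv_position] == v.sv_base


class TestAssembleProbe:
    def test_direct_concatenation(self):
        probe = d.assemble_probe("A" * 26, "+")
        assert probe == "GCCTAG" + "A" * 26 + "CTAG" + d.PRIMER_SITE
        assert len(probe) == 60

    def test_minus_orientation_is_revcomp_core(self, rng):
        t = random_dna(26, rng)
        plus = d.assemble_probe(t, "+")
        minus = d.assemble_probe(t, "-")
        assert minus[6:32] == revcomp(plus[6:32])
        # applying the reverse complement twice reproduces the + target
        assert revcomp(revcomp(t)) == t

    @pytest.mark.parametrize(
        "kw,name",
        [
            ({"flank5": "GCCTA"}, "flank5"),
            ({"flank3": "CT"}, "flank3"),
            ({"primer": "ACGT"}, "primer"),
        ],
    )
    def test_component_length_errors(self, kw, name, rng):
        with pytest.raises(ValueError, match=name):
            d.assemble_probe(random_dna(26, rng), "+", **kw)

    def test_wrong_target_length(self, rng):
        with pytest.raises(ValueError, match="target"):
            d.assemble_probe(random_dna(25, rng), "+")


class TestCreDesign:
    def test_166bp_target_count(self, rng):
        manifest = d.design_cre_array(random_dna(166, rng), n_background=0)
        assert len(manifest.targets(include_background=False)) == 2291

    def test_counting_identity_random_lengths(self, rng):
        for L in rng.integers(26, 200, size=20):
            seq = random_dna(int(L), rng)
            manifest = d.design_cre_array(seq, n_background=0)
            n_tiles = len(brute_force_offsets(int(L)))
            assert (
                len(manifest.targets(include_background=False))
                == n_tiles * (1 + 3 * 26)
                == d.expected_cre_target_count(n_tiles)
            )

    def test_single_tile_record_counts(self, rng):
        manifest = d.design_cre_array(random_dna(26, rng), n_background=0)
        assert manifest.n_targets == 79
        assert manifest.n_probes == 79 * 2 * 5

    def test_determinism(self, rng, tmp_path):
        seq = random_dna(31, rng)
        a, b = (d.design_cre_array(seq, n_background=20, rng_seed=9) for _ in range(2))
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_tsv(pa), b.to_tsv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_probe_invariants(self, rng):
        manifest = d.design_cre_array(random_dna(36, rng), n_background=15, rng_seed=1)
        probes = manifest.probes
        assert (probes["probe_seq"].str.len() == 60).all()
        assert probes["probe_seq"].str.endswith(d.PRIMER_SITE).all()
        assert probes["probe_id"].is_unique

    def test_manifest_tsv_round_trip(self, rng, tmp_path):
        manifest = d.design_cre_array(random_dna(30, rng), n_background=5, rng_seed=3)
        path = tmp_path / "m.tsv"
        manifest.to_tsv(path)
        back = d.ArrayManifest.from_tsv(path)
        assert back.design_class == "cre"
        assert back.params == manifest.params
        assert back.probes.equals(manifest.probes)


class TestSnpDesign:
    def make_specs(self, n, rng):
        from cascade_pbm.simulate import random_snp_specs

        return random_snp_specs(n, rng)

    def test_single_snp_counts(self, rng):
        manifest = d.design_snp_array(self.make_specs(1, rng), n_background=0)
        assert manifest.n_targets == 2
        assert manifest.n_probes == 20

    def test_pairs_differ_at_exactly_one_position(self, rng):
        manifest = d.design_snp_array(self.make_specs(25, rng), n_background=0)
        targets = manifest.targets()
        for rsid, g in targets.groupby("locus_id"):
            ref = g.loc[g["probe_class"] == "ref", "target_seq"].item()
            nonref = g.loc[g["probe_class"] == "nonref", "target_seq"].item()
            diffs = [i for i, (a, b) in enumerate(zip(ref, nonref)) if a != b]
            assert diffs == [13]

    def test_duplicate_rsid_rejected(self, rng):
        specs = self.make_specs(2, rng)
        specs[1].rsid = specs[0].rsid
        with pytest.raises(ValueError, match="duplicate rsID"):
            d.design_snp_array(specs, n_background=0)

    def test_ref_allele_must_match_embedded_base(self, rng):
        target = random_dna(26, rng)
        wrong = next(b for b in "ACGT" if b != target[13])
        other = next(b for b in "ACGT" if b not in (wrong, target[13]))
        with pytest.raises(ValueError, match="inconsistent"):
            d.SnpSpec.from_target("rs1", target, nonref_allele=other, ref_allele=wrong)

    def test_identical_alleles_rejected(self, rng):
        target = random_dna(26, rng)
        with pytest.raises(ValueError, match="identical"):
            d.SnpSpec.from_target("rs1", target, nonref_allele=target[13])


class TestTfbsDesign:
    def test_backbone_never_repeats_adjacent(self):
        for seed in range(1000):
            bb = d.make_backbone(np.random.default_rng(seed))
            assert len(bb) == 34
            assert all(bb[i] != bb[i + 1] for i in range(len(bb) - 1))

    def test_probe_layout(self, rng):
        cons = random_dna(10, rng)
        rec = d.design_tfbs_probe(cons, rng_seed=4)
        assert len(rec["target_seq"]) == 34
        assert rec["target_seq"][2:12] == cons
        assert len(rec["probe_seq"]) == 60
        assert rec["probe_seq"].startswith("GC")
        assert rec["probe_seq"].endswith(d.PRIMER_SITE)

    def test_determinism(self, rng):
        cons = random_dna(8, rng)
        assert d.design_tfbs_probe(cons, 7) == d.design_tfbs_probe(cons, 7)

    def test_consensus_too_long(self, rng):
        with pytest.raises(ValueError, match="too long"):
            d.design_tfbs_probe(random_dna(31, rng))

    def test_array_probe_lengths(self, rng):
        manifest = d.design_tfbs_array(
            {"site1": random_dna(8, rng)}, n_background=10, rng_seed=2
        )
        assert (manifest.probes["probe_seq"].str.len() == 60).all()


class TestBackground:
    def test_counts_and_length(self):
        bgs = d.make_background(500, rng_seed=1)
        assert len(bgs) == 500
        assert all(len(b.target_seq) == 26 for b in bgs)

    def test_empty(self):
        assert d.make_background(0) == []

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            d.make_background(-1)

    def test_determinism(self):
        a = [t.target_seq for t in d.make_background(20, rng_seed=5)]
        b = [t.target_seq for t in d.make_background(20, rng_seed=5)]
        assert a == b

    def test_genome_sampling(self, rng):
        genome = {"chr1": random_dna(200, rng), "chr2": random_dna(100, rng)}
        bgs = d.make_background(50, rng_seed=2, source=genome)
        for b in bgs:
            assert b.target_seq in genome[b.chrom]

    def test_genome_with_n_runs_skipped(self):
        genome = {"chr1": "N" * 100 + "ACGT" * 20}
        bgs = d.make_background(10, rng_seed=3, source=genome)
        assert all(set(b.target_seq) <= set("ACGT") for b in bgs)


class TestCapacityArithmetic:
    def test_span_formula(self):
        assert d.tiled_span(1) == 26
        assert d.tiled_span(2) == 31
        with pytest.raises(ValueError):
            d.tiled_span(0)
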