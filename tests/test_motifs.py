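"""Recruitment-motif construction: reset rule, delta logos, tile
integration and planted-motif recovery."""

import numpy as np
import pytest
from scipy.stats import pearsonr

import cascade_pbm as c
from cascade_pbm.motifs import RecruitmentMotif
from cascade_pbm.seq import BASE_INDEX


class TestSvReset:
    @pytest.mark.parametrize(
        "z_sv,z_seed,expected",
        [
            (2.0, 1.0, 1.0),   # sv above, seed below threshold -> reset
            (2.0, 2.5, 2.0),   # seed itself above threshold -> keep sv
            (1.0, 0.5, 1.0),   # sv below threshold -> keep sv
            (1.645, 1.0, 1.645),  # boundary: sv not strictly above
        ],
    )
    def test_rule(self, z_sv, z_seed, expected):
        assert c.sv_reset(z_sv, z_seed) == expected

    def test_never_increases_sv_when_seed_subthreshold(self, rng):
        for _ in range(200):
            z_sv = rng.normal(scale=3)
            z_seed = rng.uniform(-2, 1.645)
            assert c.sv_reset(z_sv, z_seed) <= max(z_sv, z_seed) + 1e-12
            if z_sv > 1.645:
                assert c.sv_reset(z_sv, z_seed) == z_seed


class TestDeltaLogo:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([1, 1, 1, 1], [0, 0, 0, 0]),
            ([3, 1, 1, 1], [2, 0, 0, 0]),
            ([4, 3, 2, 1], [1.5, 0.5, -0.5, -1.5]),
        ],
    )
    def test_hand_rows(self, row, expected):
        np.testing.assert_allclose(c.delta_logo(np.array([row], float)), [expected])

    def test_row_median_exactly_zero(self, rng):
        d = c.delta_logo(rng.normal(size=(30, 4)))
        np.testing.assert_allclose(np.median(d, axis=1), 0.0, atol=1e-12)

    def test_translation_invariance(self, rng):
        z = rng.normal(size=(10, 4))
        shifted = z + rng.normal(size=(10, 1))
        np.testing.assert_allclose(c.delta_logo(z), c.delta_logo(shifted), atol=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            c.delta_logo(np.array([[1.0, np.nan, 0.0, 0.0]]))


def tiny_motif(locus, positions, ref, z, seed_z):
    return RecruitmentMotif(
        locus_id=locus,
        positions=np.asarray(positions),
        ref_bases=ref,
        z_matrix=np.asarray(z, float),
        seed_z=np.asarray([seed_z], float),
    )


class TestIntegrateTiles:
    def test_single_tile_identity(self, rng):
        m = tiny_motif("l", [0, 1], "AC", rng.normal(size=(2, 4)), 2.0)
        out = c.integrate_tiles([m])
        np.testing.assert_allclose(out.z_matrix, m.z_matrix)
        assert out.ref_bases == "AC"

    def test_equal_weights_plain_mean(self):
        a = tiny_motif("l", [0], "A", [[2, 2, 2, 2]], 1.5)
        b = tiny_motif("l", [0], "A", [[4, 4, 4, 4]], 1.5)
        out = c.integrate_tiles([a, b])
        np.testing.assert_allclose(out.z_matrix, 3.0)

    def test_weighted_mean_arithmetic(self):
        a = tiny_motif("l", [0], "A", [[2, 2, 2, 2]], 1.0)
        b = tiny_motif("l", [0], "A", [[4, 4, 4, 4]], 3.0)
        out = c.integrate_tiles([a, b])
        np.testing.assert_allclose(out.z_matrix, (1 * 2 + 3 * 4) / 4)

    def test_weight_floor_guards_nonpositive_seeds(self):
        a = tiny_motif("l", [0], "A", [[2, 2, 2, 2]], -5.0)
        b = tiny_motif("l", [0], "A", [[4, 4, 4, 4]], 1.0)
        out = c.integrate_tiles([a, b])
        # negative seed floored to 0.01: heavily dominated by the bound tile
        assert 3.9 < out.z_matrix[0, 0] < 4.0

    def test_bounded_by_inputs(self, rng):
        motifs = [
            tiny_motif("l", [0, 1], "GT", rng.normal(size=(2, 4)),
                       float(rng.uniform(0.5, 3)))
            for _ in range(4)
        ]
        out = c.integrate_tiles(motifs)
        stack = np.stack([m.z_matrix for m in motifs])
        assert (out.z_matrix >= stack.min(axis=0) - 1e-9).all()
        assert (out.z_matrix <= stack.max(axis=0) + 1e-9).all()

    def test_reference_conflict_rejected(self):
        a = tiny_motif("l", [0], "A", [[1, 1, 1, 1]], 1.0)
        b = tiny_motif("l", [0], "C", [[1, 1, 1, 1]], 1.0)
        with pytest.raises(ValueError, match="conflict"):
            c.integrate_tiles([a, b])


class TestLocusZMatrix:
    @pytest.fixture()
    def snp_locus(self, rng):
        """Single-tile (26-base) locus design with a planted site."""
        planted = c.ets_like_complex()
        seq = c.synthetic_cre(26, rng_seed=8, sites={9: planted.consensus})
        manifest = c.design_cre_array({"locus1": seq}, n_background=60, rng_seed=4)
        table = c.simulate_array(manifest, planted, rng_seed=10)
        zres = c.zscore_pipeline(manifest, table)
        return planted, seq, manifest, zres

    def test_seed_z_in_every_row_at_ref_base(self, snp_locus):
        _, seq, manifest, zres = snp_locus
        m = c.locus_z_matrix(manifest, zres, "locus1", seed_thresh=None)
        seed_z = m.seed_z[0]
        # seed z appears exactly once per row, at the reference base (the
        # seed here is above the reset threshold, so no variant is reset)
        assert seed_z > 1.645
        for i, base in enumerate(seq):
            assert m.z_matrix[i, BASE_INDEX[base]] == pytest.approx(seed_z)
            assert (m.z_matrix[i] == seed_z).sum() == 1

    def test_argmax_recovers_consensus_in_site(self, snp_locus):
        planted, seq, manifest, zres = snp_locus
        m = c.locus_z_matrix(manifest, zres, "locus1", seed_thresh=None)
        cons = planted.consensus
        called = "".join("ACGT"[k] for k in m.z_matrix[9 : 9 + len(cons)].argmax(axis=1))
        assert called == cons

    def test_below_seed_threshold_returns_none(self, rng):
        from cascade_pbm.seq import random_dna

        manifest = c.design_cre_array({"dull": random_dna(26, rng)},
                                      n_background=60, rng_seed=1)
        pl = c.ets_like_complex(amplitude=0.0)
        zres = c.zscore_pipeline(manifest, c.simulate_array(manifest, pl, rng_seed=2))
        assert c.locus_z_matrix(manifest, zres, "dull", seed_thresh=1.5) is None

    def test_missing_sv_probe_is_error(self, snp_locus):
        _, _, manifest, zres = snp_locus
        import copy

        broken = copy.copy(manifest)
        sv = manifest.probes.loc[manifest.probes["probe_class"] == "sv"].iloc[0]
        pos, base = int(sv["sv_position"]), sv["sv_base"]
        broken.probes = manifest.probes[
            ~((manifest.probes["sv_position"] == pos)
              & (manifest.probes["sv_base"] == base))
        ]
        with pytest.raises(ValueError, match=f"position {pos} base {base}"):
            c.locus_z_matrix(broken, zres, "locus1", seed_thresh=None)


class TestCreWideMotif:
    def test_position_count_equals_region_length(self, cre_recovery):
        assert len(cre_recovery["motif"].positions) == 166

    def test_planted_recovery_correlation(self, cre_recovery):
        """Column-wise Pearson r > 0.9 between the delta-z matrix and the
        median-centred planted score matrix at the planted positions."""
        planted = cre_recovery["planted"]
        off = cre_recovery["site_offset"]
        d = cre_recovery["motif"].delta_matrix
        w = planted.motif_energy - np.median(
            planted.motif_energy, axis=1, keepdims=True
        )
        for i in range(planted.motif_len):
            r, _ = pearsonr(d[off + i], w[i])
            assert r > 0.9

    def test_two_planted_sites_localized(self):
        ets = c.ets_like_complex()
        seq = c.synthetic_cre(
            166, rng_seed=13, sites={30: ets.consensus, 120: ets.consensus}
        )
        manifest = c.design_cre_array({"cre2": seq}, n_background=120, rng_seed=14)
        zres = c.zscore_pipeline(
            manifest, c.simulate_array(manifest, ets, rng_seed=15)
        )
        d = c.build_cre_motif(manifest, zres, "cre2").delta_matrix
        strength = np.abs(d).max(axis=1)
        site_cols = list(range(30, 38)) + list(range(120, 128))
        off_site = np.delete(strength, site_cols)
        assert strength[site_cols].mean() > 3 * off_site.mean()

    def test_null_condition_delta_near_zero(self):
        seq = c.synthetic_cre(66, rng_seed=16)
        manifest = c.design_cre_array({"null": seq}, n_background=120, rng_seed=17)
        pl = c.ets_like_complex(amplitude=0.0)
        zres = c.zscore_pipeline(
            manifest, c.simulate_array(manifest, pl, rng_seed=18)
        )
        d = c.build_cre_motif(manifest, zres, "null").delta_matrix
        assert np.abs(d).max() < 3.0  # within 3 background sd

    def test_axis_limits_cover_all_experiments(self, cre_recovery):
        m = cre_recovery["motif"]
        lo, hi = c.delta_axis_limits([m])
        assert lo == pytest.approx(m.delta_matrix.min())
        assert hi == pytest.approx(m.delta_matrix.max())

    def test_long_form_export(self, cre_recovery, tmp_path):
        import pandas as pd
        from cascade_pbm.motifs import write_motif_tsv

        path = tmp_path / "motif.tsv"
        write_motif_tsv([cre_recovery["motif"]], path)
        df = pd.read_csv(path, sep="\t", comment="#")
        assert len(df) == 166 * 4
        assert set(df["base"]) == set("ACGT")
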