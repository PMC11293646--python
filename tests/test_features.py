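"""The 170-feature schema and the extractor's agreement with its inputs."""

import numpy as np
import pytest

from premir.features import (
    FAMILY_SIZES,
    compute_composition,
    compute_energy_features,
    extract_features,
    feature_families,
    feature_names,
    packaged_schema,
    schema_table,
    tetranucleotide_table,
)
from premir.hairpin import Verdict, disqualify, duplex_stats, infer_star, locate_hit
from premir.simulate import HairpinParams, make_hairpin


def _qualified(random_mature, params=None, seed=20):
    rec, s, truth = make_hairpin(random_mature(), params or HairpinParams(), seed=seed)
    ctx = locate_hit(s, truth.mir_span)
    verdict = disqualify(s, ctx)
    assert verdict.accepted
    star = infer_star(s, truth.mir_span)
    stats = duplex_stats(s, truth.mir_span, star)
    return s, ctx, stats, verdict, truth


class TestSchema:
    def test_family_sizes_and_total(self):
        fams = feature_families()
        assert {k: len(v) for k, v in fams.items()} == FAMILY_SIZES
        assert sum(FAMILY_SIZES.values()) == 170
        assert len(feature_names()) == 170

    def test_schema_order_is_family_blocks(self):
        table = schema_table()
        sizes = (7, 4, 5, 4, 8, 23, 36, 83)
        assert tuple(
            table.groupby("family", sort=False).size()
        ) == sizes

    def test_packaged_schema_file_matches_code(self):
        disk = packaged_schema()
        code = schema_table()
        assert list(disk["name"]) == list(code["name"])
        assert list(disk["family"]) == list(code["family"])

    def test_vector_has_stable_names_and_length(self, random_mature):
        s, ctx, stats, verdict, _ = _qualified(random_mature)
        fv1 = extract_features(s, ctx, stats, verdict=verdict)
        fv2 = extract_features(s, ctx, stats, verdict=verdict)
        assert fv1.names == feature_names()
        assert len(fv1) == 170
        assert np.array_equal(fv1.values, fv2.values)


class TestEnergyFeatures:
    def test_amfe_formula(self, random_mature):
        s, ctx, stats, _, _ = _qualified(random_mature)
        out = compute_energy_features(s, ctx, (1, len(s)))
        fe = out["en_fe_premirna"]
        assert out["en_amfe_premirna"] == pytest.approx(fe / len(s) * 100)

    def test_mfei_formula_and_gc_guard(self):
        from premir.features import _amfe, _mfei

        assert _amfe(-40.0, 100) == pytest.approx(-40.0)
        assert _mfei(-40.0, 50.0) == pytest.approx(-0.8)
        assert _mfei(-40.0, 0.0) == 0.0

    def test_all_unpaired_premirna_is_zero_energy(self):
        from premir.formats import from_dot_bracket
        from premir.hairpin import HitContext

        s = from_dot_bracket("ACGU" * 6, "." * 24)
        ctx = HitContext(s, (1, 10), "loop", None, 0, None)
        out = compute_energy_features(s, ctx, (1, 24))
        assert out["en_fe_premirna"] == 0.0
        assert out["en_amfe_premirna"] == 0.0
        assert out["en_mfei_premirna"] == 0.0


class TestComposition:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 100.0), ("AUAU", 0.0), ("GCAU", 50.0)]
    )
    def test_gc_content(self, seq, expected):
        out = compute_composition({"mature": seq})
        assert out["nc_gc_mature_pct"] == pytest.approx(expected)

    def test_empty_segment_sentinel(self):
        assert compute_composition({})["nc_gc_window_pct"] == -1.0

    def test_tetranucleotide_side_table(self):
        t = tetranucleotide_table("ACGUACGU")
        assert len(t) == 256
        assert t.sum() == pytest.approx(1.0)
        assert t["ACGU"] == pytest.approx(2 / 5)


class TestExtractFeatures:
    def test_perfect_duplex_has_zero_mismatch_features(self, random_mature):
        s, ctx, stats, verdict, _ = _qualified(random_mature)
        fv = extract_features(s, ctx, stats, verdict=verdict)
        assert fv["ms_n_mismatch"] == 0
        assert fv["ms_n_asym"] == 0
        assert fv["ms_secondary_stem"] == 0
        # seed positions (mature 2-8) all Watson-Crick paired
        for i in range(2, 9):
            assert fv[f"pc_mat{i}_state"] == 1.0

    def test_planted_bulge_recorded_at_position(self, random_mature):
        params = HairpinParams(bulges=((9, 2, "star"),))
        s, ctx, stats, verdict, truth = _qualified(random_mature, params)
        fv = extract_features(s, ctx, stats, verdict=verdict)
        assert fv["ms_n_bulges"] == 1
        assert fv["ms_bulge_1_pos"] == 9
        assert fv["ms_bulge_1_size"] == 2
        assert fv["ms_bulge_1_side"] == 2  # passenger side
        assert fv["ms_bulge_2_pos"] == -1  # sentinel

    def test_features_mirror_duplex_stats_exactly(self, random_mature):
        params = HairpinParams(
            mismatch_positions=(5, 11), bulges=((14, 1, "mir"),), ext_stem=8
        )
        s, ctx, stats, verdict, _ = _qualified(random_mature, params)
        fv = extract_features(s, ctx, stats, verdict=verdict)
        assert fv["ms_n_mismatch"] == stats.n_mismatch
        assert fv["ms_n_asym"] == stats.n_asym
        assert fv["ms_largest_loop"] == stats.largest_loop
        assert fv["ms_overhang_5p"] == stats.overhang_5p_side
        assert fv["ms_overhang_3p"] == stats.overhang_3p_side
        assert fv["ms_mature_len"] == stats.mir_len
        assert fv["ms_star_len"] == stats.star_len
        assert fv["ms_precursor_len"] == stats.precursor_len
        assert fv["ms_duplex_pairs"] == stats.n_duplex_pairs

    def test_invariant_under_metadata_renaming(self, random_mature):
        s, ctx, stats, verdict, _ = _qualified(random_mature)
        meta_a = {"query_len": 21, "query_gc_pct": 50.0, "ld": 0, "evalue": 1e-9}
        fv_a = extract_features(s, ctx, stats, meta_a, {"start": 5, "end": 105, "strand": "+"})
        fv_b = extract_features(s, ctx, stats, dict(meta_a), {"start": 5, "end": 105, "strand": "+"})
        assert np.array_equal(fv_a.values, fv_b.values)

    def test_unqualified_candidate_is_contract_error(self, random_mature):
        s, ctx, stats, _, _ = _qualified(random_mature)
        rejected = Verdict(accepted=False, violated=("vi",), stage="disqualification")
        with pytest.raises(ValueError, match="disqualify"):
            extract_features(s, ctx, stats, verdict=rejected)
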