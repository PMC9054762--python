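import numpy as np
import pandas as pd
import pytest

from idrhelix import (
    ShiftSimSpec,
    ShiftTable,
    VariantMap,
    delta_delta,
    estimate_helix_population,
    gen_shift_set,
    helicity_ranking,
    secondary_shifts,
)
from idrhelix.nmr import FULL_HELIX_OFFSETS, combined_amide_csp


def coil_table_for(sequence, rc, first_residue=1):
    """A shift table equal to random-coil values at every residue."""
    table = ShiftTable("coil")
    for i, aa in enumerate(sequence):
        idx = first_residue + i
        for atom in ("H", "N", "CA", "CB", "C"):
            ref = rc.get(aa, atom)
            if ref is not None:
                table.add(idx, aa, atom, ref)
    return table


SEQ = "MKTAYIAGQAAAAAAALESGNHV"  # helix span will cover the A-rich middle


class TestSecondaryShifts:
    def test_coil_observation_gives_all_zeros(self, rc_table):
        table = coil_table_for(SEQ, rc_table)
        prof = secondary_shifts(table, SEQ, rc_table)
        vals = prof.data[["dCA", "dCB", "dC", "dH", "dN"]].to_numpy()
        np.testing.assert_allclose(vals[~np.isnan(vals)], 0.0, atol=1e-12)

    def test_helical_sign_pattern(self, rc_table):
        # planted partial helix: positive Ca and C', negative Cb inside span
        span = (9, 17)
        spec = ShiftSimSpec("h", SEQ, span, helix_population=0.4,
                            noise_sd={a: 0.0 for a in "H N CA CB C".split()}, seed=0)
        prof = secondary_shifts(gen_shift_set(spec, rc_table), SEQ, rc_table)
        inside = prof.data.loc[span[0]:span[1]]
        assert (inside["dCA"].dropna() > 0).all()
        assert (inside["dCB"].dropna() < 0).all()
        assert (inside["dC"].dropna() > 0).all()
        outside = prof.data.drop(index=range(span[0], span[1] + 1))
        np.testing.assert_allclose(outside["dCA"].dropna(), 0.0, atol=1e-12)

    def test_glycine_has_no_cb_or_helicity_index(self, rc_table):
        seq = "AGA"
        prof = secondary_shifts(coil_table_for(seq, rc_table), seq, rc_table)
        assert np.isnan(prof.data.loc[2, "dCB"])
        assert np.isnan(prof.data.loc[2, "dCAB"])
        assert not np.isnan(prof.data.loc[1, "dCAB"])

    def test_missing_assignment_propagates_as_nan_not_zero(self, rc_table):
        table = ShiftTable("c")
        table.add(1, "A", "CA", 55.0)  # CB unassigned
        prof = secondary_shifts(table, "A", rc_table)
        assert np.isnan(prof.data.loc[1, "dCB"])
        assert np.isnan(prof.data.loc[1, "dCAB"])

    def test_residue_type_mismatch_names_residue(self, rc_table):
        table = ShiftTable("c")
        table.add(2, "G", "CA", 45.0)
        with pytest.raises(ValueError, match="residue 2"):
            secondary_shifts(table, "AA", rc_table)

    def test_parent_protein_numbering(self, rc_table):
        table = coil_table_for("AG", rc_table, first_residue=237)
        prof = secondary_shifts(table, "AG", rc_table, first_residue=237)
        assert list(prof.data.index) == [237, 238]

    def test_carbon_referencing_offset_cancels_in_index(self, rc_table):
        spec = ShiftSimSpec("h", SEQ, (9, 17), helix_population=0.4, seed=5)
        table = gen_shift_set(spec, rc_table)
        shifted = ShiftTable("h-shifted")
        for (idx, atom), val in table.shifts.items():
            off = 0.731 if atom in ("CA", "CB", "C") else 0.0
            shifted.add(idx, table.residue_types[idx], atom, val + off)
        a = secondary_shifts(table, SEQ, rc_table)
        b = secondary_shifts(shifted, SEQ, rc_table)
        pd.testing.assert_series_equal(a.data["dCAB"], b.data["dCAB"])


class TestVariantMap:
    def test_from_deletions_keeps_wildtype_numbering(self):
        vmap = VariantMap.from_deletions("d", 1, 10, [(4, 6)])
        assert vmap.pairs == [(i, i) for i in [1, 2, 3, 7, 8, 9, 10]]
        assert vmap.adjacent_to_deletion(3)
        assert vmap.adjacent_to_deletion(7)
        assert not vmap.adjacent_to_deletion(8)

    def test_renumbered_variant(self):
        vmap = VariantMap.from_deletions("d", 1, 5, [(2, 3)], renumber=True)
        assert vmap.pairs == [(1, 1), (2, 4), (3, 5)]

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            VariantMap("d", [(1, 2), (2, 1)])

    def test_deleted_range_overlapping_mapping_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            VariantMap("d", [(1, 1), (2, 2)], deleted_ranges=[(2, 3)])


class TestDeltaDelta:
    def test_identical_profiles_give_zero(self, rc_table):
        prof = secondary_shifts(coil_table_for(SEQ, rc_table), SEQ, rc_table)
        vmap = VariantMap.identity("c", 1, len(SEQ))
        dd = delta_delta(prof, prof, vmap)
        for col in ("ddCAB", "ddH", "ddN"):
            np.testing.assert_allclose(dd.data[col].dropna(), 0.0, atol=1e-12)

    def test_uniform_dca_offset_appears_only_in_span(self, rc_table):
        wt_table = coil_table_for(SEQ, rc_table)
        var_table = ShiftTable("var")
        for (idx, atom), val in wt_table.shifts.items():
            bump = 0.1 if (atom == "CA" and 5 <= idx <= 14) else 0.0
            var_table.add(idx, wt_table.residue_types[idx], atom, val + bump)
        wt = secondary_shifts(wt_table, SEQ, rc_table)
        var = secondary_shifts(var_table, SEQ, rc_table)
        dd = delta_delta(var, wt, VariantMap.identity("var", 1, len(SEQ)))
        in_span = dd.data.loc[5:14, "ddCAB"].dropna()
        np.testing.assert_allclose(in_span, 0.1, atol=1e-12)
        out_span = dd.data.drop(index=range(5, 15))["ddCAB"].dropna()
        np.testing.assert_allclose(out_span, 0.0, atol=1e-12)

    def test_wildtype_only_residue_absent_from_output(self, rc_table):
        wt = secondary_shifts(coil_table_for("AAA", rc_table), "AAA", rc_table)
        var_table = coil_table_for("AA", rc_table)  # residue 3 unassigned
        var = secondary_shifts(var_table, "AAA"[:2] + "A", rc_table)
        dd = delta_delta(var, wt, VariantMap.identity("v", 1, 3))
        assert 3 not in dd.data.index

    def test_unmapped_variant_residue_warned_and_excluded(self, rc_table, caplog):
        var = secondary_shifts(coil_table_for("AAA", rc_table), "AAA", rc_table)
        wt = secondary_shifts(coil_table_for("AAA", rc_table), "AAA", rc_table)
        vmap = VariantMap("v", [(1, 1), (2, 2)])  # residue 3 unmapped
        with caplog.at_level("WARNING", logger="idrhelix.nmr"):
            dd = delta_delta(var, wt, vmap)
        assert 3 not in dd.data.index
        assert "not covered" in caplog.text

    def test_truncation_flank_flagged(self, rc_table):
        seq_wt = "AAAAAAAAAA"
        vmap = VariantMap.from_deletions("d", 1, 10, [(4, 6)])
        var_seq = "AAAAAAA"
        var_table = ShiftTable("d")
        for v, w in vmap.pairs:
            for atom in ("H", "N", "CA", "CB", "C"):
                var_table.add(v, "A", atom, rc_table.get("A", atom))
        # variant residues keep wildtype numbering; sequence indexed by map
        var = secondary_shifts(var_table, seq_wt, rc_table)
        wt = secondary_shifts(coil_table_for(seq_wt, rc_table), seq_wt, rc_table)
        dd = delta_delta(var, wt, vmap)
        assert bool(dd.data.loc[3, "near_deletion"]) is True
        assert bool(dd.data.loc[7, "near_deletion"]) is True
        assert bool(dd.data.loc[8, "near_deletion"]) is False
        del var_seq


class TestHelicityRankingAndPopulation:
    def _profile(self, p, seed, rc, span=(9, 17)):
        noise = {a: 0.02 for a in ("H", "N", "CA", "CB", "C")}
        spec = ShiftSimSpec(f"p{p}", SEQ, span, helix_population=p,
                            noise_sd=noise, seed=seed)
        return secondary_shifts(gen_shift_set(spec, rc), SEQ, rc)

    def test_two_constructs_rank_by_planted_population(self, rc_table):
        profiles = {
            "strong": self._profile(0.5, 1, rc_table),
            "weak": self._profile(0.2, 2, rc_table),
        }
        ranking = helicity_ranking(profiles, (9, 17))
        assert ranking.order == ("strong", "weak")
        assert len(ranking.groups) == 2

    def test_three_constructs_strictly_decreasing(self, rc_table):
        profiles = {
            "a": self._profile(0.5, 3, rc_table),
            "b": self._profile(0.35, 4, rc_table),
            "c": self._profile(0.2, 5, rc_table),
        }
        ranking = helicity_ranking(profiles, (9, 17))
        assert ranking.order == ("a", "b", "c")

    def test_identical_profiles_declared_equivalent(self, rc_table):
        prof = self._profile(0.4, 6, rc_table)
        ranking = helicity_ranking({"x": prof, "y": prof}, (9, 17))
        assert len(ranking.groups) == 1
        assert set(ranking.groups[0]) == {"x", "y"}

    def test_construct_without_data_in_window_unranked(self, rc_table):
        prof = self._profile(0.4, 7, rc_table)
        empty = secondary_shifts(coil_table_for("MK", rc_table), "MK", rc_table)
        ranking = helicity_ranking({"full": prof, "short": empty}, (9, 17))
        assert ranking.unranked == ("short",)
        assert ranking.order == ("full",)

    def test_population_recovered_in_noiseless_limit(self, rc_table):
        for p in (0.0, 0.4, 1.0):
            spec = ShiftSimSpec("c", SEQ, (9, 17), helix_population=p,
                                noise_sd={a: 0.0 for a in "H N CA CB C".split()},
                                seed=0)
            prof = secondary_shifts(gen_shift_set(spec, rc_table), SEQ, rc_table)
            assert estimate_helix_population(prof, (9, 17)) == pytest.approx(p, abs=1e-9)

    def test_planted_population_scales_index_linearly(self, rc_table):
        quiet = {a: 0.0 for a in ("H", "N", "CA", "CB", "C")}
        means = []
        for p in (0.2, 0.4):
            spec = ShiftSimSpec("c", SEQ, (9, 17), helix_population=p,
                                noise_sd=quiet, seed=0)
            prof = secondary_shifts(gen_shift_set(spec, rc_table), SEQ, rc_table)
            means.append(prof.mean_helicity_index((9, 17)))
        assert means[1] == pytest.approx(2 * means[0])


def test_combined_amide_csp_norm():
    assert combined_amide_csp(0.3, 0.0) == pytest.approx(0.3)
    assert combined_amide_csp(0.0, 1.0) == pytest.approx(0.2)
    assert FULL_HELIX_OFFSETS["CA"] - FULL_HELIX_OFFSETS["CB"] > 0
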