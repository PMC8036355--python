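"""Divergence metrics, RD classification, fragments, elimination, interfaces."""

import numpy as np
import pytest

from fodm import (
    CORE_PRESENT,
    MEMBRANE_LIKE,
    NO_CORE,
    SelectionError,
    StructureModel,
    SupportError,
    UndefinedRDError,
    classify,
    eliminate_residues,
    fragment_profile,
    interface_residues,
    kl_divergence,
    rank_discordance,
    rd,
    status_from_profile,
    unit_profile,
    unit_status,
)
from fodm.metrics import parse_residue_id

from conftest import toy_unit


class TestKLDivergence:
    def test_identity_of_distributions(self):
        P = np.array([0.2, 0.5, 0.3])
        assert kl_divergence(P, P) == 0.0

    def test_hand_value_half_vs_quarter(self):
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.207519, abs=1e-6
        )

    def test_hand_value_point_mass(self):
        assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_p_terms_contribute_nothing(self):
        assert kl_divergence([0.0, 1.0], [0.5, 0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_support_violation_raises(self):
        with pytest.raises(SupportError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kl_divergence([1.0], [0.5, 0.5])


class TestRD:
    def test_zero_when_o_equals_t(self):
        O = T = np.array([0.3, 0.7])
        assert rd(O, T, np.array([0.5, 0.5])) == 0.0

    def test_one_when_o_equals_ref(self):
        O = Ref = np.array([0.5, 0.5])
        assert rd(O, np.array([0.3, 0.7]), Ref) == 1.0

    def test_derived_example(self):
        O = np.array([0.5, 0.5])
        assert rd(O, np.array([0.25, 0.75]), np.array([0.5, 0.5])) == 1.0

    def test_undefined_when_all_equal(self):
        v = np.array([0.5, 0.5])
        with pytest.raises(UndefinedRDError):
            rd(v, v, v)


class TestClassification:
    @pytest.mark.parametrize(
        "rd_tor,rd_tom,expected",
        [
            (0.49, 0.3, CORE_PRESENT),
            (0.5, 0.4, NO_CORE),        # boundary is exclusive
            (0.6, 0.7, MEMBRANE_LIKE),
            (0.6, 0.5, NO_CORE),
        ],
    )
    def test_labels(self, rd_tor, rd_tom, expected):
        assert classify(rd_tor, rd_tom) == expected

    def test_rd_comparison_identity(self, micelle_unit):
        # rd_TOM > rd_TOR iff O is closer to M than to R (Table-style bolding)
        res = unit_status(micelle_unit, K=1.0)
        assert (res.rd_TOM > res.rd_TOR) == (res.dkl_OM < res.dkl_OR)


class TestUnitStatus:
    def test_micelle_has_core(self, micelle_unit):
        res = unit_status(micelle_unit, K=1.0, unit_name="micelle")
        assert res.rd_TOR < 0.5
        assert res.classification == CORE_PRESENT
        assert 0 <= res.rd_TOR <= 1 and 0 <= res.rd_TOM <= 1

    def test_whole_fragment_reproduces_parent(self, micelle_unit):
        parent_prof, _ = unit_profile(micelle_unit, K=1.0, unit_name="parent")
        parent_res = status_from_profile(parent_prof)
        frag_res = unit_status(
            micelle_unit, mode="in_parent", parent=parent_prof, unit_name="parent"
        )
        assert frag_res.rd_TOR == pytest.approx(parent_res.rd_TOR, abs=1e-12)
        assert frag_res.rd_TOM == pytest.approx(parent_res.rd_TOM, abs=1e-12)
        assert frag_res.dkl_OT == pytest.approx(parent_res.dkl_OT, abs=1e-12)

    def test_in_parent_requires_parent(self, micelle_unit):
        with pytest.raises(ValueError):
            unit_status(micelle_unit, mode="in_parent")

    def test_fragment_outside_parent_rejected(self, micelle_unit):
        parent_prof, _ = unit_profile(micelle_unit[:50], K=1.0)
        with pytest.raises(SelectionError):
            fragment_profile(
                parent_prof, [p.residue_id for p in micelle_unit[50:60]], "frag"
            )


class TestEliminateResidues:
    def test_empty_exclusion_is_identity(self, micelle_unit):
        base = unit_status(micelle_unit, K=1.0)
        elim = eliminate_residues(micelle_unit, [], K=1.0)
        assert elim.rd_TOR == pytest.approx(base.rd_TOR, abs=1e-12)
        assert elim.eliminated == []

    def test_single_surviving_residue_has_undefined_rd(self):
        # after elimination N = 1: T = O = R = (1.0), so RD is 0/0
        unit = toy_unit([(0, 0, 0), (3, 0, 0), (0, 3, 1)], [0.4, 0.6, 0.5])
        with pytest.raises(UndefinedRDError):
            eliminate_residues(unit, ["A:1", "A:2"], K=1.0)

    def test_excluding_all_rejected(self, micelle_unit):
        with pytest.raises(SelectionError):
            eliminate_residues(
                micelle_unit, [p.residue_id for p in micelle_unit], K=1.0
            )

    def test_unknown_residue_rejected(self, micelle_unit):
        with pytest.raises(SelectionError):
            eliminate_residues(micelle_unit, ["Z:999"], K=1.0)

    def test_negligible_mass_exclusion_barely_moves_rd(self, micelle_unit):
        # a residue at the bounding-box corner (inside every per-axis extent
        # but at ~sqrt(3)*3 sigma Mahalanobis radius) with zero intrinsic H
        # and no neighbors carries ~0 mass in both T and O
        from fodm import ResiduePoint
        from fodm.synthetic import SyntheticSpec, make_micelle

        base_unit = make_micelle(
            SyntheticSpec(kind="micelle", n_residues=1000, seed=11)
        ).points
        _, field = unit_profile(base_unit, K=1.0)
        corner = field.center + field.rotation.T @ (0.997 * 3.0 * field.sigmas)
        far = ResiduePoint("A", 9999, "ALA", corner, 0.0)
        unit = list(base_unit) + [far]
        full_prof, _ = unit_profile(unit, K=1.0)
        mass = full_prof.T[-1] + full_prof.O[-1]
        assert mass < 1e-6
        assert abs(full_prof.T[-1] - full_prof.O[-1]) < 1e-6
        full = status_from_profile(full_prof)
        elim = eliminate_residues(unit, [far.residue_id], K=1.0)
        # same field stands, so the O-vs-T divergence is untouched; R and M
        # both hand every residue ~1/N baseline mass, so their divergences
        # (and hence RD) move by O(1/N) when the count drops - no more
        assert abs(elim.dkl_OT - full.dkl_OT) < 1e-6
        n = full.N
        bound = 2.0 * np.log2(n / (n - 1))
        assert abs(elim.rd_TOR - full.rd_TOR) < bound
        assert abs(elim.rd_TOM - full.rd_TOM) < bound
        ref = status_from_profile(
            fragment_profile(full_prof, full_prof.residue_ids[:-1], "u")
        )
        assert abs(elim.rd_TOR - ref.rd_TOR) < 1e-12

    def test_eliminated_residues_recorded(self, micelle_unit):
        res = eliminate_residues(micelle_unit, ["A:5", "A:7"], K=1.0)
        assert res.eliminated == ["A:5", "A:7"]
        assert res.N == len(micelle_unit) - 2

    def test_parse_residue_id(self):
        rid = parse_residue_id("B:42A")
        assert (rid.chain_id, rid.residue_number, rid.icode) == ("B", 42, "A")
        with pytest.raises(ValueError):
            parse_residue_id("nope")


class TestRankDiscordance:
    def test_equal_profiles_keep_original_order(self, micelle_unit):
        prof, _ = unit_profile(micelle_unit, K=1.0)
        prof.O = prof.T.copy()
        records = rank_discordance(prof)
        assert [r.residue_id for r in records] == prof.residue_ids
        assert all(r.label == "accordant" for r in records)

    def test_hand_sorted_example(self):
        # T = (0.5, 0.3, 0.2), O = (0.2, 0.3, 0.5): residue 1 (|d|=0.3,
        # deficiency), residue 3 (|d|=0.3, excess ranks after equal-|d|
        # deficiency? no - excess first on ties), residue 2 (0)
        unit = toy_unit([(0, 0, 0), (4, 0, 0), (0, 4, 1)], [0.5, 0.5, 0.5])
        prof, _ = unit_profile(unit, K=0.0)
        prof.T = np.array([0.5, 0.3, 0.2])
        prof.O = np.array([0.2, 0.3, 0.5])
        records = rank_discordance(prof)
        numbers = [r.residue_id.residue_number for r in records]
        assert numbers == [3, 1, 2]  # tie between 1 and 3 broken excess-first
        assert records[0].label == "excess"
        assert records[1].label == "deficiency"
        assert records[2].label == "accordant"

    def test_excess_means_o_above_t(self, micelle_unit):
        prof, _ = unit_profile(micelle_unit, K=1.0)
        for r in rank_discordance(prof):
            if r.label == "excess":
                assert r.O > r.T
            elif r.label == "deficiency":
                assert r.O < r.T


class TestInterfaceResidues:
    @staticmethod
    def _model(chain_points):
        from fodm import ResiduePoint

        pts = [
            ResiduePoint(chain, i, "ALA", np.asarray(c, dtype=float), 0.5)
            for chain, coords in chain_points.items()
            for i, c in enumerate(coords, start=1)
        ]
        return StructureModel(points=pts)

    def test_distant_chains_share_no_interface(self):
        model = self._model({"A": [(0, 0, 0)], "B": [(100, 0, 0)]})
        assert interface_residues(model, "A", "B", cutoff=9.0) == set()

    def test_close_single_residues_flagged_from_either_side(self):
        model = self._model({"A": [(0, 0, 0)], "B": [(1, 0, 0)]})
        a = interface_residues(model, "A", "B", cutoff=9.0)
        b = interface_residues(model, "B", "A", cutoff=9.0)
        assert {str(r) for r in a} == {"A:1"}
        assert {str(r) for r in b} == {"B:1"}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        coords_a = rng.uniform(0, 30, size=(40, 3))
        coords_b = rng.uniform(5, 35, size=(35, 3))
        model = self._model({"A": coords_a, "B": coords_b})
        got = interface_residues(model, "A", "B", cutoff=9.0)
        expected = set()
        for p in model.points:
            if p.chain_id != "A":
                continue
            for q in model.points:
                if q.chain_id == "B" and np.linalg.norm(p.position - q.position) <= 9.0:
                    expected.add(p.residue_id)
                    break
        assert got == expected

    def test_empty_chain_set_rejected(self):
        model = self._model({"A": [(0, 0, 0)]})
        with pytest.raises(SelectionError):
            interface_residues(model, "A", "Z", cutoff=9.0)
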