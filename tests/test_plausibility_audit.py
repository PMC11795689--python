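"""Plausibility diagnostics: SASA, SS, environments, stacks, clashes, folds."""

import itertools

import numpy as np
import pytest

from repeataudit import (
    Atom, FeatureInjection, Residue, ScoreTable3D1D, SolenoidSpec,
    StructureModel, assess_scores, assign_environment, assign_ss, audit_model,
    build_coil, build_helix, build_solenoid, classify_fold, count_clashes,
    detect_charged_stacks, detect_exposed_hydrophobics, disorder_flag,
    flag_problematic, make_unit, profile_3d1d, sasa, smooth_profile, tandem,
)
from repeataudit.plausibility_audit import (
    ALL_ENVIRONMENT_CLASSES, ChargedStack, polar_fractions, read_disorder_tsv,
)


def _one_residue_model(code="V"):
    atoms = [Atom("N", "N", [-0.6, 0.3, 0.0]), Atom("CA", "C", [0.0, 0.0, 0.0]),
             Atom("C", "C", [0.6, 0.3, 0.0]), Atom("O", "O", [0.6, 1.3, 0.0]),
             Atom("CB", "C", [0.0, 1.5, 0.0]), Atom("SCP", "C", [0.0, 4.0, 0.0])]
    return StructureModel(residues=[Residue(seqid=1, code=code, atoms=atoms)])


class TestSasa:
    def test_isolated_residue_fully_exposed(self):
        result = sasa(_one_residue_model())
        assert result.relative[0] == pytest.approx(1.0, abs=0.15)

    def test_caged_atom_has_zero_area(self):
        # a central carbon enclosed by a tight shell of carbons
        from repeataudit.plausibility_audit import _fibonacci_sphere
        shell = 2.9 * _fibonacci_sphere(60)
        residues = [
            Residue(seqid=1, code="G", atoms=[Atom("CA", "C", p)
                                              for p in shell[:30]]),
            Residue(seqid=2, code="G", atoms=[Atom("CA", "C", np.zeros(3))]),
            Residue(seqid=3, code="G", atoms=[Atom("CA", "C", p)
                                              for p in shell[30:]]),
        ]
        result = sasa(StructureModel(residues=residues))
        assert result.absolute[1] == 0.0

    def test_agreement_with_independent_reference_implementation(self):
        # biotite's Shrake-Rupley on the same atoms/radii is the oracle
        import biotite.structure as struc

        model = build_helix("VLV")
        flat = model.all_atoms()
        n = len(flat)
        arr = struc.AtomArray(n)
        from repeataudit.plausibility_audit import vdw_radii
        radii_map = vdw_radii()
        for idx, (res_i, atom) in enumerate(flat):
            arr.coord[idx] = atom.position
            arr.res_id[idx] = res_i + 1
            arr.atom_name[idx] = atom.name
            arr.element[idx] = atom.element
            arr.res_name[idx] = "UNK"
        radii = np.array([radii_map[a.element] for _, a in flat])
        ref_atom_areas = struc.sasa(arr, probe_radius=1.4, point_number=960,
                                    vdw_radii=radii)
        ref = np.zeros(len(model))
        for idx, (res_i, _) in enumerate(flat):
            ref[res_i] += ref_atom_areas[idx]
        ours = sasa(model).absolute
        assert np.all(np.abs(ours - ref) / ref <= 0.05)

    def test_unknown_element_named_in_error(self):
        model = _one_residue_model()
        model.residues[0].atoms[0].element = "XX"
        with pytest.raises(KeyError, match="XX"):
            sasa(model)


class TestAssignSS:
    def test_ideal_helix_is_mostly_helix(self, helix100):
        ss = assign_ss(helix100)
        assert np.mean(ss == "H") >= 0.90

    def test_solenoid_strands_are_mostly_strand(self, solenoid12):
        ss = assign_ss(solenoid12)
        assert np.mean(ss == "E") >= 0.90

    def test_three_residue_model_is_all_coil(self):
        ca = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], dtype=float)
        assert list(assign_ss(ca)) == ["C", "C", "C"]

    def test_coil_has_no_dominant_class(self, coil60):
        ss = assign_ss(coil60)
        assert max(np.mean(ss == "H"), np.mean(ss == "E")) < 0.25


class TestEnvironments:
    def test_exposed_class_ignores_polarity(self):
        env = assign_environment(0.9, 0.2, "H")
        assert env.burial == "E" and env.ss == "helix"
        assert assign_environment(0.9, 0.9, "H").burial == "E"

    def test_buried_apolar_sheet(self):
        env = assign_environment(0.02, 0.1, "E")
        assert env.burial == "B1" and env.ss == "sheet"

    def test_exactly_18_distinct_classes_over_input_grid(self):
        seen = set()
        for rel in (0.02, 0.2, 0.6):
            for pf in (0.1, 0.5, 0.62, 0.8):
                for ss in "HEC":
                    seen.add(assign_environment(rel, pf, ss).label)
        assert len(seen) == 18
        assert seen == {c.label for c in ALL_ENVIRONMENT_CLASSES}

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_environment(-0.1, 0.5, "H")
        with pytest.raises(ValueError):
            assign_environment(0.5, 1.5, "H")


class TestProfile3D1D:
    def test_constant_good_scores_pass(self):
        profile = assess_scores(np.full(100, 0.2))
        assert profile.mean_3d1d == pytest.approx(0.2)
        assert not profile.categorical_fail

    def test_constant_bad_scores_fail(self):
        profile = assess_scores(np.full(100, -0.1))
        assert profile.categorical_fail

    def test_smoothing_equals_bruteforce_moving_average(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            raw = rng.normal(size=rng.integers(5, 200))
            for window in (1, 5, 21):
                ours = smooth_profile(raw, window)
                half = window // 2
                expected = np.array([
                    raw[max(0, i - half):min(len(raw), i + half + 1)].mean()
                    for i in range(len(raw))])
                assert np.allclose(ours, expected)

    @pytest.mark.parametrize("window", [0, 2, -3])
    def test_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            smooth_profile(np.ones(10), window)

    def test_exact_80_percent_boundary(self):
        # 80 of 100 at threshold: fraction == 0.8 is NOT a fail (rule is < 0.8)
        raw = np.array([0.1] * 80 + [-1.0] * 20)
        profile = assess_scores(raw, window=1)
        assert profile.frac_ge_threshold == pytest.approx(0.8)
        assert not profile.categorical_fail
        raw[79] = -1.0
        assert assess_scores(raw, window=1).categorical_fail

    def test_full_profile_on_model_uses_table_scores(self, solenoid12):
        profile = profile_3d1d(solenoid12, table=ScoreTable3D1D.constant(0.25),
                               window=21)
        assert np.allclose(profile.raw_scores, 0.25)
        assert profile.mean_3d1d == pytest.approx(0.25)
        assert not profile.categorical_fail
        assert len(profile.environments) == len(solenoid12)

    def test_mean_invariant_under_renumbering(self, solenoid12):
        from copy import deepcopy

        renumbered = deepcopy(solenoid12)
        for i, res in enumerate(renumbered.residues):
            res.seqid = 100 + 2 * i
        table = ScoreTable3D1D.default()
        a = profile_3d1d(solenoid12, table=table)
        b = profile_3d1d(renumbered, table=table)
        assert a.mean_3d1d == pytest.approx(b.mean_3d1d)


class TestChargedStacks:
    def test_injected_stack_found_uncompensated(self, stack_solenoid):
        stacks = detect_charged_stacks(stack_solenoid, 12)
        assert len(stacks) == 1
        stack = stacks[0]
        assert stack.unit_position == 0
        assert stack.sign == "negative"
        assert not stack.compensated
        # terminal rung is honestly more exposed; all interior rungs stack
        assert len(stack) >= 9
        assert stack.min_member_distance <= 7.0

    def test_counter_charge_marks_stack_compensated(self):
        unit = make_unit(12, "beta", seed=3)
        model = build_solenoid(SolenoidSpec(
            sequence=tandem(unit, 10),
            injections=[FeatureInjection("charged_stack", 0, "E"),
                        FeatureInjection("compensating_counter_charge", 2, "K")]))
        stacks = detect_charged_stacks(model, 12)
        negative = [s for s in stacks if s.sign == "negative"]
        assert negative and all(s.compensated for s in negative)

    def test_clean_solenoid_has_no_stacks(self, solenoid12):
        assert detect_charged_stacks(solenoid12, 12) == []

    def test_bad_unit_length_rejected(self, solenoid12):
        with pytest.raises(ValueError):
            detect_charged_stacks(solenoid12, 0)

    def test_his_positive_is_configurable(self):
        unit = make_unit(10, "beta", seed=2)
        model = build_solenoid(SolenoidSpec(
            sequence=tandem(unit, 10),
            injections=[FeatureInjection("charged_stack", 0, "H")]))
        with_his = detect_charged_stacks(model, 10, his_positive=True)
        without = detect_charged_stacks(model, 10, his_positive=False)
        assert with_his and with_his[0].sign == "positive"
        assert without == []


class TestExposedHydrophobics:
    def test_protruding_phe_detected_on_every_rung(self):
        unit = make_unit(12, "beta", seed=3)
        model = build_solenoid(SolenoidSpec(
            sequence=tandem(unit, 10),
            injections=[FeatureInjection("surface_hydrophobic", 1, "F")]))
        hits = detect_exposed_hydrophobics(model)
        injected_hits = [i for i in hits if i % 12 == 1]
        assert len(injected_hits) >= 10

    def test_inward_hydrophobics_not_reported(self):
        # all hydrophobics buried: only check inward positions
        unit = "CICICICICICI"  # hydrophobics on the inward (even) positions
        model = build_solenoid(SolenoidSpec(sequence=tandem(unit, 10)))
        hits = detect_exposed_hydrophobics(model)
        inward_hits = [i for i in hits if i % 12 in (0, 2, 4, 6, 8, 10)
                       and i >= 12]
        assert inward_hits == []

    def test_empty_hydrophobic_set_gives_no_hits(self, solenoid12):
        assert detect_exposed_hydrophobics(solenoid12,
                                           hydrophobic_set=frozenset()) == []


class TestClashes:
    @pytest.mark.parametrize("distance,expected", [(3.1, 0), (2.9, 1)])
    def test_two_carbon_contact_arithmetic(self, distance, expected):
        # r_vdw(C)+r_vdw(C)-0.4 = 3.0; a clash is strictly below it
        residues = [
            Residue(seqid=1, code="G", atoms=[Atom("CA", "C", np.zeros(3))]),
            Residue(seqid=2, code="G", atoms=[Atom("CA", "C", [20.0, 0, 0])]),
            Residue(seqid=3, code="G", atoms=[Atom("CA", "C", [distance, 0, 0])]),
        ]
        assert count_clashes(StructureModel(residues=residues)) == expected

    def test_forged_helix_is_clash_free(self, helix100):
        assert count_clashes(helix100) == 0

    def test_forged_solenoid_grid_is_clash_free(self, solenoid12):
        assert count_clashes(solenoid12) == 0

    def test_injected_clash_detected(self):
        unit = make_unit(12, "beta", seed=3)
        model = build_solenoid(SolenoidSpec(
            sequence=tandem(unit, 10),
            injections=[FeatureInjection("clash", 1)]))
        assert count_clashes(model) >= 1

    def test_unknown_element_named(self):
        residues = [
            Residue(seqid=1, code="G", atoms=[Atom("CA", "ZZ", np.zeros(3))]),
            Residue(seqid=2, code="G", atoms=[Atom("CA", "C", [9.0, 0, 0])]),
        ]
        with pytest.raises(KeyError, match="ZZ"):
            count_clashes(StructureModel(residues=residues))


class TestClassifyFold:
    @pytest.mark.parametrize("L,rungs", [(5, 4), (5, 10), (12, 4), (12, 10),
                                         (20, 4), (20, 10), (30, 4), (30, 10)])
    def test_solenoid_grid(self, L, rungs):
        unit = make_unit(L, "beta", seed=L * rungs)
        model = build_solenoid(SolenoidSpec(sequence=tandem(unit, rungs)))
        assert classify_fold(model, L) == "beta_solenoid"

    def test_helix_decoy(self, helix100):
        assert classify_fold(helix100, 20) == "alpha_helical"

    def test_coil_decoy(self, coil60):
        assert classify_fold(coil60, 10) == "none"

    def test_unit_length_too_large_rejected(self, coil60):
        with pytest.raises(ValueError):
            classify_fold(coil60, len(coil60))


class TestProblematicRule:
    def test_confident_model_with_bad_score_and_stack(self):
        stack = ChargedStack(0, [0, 12, 24], "negative", compensated=False,
                             min_member_distance=4.8)
        assert flag_problematic(82.4, 0.05, [stack]) is True

    def test_plddt_gate_blocks_low_confidence(self):
        stack = ChargedStack(0, [0, 12, 24], "negative", compensated=False,
                             min_member_distance=4.8)
        assert flag_problematic(60.0, -0.5, [stack]) is False

    def test_good_model_not_flagged(self):
        assert flag_problematic(85.0, 0.3, []) is False

    def test_exhaustive_boundary_grid(self):
        uncomp = ChargedStack(0, [0, 1, 2], "negative", False, 4.8)
        comp = ChargedStack(0, [0, 1, 2], "negative", True, 4.8)
        for plddt, score, stacks in itertools.product(
                (69.9, 70.1), (0.09, 0.11), ([], [comp], [uncomp])):
            expected = plddt > 70 and (score < 0.1
                                       or any(not s.compensated for s in stacks))
            assert flag_problematic(plddt, score, stacks) is expected


class TestDisorder:
    @pytest.mark.parametrize("value,flagged", [(0.5, True), (0.49, False),
                                               (0.0, False)])
    def test_threshold(self, value, flagged):
        mean, flag = disorder_flag([value] * 10)
        assert mean == pytest.approx(value)
        assert flag is flagged

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            disorder_flag([0.5, 1.2])

    def test_tsv_ingestion(self, tmp_path):
        path = tmp_path / "dis.tsv"
        path.write_text("residue_index\tprobability\n2\t0.6\n1\t0.4\n3\t0.8\n")
        probs = read_disorder_tsv(path)
        assert np.allclose(probs, [0.4, 0.6, 0.8])


class TestAuditModel:
    def test_full_audit_of_problematic_model(self, stack_solenoid):
        import numpy as np

        from repeataudit import annotate_plddt

        model = annotate_plddt(stack_solenoid, np.full(len(stack_solenoid), 85.0))
        report = audit_model(model, 12, seq_id="fixture",
                             table=ScoreTable3D1D.constant(0.3))
        assert report.fold_class == "beta_solenoid"
        assert report.n_uncompensated_stacks == 1
        assert report.mean_plddt == pytest.approx(85.0)
        assert report.mean_3d1d == pytest.approx(0.3)
        assert not report.categorical_fail
        assert report.problematic  # stack route, despite a good 3D/1D score
        d = report.to_dict()
        assert d["problematic"] and d["n_stacks"] == 1
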