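import pytest

from noxevo.motifs import (
    CoreFingerprint,
    VXGPFYG_RE,
    assign_architecture,
    classify_ef_loop,
    map_ef_hand_homology,
    predict_tm_helices,
    scan_core_fingerprint,
    scan_ef_hands,
)
from noxevo.sequences import Alignment
from noxevo.simulate import PRESETS, build_root_sequence, make_family_fixture, SimulationConfig
from noxevo import annotate_sequence

CANONICAL_LOOP = "DKDGDGYISAAE"
CALPAIN_LOOP = "AKWDVCSTLNE"  # 11 residues: A1, D4, E11


class TestPredictTMHelices:
    def test_hydrophilic_sequence_has_no_helices(self):
        assert predict_tm_helices("S" * 80) == []

    def test_planted_hydrophobic_stretches_recovered(self):
        rec, truth = build_root_sequence("nox5", 3)
        tms = predict_tm_helices(rec.seq)
        assert len(tms) == 6
        for tm, (s, e) in zip(tms, truth.tm_spans):
            assert abs(tm.start - s) <= 2 and abs(tm.end - e) <= 2
        assert [t.index for t in tms] == [1, 2, 3, 4, 5, 6]

    def test_short_stretch_below_min_length_ignored(self):
        seq = "S" * 30 + "L" * 8 + "S" * 30
        assert predict_tm_helices(seq) == []

    def test_sequence_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            predict_tm_helices("MKV")


class TestCoreFingerprint:
    def test_planted_core_found_at_planted_positions(self):
        rec, truth = build_root_sequence("ca_independent", 11)
        tms = predict_tm_helices(rec.seq)
        fp = scan_core_fingerprint(rec.seq, tms)
        assert fp.is_nox_like
        assert sorted(fp.heme_his) == sorted(truth.heme_his)
        assert fp.nonheme_his_h3 == truth.nonheme_his_h3
        assert fp.tsg_motif == truth.tsg
        assert fp.vxgpfyg == truth.vxgpfyg
        assert fp.eloop_cys == truth.eloop_cys

    def test_mutated_dehydrogenase_motif_breaks_nox_call(self):
        rec, truth = build_root_sequence("nox5", 5)
        s, e = truth.vxgpfyg
        seq = rec.seq[:s - 1] + "AAAAAA" + rec.seq[e:]
        fp = scan_core_fingerprint(seq, predict_tm_helices(seq))
        assert not fp.is_nox_like

    @pytest.mark.parametrize(
        "motif,matches", [("LAGPFG", True), ("VKGPYG", True), ("LAGPAG", False),
                          ("AAGPFG", False)]
    )
    def test_vxgpfyg_pattern(self, motif, matches):
        assert bool(VXGPFYG_RE.fullmatch(motif)) is matches

    def test_few_helices_warns_and_is_not_nox(self):
        with pytest.warns(UserWarning):
            fp = scan_core_fingerprint("MKVLIEDSTA" * 5, [])
        assert not fp.is_nox_like


class TestClassifyEFLoop:
    def test_canonical_loop_roles_and_anchors(self):
        ann = classify_ef_loop(CANONICAL_LOOP)
        assert ann is not None and ann.kind == "canonical"
        assert ann.roles == {"X": 1, "Y": 3, "Z": 5, "-Y": 7, "-X": 9, "-Z": 12}
        assert ann.loop_len == 12
        assert ann.gly6 and ann.bidentate_zminus
        assert CANONICAL_LOOP[ann.roles["-Z"] - 1] in "DE"

    def test_calpain_loop_roles_and_anchors(self):
        ann = classify_ef_loop(CALPAIN_LOOP + "K")  # window must be >= 12
        assert ann is not None and ann.kind == "calpain-like"
        assert ann.roles == {"X": 1, "Z": 4, "-Y": 6, "-X": 8, "-Z": 11}
        assert ann.loop_len == 11
        assert CALPAIN_LOOP[ann.roles["-Z"] - 1] == "E"

    def test_no_acidic_anchors_gives_no_call(self):
        assert classify_ef_loop("G" * 12) is None

    def test_zminus_is_mandatory(self):
        # canonical loop with position 12 mutated away from D/E
        assert classify_ef_loop("DKDGDGYISAAK") is None

    def test_short_window_errors(self):
        with pytest.raises(ValueError):
            classify_ef_loop("DKDGD")


class TestScanEFHands:
    def test_nox5_preset_finds_calpain_first_then_canonicals(self):
        rec, truth = build_root_sequence("nox5", 2)
        anns = scan_ef_hands(rec.seq, (0, 160))
        assert [a.kind for a in anns] == [
            "calpain-like", "canonical", "canonical", "canonical"]
        assert [a.loop_start for a in anns] == [s for _, s, _ in truth.ef_hands]
        assert [a.index for a in anns] == [1, 2, 3, 4]

    def test_calcium_independent_preset_has_none(self):
        rec, _ = build_root_sequence("ca_independent", 2)
        assert annotate_sequence(rec).ef_hands == []

    def test_two_separated_loops_found_at_planted_starts(self):
        helix = "LKQMLKQM"
        seq = ("TQPK" + helix + CANONICAL_LOOP + helix + "TQPKRHTQPKRHTQ"
               + helix + CANONICAL_LOOP + helix + "TQPK")
        second = 4 + 8 + 12 + 8 + 14 + 8 + 1
        anns = scan_ef_hands(seq)
        assert [a.loop_start for a in anns] == [13, second]

    def test_position_shift_equivariance(self):
        rec, _ = build_root_sequence("noxc", 4)
        region_len = 60
        base = scan_ef_hands(rec.seq[:region_len])
        pad = "T" * 10
        shifted = scan_ef_hands(pad + rec.seq[:region_len])
        assert [a.loop_start + 10 for a in base] == [a.loop_start for a in shifted]
        assert [a.kind for a in base] == [a.kind for a in shifted]


class TestAssignArchitecture:
    def _fp(self, nox_like=True, cys=()):
        return CoreFingerprint(tm_helices=[], eloop_cys=list(cys),
                               is_nox_like=nox_like)

    def _efs(self, n, first_calpain=False):
        rec, _ = build_root_sequence("nox5", 0)
        anns = scan_ef_hands(rec.seq, (0, 160))
        if not first_calpain:
            anns = anns[1:] + anns[:1]
        return anns[:n]

    def test_four_ef_hands_is_nox5_like(self):
        call = assign_architecture(self._fp(), self._efs(4, True), 0)
        assert call.label == "NOX5-like"
        assert call.activation_class == "calcium-dependent"
        assert call.has_calpain_ef1

    def test_two_ef_hands_with_extension_is_duox_like(self):
        call = assign_architecture(self._fp(), self._efs(2), 400)
        assert call.label == "DUOX-like" and call.has_nterm_extension

    def test_two_ef_hands_without_extension_is_rboh_like(self):
        assert assign_architecture(self._fp(), self._efs(2), 10).label == "RBOH-like"

    def test_single_ef_hand_is_noxc_like(self):
        assert assign_architecture(self._fp(), self._efs(1), 0).label == "NOXC-like"

    def test_no_ef_hands_with_eloop_cys_is_calcium_independent(self):
        call = assign_architecture(self._fp(cys=(244, 257)), [], 0)
        assert call.label == "calcium-independent-like"
        assert call.activation_class == "calcium-independent"

    def test_no_ef_hands_no_cys_is_unclassified(self):
        assert assign_architecture(self._fp(), [], 0).label == "unclassified-NOX-like"

    def test_incomplete_core_is_non_nox(self):
        call = assign_architecture(self._fp(nox_like=False), [], 0)
        assert call.label == "non-NOX" and call.activation_class == "unknown"

    def test_three_ef_hands_low_confidence_nox5(self):
        call = assign_architecture(self._fp(), self._efs(3), 0)
        assert call.label == "NOX5-like" and call.low_confidence

    def test_activation_class_iff_ef_hands(self):
        for n in range(5):
            call = assign_architecture(self._fp(cys=(1,)), self._efs(n), 0)
            assert (call.activation_class == "calcium-dependent") == (n >= 1)


@pytest.fixture(scope="module")
def mapped():
    bundle = make_family_fixture(SimulationConfig(height=0.2, seed=5))
    anns = {rec.id: annotate_sequence(rec).ef_hands for rec in bundle.leaves}
    ref = "nox5_1"
    assert len(anns[ref]) == 4
    return map_ef_hand_homology(bundle.alignment, anns, ref)


class TestEFHandHomology:

    def test_reference_maps_to_itself(self, mapped):
        assert mapped["nox5_1"] == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_rboh_ef_hands_align_with_reference_3_and_4(self, mapped):
        assert mapped["rboh_1"] == {1: 3, 2: 4}

    def test_duox_ef_hands_align_with_reference_2_and_3(self, mapped):
        assert mapped["duox_1"] == {1: 2, 2: 3}

    def test_reference_without_four_ef_hands_errors(self):
        aln = Alignment(ids=["a"], rows=["MKV"])
        with pytest.raises(ValueError):
            map_ef_hand_homology(aln, {"a": []}, "a")
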