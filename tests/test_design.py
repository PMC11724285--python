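"""Sensor construction: substrates, sensing variants, MS2, reporter cassette."""

import itertools
import random

import pytest

from hairpinsense import (
    DesignConfig,
    HairpinParams,
    add_ms2,
    assemble_reporter,
    build_inert_sensor,
    build_substrate,
    design_aptamer_sensor,
    design_rna_sensor,
    design_snv_sensor,
)
from hairpinsense.design import (
    ATP_APTAMER,
    NFKB_APTAMER,
    MS2_DEFAULT,
    ReporterFlanks,
    Variant,
    construct_from_record,
    design_record,
    mismatch_count,
)
from hairpinsense.errors import AssemblyError, DesignError, SiteRejectedError
from hairpinsense.seqcore import NucSeq, audit_frame, reverse_complement, translate
from hairpinsense.structure import duplex_metrics


class TestBuildSubstrate:
    def test_model_substrate_16_pairs(self, model_substrate):
        assert len(model_substrate.pairing_map("resting").pairs) == 16

    def test_optimal_substrate_span_23(self, default_substrate):
        m = duplex_metrics(default_substrate.pairing_map("resting"))
        assert m["span"] == 23 and m["n_paired"] == 22

    def test_features_tile_sequence_exactly(self, default_substrate):
        total = sum(e - s for _, s, e in default_substrate.features)
        assert total == len(default_substrate.sequence)

    def test_minimal_substrate(self):
        c = build_substrate(HairpinParams(len_a=1, len_b=1, loop_seq="GAAA"))
        pmap = c.pairing_map("resting")
        assert len(pmap.pairs) == 2 and len(pmap.mismatches) == 1

    def test_central_mismatch_is_a_c(self, default_substrate):
        seq = default_substrate.sequence
        ((i, j),) = default_substrate.pairing_map("resting").mismatches
        assert {seq[i], seq[j]} == {"A", "C"}
        assert j == default_substrate.edit_index

    def test_short_loop_rejected(self):
        with pytest.raises(DesignError):
            HairpinParams(loop_seq="GA")

    def test_randomized_sweep_designates_one_editable_a(self):
        rng = random.Random(21)
        for _ in range(15):
            params = HairpinParams(
                len_a=rng.randint(1, 25), len_b=rng.randint(1, 25), seed=rng.randint(0, 999)
            )
            c = build_substrate(params)
            assert c.sequence[c.edit_index] == "A"
            opp = [i for (i, j) in c.resting.mismatches if j == c.edit_index]
            assert len(opp) == 1 and c.sequence[opp[0]] == "C"

    def test_seed_determinism(self):
        a = build_substrate(HairpinParams(seed=3))
        b = build_substrate(HairpinParams(seed=3))
        assert a.sequence == b.sequence and a.resting == b.resting


class TestInertSensor:
    def test_arm_length_preserved(self):
        arm = NucSeq.rna("GCU" * 13)
        c = build_inert_sensor(HairpinParams(), arm)
        assert c.feature_length("sensing_arm") == 39

    def test_empty_arm_rejected(self):
        with pytest.raises(DesignError):
            build_inert_sensor(HairpinParams(), NucSeq.rna(""))

    def test_resting_pairs_are_b_helix_plus_closures(self):
        # independent enumeration: b-side helix (len_b incl. U:A) + G:C closure
        c = build_inert_sensor(HairpinParams(len_b=12), NucSeq.rna("GCU" * 13))
        pmap = c.pairing_map("resting")
        assert len(pmap.pairs) == 13 and len(pmap.mismatches) == 1
        arm = c.feature("sensing_arm")
        assert all(not (arm[0] <= i < arm[1] or arm[0] <= j < arm[1]) for i, j in pmap.pairs)
        assert c.meta["arm_state"] == "unpaired-awaiting-target"


class TestRnaSensor:
    def test_arm_is_exact_reverse_complement(self, rna_sensor, planted_transcript):
        transcript, manifest = planted_transcript
        s = manifest["clean_site"]
        window = NucSeq.rna(transcript.residues[s : s + 39])
        arm_span = rna_sensor.feature("sensing_arm")
        assert rna_sensor.sequence[slice(*arm_span)] == reverse_complement(window).residues

    def test_active_map_mismatch_free_outside_center(self, rna_sensor):
        window = NucSeq.rna(rna_sensor.meta["target_window"])
        assert mismatch_count(rna_sensor, window) == 1

    def test_stop_containing_window_rejected(self):
        # window built as revcomp of a UAA-leading arm, so the sensor arm
        # would read a stop in frame
        window = reverse_complement(NucSeq.rna("UAAGCGCGC")).residues
        target = NucSeq.rna("GCC" * 20 + window + "G" + "GCC" * 20)
        with pytest.raises(SiteRejectedError, match="stop"):
            design_rna_sensor(target, 60, DesignConfig(arm_length=9, force_site=True))

    def test_short_arm_config(self, planted_transcript):
        transcript, manifest = planted_transcript
        s = manifest["clean_site"]
        cfg = DesignConfig(arm_length=9)
        sensor = design_rna_sensor(transcript, s + 30, cfg)
        assert sensor.feature_length("sensing_arm") == 9

    def test_bad_junction_rejected_unless_forced(self):
        target = NucSeq.rna("CCG" * 30)  # position 39 holds C, not a pairable G
        with pytest.raises(SiteRejectedError, match="junction"):
            design_rna_sensor(target, 0, DesignConfig(arm_length=39))
        sensor = design_rna_sensor(target, 0, DesignConfig(arm_length=39, force_site=True))
        assert sensor.mode == "rna_sensor"


def _snv_fixture(ref: str) -> tuple[NucSeq, int]:
    """GC backbone (no stop codons possible in the arm) with the variant at
    position 50 and a junction G at 51."""
    backbone = ("GC" * 60)[:100]
    pos = 50
    seq = backbone[:pos] + ref + "G" + backbone[pos + 2 :]
    return NucSeq.rna(seq), pos


class TestSnvSensor:
    @pytest.mark.parametrize("ref,alt", list(itertools.permutations("ACGU", 2)))
    def test_discrimination_all_12_substitutions(self, ref, alt):
        target, pos = _snv_fixture(ref)
        sensor = design_snv_sensor(target, Variant(pos, ref, alt))
        assert mismatch_count(sensor, NucSeq.rna(sensor.meta["mut_window"])) == 1
        assert mismatch_count(sensor, NucSeq.rna(sensor.meta["wt_window"])) == 2

    def test_discriminator_adjacent_to_uag_g(self):
        target, pos = _snv_fixture("A")
        sensor = design_snv_sensor(target, Variant(pos, "A", "U"))
        uag = sensor.feature("triplet_sensor")
        arm = sensor.feature("sensing_arm")
        assert arm[0] == uag[1]  # first arm base abuts the G of UAG
        assert sensor.meta["discriminator"] == "A"  # complement of the U allele

    def test_c_to_g_variant_places_c_discriminator(self):
        target, pos = _snv_fixture("C")
        sensor = design_snv_sensor(target, Variant(pos, "C", "G"))
        assert sensor.meta["discriminator"] == "C"
        assert mismatch_count(sensor, NucSeq.rna(sensor.meta["mut_window"])) == 1

    def test_identity_variant_rejected(self):
        target, pos = _snv_fixture("A")
        with pytest.raises(DesignError):
            design_snv_sensor(target, Variant(pos, "A", "A"))

    def test_edge_variant_rejected(self):
        target, _ = _snv_fixture("A")
        with pytest.raises(DesignError):
            design_snv_sensor(target, Variant(5, target[5], "U"))


class TestAptamerSensor:
    def test_atp_sensor_feature_lengths(self):
        c = design_aptamer_sensor(ATP_APTAMER)
        assert c.feature_length("aptamer") == 40
        assert c.feature_length("blocker") == 18

    def test_nfkb_extended_stem(self):
        c = design_aptamer_sensor(NFKB_APTAMER, params=HairpinParams(len_a=25, len_b=12))
        assert c.feature_length("aptamer") == 29
        m = duplex_metrics(c.pairing_map("resting"))
        assert m["n_paired"] == 37  # 25 bp a-side + 12 bp b-side

    def test_search_is_deterministic(self):
        a = design_aptamer_sensor(ATP_APTAMER)
        b = design_aptamer_sensor(ATP_APTAMER)
        assert a.sequence == b.sequence and a.meta["spacer_len"] == b.meta["spacer_len"]


class TestAddMs2:
    def test_coordinates_shift(self, default_substrate):
        c = add_ms2(default_substrate)
        shift = len(MS2_DEFAULT) + 3
        assert c.feature("ms2") == (0, len(MS2_DEFAULT))
        assert c.edit_index == default_substrate.edit_index + shift
        assert duplex_metrics(c.pairing_map("resting"))["n_paired"] == 22

    def test_double_addition_rejected(self, default_substrate):
        with pytest.raises(DesignError):
            add_ms2(add_ms2(default_substrate))

    def test_ms2_cassette_frame_clean(self, default_substrate):
        cassette = assemble_reporter(add_ms2(default_substrate))
        audit = audit_frame(cassette.full_sequence, 0)
        assert audit.stop_positions[0] == cassette.edit_index - 1


class TestAssembleReporter:
    def test_translation_stops_exactly_at_sensor_uag(self, default_substrate):
        cassette = assemble_reporter(default_substrate)
        audit = audit_frame(cassette.full_sequence, 0)
        gfp = cassette.element("gfp")
        assert audit.stop_positions == (cassette.edit_index - 1, gfp[1] - 3)
        assert cassette.full_sequence.residues.startswith("AUG")

    def test_edit_reads_through_as_tryptophan(self, default_substrate):
        cassette = assemble_reporter(default_substrate)
        before = translate(cassette.full_sequence, 0)
        after = translate(cassette.edited_sequence(), 0)
        assert before.stopped and after.stopped  # GFP terminator still stops
        assert len(after.peptide) > len(before.peptide)
        assert after.peptide[(cassette.edit_index - 1) // 3] == "W"

    def test_planted_extra_stop_fails_assembly(self, default_substrate):
        # corrupt a flank so an extra in-frame UGA precedes the sensor
        flanks = ReporterFlanks.default()
        bad_bfp = flanks.bfp[:30] + "UGA" + flanks.bfp[33:]
        bad = ReporterFlanks(bfp=bad_bfp, p2a=flanks.p2a, linker=flanks.linker, gfp=flanks.gfp)
        with pytest.raises(AssemblyError):
            assemble_reporter(default_substrate, bad)

    def test_insert_keeps_uag_codon_aligned(self, rna_sensor):
        cassette = assemble_reporter(rna_sensor)
        assert (cassette.edit_index - 1) % 3 == 0
        insert = cassette.element("insert")
        assert cassette.full_sequence[slice(*insert)] == rna_sensor.sequence.residues


class TestSerialisation:
    def test_record_roundtrip(self, rna_sensor):
        rec = design_record(rna_sensor, DesignConfig())
        back = construct_from_record(rec)
        assert back.sequence == rna_sensor.sequence
        assert back.pairing_map("active") == rna_sensor.pairing_map("active")
        assert back.edit_index == rna_sensor.edit_index
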