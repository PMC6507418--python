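"""Simulator: each molecular step and their composition, against known truth."""

import numpy as np
import pytest

from coligoseq import (
    EndProfile,
    LibraryPrepConfig,
    simulate_coligo_library,
    simulate_lbprimer_library,
    simulate_protocol_comparison,
    transcribe,
    uniform_bias_model,
    write_fastq,
)
from coligoseq.simulate import (
    ADAPTER3_CORE,
    circularize_relinearize,
    generate_reads,
    ligate_adapter3,
    reverse_transcribe,
    sample_transcripts,
)


def stop_for_length(start: int, length: int, template_length: int) -> int:
    """Stop position giving a monomer of ``length`` from ``start``."""
    return (start - length) % template_length + 1


class TestTranscription:
    def test_transcript_is_complement_of_descending_template_walk(self, dcr3):
        tr = transcribe(dcr3, start=30, stop=stop_for_length(30, 65, 82))
        assert len(tr) == 65
        # first base pairs with template position 30, last with the stop
        comp = {"A": "U", "C": "G", "G": "C", "T": "A"}
        assert tr.rna_sequence[0] == comp[dcr3.base_at(30)]
        assert tr.rna_sequence[-1] == comp[dcr3.base_at(tr.stop_pos)]
        assert tr.five_prime == "triphosphate"

    def test_multimer_length_adds_whole_laps(self, dcr3):
        stop = stop_for_length(30, 65, 82)
        assert len(transcribe(dcr3, 30, stop, laps=2)) == 65 + 82
        assert len(transcribe(dcr3, 30, stop, laps=3)) == 65 + 164

    def test_degenerate_profile_yields_identical_transcripts(self, dcr3):
        profile = EndProfile({30: 1.0}, {48: 1.0})
        rng = np.random.default_rng(0)
        out = sample_transcripts(dcr3, profile, 100, {1: 1.0}, rng)
        assert len({t.rna_sequence for t in out}) == 1

    def test_monomer_lengths_span_the_designed_range(self, dcr3, dcr3_profile):
        rng = np.random.default_rng(1)
        out = sample_transcripts(dcr3, dcr3_profile, 2000, {1: 1.0}, rng)
        assert all(60 <= len(t) <= 71 for t in out)

    def test_start_frequencies_recovered_at_scale(self, dcr3):
        profile = EndProfile({30: 0.9, 25: 0.1}, {48: 1.0})
        rng = np.random.default_rng(2)
        out = sample_transcripts(dcr3, profile, 50_000, {1: 1.0}, rng)
        freq = sum(t.start_pos == 30 for t in out) / len(out)
        assert freq == pytest.approx(0.9, abs=0.01)

    def test_empty_profile_is_an_error(self, dcr3):
        with pytest.raises(ValueError):
            EndProfile({}, {48: 1.0}).validate(dcr3)


class TestAdapterLigation:
    def test_full_efficiency_appends_22nt_adapter(self, dcr3, catalog,
                                                  clean_config):
        tr = transcribe(dcr3, 30, stop_for_length(30, 65, 82))
        rng = np.random.default_rng(0)
        out = ligate_adapter3(tr, catalog.spec("Adapter3"), clean_config, rng)
        assert out.status == "ligated"
        assert len(out.sense_sequence) == 65 + 22
        assert out.sense_sequence.endswith("C" + ADAPTER3_CORE)

    def test_zero_efficiency_leaves_all_unligated(self, dcr3, catalog):
        cfg = LibraryPrepConfig(seed=1, adapter3_ligation_efficiency=0.0)
        tr = transcribe(dcr3, 30, 48)
        rng = np.random.default_rng(0)
        outs = [ligate_adapter3(tr, catalog.spec("Adapter3"), cfg, rng)
                for _ in range(50)]
        assert all(o.status == "unligated" for o in outs)

    def test_multimer_side_reaction_rate_is_absolute(self, dcr3, catalog):
        cfg = LibraryPrepConfig(
            seed=1, protocol="standard_two_adapter",
            side_reaction_rates={"multimer": 0.2},
        )
        tr = transcribe(dcr3, 30, 48, five_prime="monophosphate")
        rng = np.random.default_rng(3)
        outs = [ligate_adapter3(tr, catalog.spec("Adapter3"), cfg, rng)
                for _ in range(10_000)]
        frac = sum(o.status == "multimer" for o in outs) / len(outs)
        assert frac == pytest.approx(0.2, abs=0.01)
        dimer = next(o for o in outs if o.status == "multimer")
        assert len(dimer.sense_sequence) == 2 * 65 + 22

    def test_unblocked_adapter_is_a_configuration_error(self, dcr3, catalog,
                                                        clean_config):
        tr = transcribe(dcr3, 30, 48)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="block"):
            ligate_adapter3(tr, catalog.spec("Adapter2"), clean_config, rng)

    def test_side_reactions_require_the_atp_protocol(self):
        with pytest.raises(ValueError):
            LibraryPrepConfig(seed=1, protocol="preadenylylated_mirna",
                              side_reaction_rates={"self_circle": 0.1})


class TestReverseTranscription:
    def test_rtprimer2_geometry(self, dcr3, catalog, clean_config):
        tr = transcribe(dcr3, 30, stop_for_length(30, 65, 82))
        rng = np.random.default_rng(0)
        chimera = ligate_adapter3(
            tr, catalog.spec("Adapter3"), clean_config, rng).sense_sequence
        cdna, ribo = reverse_transcribe(chimera, catalog.spec("RTprimer2"))
        assert len(cdna) == 48 + 65 == 113
        assert ribo == 26

    def test_rtprimer1_covers_entire_17nt_adapter(self, coligo122, catalog,
                                                  clean_config):
        tr = transcribe(coligo122, 10, stop_for_length(10, 83, 89))
        rng = np.random.default_rng(0)
        chimera = ligate_adapter3(
            tr, catalog.spec("Adapter1"), clean_config, rng).sense_sequence
        cdna, ribo = reverse_transcribe(chimera, catalog.spec("RTprimer1"))
        assert len(cdna) == 43 + 83 == 126
        assert ribo == 21

    def test_degenerate_zero_length_transcript(self, catalog):
        # chimera is the bare adapter: cDNA = primer + complement of the dC
        cdna, _ = reverse_transcribe("C" + ADAPTER3_CORE,
                                     catalog.spec("RTprimer2"))
        assert cdna == catalog.sequence("RTprimer2") + "G"

    def test_non_annealing_primer_models_failed_priming(self, dcr3, catalog,
                                                        clean_config):
        tr = transcribe(dcr3, 30, 48)
        rng = np.random.default_rng(0)
        chimera = ligate_adapter3(
            tr, catalog.spec("Adapter3"), clean_config, rng).sense_sequence
        with pytest.raises(ValueError, match="anneal"):
            reverse_transcribe(chimera, catalog.spec("RTprimer1"))


class TestCircularizeRelinearize:
    def test_rotation_is_forced_by_the_ribo_position(self):
        rng = np.random.default_rng(0)
        status, out = circularize_relinearize("abcRdef", 4, 1.0, rng)
        assert (status, out) == ("relinearized", "defabcR")

    def test_base_conservation(self):
        rng = np.random.default_rng(0)
        _, out = circularize_relinearize("ACGTACGTAC", 3, 1.0, rng)
        assert sorted(out) == sorted("ACGTACGTAC")

    def test_amplifiable_fraction_matches_efficiency(self):
        rng = np.random.default_rng(4)
        n = 10_000
        ok = sum(
            circularize_relinearize("ACGTAC", 3, 0.9, rng)[0] == "relinearized"
            for _ in range(n)
        )
        assert ok / n == pytest.approx(0.9, abs=0.01)

    def test_missing_ribo_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            circularize_relinearize("ACGT", 0, 1.0, rng)


class TestReadGeneration:
    def test_error_free_read_layout(self, dcr3, catalog, clean_config,
                                    dcr3_profile):
        profile = EndProfile({30: 1.0}, {stop_for_length(30, 65, 82): 1.0})
        reads, _, _ = simulate_coligo_library(
            dcr3, profile, {1: 1.0}, 5, clean_config, catalog)
        tr = transcribe(dcr3, 30, stop_for_length(30, 65, 82))
        for r in reads:
            assert len(r.sequence) == len(r.quals) == 110
            assert r.sequence[:65] == tr.dna_sequence
            assert r.sequence[65] == "C"
            assert r.sequence[66:87] == ADAPTER3_CORE

    def test_nontemplated_first_base_classes(self, dcr3, catalog):
        cfg = LibraryPrepConfig(seed=9, circularization_efficiency=1.0,
                                nontemplated_first_base_rate=0.25)
        profile = EndProfile({30: 1.0}, {stop_for_length(30, 65, 82): 1.0})
        reads, _, _ = simulate_coligo_library(
            dcr3, profile, {1: 1.0}, 4000, cfg, catalog)
        templated = transcribe(dcr3, 30, 1).dna_sequence[0]
        first = [r.sequence[0] for r in reads]
        frac_other = sum(b != templated for b in first) / len(first)
        assert frac_other == pytest.approx(0.25, abs=0.03)
        assert set(first) == set("ACGT")  # majority class plus three minorities

    def test_empty_input_yields_empty_fastq(self, clean_config):
        rng = np.random.default_rng(0)
        assert generate_reads([], clean_config, rng) == []

    def test_too_short_read_length_is_an_error(self, dcr3, catalog):
        cfg = LibraryPrepConfig(seed=1, read_length=20)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="read_length"):
            generate_reads([("ACGT" * 20, "id")], cfg, rng)

    def test_fixed_seed_gives_byte_identical_fastq(self, dcr3, catalog,
                                                   dcr3_profile, tmp_path):
        files = []
        for run in ("a", "b"):
            cfg = LibraryPrepConfig(seed=42, substitution_error_rate=0.01)
            reads, _, _ = simulate_coligo_library(
                dcr3, dcr3_profile, {1: 1.0}, 300, cfg, catalog)
            path = tmp_path / f"{run}.fastq"
            write_fastq(reads, path)
            files.append(path.read_bytes())
        assert files[0] == files[1]


class TestLBPrimerLibrary:
    def test_read_window_encodes_blocks_in_revcomp(self, catalog, clean_config):
        from coligoseq.oligo import revcomp

        reads, truth = simulate_lbprimer_library(
            50, None, uniform_bias_model(), clean_config, catalog)
        for r, (n7a, n7b, _) in zip(reads, truth):
            assert r.sequence[:7] == revcomp(n7a)
            assert r.sequence[7:14] == revcomp(n7b)
            assert r.sequence[14:35] == ADAPTER3_CORE

    def test_forbidden_junction_never_appears(self, catalog, clean_config):
        model = uniform_bias_model()
        model[("G", "G")] = 0.0
        _, truth = simulate_lbprimer_library(
            5000, None, model, clean_config, catalog)
        assert all(j != ("G", "G") for _, _, j in truth)

    def test_all_sixteen_junctions_present_when_unbiased(self, catalog,
                                                         clean_config):
        _, truth = simulate_lbprimer_library(
            20_000, None, uniform_bias_model(), clean_config, catalog)
        assert len({j for _, _, j in truth}) == 16

    def test_all_zero_bias_model_is_an_error(self, catalog, clean_config):
        with pytest.raises(ValueError):
            simulate_lbprimer_library(
                10, None, {(d, a): 0.0 for d in "ACGT" for a in "ACGT"},
                clean_config, catalog)

    def test_forced_position_distribution(self, catalog, clean_config):
        probs = np.full((14, 4), 0.25)
        probs[0] = [1.0, 0.0, 0.0, 0.0]  # N7a position 1 always A
        _, truth = simulate_lbprimer_library(
            500, probs, uniform_bias_model(), clean_config, catalog)
        assert all(n7a[0] == "A" for n7a, _, _ in truth)


class TestProtocolComparison:
    def test_inefficient_species_vanishes_only_in_standard_mode(self):
        table = simulate_protocol_comparison(
            {"hairpin": 0.5, "open": 0.5},
            {"hairpin": 0.05, "open": 1.0},
            n=50_000, seed=6,
        ).set_index("species")
        # closed form: 1.0 / (1.0 + 0.05) ~ 0.952
        assert table.loc["open", "standard_fraction"] == pytest.approx(
            0.952, abs=0.012)
        assert table.loc["open", "coligo_fraction"] == pytest.approx(
            0.5, abs=0.012)

    def test_equal_efficiencies_preserve_input_proportions(self):
        table = simulate_protocol_comparison(
            {"a": 0.3, "b": 0.7}, {"a": 0.5, "b": 0.5}, n=30_000, seed=7,
        ).set_index("species")
        assert table.loc["a", "standard_fraction"] == pytest.approx(0.3, abs=0.02)
        assert table.loc["a", "coligo_fraction"] == pytest.approx(0.3, abs=0.02)

    def test_single_species_is_total_in_both(self):
        table = simulate_protocol_comparison(
            {"only": 1.0}, {"only": 0.4}, n=1000, seed=8)
        assert table["standard_fraction"].iloc[0] == 1.0
        assert table["coligo_fraction"].iloc[0] == 1.0


class TestBaseConservation:
    def test_transcript_bases_survive_every_step(self, dcr3, catalog,
                                                 clean_config):
        """No transcript base is created or destroyed except by documented
        additions (adapter, primer) and the read-length truncation."""
        tr = transcribe(dcr3, 30, stop_for_length(30, 65, 82))
        rng = np.random.default_rng(0)
        chimera = ligate_adapter3(
            tr, catalog.spec("Adapter3"), clean_config, rng).sense_sequence
        assert len(chimera) == len(tr) + 22
        cdna, ribo = reverse_transcribe(chimera, catalog.spec("RTprimer2"))
        assert len(cdna) == len(tr) + 48
        _, relin = circularize_relinearize(cdna, ribo, 1.0, rng)
        assert len(relin) == len(cdna)
        assert sorted(relin) == sorted(cdna)
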