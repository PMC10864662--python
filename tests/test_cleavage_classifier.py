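import numpy as np
import pytest

from cleaveqc.cleavage_classifier import (
    NONTRYPTIC,
    PROTEIN_TERMINUS,
    TRYPTIC,
    classify_observations,
    classify_peptide,
    classify_shared_peptide,
    correlate_activity,
    specificity_profile,
    summarize_all_samples,
    summarize_sample,
)
from cleaveqc.io_formats import Modification, PeptideObservation, RunConfig


def obs(peptide, pre, post, start=10, sample="s1", intensity=100.0, mods=(), acc="P1"):
    return PeptideObservation(
        sample_id=sample, peptide=peptide, protein_accession=acc,
        start=start, end=start + len(peptide) - 1,
        preceding_residue=pre, following_residue=post,
        modifications=list(mods), intensity=intensity,
    )


class TestClassifyPeptide:
    def test_fully_tryptic(self, run_config):
        c = classify_peptide(obs("AVR", "K", "G"), run_config)
        assert c.category == "fully_tryptic"
        assert c.n_call.status == TRYPTIC and c.c_call.status == TRYPTIC

    def test_nterm_nontryptic_elastase_class(self, run_config):
        c = classify_peptide(obs("GAGK", "V", "L"), run_config)
        assert c.n_call.status == NONTRYPTIC
        assert c.n_call.protease_class == "ELANE_PRTN3"
        assert c.category == NONTRYPTIC and c.n_nontryptic_events == 1

    def test_leucine_goes_to_ctsg_not_elastase(self, run_config):
        c = classify_peptide(obs("GAGL", "K", "S"), run_config)
        assert c.c_call.status == NONTRYPTIC
        assert c.c_call.protease_class == "CTSG"

    def test_unclassified_p1_is_other(self, run_config):
        c = classify_peptide(obs("GAGG", "K", "S"), run_config)
        assert c.c_call.protease_class == "other"

    def test_protein_terminus_sentinels(self, run_config):
        c = classify_peptide(obs("GAG", "-", "-", start=1), run_config)
        assert c.n_call.status == PROTEIN_TERMINUS
        assert c.c_call.status == PROTEIN_TERMINUS
        assert c.category == "fully_tryptic"

    def test_initiator_met_removal_is_protein_terminus(self, run_config):
        c = classify_peptide(obs("GAGK", "M", "L", start=2), run_config)
        assert c.n_call.status == PROTEIN_TERMINUS
        c2 = classify_peptide(obs("GAGK", "V", "L", start=3), run_config)
        assert c2.n_call.status == NONTRYPTIC

    def test_nterm_acetylation_forces_protein_terminus(self, run_config):
        mods = [Modification(1, "Acetyl (Protein N-term)", 42.0106)]
        c = classify_peptide(obs("GAGK", "V", "L", mods=mods), run_config)
        assert c.n_call.status == PROTEIN_TERMINUS

    def test_both_termini_nontryptic_two_events(self, run_config):
        c = classify_peptide(obs("GAGA", "A", "S"), run_config)
        assert c.n_nontryptic_events == 2

    def test_strict_mode_requires_both_termini(self):
        strict = RunConfig(strict_nontryptic=True)
        semi = obs("GAGK", "V", "L")
        assert classify_peptide(semi, strict).category == "fully_tryptic"
        full = obs("GAGA", "A", "S")
        assert classify_peptide(full, strict).category == NONTRYPTIC

    def test_unmapped_observation_error(self, run_config):
        with pytest.raises(ValueError):
            classify_peptide(obs("AVR", "", "G"), run_config)

    def test_order_invariance(self, run_config):
        items = [obs("AVR", "K", "G"), obs("GAGA", "A", "S"), obs("GAGL", "K", "S")]
        fwd = [classify_peptide(o, run_config).category for o in items]
        rev = [classify_peptide(o, run_config).category for o in reversed(items)]
        assert fwd == rev[::-1]


class TestSharedPeptides:
    def test_most_tryptic_interpretation_wins(self, run_config):
        o = obs("GAGK", "V", "L")
        occurrences = [("P1", 10, 13, "V", "L"), ("P2", 4, 7, "K", "L")]
        c = classify_shared_peptide(o, occurrences, run_config)
        assert c.n_call.status == TRYPTIC
        assert c.observation.protein_accession == "P2"

    def test_no_occurrence_error(self, run_config):
        with pytest.raises(ValueError):
            classify_shared_peptide(obs("GAGK", "V", "L"), [], run_config)


class TestSummarize:
    def test_all_tryptic_zero_pct(self, run_config):
        cls = classify_observations([obs("AVR", "K", "G"), obs("MK", "-", "A", start=1)], run_config)
        s = summarize_sample(cls, "s1", run_config)
        assert s.pct_nontryptic_intensity == 0.0
        assert s.n_nontryptic_peptides == 0

    def test_pct_arithmetic(self, run_config):
        cls = classify_observations(
            [obs("AVR", "K", "G", intensity=75.0), obs("GAGA", "A", "S", intensity=25.0)],
            run_config,
        )
        s = summarize_sample(cls, "s1", run_config)
        assert s.pct_nontryptic_intensity == pytest.approx(25.0)

    def test_intensity_conservation_exact(self, run_config):
        rng = np.random.default_rng(0)
        items = []
        for i in range(200):
            pre = rng.choice(list("KRAVLG"))
            last = rng.choice(list("KRAVLG"))
            items.append(obs("GAG" + last, pre, "S", intensity=float(rng.uniform(1, 100))))
        cls = classify_observations(items, run_config)
        s = summarize_sample(cls, "s1", run_config)
        tryptic_intensity = sum(
            c.observation.intensity for c in cls if c.category == "fully_tryptic"
        )
        assert s.nontryptic_intensity + tryptic_intensity == pytest.approx(s.total_intensity, abs=1e-9)

    def test_double_nontryptic_counts_two_events_one_intensity(self, run_config):
        cls = classify_observations([obs("GAGA", "A", "S", intensity=10.0)], run_config)
        s = summarize_sample(cls, "s1", run_config)
        assert s.nontryptic_intensity == 10.0
        assert sum(s.p1_frequency.values()) == 2

    def test_proteins_ge2_tryptic(self, run_config):
        items = [
            obs("AVR", "K", "G", acc="PA"),
            obs("GGK", "R", "L", acc="PA", start=20),
            obs("LLK", "K", "S", acc="PB"),
        ]
        s = summarize_sample(classify_observations(items, run_config), "s1", run_config)
        assert s.n_proteins_ge2_tryptic == 1

    def test_zero_total_intensity_error(self, run_config):
        with pytest.raises(ValueError):
            summarize_sample([], "s1", run_config)


class TestSpecificityProfile:
    def test_all_valine_events_pure_elastase(self, run_config):
        cls = classify_observations([obs("GAGV", "K", "S"), obs("GAGK", "V", "L")], run_config)
        prof = specificity_profile([summarize_sample(cls, "s1", run_config)])
        row = prof[(prof["kind"] == "class") & (prof["key"] == "ELANE_PRTN3")]
        assert row["fraction_by_count"].iloc[0] == pytest.approx(1.0)

    def test_even_split_between_classes(self, run_config):
        cls = classify_observations([obs("GAGA", "K", "S"), obs("GAGL", "K", "S")], run_config)
        prof = specificity_profile([summarize_sample(cls, "s1", run_config)])
        fr = prof[prof["kind"] == "class"].set_index("key")["fraction_by_count"]
        assert fr["ELANE_PRTN3"] == pytest.approx(0.5)
        assert fr["CTSG"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, run_config):
        rng = np.random.default_rng(3)
        items = [
            obs("GAG" + rng.choice(list("AVLWFG")), rng.choice(list("AVLK")), "S",
                intensity=float(rng.uniform(1, 10)))
            for _ in range(50)
        ]
        prof = specificity_profile(
            [summarize_sample(classify_observations(items, run_config), "s1", run_config)]
        )
        cls_rows = prof[prof["kind"] == "class"]
        assert cls_rows["fraction_by_count"].sum() == pytest.approx(1.0)
        assert cls_rows["fraction_by_intensity"].sum() == pytest.approx(1.0)
        p1_rows = prof[prof["kind"] == "p1_residue"]
        assert p1_rows["fraction_by_count"].sum() == pytest.approx(1.0)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            specificity_profile([])


class TestCorrelateActivity:
    def _summaries(self, run_config, values):
        out = []
        for i, v in enumerate(values):
            items = [
                obs("AVR", "K", "G", sample=f"s{i}", intensity=100.0),
                obs("GAGA", "A", "S", sample=f"s{i}", intensity=v),
            ]
            out.append(
                summarize_sample(classify_observations(items, run_config), f"s{i}", run_config)
            )
        return out

    def test_perfect_linear_relation(self, run_config):
        summaries = self._summaries(run_config, [10.0, 20.0, 30.0, 40.0])
        abundance = {f"s{i}": 2 * (i + 1) + 1 for i in range(4)}
        res = correlate_activity(abundance, summaries)
        assert res.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, run_config):
        summaries = self._summaries(run_config, [40.0, 30.0, 20.0, 10.0])
        abundance = {f"s{i}": float(i) for i in range(4)}
        res = correlate_activity(abundance, summaries)
        assert res.r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self, run_config):
        summaries = self._summaries(run_config, [10.0, 10.0, 10.0])
        res = correlate_activity({f"s{i}": 1.0 for i in range(3)}, summaries)
        assert not res.defined and np.isnan(res.r)

    def test_too_few_samples_error(self, run_config):
        summaries = self._summaries(run_config, [10.0, 20.0])
        with pytest.raises(ValueError):
            correlate_activity({"s0": 1.0, "s1": 2.0}, summaries)
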