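"""Rule-based agent behavior: extraction, summarization, optimization."""

import pytest

from conftest import is_grounded, normalized
from rescue_rank.agents import (
    AgentRole,
    AgentTask,
    RulesBackend,
    extract_purification_text,
    optimize_protocol,
    run_task,
    split_sentences,
    summarize_protocol,
)
from rescue_rank.errors import AgentFailureError, EmptyProtocolError
from rescue_rank.fixtures import FixtureSpec, make_articles
from rescue_rank.litmine import MethodsText
from rescue_rank.protocol_model import ProtocolStep, ProtocolTable

CLONING = (
    "The gene was amplified by PCR and ligated into pET28a. "
    "Transformants were selected on kanamycin plates."
)
PURIFICATION = (
    "Cells were lysed in 20 mM HEPES, 300 mM NaCl, pH 7.4. "
    "The lysate was loaded onto a HisTrap column and washed with 30 mM Imidazole. "
    "The protein was eluted with 500 mM Imidazole."
)


class TestExtractor:
    def test_recovers_only_the_purification_paragraph(self):
        methods = MethodsText(
            text=f"{CLONING} {PURIFICATION}", matched_titles=["Methods"]
        )
        assert extract_purification_text(methods) == PURIFICATION

    def test_no_purification_vocabulary_raises(self):
        methods = MethodsText(text=CLONING, matched_titles=["Methods"])
        with pytest.raises(EmptyProtocolError):
            extract_purification_text(methods)

    def test_output_is_sentence_subset_of_input(self):
        methods = MethodsText(
            text=f"{CLONING} {PURIFICATION}", matched_titles=["Methods"]
        )
        out = extract_purification_text(methods)
        in_sentences = set(split_sentences(methods.text))
        assert set(split_sentences(out)) <= in_sentences


class TestSummarizer:
    def test_lysis_sentence_yields_ph_and_salt(self):
        text = (
            "Cells were lysed in lysis buffer containing 20 mM HEPES, 300 mM NaCl, "
            "5% glycerol, 30 mM Imidazole, 0.5% CHAPS, 10 mM MgCl2, "
            "3 mM β-mercaptoethanol, 1.3 mg/ml protease inhibitor cocktail and "
            "0.05 mg/ml lysozyme, pH 7.4."
        )
        table = summarize_protocol(text)
        assert len(table.steps) == 1
        step = table.steps[0]
        assert step.ph == 7.4
        assert step.salt_type == "NaCl"
        assert "protease inhibitor cocktail" in (step.buffer_supplement or "")
        assert "lysozyme" in (step.buffer_supplement or "")

    def test_elution_sentence_fields(self):
        table = summarize_protocol(
            "The protein was eluted with 25 mM HEPES, 300 mM NaCl, 500 mM Imidazole, pH 7.0."
        )
        step = table.steps[0]
        assert step.ph == 7.0
        assert step.salt_type == "NaCl"
        assert "500 mM Imidazole" in step.buffer_composition

    def test_unrecognizable_text_gives_single_bare_step(self, caplog):
        with caplog.at_level("WARNING"):
            table = summarize_protocol("Nothing of interest happened here.")
        assert len(table.steps) == 1
        step = table.steps[0]
        assert step.ph is None and step.salt_type is None
        assert step.buffer_supplement is None and step.buffer_name is None
        assert any("segmented" in r.message for r in caplog.records)

    def test_multi_step_text_preserves_step_order(self):
        table = summarize_protocol(PURIFICATION)
        labels = [s.purification_step.lower() for s in table.steps]
        assert labels == ["lysed", "loaded", "eluted"]

    def test_every_value_grounded_in_input(self):
        table = summarize_protocol(PURIFICATION)
        for step in table.steps:
            if step.buffer_composition:
                assert is_grounded(step.buffer_composition, PURIFICATION)
            if step.salt_type:
                assert is_grounded(step.salt_type, PURIFICATION)
            if step.ph is not None:
                assert f"ph {step.ph:g}" in normalized(PURIFICATION).lower()


class TestOptimizer:
    def test_identical_inputs_empty_report(self):
        table = summarize_protocol(PURIFICATION)
        report = optimize_protocol(table, [table])
        assert report.differences == []

    def test_planted_imidazole_difference_gets_recommendation(self):
        failed = summarize_protocol(
            "The protein was eluted with 25 mM HEPES, 300 mM NaCl, 250 mM Imidazole, pH 7.0."
        )
        success = summarize_protocol(
            "The protein was eluted with 25 mM HEPES, 300 mM NaCl, 500 mM Imidazole, pH 7.0."
        )
        report = optimize_protocol(failed, [success])
        conc = [d for d in report.differences if d.parameter == "concentration:imidazole"]
        assert len(conc) == 1
        assert "imidazole" in conc[0].recommendation.lower()
        assert conc[0].confidence == "low"  # single supporting protocol

    def test_confidence_scales_with_supporting_protocols(self):
        failed = summarize_protocol(
            "The protein was eluted with 250 mM Imidazole, pH 7.0."
        )
        success = summarize_protocol(
            "The protein was eluted with 500 mM Imidazole, pH 7.0."
        )
        for n, expected in ((2, "medium"), (3, "high")):
            report = optimize_protocol(failed, [success] * n)
            conc = [
                d for d in report.differences if d.parameter == "concentration:imidazole"
            ][0]
            assert conc.confidence == expected

    def test_transmembrane_annotation_drives_detergent_recommendation(self):
        table = summarize_protocol(PURIFICATION)
        report = optimize_protocol(table, [table], annotations=["transmembrane:35-57"])
        ann = [d for d in report.differences if d.parameter == "annotation:transmembrane"]
        assert len(ann) == 1
        assert "detergent" in ann[0].recommendation.lower()
        assert ann[0].confidence == "low"
        assert report.annotations_considered == ["transmembrane:35-57"]

    def test_empty_successes_gives_annotation_only_low_confidence(self):
        table = summarize_protocol(PURIFICATION)
        report = optimize_protocol(table, [], annotations=["signal_peptide:1-22"])
        assert all(d.parameter.startswith("annotation:") for d in report.differences)
        assert all(d.confidence == "low" for d in report.differences)

    def test_revised_protocol_applies_consensus(self):
        failed = summarize_protocol(
            "The protein was eluted with 25 mM HEPES, 300 mM NaCl, 250 mM Imidazole, pH 7.0."
        )
        success = summarize_protocol(
            "The protein was eluted with 25 mM HEPES, 300 mM NaCl, 500 mM Imidazole, pH 7.0."
        )
        report = optimize_protocol(failed, [success])
        assert any(
            "500 mM Imidazole" in s.buffer_composition for s in report.revised_protocol
        )


class TestSchemaEnforcement:
    class FlakyBackend:
        name = "flaky"
        deterministic = False

        def __init__(self, failures: int):
            self.failures = failures

        def run(self, task):
            if self.failures > 0:
                self.failures -= 1
                return {"not": "a table"}
            return ProtocolTable(steps=[ProtocolStep(purification_step="Lysis")])

    def test_nonconforming_output_retried_then_accepted(self):
        task = AgentTask(role=AgentRole.summarizer, payload="x")
        result = run_task(task, self.FlakyBackend(failures=2), retries=2)
        assert isinstance(result, ProtocolTable)

    def test_persistent_nonconformance_is_agent_failure(self):
        task = AgentTask(role=AgentRole.summarizer, payload="x")
        with pytest.raises(AgentFailureError):
            run_task(task, self.FlakyBackend(failures=5), retries=2)

    def test_rules_backend_is_deterministic(self):
        backend = RulesBackend()
        t1 = summarize_protocol(PURIFICATION, backend=backend)
        t2 = summarize_protocol(PURIFICATION, backend=backend)
        assert t1 == t2


class TestGroundingOverFixtureCorpus:
    def test_extraction_grounded_for_generated_articles(self, tmp_path):
        spec = FixtureSpec(seed=21, n_articles=20)
        _, manifest = make_articles(spec, tmp_path)
        for art in manifest["articles"]:
            text = art["protocol_text"]
            extracted = extract_purification_text(
                MethodsText(text=text, matched_titles=["Methods"])
            )
            assert is_grounded(extracted, text)
            table = summarize_protocol(extracted)
            for step in table.steps:
                if step.buffer_composition:
                    assert is_grounded(step.buffer_composition, text)
                if step.buffer_name:
                    assert is_grounded(step.buffer_name, text)
                if step.salt_type:
                    assert is_grounded(step.salt_type, text)
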