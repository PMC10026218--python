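"""Docking prep: mutation specs, input construction, model dissection, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degronkit.docking import (
    DockingInputSpec,
    apply_mutation,
    build_input,
    build_inputs,
    classify_docked,
    extract_components,
)
from degronkit.errors import ModelLayoutError, SequenceError
from degronkit.structure import Structure
from degronkit.synthetic import (
    STANDARD_AA,
    ToyComplexSpec,
    make_linker_model,
    make_toy_complex,
)


def _receptor_seq(length=390, seed=0, asp_at=126):
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list(STANDARD_AA), size=length)))
    seq[asp_at - 1] = "D"
    return "".join(seq)


class TestApplyMutation:
    def test_point_substitution(self):
        seq = _receptor_seq()
        mutated = apply_mutation(seq, "D126H")
        assert mutated[125] == "H"
        diffs = [i for i, (x, y) in enumerate(zip(seq, mutated)) if x != y]
        assert diffs == [125]

    def test_identity_substitution_is_noop(self):
        seq = _receptor_seq()
        assert apply_mutation(seq, "D126D") == seq

    def test_reference_mismatch_reports_both(self):
        seq = _receptor_seq()
        wrong = "A127H" if seq[126] != "A" else "C127H"
        with pytest.raises(SequenceError, match="expected .* found"):
            apply_mutation(seq, wrong)

    def test_position_out_of_range(self):
        with pytest.raises(SequenceError, match="outside"):
            apply_mutation("ACDEF", "D600H")

    def test_malformed_spec(self):
        with pytest.raises(SequenceError, match="malformed"):
            apply_mutation("ACDEF", "126H")

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_hamming_distance_at_most_one(self, data):
        seq = data.draw(st.text(alphabet=STANDARD_AA, min_size=1, max_size=40))
        pos = data.draw(st.integers(min_value=1, max_value=len(seq)))
        alt = data.draw(st.sampled_from(STANDARD_AA))
        mutated = apply_mutation(seq, f"{seq[pos - 1]}{pos}{alt}")
        hamming = sum(1 for x, y in zip(seq, mutated) if x != y)
        assert hamming == (0 if alt == seq[pos - 1] else 1)


class TestBuildInput:
    def test_default_layout(self):
        """Fragment 1–390 + 30×Gly + LKELR ⇒ 425 residues ending in LKELR."""
        spec = DockingInputSpec(receptor_seq=_receptor_seq())
        seq, fasta = build_input(spec)
        assert len(seq) == 425
        assert seq.endswith("LKELR")
        assert seq[390:420] == "G" * 30
        assert fasta.startswith(">WT ")

    def test_degenerate_linker(self):
        spec = DockingInputSpec(
            receptor_seq="ACDEF", fragment=(1, 5), linker_len=0, peptide="R"
        )
        seq, _ = build_input(spec)
        assert seq == "ACDEFR"

    def test_variant_set_differs_only_at_mutated_position(self):
        receptor = _receptor_seq()
        inputs = build_inputs(receptor, mutations=("D126H", "D126V", "D126A"))
        assert [spec.variant_name() for spec, _, _ in inputs] == ["WT", "D126H", "D126V", "D126A"]
        wt = inputs[0][1]
        for _, seq, _ in inputs[1:]:
            diffs = [i for i, (x, y) in enumerate(zip(wt, seq)) if x != y]
            assert diffs == [125]

    @settings(max_examples=50, derandomize=True)
    @given(data=st.data())
    def test_length_identity(self, data):
        receptor = data.draw(st.text(alphabet=STANDARD_AA, min_size=5, max_size=60))
        first = data.draw(st.integers(min_value=1, max_value=len(receptor)))
        last = data.draw(st.integers(min_value=first, max_value=len(receptor)))
        linker = data.draw(st.integers(min_value=0, max_value=40))
        peptide = data.draw(st.text(alphabet=STANDARD_AA, min_size=1, max_size=8))
        spec = DockingInputSpec(
            receptor_seq=receptor, fragment=(first, last), linker_len=linker, peptide=peptide
        )
        seq, _ = build_input(spec)
        assert len(seq) == (last - first + 1) + linker + len(peptide)


def _model_spec(receptor_len=10, linker_len=30, peptide="LKELR"):
    return DockingInputSpec(
        receptor_seq="A" * receptor_len,
        fragment=(1, receptor_len),
        linker_len=linker_len,
        peptide=peptide,
    )


class TestExtractComponents:
    def test_partitions_synthetic_model(self):
        model = make_linker_model(10, 30, "LKELR", docked=False, seed=4)
        comp = extract_components(model, _model_spec())
        assert (len(comp.receptor), len(comp.linker), len(comp.peptide)) == (10, 30, 5)
        assert all(r.rid.res_name == "GLY" for r in comp.linker.residues)
        assert [r.rid.res_name for r in comp.peptide.residues] == [
            "LEU", "LYS", "GLU", "LEU", "ARG",
        ]
        assert comp.numbering_map[1] == 1 and comp.numbering_map[10] == 10

    @pytest.mark.parametrize("seed", range(20))
    def test_random_specs_recover_boundaries(self, seed):
        rng = np.random.default_rng(seed)
        rec_len = int(rng.integers(3, 25))
        linker_len = int(rng.integers(0, 35))
        pep = "".join(rng.choice(list(STANDARD_AA), size=int(rng.integers(1, 8))))
        model = make_linker_model(rec_len, linker_len, pep, docked=False, seed=seed)
        comp = extract_components(model, _model_spec(rec_len, linker_len, pep))
        assert (len(comp.receptor), len(comp.linker), len(comp.peptide)) == (
            rec_len, linker_len, len(pep),
        )

    def test_non_gly_in_linker_rejected(self):
        model = make_linker_model(10, 30, "LKELR", docked=False, seed=4)
        bad = Structure(id="bad", residues=list(model.residues))
        pos = 10 + 5  # inside the linker
        from dataclasses import replace

        bad.residues[pos] = type(bad.residues[pos])(
            replace(bad.residues[pos].rid, res_name="ALA"), bad.residues[pos].atoms
        )
        with pytest.raises(ModelLayoutError, match="linker"):
            extract_components(bad, _model_spec())

    def test_length_mismatch_reports_expected_and_observed(self):
        model = make_linker_model(9, 30, "LKELR", docked=False, seed=4)
        with pytest.raises(ModelLayoutError, match="expected 10"):
            extract_components(model, _model_spec())


class TestClassifyDocked:
    @pytest.fixture
    def native(self):
        spec = ToyComplexSpec(
            n_receptor=10,
            peptide_len=5,
            planted_pairs=frozenset({(1, 1), (2, 1), (3, 2), (4, 3), (5, 5), (7, 4)}),
            seed=5,
        )
        receptor, peptide, truth = make_toy_complex(spec)
        return truth, [r.rid for r in peptide.residues]

    def test_full_recapitulation_is_docked(self, native):
        truth, pep_rids = native
        planted = frozenset(
            (r.number, next(i + 1 for i, rid in enumerate(pep_rids) if rid == p))
            for r, p in truth.pairs
        )
        model = make_linker_model(10, 30, "LKELR", docked=True, seed=6, contacts=planted)
        comp = extract_components(model, _model_spec())
        verdict, report = classify_docked(comp, truth, native_peptide=pep_rids)
        assert verdict == "docked"
        assert report.fraction == 1.0

    def test_no_contacts_is_undocked(self, native):
        truth, pep_rids = native
        model = make_linker_model(10, 30, "LKELR", docked=False, seed=6)
        comp = extract_components(model, _model_spec())
        verdict, report = classify_docked(comp, truth, native_peptide=pep_rids)
        assert verdict == "undocked"
        assert report.fraction == 0.0

    def test_verdict_invariant_to_linker_coordinates(self, native):
        """Only receptor–peptide geometry matters; the linker is excluded."""
        truth, pep_rids = native
        planted = frozenset({(1, 1), (2, 1), (3, 2), (4, 3)})
        model = make_linker_model(10, 30, "LKELR", docked=True, seed=8, contacts=planted)
        comp = extract_components(model, _model_spec())
        _, base = classify_docked(comp, truth, native_peptide=pep_rids)

        coords = model.all_coords()
        k = 0
        for res in model.residues:
            if res.rid.res_name == "GLY":
                coords[k : k + len(res.atoms)] += np.random.default_rng(1).normal(
                    scale=50.0, size=(len(res.atoms), 3)
                )
            k += len(res.atoms)
        scrambled = model.with_coords(coords)
        comp2 = extract_components(scrambled, _model_spec())
        _, after = classify_docked(comp2, truth, native_peptide=pep_rids)
        assert after.fraction == base.fraction
        assert after.matched == base.matched

    def test_threshold_is_honoured(self, native):
        truth, pep_rids = native
        planted = frozenset({(1, 1), (2, 1), (3, 2)})  # 3 of 6 native pairs
        model = make_linker_model(10, 30, "LKELR", docked=True, seed=9, contacts=planted)
        comp = extract_components(model, _model_spec())
        verdict_lo, report = classify_docked(comp, truth, threshold=0.5, native_peptide=pep_rids)
        verdict_hi, _ = classify_docked(comp, truth, threshold=0.6, native_peptide=pep_rids)
        assert report.fraction == pytest.approx(0.5)
        assert verdict_lo == "docked" and verdict_hi == "undocked"
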