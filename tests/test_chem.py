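"""Molecular core: parsing, assembly, fingerprints, and data curation."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

import linkergen as lg
from linkergen.chem import (
    COUNT_FP_500,
    FingerprintSpec,
    attachment_indices,
    fold_vector,
    mol_from_smiles,
)


class TestParseLinker:
    def test_peg_linker_fields(self):
        linker = lg.parse_linker("*CCOCC*")
        assert linker.n_attachments == 2
        assert linker.path_length == 5

    @pytest.mark.parametrize("smiles", ["*CC", "*C(*)C*", "CCC"])
    def test_wrong_marker_count_rejected(self, smiles):
        with pytest.raises(lg.AttachmentCountError):
            lg.parse_linker(smiles)

    def test_syntax_error_rejected(self):
        with pytest.raises(lg.InvalidSmiles):
            lg.parse_linker("C1CC(")

    def test_single_atom_linker(self):
        assert lg.parse_linker("*C*").path_length == 1

    def test_lenient_valence_at_markers(self):
        # markers stand in for future bonds, so *F* parses as a linker even
        # though F cannot ultimately carry two bonds (assembly rejects it)
        assert lg.parse_linker("*F*").n_attachments == 2

    def test_path_length_matches_graph_shortest_path(self, corpus):
        # independent oracle: networkx shortest path between marker anchors
        for smiles in corpus[:50]:
            mol = mol_from_smiles(smiles, lenient=True)
            g = nx.Graph(
                [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
            )
            m1, m2 = attachment_indices(mol)
            a1 = mol.GetAtomWithIdx(m1).GetNeighbors()[0].GetIdx()
            a2 = mol.GetAtomWithIdx(m2).GetNeighbors()[0].GetIdx()
            expected = nx.shortest_path_length(g, a1, a2) + 1  # bonds -> atoms
            assert lg.parse_linker(smiles).path_length == expected


class TestAssembleProtac:
    def test_chain_concatenation(self):
        assert lg.assemble_protac("*CC*", "C*", "N*") == Chem.CanonSmiles("CCCN")

    def test_symmetric_linker(self):
        assert lg.assemble_protac("*C*", "C*", "C*") == Chem.CanonSmiles("CCC")

    def test_valence_violation_raises(self):
        with pytest.raises(lg.AssemblyError):
            lg.assemble_protac("*F*", "C*", "C*")

    def test_marker_order_poi_first(self):
        # the first marker in reading order bonds the POI ligand
        protac = lg.assemble_protac("*CO*", "N*", "F*")
        assert protac == Chem.CanonSmiles("NCOF")

    def test_assembles_fixture_corpus(self, corpus, ligands):
        poi, e3 = ligands
        for smiles in corpus[:20]:
            protac = lg.assemble_protac(lg.parse_linker(smiles), poi, e3)
            assert len(Chem.GetMolFrags(Chem.MolFromSmiles(protac))) == 1


class TestMorganFingerprint:
    def test_invariant_to_smiles_rewriting(self):
        spec = COUNT_FP_500
        assert np.array_equal(
            lg.morgan_fingerprint("OCC", spec), lg.morgan_fingerprint("C(O)C", spec)
        )

    def test_invariant_under_randomization(self, corpus):
        spec = FingerprintSpec(2, 2048, True)
        for smiles in corpus[:5]:
            mol = mol_from_smiles(smiles, lenient=True)
            ref = lg.morgan_fingerprint(smiles, spec)
            for variant in Chem.MolToRandomSmilesVect(mol, 20, randomSeed=7):
                assert np.array_equal(lg.morgan_fingerprint(variant, spec), ref)

    def test_peg_repeat_has_multiplicity(self):
        fp = lg.morgan_fingerprint("OCCOCCOCCO", FingerprintSpec(2, 2048, True))
        assert fp.max() >= 2

    def test_folding_conserves_counts(self):
        raw = lg.morgan_fingerprint("OCCOCCOCCO", FingerprintSpec(2, 2048, True))
        folded = fold_vector(raw, 500, counted=True)
        assert folded.sum() == raw.sum()
        assert folded.shape == (500,)

    def test_bit_fold_is_or(self):
        raw = lg.morgan_fingerprint("OCCOCCOCCO", FingerprintSpec(2, 2048, False))
        folded = fold_vector(raw, 500, counted=False)
        assert set(np.unique(folded)) <= {0, 1}

    def test_tanimoto_identity_and_disjoint(self):
        a = lg.morgan_fingerprint("CCO", COUNT_FP_500)
        assert lg.tanimoto(a, a) == 1.0
        assert lg.tanimoto(a, np.zeros_like(a)) == 0.0


class TestPermeabilityCuration:
    @pytest.mark.parametrize(
        "raw,value,censored",
        [("<2", 1.0, True), ("2.14", 2.14, False), ("<0.5", 0.25, True)],
    )
    def test_censoring_rule(self, raw, value, censored):
        got_value, got_censored = lg.censor_permeability(raw)
        assert got_value == pytest.approx(value)
        assert got_censored is censored

    @pytest.mark.parametrize("raw", ["", "abc", "<", "< <2", "2..3"])
    def test_malformed_rejected(self, raw):
        with pytest.raises(lg.FormatError):
            lg.censor_permeability(raw)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            lg.censor_permeability("0")

    @pytest.mark.parametrize(
        "papp,expected", [(2.14, 0.3304), (1.0, 0.0), (10.0, 1.0)]
    )
    def test_log_transform(self, papp, expected):
        assert lg.log10_papp(papp) == pytest.approx(expected, abs=5e-5)

    @given(st.floats(min_value=0.01, max_value=100), st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_censored_log_monotone(self, a, b):
        # curation then log transform preserves the order of the numeric part
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert lg.log10_papp(lg.censor_permeability(f"<{lo}")[0]) < lg.log10_papp(
            lg.censor_permeability(f"<{hi}")[0]
        )


class TestApparentPermeability:
    def test_transwell_formula(self):
        p = lg.PermeabilityAssayParams(C=0.1, V=0.25, T=7200, A=0.11, C0=0.1)
        assert lg.apparent_permeability(p) == pytest.approx(0.25 / 792.0)
        assert lg.apparent_permeability(p) == pytest.approx(3.156e-4, rel=1e-3)

    def test_zero_receiver_concentration(self):
        assert lg.apparent_permeability(lg.PermeabilityAssayParams(C=0.0)) == 0.0

    def test_linearity_in_concentration(self):
        base = lg.apparent_permeability(lg.PermeabilityAssayParams(C=0.05))
        assert lg.apparent_permeability(
            lg.PermeabilityAssayParams(C=0.10)
        ) == pytest.approx(2 * base)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            lg.PermeabilityAssayParams(C=0.1, T=0)


def test_canonical_smiles_strips_stereo():
    assert lg.canonical_smiles("C[C@@H](N)O") == lg.canonical_smiles("C[C@H](N)O")
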