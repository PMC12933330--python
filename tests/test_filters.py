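"""Filter cascade semantics: boundary behavior, preset nesting, purity, and
agreement of the branched-structure rule with a brute-force enumerator."""

import itertools

import networkx as nx
import numpy as np
import pytest
from rdkit import Chem

import linkergen as lg
from linkergen.chem import BIT_FP_2048, attachment_indices, mol_from_smiles, morgan_fingerprint
from linkergen.errors import ConfigError
from linkergen.filters import (
    FilterConfig,
    ad_filter,
    apply_preset,
    attachment_point_filter,
    branch_run_length,
    branched_structure_filter,
    compile_smarts,
    linker_length_filter,
    linker_similarity_filter,
    linker_validation_filter,
    preset_filters,
    radical_atom_filter,
    ring_structure_filter,
    substructure_filter,
)


class TestAttachmentFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [("*CC*", True), ("*CC", False), ("*C(*)C*", False), ("garbage(", False)],
    )
    def test_marker_count(self, smiles, expected):
        assert attachment_point_filter(smiles)[0] is expected


class TestValidationFilter:
    def test_peg_assembles(self, ligands):
        poi, e3 = ligands
        ok, _, protac = linker_validation_filter(lg.parse_linker("*CCOCC*"), poi, e3)
        assert ok and protac

    @pytest.mark.parametrize("smiles", ["*F*", "*[H]*"])
    def test_overvalent_linker_fails(self, smiles, ligands):
        poi, e3 = ligands
        assert not linker_validation_filter(lg.parse_linker(smiles), poi, e3)[0]

    def test_missing_ligand_is_config_error(self):
        with pytest.raises(ConfigError):
            linker_validation_filter(lg.parse_linker("*CC*"), None, None)


class TestRadicalFilter:
    def test_plain_amine_passes(self):
        assert radical_atom_filter("*CCN*")[0]

    @pytest.mark.parametrize("smiles", ["*CC([CH2])C*", "*CC([O])C*"])
    def test_explicit_radical_fails(self, smiles):
        # oracle: RDKit's valence model assigns unpaired electrons here
        mol = mol_from_smiles(smiles, lenient=True)
        assert sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms()) > 0
        assert not radical_atom_filter(smiles)[0]


class TestRingFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("*C1CC1*", False),       # 3-ring
            ("*C1CCC1*", False),      # 4-ring
            ("*C1CCCC1*", True),      # 5-ring
            ("*C1CCC(CC1)*", True),   # 6-ring
            ("*C1CCCCCC1*", False),   # 7-ring
            ("*CCOCC*", True),        # acyclic
        ],
    )
    def test_ring_size_boundaries(self, smiles, expected):
        assert ring_structure_filter(smiles, FilterConfig())[0] is expected


def _branch_runs_bruteforce(smiles: str) -> int:
    """Independent enumerator: longest simple path among off-path atoms,
    with ring atoms exempt when the ring shares >= 2 atoms with the
    marker-to-marker shortest path (networkx throughout)."""
    mol = mol_from_smiles(smiles, lenient=True)
    g = nx.Graph([(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()])
    m1, m2 = attachment_indices(mol)
    path = set(nx.shortest_path(g, m1, m2))
    exempt = set()
    for cycle in nx.cycle_basis(g):
        if len(path.intersection(cycle)) >= 2:
            exempt.update(cycle)
    off = set(g.nodes) - path - exempt
    if not off:
        return 0
    sub = g.subgraph(off)
    best = 0
    for comp in nx.connected_components(sub):
        comp = list(comp)
        for a, b in itertools.combinations_with_replacement(comp, 2):
            for p in nx.all_simple_paths(sub, a, b):
                best = max(best, len(p))
            best = max(best, 1)
    return best


class TestBranchFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("*CC(C)CC*", True),        # methyl branch, run 1
            ("*CC(CC)CC*", False),      # ethyl branch, run 2
            ("*CC1CCC(C*)CC1", True),   # ring on the shortest path is exempt
            ("*CC(C)(C)CC*", True),     # gem-dimethyl: two separate run-1 branches
            ("*CCCC*", True),           # unbranched
        ],
    )
    def test_branch_boundaries(self, smiles, expected):
        assert branched_structure_filter(smiles, FilterConfig())[0] is expected

    def test_agrees_with_bruteforce_enumerator(self, corpus):
        checked = 0
        for smiles in corpus:
            mol = mol_from_smiles(smiles, lenient=True)
            if mol.GetNumAtoms() > 22:
                continue
            assert branch_run_length(smiles) == _branch_runs_bruteforce(smiles), smiles
            checked += 1
        assert checked >= 30


class TestLengthFilter:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("*" + "C" * 15 + "*", True),   # boundary inclusive
            ("*" + "C" * 16 + "*", False),
            ("*C*", True),
        ],
    )
    def test_path_length_boundary(self, smiles, expected):
        assert linker_length_filter(smiles, FilterConfig())[0] is expected


def _boundary_reference(query_fp: np.ndarray, ratio_num: int, ratio_den: int):
    """A reference bit vector whose Tanimoto to the query is exactly
    num/den: keep a fraction of the query's bits (requires divisibility)."""
    on = np.flatnonzero(query_fp)
    assert len(on) % ratio_den == 0
    keep = on[: len(on) * ratio_num // ratio_den]
    ref = np.zeros_like(query_fp)
    ref[keep] = 1
    return ref


def _find_divisible_linker(corpus, den):
    for smiles in corpus:
        fp = morgan_fingerprint(smiles, BIT_FP_2048)
        if fp.sum() % den == 0 and fp.sum() >= den:
            return smiles, fp
    raise AssertionError("no corpus linker with a divisible bit count")


class TestSimilarityFilter:
    def test_identical_to_training_passes(self, corpus):
        fps = [morgan_fingerprint(corpus[0], BIT_FP_2048)]
        assert linker_similarity_filter(corpus[0], fps, FilterConfig())[0]

    def test_disjoint_features_fail(self, corpus):
        fps = [np.zeros(2048, dtype=np.int64)]
        fps[0][0] = 1  # a feature no molecule hits is enough for sim 0
        assert not linker_similarity_filter(corpus[0], fps, FilterConfig())[0]

    def test_boundary_inclusive_at_threshold(self, corpus):
        # exactly 0.3 passes ("below 0.3" is the exclusion); just below fails
        smiles, fp = _find_divisible_linker(corpus, 10)
        at = _boundary_reference(fp, 3, 10)
        assert lg.tanimoto(fp, at) == pytest.approx(0.3)
        assert linker_similarity_filter(smiles, [at], FilterConfig())[0]
        below = at.copy()
        below[np.flatnonzero(below)[-1]] = 0  # drop one shared bit
        assert lg.tanimoto(fp, below) < 0.3
        assert not linker_similarity_filter(smiles, [below], FilterConfig())[0]

    def test_empty_reference_is_config_error(self, corpus):
        with pytest.raises(ConfigError):
            linker_similarity_filter(corpus[0], [], FilterConfig())


class TestAdFilter:
    def test_training_protac_passes(self, fitted_model):
        smiles = fitted_model.train_smiles_[0]
        assert ad_filter(smiles, fitted_model.train_ad_fps_, FilterConfig())[0]

    def test_boundary_inclusive_at_threshold(self, fitted_model, corpus, ligands):
        poi, e3 = ligands
        protacs = [lg.assemble_protac(s, poi, e3) for s in corpus[:60]]
        for protac in protacs:
            fp = morgan_fingerprint(protac, BIT_FP_2048)
            if fp.sum() % 10 == 0 and fp.sum() >= 10:
                break
        else:
            raise AssertionError("no PROTAC with divisible bit count")
        at = _boundary_reference(fp, 1, 10)
        assert lg.tanimoto(fp, at) == pytest.approx(0.1)
        assert ad_filter(protac, [at], FilterConfig())[0]
        below = at.copy()
        below[np.flatnonzero(below)[-1]] = 0
        assert not ad_filter(protac, [below], FilterConfig())[0]


class TestSubstructureFilter:
    def test_empty_list_always_passes(self):
        assert substructure_filter("c1ccccc1", [])[0]

    def test_aldehyde_alert(self):
        patterns = compile_smarts(["[CX3H1]=O"])
        assert not substructure_filter("CCC=O", patterns)[0]
        assert substructure_filter("c1ccccc1", patterns)[0]

    def test_invalid_smarts_is_config_error(self):
        with pytest.raises(ConfigError):
            compile_smarts(["[[["])


class TestPresets:
    def test_composition_order(self):
        assert preset_filters("relaxed") == ["attachment", "validation", "radical"]
        assert preset_filters("intermediate")[:3] == preset_filters("relaxed")
        assert set(preset_filters("strict")) >= set(preset_filters("intermediate"))

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            preset_filters("lenient")

    def test_evaluation_stops_at_first_failure(self, filter_config, references):
        report = apply_preset("*CC", "relaxed", filter_config, references)
        assert not report.passed
        assert report.outcomes[0][0] == "attachment"
        assert len(report.outcomes) == 1

    def test_overlong_peg_fails_strict_only(self, filter_config, references):
        linker = "*" + "CCO" * 6 + "*"  # path length 18
        inter = apply_preset(linker, "intermediate", filter_config, references)
        strict = apply_preset(linker, "strict", filter_config, references)
        assert inter.passed
        assert not strict.passed and strict.failed_at() == "length"

    def test_pass_set_nesting(self, corpus, filter_config, references):
        passed = {
            p: {
                s
                for s in corpus
                if apply_preset(s, p, filter_config, references).passed
            }
            for p in ("relaxed", "intermediate", "strict")
        }
        assert passed["strict"] <= passed["intermediate"] <= passed["relaxed"]
        assert passed["relaxed"]  # non-vacuous

    def test_filters_are_pure(self, corpus, filter_config, references):
        for smiles in corpus[:10]:
            r1 = apply_preset(smiles, "strict", filter_config, references)
            r2 = apply_preset(smiles, "strict", filter_config, references)
            assert r1.outcomes == r2.outcomes and r1.passed == r2.passed

    def test_skip_alert_override(self, filter_config, references):
        report = apply_preset(
            "*CCOCC*", "intermediate", filter_config, references, skip_alert=True
        )
        assert "alert" not in [name for name, _, _ in report.outcomes]
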