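"""PROTAC-likeness filter cascade.

Candidate linkers are screened by a sequence of structural filters organised
into three presets of increasing stringency:

* ``relaxed`` — attachment-point count, assembly validity, no radicals;
* ``intermediate`` — adds ring-size, branched-structure, structural-alert and
  specific-substructure filters (the last two applied to the assembled PROTAC);
* ``strict`` — adds linker-length, linker-similarity (to the generator's
  training corpus) and applicability-domain filters.

Filters run in a fixed order and evaluation stops at the first failure; the
:class:`FilterReport` records every filter that ran with its outcome and a
human-readable reason. Threshold boundaries are inclusive-pass: a linker at
similarity exactly 0.3, path length exactly 15, or AD similarity exactly 0.1
passes (exclusion applies to values strictly beyond the threshold).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem import (
    BIT_FP_2048,
    FingerprintSpec,
    Ligand,
    Linker,
    assemble_protac,
    attachment_indices,
    mol_from_smiles,
    morgan_fingerprint,
    parse_linker,
    tanimoto,
)
from .errors import AssemblyError, AttachmentCountError, ConfigError, InvalidSmiles

PRESETS = ("relaxed", "intermediate", "strict")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the structural filters.

    Defaults follow the stringent design regime: only 5- or 6-membered rings,
    no branch of two or more consecutive off-path atoms, linker path length at
    most 15 heavy atoms, minimum Tanimoto similarity 0.3 to the generator
    training linkers, and minimum similarity 0.1 to the permeability-model
    training PROTACs (the applicability domain).
    """

    ring_min: int = 5
    ring_max: int = 6
    max_branch_run: int = 2          # a branch run of this many atoms fails
    max_path_length: int = 15
    similarity_threshold: float = 0.3
    ad_threshold: float = 0.1
    similarity_fp: FingerprintSpec = BIT_FP_2048
    ad_fp: FingerprintSpec = BIT_FP_2048

    def __post_init__(self):
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity_threshold must be in (0, 1]")
        if not (0 < self.ad_threshold <= 1):
            raise ValueError("ad_threshold must be in (0, 1]")
        if self.ring_min > self.ring_max:
            raise ValueError("ring_min must be <= ring_max")
        if self.max_path_length < 1:
            raise ValueError("max_path_length must be >= 1")


@dataclass
class FilterReferences:
    """External data the filters compare against.

    ``linker_fps`` are fingerprints of the generator's training linkers (for
    the similarity filter); ``protac_fps`` those of the permeability model's
    training PROTACs (for the AD filter). SMARTS pattern lists are compiled
    once at load time.
    """

    poi: Ligand | None = None
    e3: Ligand | None = None
    linker_fps: list[np.ndarray] | None = None
    protac_fps: list[np.ndarray] | None = None
    alert_patterns: list[tuple[str, Chem.Mol]] = field(default_factory=list)
    specific_patterns: list[tuple[str, Chem.Mol]] = field(default_factory=list)


@dataclass
class FilterReport:
    """Auditable per-candidate record of the cascade outcome."""

    candidate: str                       # candidate SMILES as generated
    preset: str
    outcomes: list[tuple[str, bool, str]] = field(default_factory=list)
    passed: bool = False
    protac_smiles: str | None = None     # set once assembly succeeds

    def record(self, name: str, ok: bool, reason: str = "") -> bool:
        self.outcomes.append((name, ok, reason))
        return ok

    def failed_at(self) -> str | None:
        for name, ok, _ in self.outcomes:
            if not ok:
                return name
        return None


# ---------------------------------------------------------------------------
# SMARTS lists
# ---------------------------------------------------------------------------

def compile_smarts(patterns: list[str]) -> list[tuple[str, Chem.Mol]]:
    out = []
    for p in patterns:
        q = Chem.MolFromSmarts(p)
        if q is None:
            raise ConfigError(f"invalid SMARTS pattern: {p!r}")
        out.append((p, q))
    return out


def load_smarts_file(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read a SMARTS list: one pattern per line.

    A '#' opens a comment only at line start or after whitespace, since '#'
    inside a pattern is SMARTS syntax (triple bond, atomic number).
    """
    patterns = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pat = re.split(r"\s+#", line)[0].split()[0]
        if pat:
            patterns.append(pat)
    return compile_smarts(patterns)


def default_alert_patterns() -> list[tuple[str, Chem.Mol]]:
    """The package's built-in structural-alert list (user-replaceable)."""
    with resources.as_file(resources.files("linkergen.data") / "alerts.smarts") as p:
        return load_smarts_file(p)


def default_specific_patterns() -> list[tuple[str, Chem.Mol]]:
    """Built-in unstable / hard-to-synthesize motif list (user-replaceable)."""
    with resources.as_file(resources.files("linkergen.data") / "specific.smarts") as p:
        return load_smarts_file(p)


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def attachment_point_filter(smiles: str) -> tuple[bool, str]:
    """Pass iff the string parses and carries exactly two attachment markers."""
    try:
        mol = mol_from_smiles(smiles, lenient=True)
    except InvalidSmiles as exc:
        return False, f"unparseable: {exc}"
    n = len(attachment_indices(mol))
    if n != 2:
        return False, f"{n} attachment markers (need 2)"
    if len(Chem.GetMolFrags(mol)) != 1:
        return False, "disconnected fragment"
    return True, ""


def linker_validation_filter(
    linker: Linker, poi: Ligand, e3: Ligand
) -> tuple[bool, str, str | None]:
    """Pass iff the linker assembles with both ligands into a valid molecule.

    Returns (passed, reason, protac_smiles).
    """
    if poi is None or e3 is None:
        raise ConfigError("linker validation requires both POI and E3 ligands")
    try:
        protac = assemble_protac(linker, poi, e3)
    except (AssemblyError, InvalidSmiles, AttachmentCountError) as exc:
        return False, f"assembly failed: {exc}", None
    return True, "", protac


def radical_atom_filter(smiles: str) -> tuple[bool, str]:
    """Pass iff no atom carries unpaired electrons."""
    mol = mol_from_smiles(smiles, lenient=True)
    for atom in mol.GetAtoms():
        if atom.GetNumRadicalElectrons() > 0:
            return False, f"radical electrons on atom {atom.GetIdx()} ({atom.GetSymbol()})"
    return True, ""


def ring_structure_filter(linker: Linker | str, cfg: FilterConfig) -> tuple[bool, str]:
    """Pass iff every ring in the linker has between ``ring_min`` and ``ring_max`` members."""
    smiles = linker.smiles if isinstance(linker, Linker) else linker
    mol = mol_from_smiles(smiles, lenient=True)
    for ring in mol.GetRingInfo().AtomRings():
        if not (cfg.ring_min <= len(ring) <= cfg.ring_max):
            return False, f"ring of size {len(ring)} outside [{cfg.ring_min}, {cfg.ring_max}]"
    return True, ""


def _shortest_path_atoms(mol: Chem.Mol) -> tuple[set[int], set[int]]:
    """Atoms on the marker-to-marker shortest path and the ring-exempt set.

    Ring atoms are exempt from branch counting when the ring itself is
    traversed by the shortest path (shares at least two atoms with it).
    """
    m1, m2 = attachment_indices(mol)
    path = set(Chem.GetShortestPath(mol, m1, m2))
    exempt: set[int] = set()
    for ring in mol.GetRingInfo().AtomRings():
        if len(path.intersection(ring)) >= 2:
            exempt.update(ring)
    return path, exempt


def branch_run_length(linker: Linker | str) -> int:
    """Longest run of consecutive off-path atoms branching from the shortest path.

    Ring atoms of rings traversed by the path are not counted as branches.
    The run length of a branch is the number of atoms on the longest simple
    chain inside the branch component.
    """
    smiles = linker.smiles if isinstance(linker, Linker) else linker
    mol = mol_from_smiles(smiles, lenient=True)
    path, exempt = _shortest_path_atoms(mol)
    allowed = path | exempt
    off = [a.GetIdx() for a in mol.GetAtoms() if a.GetIdx() not in allowed]
    if not off:
        return 0
    adj: dict[int, list[int]] = {i: [] for i in off}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)

    best = 0

    def dfs(node: int, visited: set[int], depth: int):
        nonlocal best
        best = max(best, depth)
        for nb in adj[node]:
            if nb not in visited:
                visited.add(nb)
                dfs(nb, visited, depth + 1)
                visited.remove(nb)

    for start in off:
        dfs(start, {start}, 1)
    return best


def branched_structure_filter(linker: Linker | str, cfg: FilterConfig) -> tuple[bool, str]:
    """Fail iff some branch off the shortest path runs ``max_branch_run`` or more atoms."""
    run = branch_run_length(linker)
    if run >= cfg.max_branch_run:
        return False, f"branch run of {run} atoms (limit {cfg.max_branch_run - 1})"
    return True, ""


def linker_length_filter(linker: Linker | str, cfg: FilterConfig) -> tuple[bool, str]:
    """Pass iff the marker-to-marker path length does not exceed ``max_path_length``."""
    lk = parse_linker(linker) if isinstance(linker, str) else linker
    if lk.path_length > cfg.max_path_length:
        return False, f"path length {lk.path_length} exceeds {cfg.max_path_length}"
    return True, ""


def _max_tanimoto(fp: np.ndarray, reference: list[np.ndarray]) -> float:
    return max(tanimoto(fp, ref) for ref in reference)


def linker_similarity_filter(
    linker: Linker | str,
    training_linker_fps: list[np.ndarray],
    cfg: FilterConfig,
) -> tuple[bool, str]:
    """Pass iff the linker's max Tanimoto to the training linkers is at least the threshold."""
    if not training_linker_fps:
        raise ConfigError("similarity filter requires training linker fingerprints")
    smiles = linker.smiles if isinstance(linker, Linker) else linker
    fp = morgan_fingerprint(smiles, cfg.similarity_fp)
    sim = _max_tanimoto(fp, training_linker_fps)
    if sim < cfg.similarity_threshold:
        return False, f"max training similarity {sim:.3f} below {cfg.similarity_threshold}"
    return True, ""


def substructure_filter(
    protac_smiles: str, patterns: list[tuple[str, Chem.Mol]]
) -> tuple[bool, str]:
    """Pass iff none of the SMARTS patterns matches the assembled PROTAC."""
    mol = mol_from_smiles(protac_smiles)
    for raw, query in patterns:
        if mol.HasSubstructMatch(query):
            return False, f"matches pattern {raw}"
    return True, ""


def ad_filter(
    protac_smiles: str,
    training_protac_fps: list[np.ndarray],
    cfg: FilterConfig,
) -> tuple[bool, str]:
    """Applicability-domain gate: the assembled PROTAC must resemble the
    permeability model's training set (max Tanimoto at least ``ad_threshold``)."""
    if not training_protac_fps:
        raise ConfigError("AD filter requires training PROTAC fingerprints")
    fp = morgan_fingerprint(protac_smiles, cfg.ad_fp)
    sim = _max_tanimoto(fp, training_protac_fps)
    if sim < cfg.ad_threshold:
        return False, f"max AD similarity {sim:.3f} below {cfg.ad_threshold}"
    return True, ""


# ---------------------------------------------------------------------------
# preset composition
# ---------------------------------------------------------------------------

def preset_filters(preset: str) -> list[str]:
    """Ordered filter names evaluated under a preset."""
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    names = ["attachment", "validation", "radical"]
    if preset in ("intermediate", "strict"):
        names += ["ring", "branch", "alert", "specific"]
    if preset == "strict":
        names += ["length", "similarity", "ad"]
    return names


def apply_preset(
    candidate: str,
    preset: str,
    cfg: FilterConfig,
    refs: FilterReferences,
    skip_alert: bool = False,
) -> FilterReport:
    """Run the filter cascade for one candidate linker SMILES.

    Evaluation stops at the first failing filter; the report lists every
    filter evaluated. ``skip_alert=True`` drops the alert-substructure filter
    from the cascade (a documented preset override).
    """
    names = preset_filters(preset)
    if skip_alert and "alert" in names:
        names.remove("alert")
    report = FilterReport(candidate=candidate, preset=preset)

    linker: Linker | None = None
    for name in names:
        if name == "attachment":
            ok, reason = attachment_point_filter(candidate)
            if ok:
                linker = parse_linker(candidate)
        elif name == "validation":
            ok, reason, protac = linker_validation_filter(linker, refs.poi, refs.e3)
            if ok:
                report.protac_smiles = protac
        elif name == "radical":
            ok, reason = radical_atom_filter(candidate)
        elif name == "ring":
            ok, reason = ring_structure_filter(linker, cfg)
        elif name == "branch":
            ok, reason = branched_structure_filter(linker, cfg)
        elif name == "alert":
            ok, reason = substructure_filter(report.protac_smiles, refs.alert_patterns)
        elif name == "specific":
            ok, reason = substructure_filter(report.protac_smiles, refs.specific_patterns)
        elif name == "length":
            ok, reason = linker_length_filter(linker, cfg)
        elif name == "similarity":
            ok, reason = linker_similarity_filter(linker, refs.linker_fps, cfg)
        elif name == "ad":
            ok, reason = ad_filter(report.protac_smiles, refs.protac_fps, cfg)
        else:  # pragma: no cover
            raise ConfigError(f"unknown filter {name!r}")
        report.record(name, ok, reason)
        if not ok:
            report.passed = False
            return report
    report.passed = True
    return report
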