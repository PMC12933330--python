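"""Molecular core: linker/ligand parsing, PROTAC assembly, fingerprints, and
permeability data curation.

A *linker* is a molecule carrying exactly two attachment markers (dummy atoms,
written ``*`` in SMILES) that indicate where the protein-of-interest (POI)
ligand and the E3-ligase ligand bond. Assembly replaces each marker with a
single bond to the corresponding ligand's marker neighbour.

Parsing of linkers is deliberately lenient about valence at the markers: a
string like ``*F*`` is accepted as a linker (the markers are placeholders, not
real bonds yet) and only rejected when assembly produces an impossible
molecule. Syntactically broken SMILES are rejected immediately.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

from .errors import (
    AssemblyError,
    AttachmentCountError,
    FormatError,
    InvalidSmiles,
)

RDLogger.DisableLog("rdApp.*")

#: base width at which Morgan environments are hashed before any folding
_BASE_FP_SIZE = 2048


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan fingerprint parameters.

    ``dim`` smaller than 2048 is obtained by hashing at 2048 and folding by
    index modulo ``dim`` (counts are summed, bits are OR-ed), so total counts
    are conserved under folding.
    """

    radius: int = 2
    dim: int = 2048
    counted: bool = True

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.dim <= 0:
            raise ValueError("dim must be > 0")


#: the paper-grade defaults: counted 500-dim for the permeability model,
#: bit 2048 for similarity / applicability-domain checks
COUNT_FP_500 = FingerprintSpec(radius=2, dim=500, counted=True)
BIT_FP_2048 = FingerprintSpec(radius=2, dim=2048, counted=False)


@dataclass(frozen=True)
class Linker:
    """A linker fragment with exactly two attachment markers."""

    smiles: str                 # input spelling (reading order defines marker order)
    canonical: str              # canonical spelling, stereo stripped
    n_attachments: int
    path_length: int            # heavy atoms on the shortest marker-to-marker path,
                                # markers themselves excluded

    def __post_init__(self):
        if self.n_attachments != 2:
            raise AttachmentCountError(
                f"linker must have exactly 2 attachment markers, got {self.n_attachments}"
            )


@dataclass(frozen=True)
class Ligand:
    """A POI or E3 ligand fragment with one attachment marker."""

    smiles: str
    role: str                   # "POI" or "E3"
    canonical: str = ""
    n_attachments: int = 1

    def __post_init__(self):
        if self.role not in ("POI", "E3"):
            raise ValueError(f"ligand role must be POI or E3, got {self.role!r}")
        if self.n_attachments != 1:
            raise AttachmentCountError(
                f"ligand must have exactly 1 attachment marker, got {self.n_attachments}"
            )


@dataclass(frozen=True)
class PermeabilityRecord:
    """One PROTAC with its Caco-2 A-to-B permeability target.

    Left-censored entries ("<x") are resolved to x/2 before the log transform.
    """

    smiles: str
    raw_value: str
    papp: float                 # μcm/s after censor resolution
    log_papp: float             # log10(papp)
    censored: bool


@dataclass(frozen=True)
class PermeabilityAssayParams:
    """Inputs of the transwell apparent-permeability calculation.

    C: receiver (basolateral) concentration after incubation, μM.
    V: basolateral volume, mL.  T: duration, s.  A: membrane area, cm².
    C0: donor concentration, μM.
    """

    C: float
    V: float = 0.25
    T: float = 7200.0
    A: float = 0.11
    C0: float = 0.1

    def __post_init__(self):
        if self.C < 0:
            raise ValueError("receiver concentration C must be >= 0")
        for name in ("V", "T", "A", "C0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# parsing and canonicalization
# ---------------------------------------------------------------------------

def mol_from_smiles(smiles: str, lenient: bool = False) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`InvalidSmiles` on failure.

    With ``lenient=True`` valence checks are skipped (needed for fragments
    whose markers stand in for future bonds, e.g. ``*F*``); aromaticity and
    ring perception still run, so syntactic garbage is rejected either way.
    """
    if not smiles or not isinstance(smiles, str):
        raise InvalidSmiles(f"empty or non-string SMILES: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles, sanitize=not lenient)
    if mol is None and lenient:
        mol = None  # syntax error even without sanitization below
    if mol is None:
        if not lenient:
            # distinguish a pure valence problem from a syntax error
            raw = Chem.MolFromSmiles(smiles, sanitize=False)
            if raw is None:
                raise InvalidSmiles(f"unparseable SMILES: {smiles!r}")
            raise InvalidSmiles(f"SMILES fails sanitization: {smiles!r}")
        raise InvalidSmiles(f"unparseable SMILES: {smiles!r}")
    if lenient:
        mol.UpdatePropertyCache(strict=False)
        failed = Chem.SanitizeMol(
            mol,
            sanitizeOps=Chem.SANITIZE_ALL ^ Chem.SANITIZE_PROPERTIES,
            catchErrors=True,
        )
        if failed != Chem.SANITIZE_NONE:
            raise InvalidSmiles(f"SMILES fails sanitization ({failed}): {smiles!r}")
    return mol


def canonical_smiles(smiles: str, lenient: bool = False) -> str:
    """Canonical SMILES with stereochemistry stripped.

    One fixed canonical form is used everywhere in the package; deduplication
    and identity comparisons are string equality on this form.
    """
    mol = mol_from_smiles(smiles, lenient=lenient)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def attachment_indices(mol: Chem.Mol) -> list[int]:
    """Atom indices of the dummy-atom attachment markers, in reading order."""
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]


def _linker_mol(smiles: str) -> tuple[Chem.Mol, list[int]]:
    mol = mol_from_smiles(smiles, lenient=True)
    markers = attachment_indices(mol)
    if len(markers) != 2:
        raise AttachmentCountError(
            f"linker must have exactly 2 attachment markers, got {len(markers)}: {smiles!r}"
        )
    if len(Chem.GetMolFrags(mol)) != 1:
        raise InvalidSmiles(f"linker SMILES is disconnected: {smiles!r}")
    return mol, markers


def linker_path_length(smiles: str) -> int:
    """Heavy atoms on the shortest path between the two attachment markers.

    The markers themselves are excluded from the count, so ``*CCOCC*`` has
    path length 5. This is the package's "linker length" convention.
    """
    mol, (m1, m2) = _linker_mol(smiles)
    path = Chem.GetShortestPath(mol, m1, m2)
    return len(path) - 2


def parse_linker(smiles: str) -> Linker:
    """Parse a linker SMILES (two markers, single fragment) into a :class:`Linker`."""
    mol, markers = _linker_mol(smiles)
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    canon = Chem.MolToSmiles(mol)
    path = Chem.GetShortestPath(mol, markers[0], markers[1])
    return Linker(
        smiles=smiles,
        canonical=canon,
        n_attachments=2,
        path_length=len(path) - 2,
    )


def parse_ligand(smiles: str, role: str) -> Ligand:
    """Parse a ligand SMILES carrying exactly one attachment marker."""
    mol = mol_from_smiles(smiles, lenient=True)
    markers = attachment_indices(mol)
    if len(markers) != 1:
        raise AttachmentCountError(
            f"{role} ligand must have exactly 1 attachment marker, got {len(markers)}"
        )
    if len(Chem.GetMolFrags(mol)) != 1:
        raise InvalidSmiles(f"ligand SMILES is disconnected: {smiles!r}")
    m2 = Chem.Mol(mol)
    Chem.RemoveStereochemistry(m2)
    return Ligand(smiles=smiles, role=role, canonical=Chem.MolToSmiles(m2))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _marker_anchor(mol: Chem.Mol, marker_idx: int) -> int:
    nbrs = mol.GetAtomWithIdx(marker_idx).GetNeighbors()
    if len(nbrs) != 1:
        raise AssemblyError(
            f"attachment marker must have exactly one neighbour, got {len(nbrs)}"
        )
    return nbrs[0].GetIdx()


def assemble_protac(
    linker: Linker | str,
    poi: Ligand | str,
    e3: Ligand | str,
    try_both_orientations: bool = False,
) -> str:
    """Join a linker to the POI and E3 ligands, returning the PROTAC SMILES.

    The first attachment marker in the linker's reading order bonds to the POI
    ligand, the second to the E3 ligand; markers are removed and a single bond
    created at each junction. With ``try_both_orientations=True`` the reverse
    orientation is attempted if the first one fails sanitization.

    Raises :class:`AssemblyError` if the joined molecule violates valence
    rules or is not a single connected graph.
    """
    if isinstance(linker, str):
        linker = parse_linker(linker)
    if isinstance(poi, str):
        poi = parse_ligand(poi, "POI")
    if isinstance(e3, str):
        e3 = parse_ligand(e3, "E3")

    def _attempt(flip: bool) -> str:
        lmol, lmarkers = _linker_mol(linker.smiles)
        pmol = mol_from_smiles(poi.smiles, lenient=True)
        emol = mol_from_smiles(e3.smiles, lenient=True)
        if flip:
            lmarkers = lmarkers[::-1]

        combo = Chem.CombineMols(Chem.CombineMols(lmol, pmol), emol)
        off_p = lmol.GetNumAtoms()
        off_e = off_p + pmol.GetNumAtoms()
        pm = attachment_indices(pmol)[0] + off_p
        em = attachment_indices(emol)[0] + off_e

        rw = Chem.RWMol(combo)
        pairs = [(lmarkers[0], pm), (lmarkers[1], em)]
        anchors = [(_marker_anchor(rw, a), _marker_anchor(rw, b)) for a, b in pairs]
        for (a1, a2) in anchors:
            rw.AddBond(a1, a2, Chem.BondType.SINGLE)
        for idx in sorted([i for pair in pairs for i in pair], reverse=True):
            rw.RemoveAtom(idx)
        out = rw.GetMol()
        try:
            Chem.SanitizeMol(out)
        except Exception as exc:  # rdkit raises several sanitization types
            raise AssemblyError(f"assembled molecule fails sanitization: {exc}") from exc
        if len(Chem.GetMolFrags(out)) != 1:
            raise AssemblyError("assembled molecule is disconnected")
        Chem.RemoveStereochemistry(out)
        return Chem.MolToSmiles(out)

    try:
        return _attempt(flip=False)
    except AssemblyError:
        if try_both_orientations:
            return _attempt(flip=True)
        raise


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

_fp_generators: dict[tuple[int, int], rdFingerprintGenerator.FingerprintGenerator64] = {}


def _get_generator(radius: int, size: int):
    key = (radius, size)
    if key not in _fp_generators:
        _fp_generators[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=size
        )
    return _fp_generators[key]


def fold_vector(vec: np.ndarray, dim: int, counted: bool) -> np.ndarray:
    """Fold a fingerprint vector to ``dim`` by index modulo.

    Counts are summed across aliased indices (total count conserved); bits are
    OR-ed.
    """
    vec = np.asarray(vec)
    if vec.shape[0] == dim:
        out = vec.astype(np.int64)
    else:
        out = np.zeros(dim, dtype=np.int64)
        np.add.at(out, np.arange(vec.shape[0]) % dim, vec.astype(np.int64))
    if not counted:
        out = (out > 0).astype(np.int64)
    return out


def morgan_fingerprint(smiles: str, spec: FingerprintSpec = COUNT_FP_500) -> np.ndarray:
    """Morgan fingerprint of a molecule as a numpy int vector of length ``spec.dim``.

    Invariant to SMILES rewritings of the same molecule. Widths below the 2048
    hashing base are produced by modulo folding (see :func:`fold_vector`).
    """
    mol = mol_from_smiles(smiles, lenient=True)
    base = max(spec.dim, _BASE_FP_SIZE)
    gen = _get_generator(spec.radius, base)
    if spec.counted:
        raw = gen.GetCountFingerprintAsNumPy(mol)
    else:
        raw = gen.GetFingerprintAsNumPy(mol)
    return fold_vector(raw, spec.dim, spec.counted)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity of two fingerprint vectors.

    Uses the count generalization sum(min)/sum(max), which reduces to the
    standard bit Tanimoto on 0/1 vectors. Two all-zero vectors have
    similarity 0 by convention.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    denom = np.minimum(a, b).sum(), np.maximum(a, b).sum()
    if denom[1] == 0:
        return 0.0
    return float(denom[0]) / float(denom[1])


# ---------------------------------------------------------------------------
# permeability data curation
# ---------------------------------------------------------------------------

_CENSOR_RE = re.compile(r"^\s*(<\s*)?([0-9]+(?:\.[0-9]+)?(?:[eE][+-]?[0-9]+)?)\s*$")


def censor_permeability(raw: str | float) -> tuple[float, bool]:
    """Resolve a raw permeability entry to a numeric value in μcm/s.

    Left-censored entries "<x" (below the quantification limit x) are replaced
    by the midpoint surrogate x/2 and flagged censored; plain numbers pass
    through unflagged.
    """
    if isinstance(raw, (int, float)):
        raw = str(raw)
    m = _CENSOR_RE.match(raw)
    if not m:
        raise FormatError(f"malformed permeability entry: {raw!r}")
    value = float(m.group(2))
    if value <= 0:
        raise ValueError(f"permeability must be positive, got {value}")
    if m.group(1):
        return value / 2.0, True
    return value, False


def log10_papp(papp: float) -> float:
    """log10 of an apparent permeability in μcm/s; the model's target scale."""
    if papp <= 0:
        raise ValueError(f"papp must be > 0, got {papp}")
    return math.log10(papp)


def make_permeability_record(smiles: str, raw_value: str | float) -> PermeabilityRecord:
    """Curate one (SMILES, raw entry) pair into a :class:`PermeabilityRecord`."""
    canon = canonical_smiles(smiles, lenient=True)
    papp, censored = censor_permeability(raw_value)
    return PermeabilityRecord(
        smiles=canon,
        raw_value=str(raw_value),
        papp=papp,
        log_papp=log10_papp(papp),
        censored=censored,
    )


def apparent_permeability(p: PermeabilityAssayParams) -> float:
    """Transwell apparent permeability P_app = C·V / (T·A·C0), in cm/s.

    C and C0 share units (μM) and V is converted from mL to cm³ (numerically
    identical), so the result carries cm/s.
    """
    return (p.C * p.V) / (p.T * p.A * p.C0)
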