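"""Synthetic fixtures: a toy linker corpus and a permeability dataset with a
known structure→permeability rule.

The corpus generator composes linkers from a weighted grammar over chemically
realistic chain units — ethylene (alkane), ethylene-oxide (PEG), amide, and a
1,4-cyclohexylene insert — flanked by the two attachment markers, emulating
the PEG/alkane/amide motifs that dominate real PROTAC linkers. The
permeability generator assembles those linkers with a fixed POI/E3 ligand
pair and assigns log10 P_app by a linear rule in hydrogen-bond donor count
and excess rotatable bonds, mirroring the qualitative medicinal-chemistry
observation that both depress membrane permeability. Because the rule is
known exactly, the regression and search modules can be tested for parameter
recovery without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Descriptors, Lipinski

from .chem import (
    FingerprintSpec,
    Ligand,
    PermeabilityRecord,
    assemble_protac,
    canonical_smiles,
    mol_from_smiles,
    parse_ligand,
    parse_linker,
)
from .permeability import PermeabilityDataset

#: grammar units: SMILES chunk -> (default weight, heavy atoms added to the
#: marker-to-marker path)
GRAMMAR_UNITS = {
    "CC": 0.35,        # alkane
    "CCO": 0.35,       # PEG repeat
    "C(=O)N": 0.20,    # amide
    "C1CCC(CC1)": 0.10,  # 1,4-cyclohexylene insert
}


def default_ligands() -> tuple[Ligand, Ligand]:
    """The fixture POI and E3 ligand pair (one attachment marker each).

    Small drug-like fragments free of structural alerts: an acetanilide-like
    POI warhead and a morpholine-bearing E3 recruiter surrogate.
    """
    poi = parse_ligand("*CC(=O)Nc1ccc(C)cc1", "POI")
    e3 = parse_ligand("*CCOc1ccc(CN2CCOCC2)cc1", "E3")
    return poi, e3


def generate_linker_corpus(
    n: int,
    seed: int = 0,
    grammar_weights: dict[str, float] | None = None,
    min_units: int = 2,
    max_units: int = 7,
) -> list[str]:
    """Generate ``n`` unique valid linkers from the unit grammar.

    Every output carries exactly two attachment markers and parses as a
    single fragment; uniqueness is by canonical SMILES. Reproducible per
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = dict(GRAMMAR_UNITS)
    if grammar_weights:
        weights.update(grammar_weights)
    units = [u for u, w in weights.items() if w > 0]
    probs = np.array([weights[u] for u in units], dtype=float)
    probs /= probs.sum()

    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                f"could not generate {n} unique linkers from the given grammar"
            )
        k = int(rng.integers(min_units, max_units + 1))
        body = "".join(rng.choice(units, p=probs) for _ in range(k))
        smi = f"*{body}*"
        try:
            canon = parse_linker(smi).canonical
        except Exception:
            continue
        if canon in seen:
            continue
        seen.add(canon)
        out.append(smi)
    return out


@dataclass(frozen=True)
class FixtureRule:
    """Known linear structure→permeability rule of the fixtures.

    log10 P_app = intercept + hbd_coef·(#HBD)
                + rotb_coef·max(0, #rotatable_bonds − rotb_pivot) + noise.

    Defaults place typical fixture PROTACs on both sides of the reward
    shoulder at 0.25 log units, so the reward discriminates between
    candidates.
    """

    intercept: float = 1.2
    hbd_coef: float = -0.35
    rotb_coef: float = -0.08
    rotb_pivot: int = 8
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def true_log_papp(protac_smiles: str, rule: FixtureRule) -> float:
    """Noise-free log10 P_app of a PROTAC under the fixture rule."""
    mol = mol_from_smiles(protac_smiles)
    hbd = Lipinski.NumHDonors(mol)
    rotb = Descriptors.NumRotatableBonds(mol)
    return rule.intercept + rule.hbd_coef * hbd + rule.rotb_coef * max(0, rotb - rule.rotb_pivot)


def generate_permeability_dataset(
    n: int,
    seed: int = 0,
    rule: FixtureRule = FixtureRule(),
    ligands: tuple[Ligand, Ligand] | None = None,
    censored_fraction: float = 0.0,
    corpus: list[str] | None = None,
    spec: FingerprintSpec | None = None,
) -> tuple[PermeabilityDataset, np.ndarray]:
    """Build a synthetic permeability table with known ground truth.

    PROTACs are assembled from corpus linkers and the given ligand pair; the
    target is the fixture rule plus Gaussian noise. A ``censored_fraction``
    of records (the lowest-permeability ones, emulating assay quantification
    limits) is emitted as left-censored "<x" strings whose x/2 surrogate
    equals the noisy value, so curation reproduces the intended target.

    Returns the curated dataset and the noise-free true log10 P_app values
    (aligned with the dataset records).
    """
    if n < 3:
        raise ValueError("need n >= 3 records")
    if not (0.0 <= censored_fraction <= 1.0):
        raise ValueError("censored_fraction must be in [0, 1]")
    poi, e3 = ligands if ligands is not None else default_ligands()
    rng = np.random.default_rng(seed)

    linkers = list(corpus) if corpus is not None else generate_linker_corpus(
        4 * n, seed=seed + 1
    )
    protacs: list[str] = []
    seen: set[str] = set()
    for smi in linkers:
        if len(protacs) == n:
            break
        try:
            protac = assemble_protac(parse_linker(smi), poi, e3)
        except Exception:
            continue
        if protac in seen:
            continue
        seen.add(protac)
        protacs.append(protac)
    if len(protacs) < n:
        raise RuntimeError(f"only assembled {len(protacs)} of {n} requested PROTACs")

    truth = np.array([true_log_papp(p, rule) for p in protacs])
    noisy = truth + rng.normal(0.0, rule.noise_sd, size=n)
    papp = np.power(10.0, noisy)

    n_censored = int(round(censored_fraction * n))
    censored_idx = set(np.argsort(noisy)[:n_censored].tolist())

    records = []
    for i, (smi, p) in enumerate(zip(protacs, papp)):
        if i in censored_idx:
            raw = f"<{2.0 * p:.12g}"
        else:
            raw = f"{p:.12g}"
        value = p if i not in censored_idx else p  # surrogate x/2 == p by construction
        records.append(
            PermeabilityRecord(
                smiles=canonical_smiles(smi),
                raw_value=raw,
                papp=value,
                log_papp=float(np.log10(value)),
                censored=(i in censored_idx),
            )
        )
    dataset = PermeabilityDataset(records, spec or FingerprintSpec(2, 500, True))
    return dataset, truth
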