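"""The photophysics-oriented fingerprint (POFP).

A POFP is a 46-digit vector describing an organic luminophore. Digits 1-15
count electron-donor substructures (including the three ESIPT proton-transfer
patterns), digits 16-38 count electron acceptors, digits 39-45 count
"conjugation breakers" (bulky or saturated groups that disrupt pi-conjugation
or intermolecular packing), and digit 46 is the total number of aromatic
atoms, a proxy for the conjugation scale. Digits 1-45 are defined by SMARTS
patterns and evaluated by substructure matching; two encodings exist:

* ``num`` - each digit is the number of distinct matched atom sets;
* ``bit`` - each digit is 1 if the substructure is present, else 0.

The canonical worked example is tetraphenylethylene (TPE), whose POFP(num)
has exactly two active digits: s10 = 1 (one C=C double bond) and s46 = 24
(four phenyl rings).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.error")

N_FEATURES = 46
N_SMARTS = 45

#: Aromaticity perception used for digit 46 (recorded in output metadata so
#: aromatic-atom counts are reproducible across toolkit configurations).
AROMATICITY_MODEL = "rdkit-default"

#: Elements representable by the fingerprint: the common organic set,
#: photophysically relevant main-group elements, and the five heavy metals
#: of feature 38. Molecules containing anything else are flagged.
SUPPORTED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I",
     "Au", "Bi", "Ir", "Ru", "Eu"}
)

CATEGORIES = ("donor_esipt", "acceptor", "breaker")

# (index, name, SMARTS) in table order: 1-15 donors/ESIPT, 16-38 acceptors,
# 39-45 breakers. Patterns are kept as published (after the syntactic repair
# below); note that a few encode unusual semantics, e.g. rows 8/9 demand
# single ring-closure bonds and so do not hit aromatic thiophene/furan under
# the default aromaticity model - they are intentionally not "fixed".
_RAW_TABLE: tuple[tuple[int, str, str], ...] = (
    (1, "dialkylamino", "[c][N]([C])[C]"),
    (2, "diphenylamine", "[c][N]([c])[C]"),
    (3, "triphenylamine", "[c][N]([c])[c]"),
    (4, "methoxy", "[c][O][C]"),
    (5, "diphenyloxy", "[c][O][c]"),
    (6, "phenothiazine", "[c][S][c][c][N][c]"),
    (7, "phenoxazine", "[c][O][c][c][N][c]"),
    (8, "thiophene", "[s]-1[c][c][c][c]-1"),
    (9, "furan", "[o]-1-[c][c][c][c]-1"),
    (10, "carbon–carbon double bond", "[C]=[C]"),
    (11, "1,2-dihyroxy aromatic ring", "[O][c][c][O]"),
    (12, "naphthalene", "[c]-1[c][c][c]([c][c]-1)[c][c][c][c]-2"),
    (13, "ESIPT: enol-imide", "[N]=[C;H][c][c][O;H]"),
    (14, "ESIPT: enol-keto", "[O]=[C;H][c][c][O;H]"),
    (15, "ESIPT: 5m ring", "[c][C](=[O])[C](=[C])[O;H]"),
    (16, "cyano", "[C]#[N]"),
    (17, "carbon–nitrogen double bond", "[C]=[N]"),
    (18, "aromatic positive nitrogen", "[n+]"),
    (19, "aromatic positive oxygen", "[o+]"),
    (20, "boron as acceptor", "[c][B]"),
    (21, "BF2 bridge", "[O,N][B]([F])[F]"),
    (22, "benzothiazole", "[C][c](s)[n]"),
    (23, "benzoxazole", "[C][c](o)[n]"),
    (24, "benzoimidazole", "[C][c](n)[n]"),
    (25, "aromatic N–S–N", "[n][s][n]"),
    (26, "N=S=N", "[c][N]=[S]=[N][c]"),
    (27, "aromatic N–Se–N", "[n][se][n]"),
    (28, "TPA-BMO", "[C]=[C]([N])[C](=[O])[O]"),
    (29, "bisimide", "[c][C](=[O])[N][C](=[O])[c]"),
    (30, "aromatic nitrogen", "[n]"),
    (31, "indanone", "[C]=[C]([C](=[O])[c])[C](=[O])[c]"),
    (32, "carboxy", "[C]=[O]"),
    (33, "carbon–carbon triple bond", "[c][C]#[C]"),
    (34, "4-cyano-indanone",
     "[N]#[C][C]([C]#[N])=[C]([c])[C](=[C])[C](c)=[C]([C]#[N])[C]#[N]"),
    (35, "pyrazine-NBD",
     "[c][c][n][c][c]([c])[n,c][s][n,c][c]([c])[c][n][c][c]"),
    (36, "fluoride", "[C,c][F]"),
    (37, "flavone", "[O]=[C,c][c][c]([c])[S,s,O,o]"),
    (38, "heavy metal atoms", "[Au,Bi,Ir,Ru,Eu]"),
    (39, "spatial conflict of aromatic hydrogen", "[C][c][c]([c,C])[c]"),
    (40, "BINAP core", "[c][c]([c])[c]([c])[c]([c])[c]([c])[c]"),
    (41, "saturated aromatic bridge", "[c][C]([c])-[C]"),
    (42, "BF4 cation", "[F][B-]([F])([F])[F]"),
    (43, "PF6 cation", "[F][P-]([F])([F])([F])([F])[F]"),
    (44, "t-butyl", "[C]([C])([C])[C]"),
    (45, "continual benzene rings",
     "[c]([c])[c]([c])[c]([c])[c]([c])[c]([c])[c]([c])[c]([c])[c]([c])"),
)

#: Auditable repair table for published SMARTS that do not parse. Row 12 as
#: printed opens ring-closure 2 without closing it; it is replaced by a fused
#: naphthalene core, which is what the feature name says it encodes.
SMARTS_REPAIRS: dict[int, str] = {
    12: "[c]1[c][c][c]2[c][c][c][c][c]2[c]1",
}


class FingerprintError(ValueError):
    """Base class for record-level fingerprint failures."""

    def __init__(self, smiles: str, message: str):
        self.smiles = smiles
        super().__init__(message)


class InvalidSmilesError(FingerprintError):
    def __init__(self, smiles: str):
        super().__init__(smiles, f"invalid SMILES: {smiles!r}")


class UnsupportedElementError(FingerprintError):
    """The molecule contains an element the fingerprint cannot represent."""

    def __init__(self, smiles: str, elements: set[str]):
        self.elements = sorted(elements)
        super().__init__(
            smiles,
            f"unsupported element(s) {self.elements} in SMILES {smiles!r}",
        )


@dataclass(frozen=True)
class FeatureDef:
    """One fingerprint digit definition: a named SMARTS substructure."""

    index: int
    category: str
    name: str
    smarts: str

    def to_dict(self) -> dict:
        return {"index": self.index, "category": self.category,
                "name": self.name, "smarts": self.smarts}


def _category_for(index: int) -> str:
    if index <= 15:
        return "donor_esipt"
    if index <= 38:
        return "acceptor"
    return "breaker"


def load_feature_table() -> list[FeatureDef]:
    """Return the 45 SMARTS feature definitions in table order.

    Each returned SMARTS is guaranteed to compile; an internal inconsistency
    (a pattern failing to parse after the documented repairs) aborts with a
    message naming the feature index.
    """
    table = []
    for index, name, smarts in _RAW_TABLE:
        smarts = SMARTS_REPAIRS.get(index, smarts)
        if Chem.MolFromSmarts(smarts) is None:
            raise RuntimeError(
                f"feature {index} ({name}): SMARTS {smarts!r} does not parse"
            )
        table.append(FeatureDef(index, _category_for(index), name, smarts))
    assert len(table) == N_SMARTS
    return table


_COMPILED: list[tuple[FeatureDef, Chem.Mol]] | None = None


def _compiled_table() -> list[tuple[FeatureDef, Chem.Mol]]:
    global _COMPILED
    if _COMPILED is None:
        _COMPILED = [
            (fd, Chem.MolFromSmarts(fd.smarts)) for fd in load_feature_table()
        ]
    return _COMPILED


def feature_table_json() -> str:
    """The feature-definition table as a JSON document."""
    return json.dumps([fd.to_dict() for fd in load_feature_table()], indent=1)


def parse_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string.

    Kekulization failures on exotic aromatic systems are downgraded to
    partial sanitization with a warning (aromaticity is still perceived), so
    borderline database entries survive cleaning. Anything else that fails
    sanitization is rejected.
    """
    if not smiles or not isinstance(smiles, str):
        raise InvalidSmilesError(str(smiles))
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise InvalidSmilesError(smiles)
    err = Chem.SanitizeMol(mol, catchErrors=True)
    if err != Chem.SanitizeFlags.SANITIZE_NONE:
        ops = Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        err = Chem.SanitizeMol(mol, ops, catchErrors=True)
        if err != Chem.SanitizeFlags.SANITIZE_NONE:
            raise InvalidSmilesError(smiles)
        warnings.warn(
            f"partial sanitization (kekulization skipped) for {smiles!r}",
            stacklevel=2,
        )
    return mol


def molecule_elements(mol: Chem.Mol) -> set[str]:
    return {atom.GetSymbol() for atom in mol.GetAtoms()}


def count_substructure(mol: Chem.Mol, pattern: str | Chem.Mol) -> int:
    """Number of DISTINCT matched atom-index sets of ``pattern`` in ``mol``.

    Matches that differ only by the order of atoms within the same atom set
    (e.g. the two orientations of ``[C]=[C]`` across one double bond) count
    once, so TPE's single double bond yields 1.
    """
    if isinstance(pattern, str):
        query = Chem.MolFromSmarts(pattern)
        if query is None:
            raise ValueError(f"SMARTS pattern does not parse: {pattern!r}")
    else:
        query = pattern
    return len(mol.GetSubstructMatches(query, uniquify=True))


def aromatic_atom_count(mol: Chem.Mol) -> int:
    """Count atoms flagged aromatic (digit 46, the conjugation-scale proxy)."""
    return sum(1 for atom in mol.GetAtoms() if atom.GetIsAromatic())


@dataclass(frozen=True)
class POFPVector:
    """A 46-digit POFP for one molecule."""

    values: np.ndarray
    mode: str
    source_smiles: str
    aromaticity_model: str = AROMATICITY_MODEL

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=int)
        if vals.shape != (N_FEATURES,):
            raise ValueError(f"POFP must have {N_FEATURES} digits")
        if (vals < 0).any():
            raise ValueError("POFP digits must be non-negative")
        if self.mode not in ("bit", "num"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "bit" and (vals[:N_SMARTS] > 1).any():
            raise ValueError("bit-mode digits 1-45 must be 0 or 1")
        object.__setattr__(self, "values", vals)

    def digit(self, index: int) -> int:
        """1-based digit accessor (s1 ... s46)."""
        if not 1 <= index <= N_FEATURES:
            raise IndexError(f"digit index {index} out of range 1..{N_FEATURES}")
        return int(self.values[index - 1])


def compute_pofp(smiles: str, mode: str = "num") -> POFPVector:
    """Compute the POFP of one molecule from its SMILES.

    Digits 1-45 are substructure counts (``num``) or presence indicators
    (``bit``) in table order; digit 46 is the aromatic-atom count under the
    default aromaticity model.

    Raises
    ------
    InvalidSmilesError
        If the SMILES does not parse/sanitize.
    UnsupportedElementError
        If the molecule contains an element outside :data:`SUPPORTED_ELEMENTS`
        (flagged rather than silently fingerprinted as zeros).
    """
    if mode not in ("bit", "num"):
        raise ValueError(f"mode must be 'bit' or 'num', got {mode!r}")
    mol = parse_smiles(smiles)
    extra = molecule_elements(mol) - SUPPORTED_ELEMENTS
    if extra:
        raise UnsupportedElementError(smiles, extra)
    values = np.zeros(N_FEATURES, dtype=int)
    for fd, query in _compiled_table():
        count = count_substructure(mol, query)
        values[fd.index - 1] = min(count, 1) if mode == "bit" else count
    values[N_FEATURES - 1] = aromatic_atom_count(mol)
    return POFPVector(values=values, mode=mode, source_smiles=smiles)


@dataclass(frozen=True)
class Rejection:
    """One skipped input entry and the reason it was skipped."""

    index: int
    smiles: str
    reason: str


def fingerprint_table(
    smiles_list: Sequence[str], mode: str = "num"
) -> tuple[np.ndarray, list[str], list[Rejection]]:
    """Fingerprint a batch of SMILES.

    Returns ``(matrix, kept_smiles, rejections)`` where ``matrix`` has shape
    ``(n_valid, 46)`` with rows in input order of the valid entries, and each
    rejection records the input index, the offending SMILES, and a reason.
    """
    rows: list[np.ndarray] = []
    kept: list[str] = []
    rejections: list[Rejection] = []
    for i, smi in enumerate(smiles_list):
        try:
            fp = compute_pofp(smi, mode=mode)
        except UnsupportedElementError:
            rejections.append(Rejection(i, str(smi), "disallowed_element"))
        except FingerprintError:
            rejections.append(Rejection(i, str(smi), "invalid_smiles"))
        else:
            rows.append(fp.values)
            kept.append(smi)
    matrix = (
        np.vstack(rows) if rows else np.empty((0, N_FEATURES), dtype=int)
    )
    return matrix, kept, rejections


def feature_names() -> list[str]:
    """Human-readable names for all 46 digits (s1..s45 + aromatic count)."""
    names = [fd.name for fd in load_feature_table()]
    names.append("aromatic atom count")
    return names
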