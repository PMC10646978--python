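"""Molecule ingestion, SELFIES/one-hot representation, fingerprints and
similarity analytics shared by every other module.

Molecules are identified by canonical SMILES of the full (possibly
multi-component) entity.  Salts and co-crystals are split on the SMILES dot,
each component is tokenized to SELFIES separately, and the per-component
token lists are joined with a reserved ``[LINK]`` token.  Components are
sorted by descending heavy-atom count so input salt order never changes the
representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs

from immunoloop._vendor import selfies as sf

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

LINK_TOKEN = "[LINK]"
PAD_TOKEN = "[PAD]"


class ConfigurationError(ValueError):
    """A required column or setting is missing."""


class InputError(ValueError):
    """Input data unusable (e.g. zero parseable rows, empty reference set)."""


class EncodingError(ValueError):
    """A molecule could not be encoded in the requested representation."""


class DimensionError(ValueError):
    """Vector shapes disagree."""


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a (possibly multi-component) SMILES. Raises on parse failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _sorted_components(smiles: str) -> list[str]:
    """Component SMILES sorted by descending heavy-atom count (ties: lexicographic)."""
    comps = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise EncodingError(f"unparseable component {part!r} of {smiles!r}")
        comps.append((mol.GetNumHeavyAtoms(), Chem.MolToSmiles(mol)))
    comps.sort(key=lambda t: (-t[0], t[1]))
    return [smi for _, smi in comps]


def encode_selfies(components: Sequence[str]) -> list[str]:
    """Per-component SELFIES token lists joined with :data:`LINK_TOKEN`."""
    tokens: list[str] = []
    for i, comp in enumerate(components):
        try:
            s = sf.encoder(comp)
        except Exception as exc:  # selfies raises EncoderError subclasses
            raise EncodingError(f"component {i} ({comp!r}) not SELFIES-encodable: {exc}")
        if i > 0:
            tokens.append(LINK_TOKEN)
        tokens.extend(sf.split_selfies(s))
    return tokens


def decode_selfies(tokens: Sequence[str]) -> str:
    """Invert :func:`encode_selfies`; returns the canonical multi-component SMILES."""
    parts: list[list[str]] = [[]]
    for tok in tokens:
        if tok == PAD_TOKEN:
            continue
        if tok == LINK_TOKEN:
            parts.append([])
        else:
            parts[-1].append(tok)
    smis = [sf.decoder("".join(p)) for p in parts if p]
    return canonical_smiles(".".join(smis))


@dataclass
class Molecule:
    """One candidate: identity, canonical SMILES, components, SELFIES tokens."""

    id: str
    smiles: str
    components: list[str]
    selfies_tokens: Optional[list[str]]
    vendor: Optional[str] = None
    selfies_error: Optional[str] = None

    @classmethod
    def from_smiles(cls, mol_id: str, smiles: str, vendor: Optional[str] = None) -> "Molecule":
        comps = _sorted_components(smiles)
        canon = canonical_smiles(".".join(comps))
        tokens: Optional[list[str]] = None
        err: Optional[str] = None
        try:
            tokens = encode_selfies(comps)
        except EncodingError as exc:
            err = str(exc)
        return cls(id=mol_id, smiles=canon, components=comps,
                   selfies_tokens=tokens, vendor=vendor, selfies_error=err)

    @property
    def encodable(self) -> bool:
        return self.selfies_tokens is not None


@dataclass
class TokenVocabulary:
    """Ordered unique token list (incl. LINK and PAD) + padded sequence length."""

    tokens: list[str]
    max_len: int
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ConfigurationError("vocabulary tokens not unique")
        self._index = {t: i for i, t in enumerate(self.tokens)}

    @classmethod
    def from_molecules(cls, molecules: Iterable[Molecule]) -> "TokenVocabulary":
        seen: dict[str, None] = {}
        max_len = 0
        for m in molecules:
            if m.selfies_tokens is None:
                continue
            for t in m.selfies_tokens:
                seen.setdefault(t, None)
            max_len = max(max_len, len(m.selfies_tokens))
        toks = sorted(seen)
        for special in (LINK_TOKEN, PAD_TOKEN):
            if special not in seen:
                toks.append(special)
        return cls(tokens=toks, max_len=max_len)

    def __len__(self) -> int:
        return len(self.tokens)

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise EncodingError(f"out-of-vocabulary token {token!r}")

    @property
    def pad_index(self) -> int:
        return self._index[PAD_TOKEN]

    def to_indices(self, tokens: Sequence[str], pad: bool = True) -> np.ndarray:
        idx = [self.index(t) for t in tokens]
        if pad:
            if len(idx) > self.max_len:
                raise EncodingError(
                    f"sequence length {len(idx)} exceeds max_len {self.max_len}")
            idx = idx + [self.pad_index] * (self.max_len - len(idx))
        return np.asarray(idx, dtype=np.int64)

    def from_indices(self, indices: Sequence[int], strip_pad: bool = True) -> list[str]:
        toks = [self.tokens[int(i)] for i in indices]
        if strip_pad:
            toks = [t for t in toks if t != PAD_TOKEN]
        return toks


@dataclass
class CandidateLibrary:
    """All candidates plus the tested/untested partition."""

    molecules: list[Molecule]
    tested_ids: set[str] = field(default_factory=set)
    rejects: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.id: m for m in self.molecules}
        if len(self._by_id) != len(self.molecules):
            raise InputError("duplicate molecule ids in library")

    def __len__(self) -> int:
        return len(self.molecules)

    def __contains__(self, mol_id: str) -> bool:
        return mol_id in self._by_id

    def get(self, mol_id: str) -> Molecule:
        return self._by_id[mol_id]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]

    @property
    def untested_ids(self) -> set[str]:
        return set(self._by_id) - self.tested_ids

    def mark_tested(self, ids: Iterable[str]) -> None:
        ids = set(ids)
        unknown = ids - set(self._by_id)
        if unknown:
            raise InputError(f"unknown molecule ids marked tested: {sorted(unknown)[:5]}")
        self.tested_ids |= ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids,
             "smiles": [m.smiles for m in self.molecules],
             "vendor": [m.vendor for m in self.molecules]})


def load_library(path, smiles_column: str = "smiles",
                 id_column: Optional[str] = "id",
                 vendor_column: Optional[str] = "vendor") -> CandidateLibrary:
    """Load a candidate library from a CSV of SMILES.

    Rows whose SMILES fail to parse are logged and counted in
    ``library.rejects`` rather than silently dropped.  Ids are generated
    deterministically from row order (``MOL-<row>``) when the id column is
    absent.
    """
    df = pd.read_csv(path, dtype=str)
    if smiles_column not in df.columns:
        raise ConfigurationError(
            f"SMILES column {smiles_column!r} not in {list(df.columns)}")
    have_id = id_column is not None and id_column in df.columns
    have_vendor = vendor_column is not None and vendor_column in df.columns

    molecules: list[Molecule] = []
    rejects: list[dict] = []
    for row_no, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, smiles_column) if hasattr(row, smiles_column) else df.iloc[row_no][smiles_column]
        smiles = None if raw is None else str(raw)
        mol_id = str(df.iloc[row_no][id_column]) if have_id else f"MOL-{row_no:06d}"
        vendor = str(df.iloc[row_no][vendor_column]) if have_vendor else None
        try:
            if smiles is None or smiles == "nan" or not smiles.strip():
                raise EncodingError("empty SMILES")
            molecules.append(Molecule.from_smiles(mol_id, smiles, vendor))
        except EncodingError as exc:
            rejects.append({"row": row_no, "id": mol_id, "smiles": smiles,
                            "reason": str(exc)})
            logger.warning("rejected row %d (%s): %s", row_no, mol_id, exc)
    if not molecules:
        raise InputError(f"no parseable SMILES rows in {path}")
    return CandidateLibrary(molecules=molecules, rejects=rejects)


def to_selfies(m: Molecule) -> list[str]:
    """SELFIES token sequence of a molecule (LINK-joined components)."""
    if m.selfies_tokens is None:
        raise EncodingError(f"{m.id}: {m.selfies_error}")
    return list(m.selfies_tokens)


def one_hot_encode(m: Molecule, vocab: TokenVocabulary) -> np.ndarray:
    """Flat binary vector of length ``max_len * |tokens|`` (PAD fills the tail)."""
    idx = vocab.to_indices(to_selfies(m), pad=True)
    out = np.zeros((vocab.max_len, len(vocab)), dtype=np.float64)
    out[np.arange(vocab.max_len), idx] = 1.0
    return out.ravel()


def one_hot_decode(vec: np.ndarray, vocab: TokenVocabulary) -> list[str]:
    """Inverse of :func:`one_hot_encode`: recover the (unpadded) token sequence."""
    mat = np.asarray(vec).reshape(vocab.max_len, len(vocab))
    return vocab.from_indices(mat.argmax(axis=1), strip_pad=True)


def _as_mol(m) -> Chem.Mol:
    smiles = m.smiles if isinstance(m, Molecule) else str(m)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EncodingError(f"unparseable SMILES: {smiles!r}")
    return mol


def ecfp4_fingerprint(m, n_bits: int = 2048) -> np.ndarray:
    """2048-bit (default) ECFP4 (Morgan radius-2) fingerprint as a uint8 array.

    Multi-component molecules are fingerprinted as the single combined entity.
    """
    bv = AllChem.GetMorganFingerprintAsBitVect(_as_mol(m), radius=2, nBits=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|.  Both all-zero -> 1.0 (documented convention)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise DimensionError(f"fingerprint lengths differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def nearest_training_similarity(query_set: Sequence[Molecule],
                                reference_set: Sequence[Molecule],
                                n_bits: int = 2048) -> pd.DataFrame:
    """Per query: max Tanimoto similarity to the reference set and the argmax id.

    Vectorized over the packed fingerprint matrices; ties resolved to the
    first reference in input order.
    """
    if len(query_set) == 0 or len(reference_set) == 0:
        raise InputError("query and reference sets must be non-empty")
    Q = np.stack([ecfp4_fingerprint(m, n_bits) for m in query_set]).astype(np.float64)
    R = np.stack([ecfp4_fingerprint(m, n_bits) for m in reference_set]).astype(np.float64)
    inter = Q @ R.T
    union = Q.sum(1)[:, None] + R.sum(1)[None, :] - inter
    sim = np.where(union == 0, 1.0, inter / np.where(union == 0, 1.0, union))
    best = sim.argmax(axis=1)
    return pd.DataFrame({
        "query_id": [m.id for m in query_set],
        "similarity": sim[np.arange(len(query_set)), best],
        "reference_id": [reference_set[j].id for j in best],
    })
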