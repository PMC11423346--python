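"""Domain records, entity registries, and tabular readers/writers.

The pipeline exchanges three tab-separated tables:

* molecule table   — columns ``mol_id``, and ``smiles`` and/or ``fingerprint``
  (a 0/1 string, one character per bit);
* protein table    — columns ``prot_id``, ``sequence``;
* interaction table — columns ``mol_id``, ``prot_id``, ``label`` with labels
  in {+1, -1}.

A single "wide" table carrying all five columns is also accepted.  Entity
order is always first-appearance order in the file, never hash order, so
index assignment is reproducible across runs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    IntegrityError,
    LabelError,
    SchemaError,
    StructureError,
)

#: 20 standard amino acids plus the ambiguity/rare letters accepted on input.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AMINO_ACIDS = AMINO_ACIDS + "BZXUO"


@dataclasses.dataclass
class MoleculeRecord:
    """A small molecule: identifier plus structure.

    Either ``smiles`` or a precomputed binary ``fingerprint`` must be
    present; both may be.  Fingerprints are fixed-length 0/1 vectors
    (1024 bits by default across the package).
    """

    mol_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    mol_weight: float | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.uint8)
            if fp.ndim != 1:
                raise ValueError("fingerprint must be a 1-D bit vector")
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"fingerprint of {self.mol_id!r} has bits outside {{0,1}}")
            self.fingerprint = fp
        if self.smiles is None and self.fingerprint is None:
            raise ValueError(f"molecule {self.mol_id!r} has neither SMILES nor fingerprint")


@dataclasses.dataclass
class ProteinRecord:
    """A protein: identifier plus primary amino-acid sequence."""

    prot_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.prot_id!r} has an empty sequence")
        bad = set(self.sequence.upper()) - set(EXTENDED_AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"protein {self.prot_id!r} contains letters outside the amino-acid "
                f"alphabet: {sorted(bad)}"
            )
        self.sequence = self.sequence.upper()


class Registry:
    """Ordered, id-unique collection of entity records.

    Insertion order defines the integer index of each entity; repeated
    insertion of an identical record is a no-op, while an id reused with a
    different structure raises :class:`IntegrityError`.
    """

    def __init__(self, records: Iterable | None = None):
        self._records: list = []
        self._index: dict[str, int] = {}
        for r in records or ():
            self.add(r)

    @staticmethod
    def _key(record) -> str:
        return record.mol_id if isinstance(record, MoleculeRecord) else record.prot_id

    @staticmethod
    def _same_structure(a, b) -> bool:
        if isinstance(a, ProteinRecord):
            return a.sequence == b.sequence
        if (a.smiles is not None) and (b.smiles is not None) and a.smiles != b.smiles:
            return False
        if a.fingerprint is not None and b.fingerprint is not None:
            return bool(np.array_equal(a.fingerprint, b.fingerprint))
        return True

    def add(self, record) -> int:
        key = self._key(record)
        if key in self._index:
            idx = self._index[key]
            if not self._same_structure(self._records[idx], record):
                raise IntegrityError(
                    f"entity {key!r} appears with two different structures"
                )
            return idx
        self._index[key] = len(self._records)
        self._records.append(record)
        return self._index[key]

    def index_of(self, key: str) -> int:
        return self._index[key]

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i: int):
        return self._records[i]

    def __iter__(self):
        return iter(self._records)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    @property
    def ids(self) -> list[str]:
        return [self._key(r) for r in self._records]


@dataclasses.dataclass
class InteractionSet:
    """Indexed (molecule, protein, label) triples over two registries."""

    molecules: Registry
    proteins: Registry
    mol_idx: np.ndarray  # int array, len n_Z
    prot_idx: np.ndarray  # int array, len n_Z
    labels: np.ndarray  # +1/-1 array, len n_Z

    def __post_init__(self) -> None:
        self.mol_idx = np.asarray(self.mol_idx, dtype=np.int64)
        self.prot_idx = np.asarray(self.prot_idx, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.mol_idx) == len(self.prot_idx) == len(self.labels)):
            raise ValueError("triple arrays must share a length")
        if len(self.mol_idx) and (
            self.mol_idx.min() < 0 or self.mol_idx.max() >= len(self.molecules)
        ):
            raise ValueError("molecule index out of range")
        if len(self.prot_idx) and (
            self.prot_idx.min() < 0 or self.prot_idx.max() >= len(self.proteins)
        ):
            raise ValueError("protein index out of range")
        if len(self.labels) and not np.isin(self.labels, (-1, 1)).all():
            raise LabelError("labels must be +1 or -1")
        seen: dict[tuple[int, int], int] = {}
        for i, j, y in zip(self.mol_idx, self.prot_idx, self.labels):
            prev = seen.setdefault((int(i), int(j)), int(y))
            if prev != y:
                mol = self.molecules[int(i)].mol_id
                prot = self.proteins[int(j)].prot_id
                raise IntegrityError(
                    f"pair ({mol!r}, {prot!r}) appears with conflicting labels"
                )

    @property
    def n_M(self) -> int:
        return len(self.molecules)

    @property
    def n_P(self) -> int:
        return len(self.proteins)

    @property
    def n_Z(self) -> int:
        return len(self.labels)

    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.mol_idx.tolist(), self.prot_idx.tolist()))

    def subset(self, mask: np.ndarray) -> "InteractionSet":
        """New set over the *same* registries, keeping triples where mask."""
        mask = np.asarray(mask, dtype=bool)
        return InteractionSet(
            self.molecules, self.proteins,
            self.mol_idx[mask], self.prot_idx[mask], self.labels[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_id": [self.molecules[i].mol_id for i in self.mol_idx],
                "prot_id": [self.proteins[j].prot_id for j in self.prot_idx],
                "label": self.labels,
            }
        )


@dataclasses.dataclass
class PredictionTable:
    """Scored (molecule, protein) pairs.

    ``predicted_label`` is the sign of the margin with ties at exactly 0
    classified as +1.  ``probability`` columns exist only when the model
    carried Platt parameters.
    """

    mol_ids: list[str]
    prot_ids: list[str]
    scores: np.ndarray
    probabilities: np.ndarray | None = None

    @property
    def predicted_labels(self) -> np.ndarray:
        # sign(0) -> +1 by package convention
        return np.where(np.asarray(self.scores) >= 0, 1, -1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mol_id": self.mol_ids,
                "prot_id": self.prot_ids,
                "score": np.asarray(self.scores, dtype=float),
                "probability": (
                    np.asarray(self.probabilities, dtype=float)
                    if self.probabilities is not None
                    else np.full(len(self.mol_ids), np.nan)
                ),
                "label": self.predicted_labels,
            }
        )
        return df


# ---------------------------------------------------------------------------
# label coercion


def coerce_label(raw) -> int:
    """Map a raw table cell to +1/-1; 0 and anything else is rejected."""
    s = str(raw).strip()
    if s in {"+1", "1", "1.0", "+1.0"}:
        return 1
    if s in {"-1", "-1.0"}:
        return -1
    raise LabelError(f"label {raw!r} is not in {{+1, -1}} (0 is rejected, not coerced)")


# ---------------------------------------------------------------------------
# fingerprinting backends


def _parse_bitstring(s: str, n_bits: int) -> np.ndarray:
    s = s.strip()
    if len(s) != n_bits or set(s) - {"0", "1"}:
        raise StructureError(
            f"fingerprint string must be {n_bits} characters of 0/1, got {s[:32]!r}..."
            if len(s) > 32
            else f"fingerprint string must be {n_bits} characters of 0/1, got {s!r}"
        )
    return np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")


def fingerprint_molecule(
    smiles: str,
    n_bits: int = 1024,
    radius: int = 2,
    backend: str = "rdkit",
) -> np.ndarray:
    """Morgan (ECFP) fingerprint of a molecule as a 0/1 vector.

    ``radius=2`` with 1024 bits is the ECFP4 encoding used throughout the
    package.  Two backends exist: ``"rdkit"`` computes the fingerprint from
    the SMILES with RDKit; ``"passthrough"`` interprets ``smiles`` as a
    literal 0/1 bit string, so the math core is exercisable without a
    chemistry toolkit.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if backend == "passthrough":
        return _parse_bitstring(smiles, n_bits)
    if backend == "rdkit":
        try:
            from rdkit import Chem, RDLogger
            from rdkit.Chem import rdFingerprintGenerator
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ConfigurationError(
                "RDKit backend requested but rdkit is not importable; "
                "supply precomputed fingerprints or use backend='passthrough'"
            ) from exc
        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureError(f"unparsable SMILES: {smiles!r}")
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        fp = gen.GetFingerprintAsNumPy(mol)
        return fp.astype(np.uint8)
    raise ConfigurationError(f"unknown fingerprint backend {backend!r}")


def molecular_weight(smiles: str) -> float:
    """Average molecular weight in g/mol computed from the SMILES."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Descriptors
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "molecular weight requires rdkit; supply a mol_weight column instead"
        ) from exc
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES: {smiles!r}")
    return float(Descriptors.MolWt(mol))


# ---------------------------------------------------------------------------
# readers / writers

_SEP = {"tsv": "\t", "csv": ","}


def _read_table(path, fmt: str) -> pd.DataFrame:
    if fmt not in _SEP:
        raise ConfigurationError(f"unknown table format {fmt!r}; expected tsv or csv")
    return pd.read_csv(path, sep=_SEP[fmt], dtype=str, keep_default_na=False)


def _require(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{path}: missing required column {c!r}")


def _molecule_from_row(row, n_bits: int) -> MoleculeRecord:
    smiles = row.get("smiles") or None
    fp = None
    raw_fp = row.get("fingerprint")
    if raw_fp:
        fp = _parse_bitstring(raw_fp, len(raw_fp.strip()))
    mw = row.get("mol_weight")
    return MoleculeRecord(
        mol_id=row["mol_id"],
        smiles=smiles,
        fingerprint=fp,
        mol_weight=float(mw) if mw not in (None, "") else None,
    )


def read_molecules(path, fmt: str = "tsv", n_bits: int = 1024) -> Registry:
    """Read a molecule table into a registry (first-appearance order)."""
    df = _read_table(path, fmt)
    _require(df, ["mol_id"], path)
    if "smiles" not in df.columns and "fingerprint" not in df.columns:
        raise SchemaError(f"{path}: need a 'smiles' or 'fingerprint' column")
    reg = Registry()
    for _, row in df.iterrows():
        reg.add(_molecule_from_row(row, n_bits))
    return reg


def read_proteins(path, fmt: str = "tsv") -> Registry:
    df = _read_table(path, fmt)
    _require(df, ["prot_id", "sequence"], path)
    reg = Registry()
    for _, row in df.iterrows():
        reg.add(ProteinRecord(prot_id=row["prot_id"], sequence=row["sequence"]))
    return reg


def read_interactions(
    path,
    fmt: str = "tsv",
    molecules: Registry | str | Path | None = None,
    proteins: Registry | str | Path | None = None,
) -> InteractionSet:
    """Read an interaction table into an :class:`InteractionSet`.

    The table must carry ``mol_id``, ``prot_id`` and ``label``.  Entity
    structures come either from ``smiles``/``fingerprint``/``sequence``
    columns in the same file, or from separate molecule/protein tables
    passed (as registries or paths) via ``molecules`` / ``proteins``.
    """
    df = _read_table(path, fmt)
    _require(df, ["mol_id", "prot_id", "label"], path)

    if isinstance(molecules, (str, Path)):
        molecules = read_molecules(molecules, fmt)
    if isinstance(proteins, (str, Path)):
        proteins = read_proteins(proteins, fmt)

    inline_mols = "smiles" in df.columns or "fingerprint" in df.columns
    inline_prots = "sequence" in df.columns
    if molecules is None and not inline_mols:
        raise SchemaError(
            f"{path}: no molecule structures — add smiles/fingerprint columns "
            "or pass a molecule table"
        )
    if proteins is None and not inline_prots:
        raise SchemaError(
            f"{path}: no protein sequences — add a sequence column or pass a "
            "protein table"
        )

    mol_reg = molecules if molecules is not None else Registry()
    prot_reg = proteins if proteins is not None else Registry()
    mol_idx, prot_idx, labels = [], [], []
    for _, row in df.iterrows():
        if molecules is None:
            i = mol_reg.add(_molecule_from_row(row, 1024))
        else:
            if row["mol_id"] not in mol_reg:
                raise IntegrityError(f"unknown mol_id {row['mol_id']!r} in {path}")
            i = mol_reg.index_of(row["mol_id"])
        if proteins is None:
            j = prot_reg.add(ProteinRecord(row["prot_id"], row["sequence"]))
        else:
            if row["prot_id"] not in prot_reg:
                raise IntegrityError(f"unknown prot_id {row['prot_id']!r} in {path}")
            j = prot_reg.index_of(row["prot_id"])
        mol_idx.append(i)
        prot_idx.append(j)
        labels.append(coerce_label(row["label"]))
    return InteractionSet(mol_reg, prot_reg, np.array(mol_idx, dtype=np.int64),
                          np.array(prot_idx, dtype=np.int64),
                          np.array(labels, dtype=np.int64))


def write_interactions(dataset: InteractionSet, path, fmt: str = "tsv") -> None:
    dataset.to_frame().to_csv(path, sep=_SEP[fmt], index=False)


def write_molecules(reg: Registry, path, fmt: str = "tsv") -> None:
    rows = []
    for m in reg:
        rows.append(
            {
                "mol_id": m.mol_id,
                "smiles": m.smiles or "",
                "fingerprint": (
                    "".join(map(str, m.fingerprint.tolist()))
                    if m.fingerprint is not None
                    else ""
                ),
            }
        )
    pd.DataFrame(rows, columns=["mol_id", "smiles", "fingerprint"]).to_csv(
        path, sep=_SEP[fmt], index=False
    )


def write_proteins(reg: Registry, path, fmt: str = "tsv") -> None:
    pd.DataFrame(
        [{"prot_id": p.prot_id, "sequence": p.sequence} for p in reg],
        columns=["prot_id", "sequence"],
    ).to_csv(path, sep=_SEP[fmt], index=False)


def write_predictions(table: PredictionTable, path) -> None:
    """Write a prediction table as TSV.

    Floats are rendered with 17 significant digits so that the companion
    reader round-trips scores bit-exactly.
    """
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path) -> PredictionTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"mol_id": str, "prot_id": str},
        float_precision="round_trip",
    )
    probs = df["probability"].to_numpy(dtype=float)
    return PredictionTable(
        mol_ids=df["mol_id"].tolist(),
        prot_ids=df["prot_id"].tolist(),
        scores=df["score"].to_numpy(dtype=float),
        probabilities=None if np.isnan(probs).all() else probs,
    )


def fingerprint_matrix(molecules: Registry, n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Stack fingerprints of a molecule registry into an (n, n_bits) array.

    Molecules without a stored fingerprint are fingerprinted from their
    SMILES with the RDKit backend.
    """
    rows = []
    for m in molecules:
        if m.fingerprint is not None:
            rows.append(m.fingerprint)
        elif m.smiles is not None:
            rows.append(fingerprint_molecule(m.smiles, n_bits=n_bits, radius=radius))
        else:  # unreachable: MoleculeRecord enforces one of the two
            raise ConfigurationError(f"molecule {m.mol_id!r} has no structure")
    mat = np.asarray(rows, dtype=np.uint8)
    if mat.ndim != 2:
        raise ValueError("fingerprint lengths differ across the registry")
    return mat
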