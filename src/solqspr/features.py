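"""2D molecular descriptors, descriptor-cleanup rules, standard scaling and
Morgan fingerprints.

The default descriptor panel ("rdkit2d") is the full RDKit 2D descriptor
list (Crippen logP/MR, Lipinski counts, topological/graph indices, surface
area terms, QED, fragment counts, ...), roughly 200 descriptors.  Cleanup
removes (a) anything whose name suggests it encodes solubility itself,
(b) columns with Boolean/string outputs and (c) any column that is
missing/non-finite for at least one molecule, so every molecule ends up
described by the same set of valid numeric descriptors.  Exact column
counts depend on the toolkit version and are logged, not asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from .curation import MoleculeRecord

__all__ = [
    "FeatureMatrix",
    "Fingerprint",
    "Scaler",
    "PANELS",
    "register_panel",
    "compute_descriptors",
    "fit_scaler",
    "apply_scaler",
    "morgan_fp",
    "align_to",
]

# names that directly represent a definition of solubility are blocked
# (case-insensitive substring match)
SOLUBILITY_BLOCKLIST = ("solubility", "logs", "esol")

FP_RADIUS = 2
FP_NBITS = 2048


@dataclass(frozen=True)
class FeatureMatrix:
    """Molecules x named descriptors, dense and fully finite."""

    ids: tuple[str, ...]
    names: tuple[str, ...]
    values: np.ndarray
    dropped: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.ids), len(self.names)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.ids)} ids x {len(self.names)} descriptors"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate descriptor names")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("non-finite entries in feature matrix")

    @property
    def n_molecules(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.names))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dropped: Mapping[str, str] | None = None) -> "FeatureMatrix":
        return cls(
            ids=tuple(str(i) for i in df.index),
            names=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            dropped=dict(dropped or {}),
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path, index_col="id"))


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length Morgan (circular, radius 2) bitvector."""

    bits: tuple[int, ...]          # sorted indices of set bits
    nbits: int = FP_NBITS
    radius: int = FP_RADIUS

    def popcount(self) -> int:
        return len(self.bits)

    def to_hex(self) -> str:
        v = bytearray(self.nbits // 8)
        for b in self.bits:
            v[b // 8] |= 1 << (b % 8)
        return bytes(v).hex()


def _rdkit2d_panel() -> dict[str, Callable[[Chem.Mol], float]]:
    return {name: fn for name, fn in Descriptors.descList}


#: Registry of descriptor panels: name -> {descriptor name -> callable(mol)}.
PANELS: dict[str, Callable[[], dict[str, Callable[[Chem.Mol], float]]]] = {
    "rdkit2d": _rdkit2d_panel,
}


def register_panel(name: str, factory: Callable[[], dict[str, Callable[[Chem.Mol], float]]]) -> None:
    """Register a custom descriptor panel (e.g. a larger third-party set)."""
    PANELS[name] = factory


def compute_descriptors(
    records: Sequence[MoleculeRecord],
    panel: str = "rdkit2d",
) -> FeatureMatrix:
    """Compute a descriptor panel for standardized records and clean it up.

    Columns are dropped when the descriptor name matches the solubility
    blocklist, when any molecule yields a Boolean/str output, or when any
    molecule yields a missing/non-finite value or raises.  The drop log is
    attached to the returned matrix.
    """
    if not records:
        raise ValueError("no records to featurize")
    if panel not in PANELS:
        raise KeyError(f"unknown descriptor panel {panel!r}; known: {sorted(PANELS)}")
    funcs = PANELS[panel]()

    dropped: dict[str, str] = {}
    names: list[str] = []
    for name in funcs:
        if any(b in name.lower() for b in SOLUBILITY_BLOCKLIST):
            dropped[name] = "solubility-blocklist"
        else:
            names.append(name)

    mols = [r.mol() for r in records]
    cols: dict[str, np.ndarray] = {}
    for name in names:
        fn = funcs[name]
        vals = np.empty(len(mols))
        reason = None
        for i, m in enumerate(mols):
            try:
                v = fn(m)
            except Exception:
                reason = "invalid-output"
                break
            if isinstance(v, bool) or isinstance(v, str):
                reason = "non-numeric-output"
                break
            try:
                vals[i] = float(v)
            except (TypeError, ValueError):
                reason = "non-numeric-output"
                break
            if not np.isfinite(vals[i]):
                reason = "non-finite-output"
                break
        if reason is None:
            cols[name] = vals
        else:
            dropped[name] = reason

    if not cols:
        raise ValueError(f"all descriptors dropped; reasons: {dropped}")
    kept = sorted(cols)
    values = np.column_stack([cols[n] for n in kept])
    return FeatureMatrix(
        ids=tuple(r.id for r in records),
        names=tuple(kept),
        values=values,
        dropped=dropped,
    )


@dataclass(frozen=True)
class Scaler:
    """Per-descriptor mean/SD learned on a training matrix.

    Uses the population (divide-by-N) SD.  Zero-variance columns are
    dropped at fit time and listed in ``dropped_constant``.
    """

    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    dropped_constant: tuple[str, ...] = ()


def fit_scaler(train: FeatureMatrix) -> Scaler:
    if train.n_molecules == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    mean = train.values.mean(axis=0)
    sd = train.values.std(axis=0)  # population SD
    keep = sd > 0
    return Scaler(
        names=tuple(n for n, k in zip(train.names, keep) if k),
        mean=mean[keep],
        sd=sd[keep],
        dropped_constant=tuple(n for n, k in zip(train.names, keep) if not k),
    )


def apply_scaler(scaler: Scaler, m: FeatureMatrix) -> FeatureMatrix:
    """Transform a matrix with training statistics only."""
    missing = [n for n in scaler.names if n not in m.names]
    if missing:
        raise ValueError(f"matrix lacks columns known to the scaler: {missing}")
    idx = [m.names.index(n) for n in scaler.names]
    vals = (m.values[:, idx] - scaler.mean) / scaler.sd
    return FeatureMatrix(ids=m.ids, names=scaler.names, values=vals, dropped=m.dropped)


def align_to(m: FeatureMatrix, columns: Sequence[str]) -> FeatureMatrix:
    """Project a matrix onto a required column set, in that order."""
    missing = [c for c in columns if c not in m.names]
    if missing:
        raise ValueError(f"matrix lacks required columns: {missing}")
    idx = [m.names.index(c) for c in columns]
    return FeatureMatrix(ids=m.ids, names=tuple(columns), values=m.values[:, idx])


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


def morgan_fp(record: MoleculeRecord | Chem.Mol) -> Fingerprint:
    """Morgan fingerprint, radius 2, 2048 bits."""
    mol = record.mol() if isinstance(record, MoleculeRecord) else record
    bv = _FP_GEN.GetFingerprint(mol)
    return Fingerprint(bits=tuple(sorted(bv.GetOnBits())))


def rdkit_bitvect(fp: Fingerprint) -> DataStructs.ExplicitBitVect:
    bv = DataStructs.ExplicitBitVect(fp.nbits)
    for b in fp.bits:
        bv.SetBit(b)
    return bv


def descriptor_matrix_for(
    records: Sequence[MoleculeRecord],
    columns: Sequence[str],
    panel: str = "rdkit2d",
) -> tuple[FeatureMatrix, list[str]]:
    """Compute exactly the named descriptors for new molecules.

    Used at prediction time, when the model's training columns are fixed.
    Molecules for which any required descriptor is non-finite are dropped
    and their ids returned alongside the matrix.
    """
    funcs = PANELS[panel]()
    missing = [c for c in columns if c not in funcs]
    if missing:
        raise ValueError(f"panel {panel!r} lacks descriptors: {missing}")
    rows, ids, skipped = [], [], []
    for r in records:
        m = r.mol()
        vals = []
        ok = True
        for c in columns:
            try:
                v = float(funcs[c](m))
            except Exception:
                ok = False
                break
            if not np.isfinite(v):
                ok = False
                break
            vals.append(v)
        if ok:
            rows.append(vals)
            ids.append(r.id)
        else:
            skipped.append(r.id)
    if not rows:
        raise ValueError("no molecule had finite values for all required descriptors")
    return (
        FeatureMatrix(ids=tuple(ids), names=tuple(columns), values=np.asarray(rows, dtype=float)),
        skipped,
    )
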