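"""Data set curation: SMILES standardization, salt stripping, deduplication
and drug-likeness filters.

The curation pipeline mirrors common practice for assembling intrinsic
aqueous solubility training sets from heterogeneous literature sources:

* SMILES are validated by parsing; unparseable entries are rejected.
* Salts are neutralized by removing the lowest-molecular-weight counterion
  component (sodium, chloride, ...) and neutralizing the charge left on the
  parent; multi-component entries whose extra components are not recognized
  counterions (solvates, true mixtures) are rejected outright.
* The tautomer written in the input SMILES is preserved.
* Duplicates are identified by standard InChI; the first occurrence wins.
* Very small (heavy atoms < 4), very large (MW > 1400) and very flexible
  (rotatable bonds > 20) molecules are removed; boundary values survive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MoleculeRecord",
    "Rejection",
    "CurationReport",
    "standardize",
    "deduplicate",
    "apply_filters",
    "curate",
]


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated molecule.

    ``smiles`` is canonical and single-component, ``inchi`` the standard
    InChI derived from it, ``logS`` the experimental log10 molar intrinsic
    solubility at 298 K (may be NaN for structure-only records), ``source``
    a free-text provenance tag.
    """

    id: str
    smiles: str
    inchi: str
    logS: float = float("nan")
    source: str = ""
    salt_stripped: bool = False
    has_formal_charge: bool = False

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.smiles)
        if m is None:  # pragma: no cover - invariant of construction
            raise ValueError(f"stored SMILES no longer parses: {self.smiles!r}")
        return m


@dataclass(frozen=True)
class Rejection:
    id: str
    raw_smiles: str
    reason: str  # unparseable | multicomponent | small | large | flexible


@dataclass
class CurationReport:
    """Record-count bookkeeping for one curation run.

    Invariant: ``input == retained + rejected_* + deduplicated``.
    """

    n_input: int = 0
    rejected_unparseable: int = 0
    rejected_multicomponent: int = 0
    salt_stripped: int = 0
    deduplicated: int = 0
    rejected_small: int = 0
    rejected_large: int = 0
    rejected_flexible: int = 0
    retained: int = 0
    retained_with_formal_charge: int = 0
    rejections: list = field(default_factory=list)

    def check_conservation(self) -> None:
        total = (
            self.retained
            + self.rejected_unparseable
            + self.rejected_multicomponent
            + self.rejected_small
            + self.rejected_large
            + self.rejected_flexible
            + self.deduplicated
        )
        if total != self.n_input:
            raise AssertionError(
                f"curation does not conserve records: input={self.n_input}, accounted={total}"
            )

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "rejections"}
        d["rejections"] = [r.__dict__ for r in self.rejections]
        return json.dumps(d, indent=2)


# Counterions recognized for salt stripping, as canonical SMILES.  If every
# extra component of a multi-component entry is on this list, the lowest-MW
# components are stripped and the surviving parent neutralized; otherwise
# the entry is treated as a solvate/mixture and rejected.
_COUNTERION_SMILES = [
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]",
    "[Cl-]", "[Br-]", "[I-]", "[F-]",
    "[O-]S(=O)(=O)[O-]", "OS(=O)(=O)[O-]",        # sulfate / bisulfate
    "[N+](=O)([O-])[O-]", "[O-][N+](=O)[O-]",     # nitrate spellings
    "CC(=O)[O-]",                                  # acetate as counterion
    "[NH4+]",
]
_COUNTERIONS = {Chem.CanonSmiles(s) for s in _COUNTERION_SMILES}


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Zero out formal charges left behind by counterion removal.

    Protonates anions and deprotonates cations where a hydrogen can be
    added/removed; quaternary nitrogens and other uncorrectable charges are
    left in place.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        hs = atom.GetTotalNumHs()
        if q > 0 and hs >= q:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(hs - q, 0))
            atom.SetNoImplicit(True)
        elif q < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(hs - q)
            atom.SetNoImplicit(True)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize(
    raw_smiles: str,
    id: str = "",
    logS: float = float("nan"),
    source: str = "",
) -> MoleculeRecord | Rejection:
    """Validate and standardize one raw SMILES string.

    Returns a single-component :class:`MoleculeRecord` or a
    :class:`Rejection` with reason ``unparseable`` or ``multicomponent``.
    The tautomer of the input is preserved; only salt components are
    removed and the resulting charge neutralized.
    """
    if not raw_smiles or not raw_smiles.strip():
        return Rejection(id=id, raw_smiles=raw_smiles, reason="unparseable")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection(id=id, raw_smiles=raw_smiles, reason="unparseable")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    stripped = False
    if len(frags) > 1:
        # keep the heaviest component; everything else must be a recognized
        # counterion (the lowest-MW-component removal rule)
        frags = sorted(frags, key=Descriptors.MolWt)
        parent, others = frags[-1], frags[:-1]
        if any(Chem.MolToSmiles(f) not in _COUNTERIONS for f in others):
            return Rejection(id=id, raw_smiles=raw_smiles, reason="multicomponent")
        mol = _neutralize(parent)
        stripped = True

    smiles = Chem.MolToSmiles(mol)
    inchi = Chem.MolToInchi(Chem.MolFromSmiles(smiles))
    charged = any(a.GetFormalCharge() != 0 for a in mol.GetAtoms())
    return MoleculeRecord(
        id=id or smiles,
        smiles=smiles,
        inchi=inchi,
        logS=logS,
        source=source,
        salt_stripped=stripped,
        has_formal_charge=charged,
    )


def deduplicate(records: Iterable[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """Remove duplicate molecules by standard InChI, keeping first occurrences."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    removed = 0
    for r in records:
        if r.inchi in seen:
            removed += 1
        else:
            seen.add(r.inchi)
            out.append(r)
    return out, removed


# filter boundaries; rejection uses strict inequalities, boundary retained
MIN_HEAVY_ATOMS = 4
MAX_MOL_WEIGHT = 1400.0
MAX_ROTATABLE_BONDS = 20


def _filter_reason(mol: Chem.Mol) -> Optional[str]:
    if mol.GetNumHeavyAtoms() < MIN_HEAVY_ATOMS:
        return "small"
    if Descriptors.MolWt(mol) > MAX_MOL_WEIGHT:
        return "large"
    if rdMolDescriptors.CalcNumRotatableBonds(mol) > MAX_ROTATABLE_BONDS:
        return "flexible"
    return None


def apply_filters(
    records: Iterable[MoleculeRecord],
    report: Optional[CurationReport] = None,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the size/flexibility filters to standardized records.

    Retained records satisfy heavy atoms >= 4, MW <= 1400 and rotatable
    bonds <= 20.  A rejected record is tallied under the first matching
    reason in the order small, large, flexible.
    """
    records = list(records)
    if report is None:
        report = CurationReport(n_input=len(records))
    retained: list[MoleculeRecord] = []
    for r in records:
        reason = _filter_reason(r.mol())
        if reason is None:
            retained.append(r)
            if r.has_formal_charge:
                report.retained_with_formal_charge += 1
        else:
            setattr(report, f"rejected_{reason}", getattr(report, f"rejected_{reason}") + 1)
            report.rejections.append(Rejection(id=r.id, raw_smiles=r.smiles, reason=reason))
    report.salt_stripped += sum(r.salt_stripped for r in records)
    report.retained = len(retained)
    return retained, report


def curate(
    raw: Iterable[tuple[str, str, float, str]],
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Full pipeline: standardize -> deduplicate -> filter, with bookkeeping.

    ``raw`` yields (id, smiles, logS, source) tuples.  The returned report
    satisfies the record-conservation invariant.
    """
    raw = list(raw)
    report = CurationReport(n_input=len(raw))
    standardized: list[MoleculeRecord] = []
    for id_, smi, logS, source in raw:
        res = standardize(smi, id=id_, logS=logS, source=source)
        if isinstance(res, Rejection):
            setattr(report, f"rejected_{res.reason}", getattr(report, f"rejected_{res.reason}") + 1)
            report.rejections.append(res)
        else:
            standardized.append(res)
    deduped, removed = deduplicate(standardized)
    report.deduplicated = removed
    retained, report = apply_filters(deduped, report)
    report.check_conservation()
    return retained, report
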