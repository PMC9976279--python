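"""Standard-format I/O: molecule/prediction CSVs, run configuration and
run manifests.

The molecule CSV schema is fixed: UTF-8, header required, "." decimal,
columns ``id, smiles, logS, set_label`` plus ``truth_logS`` for synthetic
libraries.  Prediction CSVs carry ``id, y_exp, y_pred``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .curation import MoleculeRecord
from .stats import PredictionSet

__all__ = [
    "RunConfig",
    "read_molecule_csv",
    "write_molecule_csv",
    "read_predictions",
    "write_predictions",
    "write_manifest",
]

MOLECULE_COLUMNS = ("id", "smiles", "logS", "set_label")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    model_family: str = "rf"
    panel: str = "rdkit2d"
    n_resamples: int = 50
    test_frac: float = 0.30
    inner_k: int = 5
    noise_sigma: float = 0.17
    n_molecules: int = 300
    tanimoto_threshold: float = 0.5
    counterfactual_delta: float = 1.0
    cluster_threshold: float = 0.7
    min_heavy_atoms: int = 4
    max_mol_weight: float = 1400.0
    max_rotatable_bonds: int = 20
    grid: Optional[list] = None
    output_dir: str = "solqspr-out"
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must lie in (0, 1)")
        if not 0 < self.tanimoto_threshold <= 1:
            raise ValueError("tanimoto_threshold must lie in (0, 1]")
        if self.n_resamples < 1 or self.inner_k < 2:
            raise ValueError("n_resamples >= 1 and inner_k >= 2 required")
        if self.noise_sigma < 0 or self.counterfactual_delta < 0:
            raise ValueError("noise_sigma and counterfactual_delta must be >= 0")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_molecule_csv(
    path,
    records: Sequence[MoleculeRecord],
    set_label: str = "train",
    truth_logS: Optional[Sequence[float]] = None,
) -> None:
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "logS": [r.logS for r in records],
            "set_label": set_label,
        }
    )
    if truth_logS is not None:
        df["truth_logS"] = np.asarray(truth_logS, dtype=float)
    df.to_csv(path, index=False)


def read_molecule_csv(path) -> pd.DataFrame:
    """Read and schema-check a molecule CSV.

    Raises ValueError with row/column diagnostics on schema violations.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str, "set_label": str})
    missing = [c for c in MOLECULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[df["smiles"].isna() | (df["smiles"].astype(str).str.strip() == "")]
    if len(bad):
        raise ValueError(f"{path}: empty smiles at rows {list(bad[:10])}")
    if not pd.api.types.is_numeric_dtype(df["logS"]):
        coerced = pd.to_numeric(df["logS"], errors="coerce")
        bad = df.index[coerced.isna() & df["logS"].notna()]
        raise ValueError(f"{path}: non-numeric logS at rows {list(bad[:10])}")
    return df


def write_predictions(path, p: PredictionSet) -> None:
    pd.DataFrame({"id": list(p.ids), "y_exp": p.y_exp, "y_pred": p.y_calc}).to_csv(
        path, index=False
    )


def read_predictions(path) -> PredictionSet:
    df = pd.read_csv(path, dtype={"id": str})
    for c in ("id", "y_exp", "y_pred"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing prediction column {c!r}")
    return PredictionSet(ids=df["id"].tolist(), y_calc=df["y_pred"].to_numpy(), y_exp=df["y_exp"].to_numpy())


def write_manifest(out_dir, stage: str, config: RunConfig, inputs: dict) -> None:
    """Record stage provenance: inputs, config hash, seed, tool versions."""
    import sklearn
    import rdkit

    from . import __version__

    manifest = {
        "stage": stage,
        "inputs": inputs,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "solqspr": __version__,
            "rdkit": rdkit.__version__,
            "scikit-learn": sklearn.__version__,
            "numpy": np.__version__,
        },
    }
    Path(out_dir, f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))
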