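"""Reading predictor output trees and writing normalized score tables.

Real AlphaFold-Multimer deployments disagree about where confidence numbers
live (pickled result archives, ranking summaries, B-factor columns), so this
package defines one normalized per-model record and two on-disk dialects:

``confidence-json``
    One JSON sidecar per model:
    ``{"model_id": str, "iptm": float, "ptm": float, "plddt": [float, ...]}``.

``pdb-bfactor``
    One PDB or mmCIF model file per model with per-residue pLDDT stored as
    the B-factor of the residue's CA atom (first atom as fallback) — the
    standard AlphaFold convention — plus a companion JSON of the same stem
    carrying at least ``iptm`` and ``ptm``.

Converters from vendor binary archives are out of scope; the JSON schema is
the contract a site's harvest glue is expected to emit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.mmcifio import MMCIFIO
from Bio.PDB.PDBIO import PDBIO
from Bio.PDB.StructureBuilder import StructureBuilder

from .scoring import PairScore

__all__ = [
    "Dialect",
    "JobOutputHandle",
    "EmptyJobError",
    "DialectError",
    "read_job_outputs",
    "write_pair_scores",
    "read_pair_scores",
    "write_plddt_model",
]

Dialect = Literal["confidence-json", "pdb-bfactor"]

_MODEL_SUFFIXES = {".pdb": "pdb", ".cif": "cif"}


class EmptyJobError(RuntimeError):
    """A job directory holds no recognizable per-model record."""


class DialectError(ValueError):
    """A per-model record violates its dialect's schema."""


@dataclass(frozen=True)
class JobOutputHandle:
    """Locator for one prediction job's output directory."""

    job_id: str
    root: Path
    dialect: Dialect = "confidence-json"

    def __post_init__(self) -> None:
        object.__setattr__(self, "root", Path(self.root))
        if self.dialect not in ("confidence-json", "pdb-bfactor"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def bait_id(self) -> str:
        return self.job_id.split("__", 1)[0]

    @property
    def ligand_id(self) -> str:
        parts = self.job_id.split("__", 1)
        return parts[1] if len(parts) == 2 else ""


def _read_confidence_json(path: Path, *, require_plddt: bool) -> dict:
    with path.open() as fh:
        record = json.load(fh)
    for field in ("iptm", "ptm"):
        if field not in record:
            raise DialectError(f"{path}: confidence record missing field {field!r}")
    if require_plddt and "plddt" not in record:
        raise DialectError(f"{path}: confidence record missing field 'plddt'")
    record.setdefault("model_id", path.stem)
    return record


def _plddt_from_structure(path: Path) -> list[float]:
    fmt = _MODEL_SUFFIXES[path.suffix]
    parser = PDBParser(QUIET=True) if fmt == "pdb" else MMCIFParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    plddt: list[float] = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            atoms = list(residue.get_atoms())
            if not atoms:
                continue
            ca = residue["CA"] if "CA" in residue else atoms[0]
            plddt.append(float(ca.get_bfactor()))
    if not plddt:
        raise DialectError(f"{path}: no residues with atoms found")
    return plddt


def read_job_outputs(handle: JobOutputHandle):
    """Read one job's outputs into :class:`~aisid.scoring.ModelPrediction` records.

    Records are returned sorted by ``model_id``.  Inconsistent pLDDT vector
    lengths across models raise a warning (the job is still harvested); a
    directory without any per-model record raises :class:`EmptyJobError`.
    """
    from .scoring import ModelPrediction  # deferred to keep import graph flat

    root = handle.root
    if not root.is_dir():
        raise EmptyJobError(f"job output root {root} is not a directory")

    records: list[ModelPrediction] = []
    if handle.dialect == "confidence-json":
        for path in sorted(root.glob("*.json")):
            rec = _read_confidence_json(path, require_plddt=True)
            records.append(
                ModelPrediction(
                    model_id=str(rec["model_id"]),
                    iptm=float(rec["iptm"]),
                    ptm=float(rec["ptm"]),
                    plddt=rec["plddt"],
                )
            )
    else:  # pdb-bfactor
        model_files = sorted(
            p for p in root.iterdir() if p.suffix in _MODEL_SUFFIXES
        )
        for path in model_files:
            companion = path.with_suffix(".json")
            if not companion.exists():
                raise DialectError(
                    f"{path}: pdb-bfactor dialect requires a companion JSON "
                    f"({companion.name}) carrying iptm and ptm"
                )
            rec = _read_confidence_json(companion, require_plddt=False)
            records.append(
                ModelPrediction(
                    model_id=str(rec.get("model_id", path.stem)),
                    iptm=float(rec["iptm"]),
                    ptm=float(rec["ptm"]),
                    plddt=_plddt_from_structure(path),
                )
            )

    if not records:
        raise EmptyJobError(
            f"no per-model records found in {root} (dialect {handle.dialect})"
        )
    records.sort(key=lambda m: m.model_id)
    lengths = {m.n_residues for m in records}
    if len(lengths) > 1:
        warnings.warn(
            f"job {handle.job_id}: inconsistent pLDDT lengths across models: "
            f"{sorted(lengths)}",
            stacklevel=2,
        )
    return records


SCORE_COLUMNS = ["bait_id", "ligand_id", "aisidscore", "best_model_id", "n_models"]


def write_pair_scores(scores: Sequence[PairScore], destination: str | Path) -> Path:
    """Write pair scores as a TSV table, scores to 3 decimals, input order kept."""
    destination = Path(destination)
    df = pd.DataFrame(
        {
            "bait_id": [s.bait_id for s in scores],
            "ligand_id": [s.ligand_id for s in scores],
            "aisidscore": [f"{s.aisidscore:.3f}" for s in scores],
            "best_model_id": [s.best_model_id for s in scores],
            "n_models": [s.n_models for s in scores],
        },
        columns=SCORE_COLUMNS,
    )
    df.to_csv(destination, sep="\t", index=False)
    return destination


def read_pair_scores(path: str | Path) -> list[PairScore]:
    """Read a score TSV back; per-model breakdowns are not stored in the table."""
    df = pd.read_csv(path, sep="\t", dtype={"bait_id": str, "ligand_id": str,
                                            "best_model_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table {path} missing column(s): {missing}")
    return [
        PairScore(
            bait_id=row.bait_id,
            ligand_id=row.ligand_id,
            aisidscore=float(row.aisidscore),
            best_model_id=row.best_model_id,
            n_models=int(row.n_models),
        )
        for row in df.itertuples(index=False)
    ]


def write_plddt_model(
    path: str | Path,
    plddt: Sequence[float],
    chain_lengths: Sequence[int],
    *,
    model_id: str | None = None,
) -> Path:
    """Write a minimal structure file with pLDDT in the B-factor column.

    One glycine CA atom per residue, residues split across chains A, B, ...
    according to ``chain_lengths``.  Format follows the suffix (.pdb or .cif).
    Coordinates are placeholders: this file carries confidence, not geometry.
    """
    path = Path(path)
    if path.suffix not in _MODEL_SUFFIXES:
        raise ValueError(f"unsupported model suffix {path.suffix!r} (use .pdb or .cif)")
    if sum(chain_lengths) != len(plddt):
        raise ValueError("chain_lengths must sum to len(plddt)")

    builder = StructureBuilder()
    builder.init_structure(model_id or path.stem)
    builder.init_model(0)
    idx = 0
    for ci, length in enumerate(chain_lengths):
        chain_id = chr(ord("A") + ci)
        builder.init_chain(chain_id)
        builder.init_seg("    ")
        for ri in range(length):
            builder.init_residue("GLY", " ", ri + 1, " ")
            # B-factor column stores pLDDT rounded to PDB precision (2 dp)
            builder.init_atom(
                "CA",
                [float(idx), 0.0, 0.0],
                round(float(plddt[idx]), 2),
                1.0,
                " ",
                " CA ",
                element="C",
            )
            idx += 1
    structure = builder.get_structure()
    writer = PDBIO() if path.suffix == ".pdb" else MMCIFIO()
    writer.set_structure(structure)
    writer.save(str(path))
    return path
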