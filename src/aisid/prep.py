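"""Screen preparation: composite FASTA inputs, size sorting, batch manifest.

A screening project pairs one bait sequence with every member of a candidate
panel.  Each pairing becomes a two-record FASTA file (bait first) that an
AlphaFold-Multimer-style predictor consumes as one heterodimer job.  Jobs are
sorted by total residue count, small to large, because prediction wall time
grows steeply with sequence length and short jobs finishing early keeps a
limited pool of compute nodes busy.  The hand-off to whatever scheduler runs
the predictor is a plain TSV manifest; this package never submits jobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "ScreenJob",
    "read_fasta",
    "build_composite_jobs",
    "sort_jobs_by_size",
    "write_manifest",
    "read_manifest",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
#: ambiguous / non-standard one-letter codes mapped to X (predictor front-ends
#: reject them inconsistently)
NONSTANDARD_TO_X = set("UBZJO")

MANIFEST_COLUMNS = ["job_id", "composite_path", "total_residues", "output_root"]


@dataclass(frozen=True)
class SequenceRecord:
    """One protein chain: identifier plus amino-acid sequence.

    The identifier is the first whitespace-delimited token of a FASTA header
    and may not contain whitespace.  Sequences are stored uppercase over the
    20 standard residues plus X; common non-standard codes (U, B, Z, J, O)
    are mapped to X with a warning.
    """

    seq_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.seq_id or any(c.isspace() for c in self.seq_id):
            raise ValueError(f"seq_id must be non-empty without whitespace: {self.seq_id!r}")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"sequence of {self.seq_id!r} is empty")
        mapped = []
        remapped = set()
        for c in seq:
            if c in STANDARD_RESIDUES:
                mapped.append(c)
            elif c in NONSTANDARD_TO_X:
                mapped.append("X")
                remapped.add(c)
            else:
                raise ValueError(
                    f"illegal residue character {c!r} in sequence {self.seq_id!r}"
                )
        if remapped:
            warnings.warn(
                f"sequence {self.seq_id!r}: non-standard residue(s) "
                f"{sorted(remapped)} mapped to X",
                stacklevel=2,
            )
        object.__setattr__(self, "sequence", "".join(mapped))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ScreenJob:
    """One bait-ligand prediction job."""

    bait: SequenceRecord
    ligand: SequenceRecord
    composite_path: Path
    output_root: Path | None = None
    total_residues: int = field(init=False)

    def __post_init__(self) -> None:
        self.total_residues = len(self.bait) + len(self.ligand)
        self.composite_path = Path(self.composite_path)

    @property
    def job_id(self) -> str:
        return f"{self.bait.seq_id}__{self.ligand.seq_id}"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects, order preserved.

    The record id is the first whitespace token of the header.  Raises a
    parse error (with line number) if sequence data precedes the first
    header, and a validation error naming the record for illegal residues.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
    records = [
        SequenceRecord(seq_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def _write_composite_fasta(bait: SequenceRecord, ligand: SequenceRecord, path: Path) -> None:
    bio_records = [
        _BioSeqRecord(Seq(bait.sequence), id=bait.seq_id, description=""),
        _BioSeqRecord(Seq(ligand.sequence), id=ligand.seq_id, description=""),
    ]
    SeqIO.write(bio_records, str(path), "fasta")


def build_composite_jobs(
    bait: SequenceRecord,
    ligands: Sequence[SequenceRecord],
    workdir: str | Path,
    *,
    allow_self_pairing: bool = False,
) -> list[ScreenJob]:
    """Write one two-record FASTA per ligand (bait first) and return the jobs.

    File names follow ``<bait_id>__<ligand_id>.fasta``.  Ligand ids must be
    unique; pairing the bait with itself is rejected unless
    ``allow_self_pairing`` is set (the screen targets heterodimers).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    for lig in ligands:
        if lig.seq_id in seen:
            raise ValueError(f"duplicate ligand id {lig.seq_id!r}")
        seen.add(lig.seq_id)
        if lig.seq_id == bait.seq_id and not allow_self_pairing:
            raise ValueError(
                f"ligand id {lig.seq_id!r} collides with the bait id; "
                "self-pairing is excluded by default"
            )
    jobs: list[ScreenJob] = []
    for lig in ligands:
        path = workdir / f"{bait.seq_id}__{lig.seq_id}.fasta"
        _write_composite_fasta(bait, lig, path)
        jobs.append(ScreenJob(bait=bait, ligand=lig, composite_path=path))
    return jobs


def sort_jobs_by_size(jobs: Iterable[ScreenJob]) -> list[ScreenJob]:
    """Stable ascending sort by total residue count; ties keep input order."""
    return sorted(jobs, key=lambda j: j.total_residues)


def write_manifest(jobs: Sequence[ScreenJob], destination: str | Path) -> Path:
    """Write the batch manifest TSV: job_id, composite_path, total_residues, output_root.

    The manifest is the hand-off point to an external scheduler; rows are
    written in the order given.
    """
    destination = Path(destination)
    df = pd.DataFrame(
        {
            "job_id": [j.job_id for j in jobs],
            "composite_path": [str(j.composite_path) for j in jobs],
            "total_residues": [j.total_residues for j in jobs],
            "output_root": ["" if j.output_root is None else str(j.output_root) for j in jobs],
        },
        columns=MANIFEST_COLUMNS,
    )
    df.to_csv(destination, sep="\t", index=False)
    return destination


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest TSV back into a DataFrame (columns as written)."""
    df = pd.read_csv(path, sep="\t", dtype={"job_id": str, "composite_path": str},
                     keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing column(s): {missing}")
    df["total_residues"] = df["total_residues"].astype(int)
    return df
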