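"""Synthetic predictor-output generator for end-to-end pipeline testing.

Running the real structure predictor needs GPUs, network weights and sequence
databases, none of which belong in a test suite.  This backend fabricates the
predictor's *confidence* outputs instead: for every bait x ligand pair it
draws ``n_models`` (ipTM, pTM, pLDDT) records from truncated normal
distributions, with planted true pairs drawn from a higher-ipTM class than
decoys.  Two-parameter truncated normals are used because the screen's
published readouts are group means on bounded scores, not full distributions.

The same draw code backs two paths: :func:`simulate_screen` returns records
in memory (fast Monte-Carlo checks), :func:`generate_mock_outputs`
serializes them in either on-disk dialect so the harvest code path is
exercised file-for-file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .io import JobOutputHandle, write_plddt_model
from .prep import SequenceRecord
from .rank import ScreenResult
from .scoring import ModelPrediction, PairScore

__all__ = ["MockScreenSpec", "simulate_screen", "generate_mock_outputs", "table1_fixture"]

#: default seed; date-derived constant recorded in generated metadata
DEFAULT_SEED = 20221002


@dataclass
class MockScreenSpec:
    """Stated world of a synthetic screen.

    ``iptm_true`` / ``iptm_decoy`` are (mean, sd) of truncated normals on
    [0, 1] for planted true pairs and decoys; defaults (0.85, 0.03) vs
    (0.2, 0.05) give the strong binder/non-binder separation a well-behaved
    screen shows.  ``ptm_offset`` is added to each drawn ipTM (clamped to
    [0, 1]) so the two confidence terms stay correlated, as in real outputs.
    ``plddt_base`` is the (mean, sd) of per-residue pLDDT truncated to
    [0, 100]; 80 +/- 10 is a typical well-folded prediction.
    """

    baits: list[SequenceRecord]
    ligands: list[SequenceRecord]
    true_pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    n_models: int = 25
    iptm_true: tuple[float, float] = (0.85, 0.03)
    iptm_decoy: tuple[float, float] = (0.2, 0.05)
    ptm_offset: float = 0.05
    plddt_base: tuple[float, float] = (80.0, 10.0)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.iptm_true[0] <= self.iptm_decoy[0]:
            raise ValueError("iptm_true mean must exceed iptm_decoy mean")
        for name in ("iptm_true", "iptm_decoy", "plddt_base"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} sd must be positive")
        self.true_pairs = frozenset(self.true_pairs)
        bait_ids = {b.seq_id for b in self.baits}
        ligand_ids = {l.seq_id for l in self.ligands}
        for bait_id, ligand_id in self.true_pairs:
            if bait_id not in bait_ids or ligand_id not in ligand_ids:
                raise ValueError(f"true pair ({bait_id}, {ligand_id}) not in the screen")


def _trunc_draw(rng: np.random.Generator, mean: float, sd: float,
                low: float, high: float, size) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _simulate_job(
    rng: np.random.Generator, spec: MockScreenSpec, is_true: bool, n_residues: int
) -> list[ModelPrediction]:
    mean, sd = spec.iptm_true if is_true else spec.iptm_decoy
    width = max(2, len(str(spec.n_models)))
    models = []
    for i in range(spec.n_models):
        iptm = float(_trunc_draw(rng, mean, sd, 0.0, 1.0, None))
        ptm = float(np.clip(iptm + spec.ptm_offset, 0.0, 1.0))
        # pLDDT rounded to 2 decimals = B-factor column precision, so both
        # on-disk dialects carry identical values
        plddt = np.round(
            _trunc_draw(rng, spec.plddt_base[0], spec.plddt_base[1], 0.0, 100.0,
                        n_residues),
            2,
        )
        models.append(
            ModelPrediction(model_id=f"model_{i + 1:0{width}d}", iptm=iptm,
                            ptm=ptm, plddt=plddt)
        )
    return models


def simulate_screen(spec: MockScreenSpec) -> dict[tuple[str, str], list[ModelPrediction]]:
    """Draw every bait x ligand job in memory; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    jobs: dict[tuple[str, str], list[ModelPrediction]] = {}
    for bait in spec.baits:
        for ligand in spec.ligands:
            is_true = (bait.seq_id, ligand.seq_id) in spec.true_pairs
            jobs[(bait.seq_id, ligand.seq_id)] = _simulate_job(
                rng, spec, is_true, len(bait) + len(ligand)
            )
    return jobs


def generate_mock_outputs(
    spec: MockScreenSpec,
    workdir: str | Path,
    *,
    dialect: str = "confidence-json",
    overwrite: bool = False,
) -> list[JobOutputHandle]:
    """Materialize a synthetic screen as predictor-output directories.

    One directory per bait-ligand job under ``workdir``, holding
    ``spec.n_models`` per-model records in the requested dialect.  The same
    seed always produces byte-identical trees.  Raises if a job directory
    already exists unless ``overwrite`` is set.
    """
    if dialect not in ("confidence-json", "pdb-bfactor"):
        raise ValueError(f"unknown dialect {dialect!r}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    jobs = simulate_screen(spec)

    handles: list[JobOutputHandle] = []
    for bait in spec.baits:
        for ligand in spec.ligands:
            job_id = f"{bait.seq_id}__{ligand.seq_id}"
            root = workdir / job_id
            if root.exists() and not overwrite:
                raise FileExistsError(
                    f"job directory {root} exists (pass overwrite=True to replace)"
                )
            root.mkdir(parents=True, exist_ok=True)
            for model in jobs[(bait.seq_id, ligand.seq_id)]:
                record = {
                    "model_id": model.model_id,
                    "iptm": model.iptm,
                    "ptm": model.ptm,
                }
                if dialect == "confidence-json":
                    record["plddt"] = [float(v) for v in model.plddt]
                else:
                    write_plddt_model(
                        root / f"{model.model_id}.pdb",
                        model.plddt,
                        chain_lengths=[len(bait), len(ligand)],
                        model_id=model.model_id,
                    )
                with (root / f"{model.model_id}.json").open("w") as fh:
                    json.dump(record, fh, sort_keys=True, indent=1)
            handles.append(JobOutputHandle(job_id=job_id, root=root, dialect=dialect))

    meta = {
        "seed": spec.seed,
        "n_models": spec.n_models,
        "dialect": dialect,
        "n_baits": len(spec.baits),
        "n_ligands": len(spec.ligands),
        "true_pairs": sorted(map(list, spec.true_pairs)),
    }
    with (workdir / "mock_screen.json").open("w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
    return handles


# --- packaged positive-control fixture -------------------------------------

_TABLE1_BAIT = "TNFa_nanobody"
_TABLE1_TRUE_LIGAND = "TNFa"


def table1_fixture() -> tuple[ScreenResult, ScreenResult]:
    """Published positive-control screen: an anti-TNFα nanobody vs 18 TNFSF ligands.

    Returns two :class:`~aisid.rank.ScreenResult` objects built from the
    packaged score table — one for the default predictor run, one for the run
    restricted to a 2016-01-01 structure-template cutoff (which hides the
    deposited nanobody complex from the predictor).  Both are annotated with
    TNFα as the known binding partner.  Per-model breakdowns were not
    published, so ``best_model_id`` is marked ``unreported`` and ``n_models``
    carries the predictor default of 25.
    """
    from importlib.resources import files

    import pandas as pd

    table = pd.read_csv(
        files("aisid.data").joinpath("table1_tnfa_nanobody.tsv"), sep="\t"
    )
    results = []
    for column, tag in (("default", "default"), ("cutoff_2016", "cutoff_2016")):
        scores = [
            PairScore(
                bait_id=f"{_TABLE1_BAIT}:{tag}",
                ligand_id=str(row.ligand_id),
                aisidscore=float(getattr(row, column)),
                best_model_id="unreported",
                n_models=25,
            )
            for row in table.itertuples(index=False)
        ]
        results.append(
            ScreenResult(
                bait_id=f"{_TABLE1_BAIT}:{tag}",
                scores=scores,
                annotations=frozenset({_TABLE1_TRUE_LIGAND}),
            )
        )
    return results[0], results[1]
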