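"""Composite confidence scoring for bait-ligand complex predictions.

An AlphaFold-Multimer-style predictor emits, for every predicted complex
model, an interface predicted TM-score (ipTM), a whole-complex predicted
TM-score (pTM), and a per-residue pLDDT vector.  This module combines them
into the screening metric used to rank candidate binders:

* ``model confidence`` — the predictor's own composite, ``0.8*ipTM + 0.2*pTM``;
* ``avp`` — the mean pLDDT over *all* residues of both chains, expressed as a
  fraction in [0, 1];
* ``AISIDscore`` — ``max`` over a job's models of
  ``1.25 * model_confidence - 0.25 * avp``.

Subtracting a quarter of the average fold quality down-weights pairs whose
confidence is carried by well-folded individual chains rather than by the
interface, which is what a binding screen cares about.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "ModelPrediction",
    "PerModelScore",
    "PairScore",
    "compute_model_confidence",
    "compute_avp",
    "compute_aisidscore",
    "score_pair",
]

#: number of models an AlphaFold-Multimer heterodimer job produces by default
DEFAULT_N_MODELS = 25


def _check_unit_interval(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class ModelPrediction:
    """Confidence record of one predicted complex model.

    Parameters
    ----------
    model_id : str
        Label unique within a prediction job (e.g. ``model_3_multimer_v2``).
    iptm : float
        Interface predicted TM-score in [0, 1].
    ptm : float
        Whole-complex predicted TM-score in [0, 1].
    plddt : numpy.ndarray
        Per-residue pLDDT in [0, 100]; one value per residue across both
        chains, concatenated in file order.
    """

    model_id: str
    iptm: float
    ptm: float
    plddt: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValueError("model_id must be a non-empty string")
        _check_unit_interval(self.iptm, "iptm")
        _check_unit_interval(self.ptm, "ptm")
        plddt = np.asarray(self.plddt, dtype=float)
        if plddt.ndim != 1 or plddt.size == 0:
            raise ValueError("plddt must be a non-empty 1-D vector")
        if not np.all(np.isfinite(plddt)) or plddt.min() < 0.0 or plddt.max() > 100.0:
            raise ValueError("plddt values must lie in [0, 100]")
        object.__setattr__(self, "plddt", plddt)

    @property
    def n_residues(self) -> int:
        return int(self.plddt.size)


class PerModelScore(NamedTuple):
    """Score breakdown for a single model."""

    model_id: str
    model_confidence: float
    avp: float
    value: float  #: 1.25 * model_confidence - 0.25 * avp


@dataclass(frozen=True)
class PairScore:
    """Harvested screening result for one bait-ligand pair."""

    bait_id: str
    ligand_id: str
    aisidscore: float
    best_model_id: str
    n_models: int
    per_model_scores: tuple[PerModelScore, ...] = ()

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.per_model_scores and len(self.per_model_scores) != self.n_models:
            raise ValueError("per_model_scores length must equal n_models")


def compute_model_confidence(iptm: float, ptm: float) -> float:
    """Predictor composite confidence, ``0.8 * iptm + 0.2 * ptm``.

    Both arguments must lie in [0, 1]; the result does too.
    """
    iptm = _check_unit_interval(iptm, "iptm")
    ptm = _check_unit_interval(ptm, "ptm")
    return 0.8 * iptm + 0.2 * ptm


def compute_avp(plddt: Sequence[float] | np.ndarray) -> float:
    """Averaged percentage pLDDT over all residues, as a fraction in [0, 1].

    ``avp = mean(plddt) / 100`` over every residue of both chains.  The
    0-100 pLDDT scale is divided down so that avp is commensurate with the
    model confidence it is subtracted from.
    """
    plddt = np.asarray(plddt, dtype=float)
    if plddt.size == 0:
        raise ValueError("plddt vector is empty")
    if not np.all(np.isfinite(plddt)) or plddt.min() < 0.0 or plddt.max() > 100.0:
        raise ValueError("plddt values must lie in [0, 100]")
    return float(plddt.mean() / 100.0)


def _per_model_value(model: ModelPrediction) -> PerModelScore:
    confidence = compute_model_confidence(model.iptm, model.ptm)
    avp = compute_avp(model.plddt)
    return PerModelScore(model.model_id, confidence, avp, 1.25 * confidence - 0.25 * avp)


def compute_aisidscore(
    models: Sequence[ModelPrediction],
    *,
    expected_n_models: int | None = DEFAULT_N_MODELS,
) -> tuple[float, str, tuple[PerModelScore, ...]]:
    """Maximum of ``1.25 * model_confidence - 0.25 * avp`` over a job's models.

    Parameters
    ----------
    models : sequence of ModelPrediction
        At least one model.
    expected_n_models : int or None
        Nominal model count of a job (25 for a stock heterodimer run).  A
        shorter list is accepted but triggers a warning; pass ``None`` to
        silence the check.

    Returns
    -------
    aisidscore : float
        The maximum per-model value; bounded in [-0.25, 1.25].
    best_model_id : str
        Model achieving the maximum; ties resolve to the lexicographically
        smallest model_id so the choice does not depend on input order.
    per_model_scores : tuple of PerModelScore
        Breakdown for every model, in input order.
    """
    if not models:
        raise ValueError("at least one model is required")
    if expected_n_models is not None and len(models) < expected_n_models:
        warnings.warn(
            f"job has {len(models)} models, fewer than the nominal "
            f"{expected_n_models}",
            stacklevel=2,
        )
    per_model = tuple(_per_model_value(m) for m in models)
    aisidscore = max(s.value for s in per_model)
    best_model_id = min(s.model_id for s in per_model if s.value == aisidscore)
    return aisidscore, best_model_id, per_model


def score_pair(
    bait_id: str,
    ligand_id: str,
    models: Sequence[ModelPrediction],
    *,
    expected_n_models: int | None = DEFAULT_N_MODELS,
) -> PairScore:
    """Score one bait-ligand job and package the result as a :class:`PairScore`."""
    aisidscore, best_model_id, per_model = compute_aisidscore(
        models, expected_n_models=expected_n_models
    )
    return PairScore(
        bait_id=bait_id,
        ligand_id=ligand_id,
        aisidscore=aisidscore,
        best_model_id=best_model_id,
        n_models=len(models),
        per_model_scores=per_model,
    )
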