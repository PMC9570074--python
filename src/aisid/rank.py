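"""Per-bait ranking, hit statistics and screen-level reports.

After harvesting, each bait carries one AISIDscore per panel candidate.  The
screen's readout is the descending ranking of those scores; when curated
true bait-ligand pairs are known, top-k hit counts and group means quantify
how well the score separates real binders from the rest of the panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import JobOutputHandle, read_job_outputs
from .scoring import PairScore, score_pair

__all__ = [
    "ScreenResult",
    "SummaryMeans",
    "harvest_screen",
    "rank_candidates",
    "hit_statistics",
    "summary_means",
    "render_heatmap",
    "read_annotations",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """All pair scores for one bait, optionally annotated with known binders."""

    bait_id: str
    scores: list[PairScore]
    annotations: frozenset[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.ligand_id for s in self.scores]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ligand_id(s) in scores: {dupes}")
        if self.annotations is not None:
            self.annotations = frozenset(self.annotations)
            unknown = self.annotations - set(ids)
            if unknown:
                raise ValueError(
                    f"annotation id(s) not present among scored ligands: {sorted(unknown)}"
                )

    @property
    def ligand_ids(self) -> list[str]:
        return [s.ligand_id for s in self.scores]


def harvest_screen(
    bait_id: str,
    handles: Sequence[JobOutputHandle],
    *,
    annotations: Iterable[str] | None = None,
    expected_n_models: int | None = 25,
) -> ScreenResult:
    """Read every job's models, score each pair, and assemble a ScreenResult."""
    scores = []
    for handle in handles:
        models = read_job_outputs(handle)
        scores.append(
            score_pair(
                handle.bait_id or bait_id,
                handle.ligand_id,
                models,
                expected_n_models=expected_n_models,
            )
        )
    return ScreenResult(
        bait_id=bait_id,
        scores=scores,
        annotations=None if annotations is None else frozenset(annotations),
    )


def rank_candidates(result: ScreenResult) -> pd.DataFrame:
    """Rank a bait's candidates by AISIDscore, large to small.

    Ties are broken by ascending ligand_id so the table is deterministic;
    tied scores still receive distinct consecutive ranks under that order.

    Returns a DataFrame with columns ``rank`` (1-based), ``ligand_id``,
    ``aisidscore`` and, when the result carries annotations,
    ``is_known_pair``.
    """
    if not result.scores:
        raise ValueError(f"bait {result.bait_id!r} has no scores to rank")
    rows = sorted(result.scores, key=lambda s: (-s.aisidscore, s.ligand_id))
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "ligand_id": [s.ligand_id for s in rows],
            "aisidscore": [s.aisidscore for s in rows],
        }
    )
    if result.annotations is not None:
        table["is_known_pair"] = table["ligand_id"].isin(result.annotations)
    return table


def _annotated_ranks(result: ScreenResult) -> dict[str, int]:
    """Rank of each annotated ligand within its bait's ranking."""
    table = rank_candidates(result)
    lookup = dict(zip(table["ligand_id"], table["rank"]))
    return {lig: lookup[lig] for lig in sorted(result.annotations or ())}


def hit_statistics(
    results: Sequence[ScreenResult],
    k_values: Sequence[int] = (1, 3, 5),
    *,
    best_pair_only: bool = False,
) -> dict:
    """Top-k recovery counts of annotated pairs across a panel of baits.

    Every annotated (bait, ligand) pair contributes its own rank — a bait
    with three known ligands can occupy up to three top-k seats — matching
    how a multi-ligand receptor family is usually scored.  Set
    ``best_pair_only`` to count only each bait's best-ranked annotated pair.
    Results without annotations are skipped with a log line.

    Returns a dict with keys ``top_k`` (mapping k -> pair count),
    ``top1_baits`` (baits whose rank-1 candidate is annotated),
    ``total_annotated_pairs`` and ``n_annotated_baits``.
    """
    for k in k_values:
        if k < 1:
            raise ValueError(f"k values must be >= 1, got {k}")
    all_ranks: list[int] = []
    top1_baits = 0
    n_annotated_baits = 0
    for result in results:
        if result.annotations is None:
            logger.info("bait %s has no annotations; skipped", result.bait_id)
            continue
        n_annotated_baits += 1
        ranks = _annotated_ranks(result)
        pair_ranks = sorted(ranks.values())
        if best_pair_only and pair_ranks:
            pair_ranks = pair_ranks[:1]
        all_ranks.extend(pair_ranks)
        if 1 in ranks.values():
            top1_baits += 1
    return {
        "top_k": {int(k): sum(r <= k for r in all_ranks) for k in k_values},
        "top1_baits": top1_baits,
        "total_annotated_pairs": len(all_ranks),
        "n_annotated_baits": n_annotated_baits,
    }


@dataclass(frozen=True)
class SummaryMeans:
    """Group means over a screen; ``None`` marks an empty (undefined) subset."""

    mean_all: float | None
    mean_annotated: float | None
    mean_control: float | None
    min_all: float | None = None
    max_all: float | None = None


def summary_means(
    results: Sequence[ScreenResult],
    control_bait_ids: Sequence[str] = (),
) -> SummaryMeans:
    """Mean AISIDscore over all pairs, annotated (correct) pairs, and control baits.

    Control pairs are every score of the listed control baits (e.g. a
    non-binding negative-control bait screened against the same panel).
    An empty subset yields ``None`` rather than 0.
    """
    controls = set(control_bait_ids)
    all_scores: list[float] = []
    annotated: list[float] = []
    control: list[float] = []
    for result in results:
        for s in result.scores:
            all_scores.append(s.aisidscore)
            if result.annotations is not None and s.ligand_id in result.annotations:
                annotated.append(s.aisidscore)
            if result.bait_id in controls:
                control.append(s.aisidscore)

    def _mean(values: list[float]) -> float | None:
        return float(np.mean(values)) if values else None

    return SummaryMeans(
        mean_all=_mean(all_scores),
        mean_annotated=_mean(annotated),
        mean_control=_mean(control),
        min_all=float(min(all_scores)) if all_scores else None,
        max_all=float(max(all_scores)) if all_scores else None,
    )


def _score_matrix(
    results: Sequence[ScreenResult], *, strict: bool = True
) -> pd.DataFrame:
    panels = [tuple(sorted(r.ligand_ids)) for r in results]
    if len(set(panels)) > 1:
        union: set[str] = set().union(*(set(p) for p in panels))
        inter: set[str] = set(panels[0])
        for p in panels[1:]:
            inter &= set(p)
        raise ValueError(
            "results do not share one ligand panel; symmetric difference: "
            f"{sorted(union - inter)}"
        )
    ligands = list(results[0].ligand_ids)
    data = {
        r.bait_id: {s.ligand_id: s.aisidscore for s in r.scores} for r in results
    }
    matrix = pd.DataFrame.from_dict(data, orient="index")[ligands]
    if strict and matrix.isna().any().any():
        missing = [
            (b, l) for b in matrix.index for l in matrix.columns
            if pd.isna(matrix.at[b, l])
        ]
        raise ValueError(f"missing (bait, ligand) score(s): {missing}")
    return matrix


def render_heatmap(
    results: Sequence[ScreenResult],
    destination: str | Path,
    *,
    control_bait_ids: Sequence[str] = (),
    strict: bool = True,
    image_format: str = "png",
) -> tuple[Path, Path]:
    """Render the baits x ligands score heatmap and its underlying TSV matrix.

    The TSV carries scores to 3 decimals plus a rightmost ``best_known_rank``
    column: the bait's best-annotated-pair rank, ``unknown`` for baits
    without annotations, ``none`` for listed control baits.  The image marks
    annotated cells and uses a fixed [0, 1] color scale so separate runs are
    visually comparable.

    Returns ``(tsv_path, image_path)``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if not results:
        raise ValueError("no results to render")
    destination = Path(destination)
    destination.parent.mkdir(parents=True, exist_ok=True)
    matrix = _score_matrix(results, strict=strict)

    controls = set(control_bait_ids)
    rank_col = []
    for r in results:
        if r.bait_id in controls:
            rank_col.append("none")
        elif not r.annotations:
            rank_col.append("unknown")
        else:
            rank_col.append(str(min(_annotated_ranks(r).values())))
    out = matrix.map(lambda v: "" if pd.isna(v) else f"{v:.3f}")
    out["best_known_rank"] = rank_col
    tsv_path = destination.with_suffix(".tsv")
    out.to_csv(tsv_path, sep="\t", index_label="bait_id")

    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values) < 0.0 or np.nanmax(values) > 1.0:
        warnings.warn("scores outside [0, 1] clamped for display", stacklevel=2)
    fig_h = max(2.5, 0.35 * len(matrix.index) + 1.5)
    fig_w = max(4.0, 0.45 * len(matrix.columns) + 2.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    sns.heatmap(
        matrix.clip(lower=0.0, upper=1.0),
        vmin=0.0,
        vmax=1.0,
        cmap="viridis",
        cbar_kws={"label": "AISIDscore"},
        ax=ax,
    )
    # outline annotated (known-pair) cells
    col_index = {lig: j for j, lig in enumerate(matrix.columns)}
    for i, r in enumerate(results):
        for lig in r.annotations or ():
            j = col_index[lig]
            ax.add_patch(
                plt.Rectangle((j, i), 1, 1, fill=False, edgecolor="red", lw=1.5)
            )
    ax.set_xlabel("ligand")
    ax.set_ylabel("bait")
    fig.tight_layout()
    image_path = destination.with_suffix(f".{image_format}")
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    return tsv_path, image_path


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a known-pair TSV (columns bait_id, ligand_id) into bait -> ligand sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("bait_id", "ligand_id"):
        if col not in df.columns:
            raise ValueError(f"annotation table {path} missing column {col!r}")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        mapping.setdefault(row.bait_id, set()).add(row.ligand_id)
    return mapping
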