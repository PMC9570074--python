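import numpy as np
import pytest

from aisid import ModelPrediction, PairScore, ScreenResult, SequenceRecord


@pytest.fixture
def bait():
    return SequenceRecord("bait1", "MKTAYIAKQRQISFVKSHFSRQ")


@pytest.fixture
def ligands():
    seqs = [
        "ACDEFGHIKLMNPQRSTVWY",
        "MKVLITGGAGFIGSHFVRQL",
        "GSHMASMTGGQQMGRGSEF",
    ]
    return [SequenceRecord(f"lig{i}", s) for i, s in enumerate(seqs)]


def make_model(model_id="m1", iptm=0.5, ptm=0.5, plddt=(80.0, 80.0)):
    return ModelPrediction(model_id=model_id, iptm=iptm, ptm=ptm,
                           plddt=np.asarray(plddt, dtype=float))


def planted_result(bait_id, annotated_ranks, n_ligands=18):
    """ScreenResult with ligand at rank r scoring 1 - 0.01*r; annotated at given ranks."""
    scores = [
        PairScore(
            bait_id=bait_id,
            ligand_id=f"L{r:02d}",
            aisidscore=1.0 - 0.01 * r,
            best_model_id="m1",
            n_models=25,
        )
        for r in range(1, n_ligands + 1)
    ]
    annotations = frozenset(f"L{r:02d}" for r in annotated_ranks) or None
    return ScreenResult(bait_id=bait_id, scores=scores, annotations=annotations)
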