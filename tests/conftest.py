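import numpy as np
import pytest

from rlmatch.io import Condition, QuantMatrix, SampleMeta


def make_samples(n_batches: int = 3) -> list[SampleMeta]:
    return [
        SampleMeta(f"{cond.value}_b{k}", cond, f"b{k}")
        for cond in (Condition.A, Condition.B)
        for k in range(1, n_batches + 1)
    ]


def make_matrix(values, n_batches: int = 3, normalized: bool = False, symbols=None) -> QuantMatrix:
    """QuantMatrix from a (proteins x 2*n_batches) array; A columns first."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return QuantMatrix(
        accessions=[f"P{i:05d}" for i in range(n)],
        gene_symbols=list(symbols) if symbols is not None else [f"G{i}" for i in range(n)],
        intensities=values,
        samples=make_samples(n_batches),
        normalized=normalized,
    )


@pytest.fixture
def samples3():
    return make_samples(3)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_matrix(rng):
    """50-protein lognormal matrix, 3 batches per condition, no zeros."""
    return make_matrix(10 ** rng.normal(5.0, 1.0, size=(50, 6)))


@pytest.fixture(scope="session")
def study_run():
    """One shared study-scale synthetic run through the whole pipeline."""
    from rlmatch.annotation import run_funnel
    from rlmatch.quant import differential, normalize_ibaq
    from rlmatch.rlm import RLMParams, match_ligands, select_enriched_receptors
    from rlmatch.simulate import study_like_dataset

    qm, ann, kb, truth, config = study_like_dataset(seed=1)
    qn = normalize_ibaq(qm)
    records = differential(qn)
    membrane, gf, nt, counts = run_funnel(records, ann)
    candidates = select_enriched_receptors(nt, RLMParams())
    recommendations = match_ligands(
        candidates, kb, RLMParams(require_ligand_available=True)
    )
    return {
        "qm": qm,
        "qn": qn,
        "ann": ann,
        "kb": kb,
        "truth": truth,
        "config": config,
        "records": records,
        "membrane": membrane,
        "gf": gf,
        "nt": nt,
        "counts": counts,
        "candidates": candidates,
        "recommendations": recommendations,
    }
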