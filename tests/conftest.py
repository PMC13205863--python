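"""Shared fixtures; the expensive trained-model runs are session-scoped."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from pairatac import TrainConfig, fit
from pairatac.cluster import leiden_cluster
from pairatac.io_preprocess import CountMatrix
from pairatac.metrics import ari, auroc_auprc
from pairatac.simulator import apply_dropout, simulate_block
from pairatac.trainer import embed_cells, embed_peaks, impute


def make_counts(dense, **kw) -> CountMatrix:
    dense = np.asarray(dense)
    n, m = dense.shape
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"c{i}" for i in range(n)],
        [f"chr1:{100 * j}-{100 * j + 50}" for j in range(m)],
        **kw,
    )


@pytest.fixture
def small_block():
    """A modest 60x100 3-group block dataset with 40% dropout applied."""
    truth = simulate_block(60, 100, 3, 0.35, 0.04, seed=5)
    dropped = apply_dropout(truth.counts, 0.4, seed=6)
    return truth, dropped


@dataclass
class RecoveryRun:
    seed: int
    dropout: float
    truth: object
    dropped: object
    model: object
    ari_model: float
    ari_svd: float
    auroc_masked: float


def _masked_auroc(model, truth, dropped, seed) -> float:
    """auROC of open-probability imputation: masked positives vs true zeros."""
    imp = impute(model, mode="probability")
    ref = np.asarray(truth.counts.counts.todense())
    mr, mc = dropped.mask
    zr, zc = np.nonzero(ref == 0)
    rng = np.random.default_rng(seed)
    sub = rng.choice(zr.size, size=min(zr.size, 50_000), replace=False)
    scores = np.concatenate([imp[mr, mc], imp[zr[sub], zc[sub]]])
    labels = np.concatenate([np.ones(mr.size), np.zeros(sub.size)])
    return auroc_auprc(scores, labels)[0]


@pytest.fixture(scope="session")
def recovery_runs() -> list[RecoveryRun]:
    """Scaled-down recovery experiment: 4-group block data, 300 cells x 800
    peaks (p_in=0.3, p_out=0.03), dropout 0.5 and 0.2, trained with d=16,
    K=2, 200 epochs, over 3 seeds."""
    runs = []
    for seed in range(3):
        truth = simulate_block(300, 800, 4, 0.3, 0.03, seed=100 + seed)
        for dropout in (0.5, 0.2):
            dropped = apply_dropout(truth.counts, dropout, seed=200 + seed)
            cfg = TrainConfig(n_layers=2, embedding_dim=16, epochs=200, seed=seed)
            model = fit(dropped.counts, cfg)
            clusters = leiden_cluster(embed_cells(model), k=15,
                                      resolution=1.0, seed=seed)
            svd = TruncatedSVD(16, random_state=seed).fit_transform(
                dropped.counts.counts.astype(float))
            runs.append(RecoveryRun(
                seed=seed,
                dropout=dropout,
                truth=truth,
                dropped=dropped,
                model=model,
                ari_model=ari(truth.labels, clusters),
                ari_svd=ari(truth.labels,
                            leiden_cluster(svd, k=15, resolution=1.0, seed=seed)),
                auroc_masked=_masked_auroc(model, truth, dropped, seed),
            ))
    return runs
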