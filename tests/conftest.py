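import numpy as np
import pandas as pd
import pytest

from codep_evidence import (
    AnalysisConfig,
    DependencyPanel,
    DubEvidenceModel,
    SimConfig,
    simulate_panel,
)
from codep_evidence.simdata import TRANSFERASE_SET_ID

BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition simulation draw shared across the suite."""
    return simulate_panel(SimConfig(seed=BUNDLE_SEED))


@pytest.fixture(scope="session")
def fitted(default_bundle):
    """Fitted evidence integration on the default bundle (queries = planted DUBs)."""
    dep, ab, edges, tau, coll, truth = default_bundle
    model = DubEvidenceModel(
        dep,
        gene_sets=coll,
        abundance=ab,
        interactions=edges,
        similarity=tau,
        queries=truth.query_genes,
        transferase_set_id=TRANSFERASE_SET_ID,
    )
    return model.fit(), truth


@pytest.fixture
def config():
    return AnalysisConfig()


def make_panel(columns: dict, lineage: dict | None = None) -> DependencyPanel:
    """Small dependency panel from a dict of gene -> score list."""
    scores = pd.DataFrame(columns, dtype=float)
    scores.index = [f"CL{i}" for i in range(len(scores))]
    lin = pd.Series(lineage or {}, dtype=object)
    return DependencyPanel(scores=scores, lineage=lin)


def correlated_vector(x: np.ndarray, r: float) -> np.ndarray:
    """A vector whose Pearson correlation with x is exactly r (|r| <= 1)."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    xu = xc / np.linalg.norm(xc)
    e = np.zeros_like(x)
    e[0], e[1] = xu[1], -xu[0]  # orthogonal to xu in the first two coords
    e = e - e.mean()
    e = e - (e @ xu) * xu
    e /= np.linalg.norm(e)
    return r * xu + np.sqrt(1 - r * r) * e
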