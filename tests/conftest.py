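import itertools

import numpy as np
import pytest

from pottsalign import MSA, AlignConfig, ScoreTables


@pytest.fixture
def tiny_msa():
    return MSA(sequences=["AC-D", "ACAD", "AC-D", "GCAD"],
               ids=["a", "b", "c", "d"])


def random_score_tables(seed: int, L_A: int | None = None,
                        L_B: int | None = None, coupled: bool = True,
                        self_score: float = 10.0) -> ScoreTables:
    """A random dense score-table instance for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    if L_A is None:
        L_A = int(rng.integers(2, 6))
    if L_B is None:
        L_B = int(rng.integers(2, 6))
    sv = rng.normal(size=(L_A, L_B))
    sw = {}
    if coupled:
        for i, j in itertools.combinations(range(L_A), 2):
            for k, l in itertools.combinations(range(L_B), 2):
                sw[(i, j, k, l)] = float(rng.normal())
    return ScoreTables(sv=sv, sw=sw, self_score_A=self_score,
                       self_score_B=self_score)


def random_align_config(seed: int, alpha_w: float | None = None) -> AlignConfig:
    rng = np.random.default_rng(seed + 10_000)
    return AlignConfig(
        alpha_w=float(rng.uniform(0.5, 3.0)) if alpha_w is None else alpha_w,
        gap_open=float(rng.uniform(0.0, 2.0)),
        gap_extend=float(rng.uniform(0.0, 0.3)),
        offset_gamma=0.0, epsilon=1e-9)
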