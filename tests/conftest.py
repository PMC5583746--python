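import numpy as np
import pytest

from dicecurator.fp_filters import score_candidate
from dicecurator.synthetic import generate_candidate_pool


@pytest.fixture(scope="session")
def candidate_pool():
    """Rendered, analyzed pseudo-images for FP-filter studies: 40 images,
    each with 36 normal monocentrics, 5 true dicentrics (TPs) and 10
    false-positive objects, giving 200 TP and 400 FP candidates."""
    return generate_candidate_pool(0, n_images=40)


@pytest.fixture(scope="session")
def pool_scores(candidate_pool):
    """(tp_scores, fp_scores) computed once from the candidate pool."""
    tp, fp = [], []
    for image in candidate_pool:
        objects = image["objects"]
        for idx, is_fp in zip(image["candidate_idx"], image["is_fp"]):
            s = score_candidate(objects[idx], objects)
            (fp if is_fp else tp).append(s)
    return tp, fp


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
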