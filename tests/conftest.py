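import numpy as np
import pytest

from cognet.qc import PairedScores
from cognet.records import RawRecord
from cognet.scales import CONSTRUCT_ITEMS, DEFAULT_SCALES
from cognet.synthetic import make_default_truth, sample_two_wave


def clean_record(
    code: str,
    wave: str = "T1",
    fill: int | None = None,
    per_construct: dict[str, int] | None = None,
    **overrides,
) -> RawRecord:
    """Build a complete, QC-passing record.

    ``fill`` sets every item of every scale to one value (clipped into
    the scale range); ``per_construct`` overrides the item value used
    for a given construct's items.
    """
    responses = {}
    for scale in DEFAULT_SCALES:
        responses[scale.name] = [
            max(scale.response_min,
                min(scale.response_max, 1 if fill is None else fill))
        ] * scale.n_items
    if per_construct:
        for construct, value in per_construct.items():
            scale, items = CONSTRUCT_ITEMS[construct]
            v = max(scale.response_min, min(scale.response_max, value))
            for i in items:
                responses[scale.name][i - 1] = v
    kwargs = dict(
        code=code,
        wave=wave,
        responses=responses,
        response_time_s=700.0,
        lie_ok=True,
        age=20.0,
        grade=2,
        demographics={"sex": "female", "residence": "urban"},
    )
    kwargs.update(overrides)
    return RawRecord(**kwargs)


@pytest.fixture(scope="session")
def truth():
    return make_default_truth()


@pytest.fixture(scope="session")
def latent_5000(truth):
    return sample_two_wave(truth, 5000, seed=11)


@pytest.fixture()
def five_record_fixture():
    """Hand-built screening fixture: one record per exclusion reason
    plus one clean record.

    A fails the lie item; B has a missing response; C answered in
    400 s; D's depression total (27) is extreme against the wave's
    scoreable pool (A, C, D, E score 9); E is clean.  With the outlier
    threshold at |z| > 1.5 (the attainable maximum |z| over an n-record
    pool is sqrt(n-1), so the conventional 3.0 cannot fire in a
    five-record wave), applying the filters by hand retains exactly E.
    """
    a = clean_record("A", lie_ok=False)
    b = clean_record("B")
    b.responses["phq"][3] = None
    c = clean_record("C", response_time_s=400.0)
    d = clean_record("D", per_construct={"PHQ": 3})
    e = clean_record("E")
    return [a, b, c, d, e]


def paired_from_arrays(X1, X2, labels) -> PairedScores:
    import pandas as pd

    codes = [f"S{i}" for i in range(len(X1))]
    return PairedScores(
        t1=pd.DataFrame(X1, index=codes, columns=labels),
        t2=pd.DataFrame(X2, index=codes, columns=labels),
        n_t1_only=0,
        n_t2_only=0,
    )
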