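import numpy as np
import pytest

import cytocline as cc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def steep_cline_spec():
    """The steep chlorotype transition used throughout recovery tests."""
    return cc.ClineModelSpec(center=0.43, width=0.05)


def simulate_bernoulli(spec, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    y = (rng.random(n) < cc.cline_probability(x, spec)).astype(float)
    return cc.ClineData(x, y, "bernoulli")


def simulate_binomial2(spec, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n)
    k = rng.binomial(2, np.asarray(cc.cline_probability(x, spec)))
    return cc.ClineData(x, k.astype(float), "binomial2")


@pytest.fixture
def sample_table_tsv(tmp_path):
    p = tmp_path / "samples.tsv"
    p.write_text(
        "sample_id\tcontact_zone\tlat\tlon\tchlorotype\tnuclear_q\tgenotype_id\n"
        "S1\tcassiar\t58.2\t-130.0\tPT\t0.91\tG1\n"
        "S2\tcassiar\t58.3\t-128.5\tPB\t0.12\tG2\n"
        "S3\tcassiar\t58.4\t-127.0\tPB\tNA\tG3\n"
    )
    return p
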