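import numpy as np
import pandas as pd
import pytest

import m6ace
from m6ace.simulate import simulate_scenario


def make_candidates(m6, inp, positions=None, contig="chrT", strand="+"):
    """Candidate count frame from per-site m6ACE / input triplicate lists."""
    m6 = np.atleast_2d(np.asarray(m6))
    inp = np.atleast_2d(np.asarray(inp))
    n, reps = m6.shape
    if positions is None:
        positions = [100 + 7 * i for i in range(n)]
    idx = pd.MultiIndex.from_tuples([(contig, strand, p) for p in positions],
                                    names=["contig", "strand", "position"])
    cols = pd.MultiIndex.from_tuples(
        [(f"rep{r + 1}", lib) for r in range(reps) for lib in ("m6ACE", "input")],
        names=["replicate", "library"])
    data = np.empty((n, 2 * reps))
    data[:, 0::2] = m6
    data[:, 1::2] = inp
    return pd.DataFrame(data, index=idx, columns=cols)


def equal_sizes(candidates):
    return pd.Series(1.0, index=candidates.columns)


def score_calls(passed, methylome, spike_id="spike:20:+"):
    truth = set(methylome.sites.site_id)
    called = set(passed.site_id) - {spike_id}
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    prec = tp / max(tp + fp, 1)
    rec = tp / max(tp + fn, 1)
    f1 = 2 * prec * rec / max(prec + rec, 1e-12)
    return prec, rec, f1


@pytest.fixture(scope="session")
def basic_scenario():
    return simulate_scenario("basic", seed=11)


@pytest.fixture(scope="session")
def basic_calls(basic_scenario):
    sc = basic_scenario
    passed, audit, full = m6ace.call_sites(sc.reads["WT"], sc.reference)
    return passed, audit, full


@pytest.fixture(scope="session")
def demethylase_scenario():
    return simulate_scenario("demethylase-ko", seed=11)


@pytest.fixture(scope="session")
def mixture_scenario():
    return simulate_scenario("mixture", seed=11)
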