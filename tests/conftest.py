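import numpy as np
import pandas as pd
import pytest

from cupsig import rank_profile


def running_sum_es(stats: pd.Series, members, weight: float = 1.0) -> float:
    """Literal O(N) running-sum enrichment score, used as an oracle.

    Walks the ranked list gene by gene, adding |stat|^weight / W at hits and
    subtracting 1/(N - k) at misses; returns the extremum of largest
    magnitude (ties between the positive and negative extremum resolve to
    the positive one, matching the documented tie-break).
    """
    ranked = rank_profile(stats)
    hit = ranked.index.isin(set(members))
    absw = np.abs(ranked.to_numpy(dtype=float)) ** weight
    W = absw[hit].sum()
    k = int(hit.sum())
    N = len(ranked)
    if W <= 0:
        gain = hit / k
    else:
        gain = np.where(hit, absw / W, 0.0)
    step = np.where(hit, gain, -1.0 / (N - k))
    cs = np.cumsum(step)
    hi, lo = cs.max(), min(cs.min(), 0.0)
    # analytic ties (|max| == |min|) resolve to the positive extremum; the
    # tolerance absorbs cumsum rounding so the tie-break fires consistently
    return float(hi if hi >= -lo - 1e-9 else lo)


@pytest.fixture
def tiny_counts():
    return pd.DataFrame(
        [[25, 10], [75, 30], [0, 60]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
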