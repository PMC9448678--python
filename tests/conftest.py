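import numpy as np
import pytest

from screenforge import LibraryManifest, SgrnaEntry, NTC_LABEL
from screenforge.library_io import synthetic_protospacer


@pytest.fixture
def toy_manifest() -> LibraryManifest:
    """3 targeting genes x 2 sgRNAs plus 4 NTCs."""
    entries = []
    idx = 0
    for gene in ("GA", "GB", "GC"):
        for j in (1, 2):
            entries.append(
                SgrnaEntry(f"{gene}_sg{j}", synthetic_protospacer(idx), gene, False)
            )
            idx += 1
    for j in range(1, 5):
        entries.append(
            SgrnaEntry(f"NTC_sg{j}", synthetic_protospacer(idx), NTC_LABEL, True)
        )
        idx += 1
    return LibraryManifest(entries=entries, name="toy")


def mw_permutation_oracle(x, y) -> float:
    """Exhaustive two-sided Mann-Whitney p by enumerating all labelings.

    For every way of relabeling the pooled sample into groups of the observed
    sizes, the U statistic of the first group is computed from midranks; the
    two-sided p is twice the smaller tail probability of the observed U,
    capped at 1.
    """
    from itertools import combinations

    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = x.size

    def u_of(idx: tuple) -> float:
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2

    u_obs = u_of(tuple(range(n1)))
    us = np.array([u_of(c) for c in combinations(range(pooled.size), n1)])
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))
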