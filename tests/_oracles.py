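"""Independent reference implementations used only as test oracles.

The exhaustive local aligner below fills the full (unbanded) affine-gap
Smith-Waterman matrix with plain per-cell recurrences and no seeding or
banding, so it shares no code path with the package's seed-and-extend
aligner. Gap convention matches the documented scoring: a gap of length n
costs gap_open + n * gap_ext.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def sw_score_full(q, s, match, mismatch, gap_open, gap_ext):
    """Best local affine-gap alignment score over the full DP matrix."""
    m = q.shape[0]
    n = s.shape[0]
    NEG = -(10 ** 9)
    Hprev = np.zeros(n + 1, dtype=np.int64)
    Eprev = np.full(n + 1, NEG, dtype=np.int64)
    Fprev = np.full(n + 1, NEG, dtype=np.int64)
    best = 0
    for i in range(1, m + 1):
        H = np.zeros(n + 1, dtype=np.int64)
        E = np.full(n + 1, NEG, dtype=np.int64)
        F = np.full(n + 1, NEG, dtype=np.int64)
        for j in range(1, n + 1):
            e = max(H[j - 1] + gap_open + gap_ext, E[j - 1] + gap_ext)
            f = max(Hprev[j] + gap_open + gap_ext, Fprev[j] + gap_ext)
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            h = max(0, Hprev[j - 1] + sub, e, f)
            E[j] = e
            F[j] = f
            H[j] = h
            if h > best:
                best = h
        Hprev, Eprev, Fprev = H, E, F
    return best


def best_local_score(query: str, subject: str, match=2, mismatch=-3,
                     gap_open=-5, gap_ext=-2) -> int:
    """Exhaustive best local score over both strands of the query."""
    from halomag._align import encode, revcomp  # encoding only, not alignment

    fwd = sw_score_full(encode(query), encode(subject), match, mismatch,
                        gap_open, gap_ext)
    rev = sw_score_full(encode(revcomp(query)), encode(subject), match,
                        mismatch, gap_open, gap_ext)
    return max(fwd, rev)
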