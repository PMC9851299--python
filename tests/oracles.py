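"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the implementation paths they
check: the matcher oracle is an O(n*m) dynamic program over all
order-preserving pairings, and the alignment oracle is a from-scratch
affine-gap Smith-Waterman.
"""

import numpy as np

from abnovo.masses import residue_masses


def brute_force_match(pred, truth, tol, table):
    """Maximum order-preserving matching under the pairwise criterion.

    A pair (i, j) is admissible iff the prefix masses before positions i
    and j differ by < prefix_mass_tol and the residue masses differ by
    < aa_mass_tol; the DP maximises the number of admissible pairs over
    all strictly increasing pairings.
    """
    pm = residue_masses(pred, table)
    tm = residue_masses(truth, table)
    pp = np.concatenate(([0.0], np.cumsum(pm)[:-1]))
    tp = np.concatenate(([0.0], np.cumsum(tm)[:-1]))
    n, m = len(pm), len(tm)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ok = (
                abs(pp[i - 1] - tp[j - 1]) < tol.prefix_mass_tol
                and abs(pm[i - 1] - tm[j - 1]) < tol.aa_mass_tol
            )
            dp[i, j] = max(
                dp[i - 1, j], dp[i, j - 1], dp[i - 1, j - 1] + (1 if ok else 0)
            )
    return int(dp[n, m])


def smith_waterman_score(a, b, match=2, mismatch=-1, gap_open=-2, gap_extend=-1):
    """Best local alignment score with affine gaps, exhaustive DP."""
    n, m = len(a), len(b)
    neg = float("-inf")
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best
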