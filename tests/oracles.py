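"""Independent brute-force oracles shared by the test suite."""

import itertools

import numpy as np


def pdi_bruteforce(y, P):
    """PDI by exhaustive tuple enumeration with 1/t tie credit.

    One observation is taken from each category in every possible way; the
    category-j member earns credit 1 if its predicted probability for
    category j is strictly highest in the tuple, and 1/t under a t-way tie
    at the maximum.  O(prod n_c) — usable only for tiny n, which is the
    point: it is an independent check of the sort-and-count implementation.
    """
    y = np.asarray(y)
    P = np.asarray(P)
    K = P.shape[1]
    idx = [np.flatnonzero(y == c) for c in range(K)]
    per_cat = []
    for j in range(K):
        total = 0.0
        count = 0
        for tup in itertools.product(*idx):
            vals = np.array([P[i, j] for i in tup])
            mx = vals.max()
            winners = np.flatnonzero(vals == mx)
            if j in winners:
                total += 1.0 / len(winners)
            count += 1
        per_cat.append(total / count)
    return float(np.mean(per_cat)), np.array(per_cat)
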