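"""Tukey HSD / Tukey-Kramer pairwise comparisons and compact letter display."""

from __future__ import annotations

import numpy as np
from scipy.stats import studentized_range


def tukey_pairwise_p(means: np.ndarray, ns: np.ndarray, mse: float, df: float) -> np.ndarray:
    """Matrix of Tukey-Kramer adjusted p-values for all group pairs.

    The Kramer extension handles unequal group sizes:
    ``q_ij = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))`` referred to
    the studentized range with ``k`` groups and ``df`` error degrees of
    freedom.  With equal ``n`` this is exact Tukey HSD.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    k = means.size
    P = np.ones((k, k))
    if mse <= 0:
        # no residual noise: any difference is significant, equality is not
        for i in range(k):
            for j in range(i + 1, k):
                p = 0.0 if means[i] != means[j] else 1.0
                P[i, j] = P[j, i] = p
        return P
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(studentized_range.sf(q, k, df))
            P[i, j] = P[j, i] = min(max(p, 0.0), 1.0)
    return P


def compact_letter_display(pvals: np.ndarray, order: np.ndarray, alpha: float = 0.05) -> list[str]:
    """Compact letter display by insert-and-absorb.

    Starts from a single column containing every group; each
    significantly different pair splits the columns containing both;
    columns that become subsets of others are absorbed.  Letters are
    assigned to the surviving columns in the order their first member
    appears in ``order`` (so 'a' goes to the first-displayed group).

    Returns one letter-string per group (original indexing).
    """
    k = pvals.shape[0]
    columns: list[set[int]] = [set(range(k))]
    sig_pairs = [(i, j) for i in range(k) for j in range(i + 1, k) if pvals[i, j] < alpha]
    for i, j in sig_pairs:
        new_cols: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb: drop empties, duplicates, and strict subsets
        cleaned: list[set[int]] = []
        for col in new_cols:
            if col and col not in cleaned:
                cleaned.append(col)
        columns = [c for c in cleaned if not any(c < o for o in cleaned)]
    # order columns by first appearance of their members in display order
    rank = {g: r for r, g in enumerate(order)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = [""] * k
    for idx, col in enumerate(columns):
        ch = _letter(idx)
        for g in sorted(col, key=lambda g: rank[g]):
            letters[g] += ch
    # within each group keep letters in alphabetical order
    return ["".join(sorted(s)) for s in letters]


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
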