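"""Secondary-structure prediction by maximum base pairing.

A Nussinov-style dynamic program over nested (pseudoknot-free) structures,
counting Watson-Crick and G:U wobble pairs, with a minimum hairpin loop of
three unpaired bases. This is a combinatorial folder, not a thermodynamic
one: it is used to decide the pass/fail duplex geometry of candidate miRNA
precursors, for which the count and layout of pairs between the two arms is
what matters, not free energy.

Tie-breaking during traceback is deterministic: when several choices yield
the same pair count, the pair with the smaller opening index is taken.
"""

from __future__ import annotations

import numpy as np

from ._seqs import PAIRABLE, to_dna

MIN_LOOP = 3  # unpaired bases enclosed by any pair
MIN_FOLD_LEN = 50  # shorter sequences are not meaningful precursors


def _pair_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    p = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            if (seq[i], seq[j]) in PAIRABLE:
                p[i, j] = True
    return p


def max_pairing(seq: str) -> int:
    """Maximum number of nested pairs attainable for ``seq``."""
    seq = to_dna(seq)
    n = len(seq)
    if n == 0:
        return 0
    pairable = _pair_matrix(seq)
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        # dp[i, j] with j = i + span, vectorised over the split point k
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            # j paired with some k in [i, j - MIN_LOOP - 1]
            ks = np.nonzero(pairable[i : j - MIN_LOOP, j])[0] + i
            if ks.size:
                left = np.where(ks > i, dp[i, np.maximum(ks - 1, i)], 0)
                left[ks == i] = 0
                inner = dp[ks + 1, j - 1]
                cand = int(np.max(left + inner)) + 1
                if cand > best:
                    best = cand
            dp[i, j] = best
    return int(dp[0, n - 1])


def fold(seq: str) -> str:
    """Fold ``seq`` into a dot-bracket string with maximal pair count.

    Raises ``ValueError`` for sequences shorter than 50 nt, which are too
    short to form a credible stem-loop precursor.
    """
    seq = to_dna(seq)
    n = len(seq)
    if n < MIN_FOLD_LEN:
        raise ValueError(f"sequence of {n} nt is too short to fold (minimum {MIN_FOLD_LEN})")
    pairable = _pair_matrix(seq)
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            ks = np.nonzero(pairable[i : j - MIN_LOOP, j])[0] + i
            if ks.size:
                left = np.where(ks > i, dp[i, np.maximum(ks - 1, i)], 0)
                left[ks == i] = 0
                cand = left + dp[ks + 1, j - 1] + 1
                m = int(np.max(cand))
                if m > best:
                    best = m
            dp[i, j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i, j] == 0:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        # j is paired; take the smallest opening index k achieving the optimum
        target = dp[i, j]
        for k in range(i, j - MIN_LOOP):
            if not pairable[k, j]:
                continue
            left = dp[i, k - 1] if k > i else 0
            if left + dp[k + 1, j - 1] + 1 == target:
                structure[k] = "("
                structure[j] = ")"
                if k > i:
                    stack.append((i, k - 1))
                stack.append((k + 1, j - 1))
                break
    return "".join(structure)


def pair_table(structure: str) -> dict[int, int]:
    """Map each paired position to its partner (both directions)."""
    stack: list[int] = []
    partners: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            partners[i] = j
            partners[j] = i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return partners
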