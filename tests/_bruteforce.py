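"""Exhaustive-enumeration alignment oracle, independent of the package.

Enumerates every monotone alignment path recursively (no dynamic
programming), scoring with the same affine convention the package
defines: a gap of length k costs ``gap_open + k * gap_extend``; a
deletion run followed directly by an insertion run opens a new gap.
Local optima are taken as the maximum over all substring pairs of the
global optimum (terminal-gapped candidates are dominated by smaller
substring pairs, so the maximum is the Smith-Waterman score).
"""

from __future__ import annotations

import math
from functools import lru_cache


def _matrix_dict(matrix) -> dict:
    alpha = matrix.alphabet
    return {(a, b): float(matrix[a, b]) for a in alpha for b in alpha}


class BruteForceAligner:
    def __init__(self, matrix, gap_open: float, gap_extend: float):
        self.m = _matrix_dict(matrix)
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._global = lru_cache(maxsize=None)(self._global_uncached)

    def _global_uncached(self, a: str, b: str) -> float:
        m = self.m
        open_cost = self.gap_open + self.gap_extend
        extend = self.gap_extend
        la, lb = len(a), len(b)
        best = -math.inf

        def rec(i: int, j: int, score: float, state: int) -> None:
            nonlocal best
            if i == la and j == lb:
                if score > best:
                    best = score
                return
            if i < la and j < lb:
                rec(i + 1, j + 1, score + m[a[i], b[j]], 0)
            if i < la:
                rec(i + 1, j, score - (extend if state == 1 else open_cost), 1)
            if j < lb:
                rec(i, j + 1, score - (extend if state == 2 else open_cost), 2)

        rec(0, 0, 0.0, 0)
        return best

    def global_score(self, a: str, b: str) -> float:
        return self._global(a, b)

    def local_score(self, a: str, b: str) -> float:
        best = 0.0
        for i in range(len(a)):
            for k in range(i + 1, len(a) + 1):
                sub_a = a[i:k]
                for j in range(len(b)):
                    for l in range(j + 1, len(b) + 1):
                        s = self._global(sub_a, b[j:l])
                        if s > best:
                            best = s
        return best
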