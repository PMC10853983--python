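"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package internals: alignment by
exhaustive recursion, dotplot windows by direct per-position counting,
longest common substring by substring enumeration, and LTR-pair detection
by exhaustive enumeration of every admissible ungapped (offset, start,
length) triple.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def oracle_global_identity(a: str, b: str, match=1.0, mismatch=-2.0, gap=-2.0):
    """Exhaustive global alignment by recursion; returns (score, identity_pct).

    Identity counts matched columns over non-overhang columns, tracking the
    best identity among all optimal-score alignments.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int):
        # returns dict-free tuple list of (score, matches, columns) pareto?  keep simple:
        if i == len(a) and j == len(b):
            return [(0.0, 0, 0)]
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            for sc, m, c in best(i + 1, j + 1):
                options.append((s + sc, m + (a[i] == b[j]), c + 1))
        if i < len(a):
            for sc, m, c in best(i + 1, j):
                options.append((gap + sc, m, c + 1))
        if j < len(b):
            for sc, m, c in best(i, j + 1):
                options.append((gap + sc, m, c + 1))
        top = max(sc for sc, _, _ in options)
        return [o for o in set(options) if o[0] >= top - 1e-9]

    outcomes = best(0, 0)
    score = outcomes[0][0]
    ident = max(100.0 * m / c for _, m, c in outcomes if c)
    return score, ident


def oracle_window_matches(a: str, b: str, k: int, n: int) -> set:
    """All (i, j) window pairs with at most n mismatches, counted directly."""
    out = set()
    for i in range(len(a) - k + 1):
        wa = a[i : i + k]
        for j in range(len(b) - k + 1):
            wb = b[j : j + k]
            mm = sum(1 for x, y in zip(wa, wb) if x != y)
            if mm <= n:
                out.add((i, j))
    return out


def oracle_lcs(a: str, b: str) -> int:
    """Longest common substring by enumerating substrings of the shorter."""
    if len(a) > len(b):
        a, b = b, a
    best = 0
    for length in range(len(a), 0, -1):
        for i in range(len(a) - length + 1):
            if a[i : i + length] in b:
                return length
    return best


def oracle_ltr_pairs(seq: str, cfg) -> list[tuple[int, int, int, float]]:
    """Every admissible ungapped repeat pair: (start, length, offset, identity).

    Enumerates all (offset d, start, length L) with the copy pair
    seq[start:start+L] vs seq[start+d:start+d+L], keeping those meeting the
    detector's candidate definition: the length, separation and identity
    bounds, plus at least one exact shared word of length ``seed_word``
    (checked here by direct run-length counting).  Exact for
    substitution-only divergence.
    """
    s = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    out = []
    d_lo = cfg.min_ltr + cfg.min_between
    d_hi = min(cfg.max_ltr + cfg.max_between, n - cfg.min_ltr)
    for d in range(d_lo, d_hi + 1):
        m = (s[: n - d] == s[d:]).astype(np.int32)
        pref = np.concatenate([[0], np.cumsum(m)])
        max_len = min(cfg.max_ltr, d - cfg.min_between)
        if max_len < cfg.min_ltr:
            continue
        n_starts = n - d
        if n_starts < cfg.min_ltr:
            continue
        lengths = np.arange(cfg.min_ltr, max_len + 1)
        starts = np.arange(0, n_starts - cfg.min_ltr + 1)
        # matches[s_idx, l_idx] = pref[start+L] - pref[start], masked where start+L > n-d
        ends = starts[:, None] + lengths[None, :]
        valid = ends <= n_starts
        ends_c = np.minimum(ends, n_starts)
        matches = pref[ends_c] - pref[starts][:, None]
        ident = 100.0 * matches / lengths[None, :]
        ok = valid & (ident >= cfg.min_ltr_identity)
        # longest exact match run ending at each position, for the seed check
        runs = np.zeros(n_starts + 1, dtype=np.int32)
        for pos in range(n_starts):
            runs[pos + 1] = runs[pos] + 1 if m[pos] else 0
        for si, li in zip(*np.nonzero(ok)):
            start, length = int(starts[si]), int(lengths[li])
            has_seed = any(
                runs[pos] >= cfg.seed_word
                for pos in range(start + cfg.seed_word, start + length + 1)
            )
            if has_seed:
                out.append((start, length, d, float(ident[si, li])))
    return out


def oracle_resolve(pairs: list[tuple[int, int, int, float]]) -> list[tuple[int, int]]:
    """Apply the detector's overlap-resolution rule to oracle pairs; returns
    the resolved element spans [(start, end), ...] sorted by position."""
    cands = [
        (start, start + length + d, ident) for start, length, d, ident in pairs
    ]
    ranked = sorted(cands, key=lambda c: (-c[2], -(c[1] - c[0]), c[0]))
    kept: list[tuple[int, int, float]] = []
    for c in ranked:
        ok = True
        for k in kept:
            ov = max(0, min(c[1], k[1]) - max(c[0], k[0]))
            if ov / min(c[1] - c[0], k[1] - k[0]) >= 0.5:
                ok = False
                break
        if ok:
            kept.append(c)
    return sorted((c[0], c[1]) for c in kept)
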