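"""Windowed dotplot comparison of element sequences.

A dot marks every pair of windows (k = 12 by default) that differ at no
more than n = 3 positions; each pairwise panel is shaded by the longest
exact common substring normalised by the shorter sequence's length.
Rendering is optional and never affects the computed results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cassfinder.seqtypes import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class DotplotConfig:
    k: int = 12
    n: int = 3
    both_strands: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n < self.k):
            raise ValueError("need 0 <= n < k")


@dataclass
class DotplotResult:
    id_a: str
    id_b: str
    matches: set  # of (i, j) window starts
    shade_metric: float  # LCS length / min(len a, len b), in [0, 1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype="S1")


def _window_matches_arrays(a: np.ndarray, b: np.ndarray, k: int, n: int) -> set:
    la, lb = len(a), len(b)
    if la < k or lb < k:
        return set()
    # mismatch counts for all (i, j) via k shifted equality layers
    counts = np.zeros((la - k + 1, lb - k + 1), dtype=np.int16)
    for t in range(k):
        counts += a[t : la - k + 1 + t, None] != b[None, t : lb - k + 1 + t]
    ii, jj = np.nonzero(counts <= n)
    return set(zip(ii.tolist(), jj.tolist()))


def window_matches(
    a: SequenceRecord | str, b: SequenceRecord | str, cfg: DotplotConfig | None = None
) -> set:
    """All (i, j) with Hamming(a[i:i+k], b[j:j+k]) <= n."""
    cfg = cfg or DotplotConfig()
    sa = a.residues if isinstance(a, SequenceRecord) else a.upper()
    sb = b.residues if isinstance(b, SequenceRecord) else b.upper()
    if len(sa) < cfg.k or len(sb) < cfg.k:
        warnings.warn("sequence shorter than the window size; no matches")
        return set()
    matches = _window_matches_arrays(_encode(sa), _encode(sb), cfg.k, cfg.n)
    if cfg.both_strands:
        rc = _encode(reverse_complement(sb))
        for i, j in _window_matches_arrays(_encode(sa), rc, cfg.k, cfg.n):
            matches.add((i, len(sb) - cfg.k - j))
    return matches


def longest_common_substring(a: SequenceRecord | str, b: SequenceRecord | str) -> int:
    """Length of the longest exact shared substring (dynamic programming)."""
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        return 0
    aa = _encode(sa.upper())
    bb = _encode(sb.upper())
    prev = np.zeros(len(sb) + 1, dtype=np.int32)
    best = 0
    for i in range(1, len(sa) + 1):
        cur = np.zeros(len(sb) + 1, dtype=np.int32)
        eq = bb == aa[i - 1]
        cur[1:][eq] = prev[:-1][eq] + 1
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def compare_pair(
    a: SequenceRecord, b: SequenceRecord, cfg: DotplotConfig | None = None
) -> DotplotResult:
    cfg = cfg or DotplotConfig()
    lcs = longest_common_substring(a, b)
    return DotplotResult(
        id_a=a.id,
        id_b=b.id,
        matches=window_matches(a, b, cfg),
        shade_metric=lcs / min(len(a.residues), len(b.residues)),
    )


def all_vs_all(
    seqs: list[SequenceRecord], cfg: DotplotConfig | None = None
) -> dict[tuple[str, str], DotplotResult]:
    """Dotplot results for every ordered pair (the grid of panels)."""
    cfg = cfg or DotplotConfig()
    grid: dict[tuple[str, str], DotplotResult] = {}
    for a in seqs:
        for b in seqs:
            key = (a.id, b.id)
            if (b.id, a.id) in grid and a.id != b.id:
                prior = grid[(b.id, a.id)]
                grid[key] = DotplotResult(
                    id_a=a.id,
                    id_b=b.id,
                    matches={(j, i) for i, j in prior.matches},
                    shade_metric=prior.shade_metric,
                )
            else:
                grid[key] = compare_pair(a, b, cfg)
    return grid


def match_rows(grid: dict[tuple[str, str], DotplotResult]) -> list[dict]:
    rows = []
    for (ida, idb), res in sorted(grid.items()):
        for i, j in sorted(res.matches):
            rows.append({"seq_a": ida, "seq_b": idb, "i": i, "j": j})
    return rows


def shade_rows(grid: dict[tuple[str, str], DotplotResult]) -> list[dict]:
    return [
        {"seq_a": ida, "seq_b": idb, "shade_metric": f"{res.shade_metric:.4f}", "n_matches": len(res.matches)}
        for (ida, idb), res in sorted(grid.items())
    ]


def render_grid(grid, seqs, path) -> None:
    """Optional raster rendering of the all-vs-all grid (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = [s.id for s in seqs]
    n = len(ids)
    fig, axes = plt.subplots(n, n, figsize=(2 * n, 2 * n), squeeze=False)
    for r, ida in enumerate(ids):
        for c, idb in enumerate(ids):
            ax = axes[r][c]
            res = grid[(ida, idb)]
            shade = 1.0 - 0.8 * res.shade_metric
            ax.set_facecolor((shade, shade, shade))
            if res.matches:
                xs, ys = zip(*sorted(res.matches))
                ax.plot(ys, xs, ".", markersize=1, color="black")
            ax.invert_yaxis()
            ax.set_xticks([])
            ax.set_yticks([])
            if r == 0:
                ax.set_title(idb, fontsize=6)
            if c == 0:
                ax.set_ylabel(ida, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
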