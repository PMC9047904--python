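"""Nonparametric statistics for the evoked-response feature grids.

Implements the Wilcoxon rank-sum (Mann–Whitney) test, the Kruskal–Wallis
H test and Dunn's pairwise post-hoc z-tests from their rank formulas, with
midrank tie handling.  For small samples the rank-sum p-value is obtained
by exact enumeration over rank assignments; for larger samples the normal
approximation with tie correction is used.  The significance grid mirrors
the layer × feature tables of the study: the diagonal compares UP vs DOWN
at each intensity (rank-sum), off-diagonal cells compare intensity pairs
within UP (upper triangle) and DOWN (lower triangle) via Dunn's test gated
by a Kruskal–Wallis rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

ALPHA = 0.05
#: largest number of rank assignments enumerated exactly
EXACT_ENUM_LIMIT = 200_000

STAR_LEVELS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def stars(p: float) -> str:
    for thr, s in STAR_LEVELS:
        if p <= thr:
            return s
    return "ns"


def _rank_sum_stat(ranks_a: np.ndarray) -> float:
    return float(np.sum(ranks_a))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value with midrank ties.

    Exact enumeration over all C(n_a+n_b, n_a) rank assignments when that
    count is small enough, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = rankdata(pooled)
    n1, n2 = a.size, b.size
    w = _rank_sum_stat(ranks[:n1])
    if comb(n1 + n2, n1) <= EXACT_ENUM_LIMIT:
        # exact: null distribution of the rank sum over all assignments
        sums = np.fromiter(
            (ranks[list(idx)].sum() for idx in combinations(range(n1 + n2), n1)),
            dtype=float,
            count=comb(n1 + n2, n1),
        )
        mu = sums.mean()
        tail = np.mean(np.abs(sums - mu) >= abs(w - mu) - 1e-12)
        return float(min(tail, 1.0))
    mu = n1 * (n1 + n2 + 1) / 2.0
    tie_term = _tie_correction_sum(pooled)
    n = n1 + n2
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / np.sqrt(var)
    return float(min(2.0 * norm.sf(abs(z)), 1.0))


def _tie_correction_sum(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def kruskal_wallis(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis p-value (chi-square approximation)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + g.size]
        h += r.sum() ** 2 / g.size
        i += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie = 1.0 - _tie_correction_sum(pooled) / (n**3 - n)
    if tie <= 0:
        return 1.0
    h /= tie
    return float(chi2.sf(h, df=len(groups) - 1))


def dunn_pairwise(
    groups: list[np.ndarray], adjust: str = "none"
) -> dict[tuple[int, int], float]:
    """Dunn's z-test p-values for all group pairs (midrank ties corrected)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = rankdata(pooled)
    mean_ranks, sizes, i = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[i : i + g.size].mean())
        sizes.append(g.size)
        i += g.size
    tie_term = _tie_correction_sum(pooled) / (12.0 * (n - 1))
    out = {}
    for (i, j) in combinations(range(len(groups)), 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
        )
        if se == 0:
            out[(i, j)] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        out[(i, j)] = float(min(2.0 * norm.sf(abs(z)), 1.0))
    if adjust == "holm":
        out = _holm(out)
    elif adjust != "none":
        raise ValueError("adjust must be 'none' or 'holm'")
    return out


def _holm(pvals: dict) -> dict:
    items = sorted(pvals.items(), key=lambda kv: kv[1])
    m = len(items)
    adj, running = {}, 0.0
    for rank, (k, p) in enumerate(items):
        running = max(running, min((m - rank) * p, 1.0))
        adj[k] = running
    return adj


def kruskal_dunn(groups: list[np.ndarray], alpha: float = ALPHA, adjust="none"):
    """KW omnibus p plus Dunn pairwise p's; pairs are ns unless KW rejects."""
    kw_p = kruskal_wallis(groups)
    if kw_p <= alpha:
        pairs = dunn_pairwise(groups, adjust=adjust)
    else:
        pairs = {k: np.nan for k in combinations(range(len(groups)), 2)}
    return kw_p, pairs


@dataclass
class SigCell:
    feature: str
    layer: str
    comparison: str  # e.g. "UPvsDOWN@large", "large-vs-small@UP"
    p: float
    stars: str
    direction: str  # "increase" | "decrease" | "none"
    n: tuple


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    d = np.median(a) - np.median(b)
    if d > 0:
        return "increase"
    if d < 0:
        return "decrease"
    return "none"


def build_sig_table(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    alpha: float = ALPHA,
    adjust: str = "none",
) -> pd.DataFrame:
    """Significance grid over layers × features.

    ``features`` is a long table with columns layer, amp_class, state and one
    column per feature.  Missing-feature trials are dropped per cell.
    """
    meta = {"trial", "layer", "amp_class", "state"}
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c not in meta]
    classes = ["large", "medium", "small"]
    cells: list[SigCell] = []
    for feat in feature_cols:
        for layer, sub in features.groupby("layer", sort=False):
            def vals(amp, state):
                v = sub[(sub.amp_class == amp) & (sub.state == state)][feat]
                return v.dropna().to_numpy()

            # diagonal: UP vs DOWN per intensity
            for amp in classes:
                up, down = vals(amp, "UP"), vals(amp, "DOWN")
                if up.size < 1 or down.size < 1:
                    cells.append(
                        SigCell(feat, layer, f"UPvsDOWN@{amp}", np.nan, "ns",
                                "none", (up.size, down.size))
                    )
                    continue
                p = wilcoxon_rank_sum(up, down)
                cells.append(
                    SigCell(feat, layer, f"UPvsDOWN@{amp}", p, stars(p),
                            _direction(up, down), (up.size, down.size))
                )
            # off-diagonal: intensity pairs within each state (Dunn gated by KW)
            for state in ("UP", "DOWN"):
                groups = [vals(c, state) for c in classes]
                if any(g.size < 2 for g in groups):
                    for i, j in combinations(range(3), 2):
                        cells.append(
                            SigCell(feat, layer,
                                    f"{classes[i]}-vs-{classes[j]}@{state}",
                                    np.nan, "ns", "none",
                                    (groups[i].size, groups[j].size))
                        )
                    continue
                _, pairs = kruskal_dunn(groups, alpha=alpha, adjust=adjust)
                for (i, j), p in pairs.items():
                    cells.append(
                        SigCell(
                            feat, layer, f"{classes[i]}-vs-{classes[j]}@{state}",
                            p, "ns" if np.isnan(p) else stars(p),
                            _direction(groups[i], groups[j]),
                            (groups[i].size, groups[j].size),
                        )
                    )
    return pd.DataFrame([c.__dict__ for c in cells])
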