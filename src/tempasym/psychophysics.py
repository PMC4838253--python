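"""Paired-comparison scaling of tonal salience (Bradley-Terry-Luce).

Listeners hear pairs of stimuli and report which member is "more tonal".
Under the BTL model each item i carries a positive strength S_i and

    P(i beats j) = S_i / (S_i + S_j).

The maximum-likelihood strengths are found by the standard
minorisation-maximisation iteration; only strength ratios are identified,
so the fitted scale is normalised to sum to one.  The schedule presents
every ordered pair of distinct items, i.e. n(n-1) trials per block
(90 for the 10 experimental conditions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import AsymmetryResult, asymmetry_index

__all__ = [
    "PairedComparisonTable",
    "SalienceScale",
    "pair_schedule",
    "btl_fit",
    "btl_win_probability",
    "salience_ai",
    "read_win_table",
    "write_win_table",
]


@dataclass
class PairedComparisonTable:
    """Win-count matrix: wins[i, j] = times item i beat item j."""

    items: list[str]
    wins: np.ndarray

    def __post_init__(self) -> None:
        self.wins = np.asarray(self.wins, dtype=float)
        n = len(self.items)
        if self.wins.shape != (n, n):
            raise ValueError("wins must be an items x items matrix")
        if np.any(self.wins < 0):
            raise ValueError("win counts must be non-negative")
        if np.any(np.diag(self.wins) != 0):
            raise ValueError("diagonal of the win matrix must be zero")

    @property
    def n_items(self) -> int:
        return len(self.items)

    def presentations(self) -> np.ndarray:
        return self.wins + self.wins.T


@dataclass
class SalienceScale:
    """Relative pitch-salience strengths (sum to one) with rough standard
    errors from the inverse observed information (diagonal)."""

    items: list[str]
    strengths: np.ndarray
    std_errors: np.ndarray
    boundary_items: list[str] = field(default_factory=list)

    def __getitem__(self, item: str) -> float:
        return float(self.strengths[self.items.index(item)])


def pair_schedule(n_items: int) -> list[tuple[int, int]]:
    """All ordered pairs (i, j), i != j: n(n-1) trials.

    Ten conditions give 45 unordered pairs, presented in both orders for
    90 trials per block.
    """
    if n_items < 2:
        raise ValueError("need at least 2 items")
    return list(itertools.permutations(range(n_items), 2))


def _connected(pres: np.ndarray) -> bool:
    n = pres.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in np.flatnonzero(pres[i] > 0):
            if j not in seen:
                seen.add(j)
                frontier.append(int(j))
    return len(seen) == n


def btl_fit(
    table: PairedComparisonTable,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    regularize: bool = False,
) -> SalienceScale:
    """Maximum-likelihood BTL strengths via minorisation-maximisation.

    Items that win or lose every comparison have no interior MLE; they are
    flagged (and, with ``regularize=True``, stabilised by adding half a
    pseudo-win in each direction of every played pair).
    """
    wins = table.wins.copy()
    n = table.n_items
    pres = table.presentations()
    if np.any(pres.sum(axis=1) == 0):
        raise ValueError("an item is involved in no comparisons")
    if not _connected(pres):
        raise ValueError("comparison graph is disconnected; scale inestimable")

    total_wins = wins.sum(axis=1)
    total_losses = wins.sum(axis=0)
    boundary = [
        table.items[i]
        for i in range(n)
        if total_wins[i] == 0 or total_losses[i] == 0
    ]
    if regularize and boundary:
        played = pres > 0
        wins = wins + 0.5 * played
        pres = wins + wins.T

    s = np.full(n, 1.0 / n)
    w_i = wins.sum(axis=1)
    for _ in range(max_iter):
        denom = s[:, None] + s[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(pres > 0, pres / denom, 0.0)
        new = w_i / ratio.sum(axis=1)
        new = np.where(np.isfinite(new) & (new > 0), new, 1e-12)
        new /= new.sum()
        if np.max(np.abs(new - s)) < tol:
            s = new
            break
        s = new

    # curvature-based standard errors on log-strengths, mapped back
    denom = s[:, None] + s[None, :]
    p_ij = s[:, None] / denom
    info = np.where(pres > 0, pres * p_ij * (1 - p_ij), 0.0).sum(axis=1)
    with np.errstate(divide="ignore"):
        se = s / np.sqrt(np.maximum(info, 1e-300))
    return SalienceScale(list(table.items), s, se, boundary)


def btl_win_probability(scale: SalienceScale, i: str, j: str) -> float:
    si, sj = scale[i], scale[j]
    return si / (si + sj)


def salience_ai(
    scale: SalienceScale,
    half_lives_ms=(0.5, 1.0, 4.0, 16.0, 32.0),
) -> list[AsymmetryResult]:
    """Per-half-life asymmetry index of BTL salience, AI_S.

    Expects items labelled ``ramped_{hl:g}ms`` / ``damped_{hl:g}ms``.
    """
    out = []
    for hl in half_lives_ms:
        r_key = f"ramped_{hl:g}ms"
        d_key = f"damped_{hl:g}ms"
        if r_key not in scale.items or d_key not in scale.items:
            raise KeyError(f"missing condition for T1/2 = {hl} ms")
        s_r, s_d = scale[r_key], scale[d_key]
        out.append(AsymmetryResult(hl, s_r, s_d, asymmetry_index(s_r, s_d)))
    return out


def write_win_table(table: PairedComparisonTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(table.wins, index=table.items, columns=table.items)
    df.to_csv(path, sep="\t")
    return path


def read_win_table(path: str | Path) -> PairedComparisonTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PairedComparisonTable(list(df.index), df.to_numpy())
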