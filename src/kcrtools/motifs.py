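"""Flanking-window extraction and iterative motif discovery around Kcr sites.

Implements the classic motif-x strategy: ±10-residue windows around each
modified lysine form the foreground, windows around every lysine of the
searched database form the background, and motifs are grown greedily, one
(offset, residue) constraint at a time, each accepted by a binomial
upper-tail test against the background frequency at that offset. Also
provides the position × residue log2-odds matrix behind residue-abundance
heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import AMINO_ACIDS, ProteinRecord

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_MIN_OCCURRENCES = 20


@dataclass(frozen=True)
class KcrWindow:
    """A 21-mer around a modified K (index 10, 0-based), '_'-padded at termini."""

    protein_id: str
    position: int
    window: str


@dataclass
class MotifModel:
    """An accepted motif with counts against the original fg/bg sets."""

    constraints: tuple[tuple[int, str], ...]
    fg_matches: int
    fg_total: int
    bg_matches: int
    bg_total: int
    fold_increase: float
    step_pvalues: list[float] = field(default_factory=list)

    @property
    def name(self) -> str:
        return motif_name(self.constraints)


def motif_name(constraints: tuple[tuple[int, str], ...], center: str = "Kcr") -> str:
    """Render constraints in the compact field notation, e.g. ``FKcrE``.

    Unconstrained positions between the outermost constraints and the
    center are shown as '.'.
    """
    by_off = dict(constraints)
    lo = min(0, *by_off)
    hi = max(0, *by_off)
    parts = []
    for off in range(lo, hi + 1):
        if off == 0:
            parts.append(center)
        else:
            parts.append(by_off.get(off, "."))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_windows(
    proteins: list[ProteinRecord],
    sites: list[tuple[str, int]],
    flank: int = 10,
    pad: str = "_",
) -> list[KcrWindow]:
    """Cut a ``2*flank+1`` window around each site, padding at the termini."""
    seqs = {p.protein_id: p.sequence for p in proteins}
    out = []
    for pid, pos1 in sites:
        seq = seqs.get(pid)
        if seq is None:
            raise ValueError(f"site refers to unknown protein {pid!r}")
        if not 1 <= pos1 <= len(seq):
            raise ValueError(f"site position {pos1} outside protein {pid!r}")
        if seq[pos1 - 1] != "K":
            raise ValueError(f"site {pid!r}:{pos1} is {seq[pos1 - 1]!r}, not K")
        i = pos1 - 1
        left = seq[max(0, i - flank): i]
        right = seq[i + 1: i + 1 + flank]
        window = (
            pad * (flank - len(left)) + left + seq[i] + right
            + pad * (flank - len(right))
        )
        out.append(KcrWindow(pid, pos1, window))
    return out


def background_windows(
    proteins: list[ProteinRecord], residue: str = "K", flank: int = 10
) -> list[KcrWindow]:
    """One window per occurrence of ``residue`` in every database protein."""
    out = []
    for prot in proteins:
        sites = [
            (prot.protein_id, i + 1)
            for i, r in enumerate(prot.sequence)
            if r == residue
        ]
        out.extend(extract_windows([prot], sites, flank=flank))
    return out


# ---------------------------------------------------------------------------
# Binomial significance kernel
# ---------------------------------------------------------------------------

def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), stable for extreme tails."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


# ---------------------------------------------------------------------------
# Iterative motif search
# ---------------------------------------------------------------------------

def _as_matrix(windows: list[str]) -> np.ndarray:
    return np.array([list(w) for w in windows])


def _check_windows(fg: list[str], bg: list[str]) -> tuple[int, int]:
    lengths = {len(w) for w in fg} | {len(w) for w in bg}
    if len(lengths) != 1:
        raise ValueError(f"windows of mixed lengths: {sorted(lengths)}")
    (length,) = lengths
    center = length // 2
    centers = {w[center] for w in fg}
    if len(centers) != 1:
        raise ValueError(f"foreground windows with mixed center residues: {centers}")
    return length, center


def _best_candidate(
    fg_mat: np.ndarray,
    bg_mat: np.ndarray,
    center: int,
    fixed: set[int],
    min_occurrences: int,
    pad: str,
) -> tuple[float, int, str, int] | None:
    """Scan all free (offset, residue) cells; return the minimal-p candidate.

    Cells with foreground support below ``min_occurrences`` are not
    candidates. Ties are broken deterministically: smaller \\|offset\\|
    first, then the negative offset before the positive, then
    alphabetically by residue. Returns (p, offset, residue, k) or None when
    no candidate exists.
    """
    if len(fg_mat) == 0 or len(bg_mat) == 0:
        return None
    length = fg_mat.shape[1]
    best = None
    for col in range(length):
        if col == center or col in fixed:
            continue
        off = col - center
        fg_col = fg_mat[:, col]
        bg_col = bg_mat[:, col]
        n = int((fg_col != pad).sum())
        bg_n = int((bg_col != pad).sum())
        if n == 0 or bg_n == 0:
            continue
        for res in AMINO_ACIDS:
            k = int((fg_col == res).sum())
            if k < min_occurrences:
                continue
            p0 = int((bg_col == res).sum()) / bg_n
            pval = binomial_upper_tail(k, n, p0)
            key = (pval, abs(off), 0 if off < 0 else 1, res)
            if best is None or key < best[0]:
                best = (key, off, res, k)
    if best is None:
        return None
    return best[0][0], best[1], best[2], best[3]


def _matches(mat: np.ndarray, center: int, constraints) -> np.ndarray:
    mask = np.ones(len(mat), dtype=bool)
    for off, res in constraints:
        mask &= mat[:, center + off] == res
    return mask


def find_motifs(
    fg: list[KcrWindow] | list[str],
    bg: list[KcrWindow] | list[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    max_motifs: int = 50,
    pad: str = "_",
) -> list[MotifModel]:
    """Greedy iterative motif extraction (motif-x style).

    Within a motif build the most significant free (offset, residue) cell
    is accepted while its binomial upper-tail p-value is at most
    ``p_threshold`` and its foreground support is at least
    ``min_occurrences``; both foreground and background are then reduced to
    the matching windows. When no candidate passes, the motif is emitted,
    its foreground matches are removed from the global foreground, the full
    background is restored, and the search restarts. Reported counts and
    the fold increase refer to the original input sets.
    """
    fg_str = [w.window if isinstance(w, KcrWindow) else w for w in fg]
    bg_str = [w.window if isinstance(w, KcrWindow) else w for w in bg]
    if not fg_str:
        raise ValueError("foreground window set is empty")
    _, center = _check_windows(fg_str, bg_str)
    fg0 = _as_matrix(fg_str)
    bg0 = _as_matrix(bg_str)
    fg_global = fg0.copy()
    motifs: list[MotifModel] = []
    while len(motifs) < max_motifs and len(fg_global) > 0:
        fg_cur = fg_global
        bg_cur = bg0
        constraints: list[tuple[int, str]] = []
        pvals: list[float] = []
        fixed: set[int] = set()
        while True:
            cand = _best_candidate(fg_cur, bg_cur, center, fixed, min_occurrences, pad)
            if cand is None:
                break
            pval, off, res, k = cand
            if pval > p_threshold:
                break
            constraints.append((off, res))
            pvals.append(pval)
            fixed.add(center + off)
            fg_cur = fg_cur[fg_cur[:, center + off] == res]
            bg_cur = bg_cur[bg_cur[:, center + off] == res]
        if not constraints:
            break
        cons = tuple(constraints)
        fg_matches = int(_matches(fg0, center, cons).sum())
        bg_matches = int(_matches(bg0, center, cons).sum())
        fold = (fg_matches / len(fg0)) / (bg_matches / len(bg0)) if bg_matches else float("inf")
        motifs.append(
            MotifModel(cons, fg_matches, len(fg0), bg_matches, len(bg0), fold, pvals)
        )
        fg_global = fg_global[~_matches(fg_global, center, cons)]
    return motifs


# ---------------------------------------------------------------------------
# Position x residue enrichment matrix
# ---------------------------------------------------------------------------

def enrichment_matrix(
    fg: list[KcrWindow] | list[str],
    bg: list[KcrWindow] | list[str],
    pseudocount: float = 0.5,
    pad: str = "_",
) -> pd.DataFrame:
    """Log2 odds of residue frequency at each offset, foreground vs background.

    Rows are signed offsets, columns residues. Pad characters count as
    non-observations on both sides. A residue absent from both sets at an
    offset — and the whole center column — is left undefined (NaN).
    """
    fg_str = [w.window if isinstance(w, KcrWindow) else w for w in fg]
    bg_str = [w.window if isinstance(w, KcrWindow) else w for w in bg]
    _, center = _check_windows(fg_str, bg_str)
    fg_mat = _as_matrix(fg_str)
    bg_mat = _as_matrix(bg_str)
    length = fg_mat.shape[1]
    offsets = [c - center for c in range(length)]
    data = np.full((length, 20), np.nan)
    for col in range(length):
        if col == center:
            continue
        fg_col = fg_mat[:, col]
        bg_col = bg_mat[:, col]
        fg_n = int((fg_col != pad).sum())
        bg_n = int((bg_col != pad).sum())
        if fg_n == 0 or bg_n == 0:
            continue
        for j, res in enumerate(AMINO_ACIDS):
            fg_k = int((fg_col == res).sum())
            bg_k = int((bg_col == res).sum())
            if fg_k == 0 and bg_k == 0:
                continue
            fg_f = (fg_k + pseudocount) / (fg_n + 20 * pseudocount)
            bg_f = (bg_k + pseudocount) / (bg_n + 20 * pseudocount)
            data[col, j] = np.log2(fg_f) - np.log2(bg_f)
    return pd.DataFrame(data, index=offsets, columns=list(AMINO_ACIDS))


def motifs_frame(motifs: list[MotifModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"name": m.name,
             "constraints": ";".join(f"{off:+d}{res}" for off, res in m.constraints),
             "fg_matches": m.fg_matches, "fg_total": m.fg_total,
             "bg_matches": m.bg_matches, "bg_total": m.bg_total,
             "fold_increase": m.fold_increase}
            for m in motifs
        ]
    )
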