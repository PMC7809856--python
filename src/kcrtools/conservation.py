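"""Cross-species conservation of crotonylated lysines.

Orthologs between the query proteome (crotonylated proteins) and each
subject species are found by reciprocal best hit (RBH) over exact
Smith–Waterman local alignment scores (BLOSUM62, affine gaps −11/−1).
Each ortholog pair is then globally aligned (Needleman–Wunsch) and every
query lysine mapped through the alignment: conserved iff the aligned
subject column is also lysine (a gap is not). Lysines are partitioned into
crotonylated and control classes, counts accumulated per species, and the
class difference tested with a two-tailed Fisher's exact test.

The exact dynamic-programming scorer stands where a heuristic search tool
would at proteome scale; it ranks hits deterministically with no external
binary. A score floor guards against spurious RBH pairs between unrelated
short sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import hypergeom

log = logging.getLogger(__name__)

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ScoringScheme:
    """Alignment scoring: substitution matrix plus affine gap penalties.

    ``gap_open`` is charged for the first residue of a gap and
    ``gap_extend`` for each subsequent one. A matrix in NCBI format can be
    loaded with :func:`load_matrix`.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    min_rbh_score: float = 50.0
    _matrix: substitution_matrices.Array | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self._matrix is None:
            self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self) -> substitution_matrices.Array:
        return self._matrix


def load_matrix(path: str) -> substitution_matrices.Array:
    """Read a substitution matrix in standard NCBI text format."""
    with open(path) as fh:
        return substitution_matrices.read(fh)


@dataclass(frozen=True)
class OrthologPair:
    query_id: str
    subject_species: str
    subject_id: str
    forward_score: float
    reverse_score: float


@dataclass
class ConservationSummary:
    species: str
    kcr_conserved: int
    kcr_total: int
    ctrl_conserved: int
    ctrl_total: int
    fisher_p: float | None = None

    @property
    def kcr_pct(self) -> float:
        return 100.0 * self.kcr_conserved / self.kcr_total if self.kcr_total else 0.0

    @property
    def ctrl_pct(self) -> float:
        return 100.0 * self.ctrl_conserved / self.ctrl_total if self.ctrl_total else 0.0


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = float(scheme.gap_open)
    aligner.extend_gap_score = float(scheme.gap_extend)
    return aligner


def align_pair(
    a: str, b: str, scheme: ScoringScheme | None = None, mode: str = "global"
) -> tuple[float, str, str]:
    """Optimal pairwise alignment; returns (score, aligned_a, aligned_b).

    ``global`` (Needleman–Wunsch) for conservation counting, ``local``
    (Smith–Waterman) for RBH hit ranking. Gap columns are '-'.
    """
    scheme = scheme or ScoringScheme()
    for name, seq in (("a", a), ("b", b)):
        if not seq:
            raise ValueError(f"sequence {name} is empty")
        bad = set(seq) - _STANDARD
        if bad:
            raise ValueError(f"sequence {name} has non-standard residues {sorted(bad)}")
    aligner = _aligner(scheme, mode)
    aln = aligner.align(a, b)[0]
    return float(aln.score), str(aln[0]), str(aln[1])


def alignment_score(
    a: str, b: str, scheme: ScoringScheme | None = None, mode: str = "local"
) -> float:
    """Score-only alignment (fast path for all-vs-all RBH scans)."""
    scheme = scheme or ScoringScheme()
    return float(_aligner(scheme, mode).score(a, b))


# ---------------------------------------------------------------------------
# Reciprocal best hit orthology
# ---------------------------------------------------------------------------

def find_rbh(
    query_db,
    subject_db,
    scheme: ScoringScheme | None = None,
    subject_species: str = "",
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    For each query the best local-alignment score over all subjects is
    found (and vice versa); a pair is kept iff the two selections point at
    each other and the score clears the scheme's ``min_rbh_score`` floor.
    Score ties are broken lexicographically by sequence id and logged.
    """
    scheme = scheme or ScoringScheme()
    if not query_db or not subject_db:
        raise ValueError("both databases must be non-empty")
    scores: dict[tuple[str, str], float] = {}
    for q in query_db:
        for s in subject_db:
            scores[(q.protein_id, s.protein_id)] = alignment_score(
                q.sequence, s.sequence, scheme, mode="local"
            )

    def best(ids_a, ids_b, lookup):
        out = {}
        for a in ids_a:
            ranked = sorted(ids_b, key=lambda b: (-lookup(a, b), b))
            top = ranked[0]
            if len(ranked) > 1 and lookup(a, top) == lookup(a, ranked[1]):
                log.info(
                    "best-hit tie for %s: %s vs %s (score %.1f); keeping %s",
                    a, top, ranked[1], lookup(a, top), top,
                )
            out[a] = top
        return out

    q_ids = [q.protein_id for q in query_db]
    s_ids = [s.protein_id for s in subject_db]
    fwd = best(q_ids, s_ids, lambda q, s: scores[(q, s)])
    rev = best(s_ids, q_ids, lambda s, q: scores[(q, s)])
    pairs = []
    for q in q_ids:
        s = fwd[q]
        if rev[s] == q and scores[(q, s)] >= scheme.min_rbh_score:
            pairs.append(OrthologPair(q, subject_species, s, scores[(q, s)], scores[(q, s)]))
    return pairs


# ---------------------------------------------------------------------------
# Conservation counting
# ---------------------------------------------------------------------------

def count_conservation(
    aligned_query: str,
    aligned_subject: str,
    kcr_positions: set[int],
) -> tuple[int, int, int, int]:
    """Count conserved lysines of the query through a global alignment.

    Returns (kcr_conserved, kcr_total, ctrl_conserved, ctrl_total).
    ``kcr_positions`` are 1-based positions in the ungapped query. A query
    K is conserved iff the aligned subject column is 'K'; a gap is never
    conserved.
    """
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned strings differ in length")
    kcr_cons = kcr_tot = ctrl_cons = ctrl_tot = 0
    qpos = 0
    for qc, sc in zip(aligned_query, aligned_subject):
        if qc == "-":
            continue
        qpos += 1
        if qc != "K":
            continue
        conserved = sc == "K"
        if qpos in kcr_positions:
            kcr_tot += 1
            kcr_cons += conserved
        else:
            ctrl_tot += 1
            ctrl_cons += conserved
    assert qpos == len(aligned_query.replace("-", ""))
    return kcr_cons, kcr_tot, ctrl_cons, ctrl_tot


def conservation_summary(
    query_db,
    subject_db,
    species: str,
    kcr_sites: list[tuple[str, int]],
    scheme: ScoringScheme | None = None,
    pairs: list[OrthologPair] | None = None,
) -> tuple[ConservationSummary, list[OrthologPair]]:
    """RBH + global alignment + lysine conservation counts for one species."""
    scheme = scheme or ScoringScheme()
    if pairs is None:
        pairs = find_rbh(query_db, subject_db, scheme, subject_species=species)
    q_seqs = {p.protein_id: p.sequence for p in query_db}
    s_seqs = {p.protein_id: p.sequence for p in subject_db}
    sites_by_prot: dict[str, set[int]] = {}
    for pid, pos in kcr_sites:
        sites_by_prot.setdefault(pid, set()).add(pos)
    totals = [0, 0, 0, 0]
    for pair in sorted(pairs, key=lambda p: p.query_id):
        _, aq, asub = align_pair(
            q_seqs[pair.query_id], s_seqs[pair.subject_id], scheme, mode="global"
        )
        counts = count_conservation(aq, asub, sites_by_prot.get(pair.query_id, set()))
        totals = [t + c for t, c in zip(totals, counts)]
    summary = ConservationSummary(species, *totals)
    summary.fisher_p = fisher_two_tailed(
        [
            [summary.kcr_conserved, summary.kcr_total - summary.kcr_conserved],
            [summary.ctrl_conserved, summary.ctrl_total - summary.ctrl_conserved],
        ]
    )
    return summary, pairs


# ---------------------------------------------------------------------------
# Fisher's exact test (two-tailed, point-probability criterion)
# ---------------------------------------------------------------------------

def fisher_two_tailed(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table of counts.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed that of the observed
    table (allowing 1e-7 relative slack against floating-point ties).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"counts must be non-negative integers, got {table}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = range(lo, hi + 1)
    pmf = hypergeom.pmf(list(support), n, col1, row1)
    p_obs = pmf[a - lo]
    total = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    # when every table qualifies the mass sums to 1 up to rounding
    if total >= 1.0 - 1e-12:
        return 1.0
    return total
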