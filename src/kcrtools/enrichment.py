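"""Term enrichment of a differential protein set by Fisher's exact test.

Given a user-supplied annotation map (term -> protein set), each term is
tested with a two-tailed Fisher's exact test on the 2x2 table of
differential vs background membership, corrected across terms with
Benjamini–Hochberg (or Bonferroni). The background defaults to all
identified proteins of the run. Annotation retrieval (GO/KEGG lookup,
graph propagation) is out of scope: the map is an input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .conservation import fisher_two_tailed


@dataclass
class AnnotationMap:
    term_to_proteins: dict[str, set[str]]
    metadata: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = sorted(t for t, s in self.term_to_proteins.items() if not s)
        if empty:
            raise ValueError(f"terms with empty protein sets: {empty}")


def load_annotation_tsv(path: str) -> AnnotationMap:
    """Read a protein_id / term_id / namespace / label TSV into a map."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"protein_id": str, "term_id": str},
    )
    required = {"protein_id", "term_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    terms: dict[str, set[str]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for _, row in df.iterrows():
        terms.setdefault(row["term_id"], set()).add(row["protein_id"])
        meta[row["term_id"]] = (
            str(row.get("namespace", "")), str(row.get("label", "")),
        )
    return AnnotationMap(terms, meta)


@dataclass
class EnrichmentResult:
    term_id: str
    k: int            # differential proteins carrying the term
    n: int            # differential total
    K: int            # background proteins carrying the term
    N: int            # background total
    fold: float | None
    p: float
    q: float | None = None
    namespace: str = ""
    label: str = ""


def enrich(
    differential: set[str],
    background: set[str],
    annotations: AnnotationMap,
    q_threshold: float = 0.05,
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Fisher enrichment of every annotated term, sorted by p-value.

    The differential set must be a subset of the background. For each term
    the table is (k, n-k; K-k, N-n-K+k). ``correction`` is a statsmodels
    multipletests method name (``fdr_bh`` default, ``bonferroni``
    supported). ``q_threshold`` is carried for reporting; results are not
    filtered here.
    """
    offenders = sorted(differential - background)
    if offenders:
        raise ValueError(
            f"differential proteins missing from background: {offenders}"
        )
    n, N = len(differential), len(background)
    results = []
    for term in sorted(annotations.term_to_proteins):
        members = annotations.term_to_proteins[term] & background
        K = len(members)
        k = len(members & differential)
        table = [[k, n - k], [K - k, N - n - K + k]]
        p = fisher_two_tailed(table)
        fold = (k / n) / (K / N) if K > 0 and n > 0 else None
        ns, label = annotations.metadata.get(term, ("", ""))
        results.append(EnrichmentResult(term, k, n, K, N, fold, p, None, ns, label))
    if results:
        qvals = multipletests([r.p for r in results], method=correction)[1]
        for r, q in zip(results, qvals):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"term_id": r.term_id, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
             "fold": r.fold, "p": r.p, "q": r.q,
             "namespace": r.namespace, "label": r.label}
            for r in results
        ]
    )
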