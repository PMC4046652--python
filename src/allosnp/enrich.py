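"""GO term enrichment with a chi-squared / Fisher-exact fallback.

For each term, study genes are compared with the remaining background
genes in a 2x2 table.  The p-value comes from Pearson's chi-squared test
(1 df, no continuity correction) unless any expected cell count is below
5, in which case a two-sided Fisher's exact test is used instead.  Term
annotations are propagated up the ontology's is-a parents before testing,
so a gene annotated to a child also counts for every ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencyTable:
    """a: study with term; b: study without; c: background-only with;
    d: background-only without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def study_size(self) -> int:
        return self.a + self.b

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def expected(self) -> np.ndarray:
        n = self.total
        obs = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        if n == 0 or obs.sum(0).min() == 0 or obs.sum(1).min() == 0:
            return np.zeros((2, 2))
        return np.outer(obs.sum(1), obs.sum(0)) / n


@dataclass
class EnrichmentResult:
    term: str
    table: ContingencyTable
    expected_study_with_term: float
    p_value: float
    test_used: str   # 'chi_squared' | 'fisher_exact'
    direction: str   # 'over' | 'under' | 'none'
    q_value: float | None = None


def propagate_annotations(
    go_map: dict[str, list[str]], parents: dict[str, list[str]]
) -> dict[str, set[str]]:
    """Close each gene's term set over is-a ancestors; reject cyclic ontologies."""
    ancestors: dict[str, set[str]] = {}

    def climb(term: str, trail: tuple) -> set[str]:
        if term in trail:
            raise ValueError(f"cyclic ontology at {term}")
        if term in ancestors:
            return ancestors[term]
        out = {term}
        for p in parents.get(term, []):
            out |= climb(p, trail + (term,))
        ancestors[term] = out
        return out

    closed: dict[str, set[str]] = {}
    for gene, terms in go_map.items():
        s: set[str] = set()
        for t in terms:
            s |= climb(t, ())
        closed[gene] = s
    return closed


def build_contingency(
    study_genes, background_genes, term: str, go_map: dict[str, set[str] | list[str]]
) -> ContingencyTable:
    """2x2 table for one term; unannotated genes count in the 'without' cells."""
    study = set(study_genes)
    background = set(background_genes)
    missing = study - background
    if missing:
        raise ValueError(f"study genes absent from background: {sorted(missing)[:5]}")
    with_term = {g for g in background if term in go_map.get(g, ())}
    a = len(study & with_term)
    b = len(study) - a
    c = len(with_term - study)
    d = len(background - study) - c
    return ContingencyTable(a, b, c, d)


def term_test(table: ContingencyTable, term: str = "") -> EnrichmentResult:
    """Pearson chi-squared (no continuity correction) or Fisher fallback."""
    exp = table.expected()
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if obs.sum(0).min() == 0 or obs.sum(1).min() == 0:
        return EnrichmentResult(term, table, float(exp[0, 0]), 1.0,
                                "chi_squared", "none")
    if exp.min() < 5:
        test = "fisher_exact"
        _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]],
                                  alternative="two-sided")
    else:
        test = "chi_squared"
        chi2 = float((((obs - exp) ** 2) / exp).sum())
        p = float(stats.chi2.sf(chi2, df=1))
    if table.a > exp[0, 0]:
        direction = "over"
    elif table.a < exp[0, 0]:
        direction = "under"
    else:
        direction = "none"
    return EnrichmentResult(term, table, float(exp[0, 0]), float(p), test, direction)


def enrich_all(
    study_genes,
    background_genes,
    go_map: dict[str, list[str]],
    ontology_parents: dict[str, list[str]] | None = None,
    fdr: bool = True,
) -> pd.DataFrame:
    """Test every term with at least one study gene; sort by ascending p.

    No multiple-testing correction is applied to the reported p-values;
    Benjamini-Hochberg q-values are emitted as an extra column.
    """
    closed = (propagate_annotations(go_map, ontology_parents)
              if ontology_parents else {g: set(t) for g, t in go_map.items()})
    study = sorted(set(study_genes))
    background = sorted(set(background_genes))
    terms = sorted({t for g in study for t in closed.get(g, ())})
    results = []
    for term in terms:
        table = build_contingency(study, background, term, closed)
        results.append(term_test(table, term))
    results.sort(key=lambda r: (r.p_value, r.term))
    df = pd.DataFrame([
        {
            "term": r.term, "study_with_term": r.table.a,
            "study_size": r.table.study_size,
            "background_with_term": r.table.a + r.table.c,
            "background_size": r.table.total,
            "expected": r.expected_study_with_term,
            "p_value": r.p_value, "test": r.test_used, "direction": r.direction,
        }
        for r in results
    ])
    if fdr and len(df):
        df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df
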