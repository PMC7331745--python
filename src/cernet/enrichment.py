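"""Over-representation analysis of network mRNAs against GO/KEGG-style sets.

One-sided hypergeometric enrichment with fold enrichment (k/n)/(K/N) and
Benjamini–Hochberg correction across all terms tested. The background is the
universe of the gene-set collection (the union of all set members unless an
explicit universe is supplied); query genes outside it are dropped with a
logged count. No ontology-DAG propagation — GO aspects are simply three GMT
files prepared upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    k: int  # query genes in the term
    n: int  # query size (annotated)
    K: int  # term size
    N: int  # universe size
    fold_enrichment: float
    p_value: float
    q_value: float


def enrich(query: Iterable[str], collection: GeneSetCollection,
           alpha: float = 0.05) -> list[EnrichmentRow]:
    """Test every term for over-representation of ``query``.

    Returns one row per term, sorted by p ascending; rows with p < alpha are
    the significant calls (alpha only orders the caller's attention — all
    rows are returned).
    """
    query = set(query)
    annotated = query & collection.universe
    dropped = len(query) - len(annotated)
    if dropped:
        log.info("%d query gene(s) outside the universe dropped", dropped)
    if not annotated:
        log.warning("empty query after restriction to the universe")
        return []
    n, N = len(annotated), len(collection.universe)
    rows = []
    for term in sorted(collection.sets):
        desc, members = collection.sets[term]
        K = len(members)
        k = len(annotated & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fe = (k / n) / (K / N)
        rows.append((term, desc, k, K, min(p, 1.0), fe))
    q = multipletests([r[4] for r in rows], method="fdr_bh")[1]
    out = [
        EnrichmentRow(term, desc, k, n, K, N, fe, p, float(qv))
        for (term, desc, k, K, p, fe), qv in zip(rows, q)
    ]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    log.info("enrichment: %d/%d terms with p < %g",
             sum(r.p_value < alpha for r in out), len(out), alpha)
    return out


def enrichment_to_frame(rows: list[EnrichmentRow]):
    import pandas as pd

    return pd.DataFrame(
        [{"term_id": r.term_id, "description": r.description, "k": r.k,
          "n": r.n, "K": r.K, "N": r.N, "fold_enrichment": r.fold_enrichment,
          "p": r.p_value, "q": r.q_value}
         for r in rows],
        columns=["term_id", "description", "k", "n", "K", "N",
                 "fold_enrichment", "p", "q"],
    )
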