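"""The core ceRNA inference: shared-miRNA scoring and network assembly.

Sequence-predicted target pairs are first intersected with negative
coexpression edges (a pair must carry both binding and expression evidence).
Each circRNA-mRNA combination is then scored by the probability of sharing at
least its observed number of validated miRNA partners by chance — the upper
tail of a hypergeometric distribution over the universe of differentially
expressed miRNAs. Candidates that additionally show positive circRNA-mRNA
coexpression are expanded into circRNA-miRNA-mRNA triplets, and only
direction-consistent triplets survive: the circRNA and mRNA move together,
the miRNA opposite (the sponge pattern).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .coexpression import CoexprEdge
from .diffexpr import DERecord
from .mre_prediction import TargetPair

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidatedPair:
    """A miRNA-target pair supported by both sequence and coexpression."""

    mirna_id: str
    target_id: str
    target_class: str
    r: float
    p_coexpr: float
    best_score: float
    best_energy: float


@dataclass(frozen=True)
class CeRNACandidate:
    """A circRNA-mRNA pair scored by shared validated miRNA partners."""

    circ_id: str
    mrna_id: str
    shared_mirnas: tuple[str, ...]
    k: int
    K: int  # validated miRNA partners of the circRNA
    n: int  # validated miRNA partners of the mRNA
    M: int  # DE miRNA universe size
    p_hyper: float
    q_hyper: float


@dataclass(frozen=True)
class CeRNATriplet:
    """A final circRNA-miRNA-mRNA network element."""

    circ_id: str
    mirna_id: str
    mrna_id: str
    circ_direction: str
    mirna_direction: str
    mrna_direction: str


def filter_targets_by_coexpression(pairs: list[TargetPair],
                                   edges: list[CoexprEdge]) -> list[ValidatedPair]:
    """Exact set intersection of target pairs and negative coexpression edges.

    Edge endpoints are matched on (miRNA id, target id) regardless of which
    side of the edge holds the miRNA.
    """
    edge_by_key: dict[tuple[str, str], CoexprEdge] = {}
    for e in edges:
        if e.required_sign != "negative":
            raise ValueError("miRNA-target validation expects negative-sign edges")
        if e.a_class == "miRNA":
            edge_by_key[(e.a_id, e.b_id)] = e
        else:
            edge_by_key[(e.b_id, e.a_id)] = e
    out = []
    for p in pairs:
        e = edge_by_key.get((p.mirna_id, p.target_id))
        if e is None:
            continue
        out.append(ValidatedPair(p.mirna_id, p.target_id, p.target_class,
                                 e.r, e.p_value, p.best_score, p.best_energy))
    out.sort(key=lambda v: (v.mirna_id, v.target_id))
    log.info("validated pairs: %d of %d sequence pairs, %d edges",
             len(out), len(pairs), len(edges))
    return out


def cerna_score(circ_partners: set[str], mrna_partners: set[str],
                M: int) -> tuple[int, float]:
    """Shared-miRNA ceRNA score for one circRNA-mRNA pair.

    Returns (k, p) where k is the number of shared validated miRNA partners
    and p = P(X >= k) under X ~ Hypergeometric(M, K=|circ partners|,
    n=|mrna partners|): the chance of sharing at least k partners if the
    mRNA's partners were drawn at random from the M DE miRNAs.
    """
    K, n = len(circ_partners), len(mrna_partners)
    if M < K or M < n:
        raise ValueError(f"universe M={M} smaller than a partner set (K={K}, n={n})")
    k = len(circ_partners & mrna_partners)
    p = float(hypergeom.sf(k - 1, M, K, n))  # sf(k-1) = P(X >= k)
    return k, min(p, 1.0)


def build_cerna_network(validated_circ: list[ValidatedPair],
                        validated_mrna: list[ValidatedPair],
                        circ_mrna_edges: list[CoexprEdge],
                        de_records: dict[str, list[DERecord]],
                        alpha: float = 0.05, k_min: int = 1
                        ) -> tuple[list[CeRNACandidate], list[CeRNATriplet]]:
    """Assemble the direction-consistent ceRNA network.

    Steps: (1) score every circRNA-mRNA combination with shared validated
    miRNA partners, keeping k >= k_min and p_hyper < alpha (BH q reported);
    (2) keep candidates whose circRNA-mRNA pair is also a positive
    coexpression edge; (3) expand each survivor into one triplet per shared
    miRNA; (4) drop triplets violating the sponge direction pattern.

    ``de_records`` maps molecule class -> filtered DE records; the miRNA
    list defines the hypergeometric universe M and every referenced feature
    must carry a DE record.
    """
    direction: dict[str, str] = {}
    for recs in de_records.values():
        for r in recs:
            direction[r.feature_id] = r.direction
    M = len(de_records.get("miRNA", []))

    circ_partners: dict[str, set[str]] = {}
    for v in validated_circ:
        circ_partners.setdefault(v.target_id, set()).add(v.mirna_id)
    mrna_partners: dict[str, set[str]] = {}
    for v in validated_mrna:
        mrna_partners.setdefault(v.target_id, set()).add(v.mirna_id)

    scored: list[CeRNACandidate] = []
    for circ in sorted(circ_partners):
        for mrna in sorted(mrna_partners):
            k, p = cerna_score(circ_partners[circ], mrna_partners[mrna], M)
            if k < max(k_min, 1):
                continue
            shared = tuple(sorted(circ_partners[circ] & mrna_partners[mrna]))
            scored.append(CeRNACandidate(
                circ, mrna, shared, k, len(circ_partners[circ]),
                len(mrna_partners[mrna]), M, p, q_hyper=1.0))
    if scored:
        q = multipletests([c.p_hyper for c in scored], method="fdr_bh")[1]
        scored = [CeRNACandidate(c.circ_id, c.mrna_id, c.shared_mirnas, c.k,
                                 c.K, c.n, c.M, c.p_hyper, float(qi))
                  for c, qi in zip(scored, q)]
    candidates = [c for c in scored if c.p_hyper < alpha]
    log.info("ceRNA score: %d/%d circ-mRNA pairs significant (p<%g, k>=%d)",
             len(candidates), len(scored), alpha, k_min)

    pos_edges = set()
    for e in circ_mrna_edges:
        if e.required_sign != "positive":
            raise ValueError("circRNA-mRNA overlap expects positive-sign edges")
        pos_edges.add((e.a_id, e.b_id))
        pos_edges.add((e.b_id, e.a_id))
    supported = [c for c in candidates if (c.circ_id, c.mrna_id) in pos_edges]
    log.info("ceRNA network: %d/%d candidates with positive circ-mRNA coexpression",
             len(supported), len(candidates))

    triplets: list[CeRNATriplet] = []
    for c in supported:
        for mir in c.shared_mirnas:
            for fid in (c.circ_id, mir, c.mrna_id):
                if fid not in direction:
                    raise KeyError(f"feature {fid!r} has no DE record")
            t = CeRNATriplet(c.circ_id, mir, c.mrna_id,
                             direction[c.circ_id], direction[mir],
                             direction[c.mrna_id])
            if (t.circ_direction == t.mrna_direction
                    and t.mirna_direction != t.circ_direction):
                triplets.append(t)
    triplets.sort(key=lambda t: (t.circ_id, t.mirna_id, t.mrna_id))
    log.info("ceRNA network: %d direction-consistent triplets", len(triplets))
    return candidates, triplets


def validated_to_frame(pairs: list[ValidatedPair]):
    import pandas as pd

    return pd.DataFrame(
        [{"mirna_id": v.mirna_id, "target_id": v.target_id,
          "target_class": v.target_class, "r": v.r, "p_coexpr": v.p_coexpr,
          "best_score": v.best_score, "best_energy": v.best_energy}
         for v in pairs],
        columns=["mirna_id", "target_id", "target_class", "r", "p_coexpr",
                 "best_score", "best_energy"],
    )


def candidates_to_frame(candidates: list[CeRNACandidate]):
    import pandas as pd

    return pd.DataFrame(
        [{"circ_id": c.circ_id, "mrna_id": c.mrna_id,
          "shared_mirnas": ",".join(c.shared_mirnas), "k": c.k, "K": c.K,
          "n": c.n, "M": c.M, "p_hyper": c.p_hyper, "q_hyper": c.q_hyper}
         for c in candidates],
        columns=["circ_id", "mrna_id", "shared_mirnas", "k", "K", "n", "M",
                 "p_hyper", "q_hyper"],
    )


def triplets_to_frame(triplets: list[CeRNATriplet]):
    import pandas as pd

    return pd.DataFrame(
        [{"circ_id": t.circ_id, "mirna_id": t.mirna_id, "mrna_id": t.mrna_id,
          "circ_direction": t.circ_direction,
          "mirna_direction": t.mirna_direction,
          "mrna_direction": t.mrna_direction}
         for t in triplets],
        columns=["circ_id", "mirna_id", "mrna_id", "circ_direction",
                 "mirna_direction", "mrna_direction"],
    )
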