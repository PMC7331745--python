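"""Calibration and recovery metrics for the pipeline on simulated data.

These are the quantities a user should look at before trusting the pipeline
on a design like theirs: how often planted ceRNA circuits survive the whole
chain of filters, how often a circuit-free simulation emits anything at all,
and whether the DE test and the enrichment test hold their nominal type-I
error. All functions are deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .diffexpr import de_test_counts
from .enrichment import enrich
from .io_formats import ExpressionMatrix, GeneSetCollection
from .pipeline import PipelineParams, analyze
from .synthetic_data import SimulationConfig, simulate_dataset

log = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def circuit_recovery(n_seeds: int = 50,
                     sim: SimulationConfig = SimulationConfig(lfc_de=2.0),
                     params: PipelineParams = PipelineParams(),
                     seed: int = 0) -> dict:
    """End-to-end planted-circuit recovery over independent simulations.

    A planted circuit — one (circRNA, mRNA) pair with its shared miRNAs —
    counts as recovered when at least one emitted triplet connects that
    circRNA and mRNA. Returns per-stage attrition counts alongside the
    recovery fraction.
    """
    recovered = total = 0
    spurious_triplets = 0
    per_seed = []
    for s in _child_seeds(seed, n_seeds):
        ds = simulate_dataset(dataclasses.replace(sim, seed=s))
        res = analyze(ds.circ, ds.mrna, ds.mirna, ds.mirna_fa, ds.target_fa,
                      params=params)
        emitted = {(t.circ_id, t.mrna_id) for t in res.triplets}
        groups = ds.truth.circuit_groups()
        hits = sum(1 for cm in groups if cm in emitted)
        recovered += hits
        total += len(groups)
        spurious_triplets += sum(1 for cm in emitted if cm not in groups)
        per_seed.append(hits)
    return {
        "n_seeds": n_seeds,
        "circuits_total": total,
        "circuits_recovered": recovered,
        "recovery": recovered / total if total else float("nan"),
        "spurious_circ_mrna_pairs": spurious_triplets,
        "per_seed_hits": per_seed,
    }


def null_zero_triplet_rate(n_seeds: int = 100,
                           sim: SimulationConfig | None = None,
                           params: PipelineParams = PipelineParams(),
                           seed: int = 0) -> dict:
    """Fraction of circuit-free simulations that emit zero triplets."""
    if sim is None:
        sim = SimulationConfig(n_circuits=0)
    zero = 0
    counts = []
    for s in _child_seeds(seed, n_seeds):
        ds = simulate_dataset(dataclasses.replace(sim, seed=s))
        res = analyze(ds.circ, ds.mrna, ds.mirna, ds.mirna_fa, ds.target_fa,
                      params=params)
        counts.append(len(res.triplets))
        zero += len(res.triplets) == 0
    return {"n_seeds": n_seeds, "zero_triplet_seeds": zero,
            "zero_rate": zero / n_seeds, "triplet_counts": counts}


def de_type1_error(n_features: int = 1500, alpha: float = 0.05,
                   sim: SimulationConfig | None = None, seed: int = 0) -> dict:
    """Fraction of null count features with p < alpha under the Welch test.

    Simulates one circuit-free, effect-free dataset with ``n_features``
    mRNA-like NB features and runs the count DE test. The binomial standard
    error for the returned fraction is sqrt(alpha*(1-alpha)/n).
    """
    if sim is None:
        sim = SimulationConfig(n_circuits=0, lfc_de=0.0, n_mrna=n_features,
                               n_de_circ=0, n_de_mirna=0, n_de_mrna=0)
    ds = simulate_dataset(dataclasses.replace(sim, seed=seed))
    recs = de_test_counts(ds.mrna)
    frac = float(np.mean([r.p_value < alpha for r in recs]))
    se = float(np.sqrt(alpha * (1 - alpha) / len(recs)))
    return {"n_features": len(recs), "alpha": alpha, "fraction": frac,
            "binomial_se": se}


def enrichment_null_rate(n_replicates: int = 200, alpha: float = 0.05,
                         universe_size: int = 4000, n_terms: int = 40,
                         term_size: int = 200, query_size: int = 400,
                         seed: int = 0) -> dict:
    """Mean fraction of terms called significant for random queries.

    Gene sets and queries are drawn uniformly from the universe, so no term
    is truly enriched; a calibrated one-sided hypergeometric test should
    flag terms at most at the nominal rate (slightly under it, because the
    test statistic is discrete).
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(universe_size)]
    sets = {f"t{j}": (f"null set {j}",
                      frozenset(rng.choice(genes, size=term_size, replace=False)))
            for j in range(n_terms)}
    coll = GeneSetCollection(sets, frozenset(genes))
    rates = []
    for _ in range(n_replicates):
        query = rng.choice(genes, size=query_size, replace=False)
        rows = enrich(query, coll)
        rates.append(np.mean([r.p_value < alpha for r in rows]))
    rates = np.asarray(rates)
    return {"n_replicates": n_replicates, "alpha": alpha,
            "mean_rate": float(rates.mean()),
            "se": float(rates.std(ddof=1) / np.sqrt(n_replicates))}
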