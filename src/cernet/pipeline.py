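"""Orchestration: simulate -> DE -> MRE -> coexpression -> network -> ORA.

The whole analysis is a pure function of its inputs and thresholds
(:func:`analyze`); :func:`run_pipeline` wraps it with file I/O, stage
logging, and a run manifest (config echo, per-stage row counts, output
checksums) so a run is reproducible and auditable. Identical config and seed
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cerna import (CeRNACandidate, CeRNATriplet, build_cerna_network,
                    candidates_to_frame, filter_targets_by_coexpression,
                    triplets_to_frame, validated_to_frame)
from .coexpression import CoexprEdge, coexpression_edges, edges_to_frame
from .diffexpr import (DERecord, de_test_counts, de_test_intensity,
                       de_to_frame, filter_de, normalize_log2)
from .enrichment import enrich, enrichment_to_frame
from .io_formats import (ExpressionMatrix, GeneSetCollection, SeqRecord,
                         read_expression, read_fasta, read_gmt, write_network,
                         write_table)
from .mre_prediction import (AlignParams, collapse_to_pairs, mres_to_frame,
                             pairs_to_frame, predict_mres)
from .synthetic_data import (SimulatedDataset, SimulationConfig,
                             simulate_dataset, write_dataset)

log = logging.getLogger(__name__)

STAGES = ("de", "mre", "coexpr", "build", "enrich")


def resolve_steps(steps: dict[str, bool]) -> tuple[str, ...]:
    """Validate stage toggles: a disabled stage may only be followed by
    disabled stages (each stage feeds the next)."""
    for i, s in enumerate(STAGES):
        if not steps.get(s, True):
            later = [t for t in STAGES[i + 1:] if steps.get(t, True)]
            if later:
                raise ValueError(
                    f"stage '{later[0]}' depends on disabled stage '{s}'")
            return STAGES[:i]
    return STAGES


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the analysis, at the study-wide defaults."""

    fc_threshold: float = 1.5
    de_alpha: float = 0.05
    use_q: bool = False
    score_min: float = 140.0
    energy_max: float = -20.0
    seed_required: bool = True
    r_min: float = 0.9
    coexpr_alpha: float = 0.05
    cerna_alpha: float = 0.05
    k_min: int = 1
    enrich_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("de_alpha", "coexpr_alpha", "cerna_alpha", "enrich_alpha"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 <= self.r_min <= 1:
            raise ValueError("r_min must be in [0, 1]")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, in memory."""

    de_all: dict[str, list[DERecord]]
    de_kept: dict[str, list[DERecord]]
    de_summary: dict[str, dict[str, int]]
    mres: dict[str, list]  # target class -> MREs
    pairs: dict[str, list]  # target class -> TargetPairs
    edges_mir_circ: list[CoexprEdge]
    edges_mir_mrna: list[CoexprEdge]
    edges_circ_mrna: list[CoexprEdge]
    validated_circ: list
    validated_mrna: list
    candidates: list[CeRNACandidate]
    triplets: list[CeRNATriplet]
    enrichment: list


def analyze(circ: ExpressionMatrix, mrna: ExpressionMatrix,
            mirna: ExpressionMatrix, mirna_fa: list[SeqRecord],
            target_fa: list[SeqRecord],
            annotation: GeneSetCollection | None = None,
            params: PipelineParams = PipelineParams(),
            align_params: AlignParams = AlignParams(),
            stages: tuple[str, ...] = STAGES) -> AnalysisResult:
    """Run the inference on in-memory inputs (optionally truncated to a
    prefix of the stage sequence)."""
    p = params
    empty = AnalysisResult({}, {}, {}, {"circRNA": [], "mRNA": []},
                           {"circRNA": [], "mRNA": []}, [], [], [], [], [],
                           [], [], [])
    if "de" not in stages:
        return empty

    # -- differential expression -------------------------------------------
    de_all = {
        "circRNA": de_test_counts(circ, "circRNA"),
        "mRNA": de_test_counts(mrna, "mRNA"),
        "miRNA": de_test_intensity(mirna, "miRNA"),
    }
    de_kept, de_summary = {}, {}
    for cls, recs in de_all.items():
        kept, summary = filter_de(recs, p.fc_threshold, p.de_alpha, p.use_q)
        de_kept[cls], de_summary[cls] = kept, summary
        log.info("DE %s: %d kept (%d up / %d down) of %d",
                 cls, len(kept), summary["up"], summary["down"], len(recs))

    empty.de_all, empty.de_kept, empty.de_summary = de_all, de_kept, de_summary
    if "mre" not in stages:
        return empty

    de_circ_ids = {r.feature_id for r in de_kept["circRNA"]}
    de_mrna_ids = {r.feature_id for r in de_kept["mRNA"]}
    de_mir_ids = {r.feature_id for r in de_kept["miRNA"]}

    # -- sequence-level MRE prediction (DE features only) -------------------
    de_mirna_fa = [r for r in mirna_fa if r.id in de_mir_ids]
    circ_targets = [r for r in target_fa
                    if r.moltype == "circRNA_target" and r.id in de_circ_ids]
    mrna_targets = [r for r in target_fa
                    if r.moltype == "mRNA_target" and r.id in de_mrna_ids]
    mres = {
        "circRNA": predict_mres(de_mirna_fa, circ_targets, p.score_min,
                                p.energy_max, p.seed_required, align_params),
        "mRNA": predict_mres(de_mirna_fa, mrna_targets, p.score_min,
                             p.energy_max, p.seed_required, align_params),
    }
    pairs = {cls: collapse_to_pairs(m) for cls, m in mres.items()}
    for cls in mres:
        log.info("MRE %s: %d sites, %d pairs", cls, len(mres[cls]), len(pairs[cls]))
    empty.mres, empty.pairs = mres, pairs
    if "coexpr" not in stages:
        return empty

    # -- coexpression across all samples, log scale -------------------------
    circ_log = normalize_log2(circ).subset(de_circ_ids)
    mrna_log = normalize_log2(mrna).subset(de_mrna_ids)
    mirna_log = mirna.subset(de_mir_ids)
    edges_mir_circ = coexpression_edges(mirna_log, "miRNA", circ_log, "circRNA",
                                        "negative", p.r_min, p.coexpr_alpha)
    edges_mir_mrna = coexpression_edges(mirna_log, "miRNA", mrna_log, "mRNA",
                                        "negative", p.r_min, p.coexpr_alpha)
    edges_circ_mrna = coexpression_edges(circ_log, "circRNA", mrna_log, "mRNA",
                                         "positive", p.r_min, p.coexpr_alpha)
    empty.edges_mir_circ = edges_mir_circ
    empty.edges_mir_mrna = edges_mir_mrna
    empty.edges_circ_mrna = edges_circ_mrna
    if "build" not in stages:
        return empty

    # -- ceRNA network ------------------------------------------------------
    validated_circ = filter_targets_by_coexpression(pairs["circRNA"], edges_mir_circ)
    validated_mrna = filter_targets_by_coexpression(pairs["mRNA"], edges_mir_mrna)
    candidates, triplets = build_cerna_network(
        validated_circ, validated_mrna, edges_circ_mrna, de_kept,
        alpha=p.cerna_alpha, k_min=p.k_min)

    # -- over-representation of network mRNAs -------------------------------
    enrichment = []
    if "enrich" in stages and annotation is not None and annotation.sets:
        query = sorted({t.mrna_id for t in triplets})
        if query:
            enrichment = enrich(query, annotation, p.enrich_alpha)

    return AnalysisResult(de_all, de_kept, de_summary, mres, pairs,
                          edges_mir_circ, edges_mir_mrna, edges_circ_mrna,
                          validated_circ, validated_mrna, candidates,
                          triplets, enrichment)


# ---------------------------------------------------------------------------
# Configured, on-disk runs
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """One reproducible run: inputs (or simulation), thresholds, outputs."""

    outdir: str = "cernet_run"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    params: PipelineParams = field(default_factory=PipelineParams)
    # used when simulate is False: paths to the input files
    inputs: dict[str, str] = field(default_factory=dict)
    steps: dict[str, bool] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = SimulationConfig(**d.get("sim", {}))
        params = PipelineParams(**d.get("params", {}))
        cfg = cls(outdir=d.get("outdir", "cernet_run"),
                  seed=int(d.get("seed", 0)), simulate=d.get("simulate", True),
                  sim=sim, params=params, inputs=d.get("inputs", {}),
                  steps=d.get("steps", {}))
        if "seed" in d:  # the run seed also seeds the simulation
            cfg.sim = dataclasses.replace(cfg.sim, seed=int(d["seed"]))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed, "simulate": self.simulate,
            "sim": dataclasses.asdict(self.sim),
            "params": dataclasses.asdict(self.params),
            "inputs": dict(self.inputs), "steps": dict(self.steps),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(inputs: dict[str, str]) -> SimulatedDataset:
    """Assemble a dataset from user-supplied files (no truth table)."""
    from .synthetic_data import TruthTable

    required = ("circ_counts", "mrna_counts", "mirna_intensity", "design",
                "mirna_fa", "mrna_fa", "circ_fa")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"missing input path(s): {', '.join(missing)}")
    design = inputs["design"]
    circ = read_expression(inputs["circ_counts"], "counts", design)
    mrna = read_expression(inputs["mrna_counts"], "counts", design)
    mirna = read_expression(inputs["mirna_intensity"], "log_intensity", design)
    mirna_fa = read_fasta(inputs["mirna_fa"], "miRNA")
    target_fa = read_fasta(inputs["mrna_fa"], "mRNA_target") + \
        read_fasta(inputs["circ_fa"], "circRNA_target")
    annotation = read_gmt(inputs["annotation"]) if "annotation" in inputs else \
        GeneSetCollection({}, frozenset())
    return SimulatedDataset(circ, mrna, mirna, mirna_fa, target_fa,
                            annotation, TruthTable({}, [], []))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write outputs under ``config.outdir``, return the
    run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        log.info("[simulate] seed=%d", config.sim.seed)
        ds = simulate_dataset(config.sim)
        write_dataset(ds, out / "data")
    else:
        log.info("[load] reading user inputs")
        ds = load_inputs(config.inputs)

    stages = resolve_steps(config.steps)
    log.info("[analyze] running stages: %s", ", ".join(stages) or "(none)")
    res = analyze(ds.circ, ds.mrna, ds.mirna, ds.mirna_fa, ds.target_fa,
                  ds.annotation, config.params, stages=stages)

    files: dict[str, Path] = {}

    def emit(name: str, df) -> None:
        path = out / name
        write_table(df, path)
        files[name] = path

    for cls, tag in (("circRNA", "circ"), ("mRNA", "mrna"), ("miRNA", "mirna")):
        emit(f"de_{tag}_all.tsv", de_to_frame(res.de_all.get(cls, [])))
        emit(f"de_{tag}.tsv", de_to_frame(res.de_kept.get(cls, [])))
    emit("mre_circ.tsv", mres_to_frame(res.mres["circRNA"]))
    emit("mre_mrna.tsv", mres_to_frame(res.mres["mRNA"]))
    emit("pairs_circ.tsv", pairs_to_frame(res.pairs["circRNA"]))
    emit("pairs_mrna.tsv", pairs_to_frame(res.pairs["mRNA"]))
    emit("edges_mir_circ.tsv", edges_to_frame(res.edges_mir_circ))
    emit("edges_mir_mrna.tsv", edges_to_frame(res.edges_mir_mrna))
    emit("edges_circ_mrna.tsv", edges_to_frame(res.edges_circ_mrna))
    emit("validated_circ.tsv", validated_to_frame(res.validated_circ))
    emit("validated_mrna.tsv", validated_to_frame(res.validated_mrna))
    emit("candidates.tsv", candidates_to_frame(res.candidates))
    emit("triplets.tsv", triplets_to_frame(res.triplets))
    emit("enrichment.tsv", enrichment_to_frame(res.enrichment))
    write_network(res.triplets, "SIF", out / "network.sif")
    write_network(res.triplets, "GraphML", out / "network.graphml")
    files["network.sif"] = out / "network.sif"
    files["network.graphml"] = out / "network.graphml"

    row_counts = {}
    for name, path in files.items():
        if name.endswith(".tsv"):
            with open(path) as fh:
                row_counts[name] = max(0, sum(1 for _ in fh) - 1)
    manifest = {
        "cernet_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "row_counts": row_counts,
        "checksums": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("[done] %d triplets; manifest written to %s",
             len(res.triplets), out / "manifest.json")
    return manifest
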