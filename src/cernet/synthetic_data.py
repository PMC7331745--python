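"""Self-consistent synthetic OVX-like datasets with planted ceRNA circuits.

The generator emulates the study design the pipeline targets: 3 case (OVX)
vs 3 control samples, negative-binomial RNA-seq counts for circRNAs and
mRNAs (Var = mu + alpha*mu^2, library size factors log-uniform in
[0.7, 1.4]), log-normal microarray intensities for miRNAs, and a handful of
planted ceRNA circuits. Each circuit is a circRNA and an mRNA that share a
small set of miRNAs (the study's own circuits share up to three): the
circRNA and mRNA are differentially expressed in the same direction, the
shared miRNAs in the opposite direction (alternating per circuit so both
orientations occur), the target sequences carry exact reverse complements of
their partner miRNAs at recorded positions, and a per-sample latent sponge
factor adds positive circRNA-mRNA and negative miRNA-circRNA / miRNA-mRNA
correlation on top of the group effect.

Beyond the circuits, additional "decoy" features are planted as
differentially expressed without any binding sites, so that the DE tables —
in particular the miRNA universe that calibrates the hypergeometric ceRNA
score — have the same order of magnitude as a real study (tens of DE
miRNAs, not a handful). Everything planted is recorded in a TruthTable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (ExpressionMatrix, GeneSetCollection, SeqRecord,
                         write_design, write_expression, write_fasta,
                         write_gmt, write_table)
from .mre_prediction import revcomp

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset.

    Effect sizes are in log2 units; ``lfc_de`` is the planted |log2 fold
    change| of every DE feature (must be 0, for null simulations, or at
    least log2(1.5) so planted features pass the study-wide filter in
    expectation). ``nb_dispersion`` is the NB alpha in Var = mu + alpha*mu^2.
    """

    n_case: int = 3
    n_control: int = 3
    n_circ: int = 60
    n_mirna: int = 40
    n_mrna: int = 600
    n_circuits: int = 4
    mirnas_per_circuit: int = 3
    lfc_de: float = 1.5
    nb_dispersion: float = 0.1
    base_mean_log: float = 8.0  # log2 of the median baseline count
    base_sd_log: float = 1.0
    intensity_mean_log: float = 10.0
    intensity_base_sd: float = 2.0
    intensity_sd: float = 0.25  # residual SD of log2 intensities
    sponge_sd: float = 0.5  # SD of the per-sample latent sponge factor (log2)
    seed: int = 0
    seed_len: int = 7
    # decoy DE features (totals, circuit members included)
    n_de_circ: int = 12
    n_de_mirna: int = 22
    n_de_mrna: int = 60
    mirna_len: int = 22
    mrna_len: int = 500
    circ_len: int = 400
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    n_gene_sets: int = 15
    gene_set_size: int = 25

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control) < 2:
            raise ValueError("need at least 2 samples per group")
        n_circuit_mirnas = self.n_circuits * self.mirnas_per_circuit
        if self.n_circuits > min(self.n_circ, self.n_mrna) or \
                n_circuit_mirnas > self.n_mirna:
            raise ValueError("more planted circuits than available features")
        if not (self.lfc_de == 0.0 or self.lfc_de >= np.log2(1.5) - 1e-12):
            raise ValueError("lfc_de must be 0 (null) or >= log2(1.5)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if not (self.n_circuits <= self.n_de_circ <= self.n_circ
                and n_circuit_mirnas <= self.n_de_mirna <= self.n_mirna
                and self.n_circuits <= self.n_de_mrna <= self.n_mrna):
            raise ValueError("n_de_* must lie between the circuit usage and the class size")
        if self.seed_len < 6 or self.seed_len + 1 > self.mirna_len:
            raise ValueError("seed_len out of range")
        if self.mirna_len + 10 > min(self.mrna_len, self.circ_len):
            raise ValueError("targets too short to host a planted site")


@dataclass(frozen=True)
class PlantedSite:
    target_id: str
    start: int
    end: int
    mirna_id: str
    seed_type: str


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    de_features: dict[str, str]  # feature -> up|down (case vs control)
    circuits: list[tuple[str, str, str]]  # (circ, mirna, mrna)
    planted_sites: list[PlantedSite]

    def circuit_groups(self) -> dict[tuple[str, str], list[str]]:
        """(circ, mrna) -> shared planted miRNAs."""
        groups: dict[tuple[str, str], list[str]] = {}
        for c, m, g in self.circuits:
            groups.setdefault((c, g), []).append(m)
        return groups


@dataclass
class SimulatedDataset:
    circ: ExpressionMatrix
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mirna_fa: list[SeqRecord]
    target_fa: list[SeqRecord]  # mRNA and circRNA pseudo-sequences
    annotation: GeneSetCollection
    truth: TruthTable
    config: SimulationConfig = field(default_factory=SimulationConfig)


# ---------------------------------------------------------------------------
# Sequence planting
# ---------------------------------------------------------------------------

def plant_site(target_seq: str, mirna_seq: str, position: int,
               seed_len: int = 7) -> str:
    """Write a seed-complementary element into a target sequence.

    Replaces target_seq[position : position+seed_len] with the reverse
    complement of miRNA positions 2..(1+seed_len) (1-based, written 5'->3'
    on the target). seed_len 0 returns the target unchanged.
    """
    if seed_len == 0:
        return target_seq
    if seed_len < 0 or 1 + seed_len > len(mirna_seq):
        raise ValueError("seed_len out of range for this miRNA")
    if position < 0 or position + seed_len > len(target_seq):
        raise ValueError(
            f"site [{position}, {position + seed_len}) outside target of "
            f"length {len(target_seq)}")
    element = revcomp(mirna_seq[1:1 + seed_len])
    return target_seq[:position] + element + target_seq[position + seed_len:]


def _plant_full_site(target_seq: str, mirna_seq: str, position: int
                     ) -> tuple[str, int, int, str]:
    """Plant the full reverse complement of a miRNA; returns the new target
    and the (start, end, seed_type) of the seed site as the MRE scanner
    reports it."""
    L = len(mirna_seq)
    if position < 0 or position + L > len(target_seq):
        raise ValueError("full site does not fit the target")
    block = revcomp(mirna_seq)
    seq = target_seq[:position] + block + target_seq[position + L:]
    core_start = position + L - 7  # target span pairing miRNA positions 2-7
    if mirna_seq[0] == "U":  # an A faces miRNA position 1
        return seq, core_start - 1, core_start + 7, "8mer"
    return seq, core_start - 1, core_start + 6, "7mer-m8"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _directions(n: int, start_up: bool = True) -> list[str]:
    return ["up" if (i % 2 == 0) == start_up else "down" for i in range(n)]


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate one fully self-consistent dataset from ``config``.

    Identical config (including seed) gives bit-identical output.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)

    samples = [f"case_{i+1}" for i in range(cfg.n_case)] + \
              [f"ctrl_{i+1}" for i in range(cfg.n_control)]
    design = {s: ("case" if s.startswith("case") else "control") for s in samples}
    group_sign = np.array([+0.5 if design[s] == "case" else -0.5 for s in samples])
    n_s = len(samples)

    circ_ids = [f"circ_{i+1:04d}" for i in range(cfg.n_circ)]
    mir_ids = [f"mir_{i+1:04d}" for i in range(cfg.n_mirna)]
    mrna_ids = [f"gene_{i+1:04d}" for i in range(cfg.n_mrna)]

    # --- planted truth -----------------------------------------------------
    mpc = cfg.mirnas_per_circuit
    circuits: list[tuple[str, str, str]] = []
    circuit_dir: dict[str, str] = {}
    for c in range(cfg.n_circuits):
        circ, mrna = circ_ids[c], mrna_ids[c]
        up = c % 2 == 0  # alternate so both Fig-4-style orientations occur
        circuit_dir[circ] = "up" if up else "down"
        circuit_dir[mrna] = "up" if up else "down"
        for j in range(mpc):
            mir = mir_ids[c * mpc + j]
            circuit_dir[mir] = "down" if up else "up"
            circuits.append((circ, mir, mrna))

    de_features: dict[str, str] = dict(circuit_dir)
    for ids, n_de, used in ((circ_ids, cfg.n_de_circ, cfg.n_circuits),
                            (mir_ids, cfg.n_de_mirna, cfg.n_circuits * mpc),
                            (mrna_ids, cfg.n_de_mrna, cfg.n_circuits)):
        for i, d in enumerate(_directions(n_de - used)):
            de_features[ids[used + i]] = d

    if cfg.lfc_de == 0.0:
        de_features = {}

    # --- latent sponge factors --------------------------------------------
    sponge = {}  # circuit index -> per-sample latent factor (log2 units)
    for c in range(cfg.n_circuits):
        sponge[c] = rng.normal(0.0, cfg.sponge_sd, size=n_s)
    circuit_of: dict[str, tuple[int, float]] = {}  # feature -> (circuit, loading)
    for c in range(cfg.n_circuits):
        circuit_of[circ_ids[c]] = (c, +1.0)
        circuit_of[mrna_ids[c]] = (c, +1.0)
        for j in range(mpc):
            circuit_of[mir_ids[c * mpc + j]] = (c, -1.0)

    def shift_matrix(ids: list[str]) -> np.ndarray:
        """Per-feature, per-sample log2 offsets from DE and sponge factors."""
        out = np.zeros((len(ids), n_s))
        for i, fid in enumerate(ids):
            d = de_features.get(fid)
            if d is not None:
                out[i] += cfg.lfc_de * group_sign * (+1 if d == "up" else -1)
            if fid in circuit_of:
                c, loading = circuit_of[fid]
                out[i] += loading * sponge[c]
        return out

    # --- count matrices ----------------------------------------------------
    lo, hi = cfg.size_factor_range
    size_fac = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))

    def counts_matrix(ids: list[str]) -> pd.DataFrame:
        base = rng.normal(cfg.base_mean_log, cfg.base_sd_log, size=len(ids))
        mu = np.exp2(base[:, None] + shift_matrix(ids)) * size_fac[None, :]
        return pd.DataFrame(_nb_sample(rng, mu, cfg.nb_dispersion).astype(float),
                            index=ids, columns=samples)

    circ_em = ExpressionMatrix(counts_matrix(circ_ids), "counts", dict(design))
    mrna_em = ExpressionMatrix(counts_matrix(mrna_ids), "counts", dict(design))

    base_i = rng.normal(cfg.intensity_mean_log, cfg.intensity_base_sd,
                        size=cfg.n_mirna)
    inten = base_i[:, None] + shift_matrix(mir_ids) + \
        rng.normal(0.0, cfg.intensity_sd, size=(cfg.n_mirna, n_s))
    mirna_em = ExpressionMatrix(pd.DataFrame(inten, index=mir_ids, columns=samples),
                                "log_intensity", dict(design))

    # --- sequences ---------------------------------------------------------
    mirna_fa = [SeqRecord(mid, _random_seq(rng, cfg.mirna_len), "miRNA")
                for mid in mir_ids]
    mir_seq = {r.id: r.seq for r in mirna_fa}

    planted: list[PlantedSite] = []
    target_fa: list[SeqRecord] = []
    site_by_target: dict[str, list[str]] = {}
    for circ, mir, mrna in circuits:
        site_by_target.setdefault(circ, []).append(mir)
        site_by_target.setdefault(mrna, []).append(mir)

    for ids, length, moltype in ((circ_ids, cfg.circ_len, "circRNA_target"),
                                 (mrna_ids, cfg.mrna_len, "mRNA_target")):
        for tid in ids:
            seq = _random_seq(rng, length)
            pos = 40
            for mir in site_by_target.get(tid, []):
                seq, s, e, seed_type = _plant_full_site(seq, mir_seq[mir], pos)
                planted.append(PlantedSite(tid, s, e, mir, seed_type))
                pos += cfg.mirna_len + 12
            target_fa.append(SeqRecord(tid, seq, moltype))

    # --- annotation --------------------------------------------------------
    sets = {}
    set_size = min(cfg.gene_set_size, cfg.n_mrna)
    for i in range(cfg.n_gene_sets):
        members = rng.choice(mrna_ids, size=set_size, replace=False)
        sets[f"term_{i+1:03d}"] = (f"synthetic gene set {i+1}",
                                   frozenset(map(str, members)))
    annotation = GeneSetCollection(sets, frozenset(mrna_ids))

    truth = TruthTable(de_features, circuits, planted)
    return SimulatedDataset(circ_em, mrna_em, mirna_em, mirna_fa, target_fa,
                            annotation, truth, cfg)


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=int(seed))


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write all matrices, FASTA files, annotation and truth tables as text."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "circ_counts": out / "circ_counts.tsv",
        "mrna_counts": out / "mrna_counts.tsv",
        "mirna_intensity": out / "mirna_intensity.tsv",
        "design": out / "design.tsv",
        "mirna_fa": out / "mirna.fa",
        "mrna_fa": out / "mrna_targets.fa",
        "circ_fa": out / "circ_targets.fa",
        "annotation": out / "annotation.gmt",
        "truth_de": out / "truth_de.tsv",
        "truth_circuits": out / "truth_circuits.tsv",
        "truth_sites": out / "truth_sites.tsv",
    }
    write_expression(ds.circ, paths["circ_counts"])
    write_expression(ds.mrna, paths["mrna_counts"])
    write_expression(ds.mirna, paths["mirna_intensity"])
    write_design(ds.circ.design, paths["design"])
    write_fasta(ds.mirna_fa, paths["mirna_fa"])
    write_fasta([r for r in ds.target_fa if r.moltype == "mRNA_target"],
                paths["mrna_fa"])
    write_fasta([r for r in ds.target_fa if r.moltype == "circRNA_target"],
                paths["circ_fa"])
    write_gmt(ds.annotation, paths["annotation"])
    write_table(pd.DataFrame(
        [{"feature_id": f, "direction": d} for f, d in ds.truth.de_features.items()],
        columns=["feature_id", "direction"]), paths["truth_de"])
    write_table(pd.DataFrame(
        [{"circ_id": c, "mirna_id": m, "mrna_id": g} for c, m, g in ds.truth.circuits],
        columns=["circ_id", "mirna_id", "mrna_id"]), paths["truth_circuits"])
    write_table(pd.DataFrame(
        [{"target_id": s.target_id, "start": s.start, "end": s.end,
          "mirna_id": s.mirna_id, "seed_type": s.seed_type}
         for s in ds.truth.planted_sites],
        columns=["target_id", "start", "end", "mirna_id", "seed_type"]),
        paths["truth_sites"])
    return {k: str(v) for k, v in paths.items()}
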