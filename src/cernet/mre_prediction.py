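"""Sequence-level prediction of miRNA response elements (MREs).

Candidate sites are anchored by seed complementarity (miRNA positions 2-7,
1-based, with the usual 6mer / 7mer-A1 / 7mer-m8 / 8mer grades), then scored
with a miRanda-style Smith-Waterman local duplex alignment of the miRNA
against a target window extended 30 nt toward the target 5' end to capture
3'-supplementary pairing. A crude additive base-pair energy stands in for
nearest-neighbor thermodynamics; it is a filter, not a physical prediction.

Conventions, stated once and used everywhere:

* Target coordinates are 0-based half-open, 5'->3' as supplied.
* The target base opposite miRNA position 1 sits at the 3' end of the site.
* The seed-proximal miRNA region (positions 1-8) has its aligned pair scores
  doubled, the miRanda-style weighting of seed pairing.
* circRNA targets flagged circular are scanned on a linearized sequence
  extended by its first (miRNA length - 1) nt so junction-spanning sites are
  seen; coordinates are reported modulo the original length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE = {("G", "U"), ("U", "G")}

MAX_WINDOW = 80  # nt; duplex_align refuses longer windows (caller tiles)
UPSTREAM_FLANK = 30  # nt of target 5' context added to each seed anchor


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MRE:
    """One miRNA binding site on a target."""

    mirna_id: str
    target_id: str
    target_class: str  # mRNA | circRNA
    start: int
    end: int
    seed_type: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    align_score: float
    energy: float


@dataclass(frozen=True)
class TargetPair:
    """All sites of one miRNA on one target, collapsed."""

    mirna_id: str
    target_id: str
    target_class: str
    n_sites: int
    best_score: float
    best_energy: float


@dataclass(frozen=True)
class AlignParams:
    """Scoring constants for the duplex aligner (miRanda-inspired defaults)."""

    match: float = 5.0
    wobble: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -2.0
    seed_multiplier: float = 2.0
    seed_span: tuple[int, int] = (1, 8)  # 1-based inclusive miRNA positions

    energy_gc: float = -3.0
    energy_au: float = -2.0
    energy_gu: float = -1.0
    energy_other: float = 0.5  # mismatches and gaps


DEFAULT_PARAMS = AlignParams()


# ---------------------------------------------------------------------------
# Seed matching
# ---------------------------------------------------------------------------

def seed_match(mirna: SeqRecord, target: SeqRecord,
               seed_len_min: int = 6) -> list[tuple[int, int, str]]:
    """Find seed-complementary sites of ``mirna`` on ``target``.

    Every target window equal to the reverse complement of miRNA positions
    2-7 is reported, graded up to 7mer-m8 (position 8 also paired), 7mer-A1
    (an A opposite miRNA position 1) or 8mer (both). Returns (start, end,
    seed_type) with 0-based half-open target coordinates covering the
    matched span. Overlapping sites are all reported.
    """
    if seed_len_min < 6:
        raise ValueError("seed_len_min below 6 is not supported")
    m, t = mirna.seq, target.seq
    if len(m) < 8 or len(t) < seed_len_min:
        return []
    core = revcomp(m[1:7])  # miRNA positions 2-7
    sites: list[tuple[int, int, str]] = []
    i = t.find(core)
    while i != -1:
        has_m8 = i >= 1 and t[i - 1] == _COMPLEMENT[m[7]]
        has_a1 = i + 6 < len(t) and t[i + 6] == "A"
        if has_m8 and has_a1:
            sites.append((i - 1, i + 7, "8mer"))
        elif has_m8:
            sites.append((i - 1, i + 6, "7mer-m8"))
        elif has_a1:
            sites.append((i, i + 7, "7mer-A1"))
        else:
            sites.append((i, i + 6, "6mer"))
        i = t.find(core, i + 1)
    return sites


# ---------------------------------------------------------------------------
# Duplex alignment
# ---------------------------------------------------------------------------

def _pair_kind(a: str, b: str) -> str:
    if _COMPLEMENT[a] == b:
        return "GC" if {a, b} == {"G", "C"} else "AU"
    if (a, b) in _WOBBLE:
        return "GU"
    return "mismatch"


def _pair_score(mi_base: str, t_base: str, mi_pos1: int, params: AlignParams) -> float:
    kind = _pair_kind(mi_base, t_base)
    s = {"GC": params.match, "AU": params.match,
         "GU": params.wobble, "mismatch": params.mismatch}[kind]
    lo, hi = params.seed_span
    if lo <= mi_pos1 <= hi:
        s *= params.seed_multiplier
    return s


def duplex_align(mirna: SeqRecord, target_window: str,
                 params: AlignParams = DEFAULT_PARAMS
                 ) -> tuple[float, list[tuple[int, int, str]]]:
    """Local alignment of the miRNA (3'->5') against a target window (5'->3').

    Affine-gap Smith-Waterman (Gotoh) over base-pairing scores: Watson-Crick
    +5, G:U wobble +2, mismatch -3, gap open -8, gap extend -2, with pairs
    involving the seed-proximal miRNA region doubled. Returns the maximal
    local score (floored at 0) and the aligned columns of the best path as
    (miRNA position 1-based, target index 0-based or -1 for a gap, kind).
    """
    t = target_window
    if len(t) > MAX_WINDOW:
        raise ValueError(f"window of {len(t)} nt exceeds {MAX_WINDOW}; tile the target")
    # orient antiparallel: walk the miRNA 3'->5' so both strings read left to
    # right along the duplex; m_rev[i] is miRNA position len(m)-i (1-based)
    m = mirna.seq
    m_rev = m[::-1]
    n_m, n_t = len(m_rev), len(t)

    NEG = float("-inf")
    # Gotoh: H match-state, E gap in miRNA (target consumed), F gap in target
    H = [[0.0] * (n_t + 1) for _ in range(n_m + 1)]
    E = [[NEG] * (n_t + 1) for _ in range(n_m + 1)]
    F = [[NEG] * (n_t + 1) for _ in range(n_m + 1)]
    best, best_ij = 0.0, None
    for i in range(1, n_m + 1):
        mi_pos1 = n_m - (i - 1)  # 1-based miRNA position of m_rev[i-1]
        for j in range(1, n_t + 1):
            E[i][j] = max(H[i][j - 1] + params.gap_open,
                          E[i][j - 1] + params.gap_extend)
            F[i][j] = max(H[i - 1][j] + params.gap_open,
                          F[i - 1][j] + params.gap_extend)
            sub = _pair_score(m_rev[i - 1], t[j - 1], mi_pos1, params)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + sub,
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best, best_ij = H[i][j], (i, j)

    pairs: list[tuple[int, int, str]] = []
    if best_ij is not None:
        # traceback from the best cell through the three states
        i, j = best_ij
        state = "H"
        while i > 0 and j > 0:
            if state == "H":
                if H[i][j] == 0.0:
                    break
                sub = _pair_score(m_rev[i - 1], t[j - 1],
                                  n_m - (i - 1), params)
                if H[i][j] == H[i - 1][j - 1] + sub:
                    pairs.append((n_m - (i - 1), j - 1,
                                  _pair_kind(m_rev[i - 1], t[j - 1])))
                    i, j = i - 1, j - 1
                elif H[i][j] == E[i][j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                pairs.append((-1, j - 1, "gap"))
                if E[i][j] == H[i][j - 1] + params.gap_open:
                    state = "H"
                j -= 1
            else:  # F
                pairs.append((n_m - (i - 1), -1, "gap"))
                if F[i][j] == H[i - 1][j] + params.gap_open:
                    state = "H"
                i -= 1
        pairs.reverse()
    return best, pairs


def duplex_energy(pairs: list[tuple[int, int, str]],
                  params: AlignParams = DEFAULT_PARAMS) -> float:
    """Additive pair-stack pseudo-energy in kcal/mol (more negative = stabler).

    GC pairs contribute -3.0, AU -2.0, G:U wobbles -1.0; mismatches and gaps
    +0.5 each. Not a nearest-neighbor model — a documented, testable proxy.
    """
    table = {"GC": params.energy_gc, "AU": params.energy_au,
             "GU": params.energy_gu, "mismatch": params.energy_other,
             "gap": params.energy_other}
    return float(sum(table[kind] for _, _, kind in pairs))


# ---------------------------------------------------------------------------
# Site prediction and pair collapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ScanTarget:
    record: SeqRecord
    scan_seq: str
    true_len: int
    circular: bool


def _prepare_target(target: SeqRecord, mirna_len: int) -> _ScanTarget:
    circular = target.moltype == "circRNA_target"
    if circular and len(target.seq) > mirna_len:
        ext = target.seq + target.seq[: mirna_len - 1]
        return _ScanTarget(target, ext, len(target.seq), True)
    return _ScanTarget(target, target.seq, len(target.seq), circular)


def predict_mres(mirnas: list[SeqRecord], targets: list[SeqRecord],
                 score_min: float = 140.0, energy_max: float = -20.0,
                 seed_required: bool = True,
                 params: AlignParams = DEFAULT_PARAMS) -> list[MRE]:
    """Predict MREs for every miRNA x target combination.

    Seed matches anchor candidate windows (site plus 30 nt of 5' target
    flank, where miRNA 3'-supplementary pairing lands); each window is scored
    by :func:`duplex_align` and :func:`duplex_energy` and a site is kept iff
    align_score >= score_min and energy <= energy_max. With
    ``seed_required=False`` the whole target is tiled into overlapping
    windows instead and reported sites span the aligned target region.
    Output order is (mirna_id, target_id, start).
    """
    out: list[MRE] = []
    for mi in sorted(mirnas, key=lambda r: r.id):
        for tg in sorted(targets, key=lambda r: r.id):
            tclass = "circRNA" if tg.moltype == "circRNA_target" else "mRNA"
            scan = _prepare_target(tg, len(mi))
            pseudo = SeqRecord(tg.id, scan.scan_seq, tg.moltype)
            if seed_required:
                anchors = seed_match(mi, pseudo)
            else:
                anchors = [(s, min(s + 40, len(scan.scan_seq)), "6mer")
                           for s in range(0, max(1, len(scan.scan_seq) - 20), 20)]
            # a junction-spanning site appears twice on the linearized
            # circRNA (clipped near position 0 and complete in the
            # extension); keep the best-scoring representative per
            # modulo-length coordinate
            best: dict[tuple[int, int], MRE] = {}
            for start, end, seed_type in anchors:
                w_lo = max(0, start - UPSTREAM_FLANK)
                window = scan.scan_seq[w_lo:end]
                score, pairs = duplex_align(mi, window, params)
                energy = duplex_energy(pairs, params)
                if score < score_min or energy > energy_max:
                    continue
                s_mod, e_mod = start, end
                if scan.circular:
                    s_mod = start % scan.true_len
                    e_mod = ((end - 1) % scan.true_len) + 1
                key = (s_mod, e_mod)
                prev = best.get(key)
                if prev is None or score > prev.align_score:
                    best[key] = MRE(mi.id, tg.id, tclass, s_mod, e_mod,
                                    seed_type, float(score), float(energy))
            out.extend(best.values())
    out.sort(key=lambda r: (r.mirna_id, r.target_id, r.start))
    return out


def collapse_to_pairs(mres: list[MRE]) -> list[TargetPair]:
    """Collapse site-level MREs to unique (miRNA, target) pairs."""
    grouped: dict[tuple[str, str, str], list[MRE]] = {}
    for m in mres:
        grouped.setdefault((m.mirna_id, m.target_id, m.target_class), []).append(m)
    pairs = [
        TargetPair(mi, tg, tc, len(sites),
                   max(s.align_score for s in sites),
                   min(s.energy for s in sites))
        for (mi, tg, tc), sites in grouped.items()
    ]
    pairs.sort(key=lambda p: (p.mirna_id, p.target_id))
    return pairs


def mres_to_frame(mres: list[MRE]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"mirna_id": m.mirna_id, "target_id": m.target_id,
             "target_class": m.target_class, "start": m.start, "end": m.end,
             "seed_type": m.seed_type, "align_score": m.align_score,
             "energy": m.energy}
            for m in mres
        ],
        columns=["mirna_id", "target_id", "target_class", "start", "end",
                 "seed_type", "align_score", "energy"],
    )


def pairs_to_frame(pairs: list[TargetPair]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"mirna_id": p.mirna_id, "target_id": p.target_id,
             "target_class": p.target_class, "n_sites": p.n_sites,
             "best_score": p.best_score, "best_energy": p.best_energy}
            for p in pairs
        ],
        columns=["mirna_id", "target_id", "target_class", "n_sites",
                 "best_score", "best_energy"],
    )
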