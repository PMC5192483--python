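"""miRNA target-site prediction on lncRNA transcripts.

Two predictors are combined:

* a constraint-based site finder ("duplex predictor") that scans for seed
  matches (miRNA positions 2..8 by default) allowing at most one mismatch
  and one G:U wobble in the seed, extends the pairing gaplessly over the
  whole miRNA, and keeps sites with >= 12 paired bases and a
  nearest-neighbor duplex free energy <= -12 kcal/mol.  Each retained
  site receives an empirical p-value: its ΔG is ranked against the best
  ΔG the same miRNA attains on dinucleotide-preserving shuffles of the
  transcript, and the p-values are corrected by Benjamini-Hochberg
  across all tested sites;

* a miRanda-like complementarity alignment (affine-gap local DP with the
  canonical miRanda weights and 4x scaling of the seed positions), run
  with no score or energy cutoff so that any positive-scoring
  complementarity counts as a hit.

The consensus keeps pairs supported by both predictors, with the duplex
predictor's q-value below the configured FDR.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from statsmodels.stats.multitest import multipletests

from .seq import dinucleotide_shuffle, encode
from .thermo import DEFAULT_NN, NearestNeighborTable, helix_pairs_energy

__all__ = [
    "PredictionConfig",
    "SeedAnchor",
    "DuplexSite",
    "find_seed_sites",
    "extend_duplex",
    "duplex_energy",
    "site_pvalue",
    "bh_adjust",
    "miranda_like_score",
    "miranda_hit",
    "consensus_targets",
    "predict_targets",
]


@dataclass(frozen=True)
class PredictionConfig:
    """Thresholds of the site definition and of the consensus step.

    Defaults are the biophysical constraints of the screen: minimum seed
    of 7 bases with at most one mismatch and one G:U wobble, at least 12
    paired bases in the heteroduplex, -12 kcal/mol maximum folding
    energy, and FDR < 5% on the duplex predictor's empirical p-values.
    The alignment predictor runs unrestricted (no score/energy cutoffs).
    """

    min_seed: int = 7
    max_seed_mismatch: int = 1
    max_seed_gu: int = 1
    min_paired: int = 12
    max_energy: float = -12.0
    n_shuffles: int = 500
    fdr: float = 0.05
    miranda_score_min: float | None = None
    miranda_energy_max: float | None = None
    seed: int = 0


@dataclass(frozen=True)
class SeedAnchor:
    """A candidate seed match: transcript window start (0-based) plus
    seed diagnostics."""

    window_start: int
    mismatches: int
    gu: int


@dataclass
class DuplexSite:
    """A predicted binding site of one miRNA on one transcript.

    ``site_start``/``site_end`` are 1-based inclusive transcript
    coordinates of the region opposite the full miRNA (clamped to the
    transcript).  ``pairs`` holds the gapless pairing map ordered along
    the miRNA 5'->3' as (mirna_base, transcript_base, paired) triples
    for in-bounds positions.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    seed_len: int
    seed_mismatches: int
    seed_gu: int
    paired_bases: int
    delta_g: float = float("nan")
    alignment_score: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    pairs: list = field(default_factory=list, repr=False)


def find_seed_sites(mirna_seq: str, lnc_seq: str,
                    cfg: PredictionConfig = PredictionConfig()) -> list[SeedAnchor]:
    """Scan a transcript for seed matches of one miRNA.

    The seed is miRNA positions 2..(min_seed+1) from the 5' end, paired
    antiparallel against the transcript; a window is an anchor when at
    most ``max_seed_mismatch`` positions fail to pair and at most
    ``max_seed_gu`` paired positions are G:U wobbles.  All (possibly
    overlapping) anchors are returned in transcript order.
    """
    m = encode(mirna_seq)
    t = encode(lnc_seq)
    k = cfg.min_seed
    if len(m) < k + 1:
        raise ValueError(
            f"miRNA of length {len(m)} shorter than seed window {k + 1}")
    if len(t) < k:
        return []
    seed = m[1:1 + k]
    win = sliding_window_view(t, k).astype(np.int16)
    s = win + seed[::-1][None, :]
    paired = (s == 3) | (s == 5)
    gu = s == 5
    mism = k - paired.sum(axis=1)
    guc = gu.sum(axis=1)
    keep = (mism <= cfg.max_seed_mismatch) & (guc <= cfg.max_seed_gu)
    return [SeedAnchor(int(i), int(mism[i]), int(guc[i]))
            for i in np.flatnonzero(keep)]


def extend_duplex(anchor: SeedAnchor, mirna_seq: str, lnc_seq: str,
                  cfg: PredictionConfig = PredictionConfig(),
                  mirna_id: str = "mirna",
                  transcript_id: str = "transcript") -> DuplexSite | None:
    """Extend a seed anchor gaplessly over the full miRNA length.

    miRNA position j (0-based) faces transcript position
    ``window_start + min_seed - j``; positions beyond either transcript
    end are truncated and count as unpaired.  Returns ``None`` when the
    heteroduplex has fewer than ``min_paired`` paired (WC or G:U) bases.
    """
    m = encode(mirna_seq)
    t = encode(lnc_seq)
    k, s = cfg.min_seed, anchor.window_start
    n, L = len(t), len(m)
    pairs: list[tuple[int, int, bool]] = []
    lo, hi = n, -1
    for j in range(L):
        ti = s + k - j
        if ti < 0 or ti >= n:
            continue
        tot = int(m[j]) + int(t[ti])
        pairs.append((int(m[j]), int(t[ti]), tot in (3, 5)))
        lo, hi = min(lo, ti), max(hi, ti)
    paired_bases = sum(p for _, _, p in pairs)
    if paired_bases < cfg.min_paired:
        return None
    return DuplexSite(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=lo + 1,
        site_end=hi + 1,
        seed_len=k,
        seed_mismatches=anchor.mismatches,
        seed_gu=anchor.gu,
        paired_bases=paired_bases,
        pairs=pairs,
    )


def duplex_energy(site: DuplexSite,
                  nn: NearestNeighborTable = DEFAULT_NN) -> float:
    """Nearest-neighbor ΔG (kcal/mol) of a site's gapless pairing map."""
    dg = helix_pairs_energy(site.pairs, nn)
    site.delta_g = dg
    return dg


def _accepted_sites(m: np.ndarray, t: np.ndarray, cfg: PredictionConfig,
                    nn: NearestNeighborTable,
                    energy_filter: bool = True) -> list[tuple[SeedAnchor, list, int, int, int, float]]:
    """Core scanner on encoded arrays; returns accepted-site tuples.

    With ``energy_filter=False`` the ΔG threshold is not applied (used
    to build the null ΔG distribution on shuffled transcripts, where the
    energy itself is the test statistic)."""
    k = cfg.min_seed
    n, L = len(t), len(m)
    if n < k:
        return []
    seed = m[1:1 + k]
    win = sliding_window_view(t, k).astype(np.int16)
    s = win + seed[::-1][None, :]
    paired = (s == 3) | (s == 5)
    gu = s == 5
    mism = k - paired.sum(axis=1)
    guc = gu.sum(axis=1)
    keep = np.flatnonzero((mism <= cfg.max_seed_mismatch)
                          & (guc <= cfg.max_seed_gu))
    out = []
    for i in keep:
        pairs: list[tuple[int, int, bool]] = []
        lo, hi = n, -1
        pb = 0
        for j in range(L):
            ti = int(i) + k - j
            if ti < 0 or ti >= n:
                continue
            tot = int(m[j]) + int(t[ti])
            ok = tot in (3, 5)
            pb += ok
            pairs.append((int(m[j]), int(t[ti]), ok))
            lo, hi = min(lo, ti), max(hi, ti)
        if pb < cfg.min_paired:
            continue
        dg = helix_pairs_energy(pairs, nn)
        if energy_filter and dg > cfg.max_energy:
            continue
        out.append((SeedAnchor(int(i), int(mism[i]), int(guc[i])),
                    pairs, lo, hi, pb, dg))
    return out


def _null_best_dg(m: np.ndarray, shuffles: Sequence[np.ndarray],
                  cfg: PredictionConfig,
                  nn: NearestNeighborTable) -> np.ndarray:
    """Best (lowest) ΔG the miRNA attains on each shuffled transcript.

    Candidate sites on the shuffles must satisfy the seed and
    paired-base constraints; a shuffle with no candidate contributes
    +inf (it cannot beat any observed site).
    """
    out = np.full(len(shuffles), np.inf)
    for b, sh in enumerate(shuffles):
        cand = _accepted_sites(m, sh, cfg, nn, energy_filter=False)
        if cand:
            out[b] = min(dg for *_, dg in cand)
    return out


def _transcript_rng(seed: int, transcript_id: str) -> np.random.Generator:
    sub = zlib.crc32(transcript_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, sub])


def site_pvalue(site: DuplexSite, mirna_seq: str, lnc_seq: str,
                cfg: PredictionConfig = PredictionConfig(),
                nn: NearestNeighborTable = DEFAULT_NN,
                shuffles: Sequence[np.ndarray] | None = None,
                null_dg: np.ndarray | None = None) -> float:
    """Empirical significance of a predicted site's duplex stability.

    ``p = (1 + b) / (1 + n_shuffles)`` where ``b`` counts
    dinucleotide-preserving shuffles of the transcript on which the
    same miRNA attains a candidate site (seed and paired-base
    constraints satisfied) at least as stable as this one
    (``ΔG_null <= ΔG_site``).  A site whose miRNA cannot form any
    candidate in any shuffle sits at the floor ``1/(1 + n_shuffles)``.
    Deterministic given ``cfg.seed`` and the transcript id; precomputed
    ``shuffles`` or a precomputed per-pair ``null_dg`` array may be
    supplied to share work across sites of the same pair.
    """
    if cfg.n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive to define a p-value")
    m = encode(mirna_seq)
    if null_dg is None:
        if shuffles is None:
            t = encode(lnc_seq)
            rng = _transcript_rng(cfg.seed, site.transcript_id)
            shuffles = [dinucleotide_shuffle(t, rng)
                        for _ in range(cfg.n_shuffles)]
        null_dg = _null_best_dg(m, shuffles, cfg, nn)
    p = (1 + int(np.sum(null_dg <= site.delta_g))) / (1 + len(null_dg))
    site.p_value = p
    return p


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties share q)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# miRanda-like alignment predictor
# ---------------------------------------------------------------------------

MIRANDA_MATCH = 5.0
MIRANDA_GU = 1.0
MIRANDA_MISMATCH = -3.0
MIRANDA_GAP_OPEN = -9.0
MIRANDA_GAP_EXTEND = -4.0
MIRANDA_SEED_SCALE = 4.0
_MIRANDA_SEED_RANGE = (2, 8)  # miRNA positions, 1-based inclusive


def _miranda_substitution(m: np.ndarray) -> np.ndarray:
    """Per-(miRNA position, target base) substitution scores, seed-scaled."""
    sub = np.empty((len(m), 4))
    for j, mj in enumerate(m):
        for b in range(4):
            tot = int(mj) + b
            v = MIRANDA_MATCH if tot == 3 else (
                MIRANDA_GU if tot == 5 else MIRANDA_MISMATCH)
            if _MIRANDA_SEED_RANGE[0] <= j + 1 <= _MIRANDA_SEED_RANGE[1]:
                v *= MIRANDA_SEED_SCALE
            sub[j, b] = v
    return sub


def miranda_like_score(mirna_seq: str, window_seq: str) -> tuple[float, float]:
    """Best local complementarity alignment of a miRNA against a target
    window, with the implied duplex ΔG.

    Affine-gap Smith-Waterman on complementarity: +5 per Watson-Crick
    pair, +1 per G:U, -3 per mismatch, gaps -9 to open and -4 to extend;
    substitution scores for miRNA positions 2-8 are scaled 4x.  The
    miRNA is read 5'->3' against the window read 3'->5' (antiparallel).
    Returns ``(score, delta_g)``; a score of 0 means no positive-scoring
    alignment exists.
    """
    m = encode(mirna_seq)
    w = encode(window_seq)[::-1]  # read target 3'->5'
    Lm, Lw = len(m), len(w)
    sub = _miranda_substitution(m)
    NEG = -1e18
    H = np.zeros((Lm + 1, Lw + 1))
    E = np.full((Lm + 1, Lw + 1), NEG)  # gap in miRNA (consume target)
    F = np.full((Lm + 1, Lw + 1), NEG)  # gap in target (consume miRNA)
    back: dict[tuple[int, int], tuple[int, int]] = {}
    best, best_cell = 0.0, None
    for j in range(1, Lm + 1):
        for i in range(1, Lw + 1):
            E[j, i] = max(H[j, i - 1] + MIRANDA_GAP_OPEN,
                          E[j, i - 1] + MIRANDA_GAP_EXTEND)
            F[j, i] = max(H[j - 1, i] + MIRANDA_GAP_OPEN,
                          F[j - 1, i] + MIRANDA_GAP_EXTEND)
            diag = H[j - 1, i - 1] + sub[j - 1, w[i - 1]]
            h = max(0.0, diag, E[j, i], F[j, i])
            H[j, i] = h
            if h > 0:
                if h == diag:
                    back[(j, i)] = (j - 1, i - 1)
                elif h == E[j, i]:
                    back[(j, i)] = (j, i - 1)
                else:
                    back[(j, i)] = (j - 1, i)
            if h > best:
                best, best_cell = h, (j, i)
    if best_cell is None:
        return 0.0, float("nan")
    # traceback -> pairing map along the miRNA for the energy model
    pairs: list[tuple[int, int, bool]] = []
    j, i = best_cell
    while (j, i) in back and H[j, i] > 0:
        pj, pi = back[(j, i)]
        if pj == j - 1 and pi == i - 1:
            a, b = int(m[j - 1]), int(w[i - 1])
            pairs.append((a, b, (a + b) in (3, 5)))
        else:  # gap column breaks stacking
            pairs.append((-1, -1, False))
        j, i = pj, pi
    pairs.reverse()
    return float(best), helix_pairs_energy(pairs)


def miranda_hit(mirna_seq: str, lnc_seq: str,
                cfg: PredictionConfig = PredictionConfig()) -> bool:
    """Whether the alignment predictor reports any hit for the pair.

    With the default unrestricted thresholds a hit exists iff the best
    local score is positive, which is the case exactly when some miRNA
    base can pair (WC or G:U) with some transcript base — any single
    paired column already scores positively and no alignment can beat a
    score of 0 otherwise.  This closed-form shortcut avoids the DP when
    only the hit/no-hit status is needed; explicit score/energy cutoffs
    fall back to the full alignment.
    """
    if cfg.miranda_score_min is None and cfg.miranda_energy_max is None:
        m = np.unique(encode(mirna_seq)).astype(np.int16)
        t = np.unique(encode(lnc_seq)).astype(np.int16)
        tot = m[:, None] + t[None, :]
        return bool(np.any((tot == 3) | (tot == 5)))
    score, energy = miranda_like_score(mirna_seq, lnc_seq)
    if score <= 0:
        return False
    if cfg.miranda_score_min is not None and score < cfg.miranda_score_min:
        return False
    if cfg.miranda_energy_max is not None and energy > cfg.miranda_energy_max:
        return False
    return True


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

SITE_COLUMNS = [
    "mirna_id", "transcript_id", "site_start", "site_end", "seed_mismatches",
    "seed_gu", "paired_bases", "delta_g", "p_value", "q_value",
]


def scan_pairs(mirnas: Mapping[str, str], transcripts: Mapping[str, str],
               cfg: PredictionConfig = PredictionConfig(),
               nn: NearestNeighborTable = DEFAULT_NN) -> list[DuplexSite]:
    """All accepted duplex sites over the full miRNA x transcript grid."""
    sites: list[DuplexSite] = []
    enc_m = {mid: encode(s) for mid, s in mirnas.items()}
    enc_t = {tid: encode(s) for tid, s in transcripts.items()}
    for tid, t in enc_t.items():
        for mid, m in enc_m.items():
            for anchor, pairs, lo, hi, pb, dg in _accepted_sites(m, t, cfg, nn):
                sites.append(DuplexSite(
                    mirna_id=mid, transcript_id=tid,
                    site_start=lo + 1, site_end=hi + 1,
                    seed_len=cfg.min_seed,
                    seed_mismatches=anchor.mismatches, seed_gu=anchor.gu,
                    paired_bases=pb, delta_g=dg, pairs=pairs))
    return sites


def attach_significance(sites: list[DuplexSite], mirnas: Mapping[str, str],
                        transcripts: Mapping[str, str],
                        cfg: PredictionConfig = PredictionConfig(),
                        nn: NearestNeighborTable = DEFAULT_NN) -> None:
    """Shuffle p-values (shared per transcript) and global BH q-values.

    The null ΔG distribution is a property of the (miRNA, transcript)
    combination, so it is computed once per pair and each of the pair's
    sites is ranked against it; BH runs over all tested site hypotheses
    of the batch.
    """
    shuffle_cache: dict[str, list[np.ndarray]] = {}
    pair_null: dict[tuple[str, str], np.ndarray] = {}
    for site in sites:
        key = (site.mirna_id, site.transcript_id)
        if key not in pair_null:
            tid = site.transcript_id
            if tid not in shuffle_cache:
                t = encode(transcripts[tid])
                rng = _transcript_rng(cfg.seed, tid)
                shuffle_cache[tid] = [dinucleotide_shuffle(t, rng)
                                      for _ in range(cfg.n_shuffles)]
            pair_null[key] = _null_best_dg(encode(mirnas[site.mirna_id]),
                                           shuffle_cache[tid], cfg, nn)
        site_pvalue(site, mirnas[site.mirna_id], transcripts[site.transcript_id],
                    cfg, nn, null_dg=pair_null[key])
    if sites:
        qs = bh_adjust([s.p_value for s in sites])
        for site, q in zip(sites, qs):
            site.q_value = float(q)


def sites_to_frame(sites: list[DuplexSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(s, c) for c in SITE_COLUMNS} for s in sites],
        columns=SITE_COLUMNS,
    )


def consensus_targets(sites: list[DuplexSite] | pd.DataFrame,
                      miranda_hits: pd.DataFrame,
                      cfg: PredictionConfig = PredictionConfig(),
                      ) -> tuple[pd.DataFrame, dict[tuple[str, str], DuplexSite]]:
    """Intersect the two predictors into consensus (miRNA, transcript) pairs.

    A pair is kept iff it has at least one duplex-predictor site with
    ``q < cfg.fdr`` (strict) and at least one alignment-predictor hit.
    Returns the pair table (with per-pair best site by lowest q then
    lowest ΔG, and distinct-feature counts in ``attrs['summary']``) and
    the best-site objects when site objects were provided.
    """
    if isinstance(sites, pd.DataFrame):
        site_df = sites.copy()
        site_objs: list[DuplexSite] = []
    else:
        site_objs = sites
        site_df = sites_to_frame(sites)
    required = {"mirna_id", "transcript_id", "hit"}
    if not required <= set(miranda_hits.columns):
        raise ValueError(f"miranda_hits needs columns {sorted(required)}")
    universe = set(zip(miranda_hits["mirna_id"], miranda_hits["transcript_id"]))
    site_pairs = set(zip(site_df["mirna_id"], site_df["transcript_id"]))
    if site_pairs and universe and not (site_pairs & universe):
        raise ValueError(
            "predictor universes are disjoint: no (miRNA, transcript) pair "
            "was tested by both predictors")
    if site_pairs - universe:
        missing = sorted(site_pairs - universe)[0]
        raise ValueError(
            f"pair {missing} has duplex sites but was not tested by the "
            "alignment predictor")
    hit_pairs = set(zip(
        miranda_hits.loc[miranda_hits["hit"], "mirna_id"],
        miranda_hits.loc[miranda_hits["hit"], "transcript_id"]))

    sig = site_df[site_df["q_value"] < cfg.fdr]
    rows = []
    best_sites: dict[tuple[str, str], DuplexSite] = {}
    for (mid, tid), grp in sig.groupby(["mirna_id", "transcript_id"], sort=True):
        if (mid, tid) not in hit_pairs:
            continue
        grp = grp.sort_values(["q_value", "delta_g"], kind="mergesort")
        best = grp.iloc[0]
        rows.append({
            "mirna_id": mid, "transcript_id": tid,
            "n_sites": len(grp),
            "best_site_start": int(best["site_start"]),
            "best_site_end": int(best["site_end"]),
            "best_paired_bases": int(best["paired_bases"]),
            "best_delta_g": float(best["delta_g"]),
            "best_p": float(best["p_value"]),
            "best_q": float(best["q_value"]),
        })
        if site_objs:
            cand = [s for s in site_objs
                    if s.mirna_id == mid and s.transcript_id == tid
                    and s.q_value < cfg.fdr]
            best_sites[(mid, tid)] = min(
                cand, key=lambda s: (s.q_value, s.delta_g))
    pairs = pd.DataFrame(rows, columns=[
        "mirna_id", "transcript_id", "n_sites", "best_site_start",
        "best_site_end", "best_paired_bases", "best_delta_g", "best_p",
        "best_q"])
    pairs.attrs["summary"] = {
        "n_pairs": len(pairs),
        "n_mirnas": pairs["mirna_id"].nunique() if len(pairs) else 0,
        "n_transcripts": pairs["transcript_id"].nunique() if len(pairs) else 0,
    }
    return pairs, best_sites


def predict_targets(mirnas: Mapping[str, str], transcripts: Mapping[str, str],
                    cfg: PredictionConfig = PredictionConfig(),
                    nn: NearestNeighborTable = DEFAULT_NN,
                    with_alignment_scores: bool = True,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full prediction stage: scan, score, correct, intersect.

    Returns ``(sites, pairs)`` data frames.  When
    ``with_alignment_scores`` is set, consensus pairs additionally carry
    the alignment predictor's best local score.
    """
    sites = scan_pairs(mirnas, transcripts, cfg, nn)
    attach_significance(sites, mirnas, transcripts, cfg, nn)
    hits = pd.DataFrame(
        [(mid, tid, miranda_hit(ms, ts, cfg))
         for mid, ms in mirnas.items() for tid, ts in transcripts.items()],
        columns=["mirna_id", "transcript_id", "hit"])
    pairs, _ = consensus_targets(sites, hits, cfg)
    if with_alignment_scores and len(pairs):
        scores = [
            miranda_like_score(mirnas[r.mirna_id], transcripts[r.transcript_id])[0]
            for r in pairs.itertuples()
        ]
        pairs = pairs.assign(miranda_score=scores)
    elif with_alignment_scores:
        pairs = pairs.assign(miranda_score=pd.Series(dtype=float))
    return sites_to_frame(sites), pairs
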