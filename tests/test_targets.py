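import numpy as np
import pandas as pd
import pytest

from cerna_screen.seq import decode, encode, random_background, revcomp
from cerna_screen.targets import (DuplexSite, PredictionConfig, bh_adjust,
                                  consensus_targets, duplex_energy,
                                  extend_duplex, find_seed_sites,
                                  miranda_hit, miranda_like_score,
                                  predict_targets, site_pvalue,
                                  sites_to_frame)
from cerna_screen.targets import (MIRANDA_GAP_EXTEND, MIRANDA_GAP_OPEN,
                                  _accepted_sites, _miranda_substitution)
from cerna_screen.thermo import DEFAULT_NN

CFG = PredictionConfig()


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation's vectorization
# ---------------------------------------------------------------------------

def _pairs(a, b):
    return a + b in (3, 5)


def brute_force_anchors(mirna, lnc, cfg):
    """Per-position seed check by explicit loops."""
    m, t = encode(mirna), encode(lnc)
    k = cfg.min_seed
    seed = m[1:1 + k]
    out = []
    for s in range(len(t) - k + 1):
        mm = gu = 0
        for i in range(k):
            a, b = int(seed[k - 1 - i]), int(t[s + i])
            if a + b == 5:
                gu += 1
            elif a + b != 3:
                mm += 1
        if mm <= cfg.max_seed_mismatch and gu <= cfg.max_seed_gu:
            out.append((s, mm, gu))
    return out


def test_exact_complement_gives_single_anchor_at_offset():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"
    seed_rc = decode(revcomp(encode(mir)[1:8]))
    lnc = "CCCCCCCCCC" + seed_rc + "CCCCCCCCCC"
    anchors = find_seed_sites(mir, lnc, CFG)
    assert [(a.window_start, a.mismatches, a.gu) for a in anchors] == [
        (10, 0, 0)]


def test_two_seed_mismatches_rejected():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"
    seed_rc = list(decode(revcomp(encode(mir)[1:8])))
    # corrupt two positions with non-pairing, non-wobble bases
    for i in (1, 4):
        seed_rc[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[seed_rc[i]]
    lnc = "CCCC" + "".join(seed_rc) + "CCCC"
    assert find_seed_sites(mir, lnc, CFG) == []


def test_non_nucleotide_input_error_names_symbol():
    with pytest.raises(ValueError, match="'X'"):
        find_seed_sites("UGAGGUAGUA", "ACGXACGU", CFG)


@pytest.mark.parametrize("case_seed", range(4))
def test_seed_scan_matches_brute_force_random(case_seed):
    rng = np.random.default_rng(case_seed)
    for _ in range(25):
        mir = decode(rng.integers(0, 4, int(rng.integers(20, 24))).astype(np.uint8))
        lnc = decode(rng.integers(0, 4, int(rng.integers(50, 1000))).astype(np.uint8))
        got = [(a.window_start, a.mismatches, a.gu)
               for a in find_seed_sites(mir, lnc, CFG)]
        assert got == brute_force_anchors(mir, lnc, CFG)


def test_planted_full_complement_site_accepted():
    rng = np.random.default_rng(5)
    mir = decode(rng.integers(0, 4, 22).astype(np.uint8))
    site16 = decode(revcomp(encode(mir)[:16]))
    lnc = "A" * 30 + site16 + "A" * 30
    anchors = find_seed_sites(mir, lnc, CFG)
    sites = [extend_duplex(a, mir, lnc, CFG) for a in anchors]
    sites = [s for s in sites if s is not None]
    assert any(s.paired_bases >= 16 for s in sites)


def test_extension_truncated_at_transcript_start():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"
    # place the seed window at the very start: miRNA position 1 faces
    # transcript index min_seed, the 3' overhang falls off the start
    seed_rc = decode(revcomp(encode(mir)[1:8]))
    lnc = seed_rc + decode(revcomp(encode(mir)[:1]))
    anchors = [a for a in find_seed_sites(mir, lnc, CFG)
               if a.window_start == 0]
    assert anchors
    site = extend_duplex(anchors[0], mir, lnc,
                         PredictionConfig(min_paired=1))
    assert site.site_start == 1
    # only positions 1..8 of the miRNA can face the transcript
    assert len(site.pairs) == 8


def test_too_few_paired_bases_rejected():
    mir = "UGAGGUAGUAGGUUGUAUAGUU"
    seed_rc = decode(revcomp(encode(mir)[1:8]))
    lnc = "C" * 40 + seed_rc + "C" * 40  # C's pair neither A nor U tail
    anchors = find_seed_sites(mir, lnc, CFG)
    for a in anchors:
        site = extend_duplex(a, mir, lnc, CFG)
        if site is not None:
            assert site.paired_bases >= CFG.min_paired


def test_duplex_energy_written_back_to_site():
    mir = "G" * 8 + "A" * 14
    lnc = "U" * 20 + "C" * 8 + "U" * 20
    anchors = find_seed_sites(mir, lnc, CFG)
    site = extend_duplex(anchors[0], mir, lnc,
                         PredictionConfig(min_paired=5))
    dg = duplex_energy(site)
    assert site.delta_g == dg and np.isfinite(dg)


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_hand_derived_step_up():
    q = bh_adjust([0.01, 0.02, 0.04, 0.05])
    assert np.allclose(q, [0.04, 0.04, 0.05, 0.05])


def test_bh_single_and_ties():
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.1, 1.5])


def test_bh_dominates_p_and_preserves_order():
    rng = np.random.default_rng(7)
    p = rng.uniform(size=200)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# miRanda-like alignment
# ---------------------------------------------------------------------------

def oracle_miranda_score(mirna, window):
    """Independent affine-gap local alignment (plain Gotoh recursion)."""
    m = encode(mirna)
    w = encode(window)[::-1]
    sub = _miranda_substitution(m)
    NEG = -1e18
    best = 0.0
    H = [[0.0] * (len(w) + 1) for _ in range(len(m) + 1)]
    E = [[NEG] * (len(w) + 1) for _ in range(len(m) + 1)]
    F = [[NEG] * (len(w) + 1) for _ in range(len(m) + 1)]
    for j in range(1, len(m) + 1):
        for i in range(1, len(w) + 1):
            E[j][i] = max(H[j][i - 1] + MIRANDA_GAP_OPEN,
                          E[j][i - 1] + MIRANDA_GAP_EXTEND)
            F[j][i] = max(H[j - 1][i] + MIRANDA_GAP_OPEN,
                          F[j - 1][i] + MIRANDA_GAP_EXTEND)
            H[j][i] = max(0.0, H[j - 1][i - 1] + sub[j - 1, w[i - 1]],
                          E[j][i], F[j][i])
            best = max(best, H[j][i])
    return best


def test_perfect_complement_closed_form_score():
    mir = "UGAGGCUAAG"  # length 10: positions 2-8 seed-scaled
    window = decode(revcomp(encode(mir)))
    score, energy = miranda_like_score(mir, window)
    assert score == pytest.approx(5 * 3 + 20 * 7)
    assert energy < 0


def test_unalignable_sequences_score_zero_no_hit():
    score, _ = miranda_like_score("AAAAAAAAAA", "AAAAAAAAAA")
    assert score == 0.0
    assert not miranda_hit("AAAAAAAAAA", "AAAAAAAAAA")
    assert miranda_hit("AAAAAAAAAA", "AAAAAAAAUA")


def test_alignment_matches_independent_dp_oracle():
    rng = np.random.default_rng(11)
    for _ in range(30):
        mir = decode(rng.integers(0, 4, int(rng.integers(18, 23))).astype(np.uint8))
        win = decode(rng.integers(0, 4, int(rng.integers(25, 60))).astype(np.uint8))
        score, _ = miranda_like_score(mir, win)
        assert score == pytest.approx(oracle_miranda_score(mir, win))


def test_hit_shortcut_agrees_with_alignment_sign():
    rng = np.random.default_rng(13)
    for _ in range(20):
        mir = decode(rng.integers(0, 4, 20).astype(np.uint8))
        win = decode(rng.integers(0, 4, 40).astype(np.uint8))
        assert miranda_hit(mir, win) == (miranda_like_score(mir, win)[0] > 0)


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

def _one_planted(seed, n_bg=1000, n_shuffles=200):
    rng = np.random.default_rng(seed)
    while True:
        mir = decode(rng.integers(0, 4, 22).astype(np.uint8))
        if (encode(mir)[:16] < 2).sum() <= 10:  # ensure a stable plant
            break
    lnc_arr = random_background(n_bg, rng)
    off = int(rng.integers(0, n_bg - 16))
    lnc_arr[off:off + 16] = revcomp(encode(mir)[:16])
    lnc = decode(lnc_arr)
    cfg = PredictionConfig(n_shuffles=n_shuffles, seed=seed)
    sites = _accepted_sites(encode(mir), encode(lnc), cfg, DEFAULT_NN)
    planted = min(sites, key=lambda s: s[-1])
    anchor, pairs, lo, hi, pb, dg = planted
    site = DuplexSite("m", "t", lo + 1, hi + 1, cfg.min_seed,
                      anchor.mismatches, anchor.gu, pb, delta_g=dg,
                      pairs=pairs)
    return site_pvalue(site, mir, lnc, cfg)


def test_planted_strong_site_median_p_below_0_05():
    ps = [_one_planted(seed) for seed in range(20)]
    assert np.median(ps) <= 0.05


def test_pvalue_add_one_correction_bounds():
    # homopolymer-flanked site: the dinucleotide constraints force every
    # shuffle to keep the complementary run contiguous, so the site is
    # reproduced in all shuffles (p = 1); p can never be 0 or exceed 1
    mir = "G" * 10 + "A" * 12
    lnc = decode(revcomp(encode(mir)[:16])) + "A" * 30
    cfg = PredictionConfig(n_shuffles=50, seed=3)
    sites = _accepted_sites(encode(mir), encode(lnc), cfg, DEFAULT_NN)
    assert sites
    anchor, pairs, lo, hi, pb, dg = min(sites, key=lambda s: s[-1])
    site = DuplexSite("m", "t", lo + 1, hi + 1, 7, anchor.mismatches,
                      anchor.gu, pb, delta_g=dg, pairs=pairs)
    p = site_pvalue(site, mir, lnc, cfg)
    assert 1.0 / 51 <= p <= 1.0
    assert p == 1.0


def test_pvalue_requires_shuffles():
    site = DuplexSite("m", "t", 1, 10, 7, 0, 0, 16, delta_g=-20.0)
    with pytest.raises(ValueError):
        site_pvalue(site, "G" * 20, "C" * 40,
                    PredictionConfig(n_shuffles=0))


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _site_frame(rows):
    cols = ["mirna_id", "transcript_id", "site_start", "site_end",
            "seed_mismatches", "seed_gu", "paired_bases", "delta_g",
            "p_value", "q_value"]
    return pd.DataFrame(rows, columns=cols)


def test_consensus_requires_both_predictors():
    sites = _site_frame([
        ("m1", "t1", 1, 20, 0, 0, 16, -25.0, 0.001, 0.01),
        ("m2", "t1", 1, 20, 0, 0, 16, -25.0, 0.001, 0.01),
    ])
    hits = pd.DataFrame({
        "mirna_id": ["m1", "m2"], "transcript_id": ["t1", "t1"],
        "hit": [True, False]})
    pairs, _ = consensus_targets(sites, hits, CFG)
    assert list(zip(pairs.mirna_id, pairs.transcript_id)) == [("m1", "t1")]


def test_consensus_q_exactly_at_fdr_excluded():
    sites = _site_frame([
        ("m1", "t1", 1, 20, 0, 0, 16, -25.0, 0.04, 0.05),
        ("m2", "t1", 1, 20, 0, 0, 16, -25.0, 0.01, 0.049),
    ])
    hits = pd.DataFrame({
        "mirna_id": ["m1", "m2"], "transcript_id": ["t1", "t1"],
        "hit": [True, True]})
    pairs, _ = consensus_targets(sites, hits, PredictionConfig(fdr=0.05))
    assert list(pairs.mirna_id) == ["m2"]


def test_consensus_disjoint_universes_error():
    sites = _site_frame([("m1", "t1", 1, 20, 0, 0, 16, -25.0, 0.01, 0.01)])
    hits = pd.DataFrame({"mirna_id": ["m9"], "transcript_id": ["t9"],
                         "hit": [True]})
    with pytest.raises(ValueError, match="universe"):
        consensus_targets(sites, hits, CFG)


def test_consensus_reports_best_site_and_summary():
    sites = _site_frame([
        ("m1", "t1", 1, 20, 0, 0, 16, -25.0, 0.002, 0.02),
        ("m1", "t1", 40, 60, 0, 0, 14, -30.0, 0.002, 0.02),
        ("m1", "t1", 80, 99, 1, 1, 12, -13.0, 0.2, 0.4),
    ])
    hits = pd.DataFrame({"mirna_id": ["m1"], "transcript_id": ["t1"],
                         "hit": [True]})
    pairs, _ = consensus_targets(sites, hits, CFG)
    assert len(pairs) == 1
    # ties on q broken by lower ΔG
    assert pairs.best_delta_g.iloc[0] == -30.0
    assert pairs.attrs["summary"] == {"n_pairs": 1, "n_mirnas": 1,
                                      "n_transcripts": 1}


# ---------------------------------------------------------------------------
# threshold monotonicity
# ---------------------------------------------------------------------------

def _site_keys(mirnas, lncs, cfg):
    out = set()
    for mid, ms in mirnas.items():
        for tid, ts in lncs.items():
            for a, _, lo, hi, _, _ in _accepted_sites(
                    encode(ms), encode(ts), cfg, DEFAULT_NN):
                out.add((mid, tid, a.window_start))
    return out


@pytest.mark.parametrize("relax", [
    dict(min_seed=6), dict(max_seed_mismatch=2), dict(max_seed_gu=2),
    dict(min_paired=10), dict(max_energy=-8.0),
])
def test_relaxing_any_threshold_never_removes_sites(relax):
    rng = np.random.default_rng(23)
    mirnas = {f"m{i}": decode(rng.integers(0, 4, 21).astype(np.uint8))
              for i in range(8)}
    lncs = {f"t{i}": decode(rng.integers(0, 4, 400).astype(np.uint8))
            for i in range(6)}
    base = _site_keys(mirnas, lncs, CFG)
    relaxed = _site_keys(mirnas, lncs, PredictionConfig(**relax))
    if "min_seed" in relax:
        # a different seed length changes anchor identity; compare pairs
        assert {(m, t) for m, t, _ in base} <= {(m, t) for m, t, _ in relaxed}
    else:
        assert base <= relaxed
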