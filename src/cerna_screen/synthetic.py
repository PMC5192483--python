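"""Self-contained synthetic inputs with planted ceRNA structure.

The generator emulates the study design that the screen consumes: a
probe-level lncRNA array and a mature-miRNA array over tumor (MM),
replication (PCL) and normal sample groups; a toy genome with a coding
and a lncRNA exon annotation plus a probe map containing both univocal
and decoy (coding-overlapping) probes; and transcript/miRNA sequences
in which a configurable number of sponge pairs is planted.

A planted pair embeds the exact reverse complement of miRNA positions
1-16 in the host transcript — which simultaneously guarantees a perfect
seed match, >= 16 paired bases and a duplex energy far below the -12
kcal/mol threshold — and couples the pair's expression through a shared
latent factor with a negative loading on the lncRNA side, so that the
planted pairs are anti-correlated by construction.

Three independent RNG streams (annotations, sequences, expression) are
spawned from the master seed, so regenerating one artifact does not
shift the others; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ProbeRecord, TranscriptAnnotation
from .seq import decode, random_background, revcomp

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_annotations",
    "generate_sequences",
    "generate_expression",
    "generate_dataset",
    "evaluate_recovery",
    "write_dataset",
]

IG_CYTOBANDS = ("14q32.33", "2p16", "22q11")
SAFE_CYTOBANDS = ("1q21", "13q14", "12q24", "4p14", "15q25.3", "15q25.2",
                  "17q11", "3p21", "6p21", "9q33", "Xq26", "13q31", "5q31")

PLANT_LEN = 16  # miRNA positions 1..16 are embedded as reverse complement
MIN_STRONG_IN_PLANT = 6  # G/C bases required among miRNA positions 1..16


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the screen's benchmark conditions: 200 lncRNAs x
    100 miRNAs with 20 planted sponge pairs of loading 0.9, a 44-sample
    tumor cohort with 4 normals for the discovery screen plus a
    12-sample PCL replication cohort, log2-scale noise SD 0.4 and a
    2-unit log2 shift for differential features.
    """

    n_lncrna: int = 200
    n_mirna: int = 100
    n_probes_per_lncrna: int = 3
    n_decoy_coding_overlaps: int = 10
    n_ig_region_lncrna: int = 10
    n_planted_pairs: int = 20
    group_sizes: dict = field(
        default_factory=lambda: {"MM": 44, "PCL": 12, "normal": 4})
    sponge_strength: float = 0.9
    de_effect: float = 2.0
    noise_sd: float = 0.4
    de_fraction: float = 0.1
    transcript_length: tuple = (400, 800)
    seed: int = 0

    def __post_init__(self):
        if self.n_planted_pairs > self.n_lncrna * self.n_mirna:
            raise ValueError("n_planted_pairs exceeds n_lncrna * n_mirna")
        for name in ("n_lncrna", "n_mirna", "n_probes_per_lncrna",
                     "n_decoy_coding_overlaps", "n_ig_region_lncrna",
                     "n_planted_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.sponge_strength <= 1:
            # 0 disables the coupling entirely (null calibration runs)
            raise ValueError("sponge_strength must be in [0, 1]")
        if self.de_effect < 0 or self.noise_sd <= 0:
            raise ValueError("de_effect >= 0 and noise_sd > 0 required")
        if len(self.group_sizes) < 2:
            raise ValueError("group_sizes needs at least two groups")
        if not 1 <= self.n_probes_per_lncrna <= 5:
            raise ValueError("n_probes_per_lncrna must be in 1..5")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, stream])


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``planted_pairs`` holds (lncRNA gene, miRNA, site_start, site_end)
    with 1-based inclusive transcript coordinates (coordinates are None
    until sequences have been generated).
    """

    planted_pairs: list = field(default_factory=list)
    de_features: list = field(default_factory=list)
    ambiguous_probes: list = field(default_factory=list)
    ig_lncrnas: list = field(default_factory=list)

    @property
    def planted_gene_pairs(self) -> set:
        return {(l, m) for l, m, *_ in self.planted_pairs}


@dataclass
class SyntheticDataset:
    """All artifacts of one generated run."""

    config: SyntheticConfig
    truth: SyntheticTruth
    probes: list
    coding: list
    lncrna: list
    cytobands: dict  # feature id (lncRNA gene or miRNA) -> band
    transcript_seqs: dict  # transcript id -> str
    mirna_seqs: dict  # miRNA id -> str
    probe_expr: pd.DataFrame | None = None
    mirna_expr: pd.DataFrame | None = None
    groups: pd.Series | None = None


def _lnc_gene(i: int) -> str:
    return f"LNC{i + 1:04d}"


def _mirna_id(i: int) -> str:
    return f"mir-{i + 1:04d}-5p"


def generate_annotations(cfg: SyntheticConfig
                         ) -> tuple[list, list, list, SyntheticTruth, dict]:
    """Toy genome, annotations and probe map.

    Returns (probes, coding transcripts, lncRNA transcripts, partial
    truth, cytoband map).  Exactly ``n_decoy_coding_overlaps`` extra
    probes overlap a coding transcript; every other probe lies inside a
    single lncRNA exon.  The first ``n_ig_region_lncrna`` non-planted
    lncRNA genes carry immunoglobulin-locus cytobands.
    """
    rng = cfg.rng(1)
    truth = SyntheticTruth()
    probes: list[ProbeRecord] = []
    lncrna: list[TranscriptAnnotation] = []
    coding: list[TranscriptAnnotation] = []
    cytobands: dict[str, str] = {}

    # choose planted identities first so Ig bands can avoid them
    n_plant = cfg.n_planted_pairs
    lnc_order = rng.permutation(cfg.n_lncrna)
    planted_lnc = [int(i) for i in lnc_order[:n_plant]]
    remaining = [int(i) for i in lnc_order[n_plant:]]
    ig_idx = set(remaining[:cfg.n_ig_region_lncrna])
    if len(remaining) < cfg.n_ig_region_lncrna:
        raise ValueError("not enough non-planted lncRNAs for Ig regions")
    mirna_pool = rng.permutation(cfg.n_mirna)
    planted_mirna = [int(mirna_pool[i % cfg.n_mirna]) for i in range(n_plant)]
    for li, mi in zip(planted_lnc, planted_mirna):
        truth.planted_pairs.append([_lnc_gene(li), _mirna_id(mi), None, None])

    lengths = rng.integers(cfg.transcript_length[0],
                           cfg.transcript_length[1] + 1, size=cfg.n_lncrna)
    n_chrom = 4
    cursors = {f"chr{c + 1}": 1000 for c in range(n_chrom)}
    for i in range(cfg.n_lncrna):
        gene = _lnc_gene(i)
        chrom = f"chr{i % n_chrom + 1}"
        tlen = int(lengths[i])
        start = cursors[chrom]
        # two exons separated by a small intron
        e1 = tlen // 2
        intron = int(rng.integers(50, 200))
        exons = [(start, start + e1),
                 (start + e1 + intron, start + tlen + intron)]
        cursors[chrom] = start + tlen + intron + int(rng.integers(500, 1500))
        if i in ig_idx:
            band = IG_CYTOBANDS[len(truth.ig_lncrnas) % len(IG_CYTOBANDS)]
            truth.ig_lncrnas.append(gene)
        else:
            band = SAFE_CYTOBANDS[int(rng.integers(len(SAFE_CYTOBANDS)))]
        cytobands[gene] = band
        lncrna.append(TranscriptAnnotation(
            transcript_id=f"{gene}:1", gene_id=gene, source="lncrna",
            chrom=chrom, strand="+", exons=exons, cytoband=band))
        for p in range(cfg.n_probes_per_lncrna):
            exon = exons[p % 2]
            width = 25
            lo, hi = exon[0], exon[1] - width
            pos = int(rng.integers(lo, max(lo + 1, hi)))
            probes.append(ProbeRecord(
                probe_id=f"probe_{gene}_{p + 1}", chrom=chrom,
                start=pos, end=pos + width, strand="+"))

    # decoy probes: covered by a coding exon placed in a host gene's
    # intron, so regular (exonic) probes never touch the coding set
    for k in range(cfg.n_decoy_coding_overlaps):
        host = lncrna[k % len(lncrna)] if lncrna else None
        if host is None:
            break
        i0, i1 = host.exons[0][1], host.exons[1][0]
        pos = i0 + 2
        probe_id = f"probe_decoy_{k + 1}"
        probes.append(ProbeRecord(
            probe_id=probe_id, chrom=host.chrom,
            start=pos + 8, end=pos + 33, strand="+"))
        coding.append(TranscriptAnnotation(
            transcript_id=f"ENST{k + 1:06d}", gene_id=f"ENSG{k + 1:06d}",
            source="coding", chrom=host.chrom, strand="+",
            exons=[(pos, min(pos + 43, i1))],
            cytoband=cytobands[host.gene_id]))
        truth.ambiguous_probes.append(probe_id)
    if not coding:
        # keep at least one coding transcript so the set is non-trivial,
        # far from every probe
        coding.append(TranscriptAnnotation(
            transcript_id="ENST000000", gene_id="ENSG000000",
            source="coding", chrom="chr1", strand="+", exons=[(10, 500)],
            cytoband="1p36"))

    for j in range(cfg.n_mirna):
        cytobands[_mirna_id(j)] = SAFE_CYTOBANDS[
            int(rng.integers(len(SAFE_CYTOBANDS)))]
    return probes, coding, lncrna, truth, cytobands


def _random_mirna(rng: np.random.Generator) -> np.ndarray:
    """Random mature miRNA, 20-23 nt, with at least 6 G/C among the
    first 16 positions so a fully complementary 16-mer site is always
    comfortably below the duplex-energy threshold."""
    while True:
        length = int(rng.integers(20, 24))
        m = rng.integers(0, 4, size=length).astype(np.uint8)
        strong = int(np.isin(m[:PLANT_LEN], (1, 2)).sum())
        if strong >= MIN_STRONG_IN_PLANT:
            return m


def generate_sequences(cfg: SyntheticConfig, annotations, truth: SyntheticTruth
                       ) -> tuple[dict, dict]:
    """Transcript and miRNA sequences with planted binding sites.

    Background transcripts are random sequence of the fixed toy
    composition; each planted pair's transcript carries the reverse
    complement of its miRNA's positions 1-16 at a random offset,
    recorded 1-based inclusive in ``truth.planted_pairs``.
    """
    rng = cfg.rng(2)
    lnc_annots = annotations
    mirna_seqs = {_mirna_id(j): _random_mirna(rng)
                  for j in range(cfg.n_mirna)}
    planted_by_gene = {l: m for l, m, *_ in truth.planted_pairs}
    transcript_seqs: dict[str, np.ndarray] = {}
    for tr in lnc_annots:
        tlen = sum(e - s for s, e in tr.exons)
        seq = random_background(tlen, rng)
        gene = tr.gene_id
        if gene in planted_by_gene:
            m = mirna_seqs[planted_by_gene[gene]]
            if tlen < PLANT_LEN:
                raise ValueError(
                    f"transcript {tr.transcript_id} shorter than the "
                    f"{PLANT_LEN}-nt site to embed")
            site = revcomp(m[:PLANT_LEN])
            off = int(rng.integers(0, tlen - PLANT_LEN + 1))
            seq[off:off + PLANT_LEN] = site
            for rec in truth.planted_pairs:
                if rec[0] == gene:
                    rec[2], rec[3] = off + 1, off + PLANT_LEN
        transcript_seqs[tr.transcript_id] = seq
    return ({tid: decode(s) for tid, s in transcript_seqs.items()},
            {mid: decode(s) for mid, s in mirna_seqs.items()})


def generate_expression(cfg: SyntheticConfig, truth: SyntheticTruth,
                        probes, lncrna
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Probe-level and miRNA expression with the planted structure.

    Each planted miRNA follows a standard-normal latent factor z (plus
    noise); every probe of its partner lncRNA gets
    baseline - sponge_strength * z + noise, producing the expected
    negative correlation.  Differential features (a ``de_fraction``
    subset of non-planted features) are shifted up by ``de_effect`` in
    the tumor groups relative to normal.  Everything else is
    independent N(baseline, noise_sd).  Values are log2 scale.
    """
    rng = cfg.rng(3)
    samples, groups = [], []
    for g, n in cfg.group_sizes.items():
        for i in range(n):
            samples.append(f"{g}_{i + 1:03d}")
            groups.append(g)
    groups = pd.Series(groups, index=samples, name="group")
    n_samp = len(samples)
    tumor = (groups != "normal").to_numpy()

    planted_genes = {l: m for l, m, *_ in truth.planted_pairs}
    planted_mirnas = set(planted_genes.values())
    lnc_genes = [tr.gene_id for tr in lncrna]
    mirna_ids = [_mirna_id(j) for j in range(cfg.n_mirna)]

    n_de_l = int(round(cfg.de_fraction * len(lnc_genes)))
    n_de_m = int(round(cfg.de_fraction * len(mirna_ids)))
    de_l = [g for g in lnc_genes if g not in planted_genes][:n_de_l]
    de_m = [m for m in mirna_ids if m not in planted_mirnas][:n_de_m]
    truth.de_features = de_l + de_m

    # latent sponge factors, standardized across samples so each planted
    # pair's effect size is exact by construction (not just in expectation)
    z = {}
    for m in sorted(planted_mirnas):
        raw = rng.normal(size=n_samp)
        z[m] = (raw - raw.mean()) / raw.std()

    def baseline() -> float:
        return float(rng.uniform(4.0, 10.0))

    mirna_rows = {}
    for mid in mirna_ids:
        base = baseline()
        row = base + rng.normal(scale=cfg.noise_sd, size=n_samp)
        if mid in z:
            row = row + z[mid]
        if mid in de_m:
            row = row + cfg.de_effect * tumor
        mirna_rows[mid] = row
    mirna_expr = pd.DataFrame.from_dict(mirna_rows, orient="index",
                                        columns=samples)
    mirna_expr.index.name = "mirna_id"

    gene_probes: dict[str, list[str]] = {}
    for pr in probes:
        if pr.probe_id.startswith("probe_decoy_"):
            continue
        gene = pr.probe_id.split("_")[1]
        gene_probes.setdefault(gene, []).append(pr.probe_id)
    probe_rows = {}
    for gene in lnc_genes:
        base = baseline()
        signal = np.zeros(n_samp)
        if gene in planted_genes:
            signal = signal - cfg.sponge_strength * z[planted_genes[gene]]
        if gene in de_l:
            signal = signal + cfg.de_effect * tumor
        for pid in gene_probes.get(gene, []):
            probe_rows[pid] = (base + signal
                               + rng.normal(scale=cfg.noise_sd, size=n_samp))
    for pr in probes:
        if pr.probe_id.startswith("probe_decoy_"):
            probe_rows[pr.probe_id] = (baseline()
                                       + rng.normal(scale=cfg.noise_sd,
                                                    size=n_samp))
    probe_expr = pd.DataFrame.from_dict(probe_rows, orient="index",
                                        columns=samples)
    probe_expr = probe_expr.loc[[p.probe_id for p in probes]]
    probe_expr.index.name = "probe_id"
    return probe_expr, mirna_expr, groups


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """All artifacts for one config (annotations, sequences, expression)."""
    probes, coding, lncrna, truth, cytobands = generate_annotations(cfg)
    tseqs, mseqs = generate_sequences(cfg, lncrna, truth)
    probe_expr, mirna_expr, groups = generate_expression(
        cfg, truth, probes, lncrna)
    return SyntheticDataset(cfg, truth, probes, coding, lncrna, cytobands,
                            tseqs, mseqs, probe_expr, mirna_expr, groups)


def evaluate_recovery(candidates, truth: SyntheticTruth
                      ) -> tuple[float, float]:
    """Recall and precision of reported pairs against the planted ones.

    ``candidates`` is an iterable of (lncRNA id, miRNA id) or a frame
    with ``transcript_id``/``mirna_id`` columns; transcript ids are
    mapped to genes.  Pair identity is (lncRNA gene, miRNA).
    """
    planted = truth.planted_gene_pairs
    if not planted:
        raise ValueError("empty truth: recall is undefined")
    if isinstance(candidates, pd.DataFrame):
        pairs = {(t.rsplit(":", 1)[0], m)
                 for m, t in zip(candidates["mirna_id"],
                                 candidates["transcript_id"])}
    else:
        pairs = {(l.rsplit(":", 1)[0], m) for l, m in candidates}
    tp = len(pairs & planted)
    recall = tp / len(planted)
    precision = tp / len(pairs) if pairs else 0.0
    return recall, precision


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every artifact as plain text; returns the path map.

    FASTA for sequences, BED (0-based half-open) for probes, GFF3 for
    both annotation sets, TSV for expression / groups / cytobands /
    truth.
    """
    from pathlib import Path

    from .annotation import write_annotation_gff3

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in {
        "lnc_fasta": "lncrna_transcripts.fa", "mirna_fasta": "mirnas.fa",
        "probes_bed": "probes.bed", "coding_gff3": "coding.gff3",
        "lncrna_gff3": "lncrna.gff3", "probe_expr": "probe_expression.tsv",
        "mirna_expr": "mirna_expression.tsv", "groups": "groups.tsv",
        "cytobands": "cytobands.tsv", "truth": "truth.tsv",
    }.items()}
    with open(paths["lnc_fasta"], "w") as fh:
        for tid, seq in ds.transcript_seqs.items():
            fh.write(f">{tid}\n{seq}\n")
    with open(paths["mirna_fasta"], "w") as fh:
        for mid, seq in ds.mirna_seqs.items():
            fh.write(f">{mid}\n{seq}\n")
    with open(paths["probes_bed"], "w") as fh:
        for p in ds.probes:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.probe_id}\t0\t"
                     f"{p.strand}\n")
    write_annotation_gff3(ds.coding, paths["coding_gff3"])
    write_annotation_gff3(ds.lncrna, paths["lncrna_gff3"])
    ds.probe_expr.to_csv(paths["probe_expr"], sep="\t")
    ds.mirna_expr.to_csv(paths["mirna_expr"], sep="\t")
    ds.groups.rename_axis("sample").to_csv(paths["groups"], sep="\t")
    pd.Series(ds.cytobands, name="cytoband").rename_axis("feature_id") \
        .to_csv(paths["cytobands"], sep="\t")
    rows = [{"lncrna_gene": l, "mirna_id": m, "site_start": s, "site_end": e,
             "kind": "planted_pair"} for l, m, s, e in ds.truth.planted_pairs]
    rows += [{"lncrna_gene": f, "mirna_id": "", "site_start": "",
              "site_end": "", "kind": "de_feature"}
             for f in ds.truth.de_features]
    rows += [{"lncrna_gene": g, "mirna_id": "", "site_start": "",
              "site_end": "", "kind": "ig_lncrna"}
             for g in ds.truth.ig_lncrnas]
    rows += [{"lncrna_gene": p, "mirna_id": "", "site_start": "",
              "site_end": "", "kind": "decoy_probe"}
             for p in ds.truth.ambiguous_probes]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
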