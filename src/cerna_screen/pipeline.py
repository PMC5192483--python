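"""End-to-end orchestration: annotate -> select -> predict -> correlate
-> replicate, with a funnel report.

The in-memory entry point is :func:`run_screen`, which takes the loaded
artifacts (probe map, annotations, expression, sequences, group labels)
and returns every stage table plus a report of the feature counts
flowing through the funnel.  :func:`run_pipeline` is the file-based
wrapper used by the command-line interface: it loads the inputs named
in a :class:`PipelineConfig`, runs the screen and writes each stage's
output atomically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann
from .screen import ScreenConfig, pair_correlation, replicate_pairs, screen_pairs
from .selection import SelectionConfig, select_relevant
from .synthetic import SyntheticConfig, generate_dataset, write_dataset
from .targets import PredictionConfig, predict_targets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_screen", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and stage configurations for a full run.

    A master seed fans out to the stages at fixed offsets (synthetic +0,
    selection +1, prediction +2) so each stage is independently
    reproducible.
    """

    probes_bed: str | None = None
    coding_gff3: str | None = None
    lncrna_gff3: str | None = None
    probe_expr: str | None = None
    mirna_expr: str | None = None
    groups: str | None = None
    cytobands: str | None = None
    lnc_fasta: str | None = None
    mirna_fasta: str | None = None
    outdir: str = "cerna_screen_out"
    master_seed: int = 0
    tumor_group: str = "MM"
    normal_group: str = "normal"
    replication_group: str | None = "PCL"
    include_normal_in_screen: bool = False
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    prediction: PredictionConfig = field(default_factory=PredictionConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    synthetic: SyntheticConfig | None = None

    def __post_init__(self):
        base = self.master_seed & 0x7FFFFFFF
        self.selection = dataclasses.replace(self.selection,
                                             seed=(base + 1) & 0x7FFFFFFF)
        self.prediction = dataclasses.replace(self.prediction,
                                              seed=(base + 2) & 0x7FFFFFFF)
        if self.synthetic is not None:
            self.synthetic = dataclasses.replace(self.synthetic, seed=base)


@dataclass
class RunReport:
    """Funnel counts, parameter echo and per-stage wall-clock."""

    counts: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def summary(self) -> str:
        lines = ["funnel:"]
        for k, v in self.counts.items():
            lines.append(f"  {k}: {v}")
        lines.append("timings (s):")
        for k, v in self.timings.items():
            lines.append(f"  {k}: {v:.2f}")
        return "\n".join(lines)


def run_screen(probes, coding, lncrna, probe_expr, mirna_expr, groups,
               cytobands, transcript_seqs, mirna_seqs,
               sel_cfg: SelectionConfig = SelectionConfig(),
               pred_cfg: PredictionConfig = PredictionConfig(),
               scr_cfg: ScreenConfig = ScreenConfig(),
               tumor_group: str = "MM", normal_group: str = "normal",
               replication_group: str | None = "PCL",
               include_normal_in_screen: bool = False) -> dict:
    """Run every stage on in-memory artifacts.

    Returns a dict with the stage outputs (``assignment``, ``lnc_expr``,
    ``selected_lncrnas``, ``selected_mirnas``, ``sites``, ``pairs``,
    ``correlations``, ``candidates``, ``replication``) and a ``report``.
    """
    report = RunReport(
        params={"selection": dataclasses.asdict(sel_cfg),
                "prediction": dataclasses.asdict(pred_cfg),
                "screen": dataclasses.asdict(scr_cfg)},
        seeds={"selection": sel_cfg.seed, "prediction": pred_cfg.seed},
    )
    results: dict = {"report": report}
    t0 = time.perf_counter()

    # --- annotate ---------------------------------------------------------
    assignment = ann.assign_probes(probes, coding, lncrna)
    lnc_expr = ann.summarize_lncrna(probe_expr, assignment)
    results["assignment"] = assignment
    results["lnc_expr"] = lnc_expr
    report.counts["probes_in"] = len(assignment)
    report.counts["probes_assigned"] = int(
        (assignment["status"] == "assigned").sum())
    report.counts["lncrnas_detected"] = len(lnc_expr)
    report.counts["mirnas_detected"] = len(mirna_expr)
    report.timings["annotate"] = time.perf_counter() - t0

    # --- select -----------------------------------------------------------
    t0 = time.perf_counter()
    comp = groups[groups.isin([tumor_group, normal_group])]
    for g in (tumor_group, normal_group):
        if (comp == g).sum() < 2:
            raise ValueError(
                f"selection needs >= 2 {g!r} samples for the supervised "
                "comparison")
    lnc_sel, mir_sel, funnel = select_relevant(
        lnc_expr[comp.index], mirna_expr[comp.index], comp.to_numpy(),
        cytobands, sel_cfg)
    results["selected_lncrnas"] = lnc_sel
    results["selected_mirnas"] = mir_sel
    report.counts["lncrnas_selected"] = len(lnc_sel)
    report.counts["mirnas_selected"] = len(mir_sel)
    report.counts["selection_funnel"] = funnel
    report.timings["select"] = time.perf_counter() - t0

    # --- predict ----------------------------------------------------------
    t0 = time.perf_counter()
    sel_genes = set(lnc_sel)
    tseqs = {tid: s for tid, s in transcript_seqs.items()
             if tid.rsplit(":", 1)[0] in sel_genes}
    mseqs = {mid: mirna_seqs[mid] for mid in mir_sel if mid in mirna_seqs}
    sites, pairs = predict_targets(mseqs, tseqs, pred_cfg)
    results["sites"] = sites
    results["pairs"] = pairs
    report.counts["sites_tested"] = len(sites)
    report.counts["consensus_pairs"] = len(pairs)
    report.counts["consensus_summary"] = pairs.attrs.get("summary", {})
    report.timings["predict"] = time.perf_counter() - t0

    # --- correlate + screen ----------------------------------------------
    t0 = time.perf_counter()
    screen_groups = [tumor_group] + (
        [normal_group] if include_normal_in_screen else [])
    cohort = groups[groups.isin(screen_groups)].index
    if len(pairs):
        correlations = pair_correlation(
            lnc_expr[cohort], mirna_expr[cohort], pairs, scr_cfg)
        candidates = screen_pairs(correlations, scr_cfg)
        candidates = candidates.merge(
            pairs, on=["mirna_id", "transcript_id"], how="left")
        for col, feat in (("lncrna_cytoband", "lncrna_gene"),
                          ("mirna_cytoband", "mirna_id")):
            candidates[col] = candidates[feat].map(cytobands).fillna("")
    else:
        correlations = pd.DataFrame(
            columns=["mirna_id", "transcript_id", "lncrna_gene",
                     "corr_coeff", "p_value", "status"])
        candidates = correlations.assign(q_value=pd.Series(dtype=float))
    results["correlations"] = correlations
    results["candidates"] = candidates
    report.counts["pairs_correlated"] = len(correlations)
    report.counts["candidates"] = len(candidates)
    report.timings["correlate"] = time.perf_counter() - t0

    # --- replicate --------------------------------------------------------
    if replication_group is not None and len(candidates):
        t0 = time.perf_counter()
        rep_cohort = groups[groups == replication_group].index
        if len(rep_cohort) >= 3:
            replication = replicate_pairs(
                candidates, lnc_expr[rep_cohort], mirna_expr[rep_cohort],
                scr_cfg)
            results["replication"] = replication
            report.counts["replicated"] = int(replication["replicated"].sum())
            report.timings["replicate"] = time.perf_counter() - t0
    return results


def _stage(name):
    """Wrap stage execution so failures name the stage and input."""
    class _ctx:
        def __init__(self):
            self.name = name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return _ctx()


def _read_fasta(path) -> dict:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _atomic_write(df: pd.DataFrame, path: Path, **kw) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", **kw)
    tmp.replace(path)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """File-based end-to-end run; writes stage outputs under ``outdir``."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic is not None:
        with _stage("simulate"):
            ds = generate_dataset(cfg.synthetic)
            paths = write_dataset(ds, out / "synthetic")
            for attr, key in [
                    ("probes_bed", "probes_bed"), ("coding_gff3", "coding_gff3"),
                    ("lncrna_gff3", "lncrna_gff3"), ("probe_expr", "probe_expr"),
                    ("mirna_expr", "mirna_expr"), ("groups", "groups"),
                    ("cytobands", "cytobands"), ("lnc_fasta", "lnc_fasta"),
                    ("mirna_fasta", "mirna_fasta")]:
                setattr(cfg, attr, str(paths[key]))

    with _stage("load"):
        required = ["probes_bed", "coding_gff3", "lncrna_gff3", "probe_expr",
                    "mirna_expr", "groups", "cytobands", "lnc_fasta",
                    "mirna_fasta"]
        for name in required:
            p = getattr(cfg, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input {name}: {p}")
        probes = ann.read_probes_bed(cfg.probes_bed)
        coding = ann.read_annotation_gff3(cfg.coding_gff3, "coding")
        lncrna = ann.read_annotation_gff3(cfg.lncrna_gff3, "lncrna")
        probe_expr = ann.load_expression_tsv(cfg.probe_expr)
        mirna_expr = ann.load_expression_tsv(cfg.mirna_expr)
        groups = pd.read_csv(cfg.groups, sep="\t", index_col=0).iloc[:, 0]
        cytobands = pd.read_csv(cfg.cytobands, sep="\t", index_col=0) \
            .iloc[:, 0].to_dict()
        tseqs = _read_fasta(cfg.lnc_fasta)
        mseqs = _read_fasta(cfg.mirna_fasta)

    results = run_screen(
        probes, coding, lncrna, probe_expr, mirna_expr, groups, cytobands,
        tseqs, mseqs, cfg.selection, cfg.prediction, cfg.screen,
        cfg.tumor_group, cfg.normal_group, cfg.replication_group,
        cfg.include_normal_in_screen)

    with _stage("write"):
        _atomic_write(results["assignment"], out / "probe_assignment.tsv")
        _atomic_write(results["lnc_expr"], out / "lncrna_expression.tsv")
        sel = pd.DataFrame(
            [{"feature_id": f, "kind": "lncrna"}
             for f in results["selected_lncrnas"]]
            + [{"feature_id": f, "kind": "mirna"}
               for f in results["selected_mirnas"]])
        _atomic_write(sel, out / "selected_features.tsv", index=False)
        _atomic_write(results["sites"], out / "sites.tsv", index=False)
        _atomic_write(results["pairs"], out / "pairs.tsv", index=False)
        _atomic_write(results["candidates"], out / "candidates.tsv",
                      index=False)
        if "replication" in results:
            _atomic_write(results["replication"], out / "replication.tsv",
                          index=False)
        report: RunReport = results["report"]
        (out / "run_report.json").write_text(report.to_json())
        (out / "run_report.txt").write_text(report.summary() + "\n")
    return results["report"]
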