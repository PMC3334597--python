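"""Workflow glue: staged runs over a working directory.

Each stage reads the files earlier stages wrote and emits TSV outputs, so
a run is resumable and auditable.  Stage order and dependencies:

    simulate -> scan ---+
             -> signals +-> train -> profiles -> sensitivity

A JSON run manifest records the package version, seeds, thresholds and
the resolved default of every parameter the original description leaves
open (motif score threshold, pseudocount, probe-overlap rule), so every
run is reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_world, write_matrix, write_world
from .model import assemble_features, call_targets, cv_train_evaluate
from .motif import DEFAULT_PSEUDOCOUNT, DEFAULT_SCORE_FRACTION, PSSM, Background, cumulative_match_score, scan_sequence
from .profiles import cluster_sensitivity, diff_mod_profiles, target_mod_profiles
from .signals import GeneSignalMatrix, build_gene_signal_matrix
from .synthetic import SyntheticConfig, SyntheticWorld, generate_world

log = logging.getLogger("chromotif")

STAGE_ORDER = ["simulate", "scan", "signals", "train", "profiles", "sensitivity"]
STAGE_DEPS = {
    "simulate": [],
    "scan": ["simulate"],
    "signals": ["simulate"],
    "train": ["scan", "signals"],
    "profiles": ["train", "signals"],
    "sensitivity": ["profiles"],
}


@dataclass
class RunConfig:
    """Everything a staged run needs; every stochastic stage is seeded."""

    workdir: str
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    condition: str = "A"
    cutoff: float = 0.01
    widths: tuple[int, ...] = (500, 1000)
    feature_groups: tuple[str, ...] = ("hm", "pssm")
    regions: tuple[str, ...] = ("up1000", "down1000")
    repeats: int = 10
    folds: int = 2
    min_positives: int = 10
    score_fraction: float = DEFAULT_SCORE_FRACTION
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    correlation_threshold: float = 0.5
    alpha: float = 0.05
    cooperativity_margin: float = 0.02
    seed: int = 0
    max_tfs: int | None = None  # cap on TFs trained, smallest index first


def promoter_motif_scores(
    world: SyntheticWorld,
    pssm: PSSM,
    bg: Background | None = None,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Cumulative motif matching score of every gene's promoter."""
    if bg is None:
        bg = world.background
    threshold = score_fraction * pssm.max_score(bg, pseudocount)
    scores = {}
    for ann in world.annotations:
        seq = world.promoter_seq(ann.gene_id)
        hits = scan_sequence(pssm, seq, bg, score_threshold=threshold, pseudocount=pseudocount, seq_id=ann.gene_id)
        scores[ann.gene_id] = cumulative_match_score(hits)
    return pd.Series(scores, name=pssm.id)


def genome_motif_hits(
    genome: dict[str, str],
    pssm: PSSM,
    bg: Background,
    score_fraction: float = DEFAULT_SCORE_FRACTION,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genome-wide motif matches as (contig, start, end, strand, score)."""
    threshold = score_fraction * pssm.max_score(bg, pseudocount)
    rows = []
    for contig, seq in genome.items():
        for h in scan_sequence(pssm, seq, bg, score_threshold=threshold, pseudocount=pseudocount, seq_id=contig):
            rows.append((contig, h.offset, h.offset + pssm.n, h.strand, h.score))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "score"])


def assign_hits_to_promoters(world: SyntheticWorld, hits: pd.DataFrame) -> pd.DataFrame:
    """Keep hits lying inside a gene's promoter; adds a gene_id column."""
    rows = []
    for ann in world.annotations:
        sub = hits[(hits["contig"] == ann.contig) & (hits["start"] >= ann.ir_start) & (hits["end"] <= ann.ir_end)]
        for h in sub.itertuples():
            rows.append((h.contig, h.start, h.end, ann.gene_id))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id"])


def bin_motif_scores(bins: pd.DataFrame, hits: pd.DataFrame) -> pd.Series:
    """Cumulative motif score per genome bin (hit assigned by its start)."""
    scores = np.zeros(len(bins))
    width = int((bins["end"] - bins["start"]).max())
    lookup = {(r.contig, r.start): i for i, r in enumerate(bins.itertuples())}
    for h in hits.itertuples():
        key = (h.contig, (h.start // width) * width)
        i = lookup.get(key)
        if i is not None:
            scores[i] += h.score
    return pd.Series(scores, index=bins.index, name="pssm_score")


def evaluate_tf(
    world: SyntheticWorld,
    tf: str,
    signals: GeneSignalMatrix,
    groups: tuple[str, ...] = ("hm", "pssm"),
    regions: tuple[str, ...] = ("up1000", "down1000"),
    condition: str = "A",
    cutoff: float = 0.01,
    repeats: int = 10,
    seed: int = 0,
    motif_scores: pd.Series | None = None,
    min_positives: int = 10,
):
    """Convenience: labels from ChIP P-values + features -> CV evaluation."""
    labels = call_targets(world.pvalues[condition], cutoff)[tf]
    if "pssm" in groups and motif_scores is None:
        pssm = world.pssms[world.tf_names.index(tf)]
        motif_scores = promoter_motif_scores(world, pssm)
    table = assemble_features(
        signals, labels, motif_scores=motif_scores, groups=groups, regions=regions,
        expression=world.expression if "expression" in groups else None,
    )
    return cv_train_evaluate(table, repeats=repeats, seed=seed, min_positives=min_positives)


def _require(workdir: Path, stage: str, done: set[str]) -> None:
    missing = [d for d in STAGE_DEPS[stage] if d not in done and not (workdir / f".stage_{d}").exists()]
    if missing:
        raise RuntimeError(f"stage {stage!r} requires earlier stage(s) {missing}; run them first")


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    done: set[str] = set()
    world: SyntheticWorld | None = None
    cond = config.condition

    def get_world() -> SyntheticWorld:
        nonlocal world
        if world is None:
            world = read_world(workdir / "world")
        return world

    for stage in stages:
        _require(workdir, stage, done)
        log.info("stage %s (seed=%d)", stage, config.seed)
        if stage == "simulate":
            world = generate_world(config.synthetic)
            write_world(world, workdir / "world")
        elif stage == "scan":
            w = get_world()
            log.info("motif scan: threshold=%.0f%% of max score, pseudocount=%g",
                     100 * config.score_fraction, config.pseudocount)
            cols = {p.id: promoter_motif_scores(w, p, score_fraction=config.score_fraction,
                                                pseudocount=config.pseudocount) for p in w.pssms}
            scores = pd.DataFrame(cols) if cols else pd.DataFrame(index=pd.Index(w.gene_ids, name="gene_id"))
            write_matrix(scores, workdir / "motif_scores.tsv")
        elif stage == "signals":
            w = get_world()
            log.info("probe aggregation: any-overlap (>=1 bp), unweighted mean")
            for c in w.config.conditions:
                mat = build_gene_signal_matrix(w.annotations, w.tracks[c], widths=config.widths,
                                               contig_lengths=w.contig_lengths)
                mat.to_tsv(workdir / f"signals_{c}.tsv")
        elif stage == "train":
            w = get_world()
            signals = GeneSignalMatrix.from_tsv(workdir / f"signals_{cond}.tsv")
            motif_scores = pd.read_csv(workdir / "motif_scores.tsv", sep="\t", index_col=0)
            labels = call_targets(w.pvalues[cond], config.cutoff)
            write_matrix(labels, workdir / f"targets_{cond}.tsv")
            rows = []
            tfs = w.tf_names[: config.max_tfs] if config.max_tfs else w.tf_names
            for tf in tfs:
                try:
                    res = cv_train_evaluate(
                        assemble_features(signals, labels[tf],
                                          motif_scores=motif_scores[tf] if tf in motif_scores else None,
                                          groups=config.feature_groups, regions=config.regions),
                        repeats=config.repeats, folds=config.folds, seed=config.seed,
                        min_positives=config.min_positives,
                    )
                except ValueError as exc:
                    log.warning("TF %s skipped: %s", tf, exc)
                    continue
                rows.append((tf, res.auc, res.ppv_at, res.top_k))
            if not rows:
                raise RuntimeError("no TF could be trained (too few positives everywhere)")
            pd.DataFrame(rows, columns=["tf", "auc", "ppv", "top_k"]).to_csv(
                workdir / f"aucs_{cond}.tsv", sep="\t", index=False, float_format="%.6g")
        elif stage == "profiles":
            signals = GeneSignalMatrix.from_tsv(workdir / f"signals_{cond}.tsv")
            labels = pd.read_csv(workdir / f"targets_{cond}.tsv", sep="\t", index_col=0)
            raw, norm = target_mod_profiles(labels, signals)
            write_matrix(raw, workdir / "profiles_raw.tsv", index_name="tf")
            write_matrix(norm, workdir / "profiles_norm.tsv", index_name="tf")
            diff = diff_mod_profiles(labels, signals)
            write_matrix(diff, workdir / "profiles_diff.tsv", index_name="tf")
        elif stage == "sensitivity":
            norm = pd.read_csv(workdir / "profiles_norm.tsv", sep="\t", index_col=0)
            res = cluster_sensitivity(norm, seed=config.seed)
            res.labels.rename("class").rename_axis("tf").to_frame().to_csv(
                workdir / "sensitivity.tsv", sep="\t")
        (workdir / f".stage_{stage}").touch()
        done.add(stage)

    manifest = {
        "version": __version__,
        "stages": stages,
        "seed": config.seed,
        "condition": cond,
        "parameters": {k: v for k, v in asdict(config).items() if k not in ("workdir", "synthetic")},
        "synthetic": asdict(config.synthetic),
        "defaults_resolved": {
            "motif_score_threshold": f"{config.score_fraction:.0%} of max achievable log-odds",
            "pseudocount": config.pseudocount,
            "probe_overlap_rule": "any-overlap (>=1 bp), unweighted mean",
            "target_call_rule": "P < cutoff (strict)",
        },
    }
    with open(workdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
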