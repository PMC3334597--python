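"""Readers and writers for the interchange formats.

Formats: FASTA genome (via Bio.SeqIO), gene annotation TSV (0-based
half-open; a ``# coords: 1-based`` header declares 1-based input, which
is converted on read), MEME-style motif files (letter-probability
matrix blocks, written with enough digits to round-trip at 1e-9),
bedGraph probe tracks (contig, start, end, value), TSV matrices
(P-values, signals, attributes), YAML run configuration, and a JSON
manifest with SHA-256 checksums of every emitted file.

The MEME letter-probability blocks are parsed directly here rather than
through a motif library so probabilities survive a write/read cycle
bit-faithfully instead of being quantized through integer site counts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import PSSM, Background
from .signals import GeneAnnotation, SignalTrack

FLOAT_FMT = "%.12g"
ROW_SUM_TOL = 1e-6


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=contig, description="") for contig, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- MEME motifs

def write_pssms(pssms: list[PSSM], path, bg: Background | None = None) -> None:
    """Write motifs as MEME-style letter-probability matrix blocks."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if bg is not None:
            f = bg.freqs
            fh.write("Background letter frequencies\n")
            fh.write(f"A {f[0]:.6f} C {f[1]:.6f} G {f[2]:.6f} T {f[3]:.6f}\n\n")
        for p in pssms:
            fh.write(f"MOTIF {p.id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.n} nsites= 20 E= 0\n")
            for row in p.probs:
                fh.write(" " + " ".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")


def read_pssms(path) -> list[PSSM]:
    """Parse MEME-style letter-probability blocks into PSSMs.

    Rows must sum to 1 within 1e-6 (they are renormalized exactly);
    violations raise with the motif id and row index.  Duplicate ids and
    negative weights are errors; an empty file yields an empty list with
    a warning.
    """
    pssms: list[PSSM] = []
    seen: set[str] = set()
    name = None
    rows: list[list[float]] = []
    expected_w = None

    def flush() -> None:
        nonlocal name, rows, expected_w
        if name is None:
            return
        if expected_w is not None and len(rows) != expected_w:
            raise ValueError(f"motif {name!r}: expected {expected_w} rows, found {len(rows)}")
        mat = np.array(rows, dtype=float)
        if mat.size == 0:
            raise ValueError(f"motif {name!r}: empty matrix")
        if np.any(mat < 0):
            raise ValueError(f"motif {name!r}: negative weights")
        sums = mat.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > ROW_SUM_TOL)
        if len(bad):
            raise ValueError(f"motif {name!r}: row {bad[0] + 1} sums to {sums[bad[0]]:.6f}, beyond tolerance {ROW_SUM_TOL}")
        mat = mat / sums[:, None]
        if name in seen:
            raise ValueError(f"duplicate motif id {name!r}")
        seen.add(name)
        pssms.append(PSSM(name, mat))
        name, rows, expected_w = None, [], None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError("MOTIF line without an identifier")
                name = parts[1]
            elif line.startswith("letter-probability matrix"):
                toks = line.split()
                if "w=" in toks:
                    expected_w = int(toks[toks.index("w=") + 1])
            elif name is not None and line and line[0] in "0123456789.+-":
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"motif {name!r}: row with {len(vals)} columns (need 4)")
                rows.append(vals)
    flush()
    if not pssms:
        warnings.warn(f"no motifs found in {path}")
    return pssms


# ---------------------------------------------------------------- annotations

ANN_COLUMNS = ["gene_id", "contig", "atg", "strand", "orf_start", "orf_end", "ir_start", "ir_end"]


def write_annotations(annotations: list[GeneAnnotation], path) -> None:
    df = pd.DataFrame([[getattr(a, c) for c in ANN_COLUMNS] for a in annotations], columns=ANN_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# coords: 0-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_annotations(path) -> list[GeneAnnotation]:
    """Read the annotation TSV; a '# coords: 1-based' header triggers conversion."""
    one_based = False
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            one_based = "1-based" in first
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t")
    # 1-based inclusive coordinates: starts shift down by one, ends are
    # already the half-open bound after the shift
    shift = 1 if one_based else 0
    out = []
    for r in df.itertuples():
        out.append(
            GeneAnnotation(
                gene_id=str(r.gene_id), contig=str(r.contig), atg=int(r.atg) - shift, strand=str(r.strand),
                orf_start=int(r.orf_start) - shift, orf_end=int(r.orf_end),
                ir_start=int(r.ir_start) - shift, ir_end=int(r.ir_end),
            )
        )
    return out


# ---------------------------------------------------------------- bedGraph tracks

def write_signal_track(track: SignalTrack, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for mod, df in track.probes.items():
        p = directory / f"{mod}.bedgraph"
        df.to_csv(p, sep="\t", index=False, header=False, float_format=FLOAT_FMT)
        paths.append(p)
    return paths


def read_signal_tracks(paths: dict[str, Path], groups: dict[str, str], condition: str = "A") -> SignalTrack:
    """Read one bedGraph per modification into a SignalTrack.

    Records are sorted per contig by start; overlapping probes are
    permitted.  Non-numeric values or start >= end raise with the
    offending line number.
    """
    probes = {}
    for mod, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None, names=["contig", "start", "end", "value"],
                         dtype={"contig": str})
        for col in ("start", "end", "value"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[["start", "end", "value"]].isna().any().any():
            bad = int(df[["start", "end", "value"]].isna().any(axis=1).idxmax())
            raise ValueError(f"{path}: non-numeric record at line {bad + 1}")
        bad = df.index[df["start"] >= df["end"]]
        if len(bad):
            raise ValueError(f"{path}: start >= end at line {bad[0] + 1}")
        df = df.sort_values(["contig", "start"], kind="stable").reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        probes[mod] = df
    return SignalTrack(probes, groups, condition=condition)


# ---------------------------------------------------------------- matrices

def write_matrix(df: pd.DataFrame, path, index_name: str = "gene_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path, index_name: str = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------- world persistence

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_world(world, directory) -> dict:
    """Write a synthetic world to a directory; returns the checksum manifest."""
    from dataclasses import asdict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    write_fasta(world.genome, directory / "genome.fasta")
    write_annotations(world.annotations, directory / "annotations.tsv")
    write_pssms(world.pssms, directory / "motifs.meme", bg=world.background)
    for cond, track in world.tracks.items():
        write_signal_track(track, directory / "tracks" / cond)
    for cond, pv in world.pvalues.items():
        write_matrix(pv, directory / f"pvalues_{cond}.tsv")
    for cond, tt in world.true_targets.items():
        write_matrix(tt.astype(int), directory / f"truth_targets_{cond}.tsv")
    write_matrix(world.mod_effects, directory / "truth_mod_effects.tsv", index_name="tf")
    pd.Series(world.sensitive, name="sensitive").astype(int).rename_axis("tf").to_frame().to_csv(
        directory / "truth_sensitivity.tsv", sep="\t"
    )
    world.planted_sites.to_csv(directory / "truth_planted_sites.tsv", sep="\t", index=False)
    world.expression.rename_axis("gene_id").to_frame().to_csv(directory / "expression.tsv", sep="\t")
    world.attributes.to_csv(directory / "attributes.tsv", sep="\t")
    cfg_dict = asdict(cfg)
    cfg_dict["cooperative_pairs"] = [list(p) for p in cfg.cooperative_pairs]
    cfg_dict["pvalue_target_beta"] = list(cfg.pvalue_target_beta)
    cfg_dict["orf_len_range"] = list(cfg.orf_len_range)
    cfg_dict["motif_len_range"] = list(cfg.motif_len_range)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh)
    files = sorted(p for p in directory.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {"files": {str(p.relative_to(directory)): _sha256(p) for p in files}}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_world(directory):
    """Reconstruct a synthetic world from a write_world directory."""
    from .synthetic import SyntheticConfig, SyntheticWorld

    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        cfg_dict = yaml.safe_load(fh)
    cfg_dict["cooperative_pairs"] = tuple(tuple(p) for p in cfg_dict["cooperative_pairs"])
    cfg_dict["pvalue_target_beta"] = tuple(cfg_dict["pvalue_target_beta"])
    cfg_dict["orf_len_range"] = tuple(cfg_dict["orf_len_range"])
    cfg_dict["motif_len_range"] = tuple(cfg_dict["motif_len_range"])
    cfg = SyntheticConfig(**cfg_dict)
    genome = read_fasta(directory / "genome.fasta")
    annotations = read_annotations(directory / "annotations.tsv")
    pssms = read_pssms(directory / "motifs.meme") if cfg.n_tfs else []
    tf_names = [p.id for p in pssms] if pssms else [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    tracks = {}
    for cond in cfg.conditions:
        paths = {m: directory / "tracks" / cond / f"{m}.bedgraph" for m in cfg.mod_names}
        tracks[cond] = read_signal_tracks(paths, cfg.mod_groups, condition=cond)
    pvalues = {c: read_matrix(directory / f"pvalues_{c}.tsv") for c in cfg.conditions}
    true_targets = {c: read_matrix(directory / f"truth_targets_{c}.tsv").astype(bool) for c in cfg.conditions}
    mod_effects = pd.read_csv(directory / "truth_mod_effects.tsv", sep="\t", index_col=0)
    sens = pd.read_csv(directory / "truth_sensitivity.tsv", sep="\t", index_col=0)["sensitive"].astype(bool)
    planted_sites = pd.read_csv(directory / "truth_planted_sites.tsv", sep="\t")
    if planted_sites.empty:
        planted_sites = pd.DataFrame(columns=["tf", "gene_id", "contig", "start", "end", "strand"])
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)["expression"]
    attributes = pd.read_csv(directory / "attributes.tsv", sep="\t", index_col=0)
    coop = {tf_names[a]: tf_names[b] for a, b in cfg.cooperative_pairs}
    contig_lengths = {c: len(s) for c, s in genome.items()}
    return SyntheticWorld(
        config=cfg, genome=genome, contig_lengths=contig_lengths, annotations=annotations,
        tf_names=tf_names, pssms=pssms, direct_binder={t: t not in coop for t in tf_names},
        cooperativity=coop, true_targets=true_targets, pvalues=pvalues, tracks=tracks,
        sensitive=sens.to_dict(), mod_effects=mod_effects, planted_sites=planted_sites,
        expression=expression, attributes=attributes,
    )
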