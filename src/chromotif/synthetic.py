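"""Seeded synthetic worlds with planted regulatory structure.

The generator emulates the data layout of the yeast ChIP-chip era that
the method was designed for: a compact genome whose genes each own a
dedicated upstream intergenic promoter; tiling probes of ~60 bp covering
~85% of the genome; 25 chromatin features split into a 14-feature
ATG-window set (occupancy/methylation/acetylation) and an 11-feature
intergenic/ORF acetylation set; per-(TF, gene) ChIP binding P-values
skewed small for true targets; and motif instances planted in target
promoters.  A configurable fraction of TFs is *histone-sensitive*: their
target promoters receive per-modification Gaussian shifts.  Optional
extras plant TF cooperativity (one TF's targets carry another's motif),
condition-specific binding with condition-specific chromatin shifts, and
nucleosome-depletion-style dips at planted binding sites.

Everything is driven by one integer seed, so identical configurations
reproduce byte-identical worlds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .motif import ALPHABET, PSSM, Background, background_from_gc, reverse_complement, sample_site
from .signals import GeneAnnotation, IR_ORF, SignalTrack, WINDOWED

WINDOWED_NAMES = [
    "H3_occ", "H4_occ", "H3K9ac", "H3K14ac", "H4ac4",
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K36me3", "H3K79me3",
]
IR_NAMES = [
    "H2AK7ac", "H2BK11ac", "H2BK16ac", "H3K9ac", "H3K14ac",
    "H3K18ac", "H3K23ac", "H3K27ac", "H4K8ac", "H4K12ac", "H4K16ac",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; defaults mirror the emulated studies."""

    n_genes: int = 2000
    n_tfs: int = 20
    promoter_len: int = 800
    gc: float = 0.37
    n_windowed_mods: int = 14
    n_ir_mods: int = 11
    probe_len: int = 60
    probe_coverage: float = 0.85
    target_prevalence: float = 0.05
    motif_plant_prob: float = 0.8
    sensitive_fraction: float = 0.33
    modification_effect: float = 1.0
    n_affected_mods: int = 10
    pvalue_target_beta: tuple[float, float] = (0.1, 1.0)
    condition_shift: float = 1.0
    two_conditions: bool = True
    site_depletion: float = -1.5
    n_site_depletion_mods: int = 2
    cooperative_pairs: tuple[tuple[int, int], ...] = ()
    forced_insensitive: tuple[int, ...] = ()
    n_contigs: int = 4
    orf_len_range: tuple[int, int] = (500, 1500)
    spacer: int = 100
    motif_len_range: tuple[int, int] = (7, 10)
    consensus_weight: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc", "probe_coverage", "target_prevalence", "motif_plant_prob", "sensitive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if self.promoter_len < self.motif_len_range[1]:
            raise ValueError("promoter must be at least as long as the longest motif")
        if self.n_tfs > 0 and self.n_genes < 10 * self.n_tfs:
            warnings.warn("fewer than 10 genes per TF; target sets will be small")
        for a, b in self.cooperative_pairs:
            if not (0 <= a < self.n_tfs and 0 <= b < self.n_tfs) or a == b:
                raise ValueError(f"invalid cooperative pair ({a}, {b})")

    @property
    def n_mods(self) -> int:
        return self.n_windowed_mods + self.n_ir_mods

    @property
    def mod_names(self) -> list[str]:
        w = [WINDOWED_NAMES[i] if i < len(WINDOWED_NAMES) else f"WM{i:02d}" for i in range(self.n_windowed_mods)]
        r = ["IR_" + (IR_NAMES[i] if i < len(IR_NAMES) else f"AC{i:02d}") for i in range(self.n_ir_mods)]
        return w + r

    @property
    def mod_groups(self) -> dict[str, str]:
        names = self.mod_names
        return {m: (WINDOWED if i < self.n_windowed_mods else IR_ORF) for i, m in enumerate(names)}

    @property
    def conditions(self) -> list[str]:
        return ["A", "B"] if self.two_conditions else ["A"]


@dataclass
class SyntheticWorld:
    """A fully generated world: sequences, annotations, tracks, truth."""

    config: SyntheticConfig
    genome: dict[str, str]
    contig_lengths: dict[str, int]
    annotations: list[GeneAnnotation]
    tf_names: list[str]
    pssms: list[PSSM]
    direct_binder: dict[str, bool]
    cooperativity: dict[str, str]  # indirect TF -> partner whose motif is planted
    true_targets: dict[str, pd.DataFrame]  # condition -> genes x TFs bool
    pvalues: dict[str, pd.DataFrame]  # condition -> genes x TFs float
    tracks: dict[str, SignalTrack]  # condition -> track
    sensitive: dict[str, bool]
    mod_effects: pd.DataFrame  # TFs x modifications planted shift
    planted_sites: pd.DataFrame  # tf, gene_id, contig, start, end, strand
    expression: pd.Series
    attributes: pd.DataFrame  # per-TF hierarchy level, PPI degree, etc.

    @property
    def gene_ids(self) -> list[str]:
        return [a.gene_id for a in self.annotations]

    @property
    def background(self) -> Background:
        return background_from_gc(self.config.gc)

    def annotation(self, gene_id: str) -> GeneAnnotation:
        return self._ann_map[gene_id]

    def __post_init__(self) -> None:
        self._ann_map = {a.gene_id: a for a in self.annotations}

    def promoter_interval(self, gene_id: str) -> tuple[str, int, int]:
        a = self.annotation(gene_id)
        return a.contig, a.ir_start, a.ir_end

    def promoter_seq(self, gene_id: str) -> str:
        contig, s, e = self.promoter_interval(gene_id)
        return self.genome[contig][s:e]


def _random_pssm(name: str, rng: np.random.Generator, cfg: SyntheticConfig) -> PSSM:
    n = int(rng.integers(cfg.motif_len_range[0], cfg.motif_len_range[1] + 1))
    probs = np.full((n, 4), (1.0 - cfg.consensus_weight) / 3.0)
    consensus = rng.integers(0, 4, size=n)
    probs[np.arange(n), consensus] = cfg.consensus_weight
    return PSSM(name, probs)


def _layout_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[list[GeneAnnotation], dict[str, int]]:
    per_contig = np.array_split(np.arange(cfg.n_genes), cfg.n_contigs)
    annotations: list[GeneAnnotation] = []
    contig_lengths: dict[str, int] = {}
    for ci, gene_idx in enumerate(per_contig):
        contig = f"chr{ci + 1:02d}"
        pos = cfg.spacer
        for g in gene_idx:
            strand = "+" if rng.random() < 0.5 else "-"
            orf_len = int(rng.integers(*cfg.orf_len_range))
            if strand == "+":
                ir = (pos, pos + cfg.promoter_len)
                orf = (ir[1], ir[1] + orf_len)
                atg = orf[0]
                pos = orf[1] + cfg.spacer
            else:
                orf = (pos, pos + orf_len)
                ir = (orf[1], orf[1] + cfg.promoter_len)
                atg = orf[1] - 1
                pos = ir[1] + cfg.spacer
            annotations.append(
                GeneAnnotation(
                    gene_id=f"g{g:05d}", contig=contig, atg=atg, strand=strand,
                    orf_start=orf[0], orf_end=orf[1], ir_start=ir[0], ir_end=ir[1],
                )
            )
        contig_lengths[contig] = pos
    return annotations, contig_lengths


def _sample_genome(cfg: SyntheticConfig, contig_lengths: dict[str, int], rng: np.random.Generator) -> dict[str, bytearray]:
    bg = background_from_gc(cfg.gc).freqs
    out = {}
    for contig, length in contig_lengths.items():
        codes = rng.choice(4, size=length, p=bg)
        out[contig] = bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes())
    return out


def _tile_probes(cfg: SyntheticConfig, contig_lengths: dict[str, int], rng: np.random.Generator) -> pd.DataFrame:
    """Probe grid shared by all modifications; gaps dropped uniformly at random."""
    frames = []
    for contig, length in contig_lengths.items():
        starts = np.arange(0, length - cfg.probe_len + 1, cfg.probe_len, dtype=np.int64)
        n_keep = int(round(cfg.probe_coverage * len(starts)))
        keep = np.sort(rng.choice(len(starts), size=n_keep, replace=False))
        frames.append(pd.DataFrame({"contig": contig, "start": starts[keep], "end": starts[keep] + cfg.probe_len}))
    return pd.concat(frames, ignore_index=True)


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Build a complete seeded world; identical config + seed => identical world."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tf_names = [f"TF{i:03d}" for i in range(cfg.n_tfs)]
    pssms = [_random_pssm(t, rng, cfg) for t in tf_names]
    coop = {tf_names[a]: tf_names[b] for a, b in cfg.cooperative_pairs}
    direct = {t: t not in coop for t in tf_names}

    annotations, contig_lengths = _layout_genes(cfg, rng)
    genome_bytes = _sample_genome(cfg, contig_lengths, rng)
    gene_ids = [a.gene_id for a in annotations]

    # condition-specific true target sets
    true_targets: dict[str, pd.DataFrame] = {}
    for cond in cfg.conditions:
        mat = rng.random((cfg.n_genes, cfg.n_tfs)) < cfg.target_prevalence if cfg.n_tfs else np.zeros((cfg.n_genes, 0), bool)
        true_targets[cond] = pd.DataFrame(mat, index=gene_ids, columns=tf_names)

    # plant motif instances in the promoters of (union-over-conditions) targets
    site_rows = []
    ann_by_gene = {a.gene_id: a for a in annotations}
    pssm_by_tf = dict(zip(tf_names, pssms))
    for tf in tf_names:
        planted_pssm = pssm_by_tf[coop.get(tf, tf)]
        union = np.zeros(cfg.n_genes, dtype=bool)
        for cond in cfg.conditions:
            union |= true_targets[cond][tf].to_numpy()
        for gi in np.flatnonzero(union):
            if rng.random() >= cfg.motif_plant_prob:
                continue
            ann = ann_by_gene[gene_ids[gi]]
            site = sample_site(planted_pssm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            seq = site if strand == "+" else reverse_complement(site)
            offset = int(rng.integers(ann.ir_start, ann.ir_end - len(site) + 1))
            genome_bytes[ann.contig][offset : offset + len(site)] = seq.encode("ascii")
            site_rows.append((tf, ann.gene_id, ann.contig, offset, offset + len(site), strand))
    planted_sites = pd.DataFrame(site_rows, columns=["tf", "gene_id", "contig", "start", "end", "strand"])
    genome = {c: bytes(b).decode("ascii") for c, b in genome_bytes.items()}

    # sensitivity labels and per-TF planted modification shifts
    mod_names = cfg.mod_names
    n_sens = int(round(cfg.sensitive_fraction * cfg.n_tfs))
    sens_order = rng.permutation(cfg.n_tfs) if cfg.n_tfs else np.empty(0, int)
    sensitive = {t: False for t in tf_names}
    eligible = [i for i in sens_order if i not in cfg.forced_insensitive]
    for i in eligible[:n_sens]:
        sensitive[tf_names[i]] = True
    # one per-world sign template shared by all sensitive TFs: chromatin
    # marks have coherent directions (active marks up, occupancy down), so
    # sensitive TFs shift the same way on a mark, each on its own subset
    effects = np.zeros((cfg.n_tfs, cfg.n_mods))
    sign_template = rng.choice([-1.0, 1.0], size=cfg.n_mods)
    for i, tf in enumerate(tf_names):
        if not sensitive[tf]:
            continue
        chosen = rng.choice(cfg.n_mods, size=min(cfg.n_affected_mods, cfg.n_mods), replace=False)
        effects[i, chosen] = sign_template[chosen] * cfg.modification_effect
    mod_effects = pd.DataFrame(effects, index=tf_names, columns=mod_names)

    # shared probe grid, per-condition Gaussian values with planted shifts
    probes = _tile_probes(cfg, contig_lengths, rng)
    probe_starts = {c: probes.loc[probes["contig"] == c, "start"].to_numpy() for c in contig_lengths}
    probe_pos = {c: (np.flatnonzero((probes["contig"] == c).to_numpy())) for c in contig_lengths}
    tracks: dict[str, SignalTrack] = {}
    depletion_mods = list(range(min(cfg.n_site_depletion_mods, cfg.n_windowed_mods)))
    for cond in cfg.conditions:
        effect_scale = cfg.modification_effect if cond == "A" else cfg.condition_shift
        scale = effect_scale / cfg.modification_effect if cfg.modification_effect else 0.0
        values = rng.normal(size=(len(probes), cfg.n_mods))
        delta = true_targets[cond].to_numpy(dtype=float) @ effects * scale  # genes x mods
        for gi, ann in enumerate(annotations):
            row = delta[gi]
            if not row.any():
                continue
            st = probe_starts[ann.contig]
            lo = np.searchsorted(st, ann.ir_start - cfg.probe_len + 1, side="left")
            hi = np.searchsorted(st, ann.ir_end, side="left")
            if hi > lo:
                values[probe_pos[ann.contig][lo:hi]] += row
        if cfg.site_depletion and len(planted_sites) and depletion_mods:
            tgt = true_targets[cond]
            for s in planted_sites.itertuples():
                if not bool(tgt.at[s.gene_id, s.tf]):
                    continue
                st = probe_starts[s.contig]
                lo = np.searchsorted(st, s.start - cfg.probe_len + 1, side="left")
                hi = np.searchsorted(st, s.end, side="left")
                if hi > lo:
                    values[np.ix_(probe_pos[s.contig][lo:hi], depletion_mods)] += cfg.site_depletion
        per_mod = {
            mod: pd.DataFrame(
                {"contig": probes["contig"], "start": probes["start"], "end": probes["end"], "value": values[:, j]}
            )
            for j, mod in enumerate(mod_names)
        }
        tracks[cond] = SignalTrack(per_mod, cfg.mod_groups, condition=cond)

    # ChIP binding P-values consistent with the truth
    a_beta, b_beta = cfg.pvalue_target_beta
    pvalues: dict[str, pd.DataFrame] = {}
    for cond in cfg.conditions:
        p = rng.random((cfg.n_genes, cfg.n_tfs))
        tgt = true_targets[cond].to_numpy()
        if tgt.any():
            p[tgt] = rng.beta(a_beta, b_beta, size=int(tgt.sum()))
        pvalues[cond] = pd.DataFrame(p, index=gene_ids, columns=tf_names)

    expression = pd.Series(rng.lognormal(mean=1.0, sigma=1.0, size=cfg.n_genes), index=gene_ids, name="expression")

    # per-TF attribute table with planted class differences (hierarchy, PPI degree)
    rows = []
    for tf in tf_names:
        s = sensitive[tf]
        level = int(rng.choice([1, 2, 3, 4], p=[0.2, 0.5, 0.2, 0.1] if s else [0.6, 0.3, 0.07, 0.03]))
        degree = int(rng.poisson(20 if s else 8))
        rows.append((tf, level, degree))
    attributes = pd.DataFrame(rows, columns=["tf", "hierarchy_level", "ppi_degree"]).set_index("tf")

    return SyntheticWorld(
        config=cfg, genome=genome, contig_lengths=contig_lengths, annotations=annotations,
        tf_names=tf_names, pssms=pssms, direct_binder=direct, cooperativity=coop,
        true_targets=true_targets, pvalues=pvalues, tracks=tracks, sensitive=sensitive,
        mod_effects=mod_effects, planted_sites=planted_sites, expression=expression,
        attributes=attributes,
    )


def audit_planted_effect(world: SyntheticWorld, condition: str = "A") -> tuple[float, float]:
    """Recover the planted shift from the emitted track (estimate, SE).

    For every (sensitive TF, affected modification), the sign-corrected
    difference between the mean promoter-region signal of true targets
    and of non-targets estimates ``modification_effect``.  Differences
    are averaged within each TF first (a TF's modifications share its
    target set, so they are not independent draws), and the standard
    error is taken across TF-level means.  Returns (estimate, SE).
    """
    from .signals import aggregate_region_signal

    cfg = world.config
    track = world.tracks[condition]
    diffs, weights = [], []
    tgt = world.true_targets[condition]
    promoter_signal_cache: dict[str, np.ndarray] = {}
    for mod in world.mod_effects.columns:
        sig = np.array(
            [aggregate_region_signal(track, a.contig, (a.ir_start, a.ir_end), mod) for a in world.annotations]
        )
        promoter_signal_cache[mod] = sig
    tf_means = []
    for tf in world.tf_names:
        if not world.sensitive[tf]:
            continue
        mask = tgt[tf].to_numpy()
        diffs = []
        for mod in world.mod_effects.columns:
            eff = world.mod_effects.at[tf, mod]
            if eff == 0:
                continue
            sig = promoter_signal_cache[mod]
            t, n = sig[mask], sig[~mask]
            t, n = t[~np.isnan(t)], n[~np.isnan(n)]
            if len(t) < 2 or len(n) < 2:
                continue
            diffs.append(np.sign(eff) * (t.mean() - n.mean()))
        if diffs:
            tf_means.append(float(np.mean(diffs)))
    if not tf_means:
        raise ValueError("world has no planted effects to audit")
    est = float(np.mean(tf_means))
    se = float(np.std(tf_means, ddof=1) / np.sqrt(len(tf_means))) if len(tf_means) > 1 else float("inf")
    return est, se
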