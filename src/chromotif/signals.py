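"""Per-gene chromatin signals from probe-level modification tracks.

Tiling-array experiments give one value per probe per chromatin feature
(histone occupancy, methylation, acetylation).  Target-gene prediction
needs those collapsed to one value per gene per (modification, region):

* ``up500 / up1000`` and ``down500 / down1000`` — fixed windows flanking
  the ATG start codon, mirrored for minus-strand genes;
* ``IR`` — the intergenic region upstream of the gene;
* ``ORF`` — the coding region.

A region's signal is the unweighted mean of all probes overlapping it by
at least 1 bp; regions covered by no probe are missing (arrays tile only
part of the genome).  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

WINDOWED = "windowed"  # ATG-flanking window set (occupancy/methylation/acetylation)
IR_ORF = "ir_orf"  # intergenic/coding acetylation set


@dataclass
class GeneAnnotation:
    """One gene: ORF extent, strand, ATG anchor, upstream intergenic bounds.

    ``atg`` is the coordinate of the first base of the start codon: equal to
    ``orf_start`` on the + strand and ``orf_end - 1`` on the - strand.  The
    intergenic interval (to the previous gene or contig edge on the
    promoter side) is stored explicitly.
    """

    gene_id: str
    contig: str
    atg: int
    strand: str
    orf_start: int
    orf_end: int
    ir_start: int
    ir_end: int

    def __post_init__(self) -> None:
        if self.orf_start >= self.orf_end:
            raise ValueError(f"{self.gene_id}: orf_start must be < orf_end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


def gene_windows(ann: GeneAnnotation, width: int, contig_len: int | None = None) -> dict[str, tuple[int, int]]:
    """ATG-flanking windows plus IR and ORF intervals for one gene.

    + strand: upstream = [atg-width, atg), downstream = [atg, atg+width).
    - strand (mirror): upstream = [atg+1, atg+1+width), downstream =
    [atg+1-width, atg+1).  Windows are truncated at contig bounds.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if ann.strand == "+":
        up = (ann.atg - width, ann.atg)
        down = (ann.atg, ann.atg + width)
    else:
        up = (ann.atg + 1, ann.atg + 1 + width)
        down = (ann.atg + 1 - width, ann.atg + 1)
    end = contig_len if contig_len is not None else None

    def clip(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = max(0, iv[0]), iv[1]
        if end is not None:
            e = min(e, end)
        if s > e:
            raise ValueError(f"{ann.gene_id}: window {iv} lies off the contig")
        return (s, e)

    return {
        "up": clip(up),
        "down": clip(down),
        "IR": clip((ann.ir_start, ann.ir_end)),
        "ORF": clip((ann.orf_start, ann.orf_end)),
    }


class _ContigIndex:
    """Probe lookup on one contig for one modification.

    Probes sorted by start; when ends are also nondecreasing (the common
    non-overlapping tiling case) overlap queries reduce to two binary
    searches, otherwise an interval tree is used.
    """

    def __init__(self, starts: np.ndarray, ends: np.ndarray, values: np.ndarray):
        order = np.argsort(starts, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.values = values[order]
        self.monotone = bool(np.all(np.diff(self.ends) >= 0)) if len(self.ends) > 1 else True
        self._tree: IntervalTree | None = None

    def overlapping(self, start: int, end: int) -> np.ndarray:
        """Values of probes overlapping [start, end) by >= 1 bp."""
        if start >= end or len(self.starts) == 0:
            return np.empty(0)
        hi = np.searchsorted(self.starts, end, side="left")  # probes with start < end
        if self.monotone:
            lo = np.searchsorted(self.ends, start, side="right")  # probes with end > start
            return self.values[lo:hi]
        if self._tree is None:
            self._tree = IntervalTree()
            for s, e, i in zip(self.starts, self.ends, range(len(self.starts))):
                self._tree.addi(int(s), int(e), i)
        idx = sorted(iv.data for iv in self._tree.overlap(start, end))
        return self.values[idx]


@dataclass
class SignalTrack:
    """Probe-level values for a set of chromatin modifications.

    ``probes`` maps modification id -> DataFrame(contig, start, end, value);
    ``groups`` maps modification id -> WINDOWED or IR_ORF; ``condition``
    tags the growth condition the track was measured under.
    """

    probes: dict[str, pd.DataFrame]
    groups: dict[str, str]
    condition: str = "A"
    _index: dict = field(default_factory=dict, repr=False)

    @property
    def modifications(self) -> list[str]:
        return list(self.probes)

    def index_for(self, mod: str, contig: str) -> _ContigIndex:
        if mod not in self.probes:
            raise KeyError(f"unknown modification {mod!r}")
        key = (mod, contig)
        if key not in self._index:
            df = self.probes[mod]
            sub = df[df["contig"] == contig]
            self._index[key] = _ContigIndex(
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["value"].to_numpy(dtype=float),
            )
        return self._index[key]


def aggregate_region_signal(
    track: SignalTrack, contig: str, region: tuple[int, int], mod: str, rule: str = "any"
) -> float:
    """Unweighted mean of probes overlapping the region; NaN if none.

    ``rule="any"`` includes every probe overlapping by >= 1 bp;
    ``rule="midpoint"`` includes a probe only when its midpoint falls in
    the region (useful when partial edge overlaps should not count).
    """
    idx = track.index_for(mod, contig)
    if rule == "any":
        vals = idx.overlapping(*region)
    elif rule == "midpoint":
        mids = (idx.starts + idx.ends) // 2
        vals = idx.values[(mids >= region[0]) & (mids < region[1])]
    else:
        raise ValueError(f"unknown inclusion rule {rule!r}")
    if len(vals) == 0:
        return float("nan")
    return float(vals.mean())


@dataclass
class GeneSignalMatrix:
    """Genes x (modification, region) signal matrix.

    Columns are named ``"<modification>|<region>"`` with region one of
    up500/up1000/down500/down1000/IR/ORF.  ``missingness`` records the
    fraction of missing values per column; ``condition`` is inherited from
    the source track.
    """

    values: pd.DataFrame
    condition: str = "A"

    @property
    def missingness(self) -> pd.Series:
        return self.values.isna().mean()

    def columns_for(self, regions: list[str]) -> list[str]:
        return [c for c in self.values.columns if c.split("|")[1] in regions]

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        with open(path, "w") as fh:
            fh.write(f"# condition: {self.condition}\n")
            out.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "GeneSignalMatrix":
        condition = "A"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# condition:"):
                condition = first.split(":", 1)[1].strip()
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        return cls(df.set_index("gene_id"), condition=condition)


def build_gene_signal_matrix(
    annotations: list[GeneAnnotation],
    track: SignalTrack,
    widths: tuple[int, ...] = (500, 1000),
    contig_lengths: dict[str, int] | None = None,
) -> GeneSignalMatrix:
    """Aggregate every modification over every applicable gene region.

    Windowed-group modifications contribute up/down columns at each width;
    IR/ORF-group modifications contribute IR and ORF columns.  Per-column
    missingness is warned about when any column is >10% missing.
    """
    if not annotations:
        raise ValueError("no gene annotations supplied")
    if not track.probes:
        raise ValueError("signal track has no modifications")
    columns: dict[str, np.ndarray] = {}
    gene_ids = [a.gene_id for a in annotations]
    regions_per_gene = {}
    for ann in annotations:
        clen = contig_lengths.get(ann.contig) if contig_lengths else None
        per_width = {w: gene_windows(ann, w, clen) for w in widths}
        regions_per_gene[ann.gene_id] = per_width
    any_width = widths[0]
    for mod in track.modifications:
        group = track.groups.get(mod, WINDOWED)
        if group == WINDOWED:
            wanted = [(f"up{w}", w, "up") for w in widths] + [(f"down{w}", w, "down") for w in widths]
        else:
            wanted = [("IR", any_width, "IR"), ("ORF", any_width, "ORF")]
        for region_name, w, key in wanted:
            col = np.empty(len(annotations))
            for i, ann in enumerate(annotations):
                region = regions_per_gene[ann.gene_id][w][key]
                col[i] = aggregate_region_signal(track, ann.contig, region, mod)
            columns[f"{mod}|{region_name}"] = col
    df = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    bad = df.isna().mean()
    bad = bad[bad > 0.10]
    if len(bad):
        warnings.warn(f"{len(bad)} signal columns are >10% missing (partial probe coverage)")
    return GeneSignalMatrix(df, condition=track.condition)
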