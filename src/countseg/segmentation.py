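"""Decoded state paths as genomic segment annotations, and per-state summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from countseg.io_binning import BinnedGenome, CountMatrix, RegionSet

# fixed qualitative palette for BED9 itemRgb, cycled over state indices
_PALETTE = [
    (228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
    (255, 127, 0), (255, 255, 51), (166, 86, 40), (247, 129, 191),
    (153, 153, 153), (0, 109, 119), (131, 56, 236), (58, 134, 255),
    (251, 86, 7), (112, 224, 0), (155, 93, 229), (241, 91, 181),
    (0, 187, 249), (0, 245, 212), (140, 30, 63), (33, 131, 128),
]


def state_color(index: int) -> str:
    r, g, b = _PALETTE[index % len(_PALETTE)]
    return f"{r},{g},{b}"


@dataclass
class StateAnnotation:
    """Non-overlapping sorted segments covering the binned genome once.

    Consecutive segments on a chromosome always differ in state (maximal
    runs); total segment nucleotides per state is the s^nt quantity used by
    the enrichment statistics.
    """

    segments: pd.DataFrame  # chrom, start, end, state (int index)
    state_labels: tuple[str, ...]
    genome: BinnedGenome

    def __post_init__(self):
        self.state_labels = tuple(self.state_labels)
        seg = self.segments.reset_index(drop=True)
        if (seg["start"] >= seg["end"]).any():
            raise ValueError("segments must satisfy start < end")
        self.segments = seg

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def state_nucleotides(self) -> np.ndarray:
        """s^nt: total segment width per state."""
        widths = (self.segments["end"] - self.segments["start"]).to_numpy(np.int64)
        return np.bincount(self.segments["state"].to_numpy(), weights=widths,
                           minlength=self.n_states).astype(np.int64)

    def state_regions(self, state: int) -> RegionSet:
        sel = self.segments[self.segments["state"] == state]
        return RegionSet(sel[["chrom", "start", "end"]].copy(),
                         name=self.state_labels[state])

    def bin_states(self) -> np.ndarray:
        """Back-projection to the per-bin state path (global bin order)."""
        return segments_to_path(self)


def path_to_segments(path: np.ndarray, genome: BinnedGenome,
                     state_labels=None) -> StateAnnotation:
    """Run-length encode a per-bin state path into bin-aligned segments."""
    path = np.asarray(path)
    if len(path) != genome.n_bins:
        raise ValueError(f"path length {len(path)} != bin count {genome.n_bins}")
    n_states = int(path.max()) + 1 if len(path) else 0
    if state_labels is None:
        state_labels = tuple(f"S{k + 1}" for k in range(n_states))
    w = genome.bin_width
    rows = []
    offset = 0
    for chrom, ln in zip(genome.chrom_names, genome.chrom_lengths):
        nb = -(-ln // w)
        sub = path[offset:offset + nb]
        change = np.flatnonzero(np.diff(sub)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [nb]])
        for b0, b1 in zip(starts, ends):
            rows.append((chrom, int(b0) * w, min(int(b1) * w, ln), int(sub[b0])))
        offset += nb
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return StateAnnotation(seg, state_labels, genome)


def segments_to_path(annotation: StateAnnotation) -> np.ndarray:
    """Inverse of :func:`path_to_segments` on bin-aligned annotations."""
    genome = annotation.genome
    w = genome.bin_width
    path = np.full(genome.n_bins, -1, dtype=np.int64)
    offsets = genome.chrom_offsets()
    for chrom, grp in annotation.segments.groupby("chrom", sort=False):
        off = offsets[chrom]
        for start, end, state in zip(grp["start"], grp["end"], grp["state"]):
            b0 = start // w
            b1 = -(-end // w)
            path[off + b0:off + b1] = state
    if (path < 0).any():
        raise ValueError("annotation does not cover every bin")
    return path


def summarize_states(annotation: StateAnnotation, counts: CountMatrix,
                     tss: RegionSet | None = None) -> pd.DataFrame:
    """Per-state medians: per-track coverage, segment width, distance to TSS.

    Coverage is the median over a state's segments of the segment's mean bin
    count per track; distance is from segment midpoint to the nearest TSS
    midpoint, 0 if the midpoint falls inside a TSS region.
    """
    genome = annotation.genome
    w = genome.bin_width
    offsets = genome.chrom_offsets()
    tss_by_chrom = tss.by_chrom() if tss is not None else {}
    records = {k: {"n_segments": 0, "widths": [], "dists": [],
                   "cov": [[] for _ in counts.track_names]}
               for k in range(annotation.n_states)}
    for chrom, grp in annotation.segments.groupby("chrom", sort=False):
        off = offsets[chrom]
        t_starts = t_ends = None
        if chrom in tss_by_chrom:
            t_starts, t_ends = tss_by_chrom[chrom]
            t_mids = (t_starts + t_ends) // 2
        for start, end, state in zip(grp["start"], grp["end"], grp["state"]):
            rec = records[int(state)]
            rec["n_segments"] += 1
            rec["widths"].append(end - start)
            b0, b1 = start // w, -(-end // w)
            seg_counts = counts.counts[off + b0:off + b1]
            for d in range(counts.n_tracks):
                rec["cov"][d].append(float(seg_counts[:, d].mean()))
            if t_starts is not None and len(t_starts):
                mid = (start + end) // 2
                inside = np.any((t_starts <= mid) & (mid < t_ends))
                dist = 0 if inside else int(np.min(np.abs(t_mids - mid)))
                rec["dists"].append(dist)
    rows = []
    for k in range(annotation.n_states):
        rec = records[k]
        row = {"state": annotation.state_labels[k],
               "n_segments": rec["n_segments"],
               "median_width": float(np.median(rec["widths"])) if rec["widths"] else np.nan,
               "median_tss_distance": (float(np.median(rec["dists"]))
                                       if rec["dists"] else np.nan)}
        for d, name in enumerate(counts.track_names):
            row[f"median_coverage_{name}"] = (float(np.median(rec["cov"][d]))
                                              if rec["cov"][d] else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotation(annotation: StateAnnotation, path, header_lines=()) -> None:
    """Write segments as BED9 with the state label in column 4."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"#{line}\n")
        for chrom, start, end, state in annotation.segments.itertuples(index=False):
            label = annotation.state_labels[state]
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t.\t"
                     f"{start}\t{end}\t{state_color(state)}\n")


def read_annotation(path, genome: BinnedGenome,
                    state_labels=None) -> StateAnnotation:
    """Read a BED annotation; sorts and merges adjacent same-state lines."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i}: need >=4 columns (state in col 4)")
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    if state_labels is None:
        state_labels = tuple(sorted(df["label"].unique(),
                                    key=lambda s: (len(s), s)))
    label_to_idx = {lab: k for k, lab in enumerate(state_labels)}
    df["state"] = df["label"].map(label_to_idx)
    if df["state"].isna().any():
        raise ValueError(f"{path}: unknown state label")
    merged = []
    for row in df[["chrom", "start", "end", "state"]].itertuples(index=False):
        if merged and merged[-1][0] == row.chrom and merged[-1][2] == row.start \
                and merged[-1][3] == row.state:
            merged[-1][2] = row.end
        else:
            merged.append([row.chrom, row.start, row.end, int(row.state)])
    seg = pd.DataFrame(merged, columns=["chrom", "start", "end", "state"])
    return StateAnnotation(seg, state_labels, genome)
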