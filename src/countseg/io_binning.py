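"""Reading interval data, binning reads into count tracks, library-size factors.

Coordinates are 0-based half-open everywhere internally (BED convention on
disk). The genome is partitioned into consecutive fixed-width bins (200 bp by
default); each sequencing read contributes one count to the bin containing its
shifted fragment midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from countseg import intervals as iv

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 200


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class BinnedGenome:
    """Ordered fixed-width bin partition of named chromosomes.

    Bins are 0-based half-open ``[i*w, (i+1)*w)``; the last bin of each
    chromosome is truncated at the chromosome end. This is the coordinate
    frame for every count matrix and annotation.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_width: int = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if any(ln <= 0 for ln in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def genome_length(self) -> int:
        """Total genome length l in bp (used by enrichment statistics)."""
        return int(sum(self.chrom_lengths))

    def n_bins_per_chrom(self) -> np.ndarray:
        w = self.bin_width
        return np.array([-(-ln // w) for ln in self.chrom_lengths], dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return int(self.n_bins_per_chrom().sum())

    def chrom_offsets(self) -> dict[str, int]:
        """Row offset of each chromosome's first bin in the global bin order."""
        nb = self.n_bins_per_chrom()
        offs = np.concatenate([[0], np.cumsum(nb)[:-1]])
        return dict(zip(self.chrom_names, offs.astype(int)))

    def bin_table(self) -> pd.DataFrame:
        """All bins as a (chrom, start, end) frame in global bin order."""
        rows = []
        w = self.bin_width
        for name, ln in zip(self.chrom_names, self.chrom_lengths):
            nb = -(-ln // w)
            starts = np.arange(nb, dtype=np.int64) * w
            ends = np.minimum(starts + w, ln)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


def read_chrom_sizes(path, bin_width: int = DEFAULT_BIN_WIDTH) -> BinnedGenome:
    """Read a two-column chrom.sizes table into a BinnedGenome."""
    names, lengths = [], []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i}: expected 2 columns")
            try:
                ln = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: bad length {parts[1]!r}") from exc
            names.append(parts[0])
            lengths.append(ln)
    return BinnedGenome(tuple(names), tuple(lengths), bin_width)


@dataclass
class ReadSet:
    """Aligned single-end reads for one track in one cell type."""

    df: pd.DataFrame  # columns: chrom, start, end, strand
    track: str = ""
    cell_type: str = ""

    def __post_init__(self):
        bad = ~self.df["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be '+' or '-'")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RegionSet:
    """Named genomic intervals: TSSs, HOT regions, TF peaks, state calls ..."""

    df: pd.DataFrame  # columns: chrom, start, end[, label]
    name: str = ""

    def __post_init__(self):
        df = self.df
        if (df["start"] >= df["end"]).any():
            raise ValueError("regions must satisfy start < end")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            out[chrom] = (grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64))
        return out

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {c: iv.merge(s, e) for c, (s, e) in self.by_chrom().items()}

    def total_length(self) -> int:
        """Covered nucleotides after merging overlaps."""
        return sum(iv.total_length(s, e) for s, e in self.merged_by_chrom().values())


@dataclass
class CountMatrix:
    """Per-bin counts, bins (rows, global genome order) x tracks (columns)."""

    genome: BinnedGenome
    counts: np.ndarray  # (T+1, D) non-negative integers
    track_names: tuple[str, ...]
    cell_type: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (bins x tracks)")
        if counts.shape[0] != self.genome.n_bins:
            raise ValueError(
                f"count rows ({counts.shape[0]}) != genome bins ({self.genome.n_bins})")
        if counts.shape[1] != len(self.track_names):
            raise ValueError("column count != number of track names")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        self.counts = counts
        self.track_names = tuple(self.track_names)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.counts.shape[1]


@dataclass
class SizeFactors:
    """Total-count library-size factors s_{d,l} over tracks x cell types.

    ``s_{d,l} = (1/r_{d,l}) * mean_k r_{d,k}`` where r_{d,l} is the read
    total of track d in cell type l; dividing counts by s (equivalently
    scaling emission means by s) puts all cell types on the mean library
    size of each track.
    """

    factors: pd.DataFrame  # index: track, columns: cell type
    library_sizes: pd.DataFrame

    def for_cell_type(self, cell_type: str, track_names) -> np.ndarray:
        return self.factors.loc[list(track_names), cell_type].to_numpy(float)

    def mean_scaling(self, cell_type: str, track_names) -> np.ndarray:
        """Emission-mean multiplier per track: r_{d,l} / mean_k r_{d,k} = 1/s.

        A library twice as deep as the track average has its per-state
        emission means doubled; the stored total-count factors s are the
        reciprocal (they normalize counts *to* the mean library).
        """
        return 1.0 / self.for_cell_type(cell_type, track_names)

    @staticmethod
    def ones(track_names, cell_types=("",)) -> "SizeFactors":
        df = pd.DataFrame(1.0, index=list(track_names), columns=list(cell_types))
        return SizeFactors(factors=df, library_sizes=df.copy())


def read_intervals(path, format: str = "bed", genome: BinnedGenome | None = None,
                   track: str = "", cell_type: str = ""):
    """Read a BED (3+ columns) or tagAlign (6 columns, strand in column 6) file.

    Returns a :class:`ReadSet` for tagAlign and a :class:`RegionSet` for BED.
    Records on chromosomes absent from ``genome`` (if given) are dropped and
    the dropped count logged.
    """
    if format not in ("bed", "tagAlign"):
        raise ValueError(f"unknown format {format!r}")
    chroms, starts, ends, strands, labels = [], [], [], [], []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {i}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
            if start < 0 or end < 0:
                raise FormatError(f"{path}: line {i}: negative coordinate")
            if start >= end:
                raise FormatError(f"{path}: line {i}: start >= end")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            if format == "tagAlign":
                if len(parts) < 6:
                    raise FormatError(f"{path}: line {i}: tagAlign needs 6 columns")
                strand = parts[5]
                if strand == "−":  # unicode minus
                    strand = "-"
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}: line {i}: bad strand {strand!r}")
                strands.append(strand)
            else:
                labels.append(parts[3] if len(parts) > 3 else "")
    df = pd.DataFrame({"chrom": chroms,
                       "start": np.asarray(starts, dtype=np.int64),
                       "end": np.asarray(ends, dtype=np.int64)})
    if genome is not None:
        keep = df["chrom"].isin(genome.chrom_names)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("%s: dropped %d records on chromosomes outside the genome",
                        path, n_drop)
        df = df[keep].reset_index(drop=True)
        if format == "tagAlign":
            strands = [s for s, k in zip(strands, keep) if k]
        else:
            labels = [s for s, k in zip(labels, keep) if k]
    if format == "tagAlign":
        df["strand"] = strands
        return ReadSet(df, track=track, cell_type=cell_type)
    df["label"] = labels
    return RegionSet(df, name=track)


def estimate_fragment_shift(reads: ReadSet, max_shift: int = 400) -> int:
    """Half the fragment length, from plus/minus 5'-end coverage cross-correlation.

    The lag f maximizing ``sum_pos plus[pos] * minus[pos + f]`` over
    ``f = 0..max_shift`` estimates the fragment length; the returned shift is
    ``f // 2``. Ties break toward the smallest lag.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    df = reads.df
    if not (df["strand"] == "+").any() or not (df["strand"] == "-").any():
        raise ValueError("cannot estimate shift: input lacks one strand")
    corr = np.zeros(max_shift + 1)
    for _, grp in df.groupby("chrom", sort=False):
        plus5 = grp.loc[grp["strand"] == "+", "start"].to_numpy(np.int64)
        minus5 = grp.loc[grp["strand"] == "-", "end"].to_numpy(np.int64) - 1
        if len(plus5) == 0 or len(minus5) == 0:
            continue
        hi = int(max(plus5.max(), minus5.max())) + 1
        cov_p = np.bincount(plus5, minlength=hi).astype(float)
        cov_m = np.bincount(minus5, minlength=hi).astype(float)
        for f in range(max_shift + 1):
            if f < hi:
                corr[f] += float(np.dot(cov_p[: hi - f], cov_m[f:hi]))
    best = int(np.argmax(corr))
    return best // 2


def bin_counts(reads: ReadSet, genome: BinnedGenome, shift: int = 0) -> np.ndarray:
    """Count shifted fragment midpoints per bin; returns one global-bin column.

    Midpoint is ``start + shift`` for plus-strand reads and ``end - 1 - shift``
    for minus-strand reads (shift from the 5' end toward the fragment middle).
    Midpoints shifted off the chromosome are clipped to the terminal base so
    every retained read is counted (conserving the library size).
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    column = np.zeros(genome.n_bins, dtype=np.int64)
    offsets = genome.chrom_offsets()
    lengths = genome.lengths
    n_clipped = 0
    for chrom, grp in reads.df.groupby("chrom", sort=False):
        if chrom not in lengths:
            logger.info("bin_counts: dropped %d reads on unknown chromosome %s",
                        len(grp), chrom)
            continue
        ln = lengths[chrom]
        plus = grp["strand"].to_numpy() == "+"
        mid = np.where(plus,
                       grp["start"].to_numpy(np.int64) + shift,
                       grp["end"].to_numpy(np.int64) - 1 - shift)
        clipped = (mid < 0) | (mid >= ln)
        n_clipped += int(clipped.sum())
        mid = np.clip(mid, 0, ln - 1)
        idx = offsets[chrom] + mid // genome.bin_width
        column += np.bincount(idx, minlength=genome.n_bins)
    if n_clipped:
        logger.info("bin_counts: clipped %d midpoints to chromosome ends", n_clipped)
    return column


def build_count_matrix(readsets: list[ReadSet], genome: BinnedGenome,
                       shift: int = 0, cell_type: str = "") -> CountMatrix:
    """Bin one ReadSet per track into a CountMatrix (shared shift)."""
    cols = [bin_counts(rs, genome, shift) for rs in readsets]
    names = tuple(rs.track or f"track{i}" for i, rs in enumerate(readsets))
    return CountMatrix(genome, np.column_stack(cols), names, cell_type=cell_type)


def compute_size_factors(count_matrices: list[CountMatrix]) -> SizeFactors:
    """Total-count size factors from one CountMatrix per cell type."""
    if not count_matrices:
        raise ValueError("need at least one count matrix")
    tracks = count_matrices[0].track_names
    for cm in count_matrices:
        if cm.track_names != tracks:
            raise ValueError("all cell types must provide the same tracks "
                             f"({cm.track_names} != {tracks})")
    cells = [cm.cell_type or f"cell{i}" for i, cm in enumerate(count_matrices)]
    if len(set(cells)) != len(cells):
        raise ValueError("duplicate cell-type labels")
    r = pd.DataFrame(
        {cell: cm.counts.sum(axis=0) for cell, cm in zip(cells, count_matrices)},
        index=list(tracks), dtype=float)
    if (r <= 0).any().any():
        bad = [(d, l) for d in r.index for l in r.columns if r.loc[d, l] <= 0]
        raise ValueError(f"empty library for track/cell type: {bad}")
    mean_lib = r.mean(axis=1)  # mean_k r_{d,k} per track
    s = (1.0 / r).mul(mean_lib, axis=0)
    return SizeFactors(factors=s, library_sizes=r)


_COUNTS_MAGIC = "#countseg_counts\tv1"


def write_counts(cm: CountMatrix, path) -> None:
    """Write a CountMatrix as a headered TSV (chrom, start, end, tracks...)."""
    g = cm.genome
    with open(path, "w") as fh:
        fh.write(_COUNTS_MAGIC + "\n")
        fh.write(f"#cell_type\t{cm.cell_type}\n")
        fh.write(f"#bin_width\t{g.bin_width}\n")
        chrom_spec = ",".join(f"{n}:{ln}" for n, ln in zip(g.chrom_names, g.chrom_lengths))
        fh.write(f"#chrom_lengths\t{chrom_spec}\n")
        table = g.bin_table()
        for name, col in zip(cm.track_names, cm.counts.T):
            table[name] = col
        table.to_csv(fh, sep="\t", index=False)


def read_counts(path, genome: BinnedGenome | None = None) -> CountMatrix:
    """Read a CountMatrix written by :func:`write_counts` (exact round-trip)."""
    meta = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _COUNTS_MAGIC:
            raise FormatError(f"{path}: not a countseg counts file")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line.rstrip("\n")[1:].partition("\t")
            meta[key] = val
            pos = fh.tell()
        table = pd.read_csv(fh, sep="\t")
    chrom_pairs = [p.split(":") for p in meta["chrom_lengths"].split(",")]
    file_genome = BinnedGenome(tuple(p[0] for p in chrom_pairs),
                               tuple(int(p[1]) for p in chrom_pairs),
                               int(meta["bin_width"]))
    if genome is not None and (genome.chrom_names != file_genome.chrom_names
                               or genome.chrom_lengths != file_genome.chrom_lengths
                               or genome.bin_width != file_genome.bin_width):
        raise ValueError(f"{path}: bin grid does not match the supplied genome")
    expected = file_genome.bin_table()
    got = table[["chrom", "start", "end"]].reset_index(drop=True)
    if len(got) != len(expected) or not (
            got["chrom"].equals(expected["chrom"])
            and np.array_equal(got["start"], expected["start"])
            and np.array_equal(got["end"], expected["end"])):
        raise ValueError(f"{path}: bin grid in file does not tile its genome header")
    track_names = tuple(c for c in table.columns if c not in ("chrom", "start", "end"))
    counts = table[list(track_names)].to_numpy(np.int64)
    return CountMatrix(file_genome, counts, track_names, cell_type=meta.get("cell_type", ""))
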