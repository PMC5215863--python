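"""Synthetic fixtures with known truth for every stage of the pipeline.

Generates HMM-simulated count tracks (the data-generating model the
segmentation assumes: a state path from (pi, A), counts from per-state
overdispersed emissions with cell-type size factors), planted reference
region sets for benchmarking, planted GWAS catalogs for the enrichment
statistics, and a minimal read-level generator for the binning code.

Every generator takes a mandatory seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from countseg import intervals as iv
from countseg.emissions import EmissionGrid, NegBinomParams, PoilogParams
from countseg.hmm import HMMModel
from countseg.io_binning import (
    BinnedGenome,
    CountMatrix,
    ReadSet,
    RegionSet,
    SizeFactors,
)
from countseg.segmentation import StateAnnotation


@dataclass
class SimulationTruth:
    """Everything needed to score a fit against the generating process."""

    model: HMMModel
    genome: BinnedGenome
    path: np.ndarray              # shared true state path (global bin order)
    depths: dict                  # cell type -> per-track relative depth
    seed: int


def default_model(K: int = 3, D: int = 2, family: str = "negbinom",
                  self_prob: float = 0.95, bin_width: int = 200,
                  size: float = 10.0, signal_mean: float = 30.0,
                  background_mean: float = 0.3,
                  cross_mean: float = 2.0) -> HMMModel:
    """A K-state, D-track model with mark-specific signal states.

    Emulates the structure of real chromatin data: state 0 is a
    low-coverage background (~0.3 reads/bin everywhere); each signal state
    is high in "its" track (30 reads/bin by default, like a promoter in
    H3K4me3 or an enhancer in H3K4me1) and low (~2) in the others. Signal
    states are entered from and mostly return to background, so background
    carries about half the stationary mass — the regime the Poisson-tail
    initialization thresholds assume. Self-transition probability defaults
    to 0.95, matching the kilobase-scale segments of real annotations at
    200 bp bins.
    """
    params = []
    for k in range(K):
        row = []
        for d in range(D):
            if k == 0:
                mu = background_mean
            elif d == (k - 1) % D:
                mu = signal_mean * (1.25 ** ((k - 1) // D))
            else:
                mu = cross_mean
            if family == "negbinom":
                row.append(NegBinomParams(mu=mu, size=size))
            else:
                sigma = 0.5
                row.append(PoilogParams(mu_log=float(np.log(mu)) - sigma ** 2 / 2,
                                        sigma=sigma))
        params.append(row)
    pi = np.full(K, 1.0 / K)
    exit_prob = 1.0 - self_prob
    A = np.zeros((K, K))
    A[0, 0] = self_prob
    A[0, 1:] = exit_prob / (K - 1)
    for k in range(1, K):
        A[k, k] = self_prob
        A[k, 0] = exit_prob * 0.9  # signal states mostly return to background
        others = [j for j in range(1, K) if j != k]
        for j in others:
            A[k, j] = exit_prob * 0.1 / len(others)
        A[k] /= A[k].sum()
    tracks = tuple(f"mark{d + 1}" for d in range(D))
    return HMMModel(initial_probs=pi, transitions=A,
                    emissions=EmissionGrid(family, params),
                    track_names=tracks, bin_width=bin_width)


def _sample_path(model: HMMModel, T: int, rng: np.random.Generator) -> np.ndarray:
    cum_pi = np.cumsum(model.initial_probs)
    cum_A = np.cumsum(model.transitions, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(cum_pi, u[0])
    for t in range(1, T):
        path[t] = np.searchsorted(cum_A[path[t - 1]], u[t])
    return path


def _sample_counts(model: HMMModel, path: np.ndarray, s: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    T = len(path)
    D = len(model.track_names)
    counts = np.zeros((T, D), dtype=np.int64)
    for k in range(model.n_states):
        sel = path == k
        n = int(sel.sum())
        if n == 0:
            continue
        for d in range(D):
            p = model.emissions.params[k][d]
            if model.family == "negbinom":
                # NB as Poisson-Gamma: lambda ~ Gamma(r, mu*s/r)
                lam = rng.gamma(p.size, p.mu * s[d] / p.size, size=n)
            else:
                lam = np.exp(rng.normal(p.mu_log + np.log(s[d]), p.sigma, size=n))
            counts[sel, d] = rng.poisson(lam)
    return counts


def simulate_hmm_counts(model: HMMModel, genome: BinnedGenome,
                        depths: dict | None = None,
                        seed: int = 0) -> tuple[dict[str, CountMatrix], SimulationTruth]:
    """Simulate one state path and per-cell-type count matrices from it.

    All cell types share the state path (chromatin state is a property of
    the genome); their counts differ by independent emission noise and by
    ``depths``, the relative sequencing depth of each cell type (scalar or
    per-track vector) that multiplies every emission mean.
    """
    if depths is None:
        depths = {"cell0": 1.0}
    rng = np.random.default_rng(seed)
    T = genome.n_bins
    path = _sample_path(model, T, rng)
    D = len(model.track_names)
    out = {}
    norm_depths = {}
    for cell, dep in depths.items():
        s = np.broadcast_to(np.asarray(dep, dtype=float), (D,)).copy()
        norm_depths[cell] = s
        counts = _sample_counts(model, path, s, rng)
        out[cell] = CountMatrix(genome, counts, model.track_names, cell_type=cell)
    truth = SimulationTruth(model=model, genome=genome, path=path,
                            depths=norm_depths, seed=seed)
    return out, truth


# ---------------------------------------------------------------------------
# planted region sets and catalogs

def _interval_arrays(annotation: StateAnnotation, states) -> tuple[list, np.ndarray]:
    """(chrom, start, end) rows of the given states and their widths."""
    sel = annotation.segments[annotation.segments["state"].isin(list(states))]
    rows = list(sel[["chrom", "start", "end"]].itertuples(index=False, name=None))
    widths = (sel["end"] - sel["start"]).to_numpy(np.int64)
    return rows, widths


def _complement_intervals(annotation: StateAnnotation, states) -> tuple[list, np.ndarray]:
    rows = []
    sel = annotation.segments[~annotation.segments["state"].isin(list(states))]
    rows = list(sel[["chrom", "start", "end"]].itertuples(index=False, name=None))
    widths = (sel["end"] - sel["start"]).to_numpy(np.int64)
    return rows, widths


def _sample_positions(rows, widths, n, rng) -> list[tuple[str, int, int, int]]:
    """n positions uniform over the union of the given intervals.

    Returns (chrom, position, interval_start, interval_end) so callers can
    keep planted features inside the interval they landed in.
    """
    cum = np.cumsum(widths)
    total = cum[-1]
    u = rng.integers(0, total, size=n)
    idx = np.searchsorted(cum, u, side="right")
    out = []
    for k, i in enumerate(idx):
        chrom, start, end = rows[i]
        off = int(u[k] - (cum[i] - widths[i]))
        out.append((chrom, start + off, start, end))
    return out


def plant_reference_regions(annotation: StateAnnotation, target_state: int,
                            precision_in_state: float, n_regions: int,
                            width: int = 100, seed: int = 0) -> RegionSet:
    """Reference regions with a stated fraction lying inside a state.

    Each region is ``width`` bp around a uniformly drawn position, inside a
    segment of ``target_state`` with probability ``precision_in_state`` and
    outside otherwise; regions are clipped to the segment they landed in,
    so a planted "inside" region never spills into a neighboring state.
    Enables known-answer precision/recall/AUC tests.
    """
    if not 0 <= precision_in_state <= 1:
        raise ValueError("precision_in_state must be in [0, 1]")
    rng = np.random.default_rng(seed)
    in_rows, in_w = _interval_arrays(annotation, [target_state])
    if len(in_rows) == 0:
        raise ValueError(f"state {target_state} has no segments")
    out_rows, out_w = _complement_intervals(annotation, [target_state])
    inside = rng.random(n_regions) < precision_in_state
    n_in = int(inside.sum())
    pts = _sample_positions(in_rows, in_w, n_in, rng) if n_in else []
    pts += (_sample_positions(out_rows, out_w, n_regions - n_in, rng)
            if n_regions - n_in else [])
    recs = []
    for chrom, pos, seg_start, seg_end in pts:
        half = width // 2
        start = max(seg_start, pos - half)
        end = min(seg_end, start + width)
        start = max(seg_start, min(start, end - width))
        recs.append((chrom, start, end, ""))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "label"])
    return RegionSet(df, name="planted_reference")


def plant_snps(annotation: StateAnnotation, enhancer_states,
               density_ratio: float, n_snps: int = 200,
               n_background: int = 1000, n_traits: int = 4, seed: int = 0,
               randomize_sizes: bool = True) -> pd.DataFrame:
    """A GWAS-catalog-like table with one trait enriched in enhancer states.

    The focal trait ("trait_enriched") places its SNPs with density ratio
    ``density_ratio`` inside enhancer segments versus elsewhere; background
    traits are uniform over the genome. Trait sizes are Poisson-jittered
    around their nominal values by default (floored at 20 so every trait
    passes the minimum-variant filter), mimicking the variable study sizes
    of a real catalog.
    """
    if n_snps == 0 and n_background == 0:
        return pd.DataFrame(columns=["chrom", "pos", "trait"])
    rng = np.random.default_rng(seed)
    enh_rows, enh_w = _interval_arrays(annotation, list(enhancer_states))
    rest_rows, rest_w = _complement_intervals(annotation, list(enhancer_states))
    E = int(enh_w.sum())
    R = int(rest_w.sum())
    p_enh = density_ratio * E / (density_ratio * E + R)

    def place(n):
        k = int(rng.binomial(n, p_enh)) if n else 0
        pts = _sample_positions(enh_rows, enh_w, k, rng) if k else []
        pts += _sample_positions(rest_rows, rest_w, n - k, rng) if n - k else []
        return [(c, p) for c, p, _, _ in pts]

    def place_uniform(n):
        rows = enh_rows + rest_rows
        widths = np.concatenate([enh_w, rest_w])
        return [(c, p) for c, p, _, _ in
                (_sample_positions(rows, widths, n, rng) if n else [])]

    recs = []
    n_focal = (max(20, int(rng.poisson(n_snps))) if randomize_sizes and n_snps
               else n_snps)
    for chrom, pos in place(n_focal):
        recs.append((chrom, pos, "trait_enriched"))
    if n_background and n_traits:
        base = n_background // n_traits
        for j in range(n_traits):
            nb = (max(20, int(rng.poisson(base))) if randomize_sizes else base)
            for chrom, pos in place_uniform(nb):
                recs.append((chrom, pos, f"trait_bg{j}"))
    return pd.DataFrame(recs, columns=["chrom", "pos", "trait"])


# ---------------------------------------------------------------------------
# read-level generator (only to exercise the binning code)

def simulate_read_pairs(genome: BinnedGenome, n_pairs: int, lag: int,
                        read_length: int = 36, seed: int = 0,
                        jitter: int = 0) -> ReadSet:
    """Plus/minus read pairs whose 5' ends are ``lag`` bp apart.

    Emulates single-end ChIP fragments: the plus-strand 5' end at p and the
    minus-strand 5' end at p + lag (+- uniform jitter), so strand
    cross-correlation peaks at ``lag`` and the estimated half-fragment
    shift is ``lag // 2``.
    """
    rng = np.random.default_rng(seed)
    chroms, starts, ends, strands = [], [], [], []
    names = list(genome.chrom_names)
    lens = np.array([genome.lengths[c] for c in names], dtype=np.int64)
    margin = lag + read_length + abs(jitter) + 1
    probs = lens / lens.sum()
    which = rng.choice(len(names), size=n_pairs, p=probs)
    for i in range(n_pairs):
        c = names[which[i]]
        ln = int(lens[which[i]])
        p = int(rng.integers(margin, max(margin + 1, ln - margin)))
        j = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        minus5 = p + lag + j
        chroms += [c, c]
        starts += [p, minus5 - read_length + 1]
        ends += [p + read_length, minus5 + 1]
        strands += ["+", "-"]
    df = pd.DataFrame({"chrom": chroms,
                       "start": np.asarray(starts, np.int64),
                       "end": np.asarray(ends, np.int64),
                       "strand": strands})
    return ReadSet(df, track="synthetic", cell_type="sim")
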