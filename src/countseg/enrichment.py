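"""TF enrichment in states, TF-TF co-binding, and GWAS trait enrichment.

TF enrichment compares the density of a factor's peak nucleotides inside a
state with its genome-wide density: e = (TF_s^nt / TF^nt) / (s^nt / l).
GWAS enrichment tests each trait's SNPs against the rest of the catalog for
over-representation in a state group (promoters or enhancers) with a
one-sided Fisher's exact test, Benjamini-Yekutieli adjusted across all
(trait, cell type) tests. Coverage-controlled recall subsamples whole
segments to a fixed genomic coverage so methods predicting wider regions
are not trivially favored.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from countseg import intervals as iv
from countseg.io_binning import BinnedGenome, RegionSet
from countseg.segmentation import StateAnnotation

logger = logging.getLogger(__name__)


def tf_state_enrichment(tf_peaks: RegionSet, annotation: StateAnnotation,
                        genome: BinnedGenome | None = None) -> pd.DataFrame:
    """Per-state enrichment e = (TF_s^nt/TF^nt)/(s^nt/l), normalized to sum 1.

    Peak and state overlaps are counted in nucleotides on merged intervals;
    l is the genome length.
    """
    genome = genome or annotation.genome
    peaks = tf_peaks.merged_by_chrom()
    tf_nt = sum(iv.total_length(s, e) for s, e in peaks.values())
    if tf_nt == 0:
        raise ValueError("TF peak set covers zero nucleotides")
    l = genome.genome_length
    s_nt = annotation.state_nucleotides()
    e_vals = np.zeros(annotation.n_states)
    for k in range(annotation.n_states):
        state_iv = annotation.state_regions(k).merged_by_chrom()
        tf_s = sum(iv.intersect_length(*peaks[c], *state_iv[c])
                   for c in state_iv if c in peaks)
        if s_nt[k] > 0:
            e_vals[k] = (tf_s / tf_nt) / (s_nt[k] / l)
    total = e_vals.sum()
    norm = e_vals / total if total > 0 else e_vals
    return pd.DataFrame({"state": list(annotation.state_labels),
                         "enrichment": e_vals, "normalized": norm})


def _sites_in_state(peaks: RegionSet, state_iv) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Peak sites (un-merged) overlapping the state's merged intervals."""
    out = {}
    for chrom, (s, e) in peaks.by_chrom().items():
        if chrom not in state_iv:
            continue
        keep = iv.overlaps_any(s, e, *state_iv[chrom])
        if keep.any():
            out[chrom] = (s[keep], e[keep])
    return out


def _greedy_overlap_pairs(a_starts, a_ends, b_starts, b_ends) -> int:
    """Maximum 1-1 matching of overlapping interval pairs (two-pointer greedy)."""
    i = j = n = 0
    while i < len(a_starts) and j < len(b_starts):
        if min(a_ends[i], b_ends[j]) > max(a_starts[i], b_starts[j]):
            n += 1
            i += 1
            j += 1
        elif a_ends[i] <= b_starts[j]:
            i += 1
        else:
            j += 1
    return n


def cobinding_rate(tf_a: RegionSet, tf_b: RegionSet,
                   annotation: StateAnnotation, state: int,
                   mode: str = "sites") -> float:
    """Jaccard co-binding of two TFs within one chromatin state.

    ``sites`` mode (default): co-occurrences are 1-1 matched overlapping
    site pairs among sites intersecting the state; Jaccard =
    n_co / (|A| + |B| - n_co). ``nucleotides`` mode: intersection over
    union of peak nucleotides within the state.
    """
    state_iv = annotation.state_regions(state).merged_by_chrom()
    if mode == "nucleotides":
        inter = union = 0
        a_m = {c: iv.merge(*v) for c, v in _sites_in_state(tf_a, state_iv).items()}
        b_m = {c: iv.merge(*v) for c, v in _sites_in_state(tf_b, state_iv).items()}
        for c in set(a_m) | set(b_m):
            sa, ea = a_m.get(c, (np.array([], np.int64),) * 2)
            sb, eb = b_m.get(c, (np.array([], np.int64),) * 2)
            inter += iv.intersect_length(sa, ea, sb, eb)
            us, ue = iv.merge(np.concatenate([sa, sb]), np.concatenate([ea, eb]))
            union += iv.total_length(us, ue)
        if union == 0:
            logger.warning("cobinding_rate: both TF sets empty in state")
            return 0.0
        return inter / union
    if mode != "sites":
        raise ValueError(f"unknown mode {mode!r}")
    a_in = _sites_in_state(tf_a, state_iv)
    b_in = _sites_in_state(tf_b, state_iv)
    n_a = sum(len(v[0]) for v in a_in.values())
    n_b = sum(len(v[0]) for v in b_in.values())
    if n_a + n_b == 0:
        logger.warning("cobinding_rate: both TF sets empty in state")
        return 0.0
    n_co = sum(_greedy_overlap_pairs(*a_in[c], *b_in[c])
               for c in a_in if c in b_in)
    return n_co / (n_a + n_b - n_co)


def _snp_in_regions(catalog: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    by_chrom = regions.merged_by_chrom()
    mask = np.zeros(len(catalog), dtype=bool)
    for chrom, grp in catalog.groupby("chrom", sort=False):
        if chrom in by_chrom:
            mask[grp.index.to_numpy()] = iv.points_in(
                grp["pos"].to_numpy(np.int64), *by_chrom[chrom])
    return mask


def gwas_enrichment(catalog: pd.DataFrame, regions_by_cell: dict[str, RegionSet],
                    min_variants: int = 20, alternative: str = "greater"
                    ) -> pd.DataFrame:
    """Trait-wise Fisher tests of SNP overlap with a state group per cell type.

    ``catalog`` needs columns (chrom, pos, trait) with 0-based positions;
    ``regions_by_cell`` maps cell type to its promoter or enhancer regions.
    Each trait with >= min_variants SNPs is tested against the rest of the
    catalog as background; p-values are Benjamini-Yekutieli adjusted across
    all (trait, cell type) tests.
    """
    for col in ("chrom", "pos", "trait"):
        if col not in catalog.columns:
            raise ValueError(f"catalog lacks required column {col!r}")
    catalog = catalog.reset_index(drop=True)
    trait_sizes = catalog["trait"].value_counts()
    traits = [t for t in trait_sizes.index if trait_sizes[t] >= min_variants]
    rows = []
    for cell, regions in regions_by_cell.items():
        in_reg = _snp_in_regions(catalog, regions)
        for trait in traits:
            is_trait = (catalog["trait"] == trait).to_numpy()
            a = int((is_trait & in_reg).sum())
            b = int((is_trait & ~in_reg).sum())
            c = int((~is_trait & in_reg).sum())
            d = int((~is_trait & ~in_reg).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            rows.append((trait, cell, a, b, c, d, odds, p))
    res = pd.DataFrame(rows, columns=["trait", "cell_type", "n_in", "n_out",
                                      "bg_in", "bg_out", "odds_ratio", "p_value"])
    if len(res):
        res["p_adjusted"] = multipletests(res["p_value"], method="fdr_by")[1]
    else:
        res["p_adjusted"] = []
    return res


def coverage_controlled_recall(state_regions: RegionSet, snps: pd.DataFrame,
                               genome: BinnedGenome, coverage_target: float,
                               n_samples: int = 100, seed: int = 0) -> dict:
    """Recall and SNP frequency after subsampling segments to fixed coverage.

    Whole segments are drawn uniformly without replacement until their
    cumulative width first reaches ``coverage_target * genome_length``
    (overshoot on the final draw allowed). Per sample: recall = fraction of
    SNPs inside sampled segments, frequency = SNPs per sampled bp. Returns
    medians and empirical 95% CIs over ``n_samples`` draws.
    """
    if not 0 < coverage_target <= 1:
        raise ValueError("coverage_target must be in (0, 1]")
    rng = np.random.default_rng(seed)
    df = state_regions.df
    widths = (df["end"] - df["start"]).to_numpy(np.int64)
    target_bp = coverage_target * genome.genome_length
    pos_by_chrom = {c: g["pos"].to_numpy(np.int64)
                    for c, g in snps.groupby("chrom", sort=False)}
    n_snps = sum(len(v) for v in pos_by_chrom.values())

    def sample_once():
        if widths.sum() <= target_bp:
            idx = np.arange(len(df))
        else:
            perm = rng.permutation(len(df))
            cum = np.cumsum(widths[perm])
            k = int(np.searchsorted(cum, target_bp, side="left")) + 1
            idx = perm[:k]
        sampled_bp = int(widths[idx].sum())
        sub = df.iloc[idx]
        hit = 0
        for chrom, grp in sub.groupby("chrom", sort=False):
            if chrom in pos_by_chrom:
                ms, me = iv.merge(grp["start"].to_numpy(), grp["end"].to_numpy())
                hit += int(iv.points_in(pos_by_chrom[chrom], ms, me).sum())
        recall = hit / n_snps if n_snps else 0.0
        freq = hit / sampled_bp if sampled_bp else 0.0
        return recall, freq

    draws = np.array([sample_once() for _ in range(n_samples)])
    rec, freq = draws[:, 0], draws[:, 1]
    return {
        "median_recall": float(np.median(rec)),
        "recall_ci": (float(np.percentile(rec, 2.5)), float(np.percentile(rec, 97.5))),
        "median_frequency": float(np.median(freq)),
        "frequency_ci": (float(np.percentile(freq, 2.5)),
                         float(np.percentile(freq, 97.5))),
        "n_samples": n_samples,
    }
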