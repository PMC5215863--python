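"""Benchmarking a segmentation against reference regions.

A segmentation is turned into a binary classifier: each state is scored by
its precision at recalling the reference (fraction of the state's units
overlapping the reference), states are sorted by decreasing precision, and
cumulative recall/FDR and an AUC are computed by adding states in that
order. Works at segment level or at the bin level the model was fit on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from countseg import intervals as iv
from countseg.io_binning import BinnedGenome, RegionSet
from countseg.segmentation import StateAnnotation


def reference_bin_mask(reference: RegionSet, genome: BinnedGenome,
                       min_overlap: int = 1) -> np.ndarray:
    """Boolean mask over global bins: bin overlaps the reference >= min_overlap bp."""
    w = genome.bin_width
    offsets = genome.chrom_offsets()
    lengths = genome.lengths
    nbins = genome.n_bins_per_chrom()
    nb_by_chrom = dict(zip(genome.chrom_names, nbins))
    mask = np.zeros(genome.n_bins, dtype=bool)
    for chrom, (starts, ends) in reference.merged_by_chrom().items():
        if chrom not in offsets:
            continue
        off = offsets[chrom]
        ln = lengths[chrom]
        nb = nb_by_chrom[chrom]
        for s, e in zip(starts, ends):
            e = min(int(e), ln)
            if e <= s:
                continue
            b0, b1 = int(s) // w, -(-int(e) // w)
            b1 = min(b1, nb)
            bins = np.arange(b0, b1)
            ov = np.minimum(e, (bins + 1) * w) - np.maximum(s, bins * w)
            sel = bins[ov >= min_overlap]
            mask[off + sel] = True
    return mask


def _segment_overlap_flags(annotation: StateAnnotation, reference: RegionSet,
                           min_overlap: int = 1) -> np.ndarray:
    """Per segment (annotation row order): overlaps reference >= min_overlap bp."""
    ref = reference.merged_by_chrom()
    flags = np.zeros(len(annotation.segments), dtype=bool)
    pos = 0
    for chrom, grp in annotation.segments.groupby("chrom", sort=False):
        n = len(grp)
        if chrom in ref:
            rs, re = ref[chrom]
            flags[pos:pos + n] = iv.overlaps_any(
                grp["start"].to_numpy(), grp["end"].to_numpy(), rs, re,
                min_overlap=min_overlap)
        pos += n
    return flags


def state_precision_ranking(annotation: StateAnnotation, reference: RegionSet,
                            level: str = "bin",
                            min_overlap: int = 1) -> pd.DataFrame:
    """States sorted by decreasing precision for recalling the reference.

    Segment level: precision(S) = fraction of S's segments overlapping the
    reference. Bin level: fraction of S's bins that are reference ("true")
    bins. Ties break by state label order.
    """
    if len(annotation.segments) == 0:
        raise ValueError("empty annotation")
    K = annotation.n_states
    if level == "segment":
        flags = _segment_overlap_flags(annotation, reference, min_overlap)
        states = annotation.segments["state"].to_numpy()
        hits = np.bincount(states, weights=flags, minlength=K)
        totals = np.bincount(states, minlength=K)
    elif level == "bin":
        truth = reference_bin_mask(reference, annotation.genome, min_overlap)
        path = annotation.bin_states()
        hits = np.bincount(path, weights=truth, minlength=K).astype(float)
        totals = np.bincount(path, minlength=K)
    else:
        raise ValueError(f"unknown level {level!r}")
    with np.errstate(invalid="ignore"):
        precision = np.where(totals > 0, hits / np.maximum(totals, 1), 0.0)
    order = np.lexsort((np.arange(K), -precision))  # ties -> lower label index
    return pd.DataFrame({
        "state": [annotation.state_labels[k] for k in order],
        "state_index": order,
        "precision": precision[order],
        "rank": np.arange(1, K + 1),
        "n_units": totals[order],
    })


def cumulative_recall_fdr(ranking: pd.DataFrame, annotation: StateAnnotation,
                          reference: RegionSet, level: str = "bin",
                          min_overlap: int = 1) -> pd.DataFrame:
    """Cumulative recall and FDR as states are added in ranking order.

    Recall counts reference units (merged regions at segment level, true
    bins at bin level) overlapped by the union of added states; FDR is the
    fraction of added predicted units not overlapping the reference.
    """
    rows = []
    if level == "bin":
        truth = reference_bin_mask(reference, annotation.genome, min_overlap)
        n_true = int(truth.sum())
        path = annotation.bin_states()
        included = np.zeros(annotation.genome.n_bins, dtype=bool)
        for _, rank_row in ranking.iterrows():
            included |= path == rank_row["state_index"]
            tp = int((included & truth).sum())
            npred = int(included.sum())
            rows.append((rank_row["state"],
                         tp / n_true if n_true else 0.0,
                         (npred - tp) / npred if npred else 0.0))
    elif level == "segment":
        flags = _segment_overlap_flags(annotation, reference, min_overlap)
        states = annotation.segments["state"].to_numpy()
        ref_merged = reference.merged_by_chrom()
        n_ref = sum(len(s) for s, _ in ref_merged.values())
        included_states: list[int] = []
        for _, rank_row in ranking.iterrows():
            included_states.append(int(rank_row["state_index"]))
            sel = np.isin(states, included_states)
            npred = int(sel.sum())
            fdr = (npred - int(flags[sel].sum())) / npred if npred else 0.0
            # recall over merged reference regions hit by any included segment
            hit = 0
            seg = annotation.segments[sel]
            seg_by_chrom = {c: (g["start"].to_numpy(), g["end"].to_numpy())
                            for c, g in seg.groupby("chrom", sort=False)}
            for chrom, (rs, re) in ref_merged.items():
                if chrom in seg_by_chrom:
                    ss, se = seg_by_chrom[chrom]
                    ms, me = iv.merge(ss, se)
                    hit += int(iv.overlaps_any(rs, re, ms, me,
                                               min_overlap=min_overlap).sum())
            rows.append((rank_row["state"],
                         hit / n_ref if n_ref else 0.0, fdr))
    else:
        raise ValueError(f"unknown level {level!r}")
    return pd.DataFrame(rows, columns=["state", "recall", "fdr"])


def auc_score(annotation: StateAnnotation, reference: RegionSet,
              level: str = "bin", min_overlap: int = 1) -> float:
    """AUC of the rank-scored segmentation as a reference-bin classifier.

    Every bin is scored by its state's precision rank (most precise state =
    highest score); ties across bins of one state get the standard
    trapezoidal treatment.
    """
    if level != "bin":
        raise ValueError("AUC is defined at bin level")
    truth = reference_bin_mask(reference, annotation.genome, min_overlap)
    if truth.all() or not truth.any():
        raise ValueError("degenerate condition: reference covers all or no bins")
    ranking = state_precision_ranking(annotation, reference, level="bin",
                                      min_overlap=min_overlap)
    K = annotation.n_states
    score_of_state = np.empty(K)
    # rank 1 (most precise) -> highest score
    score_of_state[ranking["state_index"].to_numpy()] = \
        K - ranking["rank"].to_numpy(float)
    scores = score_of_state[annotation.bin_states()]
    return float(roc_auc_score(truth, scores))
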