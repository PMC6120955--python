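"""Pairwise correlation analyses of event and fluorescence data.

Covers the within- and across-area pairwise correlation structure:
Pearson correlations of Gaussian-smoothed event trains, distance-binned
correlation curves, inter-areal group comparisons, thresholded
correlation graphs, functional soma-to-axonal-bouton matching, and
pixel-wise seed correlation maps of movies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .traces import EventMatrix, detect_peak_events, gaussian_filter_zero_phase


class CorrelationError(ValueError):
    """Invalid inputs for a correlation analysis."""


def pearson_rows(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
    """Pearson correlation between rows of ``a`` (and rows of ``b``).

    Returns the (na x nb) matrix of correlations; rows with zero
    variance yield NaN entries.
    """
    a = np.asarray(a, dtype=float)
    a0 = a - a.mean(axis=1, keepdims=True)
    sa = np.sqrt((a0**2).sum(axis=1))
    if b is None:
        b0, sb = a0, sa
    else:
        b = np.asarray(b, dtype=float)
        if b.shape[1] != a.shape[1]:
            raise CorrelationError("row length mismatch between the two sets")
        b0 = b - b.mean(axis=1, keepdims=True)
        sb = np.sqrt((b0**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = (a0 @ b0.T) / np.outer(sa, sb)
    cc[sa == 0, :] = np.nan
    cc[:, sb == 0] = np.nan
    return cc


def filtered_event_cc_matrix(
    ev: EventMatrix,
    sigma_s: float = 0.1,
    centroids_um: np.ndarray | None = None,
    area_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson CCs of Gaussian-smoothed event trains.

    ``sigma_s`` defaults to 0.1 s for soma-soma pairs (0.5 s is the
    convention for soma-axon pairs).  Each unordered pair appears once;
    pairs involving a zero-variance unit are dropped and logged via a
    warning.  When centroids are given the table carries the Euclidean
    inter-centroid distance (µm); area labels are carried through.
    """
    if ev.n_units < 2:
        raise CorrelationError("need at least 2 units")
    if ev.n_frames < 10:
        raise CorrelationError("need at least 10 frames")
    filtered = gaussian_filter_zero_phase(ev, sigma_s)
    cc = pearson_rows(filtered.values)
    iu, ju = np.triu_indices(ev.n_units, k=1)
    ccs = cc[iu, ju]
    ok = ~np.isnan(ccs)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} pair(s) dropped (zero-variance unit)",
            stacklevel=2,
        )
    ids = np.asarray(ev.unit_ids)
    table = pd.DataFrame(
        {
            "unit_i": ids[iu[ok]],
            "unit_j": ids[ju[ok]],
            "cc": ccs[ok],
        }
    )
    if centroids_um is not None:
        centroids_um = np.asarray(centroids_um, dtype=float)
        d = np.linalg.norm(centroids_um[iu[ok]] - centroids_um[ju[ok]], axis=1)
        table["distance_um"] = d
    if area_labels is not None:
        area_labels = np.asarray(area_labels)
        table["area_i"] = area_labels[iu[ok]]
        table["area_j"] = area_labels[ju[ok]]
    return table


def distance_binned_cc(table: pd.DataFrame, bin_um: float = 250.0) -> pd.DataFrame:
    """Mean ± s.e.m. of pairwise CC in distance bins [0,b), [b,2b), ...

    Bins with no pairs are absent from the output rather than zero.
    """
    if "distance_um" not in table:
        raise CorrelationError("table has no distance column")
    bins = np.floor(table["distance_um"].to_numpy() / bin_um).astype(int)
    grouped = table.assign(bin=bins).groupby("bin")["cc"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    out["bin_start_um"] = out["bin"] * bin_um
    out["bin_stop_um"] = (out["bin"] + 1) * bin_um
    return out[["bin_start_um", "bin_stop_um", "mean", "sem", "count"]]


def inter_area_cc_compare(table: pd.DataFrame) -> dict:
    """Group pairwise CCs by member areas and compare groups.

    Pairs are grouped by the unordered set of their two units' area
    labels (e.g. RFA-CFA, RFA-MID, CFA-MID).  Returns per-group mean CC
    and two-sided Wilcoxon rank-sum p-values between every group pair;
    groups with fewer than 2 pairs are skipped.
    """
    if "area_i" not in table or "area_j" not in table:
        raise CorrelationError("table has no area labels")
    key = [
        "-".join(sorted((str(a), str(b))))
        for a, b in zip(table["area_i"], table["area_j"])
    ]
    groups = table.assign(group=key).groupby("group")["cc"]
    means = groups.mean().to_dict()
    samples = {g: s.to_numpy() for g, s in groups}
    pvals = {}
    names = sorted(samples)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            if len(samples[g1]) < 2 or len(samples[g2]) < 2:
                continue
            stat = stats.ranksums(samples[g1], samples[g2])
            pvals[f"{g1} vs {g2}"] = float(stat.pvalue)
    counts = {g: int(len(s)) for g, s in samples.items()}
    return {"group_means": means, "group_counts": counts, "p_values": pvals}


def correlation_graph(table: pd.DataFrame, threshold: float = 0.45) -> pd.DataFrame:
    """Edges (pairs) with pairwise CC above ``threshold``."""
    return table[table["cc"] > threshold].reset_index(drop=True)


@dataclass
class SomaAxonMatchTable:
    """Soma-against-bouton correlation structure and candidate matches.

    ``cc`` is the (somata x boutons) CC matrix of the retained units;
    ``per_soma`` holds, per soma, the sorted top-k CCs, the mean and
    s.d. of its full CC distribution over boutons, and the z-score of
    its top CC; ``matches`` lists (soma, bouton) pairs passing the
    match criterion.
    """

    cc: pd.DataFrame
    per_soma: pd.DataFrame
    matches: pd.DataFrame
    retained_somata: np.ndarray
    retained_boutons: np.ndarray


def soma_axon_match(
    somata: EventMatrix,
    boutons: EventMatrix,
    sigma_s: float = 0.5,
    min_peaks: int = 10,
    peak_threshold_sd: float = 2.0,
    cc_threshold: float | None = 0.6,
    z_threshold: float | None = None,
    top_k: int = 15,
) -> SomaAxonMatchTable:
    """Functionally match distant axonal boutons to candidate parent somata.

    Events are smoothed with a wide Gaussian (default 0.5 s) to absorb
    field-to-field timing offsets, units with <= ``min_peaks`` peak
    events are discarded, and every retained soma is correlated against
    every retained bouton.  A bouton is a candidate match for a soma
    when its CC exceeds ``cc_threshold`` (absolute criterion) or, if
    ``z_threshold`` is given, when its z-score against that soma's own
    CC distribution (mean subtracted, divided by the distribution s.d.)
    exceeds it.
    """

    def _retain(ev: EventMatrix) -> np.ndarray:
        filt = gaussian_filter_zero_phase(ev, sigma_s)
        counts, _ = detect_peak_events(filt, threshold_sd=peak_threshold_sd)
        return counts > min_peaks

    keep_s = _retain(somata)
    keep_b = _retain(boutons)
    if not keep_s.any() or not keep_b.any():
        raise CorrelationError(
            f"no units retained after the >{min_peaks} peak-event filter "
            f"({int(keep_s.sum())} somata, {int(keep_b.sum())} boutons)"
        )
    soma_ids = np.asarray(somata.unit_ids)[keep_s]
    bouton_ids = np.asarray(boutons.unit_ids)[keep_b]
    fs = gaussian_filter_zero_phase(somata, sigma_s).values[keep_s]
    fb = gaussian_filter_zero_phase(boutons, sigma_s).values[keep_b]
    cc = pearson_rows(fs, fb)

    per_soma_rows = []
    match_rows = []
    for i, sid in enumerate(soma_ids):
        row = cc[i]
        valid = ~np.isnan(row)
        dist = row[valid]
        mean, sd = float(dist.mean()), float(dist.std())
        order = np.argsort(row[valid])[::-1]
        top = dist[order][:top_k]
        z_top = (top[0] - mean) / sd if sd > 0 else np.nan
        per_soma_rows.append(
            {
                "soma": sid,
                "top_cc": float(top[0]),
                "top_k_ccs": top.tolist(),
                "dist_mean": mean,
                "dist_sd": sd,
                "z_top": float(z_top),
            }
        )
        z_row = (row - mean) / sd if sd > 0 else np.full_like(row, np.nan)
        for j, bid in enumerate(bouton_ids):
            if np.isnan(row[j]):
                continue
            is_match = False
            if cc_threshold is not None and row[j] > cc_threshold:
                is_match = True
            if z_threshold is not None and z_row[j] > z_threshold:
                is_match = True
            if is_match:
                match_rows.append(
                    {"soma": sid, "bouton": bid, "cc": float(row[j]),
                     "z": float(z_row[j])}
                )
    return SomaAxonMatchTable(
        cc=pd.DataFrame(cc, index=soma_ids, columns=bouton_ids),
        per_soma=pd.DataFrame(per_soma_rows),
        matches=pd.DataFrame(match_rows, columns=["soma", "bouton", "cc", "z"]),
        retained_somata=soma_ids,
        retained_boutons=bouton_ids,
    )


def top_cc_zscore(top_cc: float, dist_mean: float, dist_sd: float) -> float:
    """z-score of a top CC against its distribution: (top - mean) / s.d."""
    if dist_sd <= 0:
        raise CorrelationError("distribution s.d. must be positive")
    return (top_cc - dist_mean) / dist_sd


def pixelwise_correlation_map(
    movie: np.ndarray, seed_trace: np.ndarray, moving_avg: int = 5
) -> np.ndarray:
    """Per-pixel Pearson CC of a smoothed movie against a seed trace.

    ``movie`` is (frames, y, x) on the same clock as ``seed_trace``;
    pixel traces are boxcar-averaged over ``moving_avg`` frames first.
    Zero-variance pixels map to NaN.
    """
    movie = np.asarray(movie, dtype=float)
    seed = np.asarray(seed_trace, dtype=float)
    if movie.ndim != 3 or movie.shape[0] != seed.size:
        raise CorrelationError("movie must be (frames, y, x) on the seed clock")
    smoothed = ndimage.uniform_filter1d(movie, size=moving_avg, axis=0, mode="nearest")
    flat = smoothed.reshape(movie.shape[0], -1).T
    cc = pearson_rows(flat, seed[None, :])[:, 0]
    return cc.reshape(movie.shape[1:])
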