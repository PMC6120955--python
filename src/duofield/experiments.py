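"""Reproduction experiments: the package's headline quantities.

Each function runs one self-contained experiment on synthetic data (or
closed-form inputs) and returns the quantities a user would quote:
device-geometry numbers, the worked soma-bouton z-score, affinity-
propagation recovery, the coupling calibration of the cross-area
covariation statistic, FWHM recovery, soma-axon match recovery, and the
movement-classifier false-positive rate.  ``scripts/acceptance.py`` and
the test suite both drive these, so the printed numbers always come
from the same code paths as the library itself.
"""

from __future__ import annotations

import numpy as np

from .correlations import pearson_rows, soma_axon_match, top_cc_zscore
from .geometry import (
    DeviceConfig,
    center_distance,
    ideal_dual_field_rate,
    observable_annulus,
    pixel_throughput,
    tilt_dmc_delta,
    beam_ellipticity,
)
from .pipeline import AnalysisConfig, run_covariation
from .population import (
    affinity_propagation,
    brute_force_exemplars,
    classify_movement_related,
)
from .psf import average_plane_repeats, characterize_bead
from .synthetic import (
    SessionSpec,
    gen_bead_volume,
    gen_dual_area_session,
    gen_soma_axon_session,
)
from .traces import EventMatrix


def geometry_closed_forms() -> dict[str, float]:
    """All printed device numbers from the default configuration."""
    cfg = DeviceConfig()
    annulus = observable_annulus(cfg)
    return {
        "center_distance_180deg_mm": center_distance(cfg, 180.0),
        "center_distance_60deg_mm": center_distance(cfg, 60.0),
        "max_observable_distance_mm": 2.0 * annulus.outer_radius,
        "ideal_dual_field_rate_hz": ideal_dual_field_rate(cfg, 60.0),
        "tilt_dmc_penalty_mm": tilt_dmc_delta(8.0, 5.0),
        "mirror_aspect_ratio": beam_ellipticity(cfg),
        "throughput_dual_512_5hz_mpix": pixel_throughput(512, 512, 2, 5.0) / 1e6,
        "throughput_quad_512_9p5hz_mpix": pixel_throughput(512, 512, 4, 9.5) / 1e6,
        "throughput_dual_512x256_30hz_mpix": pixel_throughput(512, 256, 2, 30.0)
        / 1e6,
        "throughput_gain_quad_vs_dual": pixel_throughput(512, 512, 4, 9.5)
        / pixel_throughput(512, 512, 2, 5.0),
        "resampled_rate_hz": 2.0 * 5.4,
        "move_window_end_s": 20 / 10.8,
    }


def soma_axon_zscore_worked_example() -> float:
    """z-score of a 0.78 top CC against a zero-mean, 0.12-s.d. distribution."""
    return top_cc_zscore(0.78, 0.0, 0.12)


def ap_planted_recovery(seed: int = 0, n_instances: int = 20) -> dict[str, float]:
    """AP on well-separated planted similarity matrices.

    Three balanced 20-trial clusters must be recovered exactly
    (ARI = 1); on balanced 2-cluster instances of <= 12 trials the
    partition must match an exhaustive exemplar-search oracle and the
    net-similarity score must tie the optimum.
    """
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(seed)
    labels3 = np.repeat([0, 1, 2], 20)
    S = np.where(labels3[:, None] == labels3[None, :], 0.9, 0.0)
    S = S + rng.normal(0, 0.03, S.shape)
    S = (S + S.T) / 2
    res = affinity_propagation(S)
    ari3 = adjusted_rand_score(labels3, res.labels)

    matched = 0
    score_gap = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 13))
        n1 = n // 2 + int(rng.integers(-1, 2))
        lab = np.array([0] * n1 + [1] * (n - n1))
        S2 = np.where(lab[:, None] == lab[None, :], 0.9, 0.0)
        S2 = S2 + rng.normal(0, 0.01, S2.shape)
        S2 = (S2 + S2.T) / 2
        ap = affinity_propagation(S2)
        ex, bf_labels, best = brute_force_exemplars(S2)
        Sd = S2.copy()
        np.fill_diagonal(Sd, ap.preference)
        members = np.setdiff1d(np.arange(n), ap.exemplars)
        ap_score = ap.exemplars.size * ap.preference + (
            Sd[np.ix_(members, ap.exemplars)].max(axis=1).sum() if members.size else 0.0
        )
        score_gap = max(score_gap, best - ap_score)
        if adjusted_rand_score(ap.labels, bf_labels) == 1.0 and ap.k == 2:
            matched += 1
    return {
        "ari_three_planted_clusters": float(ari3),
        "k_three_planted_clusters": float(res.k),
        "brute_force_match_fraction": matched / n_instances,
        "max_score_gap_vs_oracle": float(score_gap),
    }


def _session_report(coupling: float, seed: int, n_shuffles: int) -> dict:
    spec = SessionSpec(coupling=coupling, seed=seed)
    areas, truth = gen_dual_area_session(spec)
    cfg = AnalysisConfig(seed=seed, n_shuffles=n_shuffles)
    return run_covariation(
        {a: areas[a].events_field for a in ("RFA", "CFA")},
        truth.onset_times,
        cfg,
    )


def coupling_null_and_power(
    n_seeds: int = 50, n_shuffles: int = 1000, seed0: int = 0
) -> dict[str, float]:
    """Type-I calibration at zero coupling, power at coupling 0.5.

    At c = 0 the observed cross-area intra-cluster CC should fall inside
    its own shuffle null's central 95% band; at c = 0.5 it should exceed
    the null mean.
    """
    inband = power = 0
    intra_c05 = []
    null_c05 = []
    for i in range(n_seeds):
        rep0 = _session_report(0.0, seed0 + i, n_shuffles)
        if rep0["null_band_2p5"] <= rep0["intra_cluster_cc"] <= rep0["null_band_97p5"]:
            inband += 1
        rep5 = _session_report(0.5, seed0 + i, n_shuffles)
        if rep5["intra_cluster_cc"] > rep5["shuffle_null_mean"]:
            power += 1
        intra_c05.append(rep5["intra_cluster_cc"])
        null_c05.append(rep5["shuffle_null_mean"])
    return {
        "null_inband_fraction": inband / n_seeds,
        "coupled_power_fraction": power / n_seeds,
        "coupled_intra_cluster_cc": float(np.mean(intra_c05)),
        "coupled_shuffle_null_mean": float(np.mean(null_c05)),
    }


def coupling_agreement_sweep(
    couplings=(0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 20,
    seed0: int = 0,
) -> dict[str, float]:
    """Mean inter-cluster distance-agreement r per coupling level."""
    out = {}
    ks = []
    for c in couplings:
        rs = []
        for i in range(n_seeds):
            rep = _session_report(c, seed0 + i, n_shuffles=10)
            rs.append(rep.get("distance_agreement_r", np.nan))
            ks.append(rep["k_clusters"])
        out[f"agreement_r_coupling_{c:g}"] = float(np.nanmean(rs))
    out["mean_k_clusters"] = float(np.mean(ks))
    return out


def fwhm_recovery(
    n_beads: int = 50, snr: float = 20.0, seed0: int = 0
) -> dict[str, float]:
    """Median relative FWHM recovery error over synthetic beads."""
    errs = []
    for i in range(n_beads):
        frames, _ = gen_bead_volume(snr=snr, seed=seed0 + i)
        est = characterize_bead(average_plane_repeats(frames, 5))
        errs += [
            abs(est.lateral_x - 1.0),
            abs(est.lateral_y - 1.0),
            abs(est.axial - 10.0) / 10.0,
        ]
    return {"fwhm_median_rel_error": float(np.median(errs))}


def soma_axon_recovery(n_seeds: int = 5, seed0: int = 0) -> dict[str, float]:
    """Exact parentage recovery and the CC range of the planted cluster."""
    exact = 0
    ccs = []
    for i in range(n_seeds):
        soma, bout, _m, _sf, truth, _e = gen_soma_axon_session(
            movie_duration_s=0.1, seed=seed0 + i
        )
        table = soma_axon_match(soma, bout)
        want = {(p, b) for p, bs in truth.parentage.items() for b in bs}
        got = set(zip(table.matches["soma"], table.matches["bouton"]))
        if want == got:
            exact += 1
        for p, bs in truth.parentage.items():
            ccs += list(table.cc.loc[p, bs].to_numpy())
    return {
        "parentage_exact_fraction": exact / n_seeds,
        "parent_bouton_cc_min": float(np.min(ccs)),
        "parent_bouton_cc_mean": float(np.mean(ccs)),
        "parent_bouton_cc_max": float(np.max(ccs)),
    }


def movement_classifier_type_one(
    n_neurons: int = 1000, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """False-positive rate of the movement classifier on i.i.d. nulls."""
    rng = np.random.default_rng(seed)
    fs = 10.8
    n_frames = 2500
    onsets = np.arange(100, 2400, 60) / fs
    ev = EventMatrix(
        values=np.abs(rng.normal(0, 1, (n_neurons, n_frames))), frame_rate=fs
    )
    related, _, _ = classify_movement_related(ev, onsets, alpha=alpha)
    return {"classifier_false_positive_rate": float(related.mean())}


def pearson_oracle_deviation(seed: int = 0) -> dict[str, float]:
    """Worst deviation of the vectorized CC from the two-pass formula."""
    rng = np.random.default_rng(seed)
    a = rng.random((10, 80))
    cc = pearson_rows(a)
    worst = 0.0
    for i in range(10):
        for j in range(10):
            mx, my = a[i].mean(), a[j].mean()
            num = ((a[i] - mx) * (a[j] - my)).sum()
            den = np.sqrt(((a[i] - mx) ** 2).sum() * ((a[j] - my) ** 2).sum())
            worst = max(worst, abs(cc[i, j] - num / den))
    return {"pearson_max_abs_deviation": float(worst)}
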