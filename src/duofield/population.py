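"""Trial-to-trial population covariation between two cortical areas.

The core inference chain: classify neurons as movement-related (rank-sum
of event amplitudes in a movement window against a resting window),
build per-trial population vectors (time-averaged z-scored events of
movement-related neurons), cluster trials by the similarity of one
area's population vectors with affinity propagation, and ask whether
the *other* area's population vectors are more similar within those
clusters than a trial-label shuffle null predicts.  Inter-cluster
distance matrices computed per area and correlated against each other
quantify whether the two areas share the same cluster geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .correlations import pearson_rows
from .traces import EventMatrix


class PopulationError(ValueError):
    """Invalid inputs for a population-covariation analysis."""


# ---------------------------------------------------------------------------
# movement-related classification and population vectors


def classify_movement_related(
    ev: EventMatrix,
    onset_times: np.ndarray,
    move_win: tuple[int, int] = (-5, 20),
    rest_win: tuple[int, int] = (-25, -10),
    alpha: float = 0.05,
    two_sided: bool = False,
):
    """Movement-related mask via rank-sum of movement vs. resting samples.

    Windows are in resampled frames relative to each pull onset (the
    conventional (-5, 20) and (-25, -10) frames at 10.8 Hz are 0.46 s
    before to 1.85 s after, and 2.31 to 0.93 s before, the onset).  Per
    neuron, samples are pooled over trials and compared one-sided
    (movement larger); a neuron is related iff p < alpha and the
    movement-window mean exceeds the resting-window mean.  Trials whose
    windows leave the recording are dropped and reported.
    """
    clock = ev.clock()
    onset_idx = np.searchsorted(clock, np.asarray(onset_times, dtype=float))
    lo = min(move_win[0], rest_win[0])
    hi = max(move_win[1], rest_win[1])
    ok = (onset_idx + lo >= 0) & (onset_idx + hi < ev.n_frames)
    dropped = np.flatnonzero(~ok)
    if dropped.size:
        warnings.warn(
            f"{dropped.size} trial(s) dropped: window outside recording",
            stacklevel=2,
        )
    onset_idx = onset_idx[ok]
    if onset_idx.size == 0:
        raise PopulationError("no trial window fits inside the recording")

    def _pool(win: tuple[int, int]) -> np.ndarray:
        offs = np.arange(win[0], win[1] + 1)
        idx = (onset_idx[:, None] + offs[None, :]).ravel()
        return ev.values[:, idx]

    move = _pool(move_win)
    rest = _pool(rest_win)
    alternative = "two-sided" if two_sided else "greater"
    res = stats.mannwhitneyu(move, rest, alternative=alternative, axis=1)
    pvals = np.asarray(res.pvalue)
    # direction check on the means: event trains are sparse, so medians of
    # both windows are typically zero and carry no direction information
    larger = move.mean(axis=1) > rest.mean(axis=1)
    related = (pvals < alpha) & larger
    return related, pvals, np.flatnonzero(~ok)


@dataclass(frozen=True)
class PopulationMatrix:
    """Cells x trials matrix of window-averaged z-scored events for one area."""

    area: str
    matrix: np.ndarray
    trial_ids: np.ndarray
    unit_ids: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[1]


def build_population_matrix(
    ev: EventMatrix,
    onset_times: np.ndarray,
    related_mask: np.ndarray,
    move_win: tuple[int, int] = (-5, 20),
    area: str = "",
    trial_ids: np.ndarray | None = None,
) -> PopulationMatrix:
    """Per-trial population vectors of movement-related neurons.

    Each neuron is z-scored over the full session clock, the movement
    window of every trial is sliced, and the time dimension is averaged,
    giving one cells x trials matrix.  Zero-variance neurons are
    excluded with a warning.
    """
    onsets = np.asarray(onset_times, dtype=float)
    if onsets.size < 2:
        raise PopulationError("need at least 2 trials")
    related_mask = np.asarray(related_mask, dtype=bool)
    if not related_mask.any():
        raise PopulationError("no movement-related neurons")
    values = ev.values[related_mask]
    ids = np.asarray(ev.unit_ids)[related_mask]
    sd = values.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance neuron(s) excluded",
            stacklevel=2,
        )
        values, ids, sd = values[sd > 0], ids[sd > 0], sd[sd > 0]
    if values.shape[0] == 0:
        raise PopulationError("no neurons left after variance filter")
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]

    clock = ev.clock()
    onset_idx = np.searchsorted(clock, onsets)
    offs = np.arange(move_win[0], move_win[1] + 1)
    if onset_idx.min() + offs[0] < 0 or onset_idx.max() + offs[-1] >= ev.n_frames:
        raise PopulationError("a trial window leaves the recording")
    windows = z[:, (onset_idx[:, None] + offs[None, :])]  # cells x trials x time
    matrix = windows.mean(axis=2)
    if trial_ids is None:
        trial_ids = np.arange(onsets.size)
    return PopulationMatrix(
        area=area, matrix=matrix, trial_ids=np.asarray(trial_ids), unit_ids=ids
    )


def trial_similarity_matrix(
    pm: PopulationMatrix, kind: str = "cc"
) -> np.ndarray:
    """Trials x trials similarity: Pearson CC or negative squared Euclidean."""
    x = pm.matrix.T  # trials x cells
    if kind == "cc":
        if pm.matrix.shape[0] < 2:
            raise PopulationError("CC similarity needs at least 2 cells")
        s = pearson_rows(x)
        if np.isnan(s).any():
            warnings.warn("zero-variance trial column(s): NaN similarity entries",
                          stacklevel=2)
        return s
    if kind == "neg_sq_euclidean":
        sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
        return -sq
    raise PopulationError(f"unknown similarity kind: {kind}")


# ---------------------------------------------------------------------------
# affinity propagation


@dataclass(frozen=True)
class ClusterResult:
    """Affinity-propagation output: exemplars, labels and run metadata."""

    labels: np.ndarray
    exemplars: np.ndarray
    k: int
    similarity_kind: str
    preference: float
    damping: float
    iterations: int
    converged: bool

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == self.labels[self.exemplars[cluster]])


def _resolve_preference(S: np.ndarray, preference) -> float:
    off = S[~np.eye(S.shape[0], dtype=bool)]
    if preference == "median" or preference is None:
        return float(np.median(off))
    if isinstance(preference, str) and preference.endswith("%"):
        return float(np.percentile(off, float(preference[:-1])))
    return float(preference)


def affinity_propagation(
    S: np.ndarray,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    stable_iter: int = 100,
    seed: int | None = None,
    jitter: float = 0.0,
) -> ClusterResult:
    """Exemplar-based clustering by responsibility/availability passing.

    ``S`` is a square symmetric similarity matrix (higher = more
    similar); the scalar ``preference`` — by default the median of the
    off-diagonal similarities, or a percentile given as e.g. ``"10%"``,
    or an explicit value — is placed on the diagonal and controls the
    number of exemplars.  Messages are damped by ``damping`` and the run
    stops once the exemplar set is unchanged for ``stable_iter``
    iterations.  The update is deterministic; exact ties resolve to the
    lowest index.  A nonzero ``jitter`` adds seeded noise of that
    relative magnitude to break pathological symmetry, off by default.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if S.ndim != 2 or S.shape[1] != n:
        raise PopulationError("similarity matrix must be square")
    if not 0.5 <= damping < 1.0:
        raise PopulationError("damping must be in [0.5, 1)")
    if np.isnan(S).any():
        raise PopulationError("similarity matrix contains NaN entries")
    pref_value = _resolve_preference(S, preference)
    S = S.copy()
    np.fill_diagonal(S, pref_value)
    if jitter:
        rng = np.random.default_rng(seed)
        scale = jitter * (np.abs(S).max() or 1.0)
        S = S + rng.standard_normal(S.shape) * scale

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    last_exemplars: np.ndarray | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        AS[idx, first] = first_val
        Rnew = S - first_val[:, None]
        Rnew[idx, first] = S[idx, first] - second_val
        R = damping * R + (1.0 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col_sums = Rp.sum(axis=0)
        Anew = np.minimum(0.0, col_sums[None, :] - Rp)
        np.fill_diagonal(Anew, col_sums - Rp.diagonal())
        A = damping * A + (1.0 - damping) * Anew

        exemplars = np.flatnonzero((A + R).diagonal() > 0)
        if last_exemplars is not None and exemplars.size and np.array_equal(
            exemplars, last_exemplars
        ):
            stable += 1
            if stable >= stable_iter:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    exemplars = np.flatnonzero((A + R).diagonal() > 0)
    if exemplars.size == 0:
        # degenerate run: fall back to the single best net exemplar
        exemplars = np.array([int((A + R).diagonal().argmax())])
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge within {max_iter} "
            f"iterations", stacklevel=2,
        )
    # assignment: each point to its most similar exemplar (ties -> lowest index)
    labels = exemplars[np.argmax(S[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    # relabel to consecutive ids ordered by exemplar index
    lut = {e: i for i, e in enumerate(exemplars)}
    labels = np.array([lut[e] for e in labels])
    return ClusterResult(
        labels=labels,
        exemplars=exemplars,
        k=exemplars.size,
        similarity_kind="precomputed",
        preference=pref_value,
        damping=damping,
        iterations=it,
        converged=converged,
    )


def brute_force_exemplars(S: np.ndarray, preference="median", k: int | None = None):
    """Exhaustive exemplar search maximizing the affinity-propagation score.

    The net similarity of an exemplar set E is sum_i max_{e in E}
    S[i, e] over non-exemplars plus the preference for each exemplar.
    Searches all exemplar subsets (all sizes, or only size ``k``);
    intended as an independent oracle for small n.
    """
    from itertools import combinations

    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n > 14:
        raise PopulationError("brute force limited to small instances")
    pref_value = _resolve_preference(S, preference)
    Sd = S.copy()
    np.fill_diagonal(Sd, pref_value)
    best, best_score = None, -np.inf
    sizes = range(1, n + 1) if k is None else [k]
    for size in sizes:
        for combo in combinations(range(n), size):
            members = np.setdiff1d(np.arange(n), combo, assume_unique=True)
            score = size * pref_value
            if members.size:
                score += Sd[np.ix_(members, combo)].max(axis=1).sum()
            if score > best_score:
                best_score, best = score, combo
    exemplars = np.array(best)
    labels_ex = exemplars[np.argmax(Sd[:, exemplars], axis=1)]
    labels_ex[exemplars] = exemplars
    lut = {e: i for i, e in enumerate(exemplars)}
    return exemplars, np.array([lut[e] for e in labels_ex]), best_score


# ---------------------------------------------------------------------------
# cross-area statistics


@dataclass(frozen=True)
class IntraClusterCC:
    """Observed intra-cluster CC and its trial-shuffle null."""

    observed: float
    per_cluster: dict[int, float]
    null_mean: float
    null_values: np.ndarray
    n_shuffles: int
    seed: int | None


def _mean_intra_cluster_cc(cc: np.ndarray, labels: np.ndarray) -> tuple[float, dict]:
    per_cluster: dict[int, float] = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size < 2:
            continue  # singleton clusters contribute no pairs
        sub = cc[np.ix_(members, members)]
        iu, ju = np.triu_indices(members.size, k=1)
        per_cluster[int(lab)] = float(np.nanmean(sub[iu, ju]))
    if not per_cluster:
        raise PopulationError("all clusters are singletons")
    return float(np.mean(list(per_cluster.values()))), per_cluster


def cross_area_intra_cluster_cc(
    clusters: ClusterResult,
    target: PopulationMatrix,
    n_shuffles: int = 1000,
    seed: int | None = None,
    shuffle_mode: str = "labels",
) -> IntraClusterCC:
    """Mean within-cluster CC of the *target* area's population vectors.

    Clusters come from the other area's vectors over the same trials.
    Per cluster with >= 2 member trials the mean pairwise Pearson CC of
    the target-area vectors is taken, then averaged across clusters.
    The null permutes the trial-to-cluster assignment (``shuffle_mode
    ="labels"``) or equivalently the target trial identities
    (``"trials"``) ``n_shuffles`` times; the reported null is the mean
    over shuffles along with the full shuffle distribution.
    """
    labels = np.asarray(clusters.labels)
    if labels.size != target.n_trials:
        raise PopulationError(
            "cluster labels and target trials must cover the same trial set"
        )
    cc = pearson_rows(target.matrix.T)
    observed, per_cluster = _mean_intra_cluster_cc(cc, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(labels.size)
        shuffled = labels[perm] if shuffle_mode == "labels" else labels
        cc_s = cc if shuffle_mode == "labels" else cc[np.ix_(perm, perm)]
        null[s], _ = _mean_intra_cluster_cc(cc_s, shuffled)
    return IntraClusterCC(
        observed=observed,
        per_cluster=per_cluster,
        null_mean=float(null.mean()),
        null_values=null,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def inter_cluster_distances(
    pm: PopulationMatrix, clusters: ClusterResult, metric: str = "cc"
) -> np.ndarray:
    """k x k distance matrix between cluster-mean population vectors.

    ``metric="cc"`` gives pairwise Pearson CC (unit diagonal);
    ``"euclidean"`` gives Euclidean distances.  Singleton clusters use
    their single vector as the mean.
    """
    labels = np.asarray(clusters.labels)
    if clusters.k < 2:
        raise PopulationError("need at least 2 clusters")
    means = np.stack(
        [pm.matrix[:, labels == lab].mean(axis=1) for lab in range(clusters.k)]
    )
    if metric == "cc":
        return pearson_rows(means)
    if metric == "euclidean":
        diff = means[:, None, :] - means[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise PopulationError(f"unknown metric: {metric}")


def cluster_distance_agreement(mA: np.ndarray, mB: np.ndarray):
    """Agreement of two areas' inter-cluster distance matrices.

    Pearson r between the vectorized off-diagonal upper triangles of
    the two k x k matrices (same k, same cluster indexing), with the
    regression slope and intercept.  Requires k >= 3 so that more than
    one pair exists.
    """
    mA = np.asarray(mA, dtype=float)
    mB = np.asarray(mB, dtype=float)
    if mA.shape != mB.shape or mA.shape[0] != mA.shape[1]:
        raise PopulationError("matrices must be square with matching k")
    k = mA.shape[0]
    if k < 3:
        raise PopulationError("k >= 3 required for a meaningful r")
    iu, ju = np.triu_indices(k, k=1)
    a, b = mA[iu, ju], mB[iu, ju]
    res = stats.linregress(a, b)
    return {
        "r": float(res.rvalue),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n_pairs": int(a.size),
    }


def behavior_property_clusters(
    trials,
    properties: tuple[str, ...] = (
        "lever_pull_speed",
        "lever_correlation",
        "reaction_time",
        "time_from_prev_reward",
    ),
    kind: str = "cc",
    preference="median",
    damping: float = 0.9,
    seed: int | None = None,
):
    """Cluster trials by standardized behavioral properties.

    Each property is z-scored across trials, trial similarity is the
    Pearson CC across the 4-vector (or negative squared Euclidean), and
    affinity propagation runs with the same conventions as for activity
    clusters.  Trials with undefined property values are excluded and
    reported.  Returns ``(ClusterResult, used_trial_indices)``.
    """
    props = trials.loc[:, list(properties)].to_numpy(dtype=float)
    ok = np.isfinite(props).all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} trial(s) excluded: undefined property values",
            stacklevel=2,
        )
    props = props[ok]
    if props.shape[0] < 3:
        raise PopulationError("need at least 3 trials with defined properties")
    sd = props.std(axis=0)
    if (sd == 0).any():
        sd = np.where(sd == 0, 1.0, sd)
    z = (props - props.mean(axis=0)) / sd
    if kind == "cc":
        S = pearson_rows(z)
        if np.isnan(S).any():
            raise PopulationError("zero-variance trial property vector")
    elif kind == "neg_sq_euclidean":
        S = -((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    else:
        raise PopulationError(f"unknown similarity kind: {kind}")
    result = affinity_propagation(
        S, preference=preference, damping=damping, seed=seed
    )
    return result, np.flatnonzero(ok)
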