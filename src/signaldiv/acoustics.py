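"""Note classification and acoustic complexity.

Courtship sounds are delivered as a note table: one row per temporally
separated sound element with summary acoustic features measured from the
spectrogram (duration, frequency extremes, bandwidth, peak frequency,
peak-frequency-contour summaries, entropy measures) and four manually
scored yes/no qualities (frequency modulation, nonharmonic structure,
impulsive, stochastic).

Classification is two-step and semi-automated: notes are placed in a
3-D acoustic space by a correlation-matrix PCA of the quantitative
features, partial identities are assigned by agglomerative hierarchical
clustering on Euclidean distances in that space, and the full identity is
the pair (cluster, qualitative code).  Complexity is then the same
sliding-window richness/diversity machinery used for behavior, with each
note a count-weighted point event and a 10 s default window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .diversity import TimedSequence, Token, species_scores

__all__ = [
    "ID_COLUMNS",
    "FLAG_COLUMNS",
    "CANONICAL_FEATURES",
    "PCAResult",
    "standardize_and_pca",
    "cluster_notes",
    "qualitative_code",
    "assign_note_identities",
    "notes_to_sequences",
    "acoustic_complexity",
]

ID_COLUMNS = ("species", "individual", "clip", "onset_s", "duration_s")
FLAG_COLUMNS = ("fm", "nonharmonic", "impulsive", "stochastic")

# canonical quantitative features; any extra numeric columns in a note CSV
# (e.g. further peak-frequency-contour summaries) are picked up by header
CANONICAL_FEATURES = (
    "duration_s",
    "max_freq_hz",
    "min_freq_hz",
    "bandwidth_hz",
    "peak_freq_hz",
    "peak_freq_contour_mean",
    "aggregate_entropy",
    "average_entropy",
)


@dataclass
class PCAResult:
    standardized: np.ndarray
    loadings: np.ndarray  # (n_features, n_components), orthonormal columns
    scores: np.ndarray  # (n_notes, n_components)
    variance_explained: np.ndarray
    feature_names: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def feature_columns(notes: pd.DataFrame) -> list:
    """Quantitative feature columns of a note table: every numeric column
    that is not an id or qualitative flag."""
    skip = (set(ID_COLUMNS[:4]) | set(FLAG_COLUMNS)
            | {"clip_duration_s", "true_component", "cluster_id", "qual_code"})
    cols = [
        c
        for c in notes.columns
        if c not in skip and pd.api.types.is_numeric_dtype(notes[c])
    ]
    return cols


def standardize_and_pca(
    notes: pd.DataFrame, features: list | None = None
) -> PCAResult:
    """Correlation-matrix PCA of the note features.

    Each feature is z-scored, so components are eigenvectors of the
    feature correlation matrix.  Zero-variance features are dropped with a
    warning; the component count is capped at the matrix rank.  Component
    signs follow the convention that the largest-magnitude loading of each
    component is positive.
    """
    if features is None:
        features = feature_columns(notes)
    if len(notes) < 2:
        raise ValueError("need at least 2 notes for PCA")
    if len(features) < 2:
        raise ValueError("need at least 2 features for PCA")
    X = notes[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        features = [f for f, k in zip(features, keep) if k]
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        standardized=Z,
        loadings=loadings,
        scores=scores,
        variance_explained=pca.explained_variance_ratio_.copy(),
        feature_names=list(features),
    )


def cluster_notes(
    scores: np.ndarray,
    k: int | None = None,
    method: str = "ward",
    max_auto_k: int = 20,
    min_silhouette: float = 0.5,
) -> np.ndarray:
    """Partial note identities from agglomerative hierarchical clustering
    on Euclidean distances in (typically 3-D) PC space.

    With ``k`` given, the dendrogram is cut at ``k`` clusters; otherwise
    the count is chosen by the best mean silhouette width over candidate
    cuts 2..``max_auto_k`` of the same dendrogram (merge-height gaps are
    unreliable under Ward's cluster-size inflation).  If no candidate
    reaches ``min_silhouette`` the notes are one type.  Silhouettes are
    evaluated on a deterministic subsample when n is large.  Returns
    0-based integer labels, one per note.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n == 1:
        if k is not None and k > 1:
            raise ValueError("k exceeds the number of notes")
        return np.zeros(1, dtype=int)
    if k is not None and (k < 1 or k > n):
        raise ValueError(f"k must be in [1, {n}]")
    Z = linkage(scores, method=method, metric="euclidean")
    if k is None:
        from sklearn.metrics import silhouette_score

        sub = np.arange(n) if n <= 2000 else np.linspace(0, n - 1, 2000).astype(int)
        best_k, best_s = 1, min_silhouette
        for cand in range(2, min(max_auto_k, n - 1) + 1):
            lab = fcluster(Z, t=cand, criterion="maxclust")
            if len(np.unique(lab[sub])) < 2:
                continue
            s = silhouette_score(scores[sub], lab[sub])
            if s > best_s:
                best_k, best_s = cand, s
        k = best_k
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # renumber by first appearance for input-order determinism
    _, first = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(sorted(first))}
    return np.array([order[l] for l in labels], dtype=int)


def qualitative_code(fm: bool, nonharmonic: bool, impulsive: bool, stochastic: bool) -> int:
    """Binary code 0-15 of the four qualitative note attributes, bit order
    (fm, nonharmonic, impulsive, stochastic) from high to low."""
    return (int(bool(fm)) << 3) | (int(bool(nonharmonic)) << 2) | (
        int(bool(impulsive)) << 1
    ) | int(bool(stochastic))


def assign_note_identities(
    notes: pd.DataFrame,
    k: int | None = None,
    n_components: int = 3,
    method: str = "ward",
    features: list | None = None,
) -> tuple[pd.DataFrame, PCAResult]:
    """Full note identities: acoustic-space cluster merged with the
    qualitative code.

    Returns a copy of the note table with columns ``cluster_id``,
    ``qual_code`` and ``full_id`` (a string, injective on the pair), plus
    the PCA summary.
    """
    for c in FLAG_COLUMNS:
        if c not in notes.columns:
            raise ValueError(f"note table missing flag column {c!r}")
    pca = standardize_and_pca(notes, features)
    ncomp = min(n_components, pca.n_components)
    cluster_id = cluster_notes(pca.scores[:, :ncomp], k=k, method=method)
    qual = np.array(
        [
            qualitative_code(r.fm, r.nonharmonic, r.impulsive, r.stochastic)
            for r in notes[list(FLAG_COLUMNS)].itertuples(index=False)
        ]
    )
    out = notes.copy()
    out["cluster_id"] = cluster_id
    out["qual_code"] = qual
    out["full_id"] = [f"c{c}_q{q}" for c, q in zip(cluster_id, qual)]
    return out, pca


def notes_to_sequences(notes: pd.DataFrame, label_col: str = "full_id") -> list:
    """One TimedSequence per (species, individual, clip), each note a point
    event at its onset."""
    seqs = []
    for (sp, ind, clip), grp in notes.groupby(
        ["species", "individual", "clip"], sort=True
    ):
        tokens = [
            Token(str(l), "event", float(t), float(t))
            for l, t in zip(grp[label_col], grp["onset_s"])
        ]
        dur = float(grp["clip_duration_s"].iloc[0]) if "clip_duration_s" in grp else None
        seqs.append(
            TimedSequence(
                tokens,
                clip_id=str(clip),
                individual_id=str(ind),
                species_id=str(sp),
                duration_s=dur,
            )
        )
    return seqs


def acoustic_complexity(
    notes: pd.DataFrame,
    window_len_s: float = 10.0,
    step_s: float = 1.0,
    label_col: str = "full_id",
    single_window_by: str | None = None,
) -> pd.DataFrame:
    """Species-level acoustic richness and diversity.

    Per individual, the window of maximal complexity is found across all
    clips; individual scores average to the species estimate.  Notes are
    count-weighted (each note contributes 1), being near-instantaneous
    relative to the window.
    """
    if label_col not in notes.columns:
        raise ValueError(f"notes lack identity column {label_col!r}; "
                         "run assign_note_identities first")
    seqs = notes_to_sequences(notes, label_col)
    return species_scores(
        seqs, window_len_s, step_s, event_weight_s=1.0,
        single_window_by=single_window_by,
    )
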