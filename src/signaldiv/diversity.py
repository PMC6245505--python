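"""Richness and Shannon-diversity (Hill number of order 1) for weighted
categorical distributions, plus the sliding-window machinery shared by the
behavioral and acoustic analyses.

A display sequence is scored by how many distinct elements it contains
(richness) and by the numbers equivalent of its Shannon entropy
(diversity, ``exp(H)``): the count of equally weighted categories that
would produce the same entropy.  Diversity is base-free and satisfies the
doubling property — a sequence scoring ``2x`` behaves like one with twice
as many equally represented elements as a sequence scoring ``x``.

Weights are whatever mass is natural for the modality: seconds for
behavioral states, counts for instantaneous events and notes, pixel areas
for plumage colors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

__all__ = [
    "WeightedCounts",
    "ComplexityScore",
    "Token",
    "TimedSequence",
    "WindowResult",
    "shannon_entropy",
    "numbers_equivalent",
    "richness",
    "complexity_score",
    "window_weights",
    "sliding_max_complexity",
    "aggregate_species",
    "window_sweep",
]


class UnscorableError(ValueError):
    """Raised when a distribution or individual has no positive mass."""


@dataclass(frozen=True)
class WeightedCounts:
    """A weighted categorical distribution over labeled elements."""

    labels: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(self.labels) != w.size:
            raise ValueError("labels and weights must be 1-D and equal length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "WeightedCounts":
        items = list(mapping.items())
        return cls(tuple(k for k, _ in items), np.array([v for _, v in items], float))

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def scorable(self) -> bool:
        return self.total > 0


@dataclass(frozen=True)
class ComplexityScore:
    """Richness (distinct categories) and diversity (exp of Shannon entropy)."""

    richness: int
    diversity: float


def shannon_entropy(w: WeightedCounts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of the weight proportions."""
    if not w.scorable:
        raise UnscorableError("all-zero weights: entropy undefined")
    return float(_scipy_entropy(w.weights))


def numbers_equivalent(H: float) -> float:
    """Hill number of order 1: the effective number of equally weighted
    categories, ``exp(H)``."""
    if H < 0:
        raise ValueError(f"entropy must be nonnegative, got {H}")
    return math.exp(H)


def richness(w: WeightedCounts) -> int:
    """Number of categories carrying positive weight."""
    if not w.scorable:
        raise UnscorableError("all-zero weights: richness undefined")
    return int(np.count_nonzero(w.weights > 0))


def complexity_score(w: WeightedCounts) -> ComplexityScore:
    """Richness and diversity of one weighted distribution."""
    return ComplexityScore(richness(w), numbers_equivalent(shannon_entropy(w)))


@dataclass(frozen=True)
class Token:
    """One scored behavioral element: a state (with duration) or an
    instantaneous event (``end_s == start_s``)."""

    label: str
    kind: str  # "state" | "event"
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.kind not in ("state", "event"):
            raise ValueError(f"kind must be 'state' or 'event', got {self.kind!r}")
        if self.start_s < 0 or self.end_s < self.start_s:
            raise ValueError("need 0 <= start_s <= end_s")
        if self.kind == "event" and self.end_s != self.start_s:
            raise ValueError("events are instantaneous (end_s == start_s)")


@dataclass
class TimedSequence:
    """Ordered tokens for one individual in one clip."""

    tokens: list
    clip_id: str = ""
    individual_id: str = ""
    species_id: str = ""
    duration_s: float | None = None

    def __post_init__(self):
        self.tokens = sorted(self.tokens, key=lambda t: (t.start_s, t.end_s, t.label))
        end = max((t.end_s for t in self.tokens), default=0.0)
        if self.duration_s is None:
            self.duration_s = end
        elif end > self.duration_s + 1e-9:
            raise ValueError("token extends beyond clip duration")


@dataclass(frozen=True)
class WindowResult:
    """Score of one fixed-length window inside one clip."""

    clip_id: str
    window_start_s: float
    window_len_s: float
    score: ComplexityScore


def window_weights(
    seq: TimedSequence,
    start_s: float,
    len_s: float,
    event_weight_s: float = 1.0,
) -> WeightedCounts:
    """Mass of each element inside the window [start_s, start_s + len_s).

    States contribute their overlap duration with the window; events whose
    instant falls inside contribute a nominal ``event_weight_s`` so that
    counts and durations are commensurate in one time-proportion
    distribution.
    """
    if len_s <= 0:
        raise ValueError("window length must be positive")
    if start_s < -1e-9 or start_s + len_s > seq.duration_s + 1e-9:
        raise ValueError(
            f"window [{start_s}, {start_s + len_s}) outside clip "
            f"[0, {seq.duration_s})"
        )
    end_s = start_s + len_s
    mass: dict = {}
    for t in seq.tokens:
        if t.kind == "state":
            overlap = min(t.end_s, end_s) - max(t.start_s, start_s)
            if overlap > 0:
                mass[t.label] = mass.get(t.label, 0.0) + overlap
        else:
            if start_s <= t.start_s < end_s:
                mass[t.label] = mass.get(t.label, 0.0) + event_weight_s
    return WeightedCounts.from_mapping(mass)


def _windows_of(seq: TimedSequence, window_len_s: float, step_s: float):
    """Window offsets inside one clip.  Clips shorter than the window are
    scored as a single whole-clip window rather than dropped."""
    dur = seq.duration_s
    if dur <= 0:
        return
    if dur < window_len_s:
        yield 0.0, dur
        return
    k = 0
    while k * step_s + window_len_s <= dur + 1e-9:
        yield k * step_s, window_len_s
        k += 1


def sliding_max_complexity(
    seqs: Sequence[TimedSequence],
    window_len_s: float,
    step_s: float = 1.0,
    event_weight_s: float = 1.0,
    single_window_by: str | None = None,
) -> tuple[WindowResult, WindowResult]:
    """Window of maximal complexity across all of one individual's clips.

    Every offset ``0, step, 2*step, ...`` inside each clip is scored; the
    windows maximizing richness and diversity are returned independently
    (ties broken by earliest clip, then earliest offset).  With
    ``single_window_by='diversity'`` (or ``'richness'``) a single best
    window is selected by that metric and both returned results point at
    it.

    Raises :class:`UnscorableError` if no window contains any mass.
    """
    if window_len_s <= 0 or step_s <= 0:
        raise ValueError("window_len_s and step_s must be positive")
    if single_window_by not in (None, "richness", "diversity"):
        raise ValueError(f"bad single_window_by: {single_window_by!r}")
    best_rich: WindowResult | None = None
    best_div: WindowResult | None = None
    for seq in seqs:
        for start, wlen in _windows_of(seq, window_len_s, step_s):
            w = window_weights(seq, start, wlen, event_weight_s)
            if not w.scorable:
                continue
            score = complexity_score(w)
            res = WindowResult(seq.clip_id, start, wlen, score)
            if best_rich is None or score.richness > best_rich.score.richness:
                best_rich = res
            if best_div is None or score.diversity > best_div.score.diversity + 1e-12:
                best_div = res
    if best_rich is None or best_div is None:
        raise UnscorableError("no scorable window for this individual")
    if single_window_by == "richness":
        best_div = best_rich
    elif single_window_by == "diversity":
        best_rich = best_div
    return best_rich, best_div


def aggregate_species(values: Iterable[float]) -> float:
    """Unweighted arithmetic mean of per-individual scores; NaNs (missing
    individuals) are excluded.  Returns NaN if no individual has a score —
    the species is then a candidate for phylogenetic imputation."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return float("nan")
    return float(arr.mean())


def _score_individuals(
    by_individual: Mapping[str, Sequence[TimedSequence]],
    window_len_s: float,
    step_s: float,
    event_weight_s: float,
    single_window_by: str | None,
) -> pd.DataFrame:
    rows = []
    for ind, seqs in by_individual.items():
        try:
            r, d = sliding_max_complexity(
                seqs, window_len_s, step_s, event_weight_s, single_window_by
            )
            rows.append((ind, r.score.richness, d.score.diversity))
        except UnscorableError:
            rows.append((ind, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["individual", "richness", "diversity"])


def species_scores(
    seqs: Sequence[TimedSequence],
    window_len_s: float,
    step_s: float = 1.0,
    event_weight_s: float = 1.0,
    single_window_by: str | None = None,
) -> pd.DataFrame:
    """Per-species mean of per-individual maximal-window scores.

    Individuals are keyed by ``(species_id, individual_id)``; unscorable
    individuals propagate as missing and drop out of the species mean.
    Returns a frame with columns species, richness, diversity (NaN when no
    individual of a species is scorable).
    """
    by_sp_ind: dict[tuple, list] = {}
    for s in seqs:
        by_sp_ind.setdefault((s.species_id, s.individual_id), []).append(s)
    rows = []
    for (sp, ind), ss in by_sp_ind.items():
        try:
            r, d = sliding_max_complexity(
                ss, window_len_s, step_s, event_weight_s, single_window_by
            )
            rows.append((sp, ind, float(r.score.richness), d.score.diversity))
        except UnscorableError:
            rows.append((sp, ind, np.nan, np.nan))
    per_ind = pd.DataFrame(
        rows, columns=["species", "individual", "richness", "diversity"]
    )
    out = (
        per_ind.groupby("species")[["richness", "diversity"]]
        .agg(lambda c: aggregate_species(c))
        .reset_index()
    )
    return out


def window_sweep(
    seqs: Sequence[TimedSequence],
    window_sizes_s: Sequence[float],
    step_s: float = 1.0,
    event_weight_s: float = 1.0,
) -> pd.DataFrame:
    """Species-level scores across a range of window sizes (robustness
    sweep).  Returns a long frame: species, window_s, richness, diversity."""
    frames = []
    for w in window_sizes_s:
        df = species_scores(seqs, w, step_s, event_weight_s)
        df.insert(1, "window_s", float(w))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
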