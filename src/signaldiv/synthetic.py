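"""Synthetic study data with known ground truth.

Every input class the analysis consumes can be generated here: a
pure-birth ultrametric phylogeny; multi-clip behavioral event logs with
species-specific repertoires; patchwise cone-catch specimen images with
controlled chromatic separations and log-normal pixel noise;
Gaussian-mixture note tables with qualitative flags; and display-site
covariates.  Because the generating parameters (repertoire sizes, patch
counts, mixture components, cross-trait correlations) are recorded,
every pipeline stage can be validated against truth without any external
media.

Defaults emulate the study conditions: 40 species, roughly 80% of them
sampled per modality, a handful of individuals per species with several
clips each (behavioral clips averaging near 50 s, acoustic clips
longer), three specimen views, and three display-height / display-
proximity categories.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .color import ClusterParams, ConeCatchImage, VisualModel, chromatic_jnd
from .diversity import TimedSequence, Token
from .phylo import DISPLAY_HEIGHT_LEVELS, PROXIMITY_LEVELS, Phylogeny

__all__ = [
    "SyntheticSpec",
    "gen_tree",
    "gen_behavior_logs",
    "gen_cone_catch_image",
    "gen_specimen_views",
    "gen_notes",
    "gen_covariates",
    "behavior_logs_to_sequences",
    "sequences_to_frame",
]


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study, with study-scale defaults."""

    seed: int = 0
    n_species: int = 40
    sampled_fraction: float = 0.8  # species with behavior/acoustic media
    # behavior
    repertoire_min: int = 3
    repertoire_max: int = 12
    event_fraction: float = 0.3  # share of a repertoire that is instantaneous
    individuals_per_species: int = 3
    clips_per_individual: int = 6
    clip_duration_lognorm: tuple = (4.0, 0.35)  # ln-mean, ln-sd -> mean ~ 58 s
    state_duration_lognorm: tuple = (1.2, 0.6)  # mean ~ 4 s per state bout
    event_rate_per_s: float = 0.25
    # color
    patch_min: int = 2
    patch_max: int = 8
    image_size: tuple = (24, 24)
    patch_separation_jnd: float = 8.0  # pairwise chromatic JND between patches
    pixel_noise_sd: float = 0.01  # log-catch sd, well below threshold
    specimens_per_species: int = 2
    # acoustics
    note_components_min: int = 1
    note_components_max: int = 8
    n_features: int = 15
    component_separation_sigma: float = 10.0
    notes_per_clip: int = 25
    acoustic_clip_duration_s: float = 140.0
    acoustic_clips_per_individual: int = 3
    flag_probability: float = 0.3  # per-component Bernoulli flag patterns
    # tree / traits
    birth_rate: float = 0.1
    tree_height: float = 25.0  # million years, rescaled
    cross_trait_correlation: float = 0.0
    trait_model: str = "BM"


def _species_rng(seed: int, stream: str, species_index: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per (stage, species).

    Stream names are hashed with CRC32 (stable across processes, unlike
    the salted builtin hash) so outputs are byte-identical between runs.
    """
    ss = np.random.SeedSequence(
        [seed, zlib.crc32(stream.encode()) & 0xFFFFFFFF, species_index]
    )
    return np.random.default_rng(ss)


def gen_tree(n_species: int, birth_rate: float = 0.1, seed: int = 0,
             height: float | None = None) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with tips S1..Sn.

    Lineages split at exponential waiting times; pendant edges extend to
    the present so the tree is exactly ultrametric.  If ``height`` is
    given, branch lengths are rescaled so the root-to-tip depth equals it
    (million years).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _species_rng(seed, "tree")
    # event times: start with one lineage at t=0
    times = [0.0]
    t = 0.0
    for k in range(1, n_species):
        t += rng.exponential(1.0 / (birth_rate * k))
        times.append(t)
    end = t + rng.exponential(1.0 / (birth_rate * n_species))
    # build topology: at each split, a random active lineage bifurcates
    class _N:
        __slots__ = ("children", "birth", "label")

        def __init__(self, birth):
            self.children = []
            self.birth = birth
            self.label = None

    root = _N(0.0)
    active = [root]
    for st in times[1:]:
        i = rng.integers(len(active))
        node = active.pop(i)
        a, b = _N(st), _N(st)
        node.children = [a, b]
        active.extend([a, b])
    # deterministic tip labels in traversal order
    counter = [0]

    def newick(node) -> str:
        if not node.children:
            counter[0] += 1
            return f"S{counter[0]}:{end - node.birth:.10f}"
        inner = ",".join(newick(c) for c in node.children)
        length = (node.children[0].birth - node.birth)
        return f"({inner}):{length:.10f}"

    s = newick(root).rsplit(":", 1)[0] + ";"
    phy = Phylogeny.from_newick(s)
    if height is not None:
        scale = height / phy.height
        for e in phy.tree.edges():
            if e.length is not None:
                e.length *= scale
        phy = Phylogeny(phy.tree)
    return phy


def _repertoire(spec: SyntheticSpec, species_index: int) -> tuple[list, list]:
    """Deterministic per-species repertoire: state and event labels."""
    rng = _species_rng(spec.seed, "repertoire", species_index)
    size = int(rng.integers(spec.repertoire_min, spec.repertoire_max + 1))
    n_events = min(size - 1, int(round(size * spec.event_fraction)))
    n_states = size - n_events
    states = [f"sp{species_index}_state{i}" for i in range(n_states)]
    events = [f"sp{species_index}_event{i}" for i in range(n_events)]
    return states, events


def gen_behavior_logs(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict]:
    """Behavioral event logs for all sampled species.

    Each clip is a chain of state bouts with labels drawn uniformly from
    the species' state repertoire (log-normal durations, truncated at the
    clip end) overlaid with Poisson point events.  Returns the long-form
    log (species, individual, clip, behavior, kind, start_s, end_s,
    clip_duration_s) and the ground-truth repertoire sizes per species.
    """
    n_sampled = int(round(spec.n_species * spec.sampled_fraction))
    rows = []
    truth = {}
    for si in range(1, n_sampled + 1):
        sp = f"S{si}"
        states, events = _repertoire(spec, si)
        truth[sp] = len(states) + len(events)
        rng = _species_rng(spec.seed, "behavior", si)
        for ind in range(1, spec.individuals_per_species + 1):
            ind_id = f"{sp}_i{ind}"
            for clip in range(1, spec.clips_per_individual + 1):
                clip_id = f"{ind_id}_c{clip}"
                mu, sd = spec.clip_duration_lognorm
                dur = float(rng.lognormal(mu, sd))
                t = 0.0
                while t < dur:
                    label = states[rng.integers(len(states))]
                    smu, ssd = spec.state_duration_lognorm
                    d = min(float(rng.lognormal(smu, ssd)), dur - t)
                    if d <= 0:
                        break
                    rows.append((sp, ind_id, clip_id, label, "state",
                                 round(t, 3), round(t + d, 3), round(dur, 3)))
                    t += d
                if events:
                    n_ev = rng.poisson(spec.event_rate_per_s * dur)
                    for te in np.sort(rng.uniform(0, dur, n_ev)):
                        label = events[rng.integers(len(events))]
                        rows.append((sp, ind_id, clip_id, label, "event",
                                     round(float(te), 3), round(float(te), 3),
                                     round(dur, 3)))
    df = pd.DataFrame(
        rows,
        columns=["species", "individual", "clip", "behavior", "kind",
                 "start_s", "end_s", "clip_duration_s"],
    )
    return df, truth


def behavior_logs_to_sequences(log: pd.DataFrame) -> list:
    """Parse an event-log frame into TimedSequences (one per clip)."""
    seqs = []
    for (sp, ind, clip), grp in log.groupby(["species", "individual", "clip"],
                                            sort=True):
        tokens = [
            Token(str(r.behavior), str(r.kind), float(r.start_s), float(r.end_s))
            for r in grp.itertuples(index=False)
        ]
        dur = float(grp["clip_duration_s"].iloc[0]) if "clip_duration_s" in grp else None
        seqs.append(TimedSequence(tokens, clip_id=str(clip), individual_id=str(ind),
                                  species_id=str(sp), duration_s=dur))
    return seqs


def sequences_to_frame(seqs: list) -> pd.DataFrame:
    rows = [
        (s.species_id, s.individual_id, s.clip_id, t.label, t.kind,
         t.start_s, t.end_s, s.duration_s)
        for s in seqs
        for t in s.tokens
    ]
    return pd.DataFrame(rows, columns=["species", "individual", "clip", "behavior",
                                       "kind", "start_s", "end_s",
                                       "clip_duration_s"])


def patch_log_catches(
    k: int,
    model: VisualModel,
    separation_jnd: float,
    base: float = 0.0,
) -> np.ndarray:
    """Log-catch vectors for k patches spaced ``separation_jnd`` apart in
    chromatic JND along one receptor-contrast direction.

    Consecutive patches differ by exactly the requested JND; patches i, j
    differ by |i - j| times it, so all pairs exceed the consecutive
    separation.
    """
    n = model.n_channels
    u = np.zeros(n)
    u[0] = 1.0  # pure first-channel contrast
    unit = chromatic_jnd(np.exp(u), np.ones(n), model)
    step = separation_jnd / unit
    return base + np.arange(k)[:, None] * step * u[None, :]


def gen_cone_catch_image(
    k_patches: int,
    model: VisualModel | None = None,
    image_size: tuple = (24, 24),
    separation_jnd: float = 8.0,
    noise_sd: float = 0.01,
    rng: np.random.Generator | None = None,
    border: int = 1,
) -> tuple[ConeCatchImage, np.ndarray]:
    """One specimen view: vertical color patches on a masked background.

    Patches are equal-width vertical bands whose mean log catches are
    pairwise separated by at least ``separation_jnd`` chromatic JNDs;
    pixel noise is log-normal with sd ``noise_sd`` in log-catch space (so
    within-patch JNDs are distribution-stable).  Luminance is uniform.
    Returns the image and the true patch label map (-1 on background).
    """
    if model is None:
        model = VisualModel()
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = image_size
    inner_w = w - 2 * border
    inner_h = h - 2 * border
    if inner_w < k_patches:
        raise ValueError("image too small for requested patch count")
    logq = patch_log_catches(k_patches, model, separation_jnd)
    truth = np.full((h, w), -1, dtype=int)
    f = np.zeros((h, w, model.n_channels))
    bounds = np.linspace(0, inner_w, k_patches + 1).round().astype(int)
    for p in range(k_patches):
        x0, x1 = border + bounds[p], border + bounds[p + 1]
        truth[border : border + inner_h, x0:x1] = p
        f[border : border + inner_h, x0:x1] = logq[p]
    mask = truth >= 0
    f += rng.normal(0.0, noise_sd, f.shape)
    catches = np.exp(f)
    lum = np.exp(rng.normal(0.0, noise_sd, (h, w)))
    return ConeCatchImage(catches, lum, mask), truth


def gen_specimen_views(
    spec: SyntheticSpec,
    species_index: int,
    model: VisualModel | None = None,
    specimen: int = 1,
) -> tuple[list, int]:
    """Three views (dorsal, ventral, angled) of one specimen; all views
    share the species' true patch count."""
    if model is None:
        model = VisualModel()
    rng = _species_rng(spec.seed, f"color_s{specimen}", species_index)
    k = int(
        _species_rng(spec.seed, "color_truth", species_index).integers(
            spec.patch_min, spec.patch_max + 1
        )
    )
    views = []
    for _view in ("dorsal", "ventral", "angled"):
        img, _ = gen_cone_catch_image(
            k, model, spec.image_size, spec.patch_separation_jnd,
            spec.pixel_noise_sd, rng,
        )
        views.append(img)
    return views, k


def _latent_loading(nf: int) -> np.ndarray:
    """(nf, 3) block loading matrix: each latent acoustic dimension drives
    one contiguous block of measured features, giving the correlated
    feature structure that lets three principal components carry the
    between-type separation (as in real spectrogram measurements, where
    duration-, frequency- and entropy-type variables covary in groups)."""
    M = np.zeros((nf, 3))
    bounds = np.linspace(0, nf, 4).round().astype(int)
    for d in range(3):
        M[bounds[d] : bounds[d + 1], d] = 1.0
    return M


def gen_notes(spec: SyntheticSpec, species_index: int) -> tuple[pd.DataFrame, int]:
    """Gaussian-mixture note table for one species.

    Note types live in a 3-D latent acoustic space: component means sit
    on an integer lattice scaled by ``component_separation_sigma`` (so
    all pairs are at least that many within-type standard deviations
    apart), and each latent dimension loads onto a block of measured
    features.  Each component carries a fixed qualitative flag pattern
    (drawn once per component with independent
    Bernoulli(flag_probability) bits), so the species' true
    full-identity count equals its component count.  Columns: ids,
    onset, duration, f1..f15 features, four flags, plus the true
    component label.
    """
    rng = _species_rng(spec.seed, "notes", species_index)
    m = int(rng.integers(spec.note_components_min, spec.note_components_max + 1))
    nf = spec.n_features
    side = int(np.ceil(m ** (1 / 3)))
    side = max(side, 2)
    lattice = np.array(
        [(c % side, (c // side) % side, c // side**2) for c in range(m)], float
    )
    # fixed generic rotation so every latent dimension carries
    # between-type separation (note types differ in all feature groups);
    # constant across species, keeping the acoustic space shared
    q, _ = np.linalg.qr(np.random.default_rng(12345).normal(size=(3, 3)))
    latent_means = lattice @ q.T * spec.component_separation_sigma
    M = _latent_loading(nf)
    flags = rng.random((m, 4)) < spec.flag_probability
    sp = f"S{species_index}"
    rows = []
    for ind in range(1, spec.individuals_per_species + 1):
        ind_id = f"{sp}_i{ind}"
        for clip in range(1, spec.acoustic_clips_per_individual + 1):
            clip_id = f"{ind_id}_c{clip}"
            n_notes = spec.notes_per_clip
            comps = rng.integers(0, m, n_notes)
            onsets = np.sort(rng.uniform(0, spec.acoustic_clip_duration_s, n_notes))
            latent = latent_means[comps] + rng.normal(0, 1.0, (n_notes, 3))
            feats = latent @ M.T + rng.normal(0, 0.5, (n_notes, nf))
            for i in range(n_notes):
                rows.append(
                    (sp, ind_id, clip_id, round(float(onsets[i]), 3),
                     round(float(abs(feats[i, 0]) * 0.01 + 0.05), 4),
                     *np.round(feats[i], 5),
                     *flags[comps[i]], int(comps[i]),
                     spec.acoustic_clip_duration_s)
                )
    cols = (["species", "individual", "clip", "onset_s", "duration_s"]
            + [f"f{j+1}" for j in range(nf)]
            + ["fm", "nonharmonic", "impulsive", "stochastic",
               "true_component", "clip_duration_s"])
    return pd.DataFrame(rows, columns=cols), m


def gen_covariates(spec: SyntheticSpec) -> pd.DataFrame:
    """Display-height and display-proximity categories for every species."""
    rng = _species_rng(spec.seed, "covariates")
    n = spec.n_species
    return pd.DataFrame(
        {
            "display_height": rng.choice(DISPLAY_HEIGHT_LEVELS, n),
            "proximity": rng.choice(PROXIMITY_LEVELS, n),
        },
        index=pd.Index([f"S{i}" for i in range(1, n + 1)], name="species"),
    )
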