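"""Synthetic music-emotion datasets with the structure of the original study.

The original listening study (60 MIDI excerpts in four genres, 60 participants,
each rating 12 excerpts so that every excerpt is rated by 12 unique listeners)
did not deposit its data.  This module generates datasets with the same design
and the same statistical fingerprints — a strongly collinear spectral-feature
block, physiological features coupled to latent affect (zygomaticus up /
corrugator down with valence; heart rate, respiration and skin conductance up
with arousal), and per-excerpt mean ratings obtained by averaging noisy
per-participant ratings — so every downstream stage can be exercised end to end.

The latent valence/arousal signal for each excerpt is a configurable mixture

    latent = tanh(w_perc * g(audio) + w_feel * h(physio))

of a fixed smooth map ``g`` of the audio features and a fixed smooth map ``h``
of the physiological features.  Setting the mixing weights to (1, 0) or (0, 1)
yields ground truth carried purely by one channel, which is what the
parameter-recovery tests of the committee machine rely on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AUDIO_FEATURES",
    "PHYSIO_FEATURES",
    "SPECTRAL_BLOCK",
    "GeneratorConfig",
    "ExcerptRecord",
    "StudyDesign",
    "ConfigError",
    "substream",
    "build_design",
    "generate_excerpts",
    "generate_ratings",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "excerpts_to_frame",
    "audio_z_from_values",
    "physio_z_from_values",
    "audio_latent_raw",
    "physio_latent_raw",
]

AUDIO_FEATURES = (
    "rms", "lowenergy", "eventdensity", "tempo", "pulseclarity",
    "centroid", "spread", "rolloff", "brightness", "irregularity",
    "inharmonicity", "mode",
)
PHYSIO_FEATURES = ("HR", "Resp", "SCL", "Zyg", "Corr")
SPECTRAL_BLOCK = ("centroid", "spread", "rolloff", "brightness")
GENRES = ("Blues", "Metal", "Pop", "RnB")

# Plausible observation ranges per feature; a standard-normal latent value z is
# mapped to lo + (hi - lo) * sigmoid(z).  Physio ranges are baseline-corrected
# deltas (excerpt minus white-noise baseline), hence centred on zero.
_AUDIO_RANGES = {
    "rms": (0.02, 0.30), "lowenergy": (0.30, 0.70), "eventdensity": (0.5, 8.0),
    "tempo": (60.0, 180.0), "pulseclarity": (0.0, 1.0), "centroid": (500.0, 3500.0),
    "spread": (300.0, 3000.0), "rolloff": (800.0, 6000.0), "brightness": (0.15, 0.85),
    "irregularity": (0.0, 1.0), "inharmonicity": (0.0, 0.5), "mode": (0.0, 1.0),
}
_PHYSIO_RANGES = {
    "HR": (-10.0, 10.0), "Resp": (-4.0, 4.0), "SCL": (-1.5, 1.5),
    "Zyg": (-3.0, 3.0), "Corr": (-3.0, 3.0),
}
_PHYSIO_BASELINE_RANGES = {
    "HR": (60.0, 90.0), "Resp": (12.0, 18.0), "SCL": (2.0, 10.0),
    "Zyg": (1.0, 5.0), "Corr": (1.0, 5.0),
}

# Coefficients of the fixed generative maps g (audio -> affect) and h
# (physiology -> affect), applied to standardized feature values.  Signs follow
# the correlates reported in the affective-science literature: event density
# and brightness push arousal up and valence down, major mode pushes valence
# up, smiling-muscle (Zyg) activity tracks positive valence while frowning
# (Corr) tracks negative valence, and the autonomic measures track arousal.
_G_VALENCE_LIN = {"mode": 0.9, "eventdensity": -0.45, "brightness": -0.40,
                  "pulseclarity": 0.30, "irregularity": -0.25, "rms": 0.20}
_G_VALENCE_QUAD = {"tempo": -0.15}
_G_AROUSAL_LIN = {"eventdensity": 0.80, "tempo": 0.50, "rms": 0.45,
                  "brightness": 0.30, "lowenergy": -0.30}
_G_AROUSAL_QUAD = {"rms": 0.10}
_H_VALENCE_LIN = {"Zyg": 0.75, "Corr": -0.75}
_H_AROUSAL_LIN = {"HR": 0.60, "SCL": 0.55, "Resp": 0.45}

# Couplings used when generating physiology: each excerpt has felt-affect
# drivers that blend the audio-driven affect with an independent component,
# and each physiological channel loads on the relevant driver plus noise.
_FELT_AUDIO_COUPLING = 0.5
_PHYSIO_LOADINGS = {"Zyg": 0.75, "Corr": -0.75, "HR": 0.70, "SCL": 0.70, "Resp": 0.55}


class ConfigError(ValueError):
    """Raised when a generator/partition configuration is infeasible."""


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from (seed, stage name)."""
    tag = int.from_bytes(hashlib.sha256(name.encode()).digest()[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the original design: 60 excerpts (15 per genre in four
    genres), 60 participants each rating 12 excerpts (three per genre), every
    excerpt rated by 12 unique participants.
    """

    n_excerpts: int = 60
    genres: Sequence[str] = GENRES
    excerpts_per_genre: int = 15
    n_participants: int = 60
    excerpts_per_participant: int = 12
    raters_per_excerpt: int = 12
    audio_feature_names: Sequence[str] = AUDIO_FEATURES
    physio_feature_names: Sequence[str] = PHYSIO_FEATURES
    collinear_block: Sequence[str] = SPECTRAL_BLOCK
    collinear_level: float = 0.9
    mixing_valence: tuple[float, float] = (0.8, 0.2)
    mixing_arousal: tuple[float, float] = (0.45, 0.55)
    rating_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_excerpts != len(self.genres) * self.excerpts_per_genre:
            raise ConfigError(
                f"n_excerpts={self.n_excerpts} != "
                f"{len(self.genres)} genres x {self.excerpts_per_genre} per genre")
        if (self.n_participants * self.excerpts_per_participant
                != self.n_excerpts * self.raters_per_excerpt):
            raise ConfigError(
                "participant x excerpt incidence infeasible: "
                f"{self.n_participants}*{self.excerpts_per_participant} != "
                f"{self.n_excerpts}*{self.raters_per_excerpt}")
        if self.excerpts_per_participant % len(self.genres) != 0:
            raise ConfigError(
                "excerpts_per_participant must be divisible by the number of "
                "genres for a genre-balanced listening schedule")
        for pair, name in ((self.mixing_valence, "valence"),
                           (self.mixing_arousal, "arousal")):
            w_p, w_f = pair
            if not (0.0 <= w_p <= 1.0 and 0.0 <= w_f <= 1.0):
                raise ConfigError(f"mixing weights for {name} must lie in [0, 1]")
            if abs(w_p + w_f - 1.0) > 1e-9:
                raise ConfigError(f"mixing weights for {name} must sum to 1")
        if not 0.0 <= self.collinear_level < 1.0:
            raise ConfigError("collinear_level must lie in [0, 1)")
        if self.rating_noise_sd < 0:
            raise ConfigError("rating_noise_sd must be non-negative")
        if set(self.collinear_block) - set(self.audio_feature_names):
            raise ConfigError("collinear_block must be a subset of audio features")
        # Balanced-incidence feasibility of the cyclic construction per genre.
        k = self.excerpts_per_participant // len(self.genres)
        m = self.excerpts_per_genre
        if m % k != 0 or self.n_participants % (m // k) != 0:
            raise ConfigError(
                f"no balanced incidence: {k} excerpts per participant per genre "
                f"cannot tile {m} excerpts across {self.n_participants} participants")


@dataclass
class ExcerptRecord:
    """One excerpt: genre, features, and (once rated) mean emotion ratings."""

    excerpt_id: str
    genre: str
    audio: dict[str, float]
    physio: dict[str, float]
    physio_baseline: dict[str, float] | None = None
    valence_mean: float | None = None
    arousal_mean: float | None = None
    latent_valence: float | None = None
    latent_arousal: float | None = None


@dataclass
class StudyDesign:
    """Participant-by-excerpt incidence structure plus per-pair ratings."""

    assignment: list[tuple[str, str]]
    ratings: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def excerpts_of(self, participant_id: str) -> list[str]:
        return [e for p, e in self.assignment if p == participant_id]

    def raters_of(self, excerpt_id: str) -> list[str]:
        return [p for p, e in self.assignment if e == excerpt_id]


def _participant_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _excerpt_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"E{i + 1:0{width}d}" for i in range(n)]


def build_design(config: GeneratorConfig) -> StudyDesign:
    """Build a balanced participant-by-excerpt listening schedule.

    Within each genre, participant p takes a contiguous block of k excerpts of
    a seeded random genre-specific excerpt ordering, with block starts cycling
    so that row sums (excerpts per participant) and column sums (raters per
    excerpt) are exact.  The schedule is a function of ``config.seed`` only.
    """
    config.validate()
    rng = substream(config.seed, "design")
    n_genres = len(config.genres)
    k = config.excerpts_per_participant // n_genres
    m = config.excerpts_per_genre
    participants = _participant_ids(config.n_participants)
    excerpt_ids = _excerpt_ids(config.n_excerpts)
    assignment: list[tuple[str, str]] = []
    for g in range(n_genres):
        genre_excerpts = list(np.array(excerpt_ids[g * m:(g + 1) * m])[rng.permutation(m)])
        order = rng.permutation(config.n_participants)
        for slot, p_idx in enumerate(order):
            start = (slot * k) % m
            for j in range(k):
                assignment.append((participants[p_idx], genre_excerpts[(start + j) % m]))
    assignment.sort()
    return StudyDesign(assignment=assignment)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u / (1.0 - u))


def _to_range(z: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * _sigmoid(z)


def _from_range(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return _logit((np.asarray(v, dtype=float) - lo) / (hi - lo))


def audio_z_from_values(audio: pd.DataFrame) -> pd.DataFrame:
    """Invert the range transform, recovering the latent z per audio feature."""
    return pd.DataFrame({f: _from_range(audio[f].to_numpy(), *_AUDIO_RANGES[f])
                         for f in audio.columns}, index=audio.index)


def physio_z_from_values(physio: pd.DataFrame) -> pd.DataFrame:
    """Invert the range transform for (baseline-corrected) physio features."""
    return pd.DataFrame({f: _from_range(physio[f].to_numpy(), *_PHYSIO_RANGES[f])
                         for f in physio.columns}, index=physio.index)


def _poly_score(z: pd.DataFrame, linear: dict[str, float],
                quad: dict[str, float] | None = None) -> np.ndarray:
    score = np.zeros(len(z))
    for name, c in linear.items():
        score += c * z[name].to_numpy()
    for name, c in (quad or {}).items():
        score += c * z[name].to_numpy() ** 2
    return score


def audio_latent_raw(audio_z: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Raw (pre-squash) valence/arousal scores of the audio map g."""
    return (_poly_score(audio_z, _G_VALENCE_LIN, _G_VALENCE_QUAD),
            _poly_score(audio_z, _G_AROUSAL_LIN, _G_AROUSAL_QUAD))


def physio_latent_raw(physio_z: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Raw (pre-squash) valence/arousal scores of the physiology map h."""
    return (_poly_score(physio_z, _H_VALENCE_LIN),
            _poly_score(physio_z, _H_AROUSAL_LIN))


def generate_excerpts(config: GeneratorConfig) -> list[ExcerptRecord]:
    """Draw excerpt features and compute the latent valence/arousal signal.

    The four spectral features share one latent factor with loading
    sqrt(collinear_level), so their pairwise correlations sit at the target
    level; all other audio features are independent draws plus a genre offset.
    Physiology is generated from felt-affect drivers coupled to the
    audio-driven affect, then the latent signal mixes g(audio) and h(physio)
    with the configured per-dimension weights.
    """
    config.validate()
    rng = substream(config.seed, "excerpts")
    n = config.n_excerpts
    genres = np.repeat(list(config.genres), config.excerpts_per_genre)
    ids = _excerpt_ids(n)

    load = float(np.sqrt(config.collinear_level))
    factor = rng.standard_normal(n)
    genre_factor_shift = rng.normal(0.0, 0.3, size=len(config.genres))
    genre_shift = rng.normal(0.0, 0.25, size=(len(config.genres), len(config.audio_feature_names)))
    g_idx = np.repeat(np.arange(len(config.genres)), config.excerpts_per_genre)
    factor = factor + genre_factor_shift[g_idx]

    audio_z = {}
    for j, name in enumerate(config.audio_feature_names):
        if name in config.collinear_block:
            jitter = rng.standard_normal(n)
            audio_z[name] = load * factor + np.sqrt(1.0 - load ** 2) * jitter
        else:
            audio_z[name] = rng.standard_normal(n) + genre_shift[g_idx, j]
    audio_z = pd.DataFrame(audio_z)

    g_val_raw, g_aro_raw = audio_latent_raw(audio_z)
    # Felt-affect drivers: partly the audio-driven affect, partly independent.
    a = _FELT_AUDIO_COUPLING
    d_val = a * g_val_raw / max(np.std(g_val_raw), 1e-12) + np.sqrt(1 - a ** 2) * rng.standard_normal(n)
    d_aro = a * g_aro_raw / max(np.std(g_aro_raw), 1e-12) + np.sqrt(1 - a ** 2) * rng.standard_normal(n)

    physio_z = {}
    for name in config.physio_feature_names:
        lam = _PHYSIO_LOADINGS.get(name, 0.0)
        driver = d_val if name in ("Zyg", "Corr") else d_aro
        physio_z[name] = lam * driver + np.sqrt(max(1.0 - lam ** 2, 0.0)) * rng.standard_normal(n)
    physio_z = pd.DataFrame(physio_z)

    h_val_raw, h_aro_raw = physio_latent_raw(physio_z)
    wv_p, wv_f = config.mixing_valence
    wa_p, wa_f = config.mixing_arousal
    latent_val = np.tanh(wv_p * g_val_raw + wv_f * h_val_raw)
    latent_aro = np.tanh(wa_p * g_aro_raw + wa_f * h_aro_raw)

    baseline_z = rng.standard_normal((n, len(config.physio_feature_names)))
    records = []
    for i in range(n):
        audio = {f: float(_to_range(audio_z[f].iloc[i], *_AUDIO_RANGES[f]))
                 for f in config.audio_feature_names}
        physio = {f: float(_to_range(physio_z[f].iloc[i], *_PHYSIO_RANGES[f]))
                  for f in config.physio_feature_names}
        baseline = {f: float(_to_range(baseline_z[i, j], *_PHYSIO_BASELINE_RANGES[f]))
                    for j, f in enumerate(config.physio_feature_names)}
        records.append(ExcerptRecord(
            excerpt_id=ids[i], genre=str(genres[i]), audio=audio, physio=physio,
            physio_baseline=baseline,
            latent_valence=float(latent_val[i]), latent_arousal=float(latent_aro[i]),
        ))
    return records


def generate_ratings(design: StudyDesign, excerpts: list[ExcerptRecord],
                     config: GeneratorConfig) -> StudyDesign:
    """Fill in per-pair ratings and set per-excerpt mean ratings.

    Each (participant, excerpt) rating is the excerpt's latent value plus
    N(0, rating_noise_sd) noise, clipped to the [-1, 1] rating grid; excerpt
    means average over the excerpt's raters.
    """
    rng = substream(config.seed, "ratings")
    by_id = {e.excerpt_id: e for e in excerpts}
    ratings: dict[tuple[str, str], tuple[float, float]] = {}
    for pair in design.assignment:
        e = by_id[pair[1]]
        noise = rng.normal(0.0, config.rating_noise_sd, size=2) if config.rating_noise_sd > 0 \
            else np.zeros(2)
        v = float(np.clip(e.latent_valence + noise[0], -1.0, 1.0))
        a = float(np.clip(e.latent_arousal + noise[1], -1.0, 1.0))
        ratings[pair] = (v, a)
    design.ratings = ratings
    sums: dict[str, list[float]] = {}
    for (_, eid), (v, a) in ratings.items():
        sums.setdefault(eid, [0.0, 0.0, 0.0])
        sums[eid][0] += v
        sums[eid][1] += a
        sums[eid][2] += 1
    for e in excerpts:
        sv, sa, cnt = sums[e.excerpt_id]
        e.valence_mean = sv / cnt
        e.arousal_mean = sa / cnt
    return design


def generate_dataset(config: GeneratorConfig) -> tuple[list[ExcerptRecord], StudyDesign]:
    """Convenience wrapper: design + excerpts + ratings in one call."""
    design = build_design(config)
    excerpts = generate_excerpts(config)
    generate_ratings(design, excerpts, config)
    return excerpts, design


def excerpts_to_frame(excerpts: list[ExcerptRecord]) -> pd.DataFrame:
    rows = []
    for e in excerpts:
        row: dict[str, object] = {"excerpt_id": e.excerpt_id, "genre": e.genre}
        row.update(e.audio)
        row.update(e.physio)
        if e.physio_baseline is not None:
            row.update({f"{k}_baseline": v for k, v in e.physio_baseline.items()})
        row["valence_mean"] = e.valence_mean
        row["arousal_mean"] = e.arousal_mean
        row["latent_valence"] = e.latent_valence
        row["latent_arousal"] = e.latent_arousal
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(excerpts: list[ExcerptRecord], design: StudyDesign,
                  out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``excerpts.csv`` and ``ratings.csv`` (full float precision)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    excerpts_path = out / "excerpts.csv"
    ratings_path = out / "ratings.csv"
    excerpts_to_frame(excerpts).to_csv(excerpts_path, index=False, float_format="%.17g")
    pd.DataFrame(
        [{"participant_id": p, "excerpt_id": e, "valence": v, "arousal": a}
         for (p, e), (v, a) in sorted(design.ratings.items())]
    ).to_csv(ratings_path, index=False, float_format="%.17g")
    return excerpts_path, ratings_path


def read_dataset(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the two CSV artifacts written by :func:`write_dataset`."""
    out = Path(out_dir)
    # round_trip parsing: the exact doubles written come back bit-identical
    return (pd.read_csv(out / "excerpts.csv", float_precision="round_trip"),
            pd.read_csv(out / "ratings.csv", float_precision="round_trip"))
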