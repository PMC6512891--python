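"""Synthetic face-video cohort generator with a multi-rater annotation model.

The generator emulates the structure of the motivating study — ~25 patients,
one short face video each, five psychiatrist raters annotating quality,
range, and subtype of affect — with controllable effect sizes, so that every
downstream stage (normalization, grid features, agreement statistics,
regressions, leave-one-out prediction) can be exercised and validated
without any real clinical footage.

Face model
----------
A parametric gray face on a 96x96 canvas: an elliptical head with static
eye/nose/mouth/cheek features at the canonical landmark positions.  Facial
*dynamics* are intensity modulations applied over the six rectangular part
regions (the same rectangles the analysis partition uses):

* a shared sinusoidal activity signal whose per-region amplitude is set by
  the latent *range* class (flat < blunt < restricted < full) — this is what
  the motion feature measures;
* a two-state expression process (neutral vs. a *quality*-typical
  expression, e.g. sadness for dysphoric patients) that steps region
  templates on and off — this is what the expression and label features
  measure; agitated subtypes switch roughly twice as often;
* pixel noise, and an optional rigid head-pose offset (rotation / scale /
  translation) per video that the landmark-based normalization must undo.

Rater model
-----------
Each rater annotates each patient independently by passing the latent label
through a per-rater, per-domain row-stochastic confusion matrix.  With a
shared confusion matrix C and latent prior pi the expected pairwise
agreement has the closed form sum_j pi_j sum_k C[j,k]^2, which makes the
agreement statistics an analytically controllable target.

Videos default to 300 frames — scaled down from the study's 7-10 minute
interviews; all mid-level features are length-invariant (means, SDs,
counts per video).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.transform import SimilarityTransform, warp

from .errors import ConfigurationError
from .facegrid import (
    CANONICAL_LANDMARK_FRACTIONS,
    DEFAULT_PART_LAYOUT,
    PART_NAMES,
    LandmarkSet,
    write_frames_dir,
    write_landmarks_csv,
)
from .raterstats import AnnotationTable
from .vocab import DOMAINS, EXPRESSION_CLASSES, RANGE_LABELS, SUBTYPE_LABELS

BACKGROUND = 30.0
HEAD_INTENSITY = 170.0

#: Static elliptical features (cx, cy, semi_x, semi_y, intensity), fractions
#: of the frame size.  Purely appearance; dynamics act on part rectangles.
STATIC_ELLIPSES: tuple[tuple[float, float, float, float, float], ...] = (
    (0.50, 0.52, 0.42, 0.47, HEAD_INTENSITY),  # head
    (0.28, 0.28, 0.10, 0.06, 80.0),  # left eye
    (0.72, 0.28, 0.10, 0.06, 80.0),  # right eye
    (0.50, 0.56, 0.06, 0.10, 140.0),  # nose ridge
    (0.50, 0.82, 0.18, 0.05, 90.0),  # mouth
    (0.16, 0.66, 0.09, 0.11, 150.0),  # left cheek
    (0.84, 0.66, 0.09, 0.11, 150.0),  # right cheek
)

#: Oscillation amplitude (gray levels) per latent range class: the ordering
#: flat < blunt < restricted < full is the constructed ground truth the
#: motion feature recovers.
RANGE_AMPLITUDES: dict[str, float] = {"flat": 2.0, "blunt": 6.0, "restricted": 12.0, "full": 20.0}

#: How strongly each facial part expresses the shared activity signal.
REGION_WEIGHTS: dict[str, float] = {
    "left_eye": 1.0,
    "right_eye": 1.0,
    "mouth": 1.0,
    "nose": 0.3,
    "left_cheek": 0.6,
    "right_cheek": 0.6,
}

#: Region intensity offsets (gray levels) defining each expression class.
#: Each template is (approximately) zero-mean over the whole face, so that
#: expression switching reshapes the face without shifting the per-frame
#: mean gray level — the motion feature then isolates the oscillation
#: amplitude rather than the expression process.
EXPRESSION_TEMPLATES: dict[str, dict[str, float]] = {
    "norm": {},
    "anger": {"left_eye": -45.0, "right_eye": -45.0, "left_cheek": 34.0, "right_cheek": 34.0},
    "disgust": {"nose": 45.0, "mouth": -35.0, "left_cheek": 6.0, "right_cheek": 6.0},
    "fear": {"left_eye": 40.0, "right_eye": 40.0, "mouth": -40.0, "nose": -40.0},
    "happiness": {"mouth": 45.0, "nose": -45.0, "left_eye": -15.0, "right_eye": -15.0},
    "sadness": {"mouth": -45.0, "nose": 45.0, "left_eye": 15.0, "right_eye": 15.0},
    "surprise": {"left_eye": 35.0, "right_eye": 35.0, "mouth": 45.0,
                 "left_cheek": -49.0, "right_cheek": -49.0},
}

#: Mixture over expressions shown in the "expressive" state per quality class.
QUALITY_EXPRESSIONS: dict[str, dict[str, float]] = {
    "dysphoric": {"sadness": 0.7, "anger": 0.3},
    "euthymic": {"norm": 0.5, "happiness": 0.5},
    "manic": {"surprise": 0.5, "happiness": 0.5},
}

#: Subtypes modeled as agitated: expression switching runs twice as fast.
AGITATED_SUBTYPES = frozenset({"irritable", "anxious", "frightened"})

#: Latent class priors; quality and range loosely follow the inpatient
#: profile of the motivating study (euthymic-dominant quality, blunt/
#: restricted-dominant range, "unknown"/"stupid"-dominant subtype).
DEFAULT_PRIORS: dict[str, dict[str, float]] = {
    "quality": {"dysphoric": 0.20, "euthymic": 0.70, "manic": 0.10},
    "range": {"full": 0.20, "restricted": 0.30, "blunt": 0.30, "flat": 0.20},
    "subtype": {
        lab: (0.35 if lab == "unknown" else 0.20 if lab == "stupid" else 0.045)
        for lab in SUBTYPE_LABELS
    },
}

#: Diagonal reliability of the default rater confusion matrices per domain.
DEFAULT_RELIABILITY: dict[str, float] = {"quality": 0.9, "range": 0.9, "subtype": 0.7}


@dataclass(frozen=True)
class PoseJitter:
    """Rigid head-pose offset ranges applied per video (camera vs. canonical)."""

    max_rotation: float = 0.06  # radians
    max_log_scale: float = 0.05
    max_translation: float = 3.0  # pixels


@dataclass
class EffectConfig:
    """Effect sizes tying latent affect to facial dynamics.

    All scalars are gray levels or probabilities and must be non-negative.
    The defaults define the strong-effect study conditions: range classes
    well separated in motion, quality visible in expression mixtures.
    """

    range_amplitudes: dict[str, float] = field(default_factory=lambda: dict(RANGE_AMPLITUDES))
    region_weights: dict[str, float] = field(default_factory=lambda: dict(REGION_WEIGHTS))
    #: Regions whose amplitude follows the latent range class; the rest
    #: oscillate with ``uncoupled_amplitude`` regardless of the label.
    label_coupled_regions: frozenset[str] = frozenset(PART_NAMES)
    uncoupled_amplitude: float = 8.0
    expression_strength: float = 0.5
    switch_prob: float = 1.0 / 60.0
    pixel_noise_sd: float = 2.0
    amplitude_jitter: float = 0.2  # multiplicative U(1-j, 1+j) per video
    period_frames: tuple[float, float] = (40.0, 80.0)
    pose_jitter: PoseJitter | None = field(default_factory=PoseJitter)

    def validate(self) -> None:
        scalars = (
            list(self.range_amplitudes.values())
            + list(self.region_weights.values())
            + [self.uncoupled_amplitude, self.expression_strength, self.switch_prob,
               self.pixel_noise_sd, self.amplitude_jitter]
        )
        if any(s < 0 for s in scalars):
            raise ConfigurationError("all effect scalars must be non-negative")
        if set(self.range_amplitudes) != set(RANGE_LABELS):
            raise ConfigurationError("range_amplitudes must cover all range classes")
        if not set(self.label_coupled_regions) <= set(PART_NAMES):
            raise ConfigurationError("label_coupled_regions must be facial part names")


@dataclass(frozen=True)
class LatentAffect:
    """Ground-truth affect state of one synthetic patient."""

    patient_id: str
    quality: str
    range: str
    subtype: str

    def __post_init__(self) -> None:
        for domain, value in (("quality", self.quality), ("range", self.range),
                              ("subtype", self.subtype)):
            if value not in DOMAINS[domain]:
                raise ValueError(f"{value!r} is not a {domain} label")

    def label(self, domain: str) -> str:
        return {"quality": self.quality, "range": self.range, "subtype": self.subtype}[domain]


def uniform_confusion(n_classes: int, reliability: float) -> np.ndarray:
    """Row-stochastic confusion: keep the true label w.p. ``reliability`` plus
    a uniform component over all classes."""
    if not 0.0 <= reliability <= 1.0:
        raise ConfigurationError("reliability must lie in [0, 1]")
    return reliability * np.eye(n_classes) + (1.0 - reliability) / n_classes * np.ones(
        (n_classes, n_classes)
    )


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort."""

    n_patients: int = 25
    n_raters: int = 5
    n_frames: int = 300
    frame_size: int = 96
    seed: int = 0
    affect_effect: EffectConfig = field(default_factory=EffectConfig)
    #: Per-domain latent priors (probabilities over the domain vocabulary).
    priors: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(p) for d, p in DEFAULT_PRIORS.items()}
    )
    #: rater_id -> domain -> row-stochastic confusion matrix over that
    #: domain's labels.  When None, built from ``reliability`` for every rater.
    rater_confusions: dict[str, dict[str, np.ndarray]] | None = None
    reliability: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RELIABILITY))

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("a cohort needs at least 2 patients")
        if self.n_raters < 1:
            raise ConfigurationError("a cohort needs at least 1 rater")
        self.affect_effect.validate()
        for domain, prior in self.priors.items():
            vocab = DOMAINS[domain]
            if set(prior) != set(vocab):
                raise ConfigurationError(f"prior for {domain} must cover its vocabulary")
            if abs(sum(prior.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"prior for {domain} must sum to 1")
        if self.rater_confusions is None:
            self.rater_confusions = {
                rater: {
                    domain: uniform_confusion(len(DOMAINS[domain]), self.reliability[domain])
                    for domain in DOMAINS
                }
                for rater in self.rater_ids
            }
        for rater, by_domain in self.rater_confusions.items():
            for domain, C in by_domain.items():
                C = np.asarray(C, dtype=float)
                K = len(DOMAINS[domain])
                if C.shape != (K, K):
                    raise ConfigurationError(
                        f"confusion matrix for {rater}/{domain} must be {K}x{K}"
                    )
                if np.any(C < 0) or np.any(np.abs(C.sum(axis=1) - 1.0) > 1e-9):
                    raise ConfigurationError(
                        f"confusion rows for {rater}/{domain} must be non-negative "
                        "and sum to 1"
                    )
                by_domain[domain] = C

    @property
    def rater_ids(self) -> tuple[str, ...]:
        return tuple(f"rater_{i + 1}" for i in range(self.n_raters))

    @property
    def patient_ids(self) -> tuple[str, ...]:
        return tuple(f"patient_{i:03d}" for i in range(self.n_patients))


@dataclass
class PatientVideo:
    patient_id: str
    frames: np.ndarray  # (n_frames, size, size), gray levels in [0, 255]
    landmarks: list[LandmarkSet]
    latent: LatentAffect


@dataclass
class SyntheticCohort:
    config: CohortConfig
    patients: list[PatientVideo]
    annotations: AnnotationTable

    @property
    def latents(self) -> list[LatentAffect]:
        return [p.latent for p in self.patients]


# ---------------------------------------------------------------------------
# Rendering


def _ellipse_mask(size: int, cx: float, cy: float, sx: float, sy: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx * size) / (sx * size)) ** 2 + ((yy - cy * size) / (sy * size)) ** 2 <= 1.0


def _rect_mask(size: int, rect: tuple[float, float, float, float]) -> np.ndarray:
    x0, y0, x1, y1 = rect
    yy, xx = np.mgrid[0:size, 0:size]
    cx, cy = (xx + 0.5) / size, (yy + 0.5) / size
    return (x0 <= cx) & (cx <= x1) & (y0 <= cy) & (cy <= y1)


def base_face(size: int) -> np.ndarray:
    """The static face image: background, head ellipse, facial features."""
    img = np.full((size, size), BACKGROUND)
    for cx, cy, sx, sy, val in STATIC_ELLIPSES:
        img[_ellipse_mask(size, cx, cy, sx, sy)] = val
    return img


def canonical_landmarks(size: int) -> LandmarkSet:
    return LandmarkSet(
        {n: (x * size, y * size) for n, (x, y) in CANONICAL_LANDMARK_FRACTIONS.items()}
    )


def _expression_states(
    n_frames: int, latent: LatentAffect, effect: EffectConfig, rng: np.random.Generator
) -> list[str]:
    """Two-state (neutral / quality-typical expression) switching sequence."""
    mixture = QUALITY_EXPRESSIONS[latent.quality]
    exprs = sorted(mixture, key=EXPRESSION_CLASSES.index)
    probs = np.array([mixture[e] for e in exprs])
    p_switch = effect.switch_prob * (2.0 if latent.subtype in AGITATED_SUBTYPES else 1.0)
    states: list[str] = []
    current = "norm"
    for _ in range(n_frames):
        if rng.random() < p_switch:
            if current == "norm":
                current = exprs[rng.choice(len(exprs), p=probs / probs.sum())]
            else:
                current = "norm"
        states.append(current)
    return states


def render_face_video(
    latent: LatentAffect,
    n_frames: int = 300,
    frame_size: int = 96,
    seed: int = 0,
    effect: EffectConfig | None = None,
) -> tuple[np.ndarray, list[LandmarkSet]]:
    """Render one patient's video and its per-frame ground-truth landmarks.

    Frames are gray levels in [0, 255].  Region intensities oscillate with
    amplitudes set by the latent affect (see module docstring); the
    returned landmarks are the generator's true feature coordinates,
    including any rigid pose offset.
    """
    if n_frames < 2:
        raise ValueError("a video needs at least 2 frames (motion SD undefined)")
    effect = effect or EffectConfig()
    effect.validate()
    rng = np.random.default_rng(seed)
    size = frame_size

    # per-video draws, in fixed order for reproducibility
    period = rng.uniform(*effect.period_frames)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    jitter = (
        rng.uniform(1.0 - effect.amplitude_jitter, 1.0 + effect.amplitude_jitter)
        if effect.amplitude_jitter > 0
        else 1.0
    )
    states = _expression_states(n_frames, latent, effect, rng)

    n = np.arange(n_frames)
    activity = np.sin(2.0 * math.pi * n / period + phase)
    base_amp = effect.range_amplitudes[latent.range] * jitter
    masks = {part: _rect_mask(size, DEFAULT_PART_LAYOUT[part]) for part in PART_NAMES}

    frames = np.repeat(base_face(size)[None, :, :], n_frames, axis=0)
    expr_idx = np.array([EXPRESSION_CLASSES.index(s) for s in states])
    for part in PART_NAMES:
        amp = base_amp if part in effect.label_coupled_regions else effect.uncoupled_amplitude
        osc = effect.region_weights.get(part, 0.0) * amp * activity
        tmpl = np.array(
            [EXPRESSION_TEMPLATES[e].get(part, 0.0) for e in EXPRESSION_CLASSES]
        )
        delta = osc + effect.expression_strength * tmpl[expr_idx]
        frames[:, masks[part]] += delta[:, None]
    if effect.pixel_noise_sd > 0:
        frames += rng.normal(0.0, effect.pixel_noise_sd, frames.shape)

    lm = canonical_landmarks(size)
    if effect.pose_jitter is not None:
        pj = effect.pose_jitter
        rot = rng.uniform(-pj.max_rotation, pj.max_rotation)
        scale = math.exp(rng.uniform(-pj.max_log_scale, pj.max_log_scale))
        tx, ty = rng.uniform(-pj.max_translation, pj.max_translation, size=2)
        c = (size - 1) / 2.0
        pose = (
            SimilarityTransform(translation=(-c, -c))
            + SimilarityTransform(rotation=rot, scale=scale)
            + SimilarityTransform(translation=(c + tx, c + ty))
        )
        inv = pose.inverse
        frames = np.stack(
            [
                warp(f, inv, output_shape=(size, size), order=1, cval=BACKGROUND,
                     preserve_range=True)
                for f in frames
            ]
        )
        pts = pose(lm.as_array(tuple(lm.points)))
        lm = LandmarkSet({name: tuple(p) for name, p in zip(lm.points, pts)})

    frames = np.clip(frames, 0.0, 255.0)
    return frames, [lm] * n_frames


# ---------------------------------------------------------------------------
# Latents, annotations, cohort


def _draw_latents(config: CohortConfig, rng: np.random.Generator) -> list[LatentAffect]:
    out = []
    for pid in config.patient_ids:
        picks = {}
        for domain in ("quality", "range", "subtype"):
            vocab = DOMAINS[domain]
            p = np.array([config.priors[domain][lab] for lab in vocab])
            picks[domain] = vocab[rng.choice(len(vocab), p=p)]
        out.append(LatentAffect(pid, picks["quality"], picks["range"], picks["subtype"]))
    return out


def annotate_cohort(
    latents: list[LatentAffect], config: CohortConfig, rng: np.random.Generator
) -> AnnotationTable:
    """Apply each rater's confusion matrix independently per patient and domain."""
    records = []
    for latent in latents:
        for rater in config.rater_ids:
            for domain in ("quality", "range", "subtype"):
                vocab = DOMAINS[domain]
                C = config.rater_confusions[rater][domain]
                j = vocab.index(latent.label(domain))
                k = rng.choice(len(vocab), p=C[j])
                records.append(
                    {
                        "patient_id": latent.patient_id,
                        "rater_id": rater,
                        "domain": domain,
                        "label": vocab[k],
                    }
                )
    return AnnotationTable.from_records(records)


def generate_latents_and_annotations(
    config: CohortConfig,
) -> tuple[list[LatentAffect], AnnotationTable]:
    """Latent states and rater annotations only (no video rendering).

    Used for rater-model calibration at large n, where videos are not needed.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_latent, ss_ann, _ = ss.spawn(3)
    latents = _draw_latents(config, np.random.default_rng(ss_latent))
    table = annotate_cohort(latents, config, np.random.default_rng(ss_ann))
    return latents, table


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort: videos, landmarks, latents, annotations.

    Deterministic for a fixed config and seed.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_latent, ss_ann, ss_video = ss.spawn(3)
    latents = _draw_latents(config, np.random.default_rng(ss_latent))
    table = annotate_cohort(latents, config, np.random.default_rng(ss_ann))
    video_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss_video.spawn(len(latents))]
    patients = []
    for latent, vseed in zip(latents, video_seeds):
        frames, lms = render_face_video(
            latent, config.n_frames, config.frame_size, vseed, config.affect_effect
        )
        patients.append(PatientVideo(latent.patient_id, frames, lms, latent))
    return SyntheticCohort(config, patients, table)


def analytic_pairwise_agreement(
    prior: dict[str, float] | np.ndarray,
    confusion_a: np.ndarray,
    confusion_b: np.ndarray | None = None,
    domain: str | None = None,
) -> float:
    """Expected percent agreement of two independent raters sharing a latent.

    P(agree) = sum_j pi_j sum_k C_a[j,k] * C_b[j,k]; returned in percent.
    """
    if isinstance(prior, dict):
        vocab = DOMAINS[domain] if domain else tuple(sorted(prior))
        pi = np.array([prior[lab] for lab in vocab])
    else:
        pi = np.asarray(prior, dtype=float)
    Ca = np.asarray(confusion_a, dtype=float)
    Cb = Ca if confusion_b is None else np.asarray(confusion_b, dtype=float)
    return 100.0 * float(np.sum(pi[:, None] * Ca * Cb))


# ---------------------------------------------------------------------------
# Expression training set


def generate_expression_trainingset(
    n_per_class: int,
    frame_size: int = 96,
    seed: int = 0,
    noise_sd: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled single frames for the seven expression classes.

    Each frame is the static face plus the class's region template at full
    strength plus pixel noise.  Returns (frames, labels) with
    ``7 * n_per_class`` frames in fixed class order; deterministic per seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    rng = np.random.default_rng(seed)
    base = base_face(frame_size)
    masks = {part: _rect_mask(frame_size, DEFAULT_PART_LAYOUT[part]) for part in PART_NAMES}
    frames, labels = [], []
    for cls in EXPRESSION_CLASSES:
        img = base.copy()
        for part, delta in EXPRESSION_TEMPLATES[cls].items():
            img[masks[part]] += delta
        for _ in range(n_per_class):
            f = img if noise_sd == 0 else img + rng.normal(0.0, noise_sd, img.shape)
            frames.append(np.clip(f, 0.0, 255.0))
            labels.append(cls)
    return np.stack(frames), np.array(labels)


# ---------------------------------------------------------------------------
# IO


def _config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["rater_confusions"] = {
        rater: {dom: np.asarray(C).tolist() for dom, C in by_dom.items()}
        for rater, by_dom in config.rater_confusions.items()
    }
    eff = d["affect_effect"]
    eff["label_coupled_regions"] = sorted(config.affect_effect.label_coupled_regions)
    eff["period_frames"] = list(config.affect_effect.period_frames)
    return d


def write_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=True))


def read_config(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    eff = d.pop("affect_effect", None)
    if eff is not None:
        pj = eff.pop("pose_jitter", None)
        eff["pose_jitter"] = PoseJitter(**pj) if pj is not None else None
        eff["label_coupled_regions"] = frozenset(eff.get("label_coupled_regions", PART_NAMES))
        eff["period_frames"] = tuple(eff.get("period_frames", (40.0, 80.0)))
        d["affect_effect"] = EffectConfig(**eff)
    conf = d.pop("rater_confusions", None)
    if conf is not None:
        d["rater_confusions"] = {
            rater: {dom: np.asarray(C, dtype=float) for dom, C in by_dom.items()}
            for rater, by_dom in conf.items()
        }
    return CohortConfig(**d)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write frames (PNG), landmarks (CSV), annotations, latents and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for patient in cohort.patients:
        write_frames_dir(patient.frames, outdir / "frames" / patient.patient_id)
        write_landmarks_csv(
            patient.landmarks, outdir / "frames" / f"{patient.patient_id}_landmarks.csv"
        )
    cohort.annotations.to_csv(outdir / "annotations.csv")
    import pandas as pd

    pd.DataFrame(
        [
            {"patient_id": l.patient_id, "quality": l.quality, "range": l.range,
             "subtype": l.subtype}
            for l in cohort.latents
        ]
    ).to_csv(outdir / "latents.csv", index=False)
    write_config(cohort.config, outdir / "config.yaml")
    return outdir
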