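"""Synthetic Parkinsonian speech cohort generator.

Emulates a clinical ON/OFF recording study: each patient performs seven speech
protocols (digits, months, vowels, pataka, twisters, read, monologue) in both
medication states. Two linked data products are produced per recording:

* a phone-attribute posterior stream — frames x 21 probabilities over a fixed
  inventory of distinctive phonological features (plus silence), built from a
  scripted phone template for the protocol; and
* a mono waveform (44.1 kHz source-filter synthesis: harmonic source with
  formant resonances for voiced sounds, shaped noise for fricatives, bursts
  for stops).

The OFF state degrades both products in the directions hypokinetic dysarthria
moves real speech: distinctive features drop out of articulation (sparser
quantized codes), extra pauses appear, attribute posteriors shift by
configurable offsets, speaking rate changes, loudness drops, aspiration noise
rises, and pitch jitters. Every degradation is scaled by a per-patient x
per-protocol effect multiplier, drawn log-normally so some protocols are
uninformative for some patients — which is exactly what makes personalized
protocol selection consequential.

Generation is a pure function of (config, seed): per-recording random streams
are derived from ``SeedSequence([seed, patient, protocol, state])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .errors import ConfigurationError
from .features import PosteriorStream, Waveform, write_posteriors, write_wav

# ---------------------------------------------------------------------------
# Phone-attribute inventory
# ---------------------------------------------------------------------------

#: Canonical 21-attribute inventory: "silence" plus 20 distinctive features.
ATTRIBUTES: tuple[str, ...] = (
    "silence",
    "vocalic",
    "consonantal",
    "continuant",
    "sonorant",
    "voice",
    "nasal",
    "strident",
    "fricative",
    "lateral",
    "retroflex",
    "anterior",
    "coronal",
    "labial",
    "high",
    "mid",
    "low",
    "back",
    "round",
    "tense",
    "velar",
)

SILENCE_INDEX = ATTRIBUTES.index("silence")

# Synthetic phone inventory. The feature assignments are deliberately
# simplified: only the contrasts between phones matter for classification,
# not phonetic fidelity. /t/ carries both "coronal" and "high" so that these
# two attributes are co-active within the pataka task.
_PHONE_FEATURES: dict[str, tuple[str, ...]] = {
    "sil": ("silence",),
    "a": ("vocalic", "sonorant", "voice", "continuant", "low", "back", "tense"),
    "e": ("vocalic", "sonorant", "voice", "continuant", "mid", "anterior", "tense"),
    "i": ("vocalic", "sonorant", "voice", "continuant", "high", "anterior", "tense"),
    "o": ("vocalic", "sonorant", "voice", "continuant", "mid", "back", "round", "tense"),
    "u": ("vocalic", "sonorant", "voice", "continuant", "high", "back", "round", "tense"),
    "p": ("consonantal", "labial", "anterior"),
    "t": ("consonantal", "coronal", "anterior", "high"),
    "k": ("consonantal", "velar", "back"),
    "b": ("consonantal", "labial", "anterior", "voice"),
    "d": ("consonantal", "coronal", "anterior", "voice"),
    "g": ("consonantal", "velar", "back", "voice"),
    "m": ("consonantal", "labial", "nasal", "sonorant", "voice"),
    "n": ("consonantal", "coronal", "nasal", "sonorant", "voice", "anterior"),
    "l": ("consonantal", "lateral", "sonorant", "voice", "coronal", "continuant"),
    "r": ("consonantal", "retroflex", "sonorant", "voice", "continuant"),
    "s": ("consonantal", "fricative", "strident", "continuant", "coronal", "anterior"),
    "f": ("consonantal", "fricative", "continuant", "labial", "anterior"),
    "sh": ("consonantal", "fricative", "strident", "continuant", "coronal", "high"),
    "v": ("consonantal", "fricative", "continuant", "labial", "anterior", "voice"),
    "h": ("consonantal", "fricative", "continuant"),
}

VOWELS = ("a", "e", "i", "o", "u")


@dataclass
class PhoneAttributeMap:
    """Phone label -> canonical 21-bit attribute vector."""

    attribute_names: tuple[str, ...] = ATTRIBUTES
    vectors: Mapping[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PhoneAttributeMap":
        idx = {a: i for i, a in enumerate(ATTRIBUTES)}
        vecs = {}
        for phone, feats in _PHONE_FEATURES.items():
            v = np.zeros(len(ATTRIBUTES), dtype=np.float64)
            for f in feats:
                v[idx[f]] = 1.0
            vecs[phone] = v
        return cls(vectors=vecs)

    def vector(self, phone: str) -> np.ndarray:
        try:
            return self.vectors[phone]
        except KeyError:
            raise ConfigurationError(f"unknown phone {phone!r} in template") from None


# ---------------------------------------------------------------------------
# Protocol templates
# ---------------------------------------------------------------------------

def _words(*words: str) -> tuple[str, ...]:
    out: list[str] = ["sil"]
    for w in words:
        out.extend(w.split())
        out.append("sil")
    return tuple(out)


#: Scripted phone sequences. Lengths and phone diversity differ by protocol
#: the way the clinical tasks do: vowels/pataka are short and stereotyped,
#: read/monologue are long and diverse.
PROTOCOL_TEMPLATES: dict[str, tuple[str, ...]] = {
    "digits": _words("a i n s", "t s v a i", "d r a i", "f i r", "f u e n f",
                     "s e k s", "s i b e n", "a k t", "n o i n", "t s e n"),
    "months": _words("i a n u a r", "f e b r u a r", "m e r t s", "a p r i l",
                     "m a i", "i u n i", "i u l i", "a u g u s t",
                     "s e p t e m b e r", "o k t o b e r", "n o v e m b e r",
                     "d e t s e m b e r"),
    "vowels": _words("a a", "e e", "i i", "o o", "u u"),
    "pataka": _words("p a t a k a", "p a k a t a", "p e t a k a", "p e k a t a"),
    "twisters": _words("l i b e l i l i l e m a n",
                       "d r i t e b e r i t e n e k a v a l e r i",
                       "sh l a i m i g sh u p e n d e sh e l f i sh"),
    "read": _words("d e r n o r d v i n d u n d i s o n e",
                   "sh t r i t e n s i k",
                   "v e r f o n i n e n d e r sh t e r k e r e v e r e",
                   "a l s a i n v a n d e r e r d a h e r k a m"),
    "monologue": _words("i k s e e a i n e m u t e r",
                        "d i d a s g e sh i r a b v e sh t",
                        "d i k i n d e r n e m e n k e k s e",
                        "d e r sh t u l k i p t u m",
                        "d a s v a s e r l o i f t u e b e r"),
}

PROTOCOLS: tuple[str, ...] = tuple(PROTOCOL_TEMPLATES)

#: Baseline informativeness weight per protocol, multiplying every OFF-state
#: effect. Mirrors the clinical observation that articulation-stressing tasks
#: (pataka, vowels, twisters) separate the motor states well while connected
#: speech (read, monologue) separates them poorly.
PROTOCOL_INFORMATIVENESS: dict[str, float] = {
    "pataka": 1.0,
    "vowels": 1.0,
    "twisters": 0.85,
    "digits": 0.7,
    "months": 0.7,
    "read": 0.15,
    "monologue": 0.12,
}

# phone durations in 10-ms frames
_PHONE_FRAMES = {"sil": 8}
_VOWEL_FRAMES = 12
_CONSONANT_FRAMES = 6


def _phone_frames(phone: str) -> int:
    if phone in _PHONE_FRAMES:
        return _PHONE_FRAMES[phone]
    return _VOWEL_FRAMES if phone in VOWELS else _CONSONANT_FRAMES


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default ON-minus-OFF posterior offsets. Positive means the attribute's
#: posterior is higher in the ON state. Fricative/continuant/tense run the
#: other way (stronger in OFF) to keep both signs represented.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "fricative": -0.12,
    "continuant": -0.10,
    "tense": -0.08,
    "voice": 0.10,
    "vocalic": 0.08,
}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    All OFF-state degradations are multiplied by a per-patient x per-protocol
    effect multiplier (log-normal, sigma ``patient_heterogeneity``, times the
    protocol informativeness weight).
    """

    n_patients: int = 14
    protocols: tuple[str, ...] = PROTOCOLS
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    dropout_prob_off: float = 0.35
    silence_boost_off: float = 0.12
    rate_factor_off: float = 1.1
    patient_heterogeneity: float = 0.5
    seed: int = 0
    # posterior noise model: canonically active attributes are realized
    # reliably (their posteriors essentially never fall below 0.5), while
    # inactive attributes occasionally pop above threshold — spurious
    # activations. noise_sd is a master scale; 0 returns exact binary frames.
    noise_sd: float = 1.0
    active_logit: float = 3.0
    active_noise_sd: float = 0.5
    inactive_logit: float = -1.5
    inactive_noise_sd: float = 1.2
    # speaker idiosyncrasy: per-patient x per-attribute logit offset applied
    # identically to both states (does not create ON/OFF contrast)
    speaker_variability: float = 0.4
    # audio OFF-state effects (at patient_effect == 1)
    gain_reduction_db: float = 6.0
    aspiration_level: float = 0.05
    pitch_jitter: float = 0.04
    # plumbing
    frame_period: float = 0.01
    min_duration: float = 10.0
    audio_rate: int = 44_100
    protocol_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(PROTOCOL_INFORMATIVENESS)
    )
    effect_multipliers: np.ndarray | None = None  # (n_patients, n_protocols) override

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        for p in self.protocols:
            if p not in PROTOCOL_TEMPLATES:
                raise ConfigurationError(f"unknown protocol {p!r}")
        for name, v in [
            ("dropout_prob_off", self.dropout_prob_off),
            ("silence_boost_off", self.silence_boost_off),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.rate_factor_off <= 0:
            raise ConfigurationError("rate_factor_off must be positive")
        for a, off in self.effect_sizes.items():
            if a not in ATTRIBUTES:
                raise ConfigurationError(f"unknown attribute {a!r} in effect_sizes")
            if not -1.0 <= off <= 1.0:
                raise ConfigurationError(f"effect size for {a!r} outside [-1, 1]")
        if self.effect_multipliers is not None:
            em = np.asarray(self.effect_multipliers, dtype=np.float64)
            if em.shape != (self.n_patients, len(self.protocols)):
                raise ConfigurationError(
                    "effect_multipliers must have shape (n_patients, n_protocols)"
                )

    @classmethod
    def null(cls, **kw) -> "CohortConfig":
        """A cohort with every ON/OFF effect removed (chance-level truth)."""
        kw.setdefault("effect_sizes", {})
        kw.setdefault("dropout_prob_off", 0.0)
        kw.setdefault("silence_boost_off", 0.0)
        kw.setdefault("rate_factor_off", 1.0)
        kw.setdefault("gain_reduction_db", 0.0)
        kw.setdefault("aspiration_level", 0.0)
        kw.setdefault("pitch_jitter", 0.0)
        kw.setdefault("patient_heterogeneity", 0.0)
        return cls(**kw)


def single_informative_config(
    n_patients: int = 5,
    protocols: tuple[str, ...] = ("pataka", "vowels", "read"),
    strength: float = 1.5,
    seed: int = 0,
    **kw,
) -> CohortConfig:
    """A maximally heterogeneous cohort: for each patient exactly one
    protocol carries the ON/OFF effect (cycled across patients) and the rest
    are uninformative — the regime where personalized protocol selection
    should beat the all-protocol vote."""
    mult = np.zeros((n_patients, len(protocols)))
    for i in range(n_patients):
        mult[i, i % len(protocols)] = strength
    return CohortConfig(
        n_patients=n_patients,
        protocols=protocols,
        effect_multipliers=mult,
        seed=seed,
        **kw,
    )


def _recording_seed(seed: int, patient: int, protocol: str, state: str) -> np.random.Generator:
    pidx = PROTOCOLS.index(protocol)
    sidx = 0 if state == "ON" else 1
    return np.random.default_rng(np.random.SeedSequence([seed, patient, pidx, sidx]))


def effect_multipliers(config: CohortConfig) -> np.ndarray:
    """Per-patient x per-protocol OFF-effect multipliers."""
    config.validate()
    if config.effect_multipliers is not None:
        return np.asarray(config.effect_multipliers, dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10_007]))
    raw = np.exp(
        rng.normal(
            -0.5 * config.patient_heterogeneity**2,
            config.patient_heterogeneity,
            size=(config.n_patients, len(config.protocols)),
        )
    )
    weights = np.array([config.protocol_weights.get(p, 1.0) for p in config.protocols])
    return raw * weights


# ---------------------------------------------------------------------------
# Posterior synthesis
# ---------------------------------------------------------------------------

def _expand_template(
    protocol: str,
    rate_factor: float,
    min_frames: int,
) -> list[tuple[str, int]]:
    """Repeat the protocol's phone template until >= min_frames, with
    per-phone frame counts scaled by ``rate_factor``."""
    template = PROTOCOL_TEMPLATES[protocol]
    seq: list[tuple[str, int]] = []
    total = 0
    while total < min_frames:
        for phone in template:
            n = max(1, int(round(_phone_frames(phone) * rate_factor)))
            seq.append((phone, n))
            total += n
    return seq


def synthesize_posteriors(
    protocol: str,
    state: str,
    patient_effect: float,
    attr_map: PhoneAttributeMap | None = None,
    seed: int | np.random.Generator = 0,
    config: CohortConfig | None = None,
    speaker_offset: np.ndarray | None = None,
) -> PosteriorStream:
    """Generate one recording's phone-attribute posterior stream.

    ON frames are the canonical binary vector of the current phone passed
    through a logistic-squashed Gaussian perturbation,
    ``p = expit(base_logit + noise_sd * sd * g)``, asymmetric between
    canonically active attributes (reliably realized: high base logit, low
    spread) and inactive ones (occasional spurious activations above the
    0.5 quantization threshold). With ``noise_sd`` zero the canonical vector
    is returned exactly. OFF applies, scaled by ``patient_effect``:
    per-phone-instance attribute dropout (subset codes the ON state never
    produces), inserted silence, per-attribute posterior offsets, and rate
    scaling.
    """
    cfg = config or CohortConfig()
    if protocol not in PROTOCOL_TEMPLATES:
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    if state not in ("ON", "OFF"):
        raise ConfigurationError(f"state must be ON or OFF, got {state!r}")
    amap = attr_map or PhoneAttributeMap.default()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    off = state == "OFF"
    pe = float(patient_effect)
    rate = 1.0 + (cfg.rate_factor_off - 1.0) * pe if off else 1.0
    min_frames = int(np.ceil(cfg.min_duration / cfg.frame_period * (rate if off else 1.0)))
    seq = _expand_template(protocol, rate, min_frames)

    sil_vec = np.zeros(len(ATTRIBUTES))
    sil_vec[SILENCE_INDEX] = 1.0
    p_drop = min(1.0, cfg.dropout_prob_off * pe) if off else 0.0
    p_sil = min(1.0, cfg.silence_boost_off * pe) if off else 0.0

    rows: list[np.ndarray] = []
    for phone, n in seq:
        c = amap.vector(phone).copy()
        if off and phone != "sil" and p_drop > 0:
            active = np.flatnonzero(c)
            drop = active[(rng.random(active.size) < p_drop) & (active != SILENCE_INDEX)]
            c[drop] = 0.0
        rows.append(np.tile(c, (n, 1)))
        if off and p_sil > 0 and phone != "sil" and rng.random() < p_sil:
            rows.append(np.tile(sil_vec, (max(2, n // 2), 1)))
    canon = np.concatenate(rows, axis=0)

    if cfg.noise_sd == 0.0:
        post = canon.copy()
    else:
        logits = np.where(canon > 0, cfg.active_logit, cfg.inactive_logit)
        if speaker_offset is not None:
            logits = logits + speaker_offset
        sd = np.where(canon > 0, cfg.active_noise_sd, cfg.inactive_noise_sd)
        logits = logits + cfg.noise_sd * sd * rng.standard_normal(canon.shape)
        post = 1.0 / (1.0 + np.exp(-logits))
    if off and cfg.effect_sizes:
        for attr, delta in cfg.effect_sizes.items():
            j = ATTRIBUTES.index(attr)
            post[:, j] = np.clip(post[:, j] - delta * pe, 0.0, 1.0)
    return PosteriorStream(post, ATTRIBUTES, frame_period=cfg.frame_period)


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------

_FORMANTS = {
    "a": (700, 1220), "e": (480, 1900), "i": (300, 2300),
    "o": (450, 900), "u": (320, 800),
    "m": (250, 1100), "n": (280, 1300), "l": (350, 1500), "r": (380, 1300),
}
_FRIC_BANDS = {"s": (4000, 7000), "sh": (2000, 4000), "f": (1200, 6500),
               "v": (900, 4000), "h": (400, 3000)}


def _resonate(x: np.ndarray, freq: float, bw: float, fs: int) -> np.ndarray:
    r = np.exp(-np.pi * bw / fs)
    a = [1.0, -2.0 * r * np.cos(2.0 * np.pi * freq / fs), r * r]
    return lfilter([1.0 - r], a, x)


def _bandnoise(n: int, lo: float, hi: float, fs: int, rng: np.random.Generator) -> np.ndarray:
    x = rng.standard_normal(n)
    x = _resonate(x, (lo + hi) / 2.0, hi - lo, fs)
    m = np.max(np.abs(x)) or 1.0
    return x / m


def synthesize_audio(
    protocol: str,
    state: str,
    patient_effect: float,
    seed: int | np.random.Generator = 0,
    config: CohortConfig | None = None,
) -> Waveform:
    """Source-filter synthesis of one recording (mono, 44.1 kHz, >= 10 s).

    Voiced phones are a harmonic pulse source through two formant resonators;
    fricatives are band-limited noise; stops are closure + burst. The OFF
    state, scaled by ``patient_effect``, lowers gain (hypophonia), adds
    aspiration noise (hoarseness), jitters pitch, and scales durations.
    """
    cfg = config or CohortConfig()
    if protocol not in PROTOCOL_TEMPLATES:
        raise ConfigurationError(f"unknown protocol {protocol!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = cfg.audio_rate
    off = state == "OFF"
    pe = float(patient_effect)
    rate = 1.0 + (cfg.rate_factor_off - 1.0) * pe if off else 1.0
    jitter = cfg.pitch_jitter * pe if off else 0.0

    min_frames = int(np.ceil(cfg.min_duration / cfg.frame_period))
    seq = _expand_template(protocol, rate, int(min_frames * (rate if off else 1.0)))

    pieces: list[np.ndarray] = []
    f0_base = 120.0
    for phone, nframes in seq:
        n = int(round(nframes * cfg.frame_period * fs))
        if n <= 0:
            continue
        if phone == "sil":
            pieces.append(1e-4 * rng.standard_normal(n))
            continue
        if phone in _FORMANTS:
            f0 = f0_base * (1.0 + jitter * rng.standard_normal())
            t = np.arange(n) / fs
            # mildly rich harmonic source
            src = np.zeros(n)
            for h in range(1, 9):
                if h * f0 < fs / 2:
                    src += np.sin(2 * np.pi * h * f0 * t) / h
            f1, f2 = _FORMANTS[phone]
            y = _resonate(src, f1, 90.0, fs) + 0.7 * _resonate(src, f2, 120.0, fs)
            y = 0.3 * y / (np.max(np.abs(y)) or 1.0)
            env = np.minimum(1.0, np.minimum(np.arange(n), n - np.arange(n)) / (0.005 * fs))
            pieces.append(y * env)
        elif phone in _FRIC_BANDS:
            lo, hi = _FRIC_BANDS[phone]
            pieces.append(0.12 * _bandnoise(n, lo, hi, fs, rng))
        else:  # stop: closure then burst
            n_clo = int(n * 0.6)
            burst = 0.25 * _bandnoise(n - n_clo, 500, 8000, fs, rng)
            burst *= np.exp(-np.arange(n - n_clo) / (0.01 * fs))
            pieces.append(np.concatenate([1e-4 * rng.standard_normal(n_clo), burst]))
    x = np.concatenate(pieces)

    if off and pe > 0:
        x = x * 10.0 ** (-cfg.gain_reduction_db * pe / 20.0)
        if cfg.aspiration_level > 0:
            x = x + cfg.aspiration_level * pe * _bandnoise(x.size, 300, 6000, fs, rng)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / peak
    return Waveform(x, fs)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory synthetic cohort plus its manifest and clinical-style table."""

    manifest: pd.DataFrame
    streams: dict[tuple[int, str, str], PosteriorStream]
    waveforms: dict[tuple[int, str, str], Waveform]
    clinical: pd.DataFrame
    config: CohortConfig
    multipliers: np.ndarray

    @property
    def patients(self) -> list[int]:
        return sorted(self.manifest["patient_id"].unique())


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
    audio: bool = True,
) -> Cohort:
    """Generate a full cohort; optionally write WAV/CSV files and manifest.

    Keys of ``streams``/``waveforms`` are ``(patient_id, protocol, state)``.
    The clinical-style table assigns each patient ON/OFF severity scores whose
    OFF-ON difference is correlated with the patient's mean injected effect
    multiplier.
    """
    config.validate()
    mult = effect_multipliers(config)
    rows = []
    streams: dict[tuple[int, str, str], PosteriorStream] = {}
    waves: dict[tuple[int, str, str], Waveform] = {}
    root = Path(out_dir) if out_dir is not None else None
    if root is not None:
        try:
            root.mkdir(parents=True, exist_ok=True)
        except OSError as e:
            raise IOError(f"cannot create output directory {root}: {e}") from e

    for pid in range(config.n_patients):
        spk_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 30_011, pid]))
        speaker_offset = spk_rng.normal(0.0, config.speaker_variability, len(ATTRIBUTES))
        for j, protocol in enumerate(config.protocols):
            for state in ("ON", "OFF"):
                rng = _recording_seed(config.seed, pid, protocol, state)
                stream = synthesize_posteriors(
                    protocol, state, mult[pid, j], None, rng, config,
                    speaker_offset=speaker_offset,
                )
                streams[(pid, protocol, state)] = stream
                wav_path = csv_path = ""
                if audio:
                    w = synthesize_audio(protocol, state, mult[pid, j], rng, config)
                    waves[(pid, protocol, state)] = w
                if root is not None:
                    # manifest paths are relative to the cohort directory so
                    # a cohort is byte-identical wherever it is written
                    stem = f"p{pid:02d}_{protocol}_{state}"
                    csv_path = f"{stem}.csv"
                    write_posteriors(stream, root / csv_path)
                    if audio:
                        wav_path = f"{stem}.wav"
                        write_wav(root / wav_path, waves[(pid, protocol, state)])
                rows.append(
                    dict(patient_id=pid, state=state, protocol=protocol,
                         session=0, path=wav_path or csv_path)
                )
    manifest = pd.DataFrame(rows, columns=["patient_id", "state", "protocol", "session", "path"])

    # clinical-style score table: OFF - ON severity tracks the injected effect
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 20_011]))
    mean_mult = mult.mean(axis=1)
    on_scores = np.clip(rng.normal(20, 8, config.n_patients), 2, None).round().astype(int)
    delta = np.clip(12.0 * mean_mult + rng.normal(0, 2, config.n_patients), 1, None)
    clinical = pd.DataFrame(
        {
            "ID": np.arange(1, config.n_patients + 1),
            "Gender": [("F", "M")[i % 2] for i in range(config.n_patients)],
            "Age": rng.integers(50, 80, config.n_patients),
            "III Total ON": on_scores,
            "III Total OFF": on_scores + delta.round().astype(int),
            "III.I ON": rng.integers(0, 3, config.n_patients),
            "III.I OFF": rng.integers(1, 4, config.n_patients),
        }
    )
    if root is not None:
        manifest.to_csv(root / "manifest.csv", index=False)
        clinical.to_csv(root / "clinical_scores.csv", index=False)
    return Cohort(manifest, streams, waves, clinical, config, mult)
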