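"""Leave-one-patient-out evaluation harness and clinical worked example.

One fold per patient: the held-out patient's recordings are classified by a
model trained (or, for the codebook method, built) from the remaining
patients only. Each fold contributes two patient-level predictions — one for
the ON recording set, one for the OFF set — and confusion-matrix metrics
(accuracy, sensitivity, specificity, precision; ON is the positive class)
are computed per fold and macro-averaged, with a pooled-confusion
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import crnn as crnn_mod
from . import pac as pac_mod
from .errors import ConfigurationError, ContractError, DegenerateCodebookError, LeakageError
from .features import (
    NormStats,
    extend_by_repetition,
    resample_and_quantize,
    split_test_segment,
    TARGET_RATE,
)
from .personalize import ProtocolSelection, select_protocols
from .synthetic import Cohort

STATES = ("ON", "OFF")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    undefined: tuple[str, ...] = ()
    scope: str = "pooled"


def compute_metrics(predictions: Sequence[str], truths: Sequence[str],
                    scope: str = "pooled") -> MetricsReport:
    """Confusion-matrix metrics with ON as the positive class. Ratios with a
    zero denominator are reported as nan and named in ``undefined``."""
    if len(predictions) != len(truths):
        raise ContractError("predictions and truths length mismatch")
    preds = np.asarray(predictions)
    true = np.asarray(truths)
    tp = int(np.sum((preds == "ON") & (true == "ON")))
    fp = int(np.sum((preds == "ON") & (true == "OFF")))
    tn = int(np.sum((preds == "OFF") & (true == "OFF")))
    fn = int(np.sum((preds == "OFF") & (true == "ON")))
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    rep = MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        scope=scope,
    )
    rep.undefined = tuple(undefined)
    return rep


def macro_average(fold_reports: Sequence[MetricsReport]) -> MetricsReport:
    """Mean of per-fold metrics, skipping folds where a ratio is undefined."""
    def mean_of(name: str) -> float:
        vals = [getattr(r, name) for r in fold_reports]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    return MetricsReport(
        tp=sum(r.tp for r in fold_reports),
        fp=sum(r.fp for r in fold_reports),
        tn=sum(r.tn for r in fold_reports),
        fn=sum(r.fn for r in fold_reports),
        accuracy=mean_of("accuracy"),
        sensitivity=mean_of("sensitivity"),
        specificity=mean_of("specificity"),
        precision=mean_of("precision"),
        scope="macro",
    )


@dataclass
class FoldResult:
    held_out_patient: int
    protocol_decisions: dict[tuple[str, str], str] = field(default_factory=dict)
    patient_calls: dict[str, str] = field(default_factory=dict)
    selection: ProtocolSelection | None = None
    metrics: MetricsReport | None = None


@dataclass
class LoocvResult:
    method: str
    folds: list[FoldResult]
    macro: MetricsReport
    pooled: MetricsReport

    @property
    def accuracy(self) -> float:
        return self.pooled.accuracy

    @property
    def n_calls(self) -> int:
        r = self.pooled
        return r.tp + r.fp + r.tn + r.fn


# ---------------------------------------------------------------------------
# PAC leave-one-patient-out
# ---------------------------------------------------------------------------


def loocv_pac(cohort: Cohort, count_mode: str = "frame") -> LoocvResult:
    """Per fold: per-protocol unique codebook pairs from the training
    patients, two-stage matching of the held-out patient's streams, majority
    vote across protocols per state."""
    patients = cohort.patients
    if len(patients) < 2:
        raise ConfigurationError("LOOCV needs at least 2 patients")
    protocols = cohort.config.protocols
    quantized = {
        key: pac_mod.pack_codes(pac_mod.quantize(stream))
        for key, stream in cohort.streams.items()
    }
    folds = []
    for held in patients:
        fold = FoldResult(held_out_patient=held)
        pairs = {}
        for protocol in protocols:
            books = {
                state: [
                    pac_mod.Codebook(
                        _count_codes(quantized[(pid, protocol, state)]), state, protocol
                    )
                    for pid in patients
                    if pid != held
                ]
                for state in STATES
            }
            merged = {
                state: _merge_books(books[state], state, protocol) for state in STATES
            }
            try:
                pairs[protocol] = pac_mod.make_unique(merged["ON"], merged["OFF"])
            except DegenerateCodebookError:
                continue
        decisions = {state: [] for state in STATES}
        for state in STATES:
            for protocol, pair in pairs.items():
                d = pac_mod.classify_sample(
                    quantized[(held, protocol, state)], pair, count_mode=count_mode
                )
                fold.protocol_decisions[(protocol, state)] = d.label
                decisions[state].append(d)
            fold.patient_calls[state] = pac_mod.vote_protocols(decisions[state])
        fold.metrics = compute_metrics(
            [fold.patient_calls[s] for s in STATES], list(STATES), scope="fold"
        )
        folds.append(fold)
    return _assemble("pac", folds)


def _count_codes(codes: np.ndarray) -> dict[int, int]:
    vals, counts = np.unique(codes, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts)}


def _merge_books(books, state, protocol) -> pac_mod.Codebook:
    merged: dict[int, int] = {}
    for b in books:
        for c, n in b.codes.items():
            merged[c] = merged.get(c, 0) + n
    return pac_mod.Codebook(merged, state, protocol)


def _assemble(method: str, folds: list[FoldResult]) -> LoocvResult:
    preds, truths = [], []
    for fold in folds:
        for state in STATES:
            preds.append(fold.patient_calls[state])
            truths.append(state)
    return LoocvResult(
        method=method,
        folds=folds,
        macro=macro_average([f.metrics for f in folds]),
        pooled=compute_metrics(preds, truths),
    )


# ---------------------------------------------------------------------------
# CRNN / p-CRNN leave-one-patient-out
# ---------------------------------------------------------------------------


def _resampled_audio(cohort: Cohort) -> dict[tuple[int, str, str], np.ndarray]:
    if not cohort.waveforms:
        raise ConfigurationError("cohort has no audio; regenerate with audio=True")
    return {
        key: resample_and_quantize(w).samples.astype(np.float32)
        for key, w in cohort.waveforms.items()
    }


def _batch_magnitude(segments: Sequence[np.ndarray]) -> np.ndarray:
    """Time-major STFT magnitude stack (n, frames, 201) for equal-length
    segments; numerically the batched equivalent of
    :func:`pdvoice.features.compute_spectrogram` in single precision."""
    from scipy.fft import rfft
    from scipy.signal import get_window

    from .features import HOP_SAMPLES, N_FFT

    x = np.stack([np.asarray(s, dtype=np.float32) for s in segments])
    win = get_window("hamming", N_FFT, fftbins=True).astype(np.float32)
    frames = np.lib.stride_tricks.sliding_window_view(x, N_FFT, axis=1)[:, ::HOP_SAMPLES]
    return np.abs(rfft(frames * win, axis=2))


def loocv_crnn(
    cohort: Cohort,
    cfg: crnn_mod.CrnnConfig | None = None,
    audio16k: Mapping[tuple[int, str, str], np.ndarray] | None = None,
) -> tuple[LoocvResult, LoocvResult]:
    """Run CRNN and p-CRNN on the same trained fold models.

    Returns ``(crnn_result, pcrnn_result)``. The network is trained once per
    fold on 10-s segments pooled over training patients; the held-out
    patient's segments are split 5 s / 5 s into validation and test halves
    (each extended back to 10 s by repetition). The all-protocol majority
    vote gives the CRNN call; restricting the vote to the protocols whose
    validation halves were classified correctly for both states gives the
    p-CRNN call.
    """
    cfg = cfg or crnn_mod.CrnnConfig.small()
    patients = cohort.patients
    if len(patients) < 2:
        raise ConfigurationError("LOOCV needs at least 2 patients")
    protocols = cohort.config.protocols
    audio = audio16k if audio16k is not None else _resampled_audio(cohort)
    seg_len = int(10 * TARGET_RATE)

    crnn_folds, pcrnn_folds = [], []
    for fold_i, held in enumerate(patients):
        train_segments = crnn_mod.prepare_training_set(cohort.manifest, audio, held)
        train_ids = {
            row.patient_id
            for row in cohort.manifest.itertuples(index=False)
            if row.patient_id != held
        }
        if held in train_ids:
            raise LeakageError("fold construction leaked the held-out patient")
        mags = _batch_magnitude([seg for seg, _ in train_segments])  # (n, T, F)
        flat = mags.reshape(-1, mags.shape[2])
        stats = NormStats(
            mean=flat.mean(axis=0),
            std=np.maximum(flat.std(axis=0), 1e-8),
            provenance=f"fold-{held}",
            n_frames=flat.shape[0],
        )
        x_train = ((mags - stats.mean) / stats.std).astype(np.float32)
        y_train = np.array([1.0 if st == "ON" else 0.0 for _, st in train_segments])
        fold_cfg = crnn_mod.CrnnConfig(**{**cfg.__dict__, "seed": cfg.seed + 977 * fold_i})
        model = crnn_mod.build_model(fold_cfg, input_shape=x_train.shape[1:])
        crnn_mod.train(model, x_train, y_train, fold_cfg)

        # held-out patient: per protocol x state, validation/test halves,
        # each extended back to 10 s by repetition and scored in one batch
        half_keys: list[tuple[str, str, str]] = []
        half_segs: list[np.ndarray] = []
        for protocol in protocols:
            for state in STATES:
                samples = audio[(held, protocol, state)]
                n_seg = samples.size // seg_len
                for i in range(n_seg):
                    seg = samples[i * seg_len : (i + 1) * seg_len]
                    val_half, test_half = split_test_segment(seg)
                    for tag, half in (("val", val_half), ("test", test_half)):
                        half_keys.append((protocol, state, tag))
                        half_segs.append(extend_by_repetition(half, seg_len))
        hmags = _batch_magnitude(half_segs)
        hx = ((hmags - stats.mean) / stats.std).astype(np.float32)
        all_probs = model.predict(hx)
        probs_val: dict[tuple[str, str], list[np.ndarray]] = {}
        probs_test: dict[tuple[str, str], list[np.ndarray]] = {}
        for (protocol, state, tag), p in zip(half_keys, all_probs):
            store = probs_val if tag == "val" else probs_test
            store.setdefault((protocol, state), []).append(p)
        val_pairs = [
            (p, state)
            for protocol in protocols
            for state in STATES
            for p in probs_val.get((protocol, state), [])
        ]

        if fold_cfg.threshold_mode == "fixed":
            threshold = fold_cfg.threshold
        else:
            threshold = crnn_mod.select_threshold([val_pairs], mode="grid")

        def protocol_call(store, protocol, state):
            plist = store.get((protocol, state), [])
            if not plist:
                return None, 0.0
            labels = [crnn_mod.decide(p, threshold) for p in plist]
            margin = float(
                np.sum([crnn_mod.decision_margin(p, threshold) for p in plist])
            )
            n_on = sum(1 for l in labels if l == "ON")
            if n_on * 2 != len(labels):
                call = "ON" if n_on * 2 > len(labels) else "OFF"
            else:
                call = "ON" if margin >= 0 else "OFF"
            return call, margin

        fold = FoldResult(held_out_patient=held)
        pfold = FoldResult(held_out_patient=held)
        validation_correct: dict[str, dict[str, bool]] = {}
        test_calls: dict[tuple[str, str], tuple[str, float]] = {}
        for protocol in protocols:
            validation_correct[protocol] = {}
            for state in STATES:
                vcall, _ = protocol_call(probs_val, protocol, state)
                validation_correct[protocol][state] = vcall == state
                call, margin = protocol_call(probs_test, protocol, state)
                test_calls[(protocol, state)] = (call, margin)
                fold.protocol_decisions[(protocol, state)] = call

        selection = select_protocols(validation_correct, held, protocols)
        pfold.selection = selection
        pfold.protocol_decisions = dict(fold.protocol_decisions)

        def vote(protocol_subset, state):
            calls = [test_calls[(p, state)] for p in protocol_subset
                     if test_calls[(p, state)][0] is not None]
            n_on = sum(1 for c, _ in calls if c == "ON")
            n_off = len(calls) - n_on
            if n_on != n_off:
                return "ON" if n_on > n_off else "OFF"
            margin = sum(m for _, m in calls)
            return "ON" if margin >= 0 else "OFF"

        for state in STATES:
            fold.patient_calls[state] = vote(protocols, state)
            pfold.patient_calls[state] = vote(selection.selected_protocols, state)
        for f in (fold, pfold):
            f.metrics = compute_metrics(
                [f.patient_calls[s] for s in STATES], list(STATES), scope="fold"
            )
        crnn_folds.append(fold)
        pcrnn_folds.append(pfold)

    return _assemble("crnn", crnn_folds), _assemble("pcrnn", pcrnn_folds)


def loocv(cohort: Cohort, method: str, cfg=None, **kw) -> LoocvResult:
    """Dispatch: ``method`` is 'pac', 'crnn' or 'pcrnn'."""
    if method == "pac":
        return loocv_pac(cohort, **kw)
    if method in ("crnn", "pcrnn"):
        c, p = loocv_crnn(cohort, cfg, **kw)
        return c if method == "crnn" else p
    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Clinical table worked example
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ("III Total ON", "III Total OFF", "III.I ON", "III.I OFF")


def load_clinical_table() -> pd.DataFrame:
    """The packaged per-patient UPDRS rating table (14 analyzed patients)."""
    with resources.files("pdvoice.data").joinpath("clinical_updrs.csv").open() as f:
        return pd.read_csv(f)


def summarize_clinical_table(table: pd.DataFrame) -> dict[str, float]:
    """Column means and sample standard deviations, plus the per-patient
    pre/post-levodopa difference delta = OFF - ON computed before averaging."""
    for col in CLINICAL_COLUMNS:
        if col not in table.columns:
            raise ContractError(f"clinical table missing column {col!r}")
        bad = table[table[col].isna()]
        if len(bad):
            raise ContractError(
                f"missing {col!r} for patient ID {bad.iloc[0].get('ID', '?')}"
            )
    out: dict[str, float] = {}
    n = len(table)
    for col in CLINICAL_COLUMNS:
        out[f"{col} mean"] = float(table[col].mean())
        out[f"{col} sd"] = float(table[col].std(ddof=1)) if n > 1 else float("nan")
    delta = table["III Total OFF"] - table["III Total ON"]
    out["delta UPDRS mean"] = float(delta.mean())
    out["delta UPDRS sd"] = float(delta.std(ddof=1)) if n > 1 else float("nan")
    return out
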