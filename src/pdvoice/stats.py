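"""Feature-level statistics for phone-attribute posterior streams.

Three characterizations of how the 21 phonological classes behave across the
ON/OFF motor states: a paired t-test per attribute (pairing unit: mean
posterior per patient x protocol by default), Pearson correlation between
two attributes' posterior trajectories within one state and protocol, and a
seeded 2-D t-SNE embedding of per-segment mean posterior vectors with a
nearest-centroid separability score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ContractError
from .features import PosteriorStream
from .synthetic import ATTRIBUTES, Cohort


@dataclass
class AttributeStat:
    attribute: str
    t_score: float
    p_value: float
    p_adjusted: float
    pairing_unit: str = "patient_protocol"


@dataclass
class AttributePairCorrelation:
    attribute_i: str
    attribute_j: str
    state: str
    r: float
    defined: bool = True


def attribute_mean_matrix(cohort: Cohort, state: str) -> np.ndarray:
    """Mean posterior per (patient x protocol) pair, shape (pairs, 21),
    ordered by (patient, protocol)."""
    rows = [
        cohort.streams[(pid, protocol, state)].posteriors.mean(axis=0)
        for pid in cohort.patients
        for protocol in cohort.config.protocols
    ]
    return np.asarray(rows)


def paired_ttest_per_attribute(
    on_features: np.ndarray,
    off_features: np.ndarray,
    pairing_unit: str = "patient_protocol",
    attribute_names: Sequence[str] = ATTRIBUTES,
) -> list[AttributeStat]:
    """Paired t-test per attribute; sign convention t > 0 iff mean(ON) >
    mean(OFF). Zero-variance differences use the degenerate conventions
    t = 0, p = 1 (identical samples) and t = +/-inf, p = 0 (constant nonzero
    difference). Results are sorted by |t| descending; Bonferroni-adjusted
    p-values accompany the raw ones."""
    on = np.asarray(on_features, dtype=np.float64)
    off = np.asarray(off_features, dtype=np.float64)
    if on.shape != off.shape:
        raise ContractError("ON and OFF feature matrices must have equal shape")
    if on.shape[0] < 2:
        raise ContractError("paired t-test needs at least 2 pairs")
    k = on.shape[1]
    out = []
    for j in range(k):
        d = on[:, j] - off[:, j]
        sd = d.std(ddof=1)
        if sd == 0.0:
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(d.mean()) * np.inf, 0.0
        else:
            t, p = sps.ttest_rel(on[:, j], off[:, j])
        out.append(
            AttributeStat(
                attribute=attribute_names[j],
                t_score=float(t),
                p_value=float(p),
                p_adjusted=float(min(1.0, p * k)),
                pairing_unit=pairing_unit,
            )
        )
    out.sort(key=lambda s: -abs(s.t_score))
    return out


def correlation_2d(
    streams: Sequence[PosteriorStream],
    attribute_i: str,
    attribute_j: str,
    state: str = "",
    attribute_names: Sequence[str] = ATTRIBUTES,
) -> AttributePairCorrelation:
    """Pearson correlation between two attributes' posterior time series,
    concatenated over the given recordings. Zero-variance series yield a
    flagged undefined result (r = nan)."""
    i = list(attribute_names).index(attribute_i)
    j = list(attribute_names).index(attribute_j)
    xi = np.concatenate([s.posteriors[:, i] for s in streams])
    xj = np.concatenate([s.posteriors[:, j] for s in streams])
    if xi.size < 2:
        raise ContractError("need at least 2 frames")
    if xi.max() == xi.min() or xj.max() == xj.min():
        return AttributePairCorrelation(attribute_i, attribute_j, state, float("nan"), False)
    r = float(sps.pearsonr(xi, xj).statistic)
    return AttributePairCorrelation(attribute_i, attribute_j, state, r)


def embed_protocol(
    features: np.ndarray,
    labels: Sequence[str],
    perplexity: float = 10.0,
    seed: int = 0,
    plot_path: str | None = None,
):
    """Seeded t-SNE embedding of per-segment mean posterior vectors.

    Returns (coordinates (n, 2), separability score), where separability is
    leave-none-out nearest-centroid accuracy in the embedded plane. Requires
    at least 5 segments per class; otherwise returns (None, nan) with a
    warning.
    """
    import warnings

    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    counts = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    if any(c < 5 for c in counts.values()) or len(counts) < 2:
        warnings.warn(f"too few segments per class for embedding: {counts}")
        return None, float("nan")
    perplexity = min(perplexity, (features.shape[0] - 1) / 3.0)
    coords = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(features)
    centroids = {lab: coords[labels == lab].mean(axis=0) for lab in counts}
    labs = list(centroids)
    dists = np.stack([np.linalg.norm(coords - centroids[lab], axis=1) for lab in labs])
    pred = np.asarray(labs)[dists.argmin(axis=0)]
    score = float((pred == labels).mean())
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for lab, marker in zip(labs, "ox^s"):
            sel = labels == lab
            ax.scatter(coords[sel, 0], coords[sel, 1], marker=marker, label=lab, s=18)
        ax.legend()
        ax.set_title(f"separability {score:.2f}")
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return coords, score


def cohort_embedding_scores(
    cohort: Cohort, perplexity: float = 10.0, seed: int = 0
) -> dict[str, float]:
    """Per-protocol embedded separability, using per-recording chunks of the
    posterior stream (roughly 10-s spans) as segments."""
    scores: dict[str, float] = {}
    for protocol in cohort.config.protocols:
        feats, labs = [], []
        for pid in cohort.patients:
            for state in ("ON", "OFF"):
                post = cohort.streams[(pid, protocol, state)].posteriors
                half = post.shape[0] // 2
                for chunk in (post[:half], post[half:]):
                    if chunk.size:
                        feats.append(chunk.mean(axis=0))
                        labs.append(state)
        _, score = embed_protocol(np.asarray(feats), labs, perplexity, seed)
        scores[protocol] = score
    return scores
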