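"""Phone-Attribute Codebook (PAC) classifier.

An instance-based ON/OFF classifier: posterior streams are 1-bit quantized
(threshold 0.5) into 21-bit frame codes; per speech protocol, all training
codes of one class form a codebook; codes shared between the ON and OFF
codebooks are removed so that the two books are disjoint; a test sample is
labelled by exact-match counting against the two books, with a Jaccard
nearest-code fallback when exact matching ties (including the no-match case);
the patient-level call is a majority vote across protocols.

Codes are stored packed as integers (bit k = attribute k), which makes exact
matching a hash lookup and Jaccard a popcount on bitwise AND/OR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import json
import numpy as np

from .errors import ConfigurationError, DegenerateCodebookError, UndecidableError
from .features import N_ATTRIBUTES, PosteriorStream

ON, OFF, ABSTAIN = "ON", "OFF", "ABSTAIN"

_POWERS = (1 << np.arange(N_ATTRIBUTES, dtype=np.int64))


def quantize(stream: PosteriorStream | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1-bit quantization: bit = 1 iff posterior >= threshold.

    The boundary value 0.5 maps to 1 (fixed convention; the probability of
    hitting it exactly is zero under the noise model). Returns a
    (frames, 21) uint8 matrix.
    """
    p = stream.posteriors if isinstance(stream, PosteriorStream) else np.asarray(stream)
    return (p >= threshold).astype(np.uint8)


def pack_codes(bits: np.ndarray) -> np.ndarray:
    """Pack (frames, 21) binary rows into int64 codes."""
    return np.asarray(bits, dtype=np.int64) @ _POWERS


def unpack_code(code: int) -> np.ndarray:
    return ((int(code) >> np.arange(N_ATTRIBUTES)) & 1).astype(np.uint8)


def popcount(x: np.ndarray | int) -> np.ndarray | int:
    return np.bitwise_count(np.asarray(x, dtype=np.int64))


@dataclass
class Codebook:
    """Unordered set of unique codes for one class and protocol, with
    per-code frame-occurrence counts."""

    codes: dict[int, int]
    class_label: str
    protocol: str

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def code_set(self) -> frozenset[int]:
        return frozenset(self.codes)

    def code_array(self) -> np.ndarray:
        return np.fromiter(self.codes, dtype=np.int64, count=len(self.codes))


@dataclass
class UniqueCodebookPair:
    on_codes: Codebook
    off_codes: Codebook

    def __post_init__(self) -> None:
        assert not (self.on_codes.code_set & self.off_codes.code_set), (
            "unique codebooks must be disjoint"
        )


@dataclass
class MatchDecision:
    label: str
    on_score: float
    off_score: float
    mechanism: str  # "exact" | "jaccard"
    protocol: str = ""

    @property
    def margin(self) -> float:
        return self.on_score - self.off_score


def build_codebooks(
    streams_by_class: Mapping[str, Sequence[PosteriorStream | np.ndarray]],
    protocol: str,
    threshold: float = 0.5,
) -> tuple[Codebook, Codebook]:
    """Accumulate all quantized training codes per class into codebooks."""
    books = {}
    for label in (ON, OFF):
        streams = streams_by_class.get(label, [])
        if not streams:
            raise ConfigurationError(
                f"no training streams for class {label} in protocol {protocol!r}"
            )
        counts: dict[int, int] = {}
        for s in streams:
            for code in pack_codes(quantize(s, threshold)):
                counts[int(code)] = counts.get(int(code), 0) + 1
        books[label] = Codebook(counts, label, protocol)
    return books[ON], books[OFF]


def make_unique(on: Codebook, off: Codebook) -> UniqueCodebookPair:
    """Remove shared codes from both books so their intersection is empty."""
    if on.protocol != off.protocol:
        raise ConfigurationError("codebooks must come from the same protocol")
    shared = on.code_set & off.code_set
    on_u = Codebook({c: n for c, n in on.codes.items() if c not in shared}, ON, on.protocol)
    off_u = Codebook({c: n for c, n in off.codes.items() if c not in shared}, OFF, off.protocol)
    if not on_u.codes and not off_u.codes:
        raise DegenerateCodebookError(
            f"protocol {on.protocol!r}: unique ON and OFF codebooks are both empty"
        )
    return UniqueCodebookPair(on_u, off_u)


def jaccard(a: np.ndarray | int, b: np.ndarray | int) -> float:
    """Jaccard similarity a/(a+b+c) over two binary codes; joint zeros are
    ignored. Two all-zero codes are identical, so their similarity is 1."""
    ca = int(pack_codes(np.asarray(a)[None, :])[0]) if not np.isscalar(a) else int(a)
    cb = int(pack_codes(np.asarray(b)[None, :])[0]) if not np.isscalar(b) else int(b)
    union = int(popcount(ca | cb))
    if union == 0:
        return 1.0
    return int(popcount(ca & cb)) / union


def _max_jaccard(test_codes: np.ndarray, book_codes: np.ndarray) -> np.ndarray:
    """Per test code, the maximum Jaccard similarity to any codebook code."""
    inter = popcount(test_codes[:, None] & book_codes[None, :]).astype(np.float64)
    union = popcount(test_codes[:, None] | book_codes[None, :]).astype(np.float64)
    sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return sim.max(axis=1)


def classify_sample(
    test_codes: np.ndarray,
    pair: UniqueCodebookPair,
    count_mode: str = "frame",
    always_jaccard: bool = False,
) -> MatchDecision:
    """Two-stage matching of one sample's code sequence against a codebook pair.

    Stage 1 counts exact set-membership hits per test frame (or per unique
    test code with ``count_mode="unique"``). On a tie — notably the 0 = 0
    no-match case — stage 2 scores each test code by its maximum Jaccard
    similarity to each book and sums. A persistent tie yields ABSTAIN.
    """
    if not pair.on_codes.codes and not pair.off_codes.codes:
        raise DegenerateCodebookError("degenerate codebook pair")
    codes = np.asarray(test_codes, dtype=np.int64)
    if codes.ndim == 2:
        codes = pack_codes(codes)
    if count_mode == "unique":
        codes = np.unique(codes)
    elif count_mode != "frame":
        raise ConfigurationError(f"unknown count_mode {count_mode!r}")

    protocol = pair.on_codes.protocol
    if not always_jaccard:
        on_set = pair.on_codes.code_set
        off_set = pair.off_codes.code_set
        on_score = float(sum(1 for c in codes if int(c) in on_set))
        off_score = float(sum(1 for c in codes if int(c) in off_set))
        if on_score != off_score:
            label = ON if on_score > off_score else OFF
            return MatchDecision(label, on_score, off_score, "exact", protocol)
    # Jaccard fallback (or always-Jaccard mode)
    on_score = float(_max_jaccard(codes, pair.on_codes.code_array()).sum()) if pair.on_codes.codes else 0.0
    off_score = float(_max_jaccard(codes, pair.off_codes.code_array()).sum()) if pair.off_codes.codes else 0.0
    if on_score > off_score:
        label = ON
    elif off_score > on_score:
        label = OFF
    else:
        label = ABSTAIN
    return MatchDecision(label, on_score, off_score, "jaccard", protocol)


def vote_protocols(decisions: Iterable[MatchDecision]) -> str:
    """Majority vote over non-abstaining per-protocol decisions; a tie is
    broken by the summed (on - off) score margin."""
    votes = [d for d in decisions if d.label != ABSTAIN]
    if not votes:
        raise UndecidableError("all protocols abstained")
    n_on = sum(1 for d in votes if d.label == ON)
    n_off = len(votes) - n_on
    if n_on != n_off:
        return ON if n_on > n_off else OFF
    margin = sum(d.margin for d in votes)
    return ON if margin >= 0 else OFF


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def codebook_to_json(pair: UniqueCodebookPair) -> str:
    def book(b: Codebook):
        return {
            "class": b.class_label,
            "protocol": b.protocol,
            "codes": {format(c, "021b"): n for c, n in sorted(b.codes.items())},
        }

    return json.dumps({"on": book(pair.on_codes), "off": book(pair.off_codes)}, indent=1)


def codebook_from_json(text: str) -> UniqueCodebookPair:
    doc = json.loads(text)

    def book(d):
        return Codebook(
            {int(bits, 2): n for bits, n in d["codes"].items()}, d["class"], d["protocol"]
        )

    return UniqueCodebookPair(book(doc["on"]), book(doc["off"]))
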