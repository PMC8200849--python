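"""Personalized protocol selection (p-CRNN).

The classifier stays speaker-independent; only the set of speech protocols
used at test time is personalized. Each held-out patient's recordings are
split per protocol into a validation portion (first 5 s of each 10-s
segment) and a test portion (last 5 s). A protocol is selected iff its
validation predictions are correct for both the ON and the OFF recording;
testing then uses only the selected protocols. If no protocol passes, the
full protocol set is used and the selection is flagged as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import split_test_segment


@dataclass
class ProtocolSelection:
    patient_id: int
    selected_protocols: tuple[str, ...]
    evidence: dict[str, dict[str, bool]] = field(default_factory=dict)
    fallback: bool = False


def split_patient_recordings(
    segments_by_protocol_state: Mapping[tuple[str, str], Sequence[np.ndarray]],
    rate: int = 16_000,
) -> dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]]:
    """Split each 10-s segment of each (protocol, state) recording into its
    deterministic (validation 5 s, test 5 s) halves. Protocols missing one
    of the two states are excluded with a warning."""
    protocols = {p for p, _ in segments_by_protocol_state}
    out: dict[tuple[str, str], list[tuple[np.ndarray, np.ndarray]]] = {}
    for protocol in sorted(protocols):
        if not all((protocol, st) in segments_by_protocol_state for st in ("ON", "OFF")):
            warnings.warn(f"protocol {protocol!r} missing a state; excluded")
            continue
        for state in ("ON", "OFF"):
            out[(protocol, state)] = [
                split_test_segment(seg, rate)
                for seg in segments_by_protocol_state[(protocol, state)]
            ]
    return out


def select_protocols(
    validation_correct: Mapping[str, Mapping[str, bool]],
    patient_id: int,
    all_protocols: Sequence[str],
    rule: str = "strict",
) -> ProtocolSelection:
    """Select protocols whose validation predictions succeed for both states.

    ``validation_correct[protocol][state]`` says whether that protocol's
    validation portion of that state was classified correctly (under
    ``rule="strict"`` this means every validation segment was correct; the
    caller may supply majority-based outcomes instead). An empty selection
    falls back to the full protocol set, flagged.
    """
    selected = tuple(
        p
        for p in all_protocols
        if p in validation_correct
        and validation_correct[p].get("ON", False)
        and validation_correct[p].get("OFF", False)
    )
    fallback = not selected
    if fallback:
        selected = tuple(all_protocols)
    return ProtocolSelection(
        patient_id=patient_id,
        selected_protocols=selected,
        evidence={p: dict(v) for p, v in validation_correct.items()},
        fallback=fallback,
    )
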