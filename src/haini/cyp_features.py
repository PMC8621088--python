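"""Signed CYP450 victim/perpetrator encoding and the interaction vector.

Most small-molecule drugs are cleared by cytochrome P450 enzymes, and a
large share of clinically relevant drug-drug interactions arise there: if
the victim drug A is a substrate of an enzyme and the perpetrator drug B
inhibits that enzyme, A's clearance falls and its exposure rises; if B
induces the enzyme, A's exposure falls.

Twelve enzymes are tracked, in a fixed order that must never change
within a run.  The victim side is a 0/1 substrate indicator; the
perpetrator side is +1 (inhibitor), -1 (inducer) or 0 per enzyme.  Their
elementwise product is the signed interaction vector: -1 at an enzyme
means induction of a metabolising enzyme (reduced victim exposure), +1
means inhibition of one (increased victim exposure), 0 means no
interaction at that enzyme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CYPConflictError, DimensionError, SchemaError

CYP_PANEL: tuple[str, ...] = (
    "1A2", "2A6", "2B6", "2C18", "2C19", "2C8",
    "2C9", "2D6", "2E1", "3A4", "3A5", "3A7",
)

PANEL_INDEX: dict[str, int] = {e: i for i, e in enumerate(CYP_PANEL)}

#: Names of the 12 interaction features appended to each hybrid row.
CYP_FEATURE_NAMES: tuple[str, ...] = tuple(f"CYP{e}_interaction" for e in CYP_PANEL)

ConflictPolicy = str  # "error" | "prefer-inhibitor" | "prefer-inducer" | "zero"


def _validate_enzymes(enzymes, role: str) -> frozenset[str]:
    enzymes = frozenset(enzymes)
    unknown = enzymes - set(CYP_PANEL)
    if unknown:
        raise SchemaError(f"unknown CYP enzyme(s) in {role}: {sorted(unknown)}")
    return enzymes


@dataclass(frozen=True)
class CYPProfile:
    """Per-drug CYP450 metabolism profile.

    A drug may be a substrate and a perpetrator of the same enzyme (the
    two encodings are independent), but inhibitor and inducer roles on
    one enzyme conflict and are resolved via ``conflict_policy``.
    """

    drug_id: str
    substrates: frozenset[str] = field(default_factory=frozenset)
    inhibitors: frozenset[str] = field(default_factory=frozenset)
    inducers: frozenset[str] = field(default_factory=frozenset)
    conflict_policy: ConflictPolicy = "error"

    def __post_init__(self):
        object.__setattr__(self, "substrates", _validate_enzymes(self.substrates, "substrates"))
        inhibitors = _validate_enzymes(self.inhibitors, "inhibitors")
        inducers = _validate_enzymes(self.inducers, "inducers")
        overlap = inhibitors & inducers
        if overlap:
            if self.conflict_policy == "error":
                raise CYPConflictError(
                    f"{self.drug_id}: inhibitor and inducer of {sorted(overlap)}; "
                    "set conflict_policy to prefer-inhibitor | prefer-inducer | zero "
                    "to resolve"
                )
            if self.conflict_policy == "prefer-inhibitor":
                inducers = inducers - overlap
            elif self.conflict_policy == "prefer-inducer":
                inhibitors = inhibitors - overlap
            elif self.conflict_policy == "zero":
                inhibitors = inhibitors - overlap
                inducers = inducers - overlap
            else:
                raise ValueError(f"unknown conflict policy {self.conflict_policy!r}")
        object.__setattr__(self, "inhibitors", inhibitors)
        object.__setattr__(self, "inducers", inducers)


def encode_victim(profile: CYPProfile) -> np.ndarray:
    """0/1 substrate indicator over the panel (the victim-side vector)."""
    out = np.zeros(len(CYP_PANEL), dtype=int)
    for e in profile.substrates:
        out[PANEL_INDEX[e]] = 1
    return out


def encode_perpetrator(profile: CYPProfile) -> np.ndarray:
    """Signed perpetrator vector: +1 inhibited, -1 induced, 0 otherwise."""
    out = np.zeros(len(CYP_PANEL), dtype=int)
    for e in profile.inhibitors:
        out[PANEL_INDEX[e]] = 1
    for e in profile.inducers:
        out[PANEL_INDEX[e]] = -1
    return out


def cyp_interaction(victim: np.ndarray, perpetrator: np.ndarray) -> np.ndarray:
    """Elementwise product of victim and perpetrator vectors.

    Nonzero only where the victim is metabolised by an enzyme the
    perpetrator acts on; the sign is the perpetrator's.
    """
    victim = np.asarray(victim, dtype=int)
    perpetrator = np.asarray(perpetrator, dtype=int)
    if victim.shape != (len(CYP_PANEL),) or perpetrator.shape != (len(CYP_PANEL),):
        raise DimensionError(
            f"CYP vectors must have length {len(CYP_PANEL)}; "
            f"got {victim.shape} and {perpetrator.shape}"
        )
    return victim * perpetrator


def pair_interaction_vector(victim_profile: CYPProfile,
                            perpetrator_profile: CYPProfile) -> np.ndarray:
    """Interaction vector for an ordered pair (A affected by B)."""
    return cyp_interaction(encode_victim(victim_profile),
                           encode_perpetrator(perpetrator_profile))


def build_cyp_feature_matrix(drugs, pairs) -> "pd.DataFrame":
    """12-column signed interaction-feature block for ordered pairs.

    ``drugs`` supply ``drug_id``/``cyp_profile``; ``pairs`` supply
    ``victim_id``/``perpetrator_id``.  Row index is ``victim_perpetrator``,
    matching the chemical feature matrix.
    """
    import pandas as pd

    victim = {d.drug_id: encode_victim(d.cyp_profile) for d in drugs}
    perp = {d.drug_id: encode_perpetrator(d.cyp_profile) for d in drugs}
    rows = [victim[p.victim_id] * perp[p.perpetrator_id] for p in pairs]
    index = [f"{p.victim_id}_{p.perpetrator_id}" for p in pairs]
    return pd.DataFrame(
        np.array(rows).reshape(-1, len(CYP_PANEL)),
        index=index, columns=list(CYP_FEATURE_NAMES))
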