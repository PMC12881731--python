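"""Per-gram nutrient profiles and processing retention.

A processed variant's nutrient content is the raw profile multiplied
nutrient-wise by retention fractions in [0, 1]; nutrients without a
retention entry for a process are fully retained.
"""
from __future__ import annotations

import numpy as np

from .model import NutrientProfile, ProcessingType, RetentionTable


def derive_processed_profile(
    raw_row: np.ndarray,
    process_type: ProcessingType,
    retention: RetentionTable,
    nutrients: list[str],
) -> np.ndarray:
    """Apply retention factors for one process to a raw per-gram nutrient
    vector; identity for an unprocessed food or an empty retention table."""
    if process_type is ProcessingType.NONE:
        return raw_row.copy()
    factors = np.array([retention.get(process_type, n) for n in nutrients], dtype=float)
    return raw_row * factors


def complete_profiles(
    raw_values: dict[str, np.ndarray],
    derived: dict[str, tuple[str, ProcessingType]],
    retention: RetentionTable,
    nutrients: list[str],
) -> NutrientProfile:
    """Build a full profile from raw rows plus (processed id -> (raw id,
    process)) derivations."""
    values = {fid: vec.copy() for fid, vec in raw_values.items()}
    for fid, (raw_id, process) in derived.items():
        values[fid] = derive_processed_profile(raw_values[raw_id], process, retention, nutrients)
    return NutrientProfile(nutrients=list(nutrients), values=values)
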