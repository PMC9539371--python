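"""Canonical 16-channel 10-20 montage used as the common feature space.

Heterogeneous cohorts (dense caps, revised IFCN arrays) are mapped onto this
reduced subset before any feature computation, so every spatial filter and
every per-channel statistic lives in the same 16-dimensional channel space.
"""

from __future__ import annotations

# Ordered canonical labels (old T3/T4/T5/T6 naming kept as primary).
CANONICAL_16: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4",
    "T3", "T4", "P3", "P4", "T5", "T6", "O1", "O2",
)

# Modern / vendor label aliases -> canonical label (case-insensitive lookup).
CHANNEL_ALIASES: dict[str, str] = {
    "t7": "T3",
    "t8": "T4",
    "p7": "T5",
    "p8": "T6",
    "eeg fp1": "Fp1",
    "eeg fp2": "Fp2",
}


def normalize_label(label: str) -> str:
    """Map a raw channel label onto the canonical 10-20 name.

    Strips common "EEG " prefixes and reference suffixes ("Fp1-REF"),
    resolves T7/T8/P7/P8 aliases, and canonicalizes case. Labels that do not
    belong to the 16-channel subset are returned stripped but otherwise
    untouched (the caller decides whether that is an error).
    """
    raw = label.strip()
    low = raw.lower()
    if low.startswith("eeg "):
        low = low[4:]
    low = low.split("-")[0].strip()
    if low in CHANNEL_ALIASES:
        return CHANNEL_ALIASES[low]
    for name in CANONICAL_16:
        if low == name.lower():
            return name
    return raw


# Anterior-dominant per-channel gain profile used as the default scalp
# topography of synthetic discharges: frontal maximum, fading toward occiput.
ANTERIOR_DOMINANT_WEIGHTS: dict[str, float] = {
    "Fp1": 1.00, "Fp2": 1.00,
    "F3": 0.95, "F4": 0.95, "F7": 0.85, "F8": 0.85,
    "C3": 0.75, "C4": 0.75, "T3": 0.65, "T4": 0.65,
    "P3": 0.55, "P4": 0.55, "T5": 0.50, "T6": 0.50,
    "O1": 0.40, "O2": 0.40,
}

# Channels carrying the posterior alpha rhythm in the synthetic background.
POSTERIOR_CHANNELS: tuple[str, ...] = ("P3", "P4", "T5", "T6", "O1", "O2")
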