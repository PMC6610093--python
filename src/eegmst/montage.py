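"""Canonical 10-20 electrode names and the anterior/posterior region split.

The analysis montage is the classic 21-electrode 10-20 layout; the two
earlobe references A1/A2 are dropped before network analysis, leaving the
19 scalp sites that form the nodes of every spanning tree.
"""

from __future__ import annotations

#: The 21 recording sites, in conventional order.
CHANNELS_21: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "A1", "A2", "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Pz", "Cz",
)

#: The 19 scalp sites retained for network analysis (A1/A2 removed).
CHANNELS_19: tuple[str, ...] = tuple(c for c in CHANNELS_21 if c not in ("A1", "A2"))

#: Channels excluded from the common-average reference (EMG-prone sites).
CAR_EXCLUDE_DEFAULT: frozenset[str] = frozenset({"Fp1", "Fp2", "A1", "A2"})

#: Region assignment used for regional betweenness centrality.
ANTERIOR: frozenset[str] = frozenset({"Fp1", "Fp2", "F7", "F8", "F3", "F4", "Fz"})
POSTERIOR: frozenset[str] = frozenset({"T5", "T6", "P3", "P4", "Pz", "O1", "O2"})
CENTRAL: frozenset[str] = frozenset({"C3", "C4", "Cz"})

_CANONICAL = {name.upper(): name for name in CHANNELS_21}


def normalize_label(label: str) -> str:
    """Map a label to its canonical 10-20 spelling (e.g. ``FP1`` -> ``Fp1``).

    Raises ``ValueError`` for labels outside the 21-channel montage.
    """
    key = label.strip().upper()
    # common vendor suffixes like "EEG Fp1-REF"
    if key.startswith("EEG "):
        key = key[4:]
    key = key.split("-")[0].strip()
    if key not in _CANONICAL:
        raise ValueError(f"unknown 10-20 electrode label: {label!r}")
    return _CANONICAL[key]
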