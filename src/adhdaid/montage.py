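"""Standard 10-20 montage labels and electrode-site groupings.

The 19-channel clinical 10-20 montage is the layout of the ADHD/control
recordings this package targets. Channels are grouped into six anatomical
sites (pre-frontal .. occipital); the site search in
:mod:`adhdaid.selection` operates on these groups.
"""

from __future__ import annotations

# Canonical 19-channel 10-20 montage, front to back, left before right.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Anatomical electrode sites; together they cover the montage exactly once.
SITES: dict[str, tuple[str, ...]] = {
    "pre_frontal": ("Fp1", "Fp2"),
    "frontal": ("Fz", "F3", "F4", "F7", "F8"),
    "central": ("Cz", "C3", "C4"),
    "parietal": ("Pz", "P3", "P4"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "occipital": ("O1", "O2"),
}

SITE_ORDER: tuple[str, ...] = tuple(SITES)


def site_of(channel: str) -> str:
    """Return the anatomical site a channel label belongs to."""
    for name, members in SITES.items():
        if channel in members:
            return name
    raise KeyError(f"channel {channel!r} is not in the 10-20 site partition")
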