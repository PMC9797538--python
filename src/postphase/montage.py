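"""64-channel 10-10 montage and its electrode-to-lobe assignment.

The five regions of interest are the frontal, parietal and occipital lobes
and the two temporal lobes.  There is no "central" lobe in this scheme:
central-row and centro-parietal electrodes (C*, CP*) are assigned to the
parietal lobe and fronto-central ones (FC*) to the frontal lobe, i.e. by
nearest lobe.  Mastoid leads (M1/M2) go with the adjacent temporal lobe.
The assignment ships as an editable two-column table
(``data/lobe_map_1010.tsv``) so a different montage or assignment can be
substituted without touching code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

LOBES = ("frontal", "parietal", "occipital", "temporal_left", "temporal_right")


def load_lobe_map(path: str | Path | None = None) -> dict[str, str]:
    """Read a (channel, lobe) table; validates lobes and uniqueness."""
    if path is None:
        text = (resources.files("postphase") / "data" / "lobe_map_1010.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[str, str] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:  # header row
        ch, lobe = ln.split("\t")
        if ch in mapping:
            raise ValueError(f"channel {ch!r} mapped twice")
        if lobe not in LOBES:
            raise ValueError(f"unknown lobe {lobe!r} for channel {ch!r}")
        mapping[ch] = lobe
    for lobe in LOBES:
        if lobe not in mapping.values():
            raise ValueError(f"lobe {lobe!r} has no channels")
    return mapping


DEFAULT_LOBE_MAP = load_lobe_map()
EEG_CHANNELS: tuple[str, ...] = tuple(DEFAULT_LOBE_MAP)

OCCIPITAL = frozenset(c for c, l in DEFAULT_LOBE_MAP.items() if l == "occipital")
FRONTAL_PARIETAL = frozenset(
    c for c, l in DEFAULT_LOBE_MAP.items() if l in ("frontal", "parietal")
)
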