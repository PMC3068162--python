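"""The 22 eukaryotic subcellular location sites and their integer codes.

Codes are the conventional 1..22 enumeration used throughout the package;
every label table, score vector and report indexes sites by these codes.
"""

from __future__ import annotations

#: code -> canonical site name
SITE_NAMES: dict[int, str] = {
    1: "Acrosome",
    2: "Cell membrane",
    3: "Cell wall",
    4: "Centrosome",
    5: "Chloroplast",
    6: "Cyanelle",
    7: "Cytoplasm",
    8: "Cytoskeleton",
    9: "Endoplasmic reticulum",
    10: "Endosome",
    11: "Extracellular",
    12: "Golgi apparatus",
    13: "Hydrogenosome",
    14: "Lysosome",
    15: "Melanosome",
    16: "Microsome",
    17: "Mitochondrion",
    18: "Nucleus",
    19: "Peroxisome",
    20: "Spindle pole body",
    21: "Synapse",
    22: "Vacuole",
}

#: default number of location sites
DEFAULT_C: int = 22


def site_name(code: int, C: int = DEFAULT_C) -> str:
    """Human-readable name for a site code; generic for non-default C."""
    if C == DEFAULT_C and code in SITE_NAMES:
        return SITE_NAMES[code]
    return f"Site {code}"
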