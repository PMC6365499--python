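"""Five-class tissue taxonomy shared across the pipeline.

Lung adenocarcinoma tissue is classified into four architectural growth
patterns — acinar (gland-forming), micropapillary (small tufts without
fibrovascular cores), solid (sheets without glands), cribriform (sieve-like
perforated nests) — plus a non-tumor class for benign components (alveoli,
stroma, immune cells, vessels).  Integer codes start at 1 so that 0 can mean
"background / unannotated" in label rasters.
"""

from __future__ import annotations

from enum import IntEnum


class GrowthPattern(IntEnum):
    """Tissue class codes used in tumor maps and ground-truth masks."""

    AC = 1  # acinar
    MP = 2  # micropapillary
    SO = 3  # solid
    CR = 4  # cribriform
    NT = 5  # non-tumor

    @property
    def long_name(self) -> str:
        return _LONG_NAMES[self]


_LONG_NAMES = {
    GrowthPattern.AC: "acinar",
    GrowthPattern.MP: "micropapillary",
    GrowthPattern.SO: "solid",
    GrowthPattern.CR: "cribriform",
    GrowthPattern.NT: "non-tumor",
}

#: Background / unclassified code in label rasters.
BACKGROUND = 0

#: Classes in enum order; index i corresponds to probability-vector entry i.
ALL_CLASSES = tuple(GrowthPattern)

#: Tumor growth patterns (everything except non-tumor).
TUMOR_CLASSES = (
    GrowthPattern.AC,
    GrowthPattern.MP,
    GrowthPattern.SO,
    GrowthPattern.CR,
)

#: Default mapping from annotation label strings to classes.  Keys are
#: matched case-insensitively after stripping whitespace.
DEFAULT_LABEL_MAP = {
    "ac": GrowthPattern.AC,
    "acinar": GrowthPattern.AC,
    "mp": GrowthPattern.MP,
    "micropapillary": GrowthPattern.MP,
    "so": GrowthPattern.SO,
    "solid": GrowthPattern.SO,
    "cr": GrowthPattern.CR,
    "cribriform": GrowthPattern.CR,
    "nt": GrowthPattern.NT,
    "non-tumor": GrowthPattern.NT,
    "nontumor": GrowthPattern.NT,
    "non tumor": GrowthPattern.NT,
}


def parse_label(label: str, label_map: dict[str, GrowthPattern] | None = None) -> GrowthPattern:
    """Map an annotation label string to a :class:`GrowthPattern`.

    Raises ``ValueError`` naming the offending label when it is not in the
    five-class vocabulary (e.g. "lepidic", which the pipeline does not model).
    """
    table = DEFAULT_LABEL_MAP if label_map is None else label_map
    key = label.strip().lower()
    try:
        return table[key]
    except KeyError:
        known = sorted(set(table))
        raise ValueError(
            f"unknown tissue class label {label!r}; expected one of {known}"
        ) from None
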