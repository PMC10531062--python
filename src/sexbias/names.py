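"""miRNA nomenclature harmonization and mature-to-precursor mapping.

Disease datasets typically report mature names (``hsa-miR-17-5p``) while
annotation, family and baseline resources are keyed by precursor names
(``hsa-mir-17``); comparisons against a healthy baseline are performed at
the precursor level, which requires collapsing mature arms onto their
hairpin precursors.
"""

from __future__ import annotations

import logging
import re

logger = logging.getLogger(__name__)

__all__ = ["normalize_name", "mature_to_precursor", "invert_mapping"]

_ARM_SUFFIX = re.compile(r"-(5p|3p)$", re.IGNORECASE)


def normalize_name(raw: str) -> str:
    """Canonicalize a miRNA name at the precursor level.

    Strips surrounding whitespace and lowercases (miRBase precursor names
    are lowercase, e.g. ``hsa-mir-101-1``); the species prefix is
    preserved.  Empty input is an error.
    """
    if raw is None:
        raise ValueError("miRNA name must be non-empty")
    name = str(raw).strip()
    if not name:
        raise ValueError("miRNA name must be non-empty")
    return name.lower()


def invert_mapping(precursor_to_matures: dict[str, list[str]]) -> dict[str, list[str]]:
    """Turn a precursor -> mature-list table into mature -> precursor-list.

    Names are normalized on both sides; a mature form produced by several
    precursors maps to all of them, in sorted order.
    """
    inverse: dict[str, set[str]] = {}
    for precursor, matures in precursor_to_matures.items():
        pre = normalize_name(precursor)
        for mat in matures:
            inverse.setdefault(normalize_name(mat), set()).add(pre)
    return {mat: sorted(pres) for mat, pres in inverse.items()}


def mature_to_precursor(mature: str, mapping: dict[str, list[str]]) -> list[str]:
    """Map a mature miRNA name to its precursor name(s).

    ``mapping`` is a precursor -> mature-name-list table (e.g. built from
    the annotation's Derives_from links).  Returns every precursor that
    produces the mature form.  When the mapping lacks the name, falls back
    to stripping a trailing ``-5p``/``-3p`` arm suffix (logged as a
    warning); a name with no arm suffix and no mapping entry is treated as
    already precursor-level.
    """
    name = normalize_name(mature)
    inverse = invert_mapping(mapping)
    if name in inverse:
        return inverse[name]
    fallback = _ARM_SUFFIX.sub("", name)
    if fallback != name:
        logger.warning(
            "mature name %r absent from mapping; falling back to arm-stripped %r",
            mature,
            fallback,
        )
    return [fallback]
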