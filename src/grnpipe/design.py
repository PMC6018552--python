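"""Experimental-design vocabulary shared across the pipeline.

Three unpaired fins are sampled; each fin has one or two elongated (L)
regions and a single short (S) region. The caudal fin contributes two L
regions (dorsal ``dcL`` and ventral ``vcL``) that are both contrasted
against the central short region ``cS``.
"""

from __future__ import annotations

FINS: tuple[str, ...] = ("dorsal", "anal", "caudal")

#: Elongated-region labels per fin.
L_REGIONS: dict[str, tuple[str, ...]] = {
    "dorsal": ("dL",),
    "anal": ("aL",),
    "caudal": ("dcL", "vcL"),
}

#: Short-region label per fin.
S_REGION: dict[str, str] = {
    "dorsal": "dS",
    "anal": "aS",
    "caudal": "cS",
}

#: Regeneration stages: 0 = intact fin, 1 and 2 = regenerating biopsies.
STAGES: tuple[int, ...] = (0, 1, 2)

HIGHER_L = "higher-L"
HIGHER_S = "higher-S"

CONSISTENT_L = "consistent-higher-L"
CONSISTENT_S = "consistent-higher-S"
INCONSISTENT = "inconsistent"


def regions_of(fin: str) -> tuple[str, ...]:
    """All region labels legal for ``fin`` (L regions first, then S)."""
    return L_REGIONS[fin] + (S_REGION[fin],)


def is_l_region(region: str) -> bool:
    return any(region in regs for regs in L_REGIONS.values())


def fin_of_region(region: str) -> str:
    for fin in FINS:
        if region in regions_of(fin):
            return fin
    raise ValueError(f"unknown region label {region!r}")
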