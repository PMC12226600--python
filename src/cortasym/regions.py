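"""Canonical Desikan-Killiany cortical parcellation catalogue.

The surface-reconstruction pipeline summarises cortical thickness as 34
regional means per hemisphere.  All tables read or written by this package
are canonicalised to the region order below (the order ``aparcstats2table``
emits), so downstream code can rely on positional pairing of left and right
hemisphere values.
"""

from __future__ import annotations

# 34 cortical labels, FreeSurfer aparc order.
DESIKAN_KILLIANY_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

N_REGIONS: int = len(DESIKAN_KILLIANY_REGIONS)

# Temporal-lobe labels, used by the cohort simulator to localise atrophy
# for the semantic-variant phenotype.
TEMPORAL_REGIONS: tuple[str, ...] = (
    "bankssts",
    "entorhinal",
    "fusiform",
    "inferiortemporal",
    "middletemporal",
    "parahippocampal",
    "superiortemporal",
    "temporalpole",
    "transversetemporal",
)

_CANONICAL_INDEX = {name: i for i, name in enumerate(DESIKAN_KILLIANY_REGIONS)}


def region_index(name: str) -> int:
    """Return the canonical index of a region label (case-insensitive)."""
    try:
        return _CANONICAL_INDEX[name.lower()]
    except KeyError:
        raise KeyError(f"unknown Desikan-Killiany region: {name!r}") from None
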