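"""Desikan-Killiany-Tourville (DKT) cortical parcellation registry.

The DKT atlas partitions each cortical hemisphere into 31 gyral regions
(62 regions in total).  Cortical-thickness tables consumed and produced by
this package are indexed by the ``<hemi>-<region>`` labels defined here,
e.g. ``"right fusiform"`` or ``"left superiortemporal"``.
"""

from __future__ import annotations

# The 31 cortical regions per hemisphere of the DKT protocol (FreeSurfer
# aparc.DKTatlas naming).  Note the DKT protocol drops the banks of the
# superior temporal sulcus, the frontal/temporal poles and the corpus
# callosum label relative to the older Desikan-Killiany scheme.
DKT_REGIONS: tuple[str, ...] = (
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
    "transversetemporal",
    "insula",
)

HEMISPHERES: tuple[str, str] = ("left", "right")

#: All 62 ROI labels, left hemisphere first, each hemisphere in the
#: canonical region order above.
DKT_LABELS: tuple[str, ...] = tuple(
    f"{hemi} {region}" for hemi in HEMISPHERES for region in DKT_REGIONS
)


def validate_label(label: str) -> str:
    """Return ``label`` if it is a known DKT ROI label, else raise ``KeyError``."""
    if label not in DKT_LABELS:
        raise KeyError(f"unknown DKT ROI label: {label!r}")
    return label
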