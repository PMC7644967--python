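"""Illustrative lipid target panels.

Published single-cell lipid panels list species names (sum composition) but
not the instrument target m/z, which depends on adduct choice. This module
builds an illustrative positive-mode panel by arithmetic from public
monoisotopic anchor masses: within a class, adding a CH2 shifts the mass by
14.0156500642 Da and each additional double bond removes one H2
(2.0156500638 Da). The values are synthetic reference data for testing and
simulation, not measurements.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core import LipidTarget, parse_lipid_name

__all__ = [
    "mz_for",
    "build_panel",
    "default_panel",
    "reference_presence_table",
    "DEFAULT_PANEL_NAMES",
]

_CH2 = 14.0156500642
_H2 = 2.0156500638

# (anchor carbons, anchor double bonds, anchor m/z, adduct) per class.
# Anchors: PC 34:1 / PE 34:1 / SM d34:1 / PS 34:1 / Cer d34:1 / DG 34:1 as
# [M+H]+ and TG 52:2 as [M+NH4]+, computed from their molecular formulas.
_ANCHORS = {
    "PC": (34, 1, 760.5851, "[M+H]+"),
    "PE": (34, 1, 718.5381, "[M+H]+"),
    "SM": (34, 1, 703.5749, "[M+H]+"),
    "PS": (34, 1, 762.5280, "[M+H]+"),
    "Cer": (34, 1, 538.5194, "[M+H]+"),
    "DG": (34, 1, 595.5296, "[M+H]+"),
    "TG": (52, 2, 876.8017, "[M+NH4]+"),
}

#: Names of the 37-species PC/PE/SM panel used as the default simulation panel.
#: The two marker lipids PC 34:1 and PC 36:2 (the most abundant species in
#: dopaminergic neurons) are listed first.
DEFAULT_PANEL_NAMES = (
    "PC 34:1", "PC 36:2",
    "PC 30:1", "PC 32:0", "PC 32:1", "PC 32:2", "PC 32:3", "PC 32:4",
    "PC 34:0", "PC 34:2", "PC 34:3", "PC 34:4",
    "PC 36:1", "PC 36:3", "PC 36:4", "PC 36:5",
    "PC 38:3", "PC 38:4", "PC 38:5", "PC 38:8",
    "PC 40:3", "PC 40:4", "PC 40:5", "PC 40:6", "PC 40:9",
    "PE 34:0", "PE 34:1", "PE 34:2", "PE 34:3",
    "PE 36:0", "PE 36:1", "PE 36:3", "PE 36:4", "PE 38:6",
    "SM 34:1", "SM 36:1", "SM 36:2",
)


def mz_for(name: str) -> float:
    """Illustrative target m/z (Da) for a sum-composition name, e.g. ``"PC 34:1"``."""
    cls, c, d = parse_lipid_name(name)
    c0, d0, anchor, _ = _ANCHORS[cls]
    return anchor + (c - c0) * _CH2 - (d - d0) * _H2


def build_panel(names) -> list[LipidTarget]:
    """Build LipidTarget objects for the given sum-composition names."""
    targets = []
    for name in names:
        cls, c, d = parse_lipid_name(name)
        adduct = _ANCHORS[cls][3]
        targets.append(
            LipidTarget(
                name=name,
                lipid_class=cls,
                carbons=c,
                double_bonds=d,
                adduct=adduct,
                target_mz=round(mz_for(name), 4),
            )
        )
    return targets


def default_panel() -> list[LipidTarget]:
    """The 37-species PC/PE/SM panel with illustrative m/z values."""
    return build_panel(DEFAULT_PANEL_NAMES)


def reference_presence_table() -> pd.DataFrame:
    """Bundled detection-percentage table: 37 lipids x 3 independent experiments.

    Rows are sum-composition names, columns experiment ids, entries the
    percentage of single cells in which each lipid passed QC in that
    experiment. Used to validate cross-experiment confidence tiering.
    """
    with resources.files("sclipid.data").joinpath("neuron_panel_presence.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("lipid_name")
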