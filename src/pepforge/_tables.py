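"""Bundled parameter tables: element radii/LJ terms and residue templates.

The tables are package data (JSON) loaded once at import.  Residue templates
carry the heavy-atom inventory, covalent bond list, side-chain internal
coordinates (Z-matrix rows), chi-angle atom quads and a united-atom partial
charge set (hydrogen charges folded into the parent heavy atom, pH 7
protonation: GLU/ASP deprotonated, LYS/ARG protonated).
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files("pepforge.data").joinpath(name).open() as fh:
        return json.load(fh)


def elements() -> dict:
    return _load("elements.json")


def vdw_radius(element: str) -> float:
    table = elements()["vdw_radius"]
    el = element.capitalize()
    if el not in table:
        raise KeyError(f"unknown element symbol: {element!r}")
    return table[el]


def lj_params(element: str) -> tuple[float, float]:
    """Return (rmin/2 in A, epsilon in kcal/mol) for an element."""
    table = elements()["lj"]
    el = element.capitalize()
    if el not in table:
        raise KeyError(f"no Lennard-Jones parameters for element {element!r}")
    entry = table[el]
    return entry["rmin_half"], entry["epsilon"]


COULOMB_CONSTANT = 332.0636  # kcal*A/(mol*e^2)


@lru_cache(maxsize=None)
def residue_templates() -> dict:
    data = {k: v for k, v in _load("residues.json").items() if not k.startswith("_")}
    return data


@lru_cache(maxsize=None)
def backbone_geometry() -> dict:
    return _load("residues.json")["_backbone"]


@lru_cache(maxsize=None)
def one_letter_map() -> dict:
    return {v["one_letter"]: k for k, v in residue_templates().items()}


STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# Covalent radii for distance-based bond inference on non-template residues.
COVALENT_RADIUS = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}
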