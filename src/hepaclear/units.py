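"""Clearance unit conversions.

Whole-body clearances are carried internally in L/h per kg body weight;
conversions happen only at input/output boundaries.  Cell-level clearances
are expressed in µL/min per 10^6 cells and reach whole-body units only
through the physiological scaling step in :mod:`hepaclear.ivive`.
"""

from __future__ import annotations

# canonical internal unit: L/h per kg
_TO_L_PER_H_PER_KG = {
    "L/h/kg": 1.0,
    "mL/h/kg": 1e-3,
    "mL/min/kg": 60e-3,
    "uL/min/kg": 60e-6,
}


def convert_clearance(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a whole-body clearance between the supported units.

    Supported units: ``L/h/kg``, ``mL/h/kg``, ``mL/min/kg``, ``uL/min/kg``.
    """
    try:
        f = _TO_L_PER_H_PER_KG[from_unit]
        t = _TO_L_PER_H_PER_KG[to_unit]
    except KeyError as exc:  # pragma: no cover - message, not logic
        raise ValueError(
            f"unknown clearance unit {exc}; supported: {sorted(_TO_L_PER_H_PER_KG)}"
        ) from None
    return value * f / t


def ml_min_kg_to_l_h_kg(value: float) -> float:
    """mL/min per kg -> L/h per kg (×60/1000)."""
    return convert_clearance(value, "mL/min/kg", "L/h/kg")


def l_h_kg_to_ml_h_kg(value: float) -> float:
    """L/h per kg -> mL/h per kg (×1000)."""
    return convert_clearance(value, "L/h/kg", "mL/h/kg")


CLEARANCE_UNITS = tuple(_TO_L_PER_H_PER_KG)
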