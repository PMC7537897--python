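"""Atomic-percent / mass-percent bookkeeping for EDS composition reports.

Conversions assume closure over the listed elements: the fractions are
renormalized over exactly the elements given, so the caller must supply a
complete element list (adding an explicit filler element if the measured
atom percentages do not sum to 100). Published C/O pairs for organic
matter are generally *not* reproducible under a two-element closure,
because unlisted light elements (N, H, ...) carry the missing atom
fraction — hence the explicit-closure requirement.

No ZAF/matrix correction or detector physics: pure stoichiometric
arithmetic, mass%_i = a_i M_i / sum_j a_j M_j.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "atom_to_mass_percent",
    "mass_to_atom_percent",
]

# IUPAC 2021 standard atomic weights, g/mol (common light elements;
# callers may override via the `masses` argument).
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Fe": 55.845,
    "Zn": 65.38,
}


def _resolve_masses(symbols, masses: dict[str, float] | None) -> np.ndarray:
    table = dict(ATOMIC_MASSES)
    if masses:
        table.update(masses)
    out = []
    for s in symbols:
        if s not in table:
            raise KeyError(f"no atomic mass for element {s!r}; pass masses=")
        if not table[s] > 0:
            raise ValueError(f"atomic mass for {s!r} must be > 0")
        out.append(table[s])
    return np.array(out, dtype=float)


def _validate(fractions: dict[str, float]) -> tuple[list[str], np.ndarray]:
    if not fractions:
        raise ValueError("empty composition")
    symbols = list(fractions)
    vals = np.array([fractions[s] for s in symbols], dtype=float)
    if (vals < 0).any():
        raise ValueError("percentages must be >= 0")
    if not vals.any():
        raise ValueError("all percentages are zero")
    return symbols, vals


def atom_to_mass_percent(
    fractions: dict[str, float],
    masses: dict[str, float] | None = None,
) -> dict[str, float]:
    """Convert atom% to mass% under closure over the listed elements.

    mass%_i = a_i M_i / sum_j a_j M_j x 100; the output sums to 100.
    """
    symbols, atom = _validate(fractions)
    M = _resolve_masses(symbols, masses)
    w = atom * M
    mass = 100.0 * (w / w.sum())
    return dict(zip(symbols, mass.tolist()))


def mass_to_atom_percent(
    fractions: dict[str, float],
    masses: dict[str, float] | None = None,
) -> dict[str, float]:
    """Inverse transform: a_i = (m_i / M_i) / sum_j (m_j / M_j) x 100."""
    symbols, mass = _validate(fractions)
    M = _resolve_masses(symbols, masses)
    w = mass / M
    atom = 100.0 * (w / w.sum())
    return dict(zip(symbols, atom.tolist()))
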