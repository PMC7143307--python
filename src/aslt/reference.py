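"""Published reference values for the EVOO accelerated-storage study.

These constants are the published end-products of the study — the
per-temperature apparent zero-order rate constants, the activation
energies, and the regulatory acceptability limits — and serve two roles:
as direct inputs for rates-only analyses (the raw trajectories were
never published), and as generating parameters for the synthetic study
(`aslt.synthetic`).

Units follow the publication: K270 in absorbance units/day, conjugated
trienes (CT) and hexanal in mg/kg/day, pyropheophytin a (PPP) in
percentage points/day.
"""

from __future__ import annotations

from .arrhenius import RateConstantSet

__all__ = [
    "REFERENCE_RATES",
    "REFERENCE_EA_J_MOL",
    "INITIAL_VALUES",
    "STUDY_TEMPERATURES_C",
    "reference_rate_set",
]

#: Storage temperatures of the accelerated design, degC.
STUDY_TEMPERATURES_C = (25.0, 40.0, 50.0, 60.0)

#: Apparent zero-order rate constants (k, se_k) per temperature, raw
#: units per day (absorbance/day for K270; %/day for PPP; mg/kg/day for
#: CT and hexanal).
REFERENCE_RATES: dict[str, dict[float, tuple[float, float]]] = {
    "K270": {
        25.0: (0.18e-3, 0.01e-3),
        40.0: (0.62e-3, 0.02e-3),
        50.0: (1.07e-3, 0.07e-3),
        60.0: (2.20e-3, 0.02e-3),
    },
    "PPP": {
        25.0: (0.043, 0.03),
        40.0: (0.428, 0.01),
        50.0: (1.112, 0.07),
        60.0: (5.270, 0.49),
    },
    "CT": {
        25.0: (0.36e-3, 0.01e-3),
        40.0: (1.05e-3, 0.06e-3),
        50.0: (3.01e-3, 0.11e-3),
        60.0: (9.17e-3, 0.32e-3),
    },
    "HEXANAL": {
        25.0: (2.77e-3, 0.34e-3),
        40.0: (7.24e-3, 0.73e-3),
        50.0: (16.91e-3, 0.94e-3),
        60.0: (26.62e-3, 2.88e-3),
    },
}

RATE_UNITS = {
    "K270": "AU/day",
    "PPP": "%/day",
    "CT": "mg/kg/day",
    "HEXANAL": "mg/kg/day",
}

#: Published apparent activation energies, J/mol.
REFERENCE_EA_J_MOL = {
    "K270": 58.39e3,
    "CT": 75.46e3,
    "HEXANAL": 54.78e3,
    "PPP": 102.94e3,
}

#: Initial composition of the studied oil (value, unit). Indices without
#: a published initial value (CT, hexanal, PPP) are absent.
INITIAL_VALUES = {
    "PV": (5.7, "meq O2/kg"),
    "K232": (1.81, "AU"),
    "K270": (0.15, "AU"),
    "PHENOLS": (332.9, "mg/kg"),
    "TOCOPHEROLS": (225.6, "mg/kg"),
}


def reference_rate_set(index_id: str) -> RateConstantSet:
    """Published per-temperature rate constants as a `RateConstantSet`."""
    try:
        table = REFERENCE_RATES[index_id]
    except KeyError:
        raise KeyError(
            f"no published rate constants for {index_id!r}; "
            f"available: {sorted(REFERENCE_RATES)}"
        ) from None
    entries = tuple((t, k, se) for t, (k, se) in sorted(table.items()))
    return RateConstantSet(index_id=index_id, entries=entries,
                           unit=RATE_UNITS.get(index_id, ""))
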