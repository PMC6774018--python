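"""Bundled example data.

``load_field_trial_means`` returns the published treatment-mean table of a
5-year grassland nitrogen (N) x water (W) addition experiment on the Inner
Mongolian semiarid steppe: 13 soil, plant and microbial indices, each with
mean (SE) under the four treatments (control, W, N, NW; four replicate
blocks). It is the worked input for :func:`coreacc.effects.pooled_effect`.
"""

from __future__ import annotations

from .effects import TreatmentMeansTable

__all__ = ["load_field_trial_means"]

# index name, units, (control, W, N, NW) means, (control, W, N, NW) SEs
_FIELD_TRIAL_ROWS = [
    ("SOM content", "g/kg soil", (10.30, 10.00, 12.62, 12.00), (0.94, 1.18, 1.14, 0.59)),
    ("Soil total N content", "g/kg soil", (2.72, 2.70, 2.50, 2.50), (0.15, 0.14, 0.07, 0.01)),
    ("Soil available N content", "mg/kg soil", (13.47, 19.68, 26.39, 25.88), (0.92, 1.61, 2.62, 6.03)),
    ("Soil water content", "kg/kg soil", (0.07, 0.11, 0.07, 0.11), (0.01, 0.01, 0.01, 0.01)),
    ("Soil pH", "", (7.22, 7.32, 6.43, 6.78), (0.07, 0.10, 0.03, 0.17)),
    ("Aboveground plant biomass", "g/m2", (45.93, 46.38, 47.67, 77.58), (13.02, 1.93, 5.18, 15.36)),
    ("Plant species richness", "count", (11.25, 14.25, 9.50, 11.75), (0.48, 1.44, 0.65, 1.65)),
    ("Bacterial 16S rRNA gene abundance", "1e10/g soil", (1.11, 1.10, 0.91, 1.22), (0.15, 0.14, 0.11, 0.15)),
    ("Bacterial relative abundance", "%", (93.59, 95.03, 93.65, 94.04), (0.52, 0.34, 0.18, 0.27)),
    ("Archaeal relative abundance", "%", (5.23, 4.26, 4.85, 5.10), (0.60, 0.19, 0.09, 0.21)),
    ("Fungal relative abundance", "%", (1.18, 0.71, 1.50, 0.86), (0.16, 0.17, 0.20, 0.17)),
    ("Microbial respiration", "mg CO2/kg/day", (40.56, 43.39, 36.71, 42.20), (1.07, 0.97, 1.06, 1.16)),
    ("Ammonia oxidization potential", "NO2-N mg/g soil/h", (1.52, 1.27, 9.48, 8.91), (0.60, 0.44, 0.90, 1.08)),
]

_TREATMENTS = ("control", "W", "N", "NW")


def load_field_trial_means() -> list[TreatmentMeansTable]:
    """Treatment-mean table of the grassland N x W addition field trial."""
    rows = []
    for name, units, means, ses in _FIELD_TRIAL_ROWS:
        rows.append(
            TreatmentMeansTable(
                index_name=name,
                units=units,
                means=dict(zip(_TREATMENTS, means)),
                ses=dict(zip(_TREATMENTS, ses)),
            )
        )
    return rows
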