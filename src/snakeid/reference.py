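"""Reference posterior medians from the full-scale identification challenge.

The original week-long online challenge (250 analysed participants, 100 core
species, ~10 photos each, six global regions) was fitted with the same graded
response model implemented in :mod:`snakeid.grm`.  The posterior medians of
that fit are shipped here as a static table: they parameterize the default
synthetic-challenge generator and provide population-level point estimates for
reference predictions (e.g. the probability that an average outsider
identifies the first photo of a North American colubrid to species level).

All effects are on the cumulative-logit scale.  Family effects are relative to
Boidae, region effects relative to Africa; ``discrimination`` is the intercept
of the log-scale discrimination parameter.
"""

from __future__ import annotations

import numpy as np

#: Ordered category thresholds (cut-points between scores 0|1, 1|2, 2|3).
THRESHOLDS = np.array([-2.36, -1.17, -0.53])

#: Log-scale discrimination intercept: alpha = exp(DISCRIMINATION + d_photo + d_species).
DISCRIMINATION = 0.15

#: Family contrasts, reference Boidae.
FAMILY_EFFECTS = {
    "Boidae": 0.0,
    "Colubridae": -1.97,
    "Cylindrophiidae": -2.80,
    "Elapidae": -1.25,
    "Lamprophiidae": -2.46,
    "Leptotyphlopidae": -1.58,
    "Pythonidae": -0.15,
    "Typhlopidae": -0.81,
    "Viperidae": -1.09,
}

#: Photo-region contrasts, reference Africa.
REGION_EFFECTS = {
    "Africa": 0.0,
    "Asia": -0.09,
    "Australasia": -0.26,
    "Europe": -0.04,
    "NorthAmerica": -0.00,
    "SouthAmerica": 0.30,
}

#: Main effect of the photo coming from the participant's home region.
HOME_REGION_EFFECT = 3.14

#: Region-specific modification of the home-region effect, reference Africa.
HOME_REGION_INTERACTIONS = {
    "Africa": 0.0,
    "Asia": -2.17,
    "Australasia": -0.51,
    "Europe": -2.32,
    "NorthAmerica": -1.73,
    "SouthAmerica": -1.63,
}

#: Per-prior-exposure learning effect (0-based count of earlier photos of the
#: same species seen by the participant).
TAXA_REPEAT_EFFECT = 0.08

#: Group-level standard deviations / correlations.
SD_PARTICIPANT = 1.00  # fixed, sets the latent-ability scale
SD_PHOTO_DIFFICULTY = 0.65
SD_PHOTO_DISCRIMINATION = 0.21
COR_PHOTO = 0.70
SD_SPECIES_DIFFICULTY = 0.62
SD_SPECIES_DISCRIMINATION = 0.31
COR_SPECIES = 0.34


def fixed_effect_vector(columns: list[str]) -> np.ndarray:
    """Reference medians arranged to match a design-matrix column list.

    Column names follow :func:`snakeid.grm.build_design` (which itself mirrors
    the published parameter table): bare family and region names,
    ``home_region = T``, ``taxa_repeat``, ``quality = low`` and
    ``<Region>: home_region = T`` interaction terms.
    """
    out = np.zeros(len(columns))
    for i, col in enumerate(columns):
        if col in FAMILY_EFFECTS:
            out[i] = FAMILY_EFFECTS[col]
        elif col in REGION_EFFECTS:
            out[i] = REGION_EFFECTS[col]
        elif col == "home_region = T":
            out[i] = HOME_REGION_EFFECT
        elif col == "taxa_repeat":
            out[i] = TAXA_REPEAT_EFFECT
        elif col.endswith(": home_region = T"):
            region = col.split(":")[0]
            out[i] = HOME_REGION_INTERACTIONS[region]
        elif col == "quality = low":
            out[i] = 0.0  # quality not in the top model
        else:
            raise KeyError(f"no reference estimate for design column {col!r}")
    return out
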