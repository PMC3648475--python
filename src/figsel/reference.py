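"""Reference trait parameterization for the wet/dry faba bean contrast.

Per-set means and standard deviations of the 16 leaf morpho-physiological
and phenological variables measured on 201 wet-origin and 201 dry-origin
*Vicia faba* accessions grown under well-watered conditions.  These numbers
serve two purposes:

* defaults for the synthetic trait generator (each set is emulated as a
  multivariate normal with these marginal moments), and
* inputs to the summary-statistic t-test reproduction
  (:func:`figsel.set_comparison_stats.pooled_t_from_summary`).

``published_t`` is the t statistic reported alongside each contrast
(pooled two-sample test, df = 400).  For the two temperature-depression
rows the reported t is not recoverable from the reported means and SDs
under any standard two-sample formula; they are flagged with
``t_reproducible=False`` and excluded from numeric t checks.
"""

from __future__ import annotations

from typing import NamedTuple


class TraitSummary(NamedTuple):
    wet_mean: float
    wet_sd: float
    dry_mean: float
    dry_sd: float
    published_t: float
    unit: str
    group: str
    t_reproducible: bool = True


#: Accessions per set in the reference experiment.
SET_N = 201

#: Replicates (pots) per accession in the reference experiment.
N_REPLICATES = 4

#: The 16 analysis variables, in canonical (reporting) order.
ANALYSIS_VARIABLES = (
    "stomatal_density",
    "stomatal_length",
    "stomatal_width",
    "stomatal_area",
    "stomatal_area_per_leaflet_area",
    "leaflet_area",
    "fertile_tillers",
    "photosynthetic_rate",
    "intercellular_co2",
    "stomatal_conductance",
    "water_use_efficiency",
    "transpiration_rate",
    "leaflet_temp_depression",
    "canopy_temp_depression",
    "relative_water_content",
    "days_to_flowering",
)

#: Reference per-set summary statistics (wet mean, wet sd, dry mean, dry sd,
#: reported t).  SAAL is on the conventional x10^-3 um^2 mm^-2 scale.
TRAIT_SUMMARY: dict[str, TraitSummary] = {
    "stomatal_density": TraitSummary(49.6, 12.4, 48.3, 6.1, 1.29, "mm^-2", "morphology"),
    "stomatal_length": TraitSummary(53.2, 3.9, 55.4, 2.6, 6.63, "um", "morphology"),
    "stomatal_width": TraitSummary(30.4, 1.61, 30.3, 0.92, 0.20, "um", "morphology"),
    "stomatal_area": TraitSummary(1622.0, 184.0, 1685.0, 119.0, 4.07, "um^2", "morphology"),
    "stomatal_area_per_leaflet_area": TraitSummary(
        77.9, 12.4, 80.6, 6.8, 2.67, "x10^-3 um^2 mm^-2", "morphology"
    ),
    "leaflet_area": TraitSummary(11.4, 5.9, 16.9, 5.2, 9.86, "cm^2", "morphology"),
    "fertile_tillers": TraitSummary(2.85, 1.52, 2.25, 1.1, 4.54, "count", "morphology"),
    "photosynthetic_rate": TraitSummary(7.8, 2.0, 8.2, 1.1, 2.25, "umol m^-2 s^-1", "physiology"),
    "intercellular_co2": TraitSummary(322.4, 22.3, 325.2, 10.5, 1.64, "ppm", "physiology"),
    "stomatal_conductance": TraitSummary(
        0.329, 0.119, 0.320, 0.072, 0.92, "mol m^-2 s^-1", "physiology"
    ),
    "water_use_efficiency": TraitSummary(25.6, 7.8, 26.4, 4.2, 1.24, "umol mol^-1", "physiology"),
    "transpiration_rate": TraitSummary(3.26, 0.9, 3.42, 0.5, 2.15, "mmol m^-2 s^-1", "physiology"),
    "leaflet_temp_depression": TraitSummary(
        -0.17, 0.31, -0.72, 0.19, 34.98, "degC", "physiology", t_reproducible=False
    ),
    "canopy_temp_depression": TraitSummary(
        -0.80, 1.21, -1.59, 0.48, 13.77, "degC", "physiology", t_reproducible=False
    ),
    "relative_water_content": TraitSummary(82.3, 3.9, 86.3, 2.4, 12.59, "%", "physiology"),
    "days_to_flowering": TraitSummary(50.7, 13.1, 48.3, 7.4, 2.24, "days", "phenology"),
}

#: Seed-size class mixture per set (major / equina / minor botanical types).
#: Roughly three quarters of the dry-origin material is large-seeded (major),
#: against one fifth of the wet-origin material, whose remainder splits
#: evenly between minor and equina.
SEED_CLASS_PROBS: dict[str, dict[str, float]] = {
    "dry": {"major": 0.75, "equina": 0.125, "minor": 0.125},
    "wet": {"major": 0.20, "equina": 0.40, "minor": 0.40},
}

#: Variables that cannot be negative in nature (truncation bounds for the
#: generator); relative water content is additionally bounded above by 100%.
NONNEGATIVE_VARIABLES = frozenset(ANALYSIS_VARIABLES) - {
    "leaflet_temp_depression",
    "canopy_temp_depression",
}
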