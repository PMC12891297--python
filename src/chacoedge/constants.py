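"""Shared vocabulary: land-use levels, structure variables, covariate terms.

Order matters and is relied upon throughout: land uses index the varying
effects of the multilevel model, and covariate order fixes the design-matrix
column layout.
"""

LAND_USES: tuple[str, ...] = ("cropland", "pasture", "silvopasture")

#: Forest-structure response variables (natural units: %, %, t/ha).
STRUCTURE_VARS: tuple[str, ...] = ("tree_cover", "shrub_cover", "agb")

#: Control covariates entering the model as fixed (non-varying) slopes.
COVARIATE_TERMS: tuple[str, ...] = (
    "temp",
    "precip",
    "dist_time",
    "dist_home",
    "dist_roads",
)

#: First and last year of the deforestation record.
YEAR_RANGE: tuple[int, int] = (1976, 2020)

#: Year the structure maps refer to; edge age = survey year - clearing year.
SURVEY_YEAR: int = 2020

#: Maximum distance (m) at which edges are assumed to have any effect.
MAX_EDGE_DISTANCE: float = 2000.0
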