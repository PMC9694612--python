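"""Factorial design description and the fixed 30-response schema.

The trial design crosses three categorical factors — growing year (2 levels),
locality (3 sites in Vojvodina, Serbia) and fertilization treatment (6 levels,
including an unfertilized control) — in a randomized block layout with four
replications per cell.  Thirty responses are measured per plot: thirteen
agronomic traits and seventeen essential-oil (EO) composition shares, one of
which is an unidentified chromatographic fraction ("NI").
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Agronomic traits, in roster order.  Units: cm, cm, counts, counts, g,
#: g/plant, g, %, kg/ha, kg/ha, %, %, %.
AGRONOMIC_RESPONSES: tuple[str, ...] = (
    "plant_height",
    "umbel_diameter",
    "number_of_umbels",
    "number_of_seeds",
    "thousand_seed_weight",
    "yield_per_plant",
    "plant_weight",
    "harvest_index",
    "yield_per_ha",
    "eo_yield",
    "germination_energy",
    "total_germination",
    "eo_content",
)

#: Essential-oil composition shares (% of total oil), GC elution-style order,
#: with the unidentified fraction "ni" between trans-muurola-4(14),5-diene and
#: alpha-zingiberene.
EO_RESPONSES: tuple[str, ...] = (
    "limonene",
    "cis_dihydro_carvone",
    "methyl_chavicol",
    "carvone",
    "cis_anethole",
    "trans_anethole",
    "beta_elemene",
    "alpha_himachalene",
    "trans_beta_farnesene",
    "gamma_himachalene",
    "trans_muurola_4_14_5_diene",
    "ni",
    "alpha_zingiberene",
    "beta_himachalene",
    "beta_bisabolene",
    "trans_pseudoisoeugenyl_2_methylbutyrate",
    "epoxy_pseudoisoeugenyl_2_methylbutyrate",
)

#: The full fixed response roster (13 agronomic + 17 EO = 30 columns).
RESPONSE_NAMES: tuple[str, ...] = AGRONOMIC_RESPONSES + EO_RESPONSES

#: Factor columns preceding the responses in any trial table.
FACTOR_COLUMNS: tuple[str, ...] = ("year", "locality", "fertilization", "replicate")

DEFAULT_YEARS: tuple[str, ...] = ("year_1", "year_2")
DEFAULT_LOCALITIES: tuple[str, ...] = ("Ostojićevo", "Veliki Radinci", "Mošorin")
DEFAULT_FERTILIZATIONS: tuple[str, ...] = (
    "control",
    "Slavol",
    "BactoFil",
    "Royal Ofert",
    "vermicompost",
    "NPK",
)


class DesignError(ValueError):
    """Invalid factorial design or unknown factor level."""


@dataclass(frozen=True)
class DesignSpec:
    """A full-crossing factorial design: years × localities × fertilizations.

    Parameters
    ----------
    years, localities, fertilizations
        Ordered, duplicate-free level labels.  The defaults reproduce the
        2 × 3 × 6 aniseed trial layout.
    replications
        Plots per factor cell (default 4).
    """

    years: tuple[str, ...] = DEFAULT_YEARS
    localities: tuple[str, ...] = DEFAULT_LOCALITIES
    fertilizations: tuple[str, ...] = DEFAULT_FERTILIZATIONS
    replications: int = 4

    def __post_init__(self) -> None:
        for name, levels in (
            ("years", self.years),
            ("localities", self.localities),
            ("fertilizations", self.fertilizations),
        ):
            if len(levels) == 0:
                raise DesignError(f"{name} must be non-empty")
            if len(set(levels)) != len(levels):
                raise DesignError(f"{name} contains duplicate levels: {levels}")
        if self.replications < 1:
            raise DesignError("replications must be a positive integer")

    @property
    def n_cells(self) -> int:
        """Number of distinct factor combinations in the full crossing."""
        return len(self.years) * len(self.localities) * len(self.fertilizations)

    @property
    def n_records(self) -> int:
        """Total plot count: cells × replications."""
        return self.n_cells * self.replications

    @property
    def n_inputs(self) -> int:
        """Width of the encoded design matrix (year code + two one-hot blocks)."""
        return 1 + len(self.localities) + len(self.fertilizations)

    def year_code(self, year: str) -> int:
        """Numeric 0/1 code of a year level (first year ⇒ 0)."""
        try:
            return self.years.index(year)
        except ValueError:
            raise DesignError(f"unknown year level: {year!r}") from None

    def cells(self):
        """Iterate (year, locality, fertilization) in deterministic order."""
        for year in self.years:
            for loc in self.localities:
                for fert in self.fertilizations:
                    yield year, loc, fert

    def input_names(self) -> list[str]:
        """Column labels of the encoded design matrix."""
        return (
            ["year"]
            + [f"locality={lv}" for lv in self.localities]
            + [f"fertilization={lv}" for lv in self.fertilizations]
        )
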