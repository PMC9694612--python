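"""Synthetic factorial trial generator with a known, additive effect structure.

Emulates a 2 (year) × 3 (locality) × 6 (fertilization) randomized-block aniseed
trial with four replications.  Each of the 30 responses follows

    y = intercept + year_effect · year_code + locality_effect
        + fertilization_effect + gain · year_code · fertilization_effect + ε,

with ``ε ~ N(0, noise_sd²)`` drawn independently per replicate and the optional
``gain`` term providing a year × fertilization interaction so the response
surface is genuinely nonlinear in the encoded inputs.  Essential-oil shares are
clipped at zero after the noise draw; shares are *not* renormalized to sum to
100 because each compound is modelled independently and the roster includes an
unidentified fraction.

Because the one-hot indicator block of each factor sums to one, adding a
constant to every level of a factor is indistinguishable from shifting the
intercept.  The default effect tables therefore keep each factor's effects
centred near zero, which makes the *signs* of the generating effects
identifiable — a prerequisite for checking connection-weight sensitivity
against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    DesignSpec,
    DesignError,
    EO_RESPONSES,
    FACTOR_COLUMNS,
    RESPONSE_NAMES,
)

__all__ = [
    "ResponseEffects",
    "EffectsConfig",
    "ConfigurationError",
    "default_effects",
    "generate_trial",
]


class ConfigurationError(ValueError):
    """Inconsistent effects configuration (e.g. unknown factor level)."""


#: Responses whose values carry percentage semantics (intercepts must lie in
#: [0, 100]).  All EO shares qualify, plus the percentage-valued agronomic traits.
_PERCENT_RESPONSES = frozenset(EO_RESPONSES) | {
    "harvest_index",
    "germination_energy",
    "total_germination",
    "eo_content",
}


@dataclass
class ResponseEffects:
    """Additive effect structure of a single response.

    All effects are in the response's own units.  ``nonlinear_gain`` scales a
    year × fertilization product term (default 0: purely additive).
    """

    intercept: float
    year_effect: float
    locality_effects: dict[str, float]
    fertilization_effects: dict[str, float]
    noise_sd: float
    nonlinear_gain: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be ≥ 0, got {self.noise_sd}")


@dataclass
class EffectsConfig:
    """Effect structures for every response in the fixed 30-response roster."""

    responses: dict[str, ResponseEffects]

    def __post_init__(self) -> None:
        missing = [r for r in RESPONSE_NAMES if r not in self.responses]
        if missing:
            raise ConfigurationError(f"effects missing for responses: {missing}")
        for name, eff in self.responses.items():
            if name in _PERCENT_RESPONSES and not (0.0 <= eff.intercept <= 100.0):
                raise ConfigurationError(
                    f"{name}: percentage response intercept {eff.intercept} "
                    "outside [0, 100]"
                )

    def effect_vector(self, response: str, design: DesignSpec) -> np.ndarray:
        """Generating effects aligned with the encoded input columns.

        Order: year effect, then locality effects in design order, then
        fertilization effects in design order.  Useful as ground truth when
        validating sensitivity analyses.
        """
        eff = self.responses[response]
        return np.array(
            [eff.year_effect]
            + [eff.locality_effects[lv] for lv in design.localities]
            + [eff.fertilization_effects[lv] for lv in design.fertilizations]
        )

    def to_dict(self) -> dict:
        return {
            name: {
                "intercept": eff.intercept,
                "year_effect": eff.year_effect,
                "locality_effects": dict(eff.locality_effects),
                "fertilization_effects": dict(eff.fertilization_effects),
                "noise_sd": eff.noise_sd,
                "nonlinear_gain": eff.nonlinear_gain,
            }
            for name, eff in self.responses.items()
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EffectsConfig":
        return cls(
            responses={name: ResponseEffects(**cfg) for name, cfg in data.items()}
        )


# ---------------------------------------------------------------------------
# Default effect tables.
#
# Per response: (intercept, noise_sd, span, year, {locality: f}, {fert: f})
# where effect = fraction × span.  Intercepts sit near typical observed levels
# of each trait; noise_sd reflects plot-to-plot replicate scatter; span sets
# the magnitude of the strongest factor effects.  Fractions are listed only
# for levels with a known direction of influence (vermicompost and BactoFil
# raising growth and yield traits, Royal Ofert and NPK depressing seed
# quality and yield, mineral NPK and the second year favouring the himachalene
# /zingiberene sesquiterpene group, trans-anethole — the dominant
# phenylpropanoid, ~90% of the oil — responding positively to Royal Ofert and
# NPK, site contrasts on the minor monoterpenes).  Unlisted levels receive
# small seed-dependent jitter, balanced so each factor's effects sum to ≈ 0.
# ---------------------------------------------------------------------------

_O, _V, _M = "Ostojićevo", "Veliki Radinci", "Mošorin"
_CT, _SL, _BF, _RO, _VC, _NP = (
    "control",
    "Slavol",
    "BactoFil",
    "Royal Ofert",
    "vermicompost",
    "NPK",
)

_DEFAULT_TABLE: dict[str, tuple] = {
    # --- agronomic traits -------------------------------------------------
    "plant_height": (46.0, 1.4, 8.0, -0.35,
                     {_O: -0.30, _M: 0.35},
                     {_VC: 0.55, _BF: 0.35, _RO: 0.30, _NP: -0.55, _CT: -0.25}),
    "umbel_diameter": (5.8, 0.24, 1.2, -0.30,
                       {_O: -0.25, _M: 0.30},
                       {_VC: 0.45, _BF: 0.35, _RO: -0.75, _CT: -0.10}),
    "number_of_umbels": (16.0, 0.6, 4.5, -0.35,
                         {_O: -0.25, _M: 0.35},
                         {_VC: 0.60, _BF: 0.55, _RO: -0.55, _CT: -0.25}),
    "number_of_seeds": (105.0, 3.9, 22.0, -0.30,
                        {_O: -0.35, _M: 0.30},
                        {_VC: -0.15, _NP: 0.30, _CT: -0.10}),
    "thousand_seed_weight": (4.6, 0.21, 1.0, -0.25,
                             {_O: -0.15, _M: 0.25},
                             {_VC: 0.45, _BF: 0.25, _RO: -0.65, _NP: -0.35}),
    "yield_per_plant": (9.5, 0.47, 4.5, -0.30,
                        {_O: -0.45, _M: 0.40},
                        {_VC: 0.65, _BF: 0.55, _RO: -0.55, _NP: -0.60}),
    "plant_weight": (21.0, 0.85, 5.5, -0.30,
                     {_O: -0.35, _M: 0.35},
                     {_VC: 0.50, _BF: 0.45, _NP: -0.50, _CT: -0.20}),
    "harvest_index": (42.0, 1.37, 7.0, -0.25,
                      {_M: 0.30, _O: -0.20},
                      {_VC: 0.40, _BF: 0.25, _RO: -0.35, _NP: -0.50, _CT: 0.20}),
    "yield_per_ha": (1900.0, 94.0, 520.0, -0.30,
                     {_O: -0.45, _M: 0.40},
                     {_VC: 0.60, _BF: 0.50, _RO: -0.55, _NP: -0.55}),
    "eo_yield": (80.0, 4.1, 22.0, -0.30,
                 {_O: -0.35, _M: 0.35},
                 {_VC: 0.45, _BF: 0.40, _RO: -0.70, _NP: -0.35}),
    "germination_energy": (85.0, 3.8, 12.0, -0.25,
                           {_O: -0.20, _M: 0.20},
                           {_VC: 0.30, _BF: 0.25, _RO: -0.50, _NP: -0.45}),
    "total_germination": (88.0, 3.2, 10.0, -0.20,
                          {_M: 0.20},
                          {_BF: 0.35, _RO: -0.55, _NP: -0.25, _VC: 0.25}),
    "eo_content": (4.0, 0.25, 0.9, -0.25,
                   {_M: 0.25, _O: -0.15},
                   {_VC: -0.40, _RO: -0.55, _NP: 0.40, _CT: 0.25}),
    # --- essential-oil composition shares --------------------------------
    "limonene": (0.20, 0.022, 0.07, -0.30,
                 {_O: -0.40, _V: 0.25, _M: 0.15},
                 {_CT: 0.30, _NP: 0.25}),
    "cis_dihydro_carvone": (0.32, 0.046, 0.13, -0.20,
                            {_V: -0.40, _O: 0.20, _M: 0.20},
                            {_BF: -0.55, _CT: 0.45, _SL: 0.30}),
    "methyl_chavicol": (0.85, 0.19, 0.45, -0.35,
                        {_M: 0.20, _O: -0.15},
                        {_RO: 0.50, _VC: 0.30, _NP: -0.45}),
    "carvone": (0.12, 0.014, 0.045, -0.30,
                {_O: -0.40, _V: 0.25, _M: 0.15},
                {_CT: 0.30, _NP: 0.30, _SL: 0.25}),
    "cis_anethole": (0.14, 0.03, 0.06, -0.25,
                     {_O: 0.25, _M: -0.15},
                     {_VC: 0.45, _NP: -0.30}),
    "trans_anethole": (90.0, 0.35, 2.2, -0.25,
                       {_M: 0.25, _O: -0.20},
                       {_RO: 0.60, _NP: 0.30, _VC: 0.35, _BF: -0.45, _CT: -0.45}),
    "beta_elemene": (0.10, 0.029, 0.065, -0.20,
                     {_V: -0.50, _O: 0.25, _M: 0.25},
                     {_CT: 0.55, _BF: 0.30}),
    "alpha_himachalene": (0.29, 0.034, 0.12, 0.45,
                          {_M: 0.20, _O: -0.15},
                          {_RO: -0.60, _VC: -0.55, _BF: -0.30, _NP: 0.45, _SL: 0.35}),
    "trans_beta_farnesene": (0.055, 0.019, 0.035, 0.35,
                             {_M: -0.50, _O: 0.25, _V: 0.25},
                             {_SL: -0.45, _RO: 0.35}),
    "gamma_himachalene": (2.9, 0.31, 0.95, 0.40,
                          {_M: 0.20, _O: -0.15},
                          {_RO: -0.60, _VC: -0.45, _BF: -0.25, _NP: 0.50, _SL: 0.30}),
    "trans_muurola_4_14_5_diene": (0.92, 0.16, 0.40, -0.35,
                                   {_M: 0.15, _O: -0.10},
                                   {_RO: 0.55, _VC: 0.35, _NP: -0.45}),
    "ni": (0.50, 0.025, 0.16, 0.45,
           {_M: 0.15, _O: -0.10},
           {_RO: -0.65, _VC: -0.35, _BF: -0.25, _NP: 0.40, _SL: 0.30}),
    "alpha_zingiberene": (0.52, 0.063, 0.19, 0.35,
                          {_M: 0.15, _O: -0.10},
                          {_VC: -0.50, _RO: -0.45, _BF: -0.25, _NP: 0.45, _SL: 0.30}),
    "beta_himachalene": (0.20, 0.033, 0.09, 0.35,
                         {_M: 0.15, _O: -0.10},
                         {_RO: -0.60, _NP: 0.45, _SL: 0.25}),
    "beta_bisabolene": (0.28, 0.055, 0.13, 0.25,
                        {_M: 0.15, _O: -0.10},
                        {_RO: 0.50, _CT: -0.30}),
    "trans_pseudoisoeugenyl_2_methylbutyrate": (0.20, 0.04, 0.11, 0.35,
                                                {_M: 0.15, _O: -0.10},
                                                {_RO: -0.55, _VC: -0.50,
                                                 _BF: -0.25, _NP: 0.45, _SL: 0.35}),
    "epoxy_pseudoisoeugenyl_2_methylbutyrate": (1.8, 0.026, 0.45, 0.25,
                                                {_M: 0.15, _O: -0.10},
                                                {_RO: -0.35, _NP: 0.50, _SL: 0.20}),
}


def default_effects(seed: int = 0, design: DesignSpec | None = None) -> EffectsConfig:
    """Build the default effect configuration for the 30-response roster.

    Levels whose direction of influence is fixed by the default tables keep
    their tabulated effect; remaining levels receive small jitter drawn from
    ``seed`` and are shifted so every factor's effects sum to zero per
    response (see module docstring on identifiability).

    Parameters
    ----------
    seed
        Seeds the jitter on unconstrained levels only; the tabulated effect
        structure itself is fixed.
    design
        Factor levels to populate (defaults to the 2 × 3 × 6 trial design).
    """
    design = design or DesignSpec()
    rng = np.random.default_rng(seed)
    responses: dict[str, ResponseEffects] = {}
    for name in RESPONSE_NAMES:
        intercept, noise_sd, span, year_frac, loc_frac, fert_frac = _DEFAULT_TABLE[name]
        loc = _fill_group(loc_frac, design.localities, span, rng)
        fert = _fill_group(fert_frac, design.fertilizations, span, rng)
        responses[name] = ResponseEffects(
            intercept=intercept,
            year_effect=year_frac * span,
            locality_effects=loc,
            fertilization_effects=fert,
            noise_sd=noise_sd,
        )
    return EffectsConfig(responses=responses)


def _fill_group(
    fractions: dict[str, float],
    levels: tuple[str, ...],
    span: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Turn fractional effects into response units, balancing to zero sum.

    Unconstrained levels get U(−0.06, 0.06)·span jitter and then absorb the
    group imbalance equally, so constrained signs are never altered.
    """
    unknown = [lv for lv in fractions if lv not in levels]
    if unknown:
        raise ConfigurationError(f"unknown factor level in defaults: {unknown[0]!r}")
    effects = {lv: fractions.get(lv, None) for lv in levels}
    free = [lv for lv, v in effects.items() if v is None]
    out = {lv: (v * span if v is not None else 0.0) for lv, v in effects.items()}
    for lv in free:
        out[lv] = float(rng.uniform(-0.06, 0.06) * span)
    if free:
        imbalance = sum(out.values()) / len(free)
        for lv in free:
            out[lv] -= imbalance
    return out


def generate_trial(
    design: DesignSpec, effects: EffectsConfig, seed: int
) -> pd.DataFrame:
    """Simulate a full-crossing trial table.

    Returns a tidy frame with one row per plot: ``year``, ``locality``,
    ``fertilization``, ``replicate`` (1-based) and the 30 response columns in
    roster order.  Identical ``(design, effects, seed)`` reproduce the table
    bitwise.

    Raises
    ------
    ConfigurationError
        If an effect configuration references a level absent from ``design``
        or lacks a level the design requires.
    """
    _check_levels(design, effects)
    rng = np.random.default_rng(seed)

    intercepts = np.array([effects.responses[r].intercept for r in RESPONSE_NAMES])
    year_eff = np.array([effects.responses[r].year_effect for r in RESPONSE_NAMES])
    noise_sd = np.array([effects.responses[r].noise_sd for r in RESPONSE_NAMES])
    gain = np.array([effects.responses[r].nonlinear_gain for r in RESPONSE_NAMES])
    eo_mask = np.array([r in EO_RESPONSES for r in RESPONSE_NAMES])

    rows: list[dict] = []
    for year, loc, fert in design.cells():
        ycode = design.year_code(year)
        loc_eff = np.array(
            [effects.responses[r].locality_effects[loc] for r in RESPONSE_NAMES]
        )
        fert_eff = np.array(
            [effects.responses[r].fertilization_effects[fert] for r in RESPONSE_NAMES]
        )
        cell_mean = (
            intercepts + year_eff * ycode + loc_eff + fert_eff
            + gain * ycode * fert_eff
        )
        for rep in range(1, design.replications + 1):
            values = cell_mean + rng.standard_normal(len(RESPONSE_NAMES)) * noise_sd
            values = np.where(eo_mask & (values < 0), 0.0, values)
            rows.append(
                {
                    "year": year,
                    "locality": loc,
                    "fertilization": fert,
                    "replicate": rep,
                    **dict(zip(RESPONSE_NAMES, values)),
                }
            )
    return pd.DataFrame(rows, columns=list(FACTOR_COLUMNS) + list(RESPONSE_NAMES))


def _check_levels(design: DesignSpec, effects: EffectsConfig) -> None:
    for name, eff in effects.responses.items():
        for lv in eff.locality_effects:
            if lv not in design.localities:
                raise ConfigurationError(
                    f"{name}: unknown locality level {lv!r} in effects"
                )
        for lv in eff.fertilization_effects:
            if lv not in design.fertilizations:
                raise ConfigurationError(
                    f"{name}: unknown fertilization level {lv!r} in effects"
                )
        for lv in design.localities:
            if lv not in eff.locality_effects:
                raise ConfigurationError(
                    f"{name}: effects lack locality level {lv!r}"
                )
        for lv in design.fertilizations:
            if lv not in eff.fertilization_effects:
                raise ConfigurationError(
                    f"{name}: effects lack fertilization level {lv!r}"
                )
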