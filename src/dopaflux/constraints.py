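"""Literature-derived constraint arithmetic with unit bookkeeping.

These helpers reproduce the published flux-bound derivations used to
parameterize neuronal models: wet->dry tissue conversion of the residual ATP
consumption rate, the maintenance-demand lower bound, the Parkinsonian
Complex I capacity factor, and mitochondrial protein densities.

Wet/dry conversion note: the published arithmetic (10 μmol ATP/g/min ->
106.2 μmol/gDW/h with 82.3% water) is reproduced by multiplying by the dry
mass fraction, flux = rate × 60 × (1 − water_fraction).  Dividing by the dry
fraction would be the physically expected direction for a per-gDW basis; this
module reproduces the established arithmetic and leaves the convention to the
caller's interpretation.
"""

from __future__ import annotations

#: ATPM upper bound (μmol/gDW/h), a configured constant corresponding to 10 Hz
#: tonic firing; not derivable from first principles at this granularity.
ATPM_UPPER_BOUND = 600.0


def residual_energy_conversion(rate_per_g_per_min: float, water_fraction: float) -> float:
    """Convert a residual ATP consumption rate (μmol/g wet weight/min) to μmol/gDW/h."""
    if rate_per_g_per_min <= 0:
        raise ValueError("rate must be positive")
    if not 0.0 < water_fraction < 1.0:
        raise ValueError("water fraction must lie in (0, 1)")
    return rate_per_g_per_min * 60.0 * (1.0 - water_fraction)


def atpm_lower(converted_rate: float, species_scaling: float = 10.0) -> float:
    """Maintenance-demand lower bound: the converted rate reduced by the
    rodent-to-human arborization scaling factor (default ten)."""
    if converted_rate <= 0 or species_scaling <= 0:
        raise ValueError("rates and scaling must be positive")
    return converted_rate / species_scaling


def pd_complex1_factor(min_reduction: float) -> float:
    """Capacity factor retained by Complex I in the PD condition.

    ``min_reduction`` is the smallest reported fractional activity reduction
    in post-mortem substantia nigra (0.18 for an 18–35% range), giving the
    least-constraining cap 1 − min_reduction.
    """
    if not 0.0 < min_reduction < 1.0:
        raise ValueError("reduction must lie in (0, 1)")
    return 1.0 - min_reduction


def mito_protein_density(lo: float, hi: float) -> float:
    """Midpoint of a reported mitochondrial-protein density range (mg/g wet weight)."""
    if lo <= 0 or hi <= 0:
        raise ValueError("densities must be positive")
    if lo > hi:
        raise ValueError("range must be ordered lo <= hi")
    return 0.5 * (lo + hi)


def enzyme_activity_to_flux(
    activity_per_mg_protein_per_min: float,
    protein_density_mg_per_gww: float,
    water_fraction: float,
) -> float:
    """Convert an enzyme activity (μmol/min/mg mitochondrial protein) to μmol/gDW/h.

    flux = activity × density × 60 / (1 − water_fraction); the division by the
    dry fraction converts the per-gWW product onto a dry-weight basis.
    Exposed as configuration, not hard-coded into any analysis.
    """
    if activity_per_mg_protein_per_min <= 0 or protein_density_mg_per_gww <= 0:
        raise ValueError("activity and density must be positive")
    if not 0.0 < water_fraction < 1.0:
        raise ValueError("water fraction must lie in (0, 1)")
    return (
        activity_per_mg_protein_per_min
        * protein_density_mg_per_gww
        * 60.0
        / (1.0 - water_fraction)
    )


_KINDS = {
    "residual_energy_conversion": residual_energy_conversion,
    "atpm_lower": atpm_lower,
    "pd_complex1_factor": pd_complex1_factor,
    "mito_protein_density": mito_protein_density,
}


def derive_literature_constraint(kind: str, *params: float) -> float:
    """Dispatch to one of the named constraint derivations."""
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise ValueError(
            f"unknown constraint kind {kind!r}; expected one of {sorted(_KINDS)}"
        ) from None
    return fn(*params)
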