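import pandas as pd

from thermoscale import HeatingAssay, ThermalConstants, rescaled_tolerance


def make_loglog(rates: pd.DataFrame, constants: ThermalConstants) -> pd.DataFrame:
    """(species, lam, dtr) records from a canonical multi-rate table."""
    dtr = [rescaled_tolerance(HeatingAssay(str(s), ta, tc, v), constants).value
           for s, ta, v, tc in zip(rates["species"], rates["ta"],
                                   rates["heating_rate"], rates["tc"])]
    return pd.DataFrame({"species": rates["species"],
                         "lam": rates["heating_rate"] / constants.reference_temp,
                         "dtr": dtr})


def synthetic_loglog(gamma_by_species: dict, rates=(0.05, 0.1, 0.5, 1.0),
                     prefactor: float = 1000.0) -> pd.DataFrame:
    """Exact power-law records dtr = c * (lam/lam_ref)^{-gamma}."""
    lam_ref = 0.1 / 273.15
    rows = []
    for species, gamma in gamma_by_species.items():
        for v in rates:
            lam = v / 273.15
            rows.append({"species": species, "lam": lam,
                         "dtr": prefactor * (lam / lam_ref) ** (-gamma)})
    return pd.DataFrame(rows)
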