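"""Material properties of the ablation model regions.

Defaults: platinum electrode, plastic catheter shaft, blood, myocardium.
Myocardial electrical conductivity is field-dependent and supplied by the
conductivity module, so its ``sigma`` here is None.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .geometry import Region

__all__ = ["MaterialProperties", "MaterialTable", "default_materials",
           "BLOOD_VISCOSITY"]

BLOOD_VISCOSITY = 2.1e-3  # kg/m/s


@dataclass(frozen=True)
class MaterialProperties:
    rho: float            # kg/m^3
    c: float              # J/kg/K
    k: float              # W/m/K
    sigma: float | None   # S/m; None for the field-dependent myocardium

    def __post_init__(self):
        if self.rho <= 0 or self.c <= 0 or self.k <= 0:
            raise DomainError("material properties must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise DomainError("sigma must be positive")

    @property
    def rho_c(self) -> float:
        return self.rho * self.c


MaterialTable = dict[Region, MaterialProperties]


def default_materials() -> MaterialTable:
    """Default electrical/thermal property table."""
    electrode = MaterialProperties(rho=21_500, c=132, k=71, sigma=4.6e6)
    return {
        Region.ELECTRODE_LEFT: electrode,
        Region.ELECTRODE_RIGHT: electrode,
        Region.INSULATOR: MaterialProperties(rho=70, c=1045, k=0.026,
                                             sigma=1e-5),
        Region.BLOOD: MaterialProperties(rho=1000, c=4180, k=0.54, sigma=0.99),
        Region.MYOCARDIUM: MaterialProperties(rho=1200, c=3200, k=0.53,
                                              sigma=None),
    }


_NAMES = {"electrode": (Region.ELECTRODE_LEFT, Region.ELECTRODE_RIGHT),
          "plastic_catheter": (Region.INSULATOR,),
          "insulator": (Region.INSULATOR,),
          "blood": (Region.BLOOD,),
          "myocardium": (Region.MYOCARDIUM,)}


def load_materials(rows: dict) -> MaterialTable:
    """Override defaults from a config mapping.

    ``rows`` maps material names (electrode, plastic_catheter, blood,
    myocardium) to dicts with keys rho, c, k and optionally sigma.
    """
    table = default_materials()
    for name, props in rows.items():
        key = name.strip().lower().replace(" ", "_")
        if key not in _NAMES:
            raise DomainError(f"unknown material {name!r}")
        for region in _NAMES[key]:
            base = table[region]
            table[region] = MaterialProperties(
                rho=float(props.get("rho", base.rho)),
                c=float(props.get("c", base.c)),
                k=float(props.get("k", base.k)),
                sigma=(float(props["sigma"]) if "sigma" in props
                       else base.sigma))
    return table
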