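"""Myocardial electrical conductivity: anisotropy split, fiber tensor, and the
electroporation field dependence.

The anisotropic conductivity (AC) tensor along a unit fiber direction A is

    sigma_a = sigma_t I + (sigma_l - sigma_t) A A^T

with longitudinal/transverse principal values linked to the isotropic baseline
sigma_i and anisotropy ratio R by

    sigma_l / sigma_t = R,   (sigma_l + sigma_t) / 2 = sigma_i.

Electroporation raises conductivity with local field magnitude |E| through a
sigmoid centered at 58 kV/m:

    sigma(E) = sigma_lo + (sigma_post - sigma_lo) / (1 + 10 exp(-(|E| - 58000)/3000))

applied independently to sigma_l and sigma_t in AC mode, so both principal
values converge to the single post-electroporation value sigma_post at high
field; isotropic conductivity (IC) applies the same sigmoid to the scalar
sigma_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, MissingFiberError, NormalizationError

__all__ = [
    "SIGMA_PRE", "SIGMA_POST", "E_CENTER", "E_SLOPE", "SHIFT_FACTOR",
    "ANISOTROPY_GROUPS", "ConductivityModel", "split_conductivity",
    "electroporation_sigmoid", "conductivity_tensor", "effective_conductivity",
]

SIGMA_PRE = 0.0537    # S/m, pre-electroporation myocardium (10 Hz)
SIGMA_POST = 0.281    # S/m, post-electroporation myocardium (500 kHz)
E_CENTER = 58_000.0   # V/m, sigmoid center
E_SLOPE = 3_000.0     # V/m, sigmoid slope
SHIFT_FACTOR = 10.0   # dimensionless shift in the logistic denominator

#: Anisotropy ratios of the four myocardial conductivity groups
#: (1-2: normal myocardium, 3-4: fibrillating myocardium).
ANISOTROPY_GROUPS: dict[int, float] = {1: 1.429, 2: 3.75, 3: 4.98, 4: 6.25}


def split_conductivity(sigma_i: float, ratio_R: float) -> tuple[float, float]:
    """Solve the anisotropy split for (sigma_l, sigma_t).

    sigma_l = 2 R sigma_i / (R + 1), sigma_t = 2 sigma_i / (R + 1); their mean
    is sigma_i and their ratio R.
    """
    if sigma_i <= 0:
        raise DomainError("sigma_i must be positive")
    if ratio_R < 1:
        raise DomainError("ratio_R must be >= 1 (longitudinal dominates)")
    sigma_l = 2.0 * ratio_R * sigma_i / (ratio_R + 1.0)
    sigma_t = 2.0 * sigma_i / (ratio_R + 1.0)
    return sigma_l, sigma_t


@dataclass(frozen=True)
class ConductivityModel:
    """Myocardial conductivity parameters, AC or IC mode.

    ``field_dependent=False`` freezes the baselines (no electroporation),
    used for solver linearity checks.
    """

    mode: str = "AC"                      # "AC" | "IC"
    sigma_i: float = SIGMA_PRE
    ratio_R: float = 1.0
    sigma_post: float = SIGMA_POST
    e_center: float = E_CENTER
    e_slope: float = E_SLOPE
    shift_factor: float = SHIFT_FACTOR
    field_dependent: bool = True

    def __post_init__(self):
        if self.mode not in ("AC", "IC"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.sigma_i <= 0 or self.sigma_post <= 0:
            raise DomainError("conductivities must be positive")
        if self.ratio_R < 1:
            raise DomainError("ratio_R must be >= 1")

    @classmethod
    def from_group(cls, group: int, mode: str = "AC",
                   sigma_i: float = SIGMA_PRE, **kw) -> "ConductivityModel":
        if group not in ANISOTROPY_GROUPS:
            raise DomainError(f"unknown conductivity group {group}")
        R = ANISOTROPY_GROUPS[group] if mode == "AC" else 1.0
        return cls(mode=mode, sigma_i=sigma_i, ratio_R=R, **kw)

    @property
    def sigma_l0(self) -> float:
        return split_conductivity(self.sigma_i, self.ratio_R)[0]

    @property
    def sigma_t0(self) -> float:
        return split_conductivity(self.sigma_i, self.ratio_R)[1]


def electroporation_sigmoid(e_mag, sigma_lo: float,
                            model: ConductivityModel | None = None):
    """Field-dependent conductivity rising from ``sigma_lo`` to sigma_post.

    Strictly increasing in |E|; at zero field the shift term (~2.5e9)
    suppresses the increment to ~1e-10 S/m, at high field the value saturates
    at sigma_post.  Accepts scalars or arrays of |E| (V/m).
    """
    model = model or ConductivityModel()
    e = np.asarray(e_mag, dtype=float)
    if np.any(e < 0):
        raise DomainError("|E| must be non-negative")
    if sigma_lo >= model.sigma_post:
        raise DomainError("sigma_lo must be below the post-electroporation "
                          "conductivity")
    denom = 1.0 + model.shift_factor * np.exp(
        -(e - model.e_center) / model.e_slope)
    out = sigma_lo + (model.sigma_post - sigma_lo) / denom
    return out if out.ndim else float(out)


def conductivity_tensor(fiber: np.ndarray, sigma_l, sigma_t) -> np.ndarray:
    """sigma_t I + (sigma_l - sigma_t) A A^T for unit fiber(s) A.

    ``fiber`` may be a single (3,) vector or a (K, 3) batch; ``sigma_l`` /
    ``sigma_t`` scalars or length-K arrays.  Returns (3, 3) or (K, 3, 3).
    """
    a = np.asarray(fiber, dtype=float)
    single = a.ndim == 1
    a = np.atleast_2d(a)
    norms = np.linalg.norm(a, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise NormalizationError("fiber directions must be unit vectors")
    sl = np.broadcast_to(np.asarray(sigma_l, float), a.shape[:1])
    st = np.broadcast_to(np.asarray(sigma_t, float), a.shape[:1])
    eye = np.eye(3)
    t = (st[:, None, None] * eye
         + (sl - st)[:, None, None] * a[:, :, None] * a[:, None, :])
    return t[0] if single else t


def effective_conductivity(fiber, e_mag, model: ConductivityModel):
    """Conductivity at field magnitude |E|: tensor (AC) or scalar (IC).

    AC mode applies the electroporation sigmoid independently to the
    longitudinal and transverse baselines — both converge to sigma_post at
    high field — and assembles the tensor along ``fiber``.  IC mode returns
    the scalar sigmoid from sigma_i.  Vectorized over (K,) ``e_mag`` with
    (K, 3) ``fiber``.
    """
    if model.mode == "IC":
        if not model.field_dependent:
            e_mag = np.zeros_like(np.asarray(e_mag, float))
        return electroporation_sigmoid(e_mag, model.sigma_i, model)
    if fiber is None:
        raise MissingFiberError("AC mode requires a fiber direction")
    if not model.field_dependent:
        e_mag = np.zeros_like(np.asarray(e_mag, float))
    sl = electroporation_sigmoid(e_mag, model.sigma_l0, model)
    st = electroporation_sigmoid(e_mag, model.sigma_t0, model)
    return conductivity_tensor(fiber, sl, st)
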