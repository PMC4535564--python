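"""Combined Ogden hyperelastic + exponential-kernel viscoelastic material law.

The model is evaluated for incompressible uniaxial deformation: the loading
axis carries a stretch ``lambda`` and the two transverse directions carry
``lambda**-0.5`` so the volume ratio is identically 1.  The total uniaxial
Cauchy stress is the sum of

* an Ogden hyperelastic part, ``sum_j mu_j * (lam**a_j - lam**(-a_j/2))``, and
* a hereditary (convolution) viscoelastic part with relaxation kernel
  ``G * exp(-beta * (t - tau))`` acting on the strain rate history.

Units: stresses and moduli in MPa, time in seconds, ``beta`` in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "MaterialParams",
    "DeformationHistory",
    "ogden_energy",
    "ogden_uniaxial_stress",
    "visco_stress",
    "total_uniaxial_stress",
    "CORNEA_PARAMS",
    "SCLERA_PARAMS",
]


def _as_terms(value: float | tuple | list) -> tuple[float, ...]:
    if np.isscalar(value):
        return (float(value),)
    return tuple(float(v) for v in value)


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants for one tissue.

    Parameters
    ----------
    alpha
        Dimensionless Ogden exponent(s).  A scalar gives the default
        single-term model; a sequence gives a multi-term series.
    mu
        Hyperelastic modulus (modiuli) in MPa, one per Ogden term.
    beta
        Viscoelastic decay rate in 1/s.
    g_visc
        Viscoelastic modulus in MPa; 0 switches the viscous part off.
    tissue
        Optional label carried through reports.
    """

    alpha: float | tuple[float, ...]
    mu: float | tuple[float, ...]
    beta: float
    g_visc: float
    tissue: str = ""

    def __post_init__(self) -> None:
        alphas = _as_terms(self.alpha)
        mus = _as_terms(self.mu)
        object.__setattr__(self, "alpha", alphas if len(alphas) > 1 else alphas[0])
        object.__setattr__(self, "mu", mus if len(mus) > 1 else mus[0])
        if len(alphas) != len(mus):
            raise ValueError("alpha and mu must have the same number of terms")
        if any(a == 0.0 for a in alphas):
            raise ValueError("alpha must be nonzero")
        if any(m <= 0.0 for m in mus):
            raise ValueError("mu must be positive")
        if not self.beta > 0.0:
            raise ValueError("beta must be positive")
        if self.g_visc < 0.0:
            raise ValueError("g_visc must be non-negative")

    @property
    def alphas(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.alpha, dtype=float))

    @property
    def mus(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.mu, dtype=float))

    @property
    def n_terms(self) -> int:
        return self.alphas.size


#: Optimized tissue constants (alpha, mu [MPa], beta [1/s], G [MPa]).
CORNEA_PARAMS = MaterialParams(alpha=8.1, mu=0.675, beta=0.13, g_visc=1.641, tissue="cornea")
SCLERA_PARAMS = MaterialParams(alpha=27.7, mu=0.774, beta=0.93, g_visc=1.8, tissue="sclera")

_STRAIN_CONVENTIONS = ("engineering", "logarithmic")


@dataclass
class DeformationHistory:
    """Uniaxial stretch history along the loading axis.

    ``time`` starts at 0 and is strictly increasing; ``stretch`` starts at 1.
    Transverse stretches are implied incompressible (``stretch**-0.5``).
    The scalar strain driving the viscoelastic convolution is derived from
    the stretch via ``strain_convention`` — engineering (``lam - 1``,
    default) or logarithmic (``log(lam)``).
    """

    time: np.ndarray
    stretch: np.ndarray
    strain_convention: str = "engineering"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stretch = np.asarray(self.stretch, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.stretch.shape:
            raise ValueError("time and stretch must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("history needs at least 2 samples")
        if self.time[0] != 0.0:
            raise ValueError("time must start at 0")
        if not np.all(np.diff(self.time) > 0.0):
            raise ValueError("time must be strictly increasing")
        if not np.all(self.stretch > 0.0):
            raise ValueError("stretch must be positive")
        if not np.isclose(self.stretch[0], 1.0):
            raise ValueError("stretch must start at 1 (undeformed reference)")
        if self.strain_convention not in _STRAIN_CONVENTIONS:
            raise ValueError(f"strain_convention must be one of {_STRAIN_CONVENTIONS}")

    @property
    def strain(self) -> np.ndarray:
        if self.strain_convention == "engineering":
            return self.stretch - 1.0
        return np.log(self.stretch)


def _check_stretch(stretch) -> np.ndarray:
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0.0):
        raise ValueError("stretch must be positive")
    return lam


def ogden_energy(params: MaterialParams, stretch) -> np.ndarray | float:
    """Strain-energy density W(lambda) in MPa for incompressible uniaxial stretch.

    ``W = sum_j (mu_j / alpha_j) * (lam**a_j + 2 lam**(-a_j/2) - 3)``;
    zero at the reference state ``lam == 1`` and positive elsewhere.
    """
    lam = _check_stretch(stretch)
    lam_b = lam[..., np.newaxis] if np.ndim(lam) else lam
    a = params.alphas
    m = params.mus
    w = (m / a) * (lam_b ** a + 2.0 * lam_b ** (-a / 2.0) - 3.0)
    out = np.sum(w, axis=-1)
    return float(out) if np.ndim(stretch) == 0 else out


def ogden_uniaxial_stress(params: MaterialParams, stretch) -> np.ndarray | float:
    """Uniaxial Cauchy stress (MPa) of the hyperelastic part.

    ``sigma = sum_j mu_j * (lam**a_j - lam**(-a_j/2))``: positive in tension
    (``lam > 1``), zero at ``lam == 1``.
    """
    lam = _check_stretch(stretch)
    lam_b = lam[..., np.newaxis] if np.ndim(lam) else lam
    a = params.alphas
    s = params.mus * (lam_b ** a - lam_b ** (-a / 2.0))
    out = np.sum(s, axis=-1)
    return float(out) if np.ndim(stretch) == 0 else out


def visco_stress(params: MaterialParams, history: DeformationHistory) -> np.ndarray:
    """Viscoelastic stress series (MPa) from the hereditary integral.

    Evaluates ``sigma_v(t_k) = int_0^{t_k} G exp(-beta (t_k - tau)) deps/dtau dtau``
    with the unconditionally stable exact-exponential recursion

    ``sigma_v(t_{k+1}) = exp(-beta dt) sigma_v(t_k) + G deps exp(-beta dt / 2)``

    (midpoint placement of the strain increment).  ``sigma_v(0) == 0``.
    """
    beta = params.beta
    g = params.g_visc
    deps = np.diff(history.strain)
    dts = np.diff(history.time)
    if g == 0.0:
        return np.zeros(history.time.size)
    drive = g * deps * np.exp(-beta * dts / 2.0)
    decay = np.exp(-beta * dts)
    if np.allclose(dts, dts[0], rtol=1e-10, atol=0.0):
        # uniform grid: the recursion is a first-order IIR filter
        sig = lfilter([1.0], [1.0, -decay[0]], drive)
    else:
        sig = np.empty_like(drive)
        acc = 0.0
        for k in range(drive.size):
            acc = decay[k] * acc + drive[k]
            sig[k] = acc
    return np.concatenate(([0.0], sig))


def total_uniaxial_stress(params: MaterialParams, history: DeformationHistory) -> np.ndarray:
    """Total uniaxial Cauchy stress series (MPa): hyperelastic + viscoelastic."""
    return ogden_uniaxial_stress(params, history.stretch) + visco_stress(params, history)
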