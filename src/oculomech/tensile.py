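"""Forward simulation of uniaxial strip tension tests.

A strip of tissue clamped grip-to-grip at reference length ``length0`` is
stretched at a constant crosshead rate.  The strip is treated as a
homogeneous incompressible uniaxial continuum, so the closed-form material
law applies exactly: ``lam(t) = 1 + rate * t / length0``, Cauchy stress from
the constitutive model, and force through the current cross-section
``A(t) = width * thickness / lam`` (incompressibility).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

from .constitutive import DeformationHistory, MaterialParams, total_uniaxial_stress

__all__ = [
    "StripGeometry",
    "LoadingProtocol",
    "ForceDisplacementCurve",
    "SCLERA_STRIP",
    "CORNEA_STRIP",
    "default_protocol",
    "simulate_tension",
    "curve_rmse",
    "write_curve_csv",
    "read_curve_csv",
]


@dataclass(frozen=True)
class StripGeometry:
    """Tensile strip dimensions in mm (grip-to-grip reference length)."""

    width: float
    length0: float
    thickness: float

    def __post_init__(self) -> None:
        if min(self.width, self.length0, self.thickness) <= 0.0:
            raise ValueError("all strip dimensions must be positive")

    @property
    def area0(self) -> float:
        """Reference cross-sectional area, mm^2."""
        return self.width * self.thickness


# Strip thickness is not a measured input; sclera uses the mid-range of the
# reported 1.55-1.86 mm peripapillary thickness, cornea a nominal 0.8 mm.
SCLERA_STRIP = StripGeometry(width=3.8, length0=14.5, thickness=1.7)
CORNEA_STRIP = StripGeometry(width=9.5, length0=10.0, thickness=0.8)


@dataclass(frozen=True)
class LoadingProtocol:
    """Constant-rate monotone ramp: crosshead speed, travel and sampling step."""

    rate: float  # mm/s
    max_displacement: float  # mm
    dt: float  # s

    def __post_init__(self) -> None:
        if self.rate <= 0.0 or self.max_displacement <= 0.0 or self.dt <= 0.0:
            raise ValueError("rate, max_displacement and dt must be positive")

    @property
    def duration(self) -> float:
        return self.max_displacement / self.rate


def default_protocol(rate: float, geom: StripGeometry, peak_stretch: float = 1.15,
                     n_samples: int = 200) -> LoadingProtocol:
    """Protocol reaching ``peak_stretch`` at the given rate with ``n_samples`` points."""
    if peak_stretch <= 1.0:
        raise ValueError("peak_stretch must exceed 1")
    max_disp = (peak_stretch - 1.0) * geom.length0
    duration = max_disp / rate
    return LoadingProtocol(rate=rate, max_displacement=max_disp, dt=duration / (n_samples - 1))


@dataclass
class ForceDisplacementCurve:
    """One tensile experiment: sampled time/displacement/force plus metadata."""

    time: np.ndarray  # s
    displacement: np.ndarray  # mm
    force: np.ndarray  # N
    geometry: StripGeometry
    rate: float  # mm/s
    tissue: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (self.time.shape == self.displacement.shape == self.force.shape):
            raise ValueError("time, displacement and force must share a shape")

    @property
    def stretch(self) -> np.ndarray:
        return 1.0 + self.displacement / self.geometry.length0

    def with_force(self, force: np.ndarray) -> "ForceDisplacementCurve":
        return replace(self, force=np.asarray(force, dtype=float))


def simulate_tension(params: MaterialParams, geom: StripGeometry,
                     protocol: LoadingProtocol,
                     strain_convention: str = "engineering") -> ForceDisplacementCurve:
    """Simulate a constant-rate tension test and return the force-displacement curve."""
    duration = protocol.duration
    if protocol.dt > duration:
        raise ValueError("dt exceeds the total test duration")
    n = int(round(duration / protocol.dt)) + 1
    t = np.linspace(0.0, duration, n)
    disp = protocol.rate * t
    lam = 1.0 + disp / geom.length0
    history = DeformationHistory(time=t, stretch=lam, strain_convention=strain_convention)
    sigma = total_uniaxial_stress(params, history)  # Cauchy, MPa
    force = sigma * geom.area0 / lam  # current area = A0 / lam
    return ForceDisplacementCurve(time=t, displacement=disp, force=force,
                                  geometry=geom, rate=protocol.rate,
                                  tissue=params.tissue)


def curve_rmse(simulated: ForceDisplacementCurve,
               observed: ForceDisplacementCurve) -> float:
    """Root-mean-square force error (N) with the observed curve linearly
    resampled onto the simulated displacement grid.

    Only simulated samples inside the observed displacement range are
    compared; raises if the ranges do not overlap.
    """
    d_sim = simulated.displacement
    lo = observed.displacement.min()
    hi = observed.displacement.max()
    mask = (d_sim >= lo) & (d_sim <= hi)
    if not np.any(mask):
        raise ValueError("displacement ranges of the two curves do not overlap")
    f_obs = np.interp(d_sim[mask], observed.displacement, observed.force)
    resid = simulated.force[mask] - f_obs
    return float(np.sqrt(np.mean(resid ** 2)))


# ---------------------------------------------------------------------------
# CSV round trip.  Header block of '# key: value' lines carries the metadata,
# followed by time_s, displacement_mm, force_N columns.


def write_curve_csv(curve: ForceDisplacementCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tissue: {curve.tissue}\n")
        fh.write(f"# rate_mm_per_s: {float(curve.rate)!r}\n")
        fh.write(f"# width_mm: {curve.geometry.width!r}\n")
        fh.write(f"# length0_mm: {curve.geometry.length0!r}\n")
        fh.write(f"# thickness_mm: {curve.geometry.thickness!r}\n")
        fh.write("time_s,displacement_mm,force_N\n")
        for t, d, f in zip(curve.time, curve.displacement, curve.force):
            fh.write(f"{float(t)!r},{float(d)!r},{float(f)!r}\n")


def read_curve_csv(path) -> ForceDisplacementCurve:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    data = np.genfromtxt(body, delimiter=",", names=True)
    geom = StripGeometry(width=float(meta["width_mm"]),
                         length0=float(meta["length0_mm"]),
                         thickness=float(meta["thickness_mm"]))
    return ForceDisplacementCurve(
        time=np.atleast_1d(data["time_s"]),
        displacement=np.atleast_1d(data["displacement_mm"]),
        force=np.atleast_1d(data["force_N"]),
        geometry=geom,
        rate=float(meta["rate_mm_per_s"]),
        tissue=meta.get("tissue", ""),
    )
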