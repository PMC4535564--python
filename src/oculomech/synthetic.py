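"""Generators for study-like inputs: noisy multi-rate tensile curves and
lamina cribrosa morphometry tables.

Everything here is a pure function of its parameters and a seed, so the
whole downstream pipeline is testable without any external data.  The one
piece of real data is the packaged 20-eye LC morphometry table, shipped as
a CSV fixture and loaded by :func:`load_lc_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constitutive import CORNEA_PARAMS, SCLERA_PARAMS, MaterialParams
from .tensile import (CORNEA_STRIP, SCLERA_STRIP, ForceDisplacementCurve,
                      StripGeometry, default_protocol, simulate_tension)

__all__ = [
    "NoiseModel",
    "LCMorphometry",
    "DEFAULT_RATES",
    "DEFAULT_GEOMETRIES",
    "DEFAULT_PARAMS",
    "gen_tensile_dataset",
    "gen_lc_table",
    "load_lc_table",
    "lc_table_to_frame",
]

#: Crosshead rates (mm/s) per tissue used in the tensile campaign.
DEFAULT_RATES: dict[str, tuple[float, ...]] = {
    "sclera": (0.3, 3.0, 30.0, 300.0),
    "cornea": (0.3, 30.0),
}

DEFAULT_GEOMETRIES: dict[str, StripGeometry] = {
    "sclera": SCLERA_STRIP,
    "cornea": CORNEA_STRIP,
}

DEFAULT_PARAMS: dict[str, MaterialParams] = {
    "sclera": SCLERA_PARAMS,
    "cornea": CORNEA_PARAMS,
}

#: Peak stretch per tissue for the default campaign.  The displacement
#: amplitude was not reported; these values reproduce the order of the
#: reported peak forces (sclera ~16 N at the lowest rate, tens of N for
#: cornea) and keep the viscoelastic contribution resolvable against the
#: steep scleral hyperelastic response.
DEFAULT_PEAK_STRETCH: dict[str, float] = {"sclera": 1.05, "cornea": 1.25}


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian force noise with a fixed seed."""

    force_sd: float = 0.0  # N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_sd < 0.0:
            raise ValueError("force_sd must be non-negative")


@dataclass(frozen=True)
class LCMorphometry:
    """One eye's lamina cribrosa axes (mm) and animal age (years)."""

    eye_id: int
    age: int
    naso_temporal: float
    longitudinal: float

    def __post_init__(self) -> None:
        if self.naso_temporal <= 0.0 or self.longitudinal <= 0.0:
            raise ValueError("LC axes must be positive")


def gen_tensile_dataset(params_by_tissue: dict[str, MaterialParams] | None = None,
                        geometries: dict[str, StripGeometry] | None = None,
                        rates: dict[str, tuple[float, ...]] | None = None,
                        noise: NoiseModel = NoiseModel(),
                        peak_stretch: float | dict[str, float] | None = None,
                        n_samples: int = 200) -> list[ForceDisplacementCurve]:
    """Simulate the multi-rate tensile campaign and add measurement noise.

    Returns one curve per (tissue, rate), ordered by tissue name then rate.
    With ``noise.force_sd == 0`` the output is exactly the forward model.
    ``peak_stretch`` may be a scalar or a per-tissue mapping; the default is
    :data:`DEFAULT_PEAK_STRETCH`.
    """
    params_by_tissue = dict(DEFAULT_PARAMS if params_by_tissue is None else params_by_tissue)
    geometries = dict(DEFAULT_GEOMETRIES if geometries is None else geometries)
    rates = dict(DEFAULT_RATES if rates is None else rates)
    if peak_stretch is None:
        peak_stretch = dict(DEFAULT_PEAK_STRETCH)
    rng = np.random.default_rng(noise.seed)
    curves: list[ForceDisplacementCurve] = []
    for tissue in sorted(params_by_tissue):
        params = params_by_tissue[tissue]
        geom = geometries[tissue]
        peak = (peak_stretch.get(tissue, 1.15)
                if isinstance(peak_stretch, dict) else float(peak_stretch))
        for rate in rates[tissue]:
            protocol = default_protocol(rate, geom, peak_stretch=peak,
                                        n_samples=n_samples)
            curve = simulate_tension(params, geom, protocol)
            if noise.force_sd > 0.0:
                curve = curve.with_force(
                    curve.force + rng.normal(0.0, noise.force_sd, curve.force.size))
            curve.tissue = tissue
            curves.append(curve)
    return curves


def gen_lc_table(n_per_age: dict[int, int] | None = None,
                 mean_axes: tuple[float, float] = (4.60, 3.68),
                 sd_axes: tuple[float, float] = (0.081, 0.109),
                 seed: int = 0) -> list[LCMorphometry]:
    """Draw a synthetic LC morphometry table.

    Axes are Gaussian draws truncated at zero and rounded to 0.01 mm like a
    caliper reading.  Default group sizes follow the study design
    (8 two-year-old, 8 three-year-old, 4 four-year-old eyes).
    """
    if n_per_age is None:
        n_per_age = {2: 8, 3: 8, 4: 4}
    if any(n < 0 for n in n_per_age.values()):
        raise ValueError("group sizes must be non-negative")
    if any(sd < 0 for sd in sd_axes):
        raise ValueError("sd_axes must be non-negative")
    rng = np.random.default_rng(seed)
    rows: list[LCMorphometry] = []
    eye_id = 1
    for age in sorted(n_per_age):
        for _ in range(n_per_age[age]):
            axes = []
            for mean, sd in zip(mean_axes, sd_axes):
                value = rng.normal(mean, sd)
                while value <= 0.0:  # truncate at zero; sds are tiny so rare
                    value = rng.normal(mean, sd)
                axes.append(round(value, 2))
            rows.append(LCMorphometry(eye_id=eye_id, age=age,
                                      naso_temporal=axes[0], longitudinal=axes[1]))
            eye_id += 1
    return rows


def load_lc_table() -> list[LCMorphometry]:
    """Load the packaged 20-eye LC morphometry table (the in-study data)."""
    ref = resources.files("oculomech.data").joinpath("lc_morphometry.csv")
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path)
    expected = {"eye_id", "age_years", "naso_temporal_mm", "longitudinal_mm"}
    if set(frame.columns) != expected or len(frame) != 20:
        raise ValueError("packaged LC morphometry fixture is corrupt")
    return [
        LCMorphometry(eye_id=int(r.eye_id), age=int(r.age_years),
                      naso_temporal=float(r.naso_temporal_mm),
                      longitudinal=float(r.longitudinal_mm))
        for r in frame.itertuples()
    ]


def lc_table_to_frame(table: list[LCMorphometry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "eye_id": [r.eye_id for r in table],
            "age_years": [r.age for r in table],
            "naso_temporal_mm": [r.naso_temporal for r in table],
            "longitudinal_mm": [r.longitudinal for r in table],
        }
    )
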