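"""Observed-like concentration-time profiles with known ground truth.

Stands in for digitized literature profiles: sparse sampling (8-14 points
over 24-120 h) from 1- or 2-compartment first-order oral kinetics with
multiplicative log-normal noise (CV 10-20%), plus the reported
predicted/observed validation tables shipped as bit-stable fixtures.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pk_analysis import ObservedProfile, oral_compartment_curve

__all__ = ["SyntheticSpec", "generate_profile", "builtin_fixtures",
           "DEFAULT_SAMPLING"]

#: typical digitized-study sampling schedule (h); truncate to the study span
DEFAULT_SAMPLING = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0,
                    24.0, 48.0, 72.0)

_FIXTURE_FILE = "validation_fixtures.csv"


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for one synthetic study arm."""

    n_compartments: int  # 1 | 2
    ka: float  # 1/h
    cl_f: float  # L/h
    vc_f: float  # L
    dose: float  # mg
    peripheral: tuple[tuple[float, float], ...] = ()  # (Q L/h, V L)
    times: tuple[float, ...] = DEFAULT_SAMPLING
    noise_cv: float = 0.15
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if len(self.peripheral) != self.n_compartments - 1:
            raise ValueError("peripheral constants inconsistent with model order")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if list(self.times) != sorted(self.times):
            raise ValueError("sampling times must be ascending")


def generate_profile(spec: SyntheticSpec) -> ObservedProfile:
    """Evaluate the true model and apply mean-preserving log-normal noise.

    sigma² = ln(1 + CV²) with mean correction, so the expected value at
    each time point equals the true curve and the coefficient of variation
    equals ``noise_cv``.  Deterministic under a fixed seed.
    """
    t = np.asarray(spec.times)
    curve = oral_compartment_curve(t, spec.dose, spec.ka, spec.cl_f, spec.vc_f,
                                   spec.peripheral)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv ** 2))
        noise = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=len(t))
        curve = curve * noise
    return ObservedProfile(times=tuple(t), concentrations=tuple(curve),
                           dose=spec.dose, label=spec.label)


def _fixture_text() -> str:
    return (importlib.resources.files("pregpbpk.data") / _FIXTURE_FILE).read_text()


def fixture_checksum() -> str:
    """SHA-256 of the shipped fixture file (bit-stability guard)."""
    return hashlib.sha256(_fixture_text().encode()).hexdigest()


def builtin_fixtures() -> dict[str, pd.DataFrame]:
    """The reported Pred/Obs/(%PE) validation rows as one table per study set:
    ltg_adult (5 dose rows), ltg_pregnancy (1), efv_adult (2),
    efv_pregnancy (2)."""
    df = pd.read_csv(io.StringIO(_fixture_text()), comment="#")
    return {name: group.drop(columns="fixture").reset_index(drop=True)
            for name, group in df.groupby("fixture")}
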