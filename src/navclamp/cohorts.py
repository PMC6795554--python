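"""Synthetic cohorts of virtual HEK cells and oocytes.

Between-cell structure emulated: per-cell expression scale (lognormal with
median 1), membrane capacitance spread (truncated normal), per-oocyte mobile
gating charge Qmax (truncated normal), plus the shared linear leak and
recording-noise settings.  Cohorts are pure functions of (spec, seed).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .channel import Genotype
from .clamp import CellModel, OocyteModel

__all__ = ["CohortSpec", "generate_hek_cohort", "generate_oocyte_cohort",
           "default_hek_spec", "default_oocyte_spec", "HEK_N", "OOCYTE_N"]

# group sizes as reported for the HEK recordings
HEK_N = {Genotype.WT: 40, Genotype.R1882Q: 25, Genotype.R853Q: 16}
# oocyte group sizes: Qmax cohorts (Results text) and the n=11 correlation set
OOCYTE_N = {Genotype.WT: 5, Genotype.R853Q: 6}
CORRELATION_N = 11

QMAX_MEAN = {Genotype.WT: 0.85, Genotype.R853Q: 0.44}
# tight spread for the Qmax-recovery cohorts: a homogeneous injection batch
QMAX_SD = {Genotype.WT: 0.035, Genotype.R853Q: 0.018}
# wide spread for the correlation cohort, matching the Qmax range across
# oocytes in the gating-pore correlation analysis; its recording noise is
# tuned low so the correlation reflects the expression spread, not the
# leak-line extrapolation error
CORRELATION_QMAX_SD = 0.2
CORRELATION_NOISE_SD = 3.0


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    genotype: Genotype
    n: int
    seed: int = 0
    expr_lognorm_sigma: float = 0.5
    Cm_mean: float = 16.0
    Cm_sd: float = 2.0
    Qmax_mean: float = 0.85
    Qmax_sd: float = 0.035
    noise_sd: float = 2.5
    g_leak: float = 1.0
    E_leak: float = 0.0
    endogenous_peak: float = -207.1
    g_leak_lin: float = 0.5
    E_leak_oocyte: float = -20.0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name in ("expr_lognorm_sigma", "Cm_sd", "Qmax_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        return self


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lower: float, size: int) -> np.ndarray:
    """Normal draws redrawn until above ``lower`` (exact truncation)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def generate_hek_cohort(spec: CohortSpec) -> list[CellModel]:
    """Deterministic cohort of HEK cell models for one genotype."""
    rng = np.random.default_rng(spec.seed)
    expr = np.exp(rng.normal(0.0, spec.expr_lognorm_sigma, spec.n)) \
        if spec.expr_lognorm_sigma > 0 else np.ones(spec.n)
    cm = _trunc_normal(rng, spec.Cm_mean, spec.Cm_sd, 5.0, spec.n)
    return [
        CellModel(Cm=float(cm[i]), expr=float(expr[i]), noise_sd=spec.noise_sd,
                  g_leak=spec.g_leak, E_leak=spec.E_leak,
                  endogenous_peak=spec.endogenous_peak)
        for i in range(spec.n)
    ]


def generate_oocyte_cohort(spec: CohortSpec) -> list[OocyteModel]:
    """Deterministic cohort of oocyte models; Qmax truncated normal > 0."""
    rng = np.random.default_rng(spec.seed)
    qmax = _trunc_normal(rng, spec.Qmax_mean, spec.Qmax_sd, 0.02, spec.n)
    return [
        OocyteModel(Qmax_cell=float(qmax[i]), g_leak_lin=spec.g_leak_lin,
                    E_leak=spec.E_leak_oocyte, noise_sd=spec.noise_sd, ttx=True)
        for i in range(spec.n)
    ]


def default_hek_spec(genotype: Genotype | str, seed: int = 0,
                     n: Optional[int] = None) -> CohortSpec:
    g = Genotype(genotype)
    return CohortSpec(genotype=g, n=n if n is not None else HEK_N[g], seed=seed)


def default_oocyte_spec(genotype: Genotype | str, seed: int = 0,
                        n: Optional[int] = None, correlation: bool = False) -> CohortSpec:
    """Oocyte cohort defaults.

    ``correlation=True`` selects the wide-spread n=11 configuration used for
    the gating-pore vs Qmax correlation; otherwise the tight Qmax-recovery
    cohorts (n from the Results text) are produced.
    """
    g = Genotype(genotype)
    if g not in QMAX_MEAN:
        raise ValueError(f"no oocyte data configuration for genotype {g.value}")
    if correlation:
        return CohortSpec(genotype=g, n=n if n is not None else CORRELATION_N,
                          seed=seed, Qmax_mean=QMAX_MEAN[g],
                          Qmax_sd=CORRELATION_QMAX_SD,
                          noise_sd=CORRELATION_NOISE_SD)
    return CohortSpec(genotype=g, n=n if n is not None else OOCYTE_N[g], seed=seed,
                      Qmax_mean=QMAX_MEAN[g], Qmax_sd=QMAX_SD[g], noise_sd=10.0)
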