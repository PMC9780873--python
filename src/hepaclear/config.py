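"""Run configuration: schema-validated YAML for the orchestration layer.

One human-editable document describes a study run: group definitions
with their in vitro parameters and observed clearances, the
physiological scaling and dispersion contexts, per-group PBPK
parameters, and an optional Monte Carlo section.  Unknown keys are
rejected and units are fixed by the schema (cell-level clearances in
µL/min per 10^6 cells, whole-body flows and clearances in L/h per kg).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ivive import DispersionContext, ExtendedClearanceParams, ScalingContext
from .mpbpk import MpbpkParams
from .uncertainty import LognormalSpec, MonteCarloRun


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScalingSection(_Strict):
    hepatocellularity: float = 108.0  # 10^6 cells per g liver
    liver_weight: float = 36.0  # g liver per kg body weight
    fu_buff: float = 1.0

    def build(self) -> ScalingContext:
        return ScalingContext(self.hepatocellularity, self.liver_weight, self.fu_buff)


class DispersionSection(_Strict):
    fu_p: float
    r_b: float
    d_n: float = 0.17
    q_h: float = 3.69  # L/h per kg

    def build(self) -> DispersionContext:
        return DispersionContext(fu_p=self.fu_p, r_b=self.r_b, d_n=self.d_n, q_h=self.q_h)


class GroupSection(_Strict):
    # in vitro estimates, µL/min per 10^6 cells
    clint_met_vitro: float
    ps_inf_hep: float
    ps_passive_hep: float = 0.0
    fu_inc_hepa: float
    kpuu_ss: float | None = None
    r_b: float
    observed_cl_ml_h_kg: float | None = None

    def extended_params(self, scaling: ScalingContext) -> ExtendedClearanceParams:
        from .ivive import scale_clint_met, scale_ps_inf

        clint = scale_clint_met(self.clint_met_vitro, self.fu_inc_hepa, scaling)
        ps_total = scale_ps_inf(self.ps_inf_hep, scaling)
        ps_diff = scale_ps_inf(self.ps_passive_hep, scaling)
        return ExtendedClearanceParams(
            clint_met=clint,
            ps_inf_act=max(ps_total - ps_diff, 0.0),
            ps_diff=ps_diff,
            kpuu_ss=self.kpuu_ss,
        )


class PbpkSection(_Strict):
    k_in: float
    k_out: float
    v_central: float
    v_ec: float = 0.01
    v_hep: float = 0.027
    q_h: float = 3.69
    r_b: float
    fu_p: float
    fu_hepa: float
    ps_inf_act: float
    ps_diff: float
    clint_met: float
    uptake_scaling: float = 1.0
    n_units: int = 5

    def build(self) -> MpbpkParams:
        return MpbpkParams(
            k_in=self.k_in, k_out=self.k_out, v_central=self.v_central,
            v_ec=self.v_ec, v_hep=self.v_hep, q_h=self.q_h, r_b=self.r_b,
            fu_b=self.fu_p / self.r_b, fu_hepa=self.fu_hepa,
            ps_inf_act=self.ps_inf_act, ps_diff=self.ps_diff,
            clint_met=self.clint_met, uptake_scaling=self.uptake_scaling,
            n_units=self.n_units,
        )


class LognormalSection(_Strict):
    name: str
    mean: float
    sd: float

    def build(self) -> LognormalSpec:
        return LognormalSpec(self.name, self.mean, self.sd)


class MonteCarloSection(_Strict):
    n_draws: int = 1000
    percentiles: list[float] = Field(
        default_factory=lambda: [5.0, 20.0, 35.0, 50.0, 65.0, 80.0, 95.0]
    )
    parameters: list[LognormalSection]

    def build(self, seed: int) -> MonteCarloRun:
        return MonteCarloRun(
            specs=tuple(p.build() for p in self.parameters),
            n_draws=self.n_draws,
            seed=seed,
            percentiles=tuple(self.percentiles),
        )


class RunConfig(_Strict):
    """Top-level study configuration."""

    seed: int = 0
    dose_mg_kg: float = 3.0
    output_dir: str = "hepaclear-output"
    scaling: ScalingSection = ScalingSection()
    dispersion_fu_p: float = 0.0078  # plasma fraction unbound shared across groups
    groups: dict[str, GroupSection] = Field(default_factory=dict)
    pbpk: dict[str, PbpkSection] = Field(default_factory=dict)
    monte_carlo: MonteCarloSection | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def config_hash(self) -> str:
        """Stable hash of the configuration, stamped onto every output."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def dispersion_context(self, group: str) -> DispersionContext:
        return DispersionContext(fu_p=self.dispersion_fu_p, r_b=self.groups[group].r_b)
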