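"""Parameter records for the synthetic twin cohort and the analysis pipeline.

All generating parameters are plain dataclasses so that a cohort's ground
truth can be serialized next to the data it produced and compared against
what the downstream estimators recover.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

LIPIDS = ("TG", "TC", "HDL_C", "LDL_C")

#: Haematological cell types of the reference-based deconvolution
CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran")


def _check_pd(cov: np.ndarray, what: str) -> None:
    # semidefinite is allowed: the noiseless limit (residual SDs -> 0) is legal
    if np.linalg.eigvalsh(cov).min() < -1e-8:
        raise ValueError(
            f"implied covariance for {what} is not positive definite:\n{cov}"
        )


@dataclass
class ClpmParams:
    """Generating parameters of one two-variable, two-wave cross-lagged panel.

    The panel variables are a lipid and a CpG methylation level on their
    residualized (unit-variance baseline) scales.  ``rho1`` is the
    lipid(baseline) -> methylation(follow-up) path, ``rho2`` the
    methylation(baseline) -> lipid(follow-up) path.
    """

    auto_lipid: float = 0.6
    auto_meth: float = 0.6
    rho1: float = 0.0
    rho2: float = 0.0
    baseline_cov: float = 0.2
    resid_sd_lipid: float = 0.8
    resid_sd_meth: float = 0.8
    resid_cov: float = 0.0

    @property
    def path_matrix(self) -> np.ndarray:
        """B such that (lipid_f, meth_f) = B @ (lipid_b, meth_b) + disturbance."""
        return np.array(
            [[self.auto_lipid, self.rho2], [self.rho1, self.auto_meth]]
        )

    @property
    def baseline_cov_matrix(self) -> np.ndarray:
        return np.array([[1.0, self.baseline_cov], [self.baseline_cov, 1.0]])

    @property
    def disturbance_cov(self) -> np.ndarray:
        return np.array(
            [
                [self.resid_sd_lipid**2, self.resid_cov],
                [self.resid_cov, self.resid_sd_meth**2],
            ]
        )

    def implied_cov(self) -> np.ndarray:
        """4x4 covariance of (lipid_b, meth_b, lipid_f, meth_f)."""
        phi = self.baseline_cov_matrix
        b = self.path_matrix
        psi = self.disturbance_cov
        top = np.hstack([phi, phi @ b.T])
        bot = np.hstack([b @ phi, b @ phi @ b.T + psi])
        return np.vstack([top, bot])

    def validate(self, label: str = "ClpmParams") -> None:
        if self.resid_sd_lipid <= 0 or self.resid_sd_meth <= 0:
            raise ValueError(f"{label}: residual SDs must be positive")
        _check_pd(self.implied_cov(), label)

    @property
    def is_null(self) -> bool:
        return self.rho1 == 0.0 and self.rho2 == 0.0


@dataclass
class MediationParams:
    """Generating parameters of the three-variable two-wave mediation model.

    X is the exposure (BMI), M the mediator (CpG methylation), Y the outcome
    (a lipid), all on residualized scales.  ``a`` is X_b -> M_f, ``b`` is
    M_b -> Y_f and ``c_prime`` the direct X_b -> Y_f path; ``beta_*`` are the
    autoregressions.  Indirect effect = a*b, total = a*b + c_prime.
    """

    beta_x: float = 0.6
    beta_m: float = 0.6
    beta_y: float = 0.6
    a: float = 0.2
    b: float = 0.15
    c_prime: float = 0.2
    resid_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    baseline_corr: float = 0.3

    @property
    def path_matrix(self) -> np.ndarray:
        """B with rows (X_f, M_f, Y_f) on columns (X_b, M_b, Y_b)."""
        return np.array(
            [
                [self.beta_x, 0.0, 0.0],
                [self.a, self.beta_m, 0.0],
                [self.c_prime, self.b, self.beta_y],
            ]
        )

    @property
    def baseline_cov_matrix(self) -> np.ndarray:
        r = self.baseline_corr
        return np.array([[1.0, r, r], [r, 1.0, r], [r, r, 1.0]])

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def total(self) -> float:
        return self.a * self.b + self.c_prime

    @property
    def proportion_mediated(self) -> float:
        return self.indirect / self.total

    def implied_cov(self) -> np.ndarray:
        """6x6 covariance of (X_b, M_b, Y_b, X_f, M_f, Y_f)."""
        phi = self.baseline_cov_matrix
        bmat = self.path_matrix
        psi = np.diag(np.square(self.resid_sds))
        top = np.hstack([phi, phi @ bmat.T])
        bot = np.hstack([bmat @ phi, bmat @ phi @ bmat.T + psi])
        return np.vstack([top, bot])

    def validate(self, label: str = "MediationParams") -> None:
        if any(s <= 0 for s in self.resid_sds):
            raise ValueError(f"{label}: residual SDs must be positive")
        vals = dataclasses.astuple(self)[:6]
        if not all(np.isfinite(vals)):
            raise ValueError(f"{label}: path coefficients must be finite")
        _check_pd(self.implied_cov(), label)


@dataclass
class SimulationConfig:
    """Full specification of a synthetic twin cohort.

    ``clpm_params`` maps signal-CpG index -> :class:`ClpmParams`;
    ``signal_lipids`` maps the same indices to the lipid each CpG is coupled
    with (default TG).  ``xs_effects`` plants cross-sectional EWAS signal:
    beta-scale slope per unit log-lipid.  At most one CpG per lipid may carry
    a nonzero ``rho2`` (it drives that lipid's follow-up equation).
    """

    n_pairs: int = 500
    prop_mz: float = 0.7
    n_cpgs: int = 1000
    n_snp_probes: int = 59
    followup_years: float = 4.67
    clpm_params: dict[int, ClpmParams] = field(default_factory=dict)
    signal_lipids: dict[int, str] = field(default_factory=dict)
    xs_effects: dict[int, float] = field(default_factory=dict)
    mediation_params: MediationParams | None = None
    mediator_cpg: int | None = None
    mediation_lipid: str = "HDL_C"
    icc_mz: float = 0.6
    icc_dz: float = 0.3
    batch_levels: int = 2
    cell_types: int = 6
    noise_sd: float = 0.01
    snp_noise_sd: float = 0.03
    followup_fraction: float = 1.0
    replication_style: bool = False  # adds fasting-status covariate draws
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.prop_mz <= 1.0:
            raise ValueError("prop_mz must lie in [0, 1]")
        if not (self.icc_mz >= self.icc_dz >= 0.0) or self.icc_mz >= 1.0:
            raise ValueError("require 1 > icc_mz >= icc_dz >= 0")
        if self.n_snp_probes < 2:
            raise ValueError("need at least 2 SNP probes")
        if self.n_pairs < 1 or self.n_cpgs < 1:
            raise ValueError("n_pairs and n_cpgs must be positive")
        if not 0.0 <= self.followup_fraction <= 1.0:
            raise ValueError("followup_fraction must lie in [0, 1]")
        drivers: dict[str, int] = {}
        for idx, pars in self.clpm_params.items():
            if not 0 <= idx < self.n_cpgs:
                raise ValueError(f"signal CpG index {idx} out of range")
            lip = self.signal_lipids.get(idx, "TG")
            if lip not in LIPIDS:
                raise ValueError(f"unknown lipid {lip!r} for CpG {idx}")
            try:
                pars.validate(label=f"CpG {idx}")
            except ValueError as err:
                raise ValueError(f"CpG {idx}: {err}") from None
            if pars.rho2 != 0.0:
                if lip in drivers:
                    raise ValueError(
                        f"lipid {lip} already driven by CpG {drivers[lip]}; "
                        f"CpG {idx} cannot also carry rho2 != 0"
                    )
                drivers[lip] = idx
        if self.mediation_params is not None:
            self.mediation_params.validate()
            if self.mediator_cpg is None:
                raise ValueError("mediation_params given without mediator_cpg")


@dataclass
class GroundTruth:
    """Generating parameters of a simulated cohort, for recovery tests."""

    clpm_params: dict[int, ClpmParams]
    signal_lipids: dict[int, str]
    xs_effects: dict[int, float]
    mediation_params: MediationParams | None
    mediator_cpg: int | None
    zygosity: list[str]
    cell_loadings: np.ndarray
    batch_offsets: np.ndarray
    null_cpgs: list[int]
    signal_cpgs: list[int]

    @property
    def all_null(self) -> bool:
        active = any(not p.is_null for p in self.clpm_params.values())
        return not active and not self.xs_effects

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj).__name__)

        payload = dataclasses.asdict(self)
        return json.dumps(payload, default=enc, indent=1)


@dataclass
class RunConfig:
    """One end-to-end pipeline run: simulate -> preprocess -> ewas -> clpm -> mediate."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    replication_seed_offset: int = 10_000
    stages: tuple[str, ...] = ("simulate", "preprocess", "ewas", "clpm", "mediate")
    alpha: float = 0.05
    ewas_lipids: tuple[str, ...] = LIPIDS
    ewas_model: int = 1
    strata: tuple[str, ...] = ("all",)
    zygosity_cutoff: float = 0.90
    sd_threshold: float = 3.0
    outdir: str = "lipidmeth_run"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(_as_plain(dataclasses.asdict(self)), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text)
        sim_raw = raw.pop("simulation", {})
        clpm = {
            int(k): ClpmParams(**v) for k, v in sim_raw.pop("clpm_params", {}).items()
        }
        med = sim_raw.pop("mediation_params", None)
        if med is not None:
            med = MediationParams(
                **{**med, "resid_sds": tuple(med.get("resid_sds", (1, 1, 1)))}
            )
        sim_raw["signal_lipids"] = {
            int(k): v for k, v in sim_raw.pop("signal_lipids", {}).items()
        }
        sim_raw["xs_effects"] = {
            int(k): float(v) for k, v in sim_raw.pop("xs_effects", {}).items()
        }
        sim = SimulationConfig(clpm_params=clpm, mediation_params=med, **sim_raw)
        for key in ("stages", "ewas_lipids", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
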