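"""Seeded synthetic twin cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: twin pairs with zygosity-dependent co-twin correlation, two visits
~4.67 years apart, log-normal lipids with covariate effects, logit-scale
methylation with cell-composition and batch contamination, trimodal
SNP-overlapping probes for zygosity calling, and configurable cross-lagged /
mediation effects between methylation and lipids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import TwinCohort
from .config import (
    CELL_TYPES,
    LIPIDS,
    ClpmParams,
    GroundTruth,
    MediationParams,
    SimulationConfig,
)

# log-scale location/scale per lipid, tuned to mmol/L population moments
_LIPID_LOGNORM = {
    "TG": (0.45, 0.50),
    "TC": (1.565, 0.21),
    "HDL_C": (0.27, 0.26),
    "LDL_C": (0.87, 0.30),
}

# covariate effects on the log-lipid scale: (age/yr, male, current smoker,
# current drinker, BMI per kg/m^2)
_LIPID_COVARIATE_EFFECTS = {
    "TG": (0.003, 0.15, 0.05, 0.05, 0.020),
    "TC": (0.003, 0.02, 0.00, 0.00, 0.010),
    "HDL_C": (0.001, -0.12, -0.05, 0.05, -0.015),
    "LDL_C": (0.003, 0.02, 0.00, 0.00, 0.010),
}

_LIPID_ICC = 0.3  # co-twin correlation of lipid residual processes

#: Dirichlet concentration for the six leukocyte proportions (Gran-dominant)
_CELL_ALPHA = np.array([9.0, 4.8, 3.0, 3.0, 4.2, 36.0])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_clpm_panel(
    params: ClpmParams, n: int, seed=0
) -> pd.DataFrame:
    """Draw ``n`` two-wave (lipid, methylation) observations from a CLPM.

    Baseline pairs are bivariate normal with unit variances and covariance
    ``params.baseline_cov``; follow-up values are the linear map given by the
    autoregressive/cross-lagged coefficients plus Gaussian disturbances.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    params.validate()
    rng = _rng(seed)
    base = rng.multivariate_normal(
        np.zeros(2), params.baseline_cov_matrix, size=n, method="cholesky"
    )
    dist = rng.multivariate_normal(
        np.zeros(2), params.disturbance_cov, size=n, method="cholesky"
    )
    follow = base @ params.path_matrix.T + dist
    return pd.DataFrame(
        {
            "lipid_b": base[:, 0],
            "meth_b": base[:, 1],
            "lipid_f": follow[:, 0],
            "meth_f": follow[:, 1],
        }
    )


def simulate_mediation_panel(
    params: MediationParams, n: int, seed=0
) -> pd.DataFrame:
    """Draw ``n`` six-tuples (X_b, M_b, Y_b, X_f, M_f, Y_f) from the two-wave
    mediation model (X exposure, M mediator, Y outcome)."""
    if n < 10:
        raise ValueError("need n >= 10")
    params.validate()
    rng = _rng(seed)
    base = rng.multivariate_normal(
        np.zeros(3), params.baseline_cov_matrix, size=n, method="cholesky"
    )
    dist = rng.standard_normal((n, 3)) * np.asarray(params.resid_sds)
    follow = base @ params.path_matrix.T + dist
    return pd.DataFrame(
        np.hstack([base, follow]),
        columns=["X_b", "M_b", "Y_b", "X_f", "M_f", "Y_f"],
    )


def simulate_snp_probes(
    zygosity, n_snp_probes: int = 59, seed=0, noise_sd: float = 0.03
) -> pd.DataFrame:
    """Beta-values of SNP-overlapping probes for both members of each pair.

    Genotypes (0/1/2 minor-allele dosages) map to beta modes {0.05, 0.5,
    0.95} plus Gaussian measurement noise.  MZ co-twins share the genotype at
    every probe; DZ co-twins inherit each parental allele independently, so
    they share each allele with probability 1/2.

    Returns a probes x individuals DataFrame with columns
    ``P{pair:04d}A`` / ``P{pair:04d}B``.
    """
    if n_snp_probes < 2:
        raise ValueError("need at least 2 SNP probes")
    zygosity = list(zygosity)
    rng = _rng(seed)
    n_pairs = len(zygosity)
    maf = rng.uniform(0.2, 0.5, size=n_snp_probes)
    # four parental alleles per pair per probe
    alleles = rng.random((n_snp_probes, n_pairs, 4)) < maf[:, None, None]
    # twin A takes (maternal allele 0, paternal allele 2)
    geno_a = alleles[:, :, 0].astype(int) + alleles[:, :, 2].astype(int)
    # twin B: MZ copies A; DZ draws the other transmission independently
    pick_m = rng.integers(0, 2, size=(n_snp_probes, n_pairs))
    pick_p = rng.integers(0, 2, size=(n_snp_probes, n_pairs))
    m_allele = np.take_along_axis(alleles[:, :, 0:2], pick_m[:, :, None], axis=2)[:, :, 0]
    p_allele = np.take_along_axis(alleles[:, :, 2:4], pick_p[:, :, None], axis=2)[:, :, 0]
    geno_dz = m_allele.astype(int) + p_allele.astype(int)
    is_mz = np.array([z == "MZ" for z in zygosity])
    geno_b = np.where(is_mz[None, :], geno_a, geno_dz)

    modes = np.array([0.05, 0.5, 0.95])
    cols, mat = [], []
    for j, member_geno in enumerate((geno_a, geno_b)):
        beta = modes[member_geno] + rng.normal(0.0, noise_sd, size=member_geno.shape)
        mat.append(np.clip(beta, 0.0, 1.0))
        cols.append([f"P{p:04d}{'AB'[j]}" for p in range(n_pairs)])
    out = pd.DataFrame(
        np.hstack(mat),
        index=[f"snp{j:03d}" for j in range(n_snp_probes)],
        columns=cols[0] + cols[1],
    )
    # interleave A/B per pair for readability
    order = [f"P{p:04d}{m}" for p in range(n_pairs) for m in "AB"]
    return out[order]


@dataclass
class ProbeQcTruth:
    """Which probes were generated to violate each QC filter."""

    detection: list[str]
    beads: list[str]
    non_cpg: list[str]
    multi_hit: list[str]
    snp_maf: list[str]
    sex_chromosome: list[str]


def simulate_probe_metadata(
    n_cpgs: int,
    n_samples: int,
    fail_fractions: Mapping[str, float] | None = None,
    seed=0,
):
    """Per-probe detection p-values, bead counts and annotation flags.

    ``fail_fractions`` maps filter name (detection, beads, non_cpg,
    multi_hit, snp_maf, sex_chromosome) to the fraction of probes generated
    to violate it.  Returns ``(ProbeQC, ProbeQcTruth)``; the truth records
    which probes were planted for each filter (draws are independent, so a
    probe may violate several).
    """
    from .preprocess import ProbeQC  # deferred: preprocess owns the QC type

    fail_fractions = dict(fail_fractions or {})
    for key, frac in fail_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fail fraction for {key!r} outside [0, 1]")
    rng = _rng(seed)
    probes = [f"cg{j:07d}" for j in range(n_cpgs)]

    def pick(name):
        k = int(round(fail_fractions.get(name, 0.0) * n_cpgs))
        idx = rng.choice(n_cpgs, size=k, replace=False) if k else np.array([], int)
        return np.sort(idx)

    det_idx = pick("detection")
    bead_idx = pick("beads")
    detection_p = rng.uniform(0.0, 0.01, size=(n_cpgs, n_samples))
    # failing probes: detection p = 0.2 in just over 1% of samples
    n_bad = max(int(np.floor(0.01 * n_samples)) + 1, 1)
    for j in det_idx:
        cols = rng.choice(n_samples, size=n_bad, replace=False)
        detection_p[j, cols] = 0.2
    bead_counts = 3 + rng.poisson(12, size=(n_cpgs, n_samples))
    n_low = max(int(np.floor(0.05 * n_samples)) + 1, 1)
    for j in bead_idx:
        cols = rng.choice(n_samples, size=n_low, replace=False)
        bead_counts[j, cols] = 2

    flag_names = {
        "non_cpg": "non_cpg",
        "multi_hit": "multi_hit",
        "snp_maf": "snp_maf_gt_005",
        "sex_chromosome": "sex_chromosome",
    }
    flags = pd.DataFrame(False, index=probes, columns=list(flag_names.values()))
    truth_idx = {"detection": det_idx, "beads": bead_idx}
    for name, col in flag_names.items():
        idx = pick(name)
        flags.iloc[idx, flags.columns.get_loc(col)] = True
        truth_idx[name] = idx

    sample_ids = [f"s{j:05d}" for j in range(n_samples)]
    qc = ProbeQC(
        detection_p=pd.DataFrame(detection_p, index=probes, columns=sample_ids),
        bead_counts=pd.DataFrame(bead_counts, index=probes, columns=sample_ids),
        flags=flags,
    )
    truth = ProbeQcTruth(
        detection=[probes[j] for j in truth_idx["detection"]],
        beads=[probes[j] for j in truth_idx["beads"]],
        non_cpg=[probes[j] for j in truth_idx["non_cpg"]],
        multi_hit=[probes[j] for j in truth_idx["multi_hit"]],
        snp_maf=[probes[j] for j in truth_idx["snp_maf"]],
        sex_chromosome=[probes[j] for j in truth_idx["sex_chromosome"]],
    )
    return qc, truth


def simulate_cohort(config: SimulationConfig) -> tuple[TwinCohort, GroundTruth]:
    """Generate a two-visit twin cohort and its ground-truth record.

    Methylation is generated on a logit-like latent scale (unit-variance,
    pair random effect with ICC ``icc_mz``/``icc_dz``) and squashed to (0,1);
    lipids on the natural-log scale and exponentiated.  Cross-lagged and
    mediation structure is imposed on the latent scales.  Identical config
    (including seed) gives byte-identical output.
    """
    config.validate()
    if config.mediation_params is not None:
        for idx, pars in config.clpm_params.items():
            lip = config.signal_lipids.get(idx, "TG")
            if pars.rho2 != 0.0 and lip == config.mediation_lipid and idx != config.mediator_cpg:
                raise ValueError(
                    f"lipid {lip} is both the mediation outcome and rho2-driven "
                    f"by CpG {idx}; use a different lipid or CpG"
                )
    rng = np.random.default_rng(config.seed)
    n_pairs, n_cpgs = config.n_pairs, config.n_cpgs
    n_ind = 2 * n_pairs

    # -- pair-level structure ---------------------------------------------
    n_mz = int(round(config.prop_mz * n_pairs))
    zyg_pairs = np.array(["MZ"] * n_mz + ["DZ"] * (n_pairs - n_mz))
    rng.shuffle(zyg_pairs)
    age_pair = rng.normal(50.0, 10.0, size=n_pairs)
    sex_pair = np.where(rng.random(n_pairs) < 0.68, "male", "female")

    pair_of_ind = np.repeat(np.arange(n_pairs), 2)
    zyg_ind = zyg_pairs[pair_of_ind]
    icc = np.where(zyg_ind == "MZ", config.icc_mz, config.icc_dz)

    smoking = rng.choice(["never", "former", "current"], p=[0.54, 0.13, 0.33], size=n_ind)
    alcohol = rng.choice(["never", "former", "current"], p=[0.51, 0.07, 0.42], size=n_ind)
    bmi_pair_z = rng.standard_normal(n_pairs)
    bmi_b = 24.5 + 3.5 * (
        np.sqrt(0.3) * bmi_pair_z[pair_of_ind] + np.sqrt(0.7) * rng.standard_normal(n_ind)
    )
    # standardized BMI process (exposure X of the mediation model)
    x_b = (bmi_b - 24.5) / 3.5
    med = config.mediation_params
    beta_x = med.beta_x if med is not None else 0.6
    sd_x = med.resid_sds[0] if med is not None else 0.8
    x_f = beta_x * x_b + sd_x * (
        np.sqrt(0.3) * rng.standard_normal(n_pairs)[pair_of_ind]
        + np.sqrt(0.7) * rng.standard_normal(n_ind)
    )
    bmi_f = 24.5 + 3.5 * x_f / np.sqrt(beta_x**2 + sd_x**2)

    # -- lipids on the log scale ------------------------------------------
    is_male = (sex_pair[pair_of_ind] == "male").astype(float)
    smoke_cur = (smoking == "current").astype(float)
    alc_cur = (alcohol == "current").astype(float)
    drivers = {
        config.signal_lipids.get(i, "TG"): i
        for i, p in config.clpm_params.items()
        if p.rho2 != 0.0
    }

    def lipid_resid_baseline():
        pair_z = rng.standard_normal(n_pairs)[pair_of_ind]
        ind_z = rng.standard_normal(n_ind)
        return np.sqrt(_LIPID_ICC) * pair_z + np.sqrt(1.0 - _LIPID_ICC) * ind_z

    lipid_r_b = {lip: lipid_resid_baseline() for lip in LIPIDS}

    # -- methylation latents ----------------------------------------------
    pair_g_b = rng.standard_normal((n_cpgs, n_pairs))
    ind_e_b = rng.standard_normal((n_cpgs, n_ind))
    z_b = np.sqrt(icc) * pair_g_b[:, pair_of_ind] + np.sqrt(1.0 - icc) * ind_e_b
    pair_g_f = rng.standard_normal((n_cpgs, n_pairs))
    ind_e_f = rng.standard_normal((n_cpgs, n_ind))
    eps_f = np.sqrt(icc) * pair_g_f[:, pair_of_ind] + np.sqrt(1.0 - icc) * ind_e_f

    z_f = 0.6 * z_b + 0.8 * eps_f
    for idx, pars in config.clpm_params.items():
        lip = config.signal_lipids.get(idx, "TG")
        z_f[idx] = (
            pars.auto_meth * z_b[idx]
            + pars.rho1 * lipid_r_b[lip]
            + pars.resid_sd_meth * eps_f[idx]
        )
    if med is not None:
        z_f[config.mediator_cpg] = z_f[config.mediator_cpg] + med.a * x_b

    # -- lipid follow-up ---------------------------------------------------
    lipid_r_f = {}
    for lip in LIPIDS:
        pars = config.clpm_params.get(drivers[lip]) if lip in drivers else None
        auto = pars.auto_lipid if pars is not None else 0.6
        sd = pars.resid_sd_lipid if pars is not None else 0.8
        noise = (
            np.sqrt(_LIPID_ICC) * rng.standard_normal(n_pairs)[pair_of_ind]
            + np.sqrt(1.0 - _LIPID_ICC) * rng.standard_normal(n_ind)
        )
        r_f = auto * lipid_r_b[lip] + sd * noise
        if lip in drivers:
            r_f = r_f + pars.rho2 * z_b[drivers[lip]]
        if med is not None and lip == config.mediation_lipid:
            r_f = r_f + med.c_prime * x_b + med.b * z_b[config.mediator_cpg]
        lipid_r_f[lip] = r_f

    # -- assemble specimens ------------------------------------------------
    participants = [f"P{p:04d}{m}" for p in range(n_pairs) for m in "AB"]
    n_f_pairs = int(round(config.followup_fraction * n_pairs))
    f_pairs = set(rng.choice(n_pairs, size=n_f_pairs, replace=False).tolist())

    rows, lipid_rows, beta_cols, sample_ids = [], [], [], []
    probes = [f"cg{j:07d}" for j in range(n_cpgs)]
    m0 = rng.normal(0.0, 1.5, size=n_cpgs)
    cell_loadings = rng.normal(0.0, 0.05, size=(n_cpgs, config.cell_types))
    batch_offsets = rng.normal(0.0, 0.02, size=(n_cpgs, config.batch_levels))
    batch_offsets -= batch_offsets.mean(axis=1, keepdims=True)
    alpha = (
        _CELL_ALPHA
        if config.cell_types == 6
        else np.full(config.cell_types, 60.0 / config.cell_types)
    )
    cell_names = (
        [f"cell_{c}" for c in CELL_TYPES]
        if config.cell_types == 6
        else [f"cell_t{k}" for k in range(config.cell_types)]
    )
    prop_mean = alpha / alpha.sum()

    for visit, z_lat, bmi_v, lip_r in (
        ("baseline", z_b, bmi_b, lipid_r_b),
        ("followup", z_f, bmi_f, lipid_r_f),
    ):
        for i, part in enumerate(participants):
            p = pair_of_ind[i]
            if visit == "followup" and p not in f_pairs:
                continue
            sid = f"{part}_{'b' if visit == 'baseline' else 'f'}"
            age = age_pair[p] + (config.followup_years if visit == "followup" else 0.0)
            batch = int(rng.integers(config.batch_levels))
            props = rng.dirichlet(alpha)
            loglip = {}
            for lip in LIPIDS:
                mu, sd = _LIPID_LOGNORM[lip]
                e_age, e_male, e_smoke, e_alc, e_bmi = _LIPID_COVARIATE_EFFECTS[lip]
                loglip[lip] = (
                    mu
                    + e_age * (age - 50.0)
                    + e_male * is_male[i]
                    + e_smoke * smoke_cur[i]
                    + e_alc * alc_cur[i]
                    + e_bmi * (bmi_v[i] - 24.5)
                    + sd * lip_r[lip][i]
                )
            beta_clean = expit(m0 + 0.35 * z_lat[:, i])
            contam = cell_loadings @ (props - prop_mean) + batch_offsets[:, batch]
            beta = beta_clean + contam + rng.normal(0.0, config.noise_sd, size=n_cpgs)
            for j, eff in config.xs_effects.items():
                lip = config.signal_lipids.get(j, "TG")
                mu_l = _LIPID_LOGNORM[lip][0]
                beta[j] += eff * (loglip[lip] - mu_l)
            beta_cols.append(np.clip(beta, 1e-4, 1.0 - 1e-4))
            sample_ids.append(sid)
            fasting = "ge8h"
            if config.replication_style:
                fasting = "lt8h" if rng.random() < 0.87 else "ge8h"
            rows.append(
                {
                    "participant": part,
                    "pair_id": f"pair{p:04d}",
                    "zygosity": zyg_pairs[p],
                    "visit": visit,
                    "age": age,
                    "sex": sex_pair[p],
                    "smoking": smoking[i],
                    "alcohol": alcohol[i],
                    "bmi": bmi_v[i],
                    "fasting": fasting,
                    "lipid_med": False,
                    "batch": batch,
                    **dict(zip(cell_names, props)),
                }
            )
            lipid_rows.append({lip: float(np.exp(loglip[lip])) for lip in LIPIDS})

    samples = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    lipids = pd.DataFrame(lipid_rows, index=samples.index)[list(LIPIDS)]
    beta = pd.DataFrame(
        np.column_stack(beta_cols), index=pd.Index(probes, name="probe"), columns=samples.index
    )
    snp = simulate_snp_probes(
        zyg_pairs, config.n_snp_probes, seed=rng, noise_sd=config.snp_noise_sd
    )
    snp.columns = [f"{c}_b" for c in snp.columns]

    signal = sorted(
        set(config.clpm_params) | set(config.xs_effects)
        | ({config.mediator_cpg} if med is not None else set())
    )
    active = {
        i
        for i in signal
        if (i in config.xs_effects and config.xs_effects[i] != 0.0)
        or (i in config.clpm_params and not config.clpm_params[i].is_null)
        or (med is not None and i == config.mediator_cpg)
    }
    null_cpgs = sorted(set(range(n_cpgs)) - active)
    truth = GroundTruth(
        clpm_params=dict(config.clpm_params),
        signal_lipids={i: config.signal_lipids.get(i, "TG") for i in config.clpm_params},
        xs_effects=dict(config.xs_effects),
        mediation_params=med,
        mediator_cpg=config.mediator_cpg,
        zygosity=zyg_pairs.tolist(),
        cell_loadings=cell_loadings,
        batch_offsets=batch_offsets,
        null_cpgs=null_cpgs,
        signal_cpgs=sorted(active),
    )
    cohort = TwinCohort(samples=samples, lipids=lipids, beta=beta, snp_beta=snp)
    return cohort, truth
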