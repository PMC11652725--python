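"""Synthetic cohort generator: a linear-Gaussian structural equation model
over the airway-count causal graph.

The generator emulates a COPD ex-smoker cohort at the level the analysis
consumes: demographics, smoking history, spirometry, an ordinal COPD-severity
grade, CT scanner model, and the three CT-derived airway metrics (total
airway count TAC, peripheral count TACp beyond the 7th generation, and
airway wall thickness WT, all log-normal on the natural scale). Structure:

* sex, scanner, age and pack-years are exogenous;
* BMI and (log) lung size are driven by sex;
* severity is an ordered-threshold (probit-style) discretisation of a latent
  loading on standardised age and pack-years, with thresholds chosen so the
  population group proportions are exact;
* log WT <- severity dummies + BMI + scanner + Gaussian noise;
* log TAC <- severity dummies + d * log WT + scanner + noise, and likewise
  log TACp with its own direct effects and slope d';
* spirometry (FEV1/FVC, %predicted FEV1) is emitted per severity group.

Default path coefficients are calibrated so the per-group direct effects and
wall-thickness-mediated indirect effects on the log counts equal the study's
reported values, and group marginals match its summary tables. The module
also provides the exact implied moments of the model (for population-level
oracle tests), the reference DAG, and repeat-scan pairs with a prescribed
intraclass correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .moments import Moments
from .schema import ANALYSIS_COLUMNS, SEVERITY_DUMMIES, Cohort

#: severity-group probabilities (preserved, mild, moderate, severe), from the
#: study's participant counts 362/122/116/49 of 649
GROUP_PROBS = (362 / 649, 122 / 649, 116 / 649, 49 / 649)

#: node set used for structure learning (outcome appended)
BASE_LEARNING_NODES = ("age", "sex", "bmi", "log_lung_size", "severity", "scanner", "log_wt")

#: substream order for per-node noise seeds
_NOISE_NODES = (
    "age",
    "sex",
    "pack_years",
    "scanner",
    "bmi_lung",
    "severity",
    "log_wt",
    "counts",
    "spirometry",
)


@dataclass
class GeneratorConfig:
    """Structural-equation parameters of the synthetic cohort.

    The defaults are the study conditions: group proportions and demographic /
    spirometry marginals from the cohort summary tables, direct effects
    ``direct_tac``/``direct_tacp`` and wall-thickness-mediated products
    ``indirect_tac`` equal to the reported per-group coefficients, and
    ``wt_to_tac``/``wt_to_tacp`` slopes consistent with the reported group WT
    means (the per-group severity->logWT coefficients are derived as
    ``indirect_tac / wt_to_tac``).
    """

    n: int = 649
    seed: int = 0

    # group structure and exogenous marginals
    group_probs: tuple = GROUP_PROBS
    p_male: float = 0.52
    p_flash: float = 422 / 649
    age_mean: float = 70.4
    age_sd: float = 7.64
    pack_years_mean: float = 42.7
    pack_years_sd: float = 24.3

    # sex-driven covariates
    bmi_intercept: float = 30.08
    bmi_sex_coef: float = 1.0
    bmi_sd: float = 6.08
    log_lung_size_intercept: float = 1.0486
    log_lung_size_sex_coef: float = 0.2754
    log_lung_size_sd: float = 0.113
    bmi_lung_size_residual_corr: float = 0.0

    # severity latent (standardised age/pack-years loadings; latent variance 1)
    severity_age_loading: float = 0.31
    severity_pack_years_loading: float = 0.37

    # path coefficients (per group: mild, moderate, severe)
    direct_tac: tuple = (-0.047, -0.14, -0.39)
    direct_tacp: tuple = (-0.047, -0.20, -0.61)
    indirect_tac: tuple = (-0.086, -0.19, -0.26)
    wt_to_tac: float = 4.6
    wt_to_tacp: float = 7.27
    wt_bmi_coef: float = -0.002
    wt_scanner_coef: float = -0.02
    tac_scanner_coef: float = 0.05
    tacp_scanner_coef: float = 0.05

    # residual scales and cross-count residual correlation
    wt_sd: float = 0.0386
    tac_sd: float = 0.147
    tacp_sd: float = 0.128
    count_residual_corr: float = 0.9

    # preserved-group calibration targets (natural scale)
    wt_mean_preserved: float = 1.23
    tac_mean_preserved: float = 417.94
    tacp_mean_preserved: float = 294.82

    # per-group spirometry emissions
    fev1_fvc_means: tuple = (0.76, 0.68, 0.56, 0.41)
    fev1_fvc_sds: tuple = (0.10, 0.13, 0.15, 0.12)
    fev1_pct_pred_means: tuple = (96.8, 79.3, 62.8, 37.9)
    fev1_pct_pred_sds: tuple = (16.7, 19.8, 17.2, 11.6)

    round_counts: bool = False

    def __post_init__(self):
        self.validate()

    # derived severity->logWT coefficients (shared by both count outcomes)
    @property
    def wt_severity_coefs(self) -> tuple:
        return tuple(bd / self.wt_to_tac for bd in self.indirect_tac)

    @property
    def severity_latent_sd(self) -> float:
        la, lp = self.severity_age_loading, self.severity_pack_years_loading
        return math.sqrt(1.0 - la * la - lp * lp)

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        probs = np.asarray(self.group_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("group_probs must be 4 non-negative values summing to 1")
        for name in ("age_sd", "pack_years_sd", "bmi_sd", "log_lung_size_sd", "wt_sd", "tac_sd", "tacp_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("p_male", "p_flash"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0,1]")
        la, lp = self.severity_age_loading, self.severity_pack_years_loading
        if la * la + lp * lp >= 1:
            raise ConfigError("severity latent loadings must satisfy la^2+lp^2 < 1")
        if not -1 < self.count_residual_corr < 1:
            raise ConfigError("count_residual_corr must lie in (-1,1)")
        if not -1 < self.bmi_lung_size_residual_corr < 1:
            raise ConfigError("bmi_lung_size_residual_corr must lie in (-1,1)")
        if self.wt_to_tac == 0 or self.wt_to_tacp == 0:
            raise ConfigError("wall-thickness slopes must be nonzero")

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(**overrides) -> GeneratorConfig:
    """The study-condition configuration (optionally with field overrides)."""
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# calibration helpers (closed-form log-normal moments)

def _log_mgf_bmi(cfg: GeneratorConfig, c: float) -> float:
    """log E[exp(c * BMI)] with BMI = b0 + bs*Sex + eps."""
    pm = cfg.p_male
    return (
        c * cfg.bmi_intercept
        + math.log((1 - pm) + pm * math.exp(c * cfg.bmi_sex_coef))
        + 0.5 * c * c * cfg.bmi_sd**2
    )


def _log_mgf_scanner(cfg: GeneratorConfig, c: float) -> float:
    pf = cfg.p_flash
    return math.log((1 - pf) + pf * math.exp(c))


def structural_intercepts(cfg: GeneratorConfig) -> dict:
    """Intercepts of the logWT/logTAC/logTACp equations solving the
    preserved-group natural-scale mean targets exactly."""
    b0w = (
        math.log(cfg.wt_mean_preserved)
        - _log_mgf_bmi(cfg, cfg.wt_bmi_coef)
        - _log_mgf_scanner(cfg, cfg.wt_scanner_coef)
        - 0.5 * cfg.wt_sd**2
    )

    def count_icpt(target, d, c_sc, sd):
        return (
            math.log(target)
            - d * b0w
            - _log_mgf_bmi(cfg, d * cfg.wt_bmi_coef)
            - _log_mgf_scanner(cfg, d * cfg.wt_scanner_coef + c_sc)
            - 0.5 * (d * cfg.wt_sd) ** 2
            - 0.5 * sd**2
        )

    return {
        "log_wt": b0w,
        "log_tac": count_icpt(cfg.tac_mean_preserved, cfg.wt_to_tac, cfg.tac_scanner_coef, cfg.tac_sd),
        "log_tac_p": count_icpt(
            cfg.tacp_mean_preserved, cfg.wt_to_tacp, cfg.tacp_scanner_coef, cfg.tacp_sd
        ),
    }


def true_params(cfg: GeneratorConfig) -> dict:
    """Ground-truth effect quantities implied by the config (for recovery tests)."""
    b = cfg.wt_severity_coefs
    return {
        "direct_tac": tuple(cfg.direct_tac),
        "direct_tacp": tuple(cfg.direct_tacp),
        "indirect_tac": tuple(bg * cfg.wt_to_tac for bg in b),
        "indirect_tacp": tuple(bg * cfg.wt_to_tacp for bg in b),
        "total_tac": tuple(a + bg * cfg.wt_to_tac for a, bg in zip(cfg.direct_tac, b)),
        "total_tacp": tuple(a + bg * cfg.wt_to_tacp for a, bg in zip(cfg.direct_tacp, b)),
        "wt_severity_coefs": b,
        "wt_to_tac": cfg.wt_to_tac,
        "wt_to_tacp": cfg.wt_to_tacp,
        "intercepts": structural_intercepts(cfg),
    }


def _severity_thresholds(cfg: GeneratorConfig) -> np.ndarray:
    cum = np.cumsum(cfg.group_probs)[:3]
    return stats.norm.ppf(cum)


# ---------------------------------------------------------------------------
# sampling


def _node_rng(cfg: GeneratorConfig, node: str, noise_seeds: dict | None):
    idx = _NOISE_NODES.index(node)
    key = [int(cfg.seed), idx]
    if noise_seeds and node in noise_seeds:
        key.append(int(noise_seeds[node]))
    return np.random.default_rng(key)


def generate_cohort(cfg: GeneratorConfig, noise_seeds: dict | None = None) -> Cohort:
    """Ancestral sampling over the reference DAG.

    ``noise_seeds`` optionally re-seeds the noise substream of a single node
    (keys from ``age, sex, pack_years, scanner, bmi_lung, severity, log_wt,
    counts, spirometry``) — changing one substream perturbs only that node and
    its descendants, which is the generator's core testable property.
    """
    cfg.validate()
    n = cfg.n
    icpt = structural_intercepts(cfg)

    age = cfg.age_mean + cfg.age_sd * _node_rng(cfg, "age", noise_seeds).standard_normal(n)
    sex = (_node_rng(cfg, "sex", noise_seeds).random(n) < cfg.p_male).astype(int)
    pack_years = cfg.pack_years_mean + cfg.pack_years_sd * _node_rng(
        cfg, "pack_years", noise_seeds
    ).standard_normal(n)
    scanner = (_node_rng(cfg, "scanner", noise_seeds).random(n) < cfg.p_flash).astype(int)

    rng_bl = _node_rng(cfg, "bmi_lung", noise_seeds)
    z1, z2 = rng_bl.standard_normal(n), rng_bl.standard_normal(n)
    rho_bl = cfg.bmi_lung_size_residual_corr
    eps_bmi = cfg.bmi_sd * z1
    eps_ls = cfg.log_lung_size_sd * (rho_bl * z1 + math.sqrt(1 - rho_bl**2) * z2)
    bmi = cfg.bmi_intercept + cfg.bmi_sex_coef * sex + eps_bmi
    log_lung_size = cfg.log_lung_size_intercept + cfg.log_lung_size_sex_coef * sex + eps_ls

    z_age = (age - cfg.age_mean) / cfg.age_sd
    z_py = (pack_years - cfg.pack_years_mean) / cfg.pack_years_sd
    latent = (
        cfg.severity_age_loading * z_age
        + cfg.severity_pack_years_loading * z_py
        + cfg.severity_latent_sd * _node_rng(cfg, "severity", noise_seeds).standard_normal(n)
    )
    thr = _severity_thresholds(cfg)
    severity = (
        (latent > thr[0]).astype(int) + (latent > thr[1]).astype(int) + (latent > thr[2]).astype(int)
    )

    b = np.concatenate([[0.0], cfg.wt_severity_coefs])
    a_tac = np.concatenate([[0.0], cfg.direct_tac])
    a_tacp = np.concatenate([[0.0], cfg.direct_tacp])

    log_wt = (
        icpt["log_wt"]
        + b[severity]
        + cfg.wt_bmi_coef * bmi
        + cfg.wt_scanner_coef * scanner
        + cfg.wt_sd * _node_rng(cfg, "log_wt", noise_seeds).standard_normal(n)
    )

    rng_counts = _node_rng(cfg, "counts", noise_seeds)
    zt, zp = rng_counts.standard_normal(n), rng_counts.standard_normal(n)
    rho_c = cfg.count_residual_corr
    eps_t = cfg.tac_sd * zt
    eps_p = cfg.tacp_sd * (rho_c * zt + math.sqrt(1 - rho_c**2) * zp)
    log_tac = (
        icpt["log_tac"]
        + a_tac[severity]
        + cfg.wt_to_tac * log_wt
        + cfg.tac_scanner_coef * scanner
        + eps_t
    )
    log_tacp = (
        icpt["log_tac_p"]
        + a_tacp[severity]
        + cfg.wt_to_tacp * log_wt
        + cfg.tacp_scanner_coef * scanner
        + eps_p
    )

    tac = np.exp(log_tac)
    tac_p = np.exp(log_tacp)
    clipped = tac_p > tac
    tac_p = np.minimum(tac_p, tac)
    wt = np.exp(log_wt)
    if cfg.round_counts:
        tac = np.maximum(np.round(tac), 1.0)
        tac_p = np.minimum(np.maximum(np.round(tac_p), 0.0), tac)

    rng_sp = _node_rng(cfg, "spirometry", noise_seeds)
    fev1_fvc = np.asarray(cfg.fev1_fvc_means)[severity] + np.asarray(cfg.fev1_fvc_sds)[
        severity
    ] * rng_sp.standard_normal(n)
    fev1_pct = np.asarray(cfg.fev1_pct_pred_means)[severity] + np.asarray(cfg.fev1_pct_pred_sds)[
        severity
    ] * rng_sp.standard_normal(n)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "lung_size": np.exp(log_lung_size),
            "pack_years": pack_years,
            "fev1_fvc": fev1_fvc,
            "fev1_pct_pred": fev1_pct,
            "severity": severity,
            "scanner": scanner,
            "tac": tac,
            "tac_p": tac_p,
            "wt": wt,
        },
        columns=list(ANALYSIS_COLUMNS),
    )
    meta = {
        "config": cfg.to_dict(),
        "true_params": true_params(cfg),
        "n_tacp_clipped": int(clipped.sum()),
    }
    return Cohort(df, provenance="synthetic", meta=meta)


# ---------------------------------------------------------------------------
# repeat scans


@dataclass
class RepeatMeasures:
    """Two replicate measurements per participant for each airway metric."""

    data: pd.DataFrame  # columns: participant, metric, scan1, scan2
    icc_target: float

    def pairs(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.data[self.data["metric"] == metric]
        return sub["scan1"].to_numpy(), sub["scan2"].to_numpy()


def generate_repeat_scans(
    cohort: Cohort, icc_target: float, seed: int, metrics=("tac", "tac_p", "wt")
) -> RepeatMeasures:
    """Replicate each participant's metrics under an additive Gaussian
    measurement-error model.

    The cohort value plays the role of the participant's true value; the
    error variance is ``between-subject variance * (1 - icc) / icc`` so the
    population intraclass correlation of the two replicates equals
    ``icc_target``. ``icc_target = 1`` yields exact duplicates.
    """
    if not 0 < icc_target <= 1:
        raise ConfigError("icc_target must lie in (0, 1]")
    rng = np.random.default_rng([int(seed), 90210])
    frames = []
    for metric in metrics:
        vals = cohort.data[metric].to_numpy(dtype=float)
        if icc_target == 1.0:
            noise = np.zeros((2, len(vals)))
        else:
            between = np.var(vals, ddof=1)
            err_sd = math.sqrt(between * (1 - icc_target) / icc_target)
            noise = err_sd * rng.standard_normal((2, len(vals)))
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.arange(len(vals)),
                    "metric": metric,
                    "scan1": vals + noise[0],
                    "scan2": vals + noise[1],
                }
            )
        )
    return RepeatMeasures(pd.concat(frames, ignore_index=True), icc_target)


# ---------------------------------------------------------------------------
# exact implied moments and the reference DAG


def _group_weights(cfg: GeneratorConfig):
    """pi_g, and w_g = E[zL * 1(S=g)] for the standard-normal latent."""
    pi = np.asarray(cfg.group_probs, dtype=float)
    thr = _severity_thresholds(cfg)
    pdf = stats.norm.pdf(thr)
    w = np.array([-pdf[0], pdf[0] - pdf[1], pdf[1] - pdf[2], pdf[2]])
    return pi, w


def implied_moments(cfg: GeneratorConfig, include_dummies: bool = True) -> Moments:
    """Exact population mean vector and covariance matrix of the model.

    Covers the structure-learning node set plus pack-years, both log count
    outcomes, and (optionally) the three severity dummy indicators. Severity
    enters as the 0-3 ordinal code; its covariances with the Gaussian parents
    follow from truncated-normal moments of the latent, and covariances of
    any function of severity (dummies, per-group effect shifts) are exact
    sums over the group distribution. Used as the population oracle for
    structure learning and effect-decomposition identities.
    """
    cfg.validate()
    pi, w = _group_weights(cfg)
    icpt = structural_intercepts(cfg)
    la, lp = cfg.severity_age_loading, cfg.severity_pack_years_loading
    pm, pf = cfg.p_male, cfg.p_flash
    pq_m, pq_f = pm * (1 - pm), pf * (1 - pf)

    # group-value vectors (index = severity level 0..3)
    f_id = np.array([0.0, 1.0, 2.0, 3.0])
    f_u = np.concatenate([[0.0], cfg.wt_severity_coefs])
    f_v = np.concatenate([[0.0], cfg.direct_tac])
    f_vp = np.concatenate([[0.0], cfg.direct_tacp])
    d, dp = cfg.wt_to_tac, cfg.wt_to_tacp
    bB, cw = cfg.wt_bmi_coef, cfg.wt_scanner_coef
    ct, cp_ = cfg.tac_scanner_coef, cfg.tacp_scanner_coef
    bsB, bsL = cfg.bmi_sex_coef, cfg.log_lung_size_sex_coef

    basis_var = {
        "age": cfg.age_sd**2,
        "py": cfg.pack_years_sd**2,
        "sex": pq_m,
        "sc": pq_f,
        "eB": cfg.bmi_sd**2,
        "eL": cfg.log_lung_size_sd**2,
        "ew": cfg.wt_sd**2,
        "et": cfg.tac_sd**2,
        "ep": cfg.tacp_sd**2,
    }
    basis_cross = {
        frozenset(("eB", "eL")): cfg.bmi_lung_size_residual_corr * cfg.bmi_sd * cfg.log_lung_size_sd,
        frozenset(("et", "ep")): cfg.count_residual_corr * cfg.tac_sd * cfg.tacp_sd,
    }
    # Cov(basis, zL) for the two latent-correlated exogenous variables
    latent_cov = {"age": cfg.age_sd * la, "py": cfg.pack_years_sd * lp}

    mean_bmi = cfg.bmi_intercept + bsB * pm
    mean_wt = icpt["log_wt"] + float(pi @ f_u) + bB * mean_bmi + cw * pf

    # variable -> (mean, basis loadings, group-value vector or None)
    var_spec: dict[str, tuple[float, dict, np.ndarray | None]] = {
        "age": (cfg.age_mean, {"age": 1.0}, None),
        "sex": (pm, {"sex": 1.0}, None),
        "bmi": (mean_bmi, {"sex": bsB, "eB": 1.0}, None),
        "log_lung_size": (
            cfg.log_lung_size_intercept + bsL * pm,
            {"sex": bsL, "eL": 1.0},
            None,
        ),
        "pack_years": (cfg.pack_years_mean, {"py": 1.0}, None),
        "severity": (float(pi @ f_id), {}, f_id),
        "scanner": (pf, {"sc": 1.0}, None),
        "log_wt": (mean_wt, {"sex": bB * bsB, "eB": bB, "sc": cw, "ew": 1.0}, f_u),
        "log_tac": (
            icpt["log_tac"] + float(pi @ f_v) + d * mean_wt + ct * pf,
            {"sex": d * bB * bsB, "eB": d * bB, "sc": ct + d * cw, "ew": d, "et": 1.0},
            f_v + d * f_u,
        ),
        "log_tac_p": (
            icpt["log_tac_p"] + float(pi @ f_vp) + dp * mean_wt + cp_ * pf,
            {"sex": dp * bB * bsB, "eB": dp * bB, "sc": cp_ + dp * cw, "ew": dp, "ep": 1.0},
            f_vp + dp * f_u,
        ),
    }
    if include_dummies:
        for level, col in zip((1, 2, 3), SEVERITY_DUMMIES):
            ind = np.zeros(4)
            ind[level] = 1.0
            var_spec[col] = (float(pi[level]), {}, ind)

    names = list(var_spec)

    def cov_entry(n1: str, n2: str) -> float:
        _, c1, f1 = var_spec[n1]
        _, c2, f2 = var_spec[n2]
        total = 0.0
        for b_name, v in basis_var.items():
            total += c1.get(b_name, 0.0) * c2.get(b_name, 0.0) * v
        for pair, cv in basis_cross.items():
            x, y = tuple(pair)
            total += (c1.get(x, 0.0) * c2.get(y, 0.0) + c1.get(y, 0.0) * c2.get(x, 0.0)) * cv
        if f1 is not None and f2 is not None:
            total += float(pi @ (f1 * f2)) - float(pi @ f1) * float(pi @ f2)
        # correlation of group functions with age / pack-years via the latent
        for b_name, cz in latent_cov.items():
            if f2 is not None:
                total += c1.get(b_name, 0.0) * cz * float(f2 @ w)
            if f1 is not None:
                total += c2.get(b_name, 0.0) * cz * float(f1 @ w)
        return total

    cov = pd.DataFrame(
        [[cov_entry(n1, n2) for n2 in names] for n1 in names], index=names, columns=names
    )
    mean = pd.Series({name: var_spec[name][0] for name in names})
    return Moments(mean=mean, cov=cov, n=None)


def learning_nodes(outcome: str = "log_tac") -> tuple[str, ...]:
    """Default structure-learning node set for one count outcome."""
    return BASE_LEARNING_NODES + (outcome,)


def reference_edges(outcome: str = "log_tac") -> tuple[tuple[str, str], ...]:
    """Directed edges of the reference DAG over the learning node set."""
    return (
        ("sex", "bmi"),
        ("sex", "log_lung_size"),
        ("age", "severity"),
        ("severity", "log_wt"),
        ("bmi", "log_wt"),
        ("scanner", "log_wt"),
        ("severity", outcome),
        ("scanner", outcome),
        ("log_wt", outcome),
    )
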