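"""Synthetic participant-level data with the study's latent structure.

The generator emulates a repeated-measures working-memory experiment:
five hit-rate variables driven by two uncorrelated latent processes — a
"constant" process loading equally on every condition and a "dynamic"
process whose loadings follow a fixed course (inverted-u by default) —
plus three reasoning composites driven by a criterion factor that is
regressed on both latents.  Population defaults reproduce the study
conditions: latent variances .0120 / .0121, standardized criterion
paths .45 (constant) and .48 (dynamic), condition means/SDs matching
the observed descriptives, and composite loadings calibrated to the
observed inter-composite correlations (.58 / .40 / .42).

Also provides the composite-scoring step (z-standardize six reasoning
subtests, average the two per content domain) and a parameter-recovery
simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .model import (
    REASONING_NAMES,
    WMC_NAMES,
    LoadingCourse,
    build_paper_model,
    make_course,
)

__all__ = [
    "PopulationModel",
    "generate",
    "score_bis_composites",
    "parameter_recovery_study",
    "RecoverySummary",
]

#: observed condition means; the fifth continues the difficulty trend
WMC_MEANS = (0.88, 0.77, 0.77, 0.61, 0.55)
#: observed total SDs per condition; the fifth continues the trend
WMC_TOTAL_SDS = (0.18, 0.21, 0.19, 0.23, 0.24)
#: observed correlations among the figural/numerical/verbal composites
COMPOSITE_TARGET_CORR = {"fig_num": 0.58, "fig_verb": 0.40, "num_verb": 0.42}


def _composite_loadings_from_corr(r_fn, r_fv, r_nv):
    # one-factor structure: r_ij = l_i * l_j  =>  closed-form solution
    l_f = np.sqrt(r_fn * r_fv / r_nv)
    return (float(l_f), float(r_fn / l_f), float(r_fv / l_f))


@dataclass
class PopulationModel:
    """True parameter values for the data generator.

    All quantities are in the hit-rate metric for the WMC side and in a
    standardized (unit-variance) metric for the criterion factor and its
    composites.  ``reasoning_paths`` are standardized effects of the
    constant and dynamic latents on the criterion; their squared sum
    must stay below 1.
    """

    constant_variance: float = 0.0120
    dynamic_variance: float = 0.0121
    dynamic_course: LoadingCourse = field(default_factory=lambda: make_course("inverted_u", 5))
    wmc_means: tuple = WMC_MEANS
    wmc_total_sds: tuple = WMC_TOTAL_SDS
    wmc_residual_sds: tuple | None = None  # derived from total SDs when None
    reasoning_paths: tuple = (0.45, 0.48)  # (constant, dynamic), standardized
    composite_loadings: tuple | None = None  # derived from target correlations
    error_family: str = "normal"  # or "scaled_t"
    t_df: float = 5.0
    clip_hit_rates: bool = False

    def __post_init__(self):
        if self.constant_variance <= 0 or self.dynamic_variance < 0:
            raise ValueError("latent variances must be positive (dynamic may be 0)")
        b_c, b_d = self.reasoning_paths
        if not (-1 < b_c < 1 and -1 < b_d < 1) or b_c**2 + b_d**2 >= 1:
            raise ValueError("standardized paths must lie in (-1,1) with summed R^2 < 1")
        g = self.dynamic_course.values
        if len(g) != len(self.wmc_means):
            raise ValueError("dynamic course length must match number of conditions")
        if self.wmc_residual_sds is None:
            # theta_i = SD_i^2 - psi_c - g_i^2 psi_d
            res = []
            for sd, gi in zip(self.wmc_total_sds, g):
                th = sd**2 - self.constant_variance - gi**2 * self.dynamic_variance
                if th <= 0:
                    raise ValueError(
                        f"total SD {sd} too small for the latent contribution (residual variance {th:.4g})"
                    )
                res.append(np.sqrt(th))
            self.wmc_residual_sds = tuple(res)
        if self.composite_loadings is None:
            self.composite_loadings = _composite_loadings_from_corr(
                COMPOSITE_TARGET_CORR["fig_num"],
                COMPOSITE_TARGET_CORR["fig_verb"],
                COMPOSITE_TARGET_CORR["num_verb"],
            )
        if any(not 0 < l < 1 for l in self.composite_loadings):
            raise ValueError("composite loadings must lie in (0, 1)")
        if self.error_family not in ("normal", "scaled_t"):
            raise ValueError(f"unknown error family {self.error_family!r}")
        if self.error_family == "scaled_t" and self.t_df <= 2:
            raise ValueError("scaled-t errors need df > 2 for finite variance")

    # -- implied moments ----------------------------------------------
    def to_theta(self) -> dict[str, float]:
        """Population values keyed as free parameters of the
        structural_fixedlinks spec (first composite loading fixed to 1)."""
        b_c, b_d = self.reasoning_paths
        l1, l2, l3 = self.composite_loadings
        psi_c, psi_d = self.constant_variance, self.dynamic_variance
        zeta = 1 - b_c**2 - b_d**2
        theta = {
            "Constant~~Constant": psi_c,
            "Dynamic~~Dynamic": psi_d,
            # criterion rescaled so the fixed first loading is 1
            "Reasoning=~Numerical": l2 / l1,
            "Reasoning=~Verbal": l3 / l1,
            "Reasoning~~Reasoning": l1**2 * zeta,
            "Reasoning~Constant": l1 * b_c / np.sqrt(psi_c),
            "Reasoning~Dynamic": l1 * b_d / np.sqrt(psi_d) if psi_d > 0 else 0.0,
        }
        for name, sd in zip(WMC_NAMES, self.wmc_residual_sds):
            theta[f"{name}~~{name}"] = sd**2
        for name, l in zip(REASONING_NAMES, self.composite_loadings):
            theta[f"{name}~~{name}"] = 1 - l**2
        return theta

    def structural_spec(self):
        """The two-latent structural ModelSpec matching this population
        (Dynamic loadings fixed to this population's course)."""
        from .model import fixed

        spec = build_paper_model("structural_fixedlinks")
        for y, g in zip(WMC_NAMES, self.dynamic_course.values):
            spec.loadings[(y, "Dynamic")] = fixed(g)
        spec.name = f"structural_fixedlinks ({self.dynamic_course.name})"
        return spec

    def implied_covariance(self) -> np.ndarray:
        """Population covariance of the 8 observed variables (composites
        first, then conditions), via the model-implied algebra."""
        return engine.implied_covariance(self.structural_spec(), self.to_theta())


def _draw_factory(rng: np.random.Generator, family: str, t_df: float, n: int):
    """Source of unit-variance standardized draws of length n.

    ``scaled_t`` uses a *shared* chi-square scale mixture per
    participant (a multivariate-t construction): every latent score and
    residual of one participant is divided by the same random scale.
    Marginals are scaled t with ``t_df`` degrees of freedom and unit
    variance.  The shared mixing is deliberate: with *independent*
    heavy-tailed components the ML chi-square is asymptotically robust
    and a kurtosis correction would have nothing to correct.
    """
    if family == "normal":
        return lambda: rng.standard_normal(n)
    u = rng.chisquare(t_df, n) / t_df
    scale = np.sqrt((t_df - 2) / t_df) / np.sqrt(u)
    return lambda: scale * rng.standard_normal(n)


def generate(pop: PopulationModel, n: int, seed: int) -> pd.DataFrame:
    """Generate an n x 8 raw data table (3 composites, 5 hit rates).

    Manifest hit rate i = mean_i + 1*xi_c + g_i*xi_d + eps_i with latent
    scores xi_c ~ (0, psi_c), xi_d ~ (0, psi_d).  The criterion factor is
    b_c * xi_c/sd + b_d * xi_d/sd + disturbance (unit total variance) and
    each composite is l_j * criterion + e_j (unit total variance).
    Identical seeds give identical tables.  With ``clip_hit_rates`` the
    five hit-rate columns are truncated to [0, 1] (a deliberate
    misspecification stressor; moment-level oracles then no longer hold
    exactly).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    draw = _draw_factory(rng, pop.error_family, pop.t_df, n)
    psi_c, psi_d = pop.constant_variance, pop.dynamic_variance
    xi_c = np.sqrt(psi_c) * draw()
    xi_d = np.sqrt(psi_d) * draw()
    b_c, b_d = pop.reasoning_paths
    zeta_sd = np.sqrt(1 - b_c**2 - b_d**2)
    crit = b_c * (xi_c / np.sqrt(psi_c))
    if psi_d > 0:
        crit = crit + b_d * (xi_d / np.sqrt(psi_d))
    crit = crit + zeta_sd * draw()
    cols = {}
    for name, l in zip(REASONING_NAMES, pop.composite_loadings):
        cols[name] = l * crit + np.sqrt(1 - l**2) * draw()
    g = pop.dynamic_course.values
    for i, name in enumerate(WMC_NAMES):
        y = pop.wmc_means[i] + xi_c + g[i] * xi_d + pop.wmc_residual_sds[i] * draw()
        if pop.clip_hit_rates:
            y = np.clip(y, 0.0, 1.0)
        cols[name] = y
    return pd.DataFrame(cols, columns=list(REASONING_NAMES) + list(WMC_NAMES))


def score_bis_composites(subtest_scores: pd.DataFrame) -> pd.DataFrame:
    """Score six reasoning subtests into three content composites.

    Columns must be ordered F1, F2, N1, N2, V1, V2 (two figural, two
    numerical, two verbal subtests).  Each column is z-standardized with
    its sample mean and SD (ddof 1) and the two standardized columns per
    content domain are averaged.
    """
    X = np.asarray(subtest_scores, dtype=float)
    if X.shape[1] != 6:
        raise ValueError("expected six subtest columns (F1, F2, N1, N2, V1, V2)")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [subtest_scores.columns[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance subtest column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    out = {
        "Figural": Z[:, 0:2].mean(axis=1),
        "Numerical": Z[:, 2:4].mean(axis=1),
        "Verbal": Z[:, 4:6].mean(axis=1),
    }
    return pd.DataFrame(out, index=subtest_scores.index)


# ----------------------------------------------------------------------
# Parameter recovery
# ----------------------------------------------------------------------


@dataclass
class RecoverySummary:
    """Monte-Carlo summary of structural-model parameter recovery."""

    n: int
    replications: int
    converged: int
    bias: dict[str, float]
    empirical_sd: dict[str, float]
    coverage: dict[str, float]
    z_significant_rate: dict[str, float]
    course_selection: dict[str, int]
    estimates: pd.DataFrame


_COURSES = ("linear", "quadratic", "logarithmic", "inverted_u")
_MODEL_OF_COURSE = {"linear": 2, "quadratic": 3, "logarithmic": 4, "inverted_u": 5}


def parameter_recovery_study(
    pop: PopulationModel,
    n: int = 200,
    replications: int = 200,
    seed: int = 0,
    select_course: bool = True,
) -> RecoverySummary:
    """Simulate, refit, and summarize recovery of the population values.

    For each replication: generate data, fit the two-latent structural
    model to the sample covariance matrix, and record the standardized
    criterion paths, the latent variances and their z-tests.  Optionally
    fit the four fixed-links measurement models (2-5) to the WMC block
    and record which dynamic course the joint AIC/delta-CFI rule (with
    the nonsignificant-variance rejection rule) selects.

    Coverage is the fraction of replications whose 95% Wald interval for
    an unstandardized parameter covers the population value.  Seeds are
    derived from the master seed by counter, so results are reproducible.
    """
    if replications < 50:
        raise ValueError("use >= 50 replications for stable summaries")
    from .indices import compare_models, indices_from_fit  # local import avoids cycle

    spec = pop.structural_spec()
    pop_theta = pop.to_theta()
    b_c, b_d = pop.reasoning_paths
    truth_std = {"Reasoning~Constant": b_c, "Reasoning~Dynamic": b_d}
    track_unstd = ["Constant~~Constant", "Dynamic~~Dynamic",
                   "Reasoning~Constant", "Reasoning~Dynamic"]
    rows = []
    selection = {c: 0 for c in _COURSES}
    n_conv = 0
    for rep in range(replications):
        rep_seed = int((seed * 100_003 + rep) % (2**31 - 1))
        data = generate(pop, n, rep_seed)
        moments = engine.SampleMoments.from_raw(data)
        try:
            res = engine.fit(spec, moments)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not res.converged:
            continue
        n_conv += 1
        row = {"rep": rep}
        for key, truth in truth_std.items():
            row[f"std:{key}"] = res.standardized[key]
        for key in track_unstd:
            est, se = res.theta_hat[key], res.se.get(key, np.nan)
            row[f"est:{key}"] = est
            row[f"cover:{key}"] = float(
                np.isfinite(se) and abs(est - pop_theta[key]) <= 1.96 * se
            )
        for latent in ("Constant", "Dynamic"):
            z, p = engine.variance_z_test(res, latent)
            row[f"zsig:{latent}"] = float(np.isfinite(z) and p < 0.05)
        if select_course:
            wmc = moments.subset(list(WMC_NAMES))
            reports, rejected = [], set()
            for course in _COURSES:
                mres = engine.fit(build_paper_model(_MODEL_OF_COURSE[course]), wmc)
                rep_ix = indices_from_fit(mres)
                rep_ix.model = course
                reports.append(rep_ix)
                _z, pz = engine.variance_z_test(mres, "Dynamic")
                if not (np.isfinite(pz) and pz < 0.05):
                    rejected.add(course)
            if len(rejected) < len(_COURSES):
                verdict = compare_models(reports, rejected=rejected)
                if verdict["preferred"]:
                    selection[verdict["preferred"]] += 1
        rows.append(row)
    est = pd.DataFrame(rows)
    bias, esd, cover, zrate = {}, {}, {}, {}
    for key, truth in truth_std.items():
        bias[f"std:{key}"] = float(est[f"std:{key}"].mean() - truth)
        esd[f"std:{key}"] = float(est[f"std:{key}"].std(ddof=1))
    for key in track_unstd:
        bias[key] = float(est[f"est:{key}"].mean() - pop_theta[key])
        esd[key] = float(est[f"est:{key}"].std(ddof=1))
        cover[key] = float(est[f"cover:{key}"].mean())
    for latent in ("Constant", "Dynamic"):
        zrate[latent] = float(est[f"zsig:{latent}"].mean())
    return RecoverySummary(
        n=n, replications=replications, converged=n_conv,
        bias=bias, empirical_sd=esd, coverage=cover,
        z_significant_rate=zrate, course_selection=selection, estimates=est,
    )


def null_dynamic_population(**overrides) -> PopulationModel:
    """Population with zero dynamic variance (null for the z-test)."""
    kw = dict(dynamic_variance=0.0, reasoning_paths=(0.45, 0.0))
    kw.update(overrides)
    return PopulationModel(**kw)
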