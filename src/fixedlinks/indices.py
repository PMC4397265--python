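"""Model-fit evaluation and comparison.

Implements the fit indices used to judge covariance-structure models —
chi-square p-value, CFI, RMSEA, SRMR — and the AIC-style information
criterion T - 2*df used for same-data model comparison, together with
the joint comparison rule (lower AIC *and* CFI more than .01 larger
means "better") and the substantive-rejection rule for fixed-links
models whose dynamic variance is not significant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import FitResult, SampleMoments

__all__ = [
    "FitIndexReport",
    "baseline_model",
    "compute_indices",
    "indices_from_fit",
    "compare_models",
    "format_fit_table",
]


@dataclass
class FitIndexReport:
    """Fit indices for one fitted model.

    AIC follows the difference convention AIC = T - 2*df (equivalent,
    for comparisons on the same data, to -2lnL + 2q up to a constant).
    """

    model: str
    T: float
    df: int
    p_value: float
    CFI: float
    RMSEA: float
    SRMR: float | None
    AIC: float
    baseline_T: float
    baseline_df: int

    def row(self) -> dict:
        """Printed-precision row (CFI 3 decimals, others 2)."""
        return {
            "model": self.model,
            "chi2": round(self.T, 2),
            "df": self.df,
            "p": round(self.p_value, 2),
            "CFI": round(self.CFI, 3),
            "RMSEA": round(self.RMSEA, 2),
            "SRMR": None if self.SRMR is None else round(self.SRMR, 2),
            "AIC": round(self.AIC, 2),
        }


def baseline_model(moments: SampleMoments, multiplier: float | None = None):
    """Independence-baseline statistic and degrees of freedom.

    The baseline model is diagonal Sigma with free variances; its ML
    solution is exact (sigma_ii = s_ii), so F_b = -ln|R| with R the
    sample correlation matrix, T_b = multiplier * F_b (multiplier
    defaults to n - 1) and df_b = p(p-1)/2.
    """
    p = moments.p
    d = 1.0 / np.sqrt(np.diag(moments.S))
    R = moments.S * np.outer(d, d)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("sample matrix is not positive definite")
    mult = float(multiplier if multiplier is not None else moments.n - 1)
    T_b = -mult * logdet
    return float(T_b), p * (p - 1) // 2


def compute_indices(
    T: float,
    df: int,
    T_b: float,
    df_b: int,
    n: int,
    S: np.ndarray | None = None,
    Sigma: np.ndarray | None = None,
    model: str = "",
) -> FitIndexReport:
    """Assemble a fit-index report from test statistics.

    p-value: upper tail of central chi-square(df) at T.
    CFI  = 1 - max(T - df, 0) / max(T_b - df_b, T - df, 0).
    RMSEA = sqrt(max(T - df, 0) / (df * (n - 1))).
    SRMR = rms of (s_ij - sigma_ij)/sqrt(s_ii s_jj) over the p(p+1)/2
    nonduplicated elements (requires S and Sigma).
    AIC  = T - 2*df.
    """
    if df_b <= 0 or n <= 1:
        raise ValueError("need df_b > 0 and n > 1")
    if df < 0:
        raise ValueError("negative df")
    p_value = float(stats.chi2.sf(T, df)) if df > 0 else float("nan")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    CFI = 1.0 - (num / den if den > 0 else 0.0)
    if df == 0:
        RMSEA = float("nan")
        AIC = float("nan")
    else:
        RMSEA = math.sqrt(num / (df * (n - 1)))
        AIC = T - 2 * df
    SRMR = None
    if S is not None and Sigma is not None:
        S = np.asarray(S, float)
        Sigma = np.asarray(Sigma, float)
        p = S.shape[0]
        scale = np.sqrt(np.outer(np.diag(S), np.diag(S)))
        resid = (S - Sigma) / scale
        iu = np.triu_indices(p)
        SRMR = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndexReport(
        model=model, T=float(T), df=int(df), p_value=p_value, CFI=float(CFI),
        RMSEA=float(RMSEA), SRMR=SRMR, AIC=float(AIC),
        baseline_T=float(T_b), baseline_df=int(df_b),
    )


def indices_from_fit(result: FitResult, scaled: bool = False) -> FitIndexReport:
    """Fit-index report for a FitResult, using the plain or the robustly
    rescaled statistic."""
    T = result.T_scaled if scaled else result.T
    if T is None:
        raise ValueError("no scaled statistic on this fit result")
    T_b, df_b = baseline_model(result.moments, multiplier=result.multiplier)
    return compute_indices(
        T, result.df, T_b, df_b, result.moments.n,
        S=result.moments.S, Sigma=result.implied,
        model=result.spec.name,
    )


def compare_models(
    reports: list[FitIndexReport],
    rejected: set[str] | None = None,
    delta_cfi: float = 0.01,
) -> dict:
    """Pairwise model comparison under the joint AIC + delta-CFI rule.

    Model A is "better" than B when AIC_A < AIC_B *and* CFI_A - CFI_B >
    ``delta_cfi``; otherwise the pair is "not distinguishable".  Models
    named in ``rejected`` (e.g. because their dynamic-variance z-test
    failed) are excluded from preference and flagged, regardless of fit.

    Returns ``{"pairs": [...], "rejected": [...], "preferred": name}``
    where ``preferred`` is the model that is better than every other
    non-rejected model, or the lowest-AIC non-rejected model if no model
    dominates outright (None if fewer than two candidates).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    rejected = set(rejected or ())
    pairs = []
    for i, a in enumerate(reports):
        for b in reports[i + 1:]:
            verdict = "not distinguishable"
            if a.model in rejected or b.model in rejected:
                verdict = "excluded (rejected model)"
            elif a.AIC < b.AIC and a.CFI - b.CFI > delta_cfi:
                verdict = f"{a.model} better"
            elif b.AIC < a.AIC and b.CFI - a.CFI > delta_cfi:
                verdict = f"{b.model} better"
            pairs.append({"a": a.model, "b": b.model, "verdict": verdict})
    candidates = [r for r in reports if r.model not in rejected]
    preferred = None
    if len(candidates) >= 1:
        dominating = [
            r for r in candidates
            if all(r.AIC < o.AIC and r.CFI - o.CFI > delta_cfi
                   for o in candidates if o is not r)
        ]
        if dominating:
            preferred = dominating[0].model
        elif candidates:
            preferred = min(candidates, key=lambda r: r.AIC).model
    return {"pairs": pairs, "rejected": sorted(rejected), "preferred": preferred}


def format_fit_table(reports: list[FitIndexReport], fmt: str = "tsv") -> str:
    """Emit a comparison table (columns chi2, df, p, CFI, RMSEA, SRMR,
    AIC) as delimited text or JSON."""
    rows = [r.row() for r in reports]
    if fmt == "json":
        return json.dumps(rows, indent=2)
    cols = ["model", "chi2", "df", "p", "CFI", "RMSEA", "SRMR", "AIC"]
    sep = "\t" if fmt == "tsv" else ","
    lines = [sep.join(cols)]
    for r in rows:
        lines.append(sep.join("" if r[c] is None else str(r[c]) for c in cols))
    return "\n".join(lines)
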