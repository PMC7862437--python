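r"""Horizon contrasts, the diffusion-to-logistic consistency check, and the
sensitivity analysis attributing random exploration to signal-to-noise
versus threshold changes.

In the regime the fits occupy (baseline bias and threshold slopes near 0)
the diffusion choice curve is logistic with predicted decision noise

    sigma_pred = 1 / (2 sqrt(2) |cR_mu| c0_beta)      (points)

so the relative change in random exploration between horizons obeys

    sigma(h1) / sigma(h6) = [cR_mu(h6) / cR_mu(h1)] * [c0_beta(h6) / c0_beta(h1)]

and the relative contribution of the signal-to-noise coefficient cR_mu and
the baseline threshold c0_beta is read off the two per-subject ratios.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddm_core import PARAM_NAMES

__all__ = [
    "ContrastTable",
    "SensitivityReport",
    "BONFERRONI_FACTOR",
    "horizon_contrast",
    "predicted_sigma",
    "predicted_sigma_check",
    "sensitivity_ratios",
    "theoretical_curves",
]

#: Number of parameters compared between horizons; the Bonferroni correction
#: divides the significance level by this factor regardless of how many rows
#: a caller chooses to inspect.
BONFERRONI_FACTOR = 10


@dataclass
class ContrastTable:
    """Paired horizon-6 minus horizon-1 contrasts, one row per parameter."""

    table: pd.DataFrame  # parameter, mean_diff, t, p_raw, significant
    n_subjects: int
    alpha_level: float = 0.05

    def __post_init__(self) -> None:
        assert len(self.table) == len(PARAM_NAMES)


@dataclass
class SensitivityReport:
    """Per-subject predicted noise, coefficient ratios, and cohort summaries."""

    per_subject: pd.DataFrame
    summary: dict
    n_flagged: int = 0


def _param_matrix(fits: pd.DataFrame, horizon: int) -> pd.DataFrame:
    sub = fits[fits["horizon"] == horizon].set_index("subject_id")
    return sub[list(PARAM_NAMES)]


def horizon_contrast(fits: pd.DataFrame, alpha_level: float = 0.05) -> ContrastTable:
    """Paired t-test of horizon 6 vs horizon 1 for each of the 10 parameters.

    ``fits`` holds one row per subject x horizon with the coefficient
    columns.  Subjects missing either horizon are dropped with a warning.
    Significance uses the two-sided p against alpha_level / 10 (Bonferroni).
    """
    h1 = _param_matrix(fits, 1)
    h6 = _param_matrix(fits, 6)
    common = h1.index.intersection(h6.index)
    dropped = set(h1.index).symmetric_difference(h6.index)
    if dropped:
        import warnings
        warnings.warn(f"subjects missing a horizon fit dropped: {sorted(map(str, dropped))}")
    h1, h6 = h1.loc[common], h6.loc[common]
    rows = []
    for p in PARAM_NAMES:
        d = h6[p].to_numpy(float) - h1[p].to_numpy(float)
        if len(d) >= 2 and np.std(d) > 0:
            t, pval = stats.ttest_rel(h6[p], h1[p])
        else:
            t, pval = (np.nan, 1.0) if np.allclose(d, 0) else (np.nan, np.nan)
        rows.append({"parameter": p, "mean_diff": float(np.mean(d)) if len(d) else np.nan,
                     "t": float(t), "p_raw": float(pval),
                     "significant": bool(pval < alpha_level / BONFERRONI_FACTOR)})
    return ContrastTable(table=pd.DataFrame(rows), n_subjects=len(common),
                         alpha_level=alpha_level)


def predicted_sigma(cR_mu, c0_beta):
    """Predicted logistic decision noise 1/(2 sqrt(2) |cR_mu| c0_beta), points."""
    denom = 2.0 * np.sqrt(2.0) * np.abs(np.asarray(cR_mu, float)) \
        * np.asarray(c0_beta, float)
    with np.errstate(divide="ignore"):
        return np.where(denom != 0, 1.0 / denom, np.nan)


def predicted_sigma_check(ddm_fits: pd.DataFrame, logistic_fits: pd.DataFrame) -> pd.DataFrame:
    """Correlate diffusion-predicted noise with fitted logistic noise, per horizon.

    ``logistic_fits`` holds one row per subject x horizon x info_condition
    with a ``sigma`` column; the logistic sigma is averaged over the two
    information conditions per subject before correlating.  Returns rows
    (horizon, pearson_r, pearson_p, spearman_r, n).  Requires >= 3 subjects.
    """
    out = []
    for h in (1, 6):
        dd = ddm_fits[ddm_fits["horizon"] == h].set_index("subject_id")
        lg = (logistic_fits[logistic_fits["horizon"] == h]
              .groupby("subject_id")["sigma"].mean())
        common = dd.index.intersection(lg.index)
        if len(common) < 3:
            raise ValueError("need at least 3 subjects with both fits for a correlation")
        pred = predicted_sigma(dd.loc[common, "cR_mu"], dd.loc[common, "c0_beta"])
        obs = lg.loc[common].to_numpy(float)
        ok = np.isfinite(pred) & np.isfinite(obs)
        r, p = stats.pearsonr(pred[ok], obs[ok])
        rs, _ = stats.spearmanr(pred[ok], obs[ok])
        out.append({"horizon": h, "pearson_r": float(r), "pearson_p": float(p),
                    "spearman_r": float(rs), "n": int(ok.sum())})
    return pd.DataFrame(out)


def sensitivity_ratios(ddm_fits: pd.DataFrame,
                       logistic_fits: pd.DataFrame | None = None,
                       eps: float = 1e-8) -> SensitivityReport:
    """Per-subject horizon ratios of cR_mu and c0_beta and predicted noise.

    For each subject: ratio_cR_mu = cR_mu(h6)/cR_mu(h1), ratio_c0_beta =
    c0_beta(h6)/c0_beta(h1), their product (= predicted sigma(h1)/sigma(h6),
    exactly, by construction), and predicted sigma per horizon.  Subjects
    with |denominator| <= eps are flagged and excluded from the cohort
    summaries.  If logistic fits are given, the per-condition fitted
    sigma(h1)/sigma(h6) ratios are added.  Summaries report the median
    (primary) and mean of each ratio across unflagged subjects, plus the
    dominant contributor: the coefficient with the larger |log median ratio|.
    """
    h1 = _param_matrix(ddm_fits, 1)
    h6 = _param_matrix(ddm_fits, 6)
    common = h1.index.intersection(h6.index)
    rows = []
    for sid in common:
        c1, c6 = h1.loc[sid], h6.loc[sid]
        flagged = abs(c1["cR_mu"]) <= eps or abs(c1["c0_beta"]) <= eps
        r_mu = c6["cR_mu"] / c1["cR_mu"] if not flagged else np.nan
        r_beta = c6["c0_beta"] / c1["c0_beta"] if not flagged else np.nan
        row = {
            "subject_id": sid,
            "ratio_cR_mu": r_mu,
            "ratio_c0_beta": r_beta,
            "predicted_sigma_ratio_h1_h6": r_mu * r_beta,
            "predicted_sigma_h1": float(predicted_sigma(c1["cR_mu"], c1["c0_beta"])),
            "predicted_sigma_h6": float(predicted_sigma(c6["cR_mu"], c6["c0_beta"])),
            "flagged": flagged,
        }
        if logistic_fits is not None:
            for cond in ("unequal_13", "equal_22"):
                s1 = logistic_fits[(logistic_fits["subject_id"] == sid)
                                   & (logistic_fits["horizon"] == 1)
                                   & (logistic_fits["info_condition"] == cond)]["sigma"]
                s6 = logistic_fits[(logistic_fits["subject_id"] == sid)
                                   & (logistic_fits["horizon"] == 6)
                                   & (logistic_fits["info_condition"] == cond)]["sigma"]
                row[f"logistic_sigma_ratio_h1_h6_{cond}"] = (
                    float(s1.iloc[0] / s6.iloc[0]) if len(s1) and len(s6) else np.nan)
        rows.append(row)
    per_subject = pd.DataFrame(rows)
    good = per_subject[~per_subject["flagged"]]
    summary: dict = {"n_subjects": len(per_subject), "n_used": len(good)}
    ratio_cols = [c for c in per_subject.columns
                  if c.startswith(("ratio_", "predicted_sigma_ratio", "logistic_sigma_ratio"))]
    for col in ratio_cols:
        vals = good[col].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        summary[f"median_{col}"] = float(np.median(vals)) if vals.size else float("nan")
        summary[f"mean_{col}"] = float(np.mean(vals)) if vals.size else float("nan")
    m_mu = summary.get("median_ratio_cR_mu", float("nan"))
    m_beta = summary.get("median_ratio_c0_beta", float("nan"))
    if np.isfinite(m_mu) and np.isfinite(m_beta) and m_mu > 0 and m_beta > 0:
        summary["dominant_contributor"] = (
            "cR_mu" if abs(np.log(m_mu)) >= abs(np.log(m_beta)) else "c0_beta")
    else:
        summary["dominant_contributor"] = "undetermined"
    return SensitivityReport(per_subject=per_subject, summary=summary,
                             n_flagged=int(per_subject["flagged"].sum()))


def theoretical_curves(coeffs, delta_I: int = 0,
                       delta_R_grid=None) -> pd.DataFrame:
    """Numeric choice-probability and mean-RT curves at fitted parameters.

    Evaluates the closed forms over a dR grid (default -30..30) at a fixed
    dI; rows where the resolved threshold is invalid carry NaNs.
    """
    from . import ddm_core
    if delta_R_grid is None:
        delta_R_grid = np.linspace(-30, 30, 121)
    rows = []
    for dr in np.asarray(delta_R_grid, float):
        try:
            res = ddm_core.resolve_parameters(coeffs, float(dr), delta_I)
            p = ddm_core.choice_probability(res)
            rt = ddm_core.mean_rt(res)
        except ddm_core.InvalidParameterError:
            p, rt = np.nan, np.nan
        rows.append({"delta_R": float(dr), "delta_I": delta_I,
                     "p_left": p, "mean_rt": rt})
    return pd.DataFrame(rows)
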