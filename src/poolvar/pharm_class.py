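"""Dose-response fitting and functional classification of receptor variants.

Variant pharmacology is summarised by logistic fits of normalised response
(% of wild type) against log10 agonist dose: a four-parameter logistic for
the cAMP second-messenger assay, a three-parameter logistic (Hill slope
fixed at 1) for beta-arrestin-2 coupling, whose raw readout is first
reduced to an area-under-curve above baseline.  Variants are compared to
wild type by extra-sum-of-squares F-tests (or t-tests on replicate-level
estimates) on Emax and logEC50, and labelled cLoF / pLoF / WT-like / GoF.

Variants with no ligand response at all follow a separate complete-LoF
path: no curve is fitted and the relative Emax is read from the response
at the top dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_cohort import four_pl


@dataclass
class CurveFit:
    emax: float
    logec50: float
    basal: float
    hill: float
    se: dict
    ss: float
    n: int
    n_params: int
    converged: bool
    flat: bool = False            # complete-LoF path: no fit performed
    emax_at_top: float | None = None
    ec50_reliable: bool = True


def _fit_logistic(x: np.ndarray, y: np.ndarray, n_params: int) -> tuple[np.ndarray, float, bool]:
    """Multi-start least squares of the logistic in log10(dose).

    Parameter vector: (basal, emax, logec50[, hill]); 3-parameter fits fix
    the Hill slope at 1.
    """
    lo, hi = float(np.min(y)), float(np.max(y))
    starts = np.arange(np.min(x) - 2.0, np.max(x) + 2.01, 1.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        basal, emax, logec50 = theta[:3]
        hill = theta[3] if n_params == 4 else 1.0
        return four_pl(x, basal, emax, logec50, hill) - y

    best = None
    for s in starts:
        theta0 = np.array([lo, hi, s] + ([1.0] if n_params == 4 else []))
        try:
            res = optimize.least_squares(resid, theta0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("logistic fit failed from every start")
    ss = float(2.0 * best.cost)
    return best.x, ss, bool(best.success)


def fit_dose_response(data: pd.DataFrame, n_params: int = 4, flat_range: float = 10.0) -> CurveFit:
    """Fit a logistic dose-response curve to replicate measurements.

    ``data`` needs columns dose (molar) and response (% wild type).  If the
    spread of per-dose mean responses is below ``flat_range`` the variant
    is treated as having no ligand response: no curve is fitted and the
    relative Emax is reported from the top-dose responses alone.
    """
    if n_params not in (3, 4):
        raise ValueError("n_params must be 3 or 4")
    doses = data["dose"].to_numpy(dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    y = data["response"].to_numpy(dtype=float)
    x = np.log10(doses)
    if len(np.unique(x)) < n_params:
        raise ValueError(f"need >= {n_params} distinct doses for a {n_params}-parameter fit")

    means = pd.Series(y).groupby(pd.Series(x)).mean()
    if float(means.max() - means.min()) < flat_range:
        top = float(np.mean(y[x == np.max(x)]))
        return CurveFit(
            emax=top, logec50=float("nan"), basal=float(means.min()), hill=float("nan"),
            se={}, ss=float("nan"), n=len(y), n_params=n_params,
            converged=False, flat=True, emax_at_top=top, ec50_reliable=False,
        )

    theta, ss, ok = _fit_logistic(x, y, n_params)
    basal, emax, logec50 = theta[:3]
    hill = theta[3] if n_params == 4 else 1.0
    dof = len(y) - n_params
    se: dict = {}
    if dof > 0:
        # Gauss-Newton covariance from the Jacobian at the optimum
        def resid(t: np.ndarray) -> np.ndarray:
            b, e, l = t[:3]
            h = t[3] if n_params == 4 else 1.0
            return four_pl(x, b, e, l, h) - y

        J = _jacobian(resid, theta, len(y))
        try:
            cov = np.linalg.inv(J.T @ J) * ss / dof
            names = ["basal", "emax", "logec50"] + (["hill"] if n_params == 4 else [])
            se = {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
        except np.linalg.LinAlgError:
            se = {}
    reliable = (np.min(x) - 2.0) <= logec50 <= (np.max(x) + 2.0)
    return CurveFit(
        emax=float(emax), logec50=float(logec50), basal=float(basal), hill=float(hill),
        se=se, ss=ss, n=len(y), n_params=n_params, converged=ok, ec50_reliable=bool(reliable),
    )


def _jacobian(resid, theta: np.ndarray, n: int) -> np.ndarray:
    eps = 1e-7
    J = np.empty((n, len(theta)))
    r0 = resid(theta)
    for j in range(len(theta)):
        t = theta.copy()
        t[j] += eps
        J[:, j] = (resid(t) - r0) / eps
    return J


def extra_ss_ftest(
    data_v: pd.DataFrame,
    data_wt: pd.DataFrame,
    shared_param: str,
    n_params: int = 4,
) -> tuple[float, float]:
    """Extra-sum-of-squares F-test for one parameter differing from wild type.

    Full model: independent logistic fits to variant and wild-type data.
    Reduced model: a joint fit in which ``shared_param`` ('emax' or
    'logec50') is constrained equal across the two curves.  Returns
    (F, p) with F = ((SS_r - SS_f)/(df_r - df_f)) / (SS_f / df_f).
    """
    if shared_param not in ("emax", "logec50"):
        raise ValueError("shared_param must be 'emax' or 'logec50'")
    xv = np.log10(data_v["dose"].to_numpy(dtype=float))
    yv = data_v["response"].to_numpy(dtype=float)
    xw = np.log10(data_wt["dose"].to_numpy(dtype=float))
    yw = data_wt["response"].to_numpy(dtype=float)

    _, ss_v, _ = _fit_logistic(xv, yv, n_params)
    _, ss_w, _ = _fit_logistic(xw, yw, n_params)
    ss_full = ss_v + ss_w
    n = len(yv) + len(yw)
    df_full = n - 2 * n_params

    share_idx = 1 if shared_param == "emax" else 2

    def resid(theta: np.ndarray) -> np.ndarray:
        shared = theta[0]
        tv = list(theta[1:n_params])   # variant free params
        tw = list(theta[n_params : 2 * n_params - 1])
        pv = tv[:share_idx] + [shared] + tv[share_idx:]
        pw = tw[:share_idx] + [shared] + tw[share_idx:]
        hv = pv[3] if n_params == 4 else 1.0
        hw = pw[3] if n_params == 4 else 1.0
        rv = four_pl(xv, pv[0], pv[1], pv[2], hv) - yv
        rw = four_pl(xw, pw[0], pw[1], pw[2], hw) - yw
        return np.concatenate([rv, rw])

    best = None
    for s in np.arange(min(xv.min(), xw.min()) - 2.0, max(xv.max(), xw.max()) + 2.01, 1.0):
        shared0 = float(np.mean([yv.max(), yw.max()])) if shared_param == "emax" else s
        free_v = [yv.min(), s] if shared_param == "emax" else [yv.min(), yv.max()]
        free_w = [yw.min(), s] if shared_param == "emax" else [yw.min(), yw.max()]
        if n_params == 4:
            free_v, free_w = free_v + [1.0], free_w + [1.0]
        theta0 = np.array([shared0] + free_v + free_w)
        try:
            res = optimize.least_squares(resid, theta0, method="lm", max_nfev=4000)
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("reduced-model fit failed")
    ss_red = float(2.0 * best.cost)
    df_red = n - (2 * n_params - 1)
    num = max(ss_red - ss_full, 0.0) / (df_red - df_full)
    den = ss_full / df_full
    if den <= 0:
        return float("inf"), 0.0
    F = num / den
    p = float(stats.f.sf(F, df_red - df_full, df_full))
    return float(F), p


def compare_to_wt(
    data_v: pd.DataFrame,
    data_wt: pd.DataFrame,
    method: str = "ftest",
    n_params: int = 4,
) -> dict:
    """Compare a variant's Emax and logEC50 to wild type.

    ``method='ftest'`` applies the extra-sum-of-squares F-test on pooled
    curve data (second-messenger assay); ``method='ttest'`` fits each
    replicate separately and compares replicate-level parameter estimates
    with two-sided t-tests (coupling assay).  Flat (complete-LoF) variant
    data short-circuits to a top-dose t-test on Emax.
    """
    fit_v = fit_dose_response(data_v, n_params=n_params)
    fit_wt = fit_dose_response(data_wt, n_params=n_params)
    if fit_v.flat:
        xv = np.log10(data_v["dose"].to_numpy(dtype=float))
        xw = np.log10(data_wt["dose"].to_numpy(dtype=float))
        top_v = data_v["response"].to_numpy(dtype=float)[xv == xv.max()]
        top_w = data_wt["response"].to_numpy(dtype=float)[xw == xw.max()]
        p_emax = float(stats.ttest_ind(top_v, top_w).pvalue) if min(len(top_v), len(top_w)) > 1 else 0.0
        return {
            "p_emax": p_emax, "p_ec50": float("nan"),
            "emax_ratio": fit_v.emax_at_top / fit_wt.emax if fit_wt.emax else float("nan"),
            "ec50_fold": float("nan"), "fit_v": fit_v, "fit_wt": fit_wt, "flat": True,
        }
    if method == "ftest":
        _, p_emax = extra_ss_ftest(data_v, data_wt, "emax", n_params)
        _, p_ec50 = extra_ss_ftest(data_v, data_wt, "logec50", n_params)
    elif method == "ttest":
        em_v, ec_v = _replicate_params(data_v, n_params)
        em_w, ec_w = _replicate_params(data_wt, n_params)
        if min(len(em_v), len(em_w)) < 2:
            raise ValueError("t-test comparison needs >= 2 replicates per arm")
        p_emax = float(stats.ttest_ind(em_v, em_w).pvalue)
        p_ec50 = float(stats.ttest_ind(ec_v, ec_w).pvalue)
    else:
        raise ValueError("method must be 'ftest' or 'ttest'")
    return {
        "p_emax": p_emax,
        "p_ec50": p_ec50,
        "emax_ratio": fit_v.emax / fit_wt.emax if fit_wt.emax else float("nan"),
        "ec50_fold": 10.0 ** (fit_v.logec50 - fit_wt.logec50),
        "fit_v": fit_v,
        "fit_wt": fit_wt,
        "flat": False,
    }


def _replicate_params(data: pd.DataFrame, n_params: int) -> tuple[list[float], list[float]]:
    emaxs, ecs = [], []
    for _, grp in data.groupby("replicate"):
        f = fit_dose_response(grp, n_params=n_params)
        emaxs.append(f.emax)
        ecs.append(f.logec50)
    return emaxs, ecs


def arrestin_auc(
    time: np.ndarray,
    signal: np.ndarray,
    baseline_window: tuple[float, float],
    stim_window: tuple[float, float],
    clip_below_baseline: bool = True,
) -> float:
    """Area under a kinetic trace above its pre-stimulation baseline.

    The baseline is the mean signal inside ``baseline_window``; the AUC is
    the trapezoidal integral of (signal - baseline) over ``stim_window``,
    with below-baseline excursions clipped at zero by default (receptor
    coupling cannot be negative).
    """
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if baseline_window[1] > stim_window[0]:
        raise ValueError("baseline window must precede the stimulation window")
    base_mask = (time >= baseline_window[0]) & (time <= baseline_window[1])
    stim_mask = (time >= stim_window[0]) & (time <= stim_window[1])
    if not base_mask.any() or not stim_mask.any():
        raise ValueError("empty baseline or stimulation window")
    baseline = float(signal[base_mask].mean())
    excess = signal[stim_mask] - baseline
    if clip_below_baseline:
        excess = np.clip(excess, 0.0, None)
    return float(np.trapezoid(excess, time[stim_mask]))


@dataclass
class ClassCriteria:
    """Thresholds of the functional classification rule.

    A variant with no fit (flat response) or relative Emax below
    ``clof_emax_max`` %WT is complete LoF.  Otherwise significance at
    ``alpha`` on Emax (below/above WT) or EC50 (right/left shift) drives
    partial LoF / GoF; anything else is WT-like.
    """

    clof_emax_max: float = 20.0
    alpha: float = 0.05


@dataclass
class FunctionalClass:
    label: str
    evidence: dict = field(default_factory=dict)
    ambiguous: bool = False


def classify_variant(evidence: dict, criteria: ClassCriteria | None = None) -> FunctionalClass:
    """Assign cLoF / pLoF / WT-like / GoF from comparison evidence.

    ``evidence`` is the output of :func:`compare_to_wt` (keys p_emax,
    p_ec50, emax_ratio, ec50_fold, flat).  Conflicting signals (both LoF
    and GoF directions significant) are flagged ambiguous and the more
    severe label reported.  The rule is a pure function of its inputs.
    """
    if criteria is None:
        criteria = ClassCriteria()
    flat = bool(evidence.get("flat", False))
    emax_ratio = evidence.get("emax_ratio", float("nan"))
    if flat or (np.isfinite(emax_ratio) and emax_ratio * 100.0 < criteria.clof_emax_max):
        return FunctionalClass("cLoF", evidence)
    p_emax = evidence.get("p_emax", float("nan"))
    p_ec50 = evidence.get("p_ec50", float("nan"))
    ec50_fold = evidence.get("ec50_fold", float("nan"))
    lof = (np.isfinite(p_emax) and p_emax < criteria.alpha and emax_ratio < 1.0) or (
        np.isfinite(p_ec50) and p_ec50 < criteria.alpha and np.isfinite(ec50_fold) and ec50_fold > 1.0
    )
    gof = (np.isfinite(p_emax) and p_emax < criteria.alpha and emax_ratio > 1.0) or (
        np.isfinite(p_ec50) and p_ec50 < criteria.alpha and np.isfinite(ec50_fold) and ec50_fold < 1.0
    )
    if lof and gof:
        return FunctionalClass("pLoF", evidence, ambiguous=True)
    if lof:
        return FunctionalClass("pLoF", evidence)
    if gof:
        return FunctionalClass("GoF", evidence)
    return FunctionalClass("WT-like", evidence)


def classification_table(results: dict[str, FunctionalClass]) -> pd.DataFrame:
    rows = []
    for vid, fc in sorted(results.items()):
        ev = fc.evidence
        rows.append(
            (
                vid, fc.label, fc.ambiguous,
                ev.get("emax_ratio", float("nan")), ev.get("ec50_fold", float("nan")),
                ev.get("p_emax", float("nan")), ev.get("p_ec50", float("nan")),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "label", "ambiguous", "emax_ratio", "ec50_fold", "p_emax", "p_ec50"],
    )
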