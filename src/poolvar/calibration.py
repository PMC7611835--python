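"""VAF-threshold recalibration of pooled candidate calls.

Candidate calls are labelled true or false positive from per-individual
validation sequencing, the discriminating power of the variant allele
fraction is summarised by a ROC curve, and the operating VAF cut-off is
re-chosen so that every validated true positive is retained while as many
false positives as possible are removed.

Note on "specificity": with validation labels available only for calls
(not for all negative sites), the retained-call precision TP/(TP+FP) is
the operative figure of merit; it is reported alongside the classical
specificity (fraction of false-positive calls removed), clearly labelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def label_calls(
    calls: pd.DataFrame,
    validations: pd.DataFrame,
    pool_design: pd.DataFrame,
) -> pd.DataFrame:
    """Attach TP/FP labels to candidate calls from validation records.

    ``validations`` is long format with columns (pool_id, pos,
    individual_id, carrier, zygosity): every validation attempt for pool
    members at a called site.  A call is TP iff any member of its pool is a
    confirmed carrier at that site.  Calls whose (pool, site) has no
    validation attempt are flagged ``unresolved`` and must be excluded from
    ROC analysis.
    """
    need = {"pool_id", "pos", "individual_id", "carrier"}
    if not need.issubset(validations.columns):
        raise ValueError(f"validations must have columns {sorted(need)}")
    confirmed = validations[validations.carrier].groupby(["pool_id", "pos"]).size()
    attempted = set(map(tuple, validations[["pool_id", "pos"]].itertuples(index=False)))
    out = calls.copy()
    labels, n_carriers, unresolved = [], [], []
    for row in out.itertuples():
        key = (row.pool_id, row.pos)
        if key not in attempted:
            labels.append("")
            n_carriers.append(0)
            unresolved.append(True)
            continue
        k = int(confirmed.get(key, 0))
        labels.append("TP" if k > 0 else "FP")
        n_carriers.append(k)
        unresolved.append(False)
    out["label"] = labels
    out["validated_carriers"] = n_carriers
    out["unresolved"] = unresolved
    return out


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    ppv: np.ndarray            # retained-call precision TP/(TP+FP)
    specificity: np.ndarray    # fraction of FP calls removed
    auc: float                 # rank statistic P(VAF_TP > VAF_FP) + 0.5 P(tie)
    auc_trapezoid: float       # trapezoidal integral of the empirical ROC
    n_tp: int
    n_fp: int


def _labeled_vafs(labeled: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "unresolved" in labeled.columns:
        usable = labeled[~labeled["unresolved"].astype(bool)]
    else:
        usable = labeled
    tp = usable.loc[usable.label == "TP", "vaf"].to_numpy(dtype=float)
    fp = usable.loc[usable.label == "FP", "vaf"].to_numpy(dtype=float)
    return tp, fp


def roc_analysis(labeled: pd.DataFrame) -> ROCResult:
    """ROC of VAF as a predictor of validation outcome.

    The AUC is the two-sample rank statistic (ties counted half), which
    equals the trapezoidal integral of the empirical ROC curve; both are
    computed and reported.
    """
    tp, fp = _labeled_vafs(labeled)
    if len(tp) == 0 or len(fp) == 0:
        raise ValueError("ROC requires both TP and FP labels")
    scores = np.concatenate([tp, fp])
    ranks = stats.rankdata(scores)
    auc = (ranks[: len(tp)].sum() - len(tp) * (len(tp) + 1) / 2.0) / (len(tp) * len(fp))

    grid = np.unique(scores)
    sens = np.array([(tp >= t).mean() for t in grid])
    spec = np.array([(fp < t).mean() for t in grid])
    with np.errstate(invalid="ignore"):
        kept_tp = np.array([(tp >= t).sum() for t in grid], dtype=float)
        kept_fp = np.array([(fp >= t).sum() for t in grid], dtype=float)
        ppv = np.where(kept_tp + kept_fp > 0, kept_tp / np.maximum(kept_tp + kept_fp, 1), np.nan)

    # empirical ROC polygon including the (0,0) and (1,1) anchors
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])[::-1]
    tpr = np.concatenate([[1.0], sens, [0.0]])[::-1]
    auc_trap = float(np.trapezoid(tpr, fpr))

    return ROCResult(grid, sens, ppv, spec, float(auc), auc_trap, len(tp), len(fp))


def choose_vaf_cutoff(labeled: pd.DataFrame, rule: str = "retain-all-TP", grid_step: float = 1e-4) -> float:
    """Re-choose the operating VAF cut-off from validation labels.

    Under the default rule the cut-off is the largest multiple of
    ``grid_step`` that is <= the smallest TP VAF: it removes as many FP
    calls as possible while (with the inclusive >= comparison) retaining
    every validated TP.
    """
    if rule != "retain-all-TP":
        raise ValueError(f"unknown rule {rule!r}")
    tp, _ = _labeled_vafs(labeled)
    if len(tp) == 0:
        raise ValueError("cannot choose a cutoff without any TP call")
    min_tp = float(np.min(tp))
    cutoff = float(np.floor(min_tp / grid_step + 1e-9) * grid_step)
    if cutoff > min_tp:  # floating floor overshoot at grid boundaries
        cutoff = min_tp
    assert np.all(tp >= cutoff), "cutoff construction must retain every TP"
    return cutoff


def confusion_at(labeled: pd.DataFrame, threshold: float) -> dict:
    """Retention counts and rates at an (inclusive) VAF threshold.

    ``ppv_percent`` — TP/(TP+FP) among retained calls — is the operative
    precision figure; ``specificity_percent`` is the classical fraction of
    FP calls removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    tp, fp = _labeled_vafs(labeled)
    tp_kept = int((tp >= threshold).sum())
    fp_kept = int((fp >= threshold).sum())
    retained = tp_kept + fp_kept
    return {
        "threshold": threshold,
        "tp_total": len(tp),
        "fp_total": len(fp),
        "tp_retained": tp_kept,
        "fp_retained": fp_kept,
        "sensitivity_percent": round(100.0 * tp_kept / len(tp), 2) if len(tp) else float("nan"),
        "ppv_percent": round(100.0 * tp_kept / retained, 2) if retained else float("nan"),
        "specificity_percent": round(100.0 * (len(fp) - fp_kept) / len(fp), 2) if len(fp) else float("nan"),
    }


def concordance(
    carriers_a: set[tuple[str, str]],
    carriers_b: set[tuple[str, str]],
    overlap_ids: set[str],
) -> float:
    """Agreement of two per-individual carrier call sets on shared samples.

    Both sets hold (individual_id, variant_id) carriages; only individuals
    in ``overlap_ids`` are compared.  Returns |A & B| / |A | B| over the
    overlap (1.0 when both methods detect exactly the same carriages).
    """
    if not overlap_ids:
        raise ValueError("overlap of individuals is empty")
    a = {c for c in carriers_a if c[0] in overlap_ids}
    b = {c for c in carriers_b if c[0] in overlap_ids}
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def write_roc_tsv(roc: ROCResult, path: str) -> None:
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "ppv": roc.ppv,
            "specificity": roc.specificity,
        }
    ).to_csv(path, sep="\t", index=False)


def write_calibration_report(roc: ROCResult, cutoff: float, confusion: dict, path: str) -> None:
    report = {
        "auc": roc.auc,
        "auc_trapezoid": roc.auc_trapezoid,
        "n_tp": roc.n_tp,
        "n_fp": roc.n_fp,
        "chosen_cutoff": cutoff,
        "confusion_at_cutoff": confusion,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
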