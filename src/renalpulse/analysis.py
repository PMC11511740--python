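"""Analysis layer: Sobol sensitivity, calibration, ROC/Youden, summaries.

The Sobol indices use the Saltelli design with scrambled Sobol' sequences
(scipy.stats.qmc) and the Saltelli-2010 first-order / Jansen total-order
estimators, with bootstrap confidence intervals.  The ROC scan treats
every observed score as a candidate threshold and selects the cut-off by
Youden's index J = sensitivity + specificity - 1.  Descriptive summaries
use linear-interpolation quartiles and the 1.5 IQR outlier rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import qmc

# ----------------------------------------------------------------------
# Sobol sensitivity
# ----------------------------------------------------------------------


@dataclass
class SobolResult:
    parameters: list[str]
    S1: np.ndarray
    ST: np.ndarray
    S1_ci: np.ndarray      # (k, 2) bootstrap percentile intervals
    ST_ci: np.ndarray
    base_n: int
    n_evaluations: int

    def ranking(self) -> list[str]:
        """Parameters ordered by decreasing total-order index."""
        order = np.argsort(self.ST)[::-1]
        return [self.parameters[i] for i in order]


def sobol_sensitivity(parameter_ranges: dict[str, tuple[float, float]],
                      model, base_n: int = 256, seed: int = 0,
                      n_bootstrap: int = 200) -> SobolResult:
    """Variance-based global sensitivity of ``model`` to its parameters.

    ``model`` maps a dict {parameter: value} to a scalar.  Uniform
    sampling over ``parameter_ranges`` with a Saltelli design costs
    base_n * (k + 2) evaluations.  Deterministic per seed.
    """
    names = list(parameter_ranges)
    k = len(names)
    if k < 2:
        raise ValueError("need at least two parameters")
    if base_n < 64:
        raise ValueError("base_n must be >= 64")
    lo = np.array([parameter_ranges[n][0] for n in names])
    hi = np.array([parameter_ranges[n][1] for n in names])

    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=seed)
    base = sampler.random(base_n)
    A = lo + base[:, :k] * (hi - lo)
    B = lo + base[:, k:] * (hi - lo)

    def run(X):
        out = np.empty(len(X))
        for i, x in enumerate(X):
            try:
                out[i] = model(dict(zip(names, x)))
            except Exception as exc:
                raise RuntimeError(
                    f"model evaluation failed at {dict(zip(names, x))}") from exc
        return out

    fA = run(A)
    fB = run(B)
    fAB = np.empty((base_n, k))
    for j in range(k):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        fAB[:, j] = run(ABj)

    def estimate(idx):
        a, b, ab = fA[idx], fB[idx], fAB[idx]
        var = np.var(np.concatenate([a, b]))
        if var == 0:
            return np.zeros(k), np.zeros(k)
        s1 = np.array([np.mean(b * (ab[:, j] - a)) for j in range(k)]) / var
        st = np.array([0.5 * np.mean((a - ab[:, j]) ** 2) for j in range(k)]) / var
        return s1, st

    all_idx = np.arange(base_n)
    S1, ST = estimate(all_idx)
    rng = np.random.default_rng(seed + 1)
    boots1 = np.empty((n_bootstrap, k)); bootst = np.empty((n_bootstrap, k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, base_n, base_n)
        boots1[b], bootst[b] = estimate(idx)
    S1_ci = np.percentile(boots1, [2.5, 97.5], axis=0).T
    ST_ci = np.percentile(bootst, [2.5, 97.5], axis=0).T
    return SobolResult(names, S1, ST, S1_ci, ST_ci, base_n, base_n * (k + 2))


# ----------------------------------------------------------------------
# ROC / Youden
# ----------------------------------------------------------------------

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    cutoff_sensitivity: float
    cutoff_specificity: float
    youden_j: float
    positive_class: str
    orientation: str       # 'greater': positive when score >= threshold


def roc_analysis(scores, labels, positive_class,
                 orientation: str = "auto") -> ROCResult:
    """ROC scan over every observed score as a candidate threshold.

    Orientation is chosen automatically so that AUC >= 0.5 unless forced
    ('greater' = the positive class has higher scores).  AUC is the
    trapezoidal area of the scan curve; the reported cut-off maximises
    Youden's J, ties broken toward higher sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("need both classes present")

    def scan(greater: bool):
        thr = np.unique(scores)
        sens = np.empty(len(thr)); spec = np.empty(len(thr))
        for i, t in enumerate(thr):
            pred = scores >= t if greater else scores <= t
            sens[i] = np.mean(pred[pos])
            spec[i] = np.mean(~pred[~pos])
        fpr = 1.0 - spec
        order = np.lexsort((sens, fpr))  # ascending fpr, then tpr
        x = np.concatenate([[0.0], fpr[order], [1.0]])
        y = np.concatenate([[0.0], sens[order], [1.0]])
        auc = float(np.trapezoid(y, x))
        return thr, sens, spec, auc

    if orientation == "auto":
        thr, sens, spec, auc = scan(True)
        orientation = "greater"
        if auc < 0.5:
            thr, sens, spec, auc = scan(False)
            orientation = "less"
    elif orientation in ("greater", "less"):
        thr, sens, spec, auc = scan(orientation == "greater")
    else:
        raise ValueError("orientation must be 'auto', 'greater' or 'less'")

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    best = best[np.argmax(sens[best])]  # ties toward higher sensitivity
    return ROCResult(thr, sens, spec, auc, float(thr[best]),
                     float(sens[best]), float(spec[best]), float(j[best]),
                     str(positive_class), orientation)


def concordance_auc(scores, labels, positive_class) -> float:
    """Pairwise-concordance AUC (ties count one half): independent oracle."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive_class]
    neg = scores[labels != positive_class]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (len(pos) * len(neg)))


# ----------------------------------------------------------------------
# descriptive summaries
# ----------------------------------------------------------------------

@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float              # population SD
    median: float
    q1: float
    q3: float
    iqr: float
    outliers: np.ndarray   # values outside [q1 - 1.5 iqr, q3 + 1.5 iqr]


def summarize(groups: dict[str, np.ndarray]) -> dict[str, SummaryStats]:
    """Per-group mean/SD, linear-interpolation quartiles and 1.5 IQR outliers."""
    out = {}
    for name, values in groups.items():
        x = np.asarray(values, dtype=float)
        if x.size == 0:
            raise ValueError(f"group '{name}' is empty")
        q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        mask = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        out[name] = SummaryStats(int(x.size), float(x.mean()),
                                 float(x.std()), float(med), float(q1),
                                 float(q3), float(iqr), x[mask])
    return out


# ----------------------------------------------------------------------
# stage calibration
# ----------------------------------------------------------------------

@dataclass
class CalibrationResult:
    scaling: object                # calibrated DiseaseScaling
    achieved_ri: float
    target_ri: float
    met: bool
    n_evaluations: int
    history: list


def calibrate_stage(evaluate, target_ri: float, scaling,
                    bounds_rel: float = 0.20, rel_tol: float = 0.05,
                    max_evaluations: int = 60) -> CalibrationResult:
    """Tune the renal radius / PVR / PVC multipliers of a disease stage.

    ``evaluate(scaling) -> mean RI`` runs the model on a (small)
    population.  Only the three renal tunables move — a golden-section
    line search per coordinate within +-``bounds_rel`` of the stage's
    table value, cycling until the achieved mean RI is within ``rel_tol``
    of the target or the evaluation budget is exhausted (flagged, best
    found returned).  All other stage parameters are left untouched.
    """
    if not 0.0 < target_ri < 1.0:
        raise ValueError("target RI must lie in (0, 1)")
    tunables = ("renal_radius", "renal_pvr", "renal_pvc")
    table_vals = {
        "renal_radius": scaling.renal_radius
        if scaling.renal_radius is not None else scaling.radius_factor("renal_main_l"),
        "renal_pvr": scaling.renal_pvr
        if scaling.renal_pvr is not None else scaling.pvr,
        "renal_pvc": scaling.renal_pvc
        if scaling.renal_pvc is not None else scaling.pvc,
    }
    current = replace(scaling, **{k: v for k, v in table_vals.items()})

    evals = 0
    history = []

    def cost(sc):
        nonlocal evals
        ri = evaluate(sc)
        evals += 1
        history.append(({t: getattr(sc, t) for t in tunables}, ri))
        return ri

    phi = (math.sqrt(5.0) - 1.0) / 2.0
    best_ri = cost(current)
    if abs(best_ri - target_ri) / target_ri < rel_tol:
        return CalibrationResult(current, best_ri, target_ri, True, evals, history)

    best = current
    while evals < max_evaluations:
        improved = False
        for t in tunables:
            centre = table_vals[t]
            a, b = centre * (1 - bounds_rel), centre * (1 + bounds_rel)
            x1 = b - phi * (b - a)
            x2 = a + phi * (b - a)
            f1 = abs(cost(replace(best, **{t: x1})) - target_ri)
            f2 = abs(cost(replace(best, **{t: x2})) - target_ri)
            for _ in range(6):
                if evals >= max_evaluations:
                    break
                if f1 < f2:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - phi * (b - a)
                    f1 = abs(cost(replace(best, **{t: x1})) - target_ri)
                else:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + phi * (b - a)
                    f2 = abs(cost(replace(best, **{t: x2})) - target_ri)
            x_best, f_best = (x1, f1) if f1 < f2 else (x2, f2)
            if f_best < abs(best_ri - target_ri):
                best = replace(best, **{t: x_best})
                best_ri = target_ri + f_best if best_ri > target_ri else target_ri - f_best
                improved = True
            if f_best / target_ri < rel_tol:
                achieved = evaluate(best)
                return CalibrationResult(best, achieved, target_ri,
                                         abs(achieved - target_ri) / target_ri < rel_tol,
                                         evals + 1, history)
            if evals >= max_evaluations:
                break
        if not improved:
            break
    achieved = evaluate(best)
    met = abs(achieved - target_ri) / target_ri < rel_tol
    return CalibrationResult(best, achieved, target_ri, met, evals + 1, history)
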