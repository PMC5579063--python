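"""Logistic model of side-effect-free status from network dispersion.

A family is *side-effect-free* when none of its relatives is annotated as
associated with drug side effects.  The model is a plain logistic
regression of that binary outcome on the family's network neighbourhood
score (matrix similarity):

    P(free | score) = logistic(beta0 + beta1 * score)

Outcome coding matters for the slope sign: 1 = side-effect-free.  With
beta1 > 0, tighter network neighbourhoods are more likely to be free of
side-effect proteins, and the score at which the predicted probability
crosses 0.5 is threshold_star = -beta0 / beta1.

The module also provides the Pearson correlation between network dispersion
and per-drug side-effect counts used in the anticancer case study.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .core import FamilyTable, SideEffectTable

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticSideEffectModel",
    "label_families",
    "fit_logistic",
    "predict_free_probability",
    "dispersion_sideeffect_correlation",
]


def label_families(
    family_table: FamilyTable,
    side_effects: SideEffectTable,
) -> dict[str, bool]:
    """Label each family side-effect-free iff none of its relatives is
    flagged.  Families none of whose relatives has any flag information are
    missing from the result (logged)."""
    labels: dict[str, bool] = {}
    flags = side_effects.protein_flags
    for fam, relatives in family_table.families.items():
        known = [p for p in relatives if p in flags]
        if not known:
            logger.info("label_families: no flag information for family %s", fam)
            continue
        labels[fam] = not any(flags[p] for p in known)
    return labels


@dataclass
class LogisticSideEffectModel:
    """Fitted logistic regression of P(side-effect-free | network score)."""

    beta0: float
    beta1: float
    llf: float
    slope_pvalue: float
    n_obs: int
    separation_flagged: bool = False

    @property
    def threshold_star(self) -> float:
        """Score at which the predicted free probability crosses 0.5;
        infinite when the slope is 0."""
        if self.beta1 == 0:
            return float("inf")
        return -self.beta0 / self.beta1

    def predict(self, score):
        return predict_free_probability(self, score)

    def summary(self) -> str:
        lines = [
            "Logistic side-effect model  (outcome 1 = side-effect-free)",
            f"  n observations : {self.n_obs}",
            f"  intercept beta0: {self.beta0:+.4f}",
            f"  slope beta1    : {self.beta1:+.4f}  (p = {self.slope_pvalue:.3g})",
            f"  log-likelihood : {self.llf:.4f}",
            f"  P(free | score=0)   : {float(self.predict(0.0)):.3f}",
            f"  0.5-probability score threshold: {self.threshold_star:.3f}",
        ]
        if self.separation_flagged:
            lines.append("  WARNING: (quasi-)complete separation; estimates unstable")
        return "\n".join(lines)


def fit_logistic(
    scores: Sequence[float],
    labels: Sequence[bool] | Sequence[int],
    ridge: float = 0.0,
) -> LogisticSideEffectModel:
    """Maximum-likelihood logistic fit of side-effect-free status on score.

    Plain (unpenalized) fit by default; *ridge* > 0 adds an L2 penalty as a
    guard against separation on small data sets.  Complete separation is
    flagged rather than fatal: the diverging fit's coefficients still carry
    the sign structure and an approximate threshold.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two families in each outcome class")

    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            if ridge > 0:
                res = model.fit_regularized(alpha=ridge, L1_wt=0.0, disp=False)
            else:
                res = model.fit(disp=False, gtol=1e-8, method="bfgs", maxiter=500)
        except Exception as exc:
            raise RuntimeError(f"logistic fit failed: {exc}") from exc
        for w in caught:
            if "separation" in str(w.message).lower() or "Maximum Likelihood" in str(w.message):
                separation = True
    if not np.all(np.isfinite(res.params)):
        separation = True
    if separation:
        logger.warning("fit_logistic: possible separation; coefficients may diverge")

    try:
        slope_p = float(res.pvalues[1])
    except Exception:
        slope_p = float("nan")
    return LogisticSideEffectModel(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        llf=float(res.llf),
        slope_pvalue=slope_p,
        n_obs=int(len(y)),
        separation_flagged=separation,
    )


def predict_free_probability(model: LogisticSideEffectModel, score):
    """logistic(beta0 + beta1 * score), elementwise on array input."""
    eta = model.beta0 + model.beta1 * np.asarray(score, dtype=float)
    return 1.0 / (1.0 + np.exp(-eta))


def dispersion_sideeffect_correlation(
    scores: Mapping[str, float] | Sequence[float],
    counts: Mapping[str, int] | Sequence[float],
) -> dict:
    """Pearson correlation between network scores and side-effect counts.

    When both arguments are mappings they are joined on their shared keys
    (drug or family ids); otherwise they are treated as paired sequences.
    A negative r means drugs whose targets disperse on the network (low
    matrix similarity) report more adverse reactions.  Zero variance in
    either variable makes r undefined (reported as missing).
    """
    if isinstance(scores, Mapping) and isinstance(counts, Mapping):
        keys = sorted(set(scores) & set(counts))
        x = np.array([scores[k] for k in keys], dtype=float)
        y = np.array([counts[k] for k in keys], dtype=float)
        ids = keys
    else:
        x = np.asarray(scores, dtype=float)
        y = np.asarray(counts, dtype=float)
        ids = None
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("dispersion_sideeffect_correlation: zero variance; r undefined")
        return {"r": None, "p_value": None, "n": int(len(x)), "ids": ids}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": int(len(x)), "ids": ids}
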