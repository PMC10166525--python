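"""Univariate confirmation statistics on top-ranked features.

Two-sample pooled-variance Student's t-tests on raw (pre-imputation)
values, with missing and outlier cells excluded — the traditional-analysis
counterpart to the machine-learning ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .relieff import ReliefFResult
from .simulate import CLASS_DB, CLASS_WT, FeatureTable


@dataclass
class FeatureTestResult:
    """Class-wise summary and t-test for one feature.

    Computed on clean raw values (missing/outlier cells excluded); when a
    class retains fewer than 2 clean values the result is marked not
    computable rather than raising.
    """

    feature: str
    n_wt: int
    n_db: int
    mean_wt: float
    mean_db: float
    sem_wt: float
    sem_db: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    computable: bool = True

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "n_wt": self.n_wt,
            "n_db": self.n_db,
            "mean_wt": self.mean_wt,
            "mean_db": self.mean_db,
            "sem_wt": self.sem_wt,
            "sem_db": self.sem_db,
            "t": self.t_statistic,
            "p": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "computable": self.computable,
        }


def _sem(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def ttest_feature(
    values_wt,
    values_db,
    feature: str = "",
    alpha: float = 0.05,
    equal_var: bool = True,
) -> FeatureTestResult:
    """Two-tailed two-sample t-test (pooled variance by default).

    ``equal_var=False`` switches to Welch's correction.  Two groups with
    zero variance and equal means yield t = 0, p = 1 by convention.
    """
    a = np.asarray(values_wt, dtype=float)
    b = np.asarray(values_db, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate case: no within-group variability
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return FeatureTestResult(
        feature=feature,
        n_wt=int(a.size),
        n_db=int(b.size),
        mean_wt=float(a.mean()),
        mean_db=float(b.mean()),
        sem_wt=_sem(a),
        sem_db=_sem(b),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p <= alpha),
        alpha=alpha,
    )


def top_features_report(
    table: FeatureTable,
    ranking: ReliefFResult,
    n_top: int = 5,
    outlier_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> list[FeatureTestResult]:
    """t-tests for the top-ranked features, on clean raw values.

    ``table`` should be the raw (pre-imputation) cohort; cells flagged in
    its missing mask or in ``outlier_mask`` are excluded.  Because the
    tested features were selected for separating the classes, the fraction
    reaching significance is inflated relative to the nominal alpha — the
    report documents the per-feature p-values rather than correcting them.
    """
    if outlier_mask is None:
        outlier_mask = np.zeros_like(table.missing_mask)
    dirty = table.missing_mask | np.asarray(outlier_mask, dtype=bool)
    wt_rows = table.class_rows(CLASS_WT)
    db_rows = table.class_rows(CLASS_DB)
    results = []
    for fname in ranking.ranking[:n_top]:
        (j,) = table.column_index([fname])
        wt = table.values[wt_rows[~dirty[wt_rows, j]], j]
        db = table.values[db_rows[~dirty[db_rows, j]], j]
        if wt.size < 2 or db.size < 2:
            results.append(
                FeatureTestResult(
                    feature=fname,
                    n_wt=int(wt.size),
                    n_db=int(db.size),
                    mean_wt=float(wt.mean()) if wt.size else float("nan"),
                    mean_db=float(db.mean()) if db.size else float("nan"),
                    sem_wt=_sem(wt),
                    sem_db=_sem(db),
                    t_statistic=float("nan"),
                    p_value=float("nan"),
                    significant=False,
                    alpha=alpha,
                    computable=False,
                )
            )
            continue
        results.append(ttest_feature(wt, db, feature=fname, alpha=alpha, equal_var=equal_var))
    return results
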