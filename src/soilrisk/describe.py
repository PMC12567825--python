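"""Descriptive statistics, CV classification, exceedance proportions and
Pearson correlation screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._defaults import METALS
from .io import MetalParams, SampleTable, classify

__all__ = ["summarize", "classify_cv", "pearson_matrix"]


def classify_cv(cv: float, scheme=None) -> str:
    """Dispersion class for a coefficient of variation (percent).

    Default bounds: <20 low, 20–50 moderate, 50–100 high, >100 extreme
    (half-open upper bounds; a CV exactly on a bound takes the lower class).
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    from ._defaults import CV_CLASSES
    return classify(cv, scheme or CV_CLASSES)


def summarize(samples: SampleTable, params: MetalParams) -> pd.DataFrame:
    """Per-metal summary: min/max/mean, sample SD (n−1), CV% and its class,
    and the percentage of samples strictly above the background, screening
    and intervention thresholds.

    Screening/intervention thresholds are pH-banded, so the comparison is
    made row-wise against each sample's own pH band; metals without a
    regulatory value report NaN for that exceedance.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to summarize")
    conc = samples.concentrations()
    ph = samples.df["pH"].to_numpy()

    rows = []
    for m in METALS:
        x = conc[m].to_numpy()
        mean = x.mean()
        sd = x.std(ddof=1)
        cv = 100.0 * sd / mean if mean > 0 else 0.0
        screening = np.array([params.screening_value(m, p) or np.nan for p in ph])
        intervention = np.array([params.intervention_value(m, p) or np.nan for p in ph])
        rows.append({
            "metal": m,
            "min": x.min(), "max": x.max(), "mean": mean, "sd": sd,
            "cv": cv, "cv_class": classify_cv(cv, params.cv_classes),
            "pct_gt_background": 100.0 * np.mean(x > params.background[m]),
            "pct_gt_screening": (np.nan if np.isnan(screening).all()
                                 else 100.0 * np.mean(x > screening)),
            "pct_gt_intervention": (np.nan if np.isnan(intervention).all()
                                    else 100.0 * np.mean(x > intervention)),
        })
    return pd.DataFrame(rows).set_index("metal")


def pearson_matrix(samples: SampleTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metal-by-metal Pearson r and two-sided p-values (t transform).

    Zero-variance columns yield NaN for every pair involving them. No
    multiple-testing correction is applied; the matrix is descriptive.
    """
    conc = samples.concentrations()
    n = len(conc)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    X = conc.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    r = np.full((len(METALS), len(METALS)), np.nan)
    ok = sd > 0
    sub = np.corrcoef(X[:, ok], rowvar=False)
    r[np.ix_(ok, ok)] = sub
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    np.fill_diagonal(p, 0.0)
    idx = list(METALS)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))
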