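"""Geoaccumulation and potential-ecological-risk indices.

Geoaccumulation (Müller) index: ``Igeo = log2(Ci / (1.5 · Bi))``, where the
factor 1.5 absorbs lithogenic variability of the background ``Bi``. The
seven Müller classes are half-open intervals (lo, hi] from "unpolluted"
(Igeo ≤ 0) to "extremely polluted" (Igeo > 5).

Hakanson ecological risk: contamination factor ``Cf = Ci / Cn``, single-metal
risk ``Er = Tr · Cf`` with the metal's toxic-response factor ``Tr``, and the
integrated index ``RI = Σ Er`` over the eight metals. Er classes at
40/80/160/320 and RI classes at 150/300/600 (half-open upper bounds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._defaults import METALS
from .io import ConfigError, MetalParams, SampleTable, classify

__all__ = ["igeo", "igeo_table", "ecological_risk", "risk_class_shares",
           "IndexResult"]


def igeo(ci: float | np.ndarray, bi: float,
         scheme=None) -> tuple[np.ndarray, np.ndarray]:
    """Geoaccumulation index and Müller class for concentration(s) ``ci``
    against background ``bi`` (both mg·kg⁻¹, strictly positive)."""
    ci = np.asarray(ci, dtype=float)
    if np.any(ci <= 0) or bi <= 0:
        raise ValueError("igeo requires positive concentration and background")
    from ._defaults import IGEO_CLASSES
    scheme = scheme or IGEO_CLASSES
    values = np.atleast_1d(np.log2(ci / (1.5 * bi)))
    labels = np.array([classify(v, scheme) for v in values])
    return values, labels


@dataclass
class IndexResult:
    """Per-sample/metal pollution indices and their class labels."""

    igeo: pd.DataFrame          # n × metals
    igeo_class: pd.DataFrame
    cf: pd.DataFrame            # contamination factors
    eri: pd.DataFrame           # toxicity-weighted risk per metal
    eri_class: pd.DataFrame
    ri: pd.Series               # per-sample integrated index
    ri_class: pd.Series


def igeo_table(samples: SampleTable, params: MetalParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    conc = samples.concentrations()
    vals, labels = {}, {}
    for m in METALS:
        v, lab = igeo(conc[m].to_numpy(), params.background[m], params.igeo_classes)
        vals[m], labels[m] = v, lab
    idx = conc.index
    return (pd.DataFrame(vals, index=idx), pd.DataFrame(labels, index=idx))


def ecological_risk(samples: SampleTable, params: MetalParams) -> IndexResult:
    """Hakanson risk indices for every sample, plus geoaccumulation."""
    for m in METALS:
        if m not in params.toxic_response:
            raise ConfigError(f"toxic_response missing for {m}")
        if params.background[m] <= 0:
            raise ConfigError(f"background for {m} must be positive")
    conc = samples.concentrations()
    cf = conc / pd.Series(params.background)[list(METALS)]
    eri = cf * pd.Series(params.toxic_response)[list(METALS)]
    ri = eri.sum(axis=1)

    ig, ig_class = igeo_table(samples, params)
    eri_class = eri.apply(lambda col: [classify(v, params.eri_classes) for v in col])
    ri_class = pd.Series([classify(v, params.ri_classes) for v in ri],
                         index=ri.index, name="ri_class")
    return IndexResult(igeo=ig, igeo_class=ig_class, cf=cf, eri=eri,
                       eri_class=eri_class, ri=ri, ri_class=ri_class)


def risk_class_shares(labels: pd.DataFrame, scheme) -> pd.DataFrame:
    """Percentage of samples per class for each metal; rows sum to 100.

    ``labels`` is a per-sample × metal class-label table; ``scheme`` fixes
    the class order of the output columns.
    """
    if len(labels) == 0:
        raise ValueError("empty result")
    order = [lab for _, lab in scheme]
    out = {}
    for m in labels.columns:
        counts = labels[m].value_counts()
        out[m] = [100.0 * counts.get(lab, 0) / len(labels) for lab in order]
    return pd.DataFrame(out, index=order).T
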