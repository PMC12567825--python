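"""Domain types, parameter loading and CSV I/O.

The sample table is a thin, validated wrapper around a pandas DataFrame with
one row per soil sample (id, planar x/y in metres, pH, and the eight metal
concentrations in mg·kg⁻¹). Parameter tables (backgrounds, detection limits,
regulatory thresholds, exposure constants, toxicity values) are loaded from
a YAML config that overrides the documented defaults; everything any
downstream equation consumes is reachable from these objects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _defaults as D
from ._defaults import METALS, PATHWAYS, PH_BANDS

log = logging.getLogger("soilrisk")

__all__ = [
    "METALS",
    "PATHWAYS",
    "SampleTable",
    "MetalParams",
    "ExposureProfile",
    "RunConfig",
    "SchemaError",
    "ConfigError",
    "read_samples",
    "load_params",
    "ph_band",
    "classify",
    "setup_logging",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class ConfigError(ValueError):
    """Parameter configuration is missing or invalid."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


def classify(value: float, scheme: Sequence[tuple[float, str]]) -> str:
    """Map ``value`` onto a half-open class scheme ``((hi, label), ...)``.

    Classes are intervals (lo, hi] with the first lo = -inf, so a value
    exactly on a boundary belongs to the lower class.
    """
    for hi, label in scheme:
        if value <= hi:
            return label
    return scheme[-1][1]


def ph_band(ph: float) -> str:
    """GB 15618-2018 pH band label for a soil pH."""
    if ph <= 5.5:
        return "<=5.5"
    if ph <= 6.5:
        return "5.5-6.5"
    if ph <= 7.5:
        return "6.5-7.5"
    return ">7.5"


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Validated soil-sample table.

    Attributes
    ----------
    df : DataFrame with columns ``sample_id``, ``x``, ``y``, ``pH`` and one
        column per metal in :data:`METALS` (mg·kg⁻¹).
    flags : DataFrame recording per-row validation actions (may be empty).
    """

    df: pd.DataFrame
    flags: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "metal", "action"])
    )

    REQUIRED = ("sample_id", "x", "y", "pH")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED + METALS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if len(self.df) == 0:
            raise SchemaError("empty sample table")
        if self.df["sample_id"].duplicated().any():
            dups = self.df.loc[self.df["sample_id"].duplicated(), "sample_id"]
            raise SchemaError(f"duplicated sample_id(s): {sorted(set(dups))}")
        conc = self.df[list(METALS)].to_numpy(dtype=float)
        if not np.all(conc > 0):
            raise SchemaError("non-positive concentration after validation")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def metals(self) -> tuple[str, ...]:
        return METALS

    def concentrations(self) -> pd.DataFrame:
        """The n×8 concentration matrix X, indexed by sample_id."""
        return self.df.set_index("sample_id")[list(METALS)].astype(float)

    def coords(self) -> np.ndarray:
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | Path, *, mdl: Mapping[str, float] | None = None,
                 policy: str = "drop") -> "SampleTable":
        return read_samples(path, mdl=mdl, policy=policy)


def read_samples(path: str | Path, *, mdl: Mapping[str, float] | None = None,
                 policy: str = "drop") -> SampleTable:
    """Read and validate a soil-sample CSV.

    Rows with missing or non-positive concentrations are flagged and, per
    ``policy``, either dropped (``"drop"``, default) or imputed at
    (5/6)·MDL (``"impute"``; requires ``mdl``). Positive values at or below
    the MDL are left as reported — censoring for statistics is applied where
    a stage needs it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in SampleTable.REQUIRED + METALS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise SchemaError("no sample rows in input")
    if policy not in ("drop", "impute"):
        raise ConfigError(f"unknown validation policy {policy!r}")
    if policy == "impute" and mdl is None:
        mdl = dict(D.MDL)

    flags: list[dict[str, str]] = []
    conc = df[list(METALS)].apply(pd.to_numeric, errors="coerce")
    bad = conc.isna() | (conc <= 0)
    if bad.to_numpy().any():
        for i in df.index[bad.any(axis=1)]:
            for m in METALS:
                if bad.at[i, m]:
                    flags.append({"sample_id": str(df.at[i, "sample_id"]),
                                  "metal": m, "action": policy})
        if policy == "drop":
            keep = ~bad.any(axis=1)
            log.warning("dropping %d row(s) with invalid concentrations",
                        int((~keep).sum()))
            df = df.loc[keep]
        else:
            for m in METALS:
                fill = 5.0 / 6.0 * float(mdl[m])  # type: ignore[index]
                conc.loc[bad[m], m] = fill
            df = df.assign(**{m: conc[m] for m in METALS})
        if len(df) == 0:
            raise SchemaError("no valid rows left after validation")
    df = df.assign(**{m: pd.to_numeric(df[m]) for m in METALS})
    return SampleTable(df.copy(), pd.DataFrame(flags, columns=["sample_id", "metal", "action"]))


def censor_below_mdl(conc: pd.DataFrame, mdl: Mapping[str, float]) -> pd.DataFrame:
    """Replace values ≤ MDL by (5/6)·MDL, the single censoring rule used
    for statistics and uncertainty construction."""
    out = conc.copy()
    for m in out.columns:
        lim = float(mdl[m])
        out.loc[out[m] <= lim, m] = 5.0 / 6.0 * lim
    return out


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

@dataclass
class MetalParams:
    """Per-metal constants consumed by the index, receptor and risk stages."""

    background: dict[str, float]
    mdl: dict[str, float]
    toxic_response: dict[str, float]
    screening: dict[str, dict[str, float]]      # metal -> pH band -> mg/kg
    intervention: dict[str, dict[str, float]]   # metal -> pH band -> mg/kg
    rfd: dict[str, dict[str, float]]            # metal -> pathway -> mg/kg/d
    sf: dict[str, dict[str, float]]             # metal -> pathway -> 1/(mg/kg/d)
    rsd: dict[str, float]
    cv_classes: tuple = D.CV_CLASSES
    igeo_classes: tuple = D.IGEO_CLASSES
    eri_classes: tuple = D.ERI_CLASSES
    ri_classes: tuple = D.RI_CLASSES

    def __post_init__(self) -> None:
        for name in ("background", "mdl", "toxic_response", "rsd"):
            table = getattr(self, name)
            for m in METALS:
                if m not in table:
                    raise ConfigError(f"{name} missing metal {m}")
                if table[m] is None or float(table[m]) <= 0:
                    if name == "rsd" and float(table[m]) == 0:
                        continue  # a zero RSD is a legal limiting case
                    raise ConfigError(f"{name}[{m}] must be positive")

    @classmethod
    def defaults(cls) -> "MetalParams":
        return cls(
            background=dict(D.BACKGROUND),
            mdl=dict(D.MDL),
            toxic_response=dict(D.TOXIC_RESPONSE),
            screening={m: dict(v) for m, v in D.SCREENING.items()},
            intervention={m: dict(v) for m, v in D.INTERVENTION.items()},
            rfd={m: dict(v) for m, v in D.RFD.items()},
            sf={m: dict(v) for m, v in D.SF.items()},
            rsd=dict(D.RSD),
        )

    def screening_value(self, metal: str, ph: float = 7.7) -> float | None:
        table = self.screening.get(metal)
        return None if table is None else table.get(ph_band(ph))

    def intervention_value(self, metal: str, ph: float = 7.7) -> float | None:
        table = self.intervention.get(metal)
        return None if table is None else table.get(ph_band(ph))

    @property
    def carcinogenic_metals(self) -> tuple[str, ...]:
        """Metals entering the carcinogenic sum: those with any slope factor."""
        return tuple(m for m in METALS if self.sf.get(m))


@dataclass
class ExposureProfile:
    """Cohort-specific exposure constants (units in the field's convention:
    IngR mg/d, InhR m³/d, EF d/a, ED a, BW kg, PEF m³/kg, SA cm²,
    AF mg·cm⁻²·d⁻¹, ABS unitless, averaging times in days)."""

    cohort: str
    IngR: float
    InhR: float
    EF: float
    ED: float
    BW: float
    PEF: float
    SA: float
    AF: float
    ABS: float
    AT_ca: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "cohort":
                continue
            if float(getattr(self, f.name)) <= 0:
                raise ConfigError(f"exposure parameter {f.name} must be positive")

    @property
    def AT_nc(self) -> float:
        """Non-carcinogenic averaging time: ED × 365 days."""
        return self.ED * 365.0

    @classmethod
    def defaults(cls, cohort: str) -> "ExposureProfile":
        if cohort not in D.EXPOSURE:
            raise ConfigError(f"unknown cohort {cohort!r}")
        return cls(cohort=cohort, **D.EXPOSURE[cohort])


@dataclass
class RunConfig:
    """Run-level settings: scan range for the factor count, solver restarts,
    seed, kriging grid, and output directory."""

    seed: int = 0
    n_factors_scan: tuple[int, int] = (3, 5)
    pmf_restarts: int = 20
    grid: dict = field(default_factory=lambda: {
        "origin": (0.0, 0.0), "cell": 50.0, "nx": 20, "ny": 20})
    outdir: str = "soilrisk_out"
    sample_policy: str = "drop"
    log_concentrations: bool = True   # log-transform before kriging
    pmf_enabled: bool = True

    def validate(self, n_metals: int = len(METALS)) -> None:
        lo, hi = self.n_factors_scan
        if not (2 <= lo <= hi <= n_metals - 1):
            raise ConfigError(
                f"factor scan range {self.n_factors_scan} outside [2, {n_metals - 1}]")


def _deep_update(base: dict, upd: Mapping) -> dict:
    for k, v in upd.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_params(path: str | Path | None = None
                ) -> tuple[MetalParams, dict[str, ExposureProfile], RunConfig]:
    """Load parameter tables, overriding defaults from a YAML config.

    The config may contain sections ``metals`` (keys matching
    :class:`MetalParams` fields), ``exposure`` (``adult``/``child`` maps) and
    ``run`` (:class:`RunConfig` fields). An empty or absent file yields the
    documented defaults; every override is logged.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}

    params = MetalParams.defaults()
    for key, val in (raw.get("metals") or {}).items():
        if not hasattr(params, key):
            raise ConfigError(f"unknown metals parameter {key!r}")
        current = getattr(params, key)
        if isinstance(current, dict) and isinstance(val, Mapping):
            _deep_update(current, val)
        else:
            setattr(params, key, val)
        log.info("override metals.%s from config", key)
    params.__post_init__()

    profiles: dict[str, ExposureProfile] = {}
    for cohort in ("adult", "child"):
        base = dict(D.EXPOSURE[cohort])
        over = (raw.get("exposure") or {}).get(cohort) or {}
        unknown = set(over) - set(base)
        if unknown:
            raise ConfigError(f"unknown exposure parameter(s) {sorted(unknown)}")
        base.update(over)
        if over:
            log.info("override exposure.%s: %s", cohort, sorted(over))
        profiles[cohort] = ExposureProfile(cohort=cohort, **base)

    run_kwargs = dict(raw.get("run") or {})
    if "n_factors_scan" in run_kwargs:
        run_kwargs["n_factors_scan"] = tuple(run_kwargs["n_factors_scan"])
    run = RunConfig(**run_kwargs)
    run.validate()
    return params, profiles, run


def config_hash(path: str | Path | None) -> str:
    """Stable short hash of the effective config text (empty config → hash
    of the empty string), recorded in the run manifest."""
    text = "" if path is None else Path(path).read_text()
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
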