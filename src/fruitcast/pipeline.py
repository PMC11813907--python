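"""End-to-end orchestration: calibrate -> thermal time -> curves -> features
-> split -> cross-validate -> fit -> evaluate.

The in-memory entry point is :func:`analyze_cohort`; :func:`run_pipeline`
is the file-based wrapper driven by a YAML config (see
:class:`PipelineConfig`), writing the anchor table, fitted model(s) and an
evaluation report per cultivar.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from . import io as fio
from .allometry import DensityFit, DiameterPair, calibrate_density, estimate_mass, fruit_volume_index
from .errors import ConfigError, DegenerateDataError, InsufficientDataError
from .evaluation import evaluate
from .growth_curve import (
    SCHEMES,
    AnchorScheme,
    GrowthObservation,
    anchor_sizes,
    fit_growth_curve,
    is_extrapolated,
    suspect_anchor_values,
)
from .modeling import (
    DEFAULT_LAMBDA_GRID,
    SplitSpec,
    build_feature_table,
    cv_select_lambda,
    fit_ridge,
    make_model,
    predict,
    split_train_test,
)
from .synthetic_data import FruitRecord
from .thermal_time import TemperatureSeries, ThermalClock, mean_temperature

logger = logging.getLogger("fruitcast")

__all__ = [
    "AnchorRecord",
    "PipelineConfig",
    "anchor_fruits",
    "analyze_cohort",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnchorRecord:
    """One fruit after curve fitting: anchor masses plus QC metadata."""

    fruit_id: str
    cultivar: str
    scheme: str
    anchor_taus: Tuple[float, ...]
    anchor_values: Tuple[float, ...]
    r2: float
    qc_pass: bool
    extrapolated: bool
    suspect: bool
    harvest_mass: Optional[float]
    mean_temp: Optional[float]


def anchor_fruits(
    series: TemperatureSeries,
    fruits: Sequence[FruitRecord],
    density_fits: Dict[str, DensityFit],
    scheme: AnchorScheme,
) -> Tuple[List[AnchorRecord], Dict[str, int]]:
    """Fit each fruit's growth curve and extract anchor masses.

    Fruits with fewer than 4 in-window observations are dropped and
    counted; fruits failing the r^2 gate keep a record with
    ``qc_pass=False`` so downstream stages can report exclusion rates.
    Returns ``(records, counts)`` where counts tracks fruits in, excluded
    for data shortage, excluded by the gate, and lacking harvest mass.
    """
    records: List[AnchorRecord] = []
    counts = {"fruits_in": 0, "too_few_obs": 0, "gate_failed": 0, "no_harvest": 0}
    for fruit in fruits:
        counts["fruits_in"] += 1
        fit = density_fits.get(fruit.cultivar)
        if fit is None:
            raise ConfigError(
                f"stage anchor ({fruit.fruit_id}): no density calibration for "
                f"cultivar {fruit.cultivar!r}"
            )
        clock = ThermalClock(anthesis=fruit.anthesis, series=series)
        obs: List[GrowthObservation] = []
        last_in_window: Optional[_dt.date] = None
        for date, long_cm, short_cm in fruit.measurements:
            pair, _swapped = DiameterPair.from_measurement(long_cm, short_cm)
            tau = clock.series.degree_days(fruit.anthesis, date, base=clock.base)
            c = estimate_mass(fruit_volume_index(pair), fit)
            obs.append(GrowthObservation(tau=tau, c_fruit=c))
            if tau < scheme.window_max:
                last_in_window = date
        try:
            curve = fit_growth_curve(obs, scheme)
        except InsufficientDataError:
            counts["too_few_obs"] += 1
            logger.debug("stage curve-fit (%s): too few in-window observations", fruit.fruit_id)
            continue
        except DegenerateDataError as e:
            raise DegenerateDataError(f"stage curve-fit ({fruit.fruit_id}): {e}") from e
        mean_temp = (
            mean_temperature(clock, last_in_window)
            if last_in_window is not None and last_in_window > fruit.anthesis
            else None
        )
        if not curve.qc_pass:
            counts["gate_failed"] += 1
            records.append(
                AnchorRecord(
                    fruit.fruit_id, fruit.cultivar, scheme.name, scheme.anchors,
                    tuple(float(curve(a)) for a in scheme.anchors),
                    curve.r2, False, is_extrapolated(curve, scheme), False,
                    fruit.harvest_mass_g, mean_temp,
                )
            )
            continue
        values = anchor_sizes(curve, scheme)
        if fruit.harvest_mass_g is None:
            counts["no_harvest"] += 1
        records.append(
            AnchorRecord(
                fruit.fruit_id, fruit.cultivar, scheme.name, scheme.anchors,
                tuple(float(v) for v in values),
                curve.r2, True, is_extrapolated(curve, scheme),
                suspect_anchor_values(values),
                fruit.harvest_mass_g, mean_temp,
            )
        )
    return records, counts


def analyze_cohort(
    series: TemperatureSeries,
    fruits: Sequence[FruitRecord],
    calibration: Dict[str, List[Tuple[float, float]]],
    scheme: AnchorScheme,
    include_mean_temp: bool = False,
    model: str = "ridge",
    train_fraction: float = 0.8,
    seed: int = 0,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    cv_folds: int = 10,
    cv_repeats: int = 3,
) -> Tuple[List[dict], List[AnchorRecord], Dict[str, object]]:
    """Run the full analysis per cultivar on in-memory data.

    Returns ``(reports, anchor_records, fitted_models)``; each report is a
    JSON-ready dict with held-out MAPE (%), R^2 and RMSE (g).
    """
    density_fits = {c: calibrate_density(pairs) for c, pairs in calibration.items()}
    records, counts = anchor_fruits(series, fruits, density_fits, scheme)
    logger.info("anchoring (%s): %s", scheme.name, counts)

    reports: List[dict] = []
    models: Dict[str, object] = {}
    cultivars = sorted({r.cultivar for r in records})
    for cultivar in cultivars:
        crecs = [r for r in records if r.cultivar == cultivar]
        rows = build_feature_table(crecs, scheme, include_mean_temp=include_mean_temp)
        train, test = split_train_test(rows, SplitSpec(train_fraction, seed))
        if model == "ridge":
            lam = cv_select_lambda(
                train, lambda_grid, k_folds=cv_folds, repeats=cv_repeats, seed=seed
            )
            fitted = fit_ridge(train, lam)
            pred = predict(fitted, test)
        else:
            fitted = make_model(model, seed=seed).fit(train)
            pred = fitted.predict(test)
        obs = [r.target for r in test]
        rep = evaluate(pred, obs)
        models[cultivar] = fitted
        reports.append(
            {
                "cultivar": cultivar,
                "scheme": scheme.name,
                "model": model,
                "include_mean_temp": include_mean_temp,
                "n_train": len(train),
                "n_test": rep.n,
                "mape_pct": round(rep.mape, 4),
                "r2": round(rep.r2, 4),
                "rmse_g": round(rep.rmse, 4),
                "density": round(density_fits[cultivar].density, 6),
                "excluded_gate": sum(
                    1 for r in crecs if not r.qc_pass
                ),
                "seed": seed,
            }
        )
    return reports, records, models


@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline settings, usually loaded from ``config.yaml``."""

    temperature: Path
    measurements: Path
    calibration: Path
    output_dir: Path
    scheme: str = "E500"
    include_mean_temp: bool = False
    model: str = "ridge"
    train_fraction: float = 0.8
    seed: int = 0
    lambda_grid: Tuple[float, ...] = DEFAULT_LAMBDA_GRID
    cv_folds: int = 10
    cv_repeats: int = 3

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(
                f"unknown scheme {self.scheme!r}; choose one of {sorted(SCHEMES)}"
            )
        if self.model not in ("ridge", "extra_trees", "gbdt"):
            raise ConfigError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a mapping")
        known = {
            "temperature", "measurements", "calibration", "output_dir", "scheme",
            "include_mean_temp", "model", "train_fraction", "seed", "lambda_grid",
            "cv_folds", "cv_repeats",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("temperature", "measurements", "calibration", "output_dir"):
            if key not in raw:
                raise ConfigError(f"config missing required key {key!r}")
            raw[key] = Path(raw[key])
        if "lambda_grid" in raw:
            raw["lambda_grid"] = tuple(float(x) for x in raw["lambda_grid"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> List[dict]:
    """Execute the file-based pipeline and persist all artifacts.

    Writes ``anchors.csv``, one ``model_<cultivar>.json`` per cultivar
    (ridge only) and ``report.json`` into ``config.output_dir``.
    """
    for key in ("temperature", "measurements", "calibration"):
        p = getattr(config, key)
        if not Path(p).exists():
            raise ConfigError(f"{key} file not found: {p}")
    from .thermal_time import read_temperature_csv

    series = read_temperature_csv(config.temperature)
    fruits = fio.read_measurements_csv(config.measurements)
    calibration = fio.read_calibration_csv(config.calibration)
    scheme = SCHEMES[config.scheme]
    reports, records, models = analyze_cohort(
        series,
        fruits,
        calibration,
        scheme,
        include_mean_temp=config.include_mean_temp,
        model=config.model,
        train_fraction=config.train_fraction,
        seed=config.seed,
        lambda_grid=config.lambda_grid,
        cv_folds=config.cv_folds,
        cv_repeats=config.cv_repeats,
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_anchor_csv(records, out / "anchors.csv")
    for cultivar, model in models.items():
        ridge = getattr(model, "model", None)
        if ridge is not None:
            slug = cultivar.lower().replace(" ", "-")
            (out / f"model_{slug}.json").write_text(ridge.to_json() + "\n", encoding="utf-8")
        elif hasattr(model, "to_json"):
            slug = cultivar.lower().replace(" ", "-")
            (out / f"model_{slug}.json").write_text(model.to_json() + "\n", encoding="utf-8")
    fio.write_report_json(reports, out / "report.json")
    return reports
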