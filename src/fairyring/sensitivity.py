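"""One-at-a-time parameter sensitivity of the fairy-ring biometrics.

Each model parameter is varied by +/-50% around its base value while all the
others stay fixed; each level is one full simulation followed by biometric
extraction. Per (metric, parameter) pair the analysis reports the sign of
the Pearson correlation between parameter level and metric, and the fold
change

    fc = (max(X) - min(X)) / min(X)        (always >= 0 when defined),

and assembles the column-normalized matrix used for heatmap display (each
metric column divided by its own maximum, so intensities are comparable only
within a column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .biometrics import compute_biometrics, Transect
from .engine import SimConfig, run

__all__ = [
    "METRICS",
    "DEFAULT_MULTIPLIERS",
    "SweepSpec",
    "SensitivityTable",
    "sweep",
    "fold_change",
    "correlation_sign",
    "build_heatmap",
    "run_sensitivity",
]

logger = logging.getLogger(__name__)

METRICS = ("FB", "PS", "PI", "BZ", "RW")

#: Five levels spanning the published +/-50% envelope.
DEFAULT_MULTIPLIERS = (0.5, 0.75, 1.0, 1.25, 1.5)

#: Pearson coefficients smaller than this in magnitude are reported as sign 0
#: (insensitive parameter; the residual r is numerical noise).
SIGN_DEADZONE = 0.1


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep: ``parameter`` scaled by each of ``multipliers``
    (strictly increasing, >= 3 levels) on top of ``base``."""

    parameter: str
    base: SimConfig
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        m = np.asarray(self.multipliers, float)
        if len(m) < 3 or not np.all(np.diff(m) > 0):
            raise ValueError("multipliers must be >= 3 strictly increasing levels")

    @property
    def levels(self) -> np.ndarray:
        base_value = getattr(self.base.resolved_params(), self.parameter)
        return np.asarray(self.multipliers, float) * base_value


def _default_runner(config: SimConfig) -> dict[str, float]:
    """Run one simulation and return the biometric metrics of its final
    transect."""
    traj = run(config)
    x, F, P = traj.final_transect()
    rec = compute_biometrics(Transect(x, F, P, time=traj.times[-1]))
    return rec.as_dict()


def sweep(
    spec: SweepSpec,
    runner: Callable[[SimConfig], Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Metric values per level for one parameter.

    Returns a DataFrame indexed by level value with one column per metric
    plus a boolean ``failed`` column: a level whose run raises is flagged
    and carried as NaN, never silently dropped.
    """
    if runner is None:
        runner = _default_runner
    base_params = spec.base.resolved_params()
    rows = []
    for level in spec.levels:
        cfg = spec.base.replace(
            params=base_params.replace(**{spec.parameter: float(level)}),
            hypothesis_mode=None,
        )
        try:
            metrics = dict(runner(cfg))
            metrics["failed"] = False
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            logger.warning("sweep %s=%g failed: %s", spec.parameter, level, exc)
            metrics = {m: float("nan") for m in METRICS}
            metrics["failed"] = True
        rows.append(metrics)
    df = pd.DataFrame(rows, index=pd.Index(spec.levels, name=spec.parameter))
    return df


def fold_change(values: Sequence[float]) -> float:
    """Relative span ``(max - min)/min`` of the defined metric values.

    NaN (undefined/failed levels) are ignored; the result is NaN when no
    defined values remain or when ``min == 0`` (the ratio is undefined).
    Negative metric values are an error — biometrics are non-negative by
    construction.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("fold_change of an empty sequence")
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    if np.any(v < 0):
        raise ValueError("fold_change expects non-negative metric values")
    lo, hi = float(v.min()), float(v.max())
    if lo == 0.0:
        return float("nan")
    return (hi - lo) / lo


def correlation_sign(levels: Sequence[float], values: Sequence[float]) -> int:
    """Sign of the Pearson correlation between parameter level and metric.

    Returns 0 for zero variance, fewer than 3 defined pairs, or
    ``|r| < 0.1`` (dead zone: such an r on a 5-level sweep is noise)."""
    lv = np.asarray(levels, float)
    vv = np.asarray(values, float)
    ok = np.isfinite(lv) & np.isfinite(vv)
    lv, vv = lv[ok], vv[ok]
    if len(lv) < 3 or np.ptp(lv) == 0 or np.ptp(vv) == 0:
        return 0
    r = stats.pearsonr(lv, vv).statistic
    if not np.isfinite(r) or abs(r) < SIGN_DEADZONE:
        return 0
    return 1 if r > 0 else -1


@dataclass
class SensitivityTable:
    """Long-form results plus the heatmap matrices.

    ``table`` has one row per (parameter, metric) with sign, fold change and
    per-level raw values; ``fc`` / ``fc_normalized`` / ``signs`` are
    parameter-by-metric matrices (rows = parameters, columns = metrics).
    """

    table: pd.DataFrame
    fc: pd.DataFrame
    fc_normalized: pd.DataFrame
    signs: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_heatmap(fc: pd.DataFrame, signs: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a fold-change matrix (columns = metrics).

    Each column is divided by its own maximum so intensities compare only
    within a metric; undefined cells stay NaN, and a column with no defined
    value is emitted as all-NaN with a warning."""
    norm = fc.copy()
    for col in norm.columns:
        colmax = norm[col].max(skipna=True)
        if not np.isfinite(colmax) or colmax == 0:
            logger.warning("heatmap column %s has no defined fold change", col)
            norm[col] = np.nan
        else:
            norm[col] = norm[col] / colmax
    return norm


def run_sensitivity(
    base: SimConfig,
    parameters: Sequence[str] | None = None,
    multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
    runner: Callable[[SimConfig], Mapping[str, float]] | None = None,
) -> SensitivityTable:
    """Full one-at-a-time analysis over ``parameters`` (default: every model
    parameter) on a common base configuration."""
    from .params import PARAM_NAMES

    if parameters is None:
        parameters = PARAM_NAMES
    records = []
    fc_mat: dict[str, dict[str, float]] = {}
    sign_mat: dict[str, dict[str, int]] = {}
    for name in parameters:
        df = sweep(SweepSpec(name, base, multipliers), runner=runner)
        levels = df.index.to_numpy()
        fc_mat[name] = {}
        sign_mat[name] = {}
        for metric in METRICS:
            vals = df[metric].to_numpy()
            fc = fold_change(vals)
            sign = correlation_sign(levels, vals)
            fc_mat[name][metric] = fc
            sign_mat[name][metric] = sign
            records.append(
                {
                    "parameter": name,
                    "metric": metric,
                    "sign": sign,
                    "fold_change": fc,
                    **{f"value_x{m:g}": v for m, v in zip(multipliers, vals)},
                    "n_failed": int(df["failed"].sum()),
                }
            )
    fc_df = pd.DataFrame(fc_mat).T.loc[list(parameters), list(METRICS)]
    sign_df = pd.DataFrame(sign_mat).T.loc[list(parameters), list(METRICS)]
    norm = build_heatmap(fc_df, sign_df)
    table = pd.DataFrame(records)
    table = table.merge(
        norm.stack(future_stack=True)
        .rename("fold_change_normalized")
        .reset_index()
        .rename(columns={"level_0": "parameter", "level_1": "metric"}),
        on=["parameter", "metric"],
        how="left",
    )
    return SensitivityTable(table=table, fc=fc_df, fc_normalized=norm, signs=sign_df)
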