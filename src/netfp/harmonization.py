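"""Edgewise linear confound models.

Each network edge gets its own ordinary-least-squares model of the form

    edge ~ intercept + batch (one-hot, reference level) + sex + genotype
           + age (centered) + dose/weight (centered)

fitted on a designated subset of scans (typically the healthy controls of
the training split).  Residualization subtracts the covariate contributions
while retaining the intercept, so corrected values stay on the similarity
scale.  Covariate-effect summaries reduce the per-edge standardized betas
of one covariate to a Cohen's d versus zero with a bootstrap CI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignSpec",
    "HarmonizationModel",
    "EffectSummary",
    "fit_edgewise_model",
    "residualize",
    "summarize_effect",
]

DEFAULT_COVARIATES = ("batch", "sex", "genotype", "age", "dw")


@dataclass(frozen=True)
class DesignSpec:
    """Everything needed to rebuild the design matrix for new scans."""

    covariates: tuple[str, ...]
    categorical_levels: dict[str, list[str]] = field(default_factory=dict)  # ref = first
    centering: dict[str, float] = field(default_factory=dict)
    standardize: bool = False
    scale: dict[str, float] = field(default_factory=dict)  # per design column, if standardize

    def column_names(self) -> list[str]:
        cols = []
        for cov in self.covariates:
            if cov in self.categorical_levels:
                cols += [f"{cov}[{lv}]" for lv in self.categorical_levels[cov][1:]]
            else:
                cols.append(cov)
        return cols

    def build(self, covariates: pd.DataFrame) -> pd.DataFrame:
        """Design matrix (without intercept) for the given scans."""
        cols: dict[str, np.ndarray] = {}
        for cov in self.covariates:
            if cov not in covariates.columns:
                raise ValueError(f"covariate {cov!r} missing from the covariate table")
            if cov in self.categorical_levels:
                levels = self.categorical_levels[cov]
                vals = covariates[cov].astype(str)
                unknown = set(vals) - set(levels)
                if unknown:
                    raise ValueError(
                        f"covariate {cov!r} has unseen level(s) {sorted(unknown)}"
                    )
                for lv in levels[1:]:
                    cols[f"{cov}[{lv}]"] = (vals == lv).to_numpy(dtype=float)
            else:
                x = covariates[cov].to_numpy(dtype=float)
                cols[cov] = x - self.centering.get(cov, 0.0)
        design = pd.DataFrame(cols, index=covariates.index)
        if self.standardize:
            for c in design.columns:
                design[c] = (design[c] - self.centering.get(f"z:{c}", 0.0)) / self.scale[c]
        return design


@dataclass
class HarmonizationModel:
    """Per-edge OLS coefficients plus the design specification."""

    spec: DesignSpec
    intercept: pd.Series  # index = edges
    coefficients: pd.DataFrame  # index = design columns, columns = edges
    fit_scan_ids: list[str]
    outcome_scale: pd.Series | None = None  # per-edge SD if outcomes were z-scored
    outcome_center: pd.Series | None = None

    def to_json(self, path: str | Path, coefficient_path: str | Path) -> None:
        """Serialize: design spec as JSON, coefficient table as TSV."""
        coef = pd.concat([self.intercept.to_frame("intercept").T, self.coefficients])
        coef.to_csv(coefficient_path, sep="\t", float_format="%.17g", index_label="term")
        payload = {
            "covariates": list(self.spec.covariates),
            "categorical_levels": self.spec.categorical_levels,
            "centering": self.spec.centering,
            "standardize": self.spec.standardize,
            "scale": self.spec.scale,
            "fit_scan_ids": self.fit_scan_ids,
            "coefficient_table": str(coefficient_path),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        payload = json.loads(Path(path).read_text())
        coef = pd.read_csv(payload["coefficient_table"], sep="\t", index_col="term")
        coef.index.name = None
        spec = DesignSpec(
            covariates=tuple(payload["covariates"]),
            categorical_levels=payload["categorical_levels"],
            centering=payload["centering"],
            standardize=payload["standardize"],
            scale=payload["scale"],
        )
        return cls(
            spec=spec,
            intercept=coef.loc["intercept"],
            coefficients=coef.drop(index="intercept"),
            fit_scan_ids=list(payload["fit_scan_ids"]),
        )


@dataclass(frozen=True)
class EffectSummary:
    """Cohen's d of one covariate's per-edge beta distribution vs zero."""

    covariate: str
    betas: pd.Series
    cohens_d: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cohens_d <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    x = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    bad = np.where(diag[1:] <= tol)[0]  # skip intercept
    return [design.columns[i] for i in bad]


def fit_edgewise_model(
    edge_table: pd.DataFrame,
    covariates: pd.DataFrame,
    fit_subset: Sequence[str] | None = None,
    covariate_names: Sequence[str] = DEFAULT_COVARIATES,
    standardize: bool = False,
) -> HarmonizationModel:
    """OLS per edge on the fit subset.

    Categorical covariates (non-numeric columns) are one-hot coded against
    the alphabetically first level; numeric covariates are centered on the
    fit subset.  With ``standardize=True`` both design columns and outcomes
    are z-scored on the fit subset (standardized betas, for effect
    summaries).
    """
    fit_ids = list(fit_subset) if fit_subset is not None else list(edge_table.index)
    missing = set(fit_ids) - set(edge_table.index)
    if missing:
        raise ValueError(f"fit subset scan(s) not in edge table: {sorted(missing)[:5]}")
    cov_fit = covariates.loc[fit_ids]

    categorical: dict[str, list[str]] = {}
    centering: dict[str, float] = {}
    for cov in covariate_names:
        if cov not in covariates.columns:
            raise ValueError(f"covariate {cov!r} missing from the covariate table")
        if covariates[cov].dtype == object or isinstance(
            covariates[cov].dtype, pd.CategoricalDtype
        ):
            categorical[cov] = sorted(covariates[cov].astype(str).unique())
        else:
            centering[cov] = float(cov_fit[cov].mean())

    spec = DesignSpec(
        covariates=tuple(covariate_names),
        categorical_levels=categorical,
        centering=centering,
        standardize=False,
    )
    design_fit = spec.build(cov_fit)

    if standardize:
        scale: dict[str, float] = {}
        z_center: dict[str, float] = {}
        for c in design_fit.columns:
            sd = float(design_fit[c].std(ddof=0))
            if sd == 0.0:
                raise ValueError(f"design column {c!r} is constant on the fit subset")
            scale[c] = sd
            z_center[f"z:{c}"] = float(design_fit[c].mean())
        spec = DesignSpec(
            covariates=tuple(covariate_names),
            categorical_levels=categorical,
            centering={**centering, **z_center},
            standardize=True,
            scale=scale,
        )
        design_fit = spec.build(cov_fit)

    n, p = design_fit.shape
    if n < p + 2:
        raise ValueError(
            f"fit subset has {n} scans but the design needs at least {p + 2}"
        )
    x = np.column_stack([np.ones(n), design_fit.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(design_fit)
        raise ValueError(
            f"rank-deficient design on the fit subset; collinear column(s): {bad}"
        )

    y = edge_table.loc[fit_ids].to_numpy(dtype=float)
    outcome_scale = outcome_center = None
    if standardize:
        mu = y.mean(axis=0)
        sd = y.std(axis=0, ddof=0)
        if np.any(sd == 0.0):
            raise ValueError("cannot z-score constant edge(s) on the fit subset")
        y = (y - mu) / sd
        outcome_center = pd.Series(mu, index=edge_table.columns)
        outcome_scale = pd.Series(sd, index=edge_table.columns)

    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return HarmonizationModel(
        spec=spec,
        intercept=pd.Series(beta[0], index=edge_table.columns),
        coefficients=pd.DataFrame(
            beta[1:], index=design_fit.columns, columns=edge_table.columns
        ),
        fit_scan_ids=fit_ids,
        outcome_scale=outcome_scale,
        outcome_center=outcome_center,
    )


def residualize(
    model: HarmonizationModel, edge_table: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Subtract covariate contributions (keep the intercept).

    corrected = observed - design @ coefficients, so values remain on the
    similarity scale.  Requires covariates for every scan in the table.
    """
    if model.spec.standardize:
        raise ValueError("residualize with a model fitted on raw (non-z-scored) data")
    missing = set(edge_table.index) - set(covariates.index)
    if missing:
        raise ValueError(f"covariates missing for scan(s) {sorted(missing)[:5]}")
    design = model.spec.build(covariates.loc[edge_table.index])
    design = design[model.coefficients.index]  # enforce column order
    adjustment = design.to_numpy(dtype=float) @ model.coefficients.to_numpy(dtype=float)
    return pd.DataFrame(
        edge_table.to_numpy(dtype=float) - adjustment,
        index=edge_table.index,
        columns=edge_table.columns,
    )


def summarize_effect(
    model: HarmonizationModel,
    covariate: str,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EffectSummary:
    """Cohen's d (mean/SD over edges) of one covariate's betas, vs zero.

    The model must have been fitted with ``standardize=True``.  The 95% CI
    is a percentile bootstrap over edges.
    """
    if not model.spec.standardize:
        raise ValueError("summarize_effect requires a model fitted with standardize=True")
    if covariate in model.coefficients.index:
        betas = model.coefficients.loc[covariate]
    else:
        rows = [
            r for r in model.coefficients.index if r == covariate or r.startswith(f"{covariate}[")
        ]
        if len(rows) != 1:
            raise ValueError(
                f"covariate {covariate!r} does not map to exactly one design column "
                f"(candidates: {rows})"
            )
        betas = model.coefficients.loc[rows[0]]
    b = betas.to_numpy(dtype=float)
    sd = b.std(ddof=1)
    if sd == 0.0:
        raise ValueError("degenerate beta distribution: zero variance across edges")
    d = float(b.mean() / sd)

    rng = np.random.default_rng(seed)
    ds_parts = []
    for start in range(0, n_boot, 500):  # chunked to bound memory
        size = min(500, n_boot - start)
        idx = rng.integers(0, b.size, size=(size, b.size))
        samples = b[idx]
        means = samples.mean(axis=1)
        sds = samples.std(axis=1, ddof=1)
        ok = sds > 0
        ds_parts.append(means[ok] / sds[ok])
    ds = np.concatenate(ds_parts)
    lo, hi = np.percentile(ds, [2.5, 97.5])
    lo, hi = float(min(lo, d)), float(max(hi, d))
    return EffectSummary(covariate=covariate, betas=betas, cohens_d=d, ci_low=lo, ci_high=hi)
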