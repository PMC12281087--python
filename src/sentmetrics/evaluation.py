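"""Statistical harness: join metrics with reading records, fit additive mixed
models, compare them by AIC, and correlate metrics.

The modelling follows the standard design for sentence reading measures: the
response is ln(reading speed in words/second); a *base* model carries the
control predictors (smooths of mean word length and mean log word frequency),
language as a parametric fixed factor, and a participant random intercept;
a *full* model adds a smooth of the metric under test. Model quality is
compared by

    delta_AIC = AIC(full) - AIC(base)

with negative values favouring the metric. Per-term significance uses the
raw p < .01 convention. Smooths are penalized thin-plate splines (basis size
9 by default) selected by REML; the AIC is the conditional AIC reported by
the fitted penalized-likelihood object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rgam import RGamError, run_gam_fits, validate_identifier
from .corpus import (
    Document,
    FrequencyTable,
    ReadingRecord,
    compute_reading_speed,
    mean_log_word_frequency,
    mean_word_length,
)

__all__ = [
    "SmoothTerm",
    "ModelSpec",
    "ModelFit",
    "ComparisonResult",
    "SIGNIFICANCE_LEVEL",
    "build_sentence_table",
    "base_model_spec",
    "with_metric",
    "fit_additive_model",
    "fit_models",
    "compare_models",
    "compare_to_base",
    "correlate_metrics",
    "export_partial_effects",
    "partial_effect_slope",
]

logger = logging.getLogger(__name__)

#: A smooth term is called significant when its p-value is below .01.
SIGNIFICANCE_LEVEL = 0.01


@dataclass(frozen=True)
class SmoothTerm:
    predictor: str
    basis_size: int = 9
    by: str | None = None  # optional per-level smooths (factor interaction)

    def to_r(self) -> str:
        validate_identifier(self.predictor)
        parts = [self.predictor, f"k={int(self.basis_size)}"]
        if self.by is not None:
            parts.insert(1, f"by={validate_identifier(self.by)}")
        return f"s({', '.join(parts)})"


@dataclass(frozen=True)
class ModelSpec:
    """Response + smooth terms + parametric factors + random intercept."""

    response: str = "log_speed"
    smooth_terms: tuple[SmoothTerm, ...] = ()
    factor_terms: tuple[str, ...] = ()
    random_intercept: str | None = "participant"

    def to_r_formula(self) -> str:
        rhs: list[str] = [t.to_r() for t in self.smooth_terms]
        rhs += [validate_identifier(f) for f in self.factor_terms]
        if self.random_intercept:
            rhs.append(f's({validate_identifier(self.random_intercept)}, bs="re")')
        if not rhs:
            rhs = ["1"]
        return f"{validate_identifier(self.response)} ~ {' + '.join(rhs)}"

    def columns(self) -> set[str]:
        cols = {self.response}
        cols |= {t.predictor for t in self.smooth_terms}
        cols |= {t.by for t in self.smooth_terms if t.by}
        cols |= set(self.factor_terms)
        if self.random_intercept:
            cols.add(self.random_intercept)
        return cols

    def contains(self, other: "ModelSpec") -> bool:
        return (
            self.response == other.response
            and set(other.smooth_terms) <= set(self.smooth_terms)
            and set(other.factor_terms) <= set(self.factor_terms)
            and other.random_intercept == self.random_intercept
        )


@dataclass
class ModelFit:
    """A fitted additive model: AIC, per-term tests, partial-effect curves."""

    spec: ModelSpec
    aic: float
    n_obs: int
    smooth_terms: dict[str, dict[str, float]]  # term label -> edf/F/p
    parametric: dict[str, dict[str, float]]
    partial_effects: dict[str, pd.DataFrame]  # predictor -> grid/effect/lower/upper
    coefficients: np.ndarray

    def term_p_value(self, predictor: str) -> float:
        label = f"s({predictor})"
        if label not in self.smooth_terms:
            raise KeyError(f"no smooth term for {predictor!r} in fit")
        return self.smooth_terms[label]["p"]

    def is_significant(self, predictor: str) -> bool:
        return self.term_p_value(predictor) < SIGNIFICANCE_LEVEL


@dataclass
class ComparisonResult:
    delta_aic: float
    base: ModelFit
    full: ModelFit


def build_sentence_table(
    records: Sequence[ReadingRecord],
    metric_tables: Mapping[str, pd.DataFrame],
    corpus: Sequence[Document],
    freqs: FrequencyTable,
) -> pd.DataFrame:
    """Inner-join reading records with per-sentence metrics and controls.

    ``metric_tables`` maps a column name (e.g. ``"surprisal"``) to a metric
    table holding ``doc_id``, ``sentence_index``, ``value``. The result has
    one row per surviving (participant, sentence): ``log_speed`` (the
    response, ln words/second), ``mean_word_length``, ``mean_log_wordfreq``,
    one column per metric, plus ``language`` and ``participant``. Unmatched
    records are counted and logged, an empty join is an error.
    """
    if not records:
        raise ValueError("no reading records")
    rows = [
        {
            "language": r.language,
            "participant": r.participant,
            "doc_id": r.doc_id,
            "sentence_index": r.sentence_index,
            "log_speed": math.log(compute_reading_speed(r)),
        }
        for r in records
    ]
    table = pd.DataFrame(rows)

    controls = []
    for doc in corpus:
        for s in doc.sentences:
            controls.append(
                {
                    "doc_id": doc.doc_id,
                    "sentence_index": s.index,
                    "mean_word_length": mean_word_length(s),
                    "mean_log_wordfreq": mean_log_word_frequency(s, freqs),
                }
            )
    table = table.merge(pd.DataFrame(controls), on=["doc_id", "sentence_index"], how="inner")

    for name, mt in metric_tables.items():
        sub = mt[["doc_id", "sentence_index", "value"]].rename(columns={"value": name})
        before = len(table)
        table = table.merge(sub, on=["doc_id", "sentence_index"], how="inner")
        dropped = before - len(table)
        if dropped:
            logger.info("join: dropped %d rows lacking %s", dropped, name)
    if table.empty:
        raise ValueError("empty join: no reading record matched the metric tables")
    if not np.isfinite(
        table.select_dtypes(include=[np.number]).to_numpy()
    ).all():
        raise ValueError("non-finite predictor or response after join")
    return table


def base_model_spec(basis_size: int = 9, language_factor: bool = True) -> ModelSpec:
    """Control-only model: smooths of word length and log frequency,
    language fixed factor, participant random intercept."""
    return ModelSpec(
        response="log_speed",
        smooth_terms=(
            SmoothTerm("mean_word_length", basis_size),
            SmoothTerm("mean_log_wordfreq", basis_size),
        ),
        factor_terms=("language",) if language_factor else (),
        random_intercept="participant",
    )


def with_metric(spec: ModelSpec, *metrics: str, basis_size: int = 9) -> ModelSpec:
    """Extend a spec with one smooth per named metric column."""
    extra = tuple(SmoothTerm(m, basis_size) for m in metrics)
    return replace(spec, smooth_terms=spec.smooth_terms + extra)


def _spec_payload(table: pd.DataFrame, spec: ModelSpec) -> dict:
    missing = spec.columns() - set(table.columns)
    if missing:
        raise ValueError(f"table lacks column(s) required by the model: {sorted(missing)}")
    factors = list(spec.factor_terms)
    if spec.random_intercept:
        factors.append(spec.random_intercept)
    smooth_vars = [t.predictor for t in spec.smooth_terms]
    for v in smooth_vars:
        if table[v].nunique() < 2:
            raise ValueError(f"predictor {v!r} is constant; cannot fit a smooth")
    return {"formula": spec.to_r_formula(), "factors": factors, "smooth_vars": smooth_vars}


def _to_fit(spec: ModelSpec, payload: dict) -> ModelFit:
    partials = {
        var: pd.DataFrame(
            {
                "grid": pe["grid"],
                "effect": pe["effect"],
                "lower": pe["lower"],
                "upper": pe["upper"],
            }
        )
        for var, pe in payload.get("partial_effects", {}).items()
    }
    return ModelFit(
        spec=spec,
        aic=float(payload["aic"]),
        n_obs=int(payload["n_obs"]),
        smooth_terms={k: dict(v) for k, v in payload.get("smooth_terms", {}).items()},
        parametric={k: dict(v) for k, v in payload.get("parametric", {}).items()},
        partial_effects=partials,
        coefficients=np.asarray(payload.get("coefficients", []), dtype=float),
    )


def fit_models(
    table: pd.DataFrame, specs: Mapping[str, ModelSpec], grid_points: int = 100
) -> dict[str, ModelFit]:
    """Fit several specs against the same rows in one engine session.

    Rows with any missing value in any spec's columns are dropped up front so
    every model sees identical data (a precondition for AIC comparison).
    """
    needed = sorted(set().union(*(s.columns() for s in specs.values())))
    data = table.dropna(subset=[c for c in needed if c in table.columns])
    payloads = {name: _spec_payload(data, spec) for name, spec in specs.items()}
    results = run_gam_fits(data[needed], payloads, grid_points=grid_points)
    return {name: _to_fit(specs[name], results[name]) for name in specs}


def fit_additive_model(
    table: pd.DataFrame, spec: ModelSpec, grid_points: int = 100
) -> ModelFit:
    """Fit a single penalized-spline additive mixed model."""
    return fit_models(table, {"model": spec}, grid_points=grid_points)["model"]


def compare_models(
    table: pd.DataFrame, base_spec: ModelSpec, full_spec: ModelSpec
) -> ComparisonResult:
    """delta_AIC = AIC(full) - AIC(base), both fitted on identical rows."""
    if not full_spec.contains(base_spec):
        raise ValueError("full model must contain every term of the base model")
    fits = fit_models(table, {"base": base_spec, "full": full_spec})
    base, full = fits["base"], fits["full"]
    if base.n_obs != full.n_obs:
        raise RGamError(
            f"row mismatch between fits: base n={base.n_obs}, full n={full.n_obs}"
        )
    return ComparisonResult(delta_aic=full.aic - base.aic, base=base, full=full)


def compare_to_base(
    table: pd.DataFrame,
    base_spec: ModelSpec,
    full_specs: Mapping[str, ModelSpec],
) -> dict[str, ComparisonResult]:
    """Compare several full models against one base in a single session."""
    for name, fs in full_specs.items():
        if not fs.contains(base_spec):
            raise ValueError(f"full model {name!r} does not contain the base model")
    all_specs: dict[str, ModelSpec] = {"base": base_spec, **full_specs}
    fits = fit_models(table, all_specs)
    base = fits["base"]
    out: dict[str, ComparisonResult] = {}
    for name in full_specs:
        full = fits[name]
        if full.n_obs != base.n_obs:
            raise RGamError(f"row mismatch between fits for {name!r}")
        out[name] = ComparisonResult(delta_aic=full.aic - base.aic, base=base, full=full)
    return out


def correlate_metrics(
    table: pd.DataFrame, metric_a: str, metric_b: str, method: str = "spearman"
) -> float:
    """Rank (Spearman) correlation between two metric columns, ties averaged."""
    if method != "spearman":
        raise ValueError(f"unsupported correlation method {method!r}")
    a = table[metric_a].to_numpy(dtype=float)
    b = table[metric_b].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 rows to correlate")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("undefined correlation: constant input")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def partial_effect_slope(fit: ModelFit, predictor: str) -> float:
    """Least-squares slope of the fitted partial-effect curve.

    A linear summary of a smooth: with a linear generative truth this
    recovers the coefficient (per unit of the predictor).
    """
    if predictor not in fit.partial_effects:
        raise KeyError(f"fit has no partial effect for {predictor!r}")
    pe = fit.partial_effects[predictor]
    slope, _ = np.polyfit(pe["grid"].to_numpy(), pe["effect"].to_numpy(), 1)
    return float(slope)


def export_partial_effects(
    fit: ModelFit, out_dir: str | Path, plot: bool = False
) -> list[Path]:
    """Write one TSV (grid, effect, lower, upper) per smooth term.

    With ``plot=True`` a PNG per term is written alongside (requires
    matplotlib).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not fit.partial_effects:
        raise ValueError("fit has no partial-effect curves")
    paths: list[Path] = []
    for predictor, pe in fit.partial_effects.items():
        path = out_dir / f"partial_effect_{predictor}.tsv"
        pe.to_csv(path, sep="\t", index=False)
        paths.append(path)
        if plot:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, ax = plt.subplots(figsize=(4, 3))
            ax.fill_between(pe["grid"], pe["lower"], pe["upper"], alpha=0.3, color="green")
            ax.plot(pe["grid"], pe["effect"], color="tab:blue")
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_xlabel(predictor)
            ax.set_ylabel("partial effect on ln(reading speed)")
            fig.tight_layout()
            png = out_dir / f"partial_effect_{predictor}.png"
            fig.savefig(png, dpi=120)
            plt.close(fig)
            paths.append(png)
    return paths
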