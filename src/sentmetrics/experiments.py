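"""Seeded replicate experiments over the full simulate -> fit -> compare stack.

Two standard designs:

- :func:`effect_direction_replicate`: data generated with the default active
  effects; measures whether adding each metric to the base model lowers AIC
  and whether the fitted partial-effect slopes recover the true signs.
- :func:`null_calibration_replicate`: data generated with both metric effects
  zeroed; measures whether the model comparison correctly declines to prefer
  the full model and whether the null smooths' p-values stay insignificant.

Each replicate is a fresh end-to-end run under its own seed; aggregation over
seeds happens in the caller.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Any

from .evaluation import (
    base_model_spec,
    build_sentence_table,
    compare_to_base,
    partial_effect_slope,
    with_metric,
)
from .simulate import EffectSizes, SimConfig, simulate_dataset

__all__ = ["effect_direction_replicate", "null_calibration_replicate"]


def _joined_table(config: SimConfig):
    ds = simulate_dataset(config)
    table = build_sentence_table(
        ds.records,
        {"surprisal": ds.surprisal, "relevance": ds.relevance},
        ds.corpus,
        ds.frequencies,
    )
    return ds, table


def effect_direction_replicate(seed: int, config: SimConfig | None = None) -> dict[str, Any]:
    """One replicate of the effect-recovery design (default study conditions).

    Fits base, base+surprisal, base+relevance, and the joint model in one
    engine session; returns the three delta-AIC values and the fitted
    partial-effect slopes from both the single-metric and joint models.
    """
    config = replace(config or SimConfig(), seed=seed)
    _, table = _joined_table(config)
    base = base_model_spec()
    res = compare_to_base(
        table,
        base,
        {
            "surprisal": with_metric(base, "surprisal"),
            "relevance": with_metric(base, "relevance"),
            "joint": with_metric(base, "surprisal", "relevance"),
        },
    )
    return {
        "seed": seed,
        "n": res["joint"].full.n_obs,
        "delta_aic_surprisal": res["surprisal"].delta_aic,
        "delta_aic_relevance": res["relevance"].delta_aic,
        "delta_aic_joint": res["joint"].delta_aic,
        "slope_surprisal": partial_effect_slope(res["surprisal"].full, "surprisal"),
        "slope_relevance": partial_effect_slope(res["relevance"].full, "relevance"),
        "slope_surprisal_joint": partial_effect_slope(res["joint"].full, "surprisal"),
        "slope_relevance_joint": partial_effect_slope(res["joint"].full, "relevance"),
    }


def null_calibration_replicate(seed: int, config: SimConfig | None = None) -> dict[str, Any]:
    """One replicate with both metric effects set to zero in the generator.

    Returns the joint-model delta AIC and the p-values of the (null) metric
    smooths in the joint fit.
    """
    base_cfg = config or SimConfig()
    null_effects = replace(base_cfg.effects, b_surp=0.0, b_rel=0.0)
    cfg = replace(base_cfg, effects=null_effects, seed=seed)
    _, table = _joined_table(cfg)
    base = base_model_spec()
    res = compare_to_base(
        table, base, {"joint": with_metric(base, "surprisal", "relevance")}
    )
    joint = res["joint"].full
    return {
        "seed": seed,
        "n": joint.n_obs,
        "delta_aic_joint": res["joint"].delta_aic,
        "p_surprisal": joint.term_p_value("surprisal"),
        "p_relevance": joint.term_p_value("relevance"),
    }
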