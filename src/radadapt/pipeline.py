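"""End-to-end orchestration: cohort -> split -> impute -> rank -> train ->
calibrate -> decision curves.

This is the convenience layer the examples and the reproduction script
drive; every stage is the corresponding public module function, in the
order the analysis prescribes (imputation before filtering, filters and
ranks on train-CV rows only, calibration on pooled out-of-fold validation
predictions, decision curves on the held-out test set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from radadapt.calibration import OperatingPoint, PlattMap, brier, fit_platt, select_threshold
from radadapt.dca import DecisionCurve, decision_curve
from radadapt.imputation import ImputationModel, apply_imputer, fit_imputer
from radadapt.models import (
    BuildSpec,
    MetricPanel,
    TrainedModel,
    metrics_from_probs,
    oof_predictions,
    tune_and_train,
)
from radadapt.ranking import FilterTrace, PermutationImportance, RankingReport, rank_features
from radadapt.splitting import SplitPlan, make_folds, make_split
from radadapt.synthetic import SyntheticCohort, SyntheticConfig, generate_cohort
from radadapt.table import FeatureTable


@dataclass
class PipelineResult:
    """Everything one pipeline run produces, stage by stage."""

    cohort: SyntheticCohort
    table: FeatureTable  # imputed
    plan: SplitPlan
    imputer: ImputationModel
    ranking: RankingReport
    trace: FilterTrace
    perm: PermutationImportance
    model: TrainedModel
    oof_raw: pd.Series
    platt: PlattMap
    operating_point: OperatingPoint
    val_metrics: MetricPanel
    test_metrics: MetricPanel
    test_raw: pd.Series
    test_calibrated: pd.Series
    dca_raw: DecisionCurve
    dca_calibrated: DecisionCurve
    brier_raw: float
    brier_calibrated: float
    extras: dict = field(default_factory=dict)


def run_pipeline(
    config: SyntheticConfig,
    seed: int = 0,
    *,
    build: BuildSpec | None = None,
    test_fraction: float = 0.15,
    k_folds: int = 5,
    top_k: int = 500,
    n_repeats: int = 100,
    pt_grid=None,
) -> PipelineResult:
    """Run the full analysis on a synthetic cohort.

    ``seed`` drives the split and model search; the cohort's own seed lives
    in ``config``.  The default build is the gradient-boosted model on the
    top-K consensus features (the study's best performer).
    """
    cohort = generate_cohort(config)
    plan = make_split(cohort.labels, test_fraction=test_fraction, seed=seed)
    make_folds(plan, cohort.labels, k=k_folds)

    imputer = fit_imputer(cohort.table, plan.train_ids, test_ids=plan.test_ids)
    table = apply_imputer(imputer, cohort.table)

    ranking, trace, perm = rank_features(
        table.features, table.labels, plan, k=top_k, n_repeats=n_repeats, seed=seed
    )

    if build is None:
        build = BuildSpec(base="GBT", feature_set="TOP_K", k=top_k, n_trials=25, seed=seed)
    model = tune_and_train(build, table, plan, top_k_features=ranking.top_k)

    # Platt calibration on pooled out-of-fold validation predictions
    oof_raw = oof_predictions(model, table, plan)
    y_train = table.labels.loc[plan.train_ids]
    platt = fit_platt(oof_raw.to_numpy(), y_train.to_numpy(), fitted_on=plan.train_ids)
    oof_cal = platt.transform(oof_raw.to_numpy())
    op = select_threshold(y_train.to_numpy(), oof_cal)

    val_metrics = metrics_from_probs(y_train.to_numpy(), oof_cal, threshold=op.t_star)

    y_test = table.labels.loc[plan.test_ids]
    test_raw = pd.Series(
        model.predict_proba(table.features.loc[plan.test_ids]), index=plan.test_ids
    )
    test_cal = pd.Series(platt.transform(test_raw.to_numpy()), index=plan.test_ids)
    test_metrics = metrics_from_probs(y_test.to_numpy(), test_cal.to_numpy(), threshold=op.t_star)

    dca_raw = decision_curve(y_test.to_numpy(), test_raw.to_numpy(), pt_grid)
    dca_cal = decision_curve(y_test.to_numpy(), test_cal.to_numpy(), pt_grid)

    return PipelineResult(
        cohort=cohort,
        table=table,
        plan=plan,
        imputer=imputer,
        ranking=ranking,
        trace=trace,
        perm=perm,
        model=model,
        oof_raw=oof_raw,
        platt=platt,
        operating_point=op,
        val_metrics=val_metrics,
        test_metrics=test_metrics,
        test_raw=test_raw,
        test_calibrated=test_cal,
        dca_raw=dca_raw,
        dca_calibrated=dca_cal,
        brier_raw=brier(y_test.to_numpy(), test_raw.to_numpy()),
        brier_calibrated=brier(y_test.to_numpy(), test_cal.to_numpy()),
    )
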