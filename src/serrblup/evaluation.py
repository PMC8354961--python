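"""Cross-validation workflows and predictive-ability metrics.

The evaluation protocol is fivefold random cross-validation with five
replicates: within the target environment the phenotyped lines are
partitioned into five near-equal folds, each fold is predicted from the
other four, and the 25 fold-level predictive abilities (Pearson correlation
between predicted and observed phenotypes in the test fold) are averaged.

Three kernels can drive the prediction (additive GBLUP, full-epistasis
ERRBLUP, selected-epistasis sERRBLUP), each in a univariate or a bivariate
(two-environment) mixed model. For sERRBLUP across environments the
interaction selection is computed once from the full data of the selection
environment(s) and reused across folds; in within-environment mode the
selection is recomputed per fold from the training lines only, so test
phenotypes never inform it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PhenotypeTable
from .interaction_effects import (backsolve_effects, effect_variances,
                                  select_top_columns)
from .kernels import (RelationshipMatrix, err_kernel, grm_vanraden,
                      interaction_columns, serr_kernel)
from .mixed_models import (estimate_bivariate_with_fallback, fit_bivariate,
                           fit_univariate, reml_univariate)

__all__ = [
    "CVDesign",
    "CVResult",
    "make_folds",
    "predictive_ability",
    "prediction_accuracy",
    "joint_environment_phenotype",
    "select_interactions",
    "run_univariate_cv",
    "run_bivariate_cv",
]

MODELS = ("GBLUP", "ERRBLUP", "sERRBLUP")


@dataclass
class CVDesign:
    """Reproducible fold partitions: per replicate, a disjoint cover."""

    n_folds: int
    n_replicates: int
    seed: int
    partitions: list  # [replicate][fold] -> array of line ids

    def training_subsets(self):
        """All (replicate, fold, train_ids, test_ids) in order."""
        out = []
        for r, folds in enumerate(self.partitions):
            all_ids = np.concatenate(folds)
            for f, test in enumerate(folds):
                test_set = set(test)
                train = np.array([l for l in all_ids if l not in test_set])
                out.append((r, f, train, test))
        return out


@dataclass
class CVResult:
    """Per-fold predictive abilities and their mean over 25 repetitions."""

    records: pd.DataFrame
    model: dict
    n_excluded: int = 0
    h2: float | None = None
    fallback_flags: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.records["predictive_ability"]))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.records["predictive_ability"], ddof=1))

    @property
    def accuracy(self) -> float | None:
        return None if self.h2 is None else prediction_accuracy(self.mean, self.h2)

    def to_tsv(self, path) -> None:
        df = self.records.copy()
        for key in ("model", "mode", "target_env", "selection_env", "pi"):
            df[key] = str(self.model.get(key, ""))
        df.to_csv(path, sep="\t", index=False)


def make_folds(line_ids, k: int = 5, reps: int = 5, seed: int = 0) -> CVDesign:
    """Random partitions into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    ids = np.asarray(list(line_ids))
    if ids.size < k:
        raise ValueError("fewer lines than folds")
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(reps):
        perm = rng.permutation(ids)
        partitions.append([np.sort(chunk) for chunk in np.array_split(perm, k)])
    return CVDesign(n_folds=k, n_replicates=reps, seed=seed, partitions=partitions)


def predictive_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and observations.

    Undefined correlations (constant input) return NaN with a warning so the
    caller can exclude the fold from the average.
    """
    predicted = np.asarray(predicted, float)
    observed = np.asarray(observed, float)
    if predicted.shape != observed.shape:
        raise ValueError("length mismatch")
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        warnings.warn("constant vector: predictive ability undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(predicted, observed)[0, 1])


def prediction_accuracy(pa: float, h2: float) -> float:
    """Predictive ability divided by the square root of the heritability."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("heritability must lie in (0, 1]")
    return pa / math.sqrt(h2)


def joint_environment_phenotype(phenos: PhenotypeTable, target_env) -> pd.Series:
    """Per-line mean phenotype over all non-target environments.

    Lines observed nowhere outside the target environment are absent from
    the result (treated as unphenotyped in the joint environment).
    """
    others = [e for e in phenos.environments if e != target_env]
    if not others:
        raise ValueError("no non-target environment available")
    sub = phenos.data[phenos.data["environment"].isin(others)]
    return sub.groupby("line", sort=False)["value"].mean()


# ---------------------------------------------------------------------------
# Kernel / selection assembly


def _selection_series(phenos: PhenotypeTable, selection_envs, target_env) -> pd.Series:
    if selection_envs == "joint":
        return joint_environment_phenotype(phenos, target_env)
    if isinstance(selection_envs, (list, tuple, set)):
        sub = phenos.data[phenos.data["environment"].isin(list(selection_envs))]
        if sub.empty:
            raise ValueError(f"unknown environments {selection_envs!r}")
        return sub.groupby("line", sort=False)["value"].mean()
    return phenos.env_series(selection_envs)


def select_interactions(g: GenotypeMatrix, y: pd.Series, pi: float,
                        criterion: str = "effect_variance"):
    """Full-data interaction selection on one environment's phenotypes.

    Fits ERRBLUP by REML on the phenotyped lines, backsolves all pairwise
    interaction effects, scores them, and returns (SelectionResult, scores).
    """
    g_sel = g.subset_lines(list(y.index))
    enc = interaction_columns(g_sel)
    gamma = err_kernel(g_sel)
    vc = reml_univariate(y.to_numpy(float), gamma)
    eff = backsolve_effects(g_sel, enc, y.to_numpy(float), vc.mu_hat,
                            max(vc.sigma2_g, 1e-12), vc.sigma2_eps, gamma)
    eff = effect_variances(eff, enc)
    scores = eff.scores(criterion)
    return select_top_columns(scores, pi, criterion), scores


def _build_kernel(model: str, g: GenotypeMatrix, phenos: PhenotypeTable,
                  target_env, selection_envs, pi, criterion) -> RelationshipMatrix:
    if model == "GBLUP":
        return grm_vanraden(g)
    if model == "ERRBLUP":
        return err_kernel(g)
    if model == "sERRBLUP":
        if pi is None:
            raise ValueError("sERRBLUP requires a selection proportion pi")
        y_sel = _selection_series(phenos, selection_envs, target_env)
        sel, _ = select_interactions(g, y_sel, pi, criterion)
        return serr_kernel(g, sel.column_ids)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _check_model(model: str) -> None:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _fold_pa(predicted, observed) -> float:
    """Fold-level predictive ability; NaN (excluded) when undefined."""
    if np.asarray(observed).size < 3:
        warnings.warn("test fold too small for a correlation; fold excluded",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return predictive_ability(predicted, observed)


def _resolve_h2(h2, y: np.ndarray, gamma: RelationshipMatrix,
                idx: np.ndarray):
    """User-supplied h2, or a full-data GBLUP-based approximation ('auto')."""
    if h2 is None or isinstance(h2, (int, float)):
        return h2
    if h2 == "auto":
        vc = reml_univariate(y, gamma.subset(idx))
        tot = vc.sigma2_g + vc.sigma2_eps
        return vc.sigma2_g / tot if tot > 0 else None
    raise ValueError("h2 must be a number, None, or 'auto'")


# ---------------------------------------------------------------------------
# Cross-validation drivers


def run_univariate_cv(model: str, g: GenotypeMatrix, phenos: PhenotypeTable,
                      target_env, selection_envs=None, pi: float | None = None,
                      criterion: str = "effect_variance",
                      design: CVDesign | None = None,
                      h2=None, seed: int = 0) -> CVResult:
    """Univariate cross-validated prediction within the target environment.

    For sERRBLUP, ``selection_envs`` names the environment(s) whose full
    data drive the interaction selection ('joint' = average of all
    non-target environments); passing the target environment itself switches
    to within-environment mode, where the selection is recomputed from each
    training fold. Variance components are re-estimated per fold from the
    training lines.
    """
    _check_model(model)
    phenos.check_lines(g)
    y_target = phenos.env_series(target_env)
    if design is None:
        design = make_folds(y_target.index, seed=seed)
    within_mode = model == "sERRBLUP" and selection_envs == target_env
    gamma = None
    if not within_mode:
        gamma = _build_kernel(model, g, phenos, target_env, selection_envs,
                              pi, criterion)
    lookup = {l: i for i, l in enumerate(g.line_ids)}
    rows = []
    n_excluded = 0
    for rep, fold, train, test in design.training_subsets():
        y_tr = y_target.loc[train]
        if within_mode:
            sel, _ = select_interactions(g, y_tr, pi, criterion)
            gamma_fold = serr_kernel(g, sel.column_ids)
        else:
            gamma_fold = gamma
        tr_idx = np.array([lookup[l] for l in train], dtype=np.intp)
        te_idx = np.array([lookup[l] for l in test], dtype=np.intp)
        vc = reml_univariate(y_tr.to_numpy(float), gamma_fold.subset(tr_idx))
        pred = fit_univariate(y_tr.to_numpy(float), gamma_fold, vc, tr_idx)
        pa = _fold_pa(pred.g_hat[te_idx], y_target.loc[test].to_numpy(float))
        if np.isnan(pa):
            n_excluded += 1
        rows.append({"replicate": rep, "fold": fold, "predictive_ability": pa})
    h2_val = _resolve_h2(h2, y_target.to_numpy(float),
                         gamma if gamma is not None else grm_vanraden(g),
                         np.array([lookup[l] for l in y_target.index]))
    return CVResult(
        records=pd.DataFrame(rows),
        model={"model": model, "mode": "univariate", "target_env": target_env,
               "selection_env": selection_envs, "pi": pi,
               "criterion": criterion, "seed": design.seed},
        n_excluded=n_excluded, h2=h2_val)


def run_bivariate_cv(model: str, g: GenotypeMatrix, phenos: PhenotypeTable,
                     target_env, second_envs, pi: float | None = None,
                     criterion: str = "effect_variance",
                     design: CVDesign | None = None,
                     h2=None, seed: int = 0,
                     max_iter_full: int = 100,
                     max_iter_fold: int = 50) -> CVResult:
    """Bivariate cross-validated prediction of the target environment.

    Each fold trains on the full data of the second environment(s) plus the
    target-environment training lines; the masked test fold is predicted
    from the bivariate mixed model. Variance components follow the
    two-stage protocol: full-data EM capped at ``max_iter_full`` updates,
    per-fold re-estimation capped at ``max_iter_fold`` with the full-data
    estimates as start values and as fixed fallback on non-convergence.
    For sERRBLUP the interaction selection comes from the second
    environment's full data.
    """
    _check_model(model)
    phenos.check_lines(g)
    y_target = phenos.env_series(target_env)
    y_second = _selection_series(phenos, second_envs, target_env)
    shared = set(y_target.index) & set(y_second.index)
    if len(shared) < 2:
        raise ValueError("environments share fewer than 2 phenotyped lines")
    if design is None:
        design = make_folds(y_target.index, seed=seed)
    gamma = _build_kernel(model, g, phenos, target_env, second_envs, pi, criterion)
    subsets = design.training_subsets()
    fb = estimate_bivariate_with_fallback(
        y_second, y_target, gamma, [tr for _, _, tr, _ in subsets],
        max_iter_full=max_iter_full, max_iter_fold=max_iter_fold)
    lookup = {l: i for i, l in enumerate(g.line_ids)}
    rows = []
    n_excluded = 0
    for (rep, fold, train, test), bvc in zip(subsets, fb.folds):
        pred = fit_bivariate(y_second, y_target.loc[train], list(test),
                             gamma, bvc)
        pa = _fold_pa(pred.y_hat, y_target.loc[test].to_numpy(float))
        if np.isnan(pa):
            n_excluded += 1
        rows.append({"replicate": rep, "fold": fold, "predictive_ability": pa,
                     "fallback": bvc.fixed_fallback_used})
    h2_val = _resolve_h2(h2, y_target.to_numpy(float), gamma,
                         np.array([lookup[l] for l in y_target.index]))
    return CVResult(
        records=pd.DataFrame(rows),
        model={"model": model, "mode": "bivariate", "target_env": target_env,
               "selection_env": second_envs, "pi": pi,
               "criterion": criterion, "seed": design.seed},
        n_excluded=n_excluded, h2=h2_val,
        fallback_flags=[b.fixed_fallback_used for b in fb.folds])
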