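"""Quartile categorization, Goodman-Kruskal Gamma, width tuning by
repeated stratified cross-validation, and held-out with/without-profile
comparison.

All training-derived quantities — quartile cutoffs, the pattern-class
grid extents, sparse-column support, and the fitted model — come from
the training partition only; held-out subjects never influence them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from funcprofile.ordinal import OrdinalGAM, class_weights
from funcprofile.profiles import build_grid, drop_sparse_classes, profile_table

logger = logging.getLogger(__name__)

#: Clinical covariates of the composite descriptor (profile excluded).
COVARIATE_PREDICTORS = ["bmi", "age", "sex", "height", "oa_subcohort"]

MEASURES = ("walk400_time", "walk20_pace", "sitstand_rate")


@dataclass
class CohortData:
    """Feature inputs for one cohort, downstream of segmentation.

    segments
        All segments on valid days: subject_id, day, start, end, mean,
        sd, duration.
    valid_days
        subject_id -> number of valid days K (subjects with K = 0 are
        already excluded).
    covariates, capacity
        One row per subject (io_epoch schemas).
    """

    segments: pd.DataFrame
    valid_days: pd.Series
    covariates: pd.DataFrame
    capacity: pd.DataFrame


@dataclass
class EvaluationReport:
    measure: str
    interval_width: float
    gamma_with_profile: float
    gamma_without_profile: float
    delta: float
    n_train: int
    n_test: int
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def quartile_categorize(train_values, new_values) -> np.ndarray:
    """Ordinal categories 1 < 2 < 3 from training quartiles.

    Q1 and Q3 are linear-interpolation empirical quartiles of the
    training values; a new value is category 1 when strictly below Q1,
    3 when strictly above Q3, and 2 otherwise (values exactly at a
    cutoff fall in the interquartile category).
    """
    train = np.asarray(train_values, dtype=float)
    if train.size < 4:
        raise ValueError("need at least 4 training values for quartiles")
    q1, q3 = np.quantile(train, [0.25, 0.75])
    new = np.asarray(new_values, dtype=float)
    cats = np.full(new.shape, 2, dtype=np.int64)
    cats[new < q1] = 1
    cats[new > q3] = 3
    return cats


def goodman_kruskal_gamma(predicted, true) -> float:
    """Gamma = (C - D)/(C + D) over all unordered pairs.

    C counts pairs whose strict order agrees on both vectors, D pairs
    where it strictly disagrees; pairs tied on either vector drop out.
    NaN (with a warning) when every pair is tied.
    """
    p = np.asarray(predicted)
    t = np.asarray(true)
    if p.shape != t.shape:
        raise ValueError("predicted and true must have equal length")
    if p.size < 2:
        raise ValueError("need at least two observations")
    pl, pi = np.unique(p, return_inverse=True)
    tl, ti = np.unique(t, return_inverse=True)
    tab = np.zeros((pl.size, tl.size))
    np.add.at(tab, (pi, ti), 1.0)
    conc = disc = 0.0
    for i in range(pl.size):
        for j in range(tl.size):
            if tab[i, j] == 0:
                continue
            conc += tab[i, j] * tab[i + 1 :, j + 1 :].sum()
            disc += tab[i, j] * tab[i + 1 :, :j].sum()
    if conc + disc == 0:
        warnings.warn("Gamma undefined: all pairs tied", RuntimeWarning)
        return float("nan")
    return float((conc - disc) / (conc + disc))


def _measure_frame(cohort: CohortData, measure: str) -> pd.DataFrame:
    """Subjects with valid days, full covariates, and the measure."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; one of {MEASURES}")
    cov = cohort.covariates.set_index("subject_id")
    cap = cohort.capacity.set_index("subject_id")[measure]
    ids = [
        sid
        for sid in cohort.valid_days.index
        if sid in cov.index and sid in cap.index and np.isfinite(cap.loc[sid])
    ]
    out = cov.loc[ids, ["bmi", "age", "sex", "height", "oa_subcohort"]].copy()
    out["capacity"] = cap.loc[ids]
    return out


def _fit_and_predict(
    cohort: CohortData,
    frame: pd.DataFrame,
    train_ids,
    test_ids,
    width: float,
    with_profile: bool,
    min_support: int,
    model_kwargs: dict,
):
    """One train/test pass; every derived quantity from training only."""
    train_ids = list(train_ids)
    test_ids = list(test_ids)
    train_vals = frame.loc[train_ids, "capacity"].to_numpy()
    y_train = quartile_categorize(train_vals, train_vals)
    y_test = quartile_categorize(train_vals, frame.loc[test_ids, "capacity"].to_numpy())
    X_train = frame.loc[train_ids, COVARIATE_PREDICTORS].copy()
    X_test = frame.loc[test_ids, COVARIATE_PREDICTORS].copy()
    if with_profile:
        seg_train = cohort.segments[cohort.segments["subject_id"].isin(train_ids)]
        grid = build_grid(seg_train, width)
        prof_train = profile_table(
            seg_train, grid, cohort.valid_days.loc[train_ids]
        )
        prof_train = drop_sparse_classes(prof_train, min_support)
        cols = [c for c in prof_train.columns if c not in ("subject_id", "K")]
        seg_test = cohort.segments[cohort.segments["subject_id"].isin(test_ids)]
        prof_test = profile_table(seg_test, grid, cohort.valid_days.loc[test_ids])
        X_train = X_train.join(prof_train.set_index("subject_id")[cols])
        X_test = X_test.join(prof_test.set_index("subject_id")[cols])
        # profile smooths get their own smoothing parameter, tuned
        # separately from the clinical-covariate smooths
        model_kwargs = {
            "term_groups": {c: 1 for c in cols},
            **model_kwargs,
        }
    w = class_weights(y_train)
    model = OrdinalGAM(**model_kwargs)
    model.fit(X_train, y_train, weights=w)
    return model.predict(X_test), y_test


def cv_tune_width(
    cohort: CohortData,
    measure: str,
    candidate_widths,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    min_support: int = 10,
    model_kwargs: dict | None = None,
):
    """Repeated stratified k-fold CV of held-out Gamma per interval width.

    The grid, profiles, quartile cutoffs and fit are rebuilt from each
    fold's training split.  Folds whose Gamma is undefined (all pairs
    tied) or that observe a single category are excluded from the mean
    and logged.  Returns (selected width, tidy results frame); ties on
    the mean Gamma go to the smaller width.
    """
    widths = list(candidate_widths)
    if len(widths) < 2:
        raise ValueError("need at least 2 candidate widths")
    model_kwargs = model_kwargs or {}
    frame = _measure_frame(cohort, measure)
    ids = np.array(frame.index)
    strat = quartile_categorize(frame["capacity"], frame["capacity"])
    rows = []
    for rep in range(repeats):
        rep_seed = int(
            np.random.SeedSequence([seed, rep]).generate_state(1, np.uint32)[0]
            % (2**31)
        )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        splits = list(skf.split(ids, strat))
        for width in widths:
            for k, (tr, te) in enumerate(splits):
                if np.unique(strat[tr]).size < 2:
                    logger.warning(
                        "fold %d rep %d: single observed category; skipped", k, rep
                    )
                    continue
                pred, truth = _fit_and_predict(
                    cohort, frame, ids[tr], ids[te], width, True,
                    min_support, model_kwargs,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    g = goodman_kruskal_gamma(pred, truth)
                if np.isnan(g):
                    logger.warning(
                        "fold %d rep %d width %g: Gamma undefined; skipped",
                        k, rep, width,
                    )
                    continue
                rows.append((width, rep, k, g))
    results = pd.DataFrame(rows, columns=["width", "repeat", "fold", "gamma"])
    means = results.groupby("width", sort=False)["gamma"].mean()
    means = means.reindex(widths)
    best = means.max()
    selected = min(w for w, m in means.items() if m == best)
    return selected, results


def holdout_evaluate(
    cohort: CohortData,
    measure: str,
    width: float,
    split_fraction: float = 0.8,
    seed: int = 0,
    min_support: int = 10,
    model_kwargs: dict | None = None,
) -> EvaluationReport:
    """Stratified 80/20 holdout comparison of the full descriptor
    against covariates alone, reported as held-out Gammas and their
    difference."""
    model_kwargs = model_kwargs or {}
    frame = _measure_frame(cohort, measure)
    ids = np.array(frame.index)
    strat = quartile_categorize(frame["capacity"], frame["capacity"])
    tr, te = train_test_split(
        np.arange(ids.size),
        train_size=split_fraction,
        stratify=strat,
        random_state=int(seed) % (2**31),
        shuffle=True,
    )
    gammas = {}
    for with_profile in (True, False):
        pred, truth = _fit_and_predict(
            cohort, frame, ids[tr], ids[te], width, with_profile,
            min_support, model_kwargs,
        )
        if np.unique(truth).size < 2:
            warnings.warn(
                f"held-out partition for {measure} lacks a category", RuntimeWarning
            )
        gammas[with_profile] = goodman_kruskal_gamma(pred, truth)
    return EvaluationReport(
        measure=measure,
        interval_width=float(width),
        gamma_with_profile=gammas[True],
        gamma_without_profile=gammas[False],
        delta=gammas[True] - gammas[False],
        n_train=len(tr),
        n_test=len(te),
        seed=int(seed),
    )
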