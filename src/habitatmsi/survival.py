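"""Prognostic modeling: ridge-penalized Cox models and their evaluation.

Three model families are supported, following the clinical / radiomic /
combined design: the C Model uses four encoded clinical covariates
(dichotomized age, ordinal T and N stage, dichotomized plasma cfEBV
DNA), the R Model uses MSI feature profiles, and the CR Model uses both.
All are L2-penalized Cox proportional-hazards fits (Breslow ties) with
internally standardized columns; the penalty can be fixed or chosen by
K-fold cross-validated partial likelihood on the training split.

Evaluation: Harrell's C-index (tied risks count 1/2) with percentile-
bootstrap confidence intervals, IPCW cumulative/dynamic AUC at a fixed
horizon (default 60 months), Kaplan-Meier curves and the two-sample
log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

EBV_CUTOFF_COPIES_PER_ML = 4000.0
DEFAULT_AUC_HORIZON_MONTHS = 60.0

CLINICAL_COLUMNS = ["age_ge_median", "t_stage", "n_stage", "ebv_ge_4000"]


@dataclass
class DesignMatrix:
    X: pd.DataFrame
    age_median: float | None = None


def encode_clinical(
    records: pd.DataFrame, age_median: float | None = None
) -> DesignMatrix:
    """Encode clinical covariates in a fixed column order.

    Age is dichotomized at the (training) median with the >= convention;
    cfEBV DNA at 4000 copies/mL (>= is positive); T stage stays ordinal
    1-4 and N stage ordinal 0-3.  Pass the training median when encoding
    a test cohort.
    """
    needed = ["age_years", "t_stage", "n_stage", "ebv_dna_copies_per_ml"]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns {missing_cols}")
    bad = records[needed].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"missing covariate values for patients {list(records.index[bad])}"
        )
    if age_median is None:
        age_median = float(records["age_years"].median())
    X = pd.DataFrame(
        {
            "age_ge_median": (records["age_years"] >= age_median).astype(int),
            "t_stage": records["t_stage"].astype(int),
            "n_stage": records["n_stage"].astype(int),
            "ebv_ge_4000": (
                records["ebv_dna_copies_per_ml"] >= EBV_CUTOFF_COPIES_PER_ML
            ).astype(int),
        },
        index=records.index,
    )
    return DesignMatrix(X=X, age_median=age_median)


@dataclass
class CoxFit:
    coef: np.ndarray  # on the original column scale
    coef_std: np.ndarray  # on the standardized scale
    columns: list[str]
    penalty: float
    converged: bool
    n_iterations: int
    col_mean: np.ndarray
    col_sd: np.ndarray

    def risk_scores(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Linear predictor (log relative hazard) for new rows."""
        Xa = np.asarray(X, dtype=float)
        Xs = (Xa - self.col_mean) / self.col_sd
        return Xs @ self.coef_std


def breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Cox partial log-likelihood with Breslow tie handling (used for
    cross-validation scoring and as a reference in tests)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_risk = -np.inf
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        block = eta_o[i:j]
        log_risk = np.logaddexp(log_risk, np.logaddexp.reduce(block))
        ev = e_o[i:j] == 1
        d = int(ev.sum())
        if d > 0:
            ll += float(block[ev].sum()) - d * log_risk
        i = j
    return float(ll)


def fit_cox_ridge(
    X: pd.DataFrame | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    penalty: float = 1.0,
    max_iter: int = 100,
) -> CoxFit:
    """L2-penalized Cox fit (Breslow ties) on internally standardized
    columns; coefficients are reported on both scales."""
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        columns = [f"x{i}" for i in range(Xa.shape[1])]
    mean = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (Xa - mean) / sd
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxPHSurvivalAnalysis(
        alpha=penalty, ties="breslow", n_iter=max_iter, tol=1e-9
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            model.fit(Xs, y)
        except Warning as w:  # optimizer warning -> flag, refit quietly
            converged = False
            warnings.warn(f"Cox fit did not fully converge: {w}", stacklevel=2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xs, y)
    coef_std = np.asarray(model.coef_, dtype=float)
    return CoxFit(
        coef=coef_std / sd,
        coef_std=coef_std,
        columns=columns,
        penalty=penalty,
        converged=converged,
        n_iterations=max_iter,
        col_mean=mean,
        col_sd=sd,
    )


def cv_select_penalty(
    X: pd.DataFrame | np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    grid: np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Pick the ridge penalty maximizing held-out partial likelihood."""
    if grid is None:
        grid = np.logspace(-1, 2, 5)
    Xa = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(time)
    rng = np.random.default_rng(seed)
    # stratify folds by event status so each fold has events
    folds = np.zeros(n, dtype=int)
    for grp in (event == 1, event == 0):
        idx = np.nonzero(grp)[0]
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    scores = []
    for lam in grid:
        s = 0.0
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            if event[tr].sum() < 1 or event[te].sum() < 1:
                continue
            fit = fit_cox_ridge(Xa[tr], time[tr], event[tr], penalty=lam)
            Xs_te = (Xa[te] - fit.col_mean) / fit.col_sd
            s += breslow_partial_loglik(
                fit.coef_std, Xs_te, time[te], event[te]
            )
        scores.append(s)
    return float(grid[int(np.argmax(scores))])


def c_index(risk_scores: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance of risk scores against observed outcomes
    (higher risk should pair with shorter survival; ties count 1/2)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk_scores, dtype=float)
    if event.sum() == 0:
        raise ValueError("no events: C-index undefined")
    # lifelines scores higher prediction = longer survival, so negate
    return float(concordance_index(time, -risk, event))


def time_dependent_auc(
    risk_scores: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    horizon: float = DEFAULT_AUC_HORIZON_MONTHS,
    train_time: np.ndarray | None = None,
    train_event: np.ndarray | None = None,
) -> float:
    """Cumulative/dynamic AUC at one horizon with IPCW weights estimated
    from the (training) censoring distribution."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.any((time <= horizon) & (event == 1)):
        raise ValueError(f"no events on or before horizon {horizon}")
    if not np.any(time > horizon):
        raise ValueError(f"no patients at risk beyond horizon {horizon}")
    if train_time is None:
        train_time, train_event = time, event
    y_train = Surv.from_arrays(
        event=np.asarray(train_event, dtype=int).astype(bool),
        time=np.asarray(train_time, dtype=float),
    )
    y_test = Surv.from_arrays(event=event.astype(bool), time=time)
    auc, _ = cumulative_dynamic_auc(
        y_train, y_test, np.asarray(risk_scores, dtype=float), [horizon]
    )
    return float(auc[0])


@dataclass
class KMLogrankResult:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival
    statistic: float
    p_value: float


def km_logrank(
    groups: np.ndarray | pd.Series,
    time: np.ndarray,
    event: np.ndarray,
) -> KMLogrankResult:
    """Kaplan-Meier curves per group and the two-sample log-rank test."""
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(uniq)}")
    curves = {}
    for g in uniq:
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"group {g} is empty")
        if event[sel].sum() == 0:
            warnings.warn(f"group {g} has zero events", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a = groups == uniq[0]
    res = logrank_test(time[a], time[~a], event[a], event[~a])
    return KMLogrankResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def bootstrap_ci(
    metric_fn,
    data: tuple[np.ndarray, ...],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI over patient-level resamples.

    ``metric_fn`` receives the resampled arrays; resamples on which it
    raises (e.g. no events) are redrawn, up to ``max_redraws`` extra
    attempts each, with a warning.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(data[0])
    vals = []
    n_redraws = 0
    for _ in range(n_boot):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                vals.append(metric_fn(*(np.asarray(d)[idx] for d in data)))
                break
            except (ValueError, ZeroDivisionError):
                n_redraws += 1
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
    if n_redraws:
        warnings.warn(
            f"{n_redraws} degenerate bootstrap resamples were redrawn",
            stacklevel=2,
        )
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class ModelGridParams:
    penalty: float | str = "cv"  # "cv" or a fixed value
    horizon: float = DEFAULT_AUC_HORIZON_MONTHS
    n_boot: int = 200
    seed: int = 0


def _model_design(
    model: str,
    clinical: pd.DataFrame,
    msi: pd.DataFrame | None,
) -> pd.DataFrame:
    if model == "C":
        return clinical
    if model == "R":
        assert msi is not None
        return msi
    if model == "CR":
        assert msi is not None
        return pd.concat([clinical, msi], axis=1)
    raise ValueError(f"unknown model {model!r}")


def run_model_grid(
    msi_tables: dict[tuple[str, str], pd.DataFrame],
    records: pd.DataFrame,
    split: pd.Series,
    models: tuple[str, ...] = ("C", "R", "CR"),
    params: ModelGridParams | None = None,
) -> pd.DataFrame:
    """Fit and evaluate every (channel, region, model) cell.

    ``msi_tables`` maps (channel, region) to a patient-indexed MSI
    feature table; ``records`` is indexed by patient with survival and
    clinical columns; ``split`` holds "train"/"test" per patient.  The C
    Model is clinical-only and therefore identical across cells; it is
    reported once per split under channel="-", region="-".

    For the KM/log-rank column patients are grouped by the training-
    median risk score.  Returns one row per cell and split.
    """
    p = params or ModelGridParams()
    tr = split == "train"
    te = split == "test"
    enc = encode_clinical(records.loc[tr])
    clin_all = encode_clinical(records, age_median=enc.age_median).X
    t_all = records["time_months"].to_numpy(float)
    e_all = records["event"].to_numpy(int)
    rows = []

    def evaluate(cell_models, channel, region, msi_df):
        for model in cell_models:
            design = _model_design(model, clin_all, msi_df)
            X_tr = design.loc[tr]
            lam = p.penalty
            if lam == "cv":
                lam = cv_select_penalty(
                    X_tr, t_all[tr.to_numpy()], e_all[tr.to_numpy()], seed=p.seed
                )
            fit = fit_cox_ridge(
                X_tr, t_all[tr.to_numpy()], e_all[tr.to_numpy()], penalty=lam
            )
            risk_all = fit.risk_scores(design)
            thresh = float(np.median(risk_all[tr.to_numpy()]))
            for split_name, sel in (("train", tr.to_numpy()), ("test", te.to_numpy())):
                if sel.sum() == 0:
                    continue
                risk, t, e = risk_all[sel], t_all[sel], e_all[sel]
                ci = c_index(risk, t, e)
                lo, hi = bootstrap_ci(
                    c_index, (risk, t, e), n_boot=p.n_boot, seed=p.seed
                )
                try:
                    auc = time_dependent_auc(
                        risk,
                        t,
                        e,
                        horizon=p.horizon,
                        train_time=t_all[tr.to_numpy()],
                        train_event=e_all[tr.to_numpy()],
                    )
                except ValueError:
                    auc = np.nan
                grp = np.where(risk > thresh, "high", "low")
                if len(np.unique(grp)) == 2 and e.sum() > 0:
                    lr = km_logrank(grp, t, e)
                    lr_p = lr.p_value
                else:
                    lr_p = np.nan
                rows.append(
                    {
                        "channel": channel,
                        "region": region,
                        "model": model,
                        "split": split_name,
                        "penalty": lam,
                        "c_index": ci,
                        "ci_low": lo,
                        "ci_high": hi,
                        "auc": auc,
                        "logrank_p": lr_p,
                    }
                )

    if "C" in models:
        evaluate(("C",), "-", "-", None)
    cell_models = tuple(m for m in models if m != "C")
    for (channel, region), msi_df in msi_tables.items():
        msi_aligned = msi_df.loc[records.index]
        evaluate(cell_models, channel, region, msi_aligned)
    return pd.DataFrame(rows)
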