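"""Goodness-of-fit diagnostics: residual tables, Q-Q data, and the VPC.

Conditional weighted residuals (CWRES) are computed from the same FOCE
linearization used for estimation: the log-scale prediction is linearized at
each subject's conditional mode η̂, giving a population-level linear
approximation ``f(η̂) − G η̂`` with covariance ``G Ω Gᵀ + σ² I``; whitening the
observed-minus-linearized residual by the Cholesky factor of that covariance
yields residuals that are approximately standard normal when the model is
correct.  The visual predictive check (VPC) compares observed concentration
percentiles per time bin with the spread of the same percentiles across
model-simulated replicate trials.

Diagnostics never mutate the dataset or the fit; everything returned is a
fresh tidy table ready for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .dataset import PKDataset
from .estimation import (EstimationOptions, FitResult, _Cohort, _eval_logpred,
                         _f_and_g, build_subjects)

__all__ = ["ResidualTable", "compute_cwres", "qq_data", "VPCResult", "vpc"]


@dataclass
class ResidualTable:
    """One row per retained observation; `skipped_subjects` lists subjects
    whose model-implied covariance was singular."""

    table: pd.DataFrame
    skipped_subjects: list = field(default_factory=list)


def compute_cwres(fit: FitResult, dataset: PKDataset,
                  options: EstimationOptions | None = None) -> ResidualTable:
    """Population/individual predictions and conditional weighted residuals.

    Works on log-transformed data throughout (matching the error model);
    `pred` and `ipred` columns are reported on the concentration scale.
    """
    options = options or EstimationOptions()
    pop = fit.population
    subjects = build_subjects(dataset, options.max_doses_back)
    eta_by_sid = {row["ID"]: np.array([row["eta_cl"], row["eta_v2"],
                                       row["eta_v3"]])
                  for _, row in fit.ebe.iterrows()}
    rows = []
    skipped = []
    for subj in subjects:
        if subj.n_obs == 0:
            continue
        eta = eta_by_sid.get(subj.sid, np.zeros(3))
        cohort = _Cohort([subj])
        arrays = cohort.resolve(pop)
        omega = arrays["omega"][0]
        sigma = arrays["sigma"][0]
        active = omega > 0
        f_hat, G_full = _f_and_g(cohort, pop, arrays,
                                 eta[None, :], options.fd_step)
        G = G_full[:, active]
        f0 = _eval_logpred(cohort, pop, arrays,
                           np.zeros((1, 1, 3)))[0]
        y = subj.y
        # linearized population prediction and its covariance
        pred_lin = f_hat - G @ eta[active]
        cov = (G * omega[active] ** 2) @ G.T + sigma ** 2 * np.eye(subj.n_obs)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            skipped.append(subj.sid)
            warnings.warn(f"singular model covariance for subject "
                          f"{subj.sid!r}; excluded from the residual table",
                          RuntimeWarning)
            continue
        cwres = solve_triangular(L, y - pred_lin, lower=True)
        iwres = (y - f_hat) / sigma
        tad = _time_after_dose(dataset, subj.sid, subj.obs_times)
        for j in range(subj.n_obs):
            rows.append({
                "ID": subj.sid, "STUDY": subj.study,
                "time": subj.obs_times[j], "time_after_dose": tad[j],
                "dv": float(np.exp(y[j])),
                "pred": float(np.exp(f0[j])), "ipred": float(np.exp(f_hat[j])),
                "cwres": float(cwres[j]), "iwres": float(iwres[j]),
            })
    return ResidualTable(table=pd.DataFrame(rows), skipped_subjects=skipped)


def _time_after_dose(dataset: PKDataset, sid, obs_times: np.ndarray) -> np.ndarray:
    dose_times, _ = dataset.expanded_doses(sid)
    out = np.empty(obs_times.size)
    for j, t in enumerate(obs_times):
        prior = dose_times[dose_times <= t]
        out[j] = t - prior[-1] if prior.size else np.nan
    return out


def qq_data(residuals: ResidualTable | pd.DataFrame) -> pd.DataFrame:
    """Ordered CWRES against normal scores (a pure function of the table)."""
    table = residuals.table if isinstance(residuals, ResidualTable) else residuals
    values = np.sort(table["cwres"].to_numpy())
    n = values.size
    scores = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    return pd.DataFrame({"normal_score": scores, "cwres": values})


@dataclass
class VPCResult:
    """Per-bin observed percentiles and simulated percentile bands."""

    observed: pd.DataFrame   # bin, p5, p50, p95, n_obs
    bands: pd.DataFrame      # bin, percentile, lo, mid, hi (across replicates)
    n_sim: int


def vpc(fit: FitResult, design, dataset: PKDataset, n_sim: int = 200,
        seed: int = 0, band: float = 90.0) -> VPCResult:
    """Visual predictive check against `n_sim` simulated replicate trials.

    Replicates keep the observed trial exactly as designed — the same
    subjects, covariates, doses, and sampling times — and redraw only the
    random effects and residual errors from the fitted model.  Observations
    are binned by nominal sample time for the scheduled-rich design and by
    sampling occasion (post-dose vs trough windows) for the sparse design;
    for each bin the 5th/50th/95th observed percentiles are compared with the
    `band`% interval of those percentiles across replicates.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    obs = dataset.observations
    obs_binned = _bin(design, obs["TIME"].to_numpy(), obs["DV"].to_numpy())
    observed = _percentiles(obs_binned)

    pop = fit.population
    subjects = build_subjects(dataset)
    cohort = _Cohort(subjects)
    arrays = cohort.resolve(pop)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7C]))
    omega = arrays["omega"]                       # (n, 3)
    etas = (rng.standard_normal((n_sim, cohort.n, 3)) * omega[None, :, :])
    log_pred = _eval_logpred(cohort, pop, arrays, etas)   # (n_sim, n_obs)
    sigma_obs = arrays["sigma"][cohort.obs_subj]
    eps = rng.standard_normal(log_pred.shape) * sigma_obs[None, :]
    dv_sim = np.exp(log_pred + eps)
    times = np.concatenate([s.obs_times for s in cohort.subjects])

    per_rep: list[pd.DataFrame] = []
    for rep in range(n_sim):
        pct = _percentiles(_bin(design, times, dv_sim[rep]))
        pct["rep"] = rep
        per_rep.append(pct)
    sims = pd.concat(per_rep, ignore_index=True)
    lo_q, hi_q = (50 - band / 2) / 100, (50 + band / 2) / 100
    out_rows = []
    for pname in ("p5", "p50", "p95"):
        g = sims.groupby("bin")[pname]
        out_rows.append(pd.DataFrame({
            "bin": g.quantile(0.5).index,
            "percentile": pname,
            "lo": g.quantile(lo_q).to_numpy(),
            "mid": g.quantile(0.5).to_numpy(),
            "hi": g.quantile(hi_q).to_numpy(),
        }))
    bands = pd.concat(out_rows, ignore_index=True)
    empty_bins = observed.loc[observed["n_obs"] == 0, "bin"].tolist()
    if empty_bins:
        warnings.warn(f"empty VPC time bins: {empty_bins}", RuntimeWarning)
    return VPCResult(observed=observed, bands=bands, n_sim=n_sim)


def _bin(design, times: np.ndarray, dv: np.ndarray) -> pd.DataFrame:
    if getattr(design, "schedule", "single") == "single":
        nominal = np.asarray(design.sample_times_h, float)
        idx = np.abs(times[:, None] - nominal[None, :]).argmin(axis=1)
        labels = nominal[idx]
    else:
        labels = np.where(times < 24.0, "day1", "trough")
    return pd.DataFrame({"bin": labels, "dv": dv})


def _percentiles(binned: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for b, grp in binned.groupby("bin"):
        v = grp["dv"].to_numpy()
        rows.append({"bin": b, "p5": np.percentile(v, 5),
                     "p50": np.percentile(v, 50),
                     "p95": np.percentile(v, 95), "n_obs": v.size})
    return pd.DataFrame(rows)
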