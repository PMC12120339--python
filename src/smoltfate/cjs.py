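"""Cormack-Jolly-Seber migration success from section capture histories.

Occasions are the release plus the ordered receiver sections; apparent
survival (Phi) applies to the intervals between occasions and detection
probability (p) to the recapture occasions.  The likelihood is the exact
CJS likelihood conditional on first release, computed per individual so
fish-level covariates (origin, fork length, tag-to-body-mass ratio) can
enter the logit-linear predictors.  Model selection uses QAICc with an
over-dispersion factor from a parametric bootstrap of the global model,
followed by QAICc-weight model averaging with unconditional variances.

Predation bias: "biased" capture histories keep every tag and every
detection; "unbiased" histories drop tags classified as predators, since
their post-ingestion detections belong to the predator, not the smolt.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .layout import ArrayLayout

_EPS = 1e-10


# ---------------------------------------------------------------------------
# capture histories


def build_capture_histories(
    detections: pd.DataFrame,
    layout: ArrayLayout,
    cohort: pd.DataFrame,
    fates: pd.Series | None = None,
    mode: str = "biased",
) -> pd.DataFrame:
    """One row per released fish: 0/1 per section plus covariates.

    ``cohort`` needs columns fish_id, origin, fork_length_mm, mass_g and
    tag_weight_g (or tag_mass_ratio).  ``mode="biased"`` keeps all tags;
    ``mode="unbiased"`` drops every tag whose fate is predator, which
    requires ``fates`` (tags absent from ``fates`` are treated as smolt:
    tags never detected beyond the lake are unclassifiable but their fish
    were released all the same).
    """
    if mode not in ("biased", "unbiased"):
        raise ValueError("mode must be 'biased' or 'unbiased'")
    if mode == "unbiased" and fates is None:
        raise ValueError("unbiased histories require fate assignments")
    if "section" not in detections.columns:
        from .io import assign_sections

        detections = assign_sections(detections, layout)
    sections = [s.value for s in layout.sections]
    cohort = cohort.set_index("fish_id") if "fish_id" in cohort.columns else cohort
    if mode == "unbiased":
        predators = set(fates.index[fates == "predator"])
        cohort = cohort.loc[[i for i in cohort.index if i not in predators]]
    seen = detections.groupby(["transmitter_id", "section"]).size().unstack(fill_value=0)
    out = pd.DataFrame(index=cohort.index)
    for sec in sections:
        col = seen[sec] if sec in seen.columns else pd.Series(0, index=seen.index)
        out[sec] = (col.reindex(cohort.index).fillna(0) > 0).astype(int)
    out["origin"] = cohort["origin"]
    out["fork_length_mm"] = cohort["fork_length_mm"]
    if "tag_mass_ratio" in cohort.columns:
        out["tag_mass_ratio"] = cohort["tag_mass_ratio"]
    else:
        out["tag_mass_ratio"] = cohort["tag_weight_g"] / cohort["mass_g"]
    out.index.name = "fish_id"
    return out


def history_matrix(histories: pd.DataFrame, layout: ArrayLayout) -> np.ndarray:
    """(n, T) binary matrix: release column of ones, then the sections."""
    sections = [s.value for s in layout.sections]
    H = histories[sections].to_numpy(dtype=int)
    return np.column_stack([np.ones(len(H), dtype=int), H])


# ---------------------------------------------------------------------------
# design matrices


_TERMS = ("Location", "Origin", "FL", "TMR", "Location*Origin")


@dataclass
class CJSDesign:
    """Per-individual logit-linear design for Phi (intervals) and p (occasions).

    ``X_phi`` has shape (n, J, K_phi) for the J = T-1 intervals; ``X_p``
    has shape (n, J, K_p) for recapture occasions 2..T.  FL and TMR are
    standardized before entering the design.
    """

    phi_terms: tuple[str, ...]
    p_terms: tuple[str, ...]
    X_phi: np.ndarray
    X_p: np.ndarray
    phi_names: list[str]
    p_names: list[str]

    @property
    def K(self) -> int:
        return self.X_phi.shape[2] + self.X_p.shape[2]

    def split(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = self.X_phi.shape[2]
        return params[:k], params[k:]

    def probabilities(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        b_phi, b_p = self.split(np.asarray(params, dtype=float))
        phi = _expit(self.X_phi @ b_phi)
        p = _expit(self.X_p @ b_p)
        return phi, p


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _standardize(x: np.ndarray) -> np.ndarray:
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _term_blocks(
    terms: tuple[str, ...], n: int, J: int, covars: dict[str, np.ndarray], kind: str
) -> tuple[np.ndarray, list[str]]:
    blocks = [np.ones((n, J, 1))]
    names = [f"{kind}:intercept"]
    occ = np.broadcast_to(np.eye(J)[None, :, 1:], (n, J, J - 1))
    for term in terms:
        if term in (".", ""):
            continue
        if term == "Location":
            blocks.append(occ)
            names += [f"{kind}:loc{j + 2}" for j in range(J - 1)]
        elif term == "Origin":
            blocks.append(np.broadcast_to(covars["origin"][:, None, None], (n, J, 1)))
            names.append(f"{kind}:origin")
        elif term == "FL":
            blocks.append(np.broadcast_to(covars["fl"][:, None, None], (n, J, 1)))
            names.append(f"{kind}:fl")
        elif term == "TMR":
            blocks.append(np.broadcast_to(covars["tmr"][:, None, None], (n, J, 1)))
            names.append(f"{kind}:tmr")
        elif term == "Location*Origin":
            if "Origin" not in terms:
                blocks.append(np.broadcast_to(covars["origin"][:, None, None], (n, J, 1)))
                names.append(f"{kind}:origin")
            blocks.append(occ * covars["origin"][:, None, None])
            names += [f"{kind}:loc{j + 2}:origin" for j in range(J - 1)]
        else:
            raise ValueError(f"unknown model term {term!r}; use one of {_TERMS} or '.'")
    return np.concatenate(blocks, axis=2), names


def build_design(
    histories: pd.DataFrame,
    layout: ArrayLayout,
    phi_terms: tuple[str, ...] | str = ".",
    p_terms: tuple[str, ...] | str = ".",
) -> CJSDesign:
    if isinstance(phi_terms, str):
        phi_terms = (phi_terms,)
    if isinstance(p_terms, str):
        p_terms = (p_terms,)
    n = len(histories)
    J = len(layout.sections)
    covars = {
        "origin": (histories["origin"].astype(str) == "ranched").to_numpy(dtype=float),
        "fl": _standardize(histories["fork_length_mm"].to_numpy(dtype=float)),
        "tmr": _standardize(histories["tag_mass_ratio"].to_numpy(dtype=float)),
    }
    X_phi, phi_names = _term_blocks(tuple(phi_terms), n, J, covars, "phi")
    X_p, p_names = _term_blocks(tuple(p_terms), n, J, covars, "p")
    return CJSDesign(tuple(phi_terms), tuple(p_terms), X_phi, X_p, phi_names, p_names)


# ---------------------------------------------------------------------------
# likelihood


def cjs_neg_log_lik(params: np.ndarray, design: CJSDesign, H: np.ndarray) -> float:
    """Exact CJS negative log-likelihood conditional on first release.

    ``H`` is the (n, T) history matrix whose first column is the release.
    Each individual contributes survival and detection terms up to its last
    detection and the probability of never being seen again afterwards.
    """
    n, T = H.shape
    if design.X_phi.shape[:2] != (n, T - 1):
        raise ValueError(
            f"design covers {design.X_phi.shape[0]} fish x {design.X_phi.shape[1]} "
            f"intervals but histories are {n} x {T - 1}"
        )
    phi, p = design.probabilities(params)
    phi = np.clip(phi, _EPS, 1 - _EPS)
    p = np.clip(p, _EPS, 1 - _EPS)

    last = (T - 1) - np.argmax(H[:, ::-1], axis=1)  # last occasion detected
    # chi[:, j]: P(never detected after occasion j | alive at j)
    chi = np.ones((n, T))
    for j in range(T - 2, -1, -1):
        chi[:, j] = (1 - phi[:, j]) + phi[:, j] * (1 - p[:, j]) * chi[:, j + 1]

    j_idx = np.arange(T - 1)[None, :]
    active = j_idx < last[:, None]  # intervals before the last detection
    det = H[:, 1:]
    ll_obs = active * (
        np.log(phi) + det * np.log(p) + (1 - det) * np.log(1 - p)
    )
    ll = ll_obs.sum() + np.log(chi[np.arange(n), last]).sum()
    return float(-ll)


@dataclass
class CJSFit:
    design: CJSDesign = field(repr=False)
    params: np.ndarray
    cov: np.ndarray = field(repr=False)
    neg_log_lik: float = np.nan
    K: int = 0
    n_released: int = 0
    converged: bool = True
    boundary: bool = False
    qaicc: float = np.nan
    weight: float = np.nan

    @property
    def model_name(self) -> str:
        fmt = lambda t: ",".join(t) if t != (".",) else "."
        return f"Phi({fmt(self.design.phi_terms)})p({fmt(self.design.p_terms)})"

    def _real_scale(self, X: np.ndarray, offset: int, size: int) -> pd.DataFrame:
        """Mean-covariate real-scale estimates with delta-method Wald CIs."""
        xbar = X.mean(axis=0)  # (J, K)
        k = X.shape[2]
        beta = self.params[offset : offset + k]
        cov = self.cov[offset : offset + k, offset : offset + k]
        eta = xbar @ beta
        est = _expit(eta)
        se_eta = np.sqrt(np.einsum("jk,kl,jl->j", xbar, cov, xbar).clip(0))
        lo = _expit(eta - 1.96 * se_eta)
        hi = _expit(eta + 1.96 * se_eta)
        se = est * (1 - est) * se_eta
        return pd.DataFrame({"estimate": est, "se": se, "ci_lo": lo, "ci_hi": hi})

    def phi_by_interval(self) -> pd.DataFrame:
        return self._real_scale(self.design.X_phi, 0, self.design.X_phi.shape[2])

    def p_by_occasion(self) -> pd.DataFrame:
        k = self.design.X_phi.shape[2]
        return self._real_scale(self.design.X_p, k, self.design.X_p.shape[2])

    @property
    def terminal_confounded(self) -> bool:
        """Last-interval Phi and last-occasion p are separately identifiable
        only when one of them is constrained across occasions."""
        return "Location" in self.design.phi_terms and "Location" in self.design.p_terms

    def terminal_product(self) -> float:
        """The identifiable product: last-interval Phi x last-occasion p."""
        return float(
            self.phi_by_interval()["estimate"].iloc[-1]
            * self.p_by_occasion()["estimate"].iloc[-1]
        )


def fit_cjs(
    histories: pd.DataFrame,
    layout: ArrayLayout,
    phi_terms: tuple[str, ...] | str = ".",
    p_terms: tuple[str, ...] | str = ".",
    n_starts: int = 3,
    seed: int = 0,
) -> CJSFit:
    """Maximum-likelihood CJS fit via quasi-Newton optimisation.

    Runs L-BFGS-B from the null start and ``n_starts - 1`` random starts,
    keeps the best optimum, and takes the covariance from the inverse
    numerical Hessian.  Estimates pinned at the boundary (all-ones
    histories) are flagged rather than an error.
    """
    H = history_matrix(histories, layout)
    if H[:, 1:].sum() == 0:
        raise ValueError("no re-detections: the CJS likelihood is uninformative")
    design = build_design(histories, layout, phi_terms, p_terms)
    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(n_starts, 1)):
        x0 = np.zeros(design.K) if s == 0 else rng.normal(0, 1.0, design.K)
        res = optimize.minimize(
            cjs_neg_log_lik,
            x0,
            args=(design, H),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("CJS optimisation failed from all starts")
    hess = _numerical_hessian(lambda b: cjs_neg_log_lik(b, design, H), best.x)
    cov = _safe_inverse(hess)
    boundary = bool(np.any(np.abs(best.x) > 12))
    return CJSFit(
        design=design,
        params=best.x,
        cov=cov,
        neg_log_lik=float(best.fun),
        K=design.K,
        n_released=len(histories),
        converged=bool(best.success or best.fun < np.inf),
        boundary=boundary,
    )


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    hess = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.eye(k)[i] * h
            ej = np.eye(k)[j] * h
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    if not np.isfinite(hess).all():
        hess[~np.isfinite(hess)] = 0.0
    _ = f0
    return hess


def _safe_inverse(mat: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(mat)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(mat)


# ---------------------------------------------------------------------------
# simulation from a CJS model (tests, bootstrap GOF)


def simulate_cjs_histories(
    n: int,
    phi: float | np.ndarray,
    p: float | np.ndarray,
    n_occasions: int,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Simulate (n, T) capture histories released at occasion 0.

    ``phi``/``p`` may be scalars, per-interval vectors of length T-1, or
    (n, T-1) per-individual matrices.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    T = n_occasions
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n, T - 1))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n, T - 1))
    H = np.zeros((n, T), dtype=int)
    H[:, 0] = 1
    alive = np.ones(n, dtype=bool)
    for j in range(T - 1):
        alive &= rng.random(n) < phi[:, j]
        H[:, j + 1] = alive & (rng.random(n) < p[:, j])
    return H


# ---------------------------------------------------------------------------
# goodness of fit, model ranking, averaging


def _saturated_nll(H: np.ndarray) -> float:
    """Multinomial saturated negative log-likelihood over history patterns."""
    _, counts = np.unique(H, axis=0, return_counts=True)
    n = counts.sum()
    return float(-(counts * np.log(counts / n)).sum())


def cjs_deviance(fit: "CJSFit", H: np.ndarray) -> float:
    """Model deviance against the saturated multinomial of history patterns."""
    return 2.0 * (fit.neg_log_lik - _saturated_nll(H))


@dataclass
class GofResult:
    c_hat: float
    c_hat_raw: float
    n_sim: int
    observed_deviance: float
    simulated_deviances: np.ndarray = field(repr=False, default=None)


def bootstrap_gof(
    fit: CJSFit,
    histories: pd.DataFrame,
    layout: ArrayLayout,
    n_sim: int = 1000,
    seed: int = 0,
) -> GofResult:
    """Parametric-bootstrap over-dispersion factor for the global model.

    Simulates ``n_sim`` datasets from the fitted model (same releases and
    covariates), refits, and takes c-hat as observed deviance over the mean
    simulated deviance; values below 1 are reported but floored at 1 for
    quasi-likelihood use.
    """
    rng = np.random.default_rng(seed)
    phi, p = fit.design.probabilities(fit.params)
    T = phi.shape[1] + 1
    obs_dev = cjs_deviance(fit, history_matrix(histories, layout))
    devs = np.empty(n_sim)
    sim_hist = histories.copy()
    sections = [s.value for s in layout.sections]
    for s in range(n_sim):
        H = np.zeros((len(histories), T), dtype=int)
        H[:, 0] = 1
        alive = np.ones(len(histories), dtype=bool)
        for j in range(T - 1):
            alive &= rng.random(len(histories)) < phi[:, j]
            H[:, j + 1] = alive & (rng.random(len(histories)) < p[:, j])
        sim_hist[sections] = H[:, 1:]
        try:
            refit = fit_cjs(
                sim_hist, layout, fit.design.phi_terms, fit.design.p_terms, n_starts=1
            )
            devs[s] = cjs_deviance(refit, H)
        except ValueError:  # degenerate simulation with no re-detections
            devs[s] = np.nan
    mean_dev = float(np.nanmean(devs))
    raw = obs_dev / mean_dev if mean_dev > 0 else 1.0
    return GofResult(
        c_hat=max(raw, 1.0),
        c_hat_raw=float(raw),
        n_sim=n_sim,
        observed_deviance=obs_dev,
        simulated_deviances=devs,
    )


def rank_models_qaicc(fits: list[CJSFit], c_hat: float = 1.0) -> pd.DataFrame:
    """QAICc model table: K, QAICc, delta, and Akaike weights (ascending).

    QAICc = 2 nll / c-hat + 2K + 2K(K+1)/(n - K - 1) with n the number of
    released individuals; at c-hat = 1 this is ordinary AICc.
    """
    if c_hat < 1.0:
        raise ValueError("c_hat below 1 should be floored at 1 before ranking")
    rows = []
    for fit in fits:
        n_eff = fit.n_released
        if n_eff <= fit.K + 1:
            raise ValueError(
                f"{fit.model_name}: effective sample size {n_eff} too small for K={fit.K}"
            )
        qaicc = (
            2.0 * fit.neg_log_lik / c_hat
            + 2.0 * fit.K
            + 2.0 * fit.K * (fit.K + 1) / (n_eff - fit.K - 1)
        )
        fit.qaicc = float(qaicc)
        rows.append({"model": fit.model_name, "K": fit.K, "QAICc": float(qaicc)})
    table = pd.DataFrame(rows).sort_values("QAICc", kind="mergesort").reset_index(drop=True)
    table["dQAICc"] = table["QAICc"] - table["QAICc"].iloc[0]
    w = np.exp(-0.5 * table["dQAICc"])
    table["weight"] = w / w.sum()
    weights = dict(zip(table["model"], table["weight"]))
    for fit in fits:
        fit.weight = float(weights[fit.model_name])
    return table


def model_average(fits: list[CJSFit]) -> dict[str, pd.DataFrame]:
    """QAICc-weight model averaging of real-scale Phi and p.

    Unconditional variance folds model-selection uncertainty in:
    var = sum_i w_i (var_i + (est_i - avg)^2).
    """
    weights = np.array([fit.weight for fit in fits], dtype=float)
    if not np.isfinite(weights).all():
        raise ValueError("fits must be ranked (rank_models_qaicc) before averaging")
    weights = weights / weights.sum()
    out = {}
    for name, grab in (("phi", lambda f: f.phi_by_interval()), ("p", lambda f: f.p_by_occasion())):
        tables = [grab(f) for f in fits]
        est = np.stack([t["estimate"].to_numpy() for t in tables])
        var = np.stack([t["se"].to_numpy() ** 2 for t in tables])
        avg = weights @ est
        unc_var = weights @ (var + (est - avg) ** 2)
        se = np.sqrt(unc_var)
        out[name] = pd.DataFrame(
            {
                "estimate": avg,
                "se": se,
                "ci_lo": np.clip(avg - 1.96 * se, 0, 1),
                "ci_hi": np.clip(avg + 1.96 * se, 0, 1),
            }
        )
    return out


def migration_success_profile(
    histories_biased: pd.DataFrame,
    histories_unbiased: pd.DataFrame,
    layout: ArrayLayout,
) -> pd.DataFrame:
    """Per-section, per-origin proportion of released fish detected at or
    beyond each section, in biased and unbiased modes.

    Both modes share the full release count as denominator: in unbiased
    mode a predated fish counts as a failed migrant (it is dead), so
    removing predator detections can only lower the proportion and the
    biased curve bounds the unbiased curve from above at every section.
    """
    sections = [s.value for s in layout.sections]
    rows = []
    released = histories_biased.groupby("origin").size()
    for origin, n_rel in released.items():
        hb = histories_biased[histories_biased["origin"] == origin]
        hu = histories_unbiased[histories_unbiased["origin"] == origin]
        for i, sec in enumerate(sections):
            beyond = sections[i:]
            rows.append(
                {
                    "origin": origin,
                    "section": sec,
                    "biased": float((hb[beyond].sum(axis=1) > 0).sum() / n_rel),
                    "unbiased": float((hu[beyond].sum(axis=1) > 0).sum() / n_rel),
                }
            )
    return pd.DataFrame(rows)


def candidate_model_set() -> list[tuple[str | tuple[str, ...], str | tuple[str, ...]]]:
    """The candidate (phi_terms, p_terms) pool used for ranking."""
    phis = [".", "Location", "Origin", "FL", "TMR", ("Location*Origin",)]
    ps = [".", "Location"]
    return list(itertools.product(phis, ps))
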