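"""Maximum-likelihood estimation of the sequential best-worst utility model.

The model: the utility respondent j derives from item i is
``U_ij = V_ij + eps_ij`` with iid Gumbel noise, so each choice occasion is a
conditional logit over its alternative set.  With the -1 coding of
worst-side occasions already folded into the design rows (see
:mod:`ascotval.coding`), the probability of the observed pick on an
occasion is ``exp(x_chosen @ beta) / sum_alt exp(x_alt @ beta)``.

Two estimators:

* :class:`BestWorstMNL` — plain conditional logit (all occasions pooled,
  independent).  Globally concave likelihood, solved by Newton iterations
  with the analytic gradient and Hessian; cluster-robust (sandwich)
  standard errors by respondent.
* :class:`BestWorstMixedLogit` — random coefficients on the 7 domain
  constants, ``beta_p = beta_p^m + beta_p^s * eta`` with eta standard
  normal (``distribution="normal"``) or the coefficient log-normal,
  ``beta_p = exp(m_p + s_p * eta)`` (``distribution="lognormal"``).
  Estimated by simulated maximum likelihood over scrambled Halton draws;
  the likelihood contribution of a cluster (a respondent, or a
  respondent's best-side/worst-side half under
  ``cluster_scheme="respondent_by_sign"``) is the average over draws of
  the product of its occasions' choice probabilities.

Both estimators follow sklearn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores) and consume the long-format
choice table produced by :func:`ascotval.coding.responses_to_long`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, ndtri
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .coding import DESIGN_COLUMNS, OCCASIONS, ChoiceOccasion, code_row
from .coefficients import CoefficientTable
from .states import DOMAINS

__all__ = [
    "BestWorstMNL",
    "BestWorstMixedLogit",
    "EstimationError",
    "IdentifiabilityError",
    "occasion_logprob",
    "fit_mnl",
    "fit_mixed",
    "RANDOM_DOMAINS",
]

_NAME_TO_P = {d.name: d.p_index for d in DOMAINS}
_OCC_RANK = {name: k for k, (name, _, _) in enumerate(OCCASIONS)}

# the 7 domain constants that carry random coefficients, in design-column order
RANDOM_DOMAINS: tuple[str, ...] = tuple(
    next(d.name for d in DOMAINS if d.p_index == int(c[1]))
    for c in DESIGN_COLUMNS[:7]
)


class EstimationError(RuntimeError):
    """Optimization failed to converge; carries diagnostics."""


class IdentifiabilityError(ValueError):
    """The design matrix is rank deficient; names the involved columns."""


def occasion_logprob(
    occasion: ChoiceOccasion, beta: np.ndarray | CoefficientTable
) -> float:
    """Log choice probability of one occasion under coefficient vector beta.

    Overflow-guarded by max-subtraction: finite for |V| up to ~700.
    """
    if isinstance(beta, CoefficientTable):
        beta = beta.coef_vector()
    beta = np.asarray(beta, dtype=float)
    rows = np.array(
        [code_row(name, level, occasion.sign) for name, level in occasion.alternatives]
    )
    v = rows @ beta
    chosen_idx = [name for name, _ in occasion.alternatives].index(occasion.chosen)
    return float(v[chosen_idx] - logsumexp(v))


# ----------------------------------------------------------------------
# compiled arrays


@dataclass
class _ChoiceArrays:
    X: np.ndarray  # (n_rows, 31) sign-coded design
    chosen_row: np.ndarray  # (n_occ,) row index of the chosen alternative
    sign: np.ndarray  # (n_rows,)
    dom_col: np.ndarray  # (n_rows,) 0..6 domain column, 7 = control (no column)
    lev_col: np.ndarray  # (n_rows,) 0..23 level column, 24 = level 4 (no column)
    row_occ: np.ndarray  # (n_rows,) occasion index
    occ_ptr: np.ndarray  # (n_occ+1,) row offsets per occasion
    occ_cluster_ptr: np.ndarray  # (n_c+1,) occasion offsets per cluster
    row_cluster: np.ndarray  # (n_rows,)
    n_occ: int
    n_clusters: int
    n_respondents: int
    respondent_of_row: np.ndarray  # (n_rows,) respondent index (for sandwich SEs)


def _compile(choice_data: pd.DataFrame, cluster_scheme: str) -> _ChoiceArrays:
    df = choice_data
    required = {"respondent_id", "task", "occasion", "sign", "alt_domain",
                "alt_level", "chosen"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"choice data lacks columns {sorted(missing)}")
    missing_x = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing_x:
        raise ValueError(f"choice data lacks design columns {missing_x}")

    resp = df["respondent_id"].to_numpy()
    task = df["task"].to_numpy()
    occ_rank = df["occasion"].map(_OCC_RANK).to_numpy()
    if np.any(pd.isna(occ_rank)):
        raise ValueError("unknown occasion labels in choice data")
    side = np.where(df["sign"].to_numpy() > 0, 0, 1)

    resp_codes = pd.factorize(resp, sort=True)[0]
    if cluster_scheme == "respondent":
        cluster = resp_codes
    elif cluster_scheme == "respondent_by_sign":
        cluster = resp_codes * 2 + side
    else:
        raise ValueError(f"unknown cluster_scheme {cluster_scheme!r}")

    order = np.lexsort((np.arange(len(df)), occ_rank, task, resp_codes, cluster))
    df = df.iloc[order]
    cluster = cluster[order]
    resp_codes = resp_codes[order]

    occ_key = pd.MultiIndex.from_arrays(
        [cluster, resp_codes, df["task"].to_numpy(),
         df["occasion"].map(_OCC_RANK).to_numpy()]
    )
    occ_id, _ = pd.factorize(occ_key, sort=False)  # already sorted
    n_occ = occ_id.max() + 1
    occ_ptr = np.searchsorted(occ_id, np.arange(n_occ + 1))

    chosen = df["chosen"].to_numpy().astype(bool)
    per_occ = np.add.reduceat(chosen.astype(int), occ_ptr[:-1])
    if not np.all(per_occ == 1):
        raise ValueError("every occasion must have exactly one chosen alternative")
    chosen_row = np.flatnonzero(chosen)

    occ_cluster = cluster[occ_ptr[:-1]]
    cluster_codes = pd.factorize(occ_cluster, sort=False)[0]
    n_clusters = cluster_codes.max() + 1
    occ_cluster_ptr = np.searchsorted(cluster_codes, np.arange(n_clusters + 1))

    p = df["alt_domain"].map(_NAME_TO_P).to_numpy()
    q = df["alt_level"].to_numpy()
    dom_slot = {pp: i for i, pp in enumerate(pp for pp in range(1, 9) if pp != 5)}
    dom_col = np.array([dom_slot.get(pp, 7) for pp in p])
    lev_col = np.where(q == 4, 24, (p - 1) * 3 + (q - 1))

    row_occ = np.repeat(np.arange(n_occ), np.diff(occ_ptr))
    row_cluster = pd.factorize(cluster, sort=False)[0]

    return _ChoiceArrays(
        X=df[list(DESIGN_COLUMNS)].to_numpy(dtype=float),
        chosen_row=chosen_row,
        sign=df["sign"].to_numpy(dtype=float),
        dom_col=dom_col,
        lev_col=lev_col,
        row_occ=row_occ,
        occ_ptr=occ_ptr,
        occ_cluster_ptr=occ_cluster_ptr,
        row_cluster=row_cluster,
        n_occ=int(n_occ),
        n_clusters=int(n_clusters),
        n_respondents=int(resp_codes.max() + 1),
        respondent_of_row=resp_codes,
    )


def _check_rank(data: _ChoiceArrays) -> None:
    # information matrix at beta = 0 must be full rank for identification
    H = _mnl_hessian(np.zeros(31), data)
    eigvals, eigvecs = np.linalg.eigh(-H)
    bad = eigvals < 1e-8 * max(eigvals.max(), 1.0)
    if bad.any():
        cols = set()
        for v in eigvecs.T[bad]:
            cols.update(np.array(DESIGN_COLUMNS)[np.abs(v) > 0.3])
        raise IdentifiabilityError(
            f"design matrix is rank deficient; collinear columns involve "
            f"{sorted(cols)}"
        )


# ----------------------------------------------------------------------
# simulated likelihood (plain MNL is the R=1, no-mixing special case)


def _halton_eta(n_clusters: int, n_draws: int, seed: int) -> np.ndarray:
    """Standard-normal scrambled Halton draws, (n_clusters, n_draws, 7)."""
    engine = qmc.Halton(d=7, scramble=True, seed=seed)
    engine.fast_forward(100)  # burn-in
    u = engine.random(n_clusters * n_draws)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return ndtri(u).reshape(n_clusters, n_draws, 7)


def _sim_loglik(
    theta: np.ndarray,
    data: _ChoiceArrays,
    eta: np.ndarray | None,
    distribution: str,
    want_grad: bool = True,
    want_scores: bool = False,
    draw_chunk: int | None = None,
):
    """Simulated log likelihood, analytic gradient, per-cluster scores.

    ``theta`` is the 31 fixed/mean parameters (design-column order),
    followed by 7 mixing scales when ``eta`` is given.  Draws are chunked
    so memory stays bounded at ~n_rows * chunk doubles per array.
    """
    mixed = eta is not None
    if mixed and eta.shape[2] == 7:
        # zero slot for control rows, which carry no random coefficient
        eta = np.concatenate([eta, np.zeros(eta.shape[:2] + (1,))], axis=2)
    beta = theta[:31]
    n_rows = data.X.shape[0]
    R = eta.shape[1] if mixed else 1
    if draw_chunk is None:
        draw_chunk = max(1, int(2.0e7 / max(n_rows, 1)))

    if mixed:
        s = theta[31:]
        s_ext = np.append(s, 0.0)
        if distribution == "lognormal":
            m_ext = np.append(beta[:7], -np.inf)
            base = data.X[:, 7:] @ beta[7:]
        else:
            m_ext = None
            base = data.X @ beta
    else:
        base = data.X @ beta

    dc, rc = data.dom_col, data.row_cluster

    def chunk_V(r0, r1):
        if not mixed:
            return base[:, None]
        eta_rows = eta[rc[:, None], r0 + np.arange(r1 - r0)[None, :], dc[:, None]]
        if distribution == "lognormal":
            b = np.exp(m_ext[dc][:, None] + s_ext[dc][:, None] * eta_rows)
            return base[:, None] + data.sign[:, None] * b, eta_rows, b
        V = base[:, None] + data.sign[:, None] * (s_ext[dc][:, None] * eta_rows)
        return V, eta_rows, None

    # pass 1: per-cluster per-draw log likelihood
    ell = np.empty((data.n_clusters, R))
    for r0 in range(0, R, draw_chunk):
        r1 = min(R, r0 + draw_chunk)
        out = chunk_V(r0, r1)
        V = out[0] if mixed else out
        vmax = np.maximum.reduceat(V, data.occ_ptr[:-1], axis=0)
        expV = np.exp(V - vmax[data.row_occ])
        denom = np.add.reduceat(expV, data.occ_ptr[:-1], axis=0)
        logp = V[data.chosen_row] - vmax - np.log(denom)
        ell[:, r0:r1] = np.add.reduceat(logp, data.occ_cluster_ptr[:-1], axis=0)

    Lc = logsumexp(ell, axis=1) - np.log(R)
    ll = float(Lc.sum())
    if not want_grad and not want_scores:
        return ll, None, None

    w = np.exp(ell - Lc[:, None] - np.log(R))  # (n_c, R), rows sum to 1

    n_par = 38 if mixed else 31
    grad = np.zeros(n_par)
    scores = np.zeros((data.n_clusters, n_par)) if want_scores else None
    chosen_mask = np.zeros(n_rows)
    chosen_mask[data.chosen_row] = 1.0

    # pass 2: gradient via draw-weighted residuals
    for r0 in range(0, R, draw_chunk):
        r1 = min(R, r0 + draw_chunk)
        out = chunk_V(r0, r1)
        if mixed:
            V, eta_rows, b = out
        else:
            V, eta_rows, b = out, None, None
        vmax = np.maximum.reduceat(V, data.occ_ptr[:-1], axis=0)
        expV = np.exp(V - vmax[data.row_occ])
        denom = np.add.reduceat(expV, data.occ_ptr[:-1], axis=0)
        prob = expV / denom[data.row_occ]
        d = (chosen_mask[:, None] - prob) * w[rc, r0:r1]

        u = d.sum(axis=1) * data.sign  # fixed/mean weight per row
        g_lev = np.bincount(data.lev_col, weights=u, minlength=25)[:24]
        if mixed and distribution == "lognormal":
            u_m = (d * b).sum(axis=1) * data.sign
            g_dom = np.bincount(dc, weights=u_m, minlength=8)[:7]
            u_s = (d * b * eta_rows).sum(axis=1) * data.sign
            g_s = np.bincount(dc, weights=u_s, minlength=8)[:7]
        else:
            g_dom = np.bincount(dc, weights=u, minlength=8)[:7]
            if mixed:
                u_s = (d * eta_rows).sum(axis=1) * data.sign
                g_s = np.bincount(dc, weights=u_s, minlength=8)[:7]
            else:
                g_s = None
        grad[:7] += g_dom
        grad[7:31] += g_lev
        if mixed:
            grad[31:] += g_s

        if want_scores:
            base_idx = rc * n_par
            flat = scores.reshape(-1)
            w_dom = u_m if (mixed and distribution == "lognormal") else u
            keep = dc < 7
            flat += np.bincount(
                base_idx[keep] + dc[keep], weights=w_dom[keep],
                minlength=data.n_clusters * n_par,
            )
            keep_l = data.lev_col < 24
            flat += np.bincount(
                base_idx[keep_l] + 7 + data.lev_col[keep_l],
                weights=u[keep_l], minlength=data.n_clusters * n_par,
            )
            if mixed:
                flat += np.bincount(
                    base_idx[keep] + 31 + dc[keep], weights=u_s[keep],
                    minlength=data.n_clusters * n_par,
                )
    return ll, grad, scores


def _mnl_hessian(beta: np.ndarray, data: _ChoiceArrays) -> np.ndarray:
    """Analytic Hessian of the pooled conditional-logit log likelihood."""
    v = data.X @ beta
    vmax = np.maximum.reduceat(v, data.occ_ptr[:-1])
    expv = np.exp(v - vmax[data.row_occ])
    denom = np.add.reduceat(expv, data.occ_ptr[:-1])
    p = expv / denom[data.row_occ]
    pX = p[:, None] * data.X
    E = np.add.reduceat(pX, data.occ_ptr[:-1], axis=0)  # (n_occ, 31)
    return -(data.X.T @ pX - E.T @ E)


# ----------------------------------------------------------------------
# estimators


class BestWorstMNL(BaseEstimator):
    """Pooled conditional logit for exploded best-worst data (model "mnl").

    Newton-Raphson on the globally concave log likelihood; standard errors
    are cluster-robust (sandwich) with clusters = respondents.

    Parameters
    ----------
    tol : float
        Convergence threshold on max |gradient| / n_occasions.
    max_iter : int
        Newton iteration cap.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 60):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, choice_data: pd.DataFrame) -> "BestWorstMNL":
        data = _compile(choice_data, "respondent")
        _check_rank(data)
        beta = np.zeros(31)
        ll, grad, _ = _sim_loglik(beta, data, None, "none")
        for _ in range(self.max_iter):
            H = _mnl_hessian(beta, data)
            step = np.linalg.solve(-H, grad)
            # step-halving line search (rarely needed: concave LL)
            for _ in range(30):
                ll_new, grad_new, _ = _sim_loglik(beta + step, data, None, "none")
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            beta = beta + step
            ll, grad = ll_new, grad_new
            if np.abs(grad).max() / data.n_occ < self.tol:
                break
        else:
            raise EstimationError(
                f"MNL Newton did not converge in {self.max_iter} iterations; "
                f"max|grad|/n_occ = {np.abs(grad).max() / data.n_occ:.3g}"
            )

        H = _mnl_hessian(beta, data)
        # sandwich with respondent clusters (independent of the fit's pooling)
        _, _, scores = self._respondent_scores(beta, data)
        bread = np.linalg.inv(-H)
        meat = scores.T @ scores
        cov = bread @ meat @ bread

        self.coef_ = beta
        self.se_ = np.sqrt(np.diag(cov))
        self.cov_ = cov
        self.loglik_ = ll
        self.gradient_max_ = float(np.abs(grad).max())
        self.n_occasions_ = data.n_occ
        self.n_respondents_ = data.n_respondents
        self.coefficient_table_ = CoefficientTable.from_vectors(
            self.coef_, self.se_, model_id="mnl",
            cluster_scheme="respondent", log_likelihood=ll, n_draws=0,
        )
        return self

    @staticmethod
    def _respondent_scores(beta, data):
        return _sim_loglik(beta, data, None, "none", want_scores=True)

    def loglik(self, choice_data: pd.DataFrame, beta: np.ndarray | None = None) -> float:
        """Pooled log likelihood at ``beta`` (default: the fitted optimum)."""
        data = _compile(choice_data, "respondent")
        b = self.coef_ if beta is None else np.asarray(beta, dtype=float)
        ll, _, _ = _sim_loglik(b, data, None, "none", want_grad=False)
        return ll


class BestWorstMixedLogit(BaseEstimator):
    """Mixed logit by simulated maximum likelihood (models #1/#2/#4).

    Random coefficients sit on the 7 domain constants; level effects stay
    fixed.  ``distribution="normal"`` uses beta_p = m_p + s_p * eta;
    ``"lognormal"`` uses beta_p = exp(m_p + s_p * eta) and reports the
    log-scale location m_p as the domain constant.  The cluster whose
    occasions share one set of draws is the respondent
    (``cluster_scheme="respondent"``) or the respondent's best-side /
    worst-side halves (``"respondent_by_sign"``).

    Scrambled Halton draws (seed-deterministic, assigned to clusters in
    sorted respondent-id order so the fit is invariant to row order).
    """

    def __init__(
        self,
        distribution: str = "normal",
        cluster_scheme: str = "respondent",
        n_draws: int = 500,
        seed: int = 0,
        se_method: str = "opg",
        tol: float = 1e-6,
        max_iter: int = 500,
        start: np.ndarray | None = None,
    ):
        self.distribution = distribution
        self.cluster_scheme = cluster_scheme
        self.n_draws = n_draws
        self.seed = seed
        self.se_method = se_method
        self.tol = tol
        self.max_iter = max_iter
        self.start = start

    def fit(self, choice_data: pd.DataFrame) -> "BestWorstMixedLogit":
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        data = _compile(choice_data, self.cluster_scheme)
        _check_rank(data)
        eta = _halton_eta(data.n_clusters, self.n_draws, self.seed)

        if self.start is not None:
            theta0 = np.asarray(self.start, dtype=float).copy()
        else:
            mnl = BestWorstMNL().fit(choice_data)
            beta0 = mnl.coef_.copy()
            if self.distribution == "lognormal":
                # log-scale location for the (positive) domain constants
                beta0[:7] = np.log(np.clip(beta0[:7], 0.05, None))
            theta0 = np.concatenate([beta0, np.full(7, 0.1)])

        def negll(theta):
            ll, grad, _ = _sim_loglik(theta, data, eta, self.distribution)
            return -ll, -grad

        res = optimize.minimize(
            negll, theta0, jac=True, method="L-BFGS-B",
            options={
                "maxiter": self.max_iter,
                "ftol": 1e-11,
                "gtol": self.tol * max(data.n_occ, 1),
                "maxcor": 30,
            },
        )
        if not res.success and "ABNORMAL" in str(res.message):
            raise EstimationError(f"mixed-logit optimization failed: {res.message}")
        theta = res.x.copy()
        theta[31:] = np.abs(theta[31:])  # scale sign is not identified

        ll, grad, scores = _sim_loglik(
            theta, data, eta, self.distribution, want_scores=True
        )
        if self.se_method == "opg":
            cov = np.linalg.pinv(scores.T @ scores)
        elif self.se_method == "hessian":
            H = self._fd_hessian(theta, data, eta)
            cov = np.linalg.pinv(-H)
        else:
            raise ValueError(f"unknown se_method {self.se_method!r}")
        se = np.sqrt(np.clip(np.diag(cov), 0, None))

        self.coef_ = theta[:31]
        self.mixing_sd_ = theta[31:]
        self.se_ = se[:31]
        self.mixing_sd_se_ = se[31:]
        self.cov_ = cov
        self.loglik_ = ll
        self.gradient_max_ = float(np.abs(grad).max())
        self.n_occasions_ = data.n_occ
        self.n_clusters_ = data.n_clusters
        self.n_respondents_ = data.n_respondents
        table = CoefficientTable.from_vectors(
            self.coef_, self.se_,
            model_id=f"mixed_{self.distribution}",
            cluster_scheme=self.cluster_scheme,
            log_likelihood=ll, n_draws=self.n_draws, seed=self.seed,
        )
        table.mixing_sd = {
            name: (float(self.mixing_sd_[k]), float(self.mixing_sd_se_[k]))
            for k, name in enumerate(RANDOM_DOMAINS)
        }
        self.coefficient_table_ = table
        return self

    def _fd_hessian(self, theta, data, eta, h: float = 1e-5) -> np.ndarray:
        n = len(theta)
        H = np.zeros((n, n))
        for j in range(n):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp, _ = _sim_loglik(tp, data, eta, self.distribution)
            _, gm, _ = _sim_loglik(tm, data, eta, self.distribution)
            H[:, j] = (gp - gm) / (2 * h)
        return (H + H.T) / 2

    def loglik(
        self,
        choice_data: pd.DataFrame,
        beta: np.ndarray | None = None,
        mixing_sd: np.ndarray | None = None,
    ) -> float:
        """Simulated log likelihood at given parameters (default: fitted)."""
        data = _compile(choice_data, self.cluster_scheme)
        b = self.coef_ if beta is None else np.asarray(beta, dtype=float)
        s = self.mixing_sd_ if mixing_sd is None else np.asarray(mixing_sd, float)
        eta = _halton_eta(data.n_clusters, self.n_draws, self.seed)
        theta = np.concatenate([b, s])
        ll, _, _ = _sim_loglik(theta, data, eta, self.distribution, want_grad=False)
        return ll


def fit_mnl(choice_data: pd.DataFrame, **kwargs) -> CoefficientTable:
    """Fit the pooled conditional logit and return its coefficient table."""
    return BestWorstMNL(**kwargs).fit(choice_data).coefficient_table_


def fit_mixed(
    choice_data: pd.DataFrame,
    distribution: str = "normal",
    cluster_scheme: str = "respondent",
    n_draws: int = 500,
    seed: int = 0,
    **kwargs,
) -> CoefficientTable:
    """Fit the mixed logit and return its coefficient table."""
    est = BestWorstMixedLogit(
        distribution=distribution, cluster_scheme=cluster_scheme,
        n_draws=n_draws, seed=seed, **kwargs,
    )
    return est.fit(choice_data).coefficient_table_
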