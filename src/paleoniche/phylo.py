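"""Phylogenetic comparative statistics on time-calibrated trees.

Continuous and discrete ancestral-state reconstruction, phylogenetic signal
(Pagel's lambda, Blomberg's K), a nine-model trait-evolution suite compared
by AICc, phylogenetic generalized least squares, per-time-bin branch means
and niche thresholds, lineage-through-time curves, and a contrast-based
rate-through-time proxy.

All continuous-trait machinery works on the Brownian covariance implied by
shared root-to-MRCA path lengths and therefore handles non-contemporaneous
(fossil) tips without assuming ultrametricity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import cholesky, LinAlgError
from scipy import optimize, stats

from .trees import TimeTree

__all__ = [
    "AsrResult", "SignalResult", "asr_bm", "asr_mk",
    "pagel_lambda", "blomberg_k", "phylo_signal",
    "fit_evo_models", "pgls", "branch_bin_means", "niche_thresholds_by_bin",
    "ltt", "rate_through_time_proxy", "bm_mvn_loglik",
]


# --------------------------------------------------------------------- MVN core

def _gls_profile(R: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Profile ML for y ~ N(X beta, sigma2 R): returns (logL, beta, sigma2)."""
    n = y.size
    L = cholesky(R)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    # whiten
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = 1e-300
    logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(logL), beta, sigma2


def bm_mvn_loglik(C: np.ndarray, y: np.ndarray, sigma2: float, mu) -> float:
    """Direct multivariate-normal log density of y ~ N(mu, sigma2*C)."""
    n = y.size
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    V = sigma2 * C
    L = cholesky(V)
    z = np.linalg.solve(L, y - mu)
    return float(-0.5 * (n * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum() + z @ z))


def _tip_values_array(tree: TimeTree, tip_values) -> np.ndarray:
    if isinstance(tip_values, dict):
        return np.array([tip_values[tree.labels[i]] for i in tree.tips], dtype=float)
    x = np.asarray(tip_values, dtype=float)
    if x.size != tree.n_tips:
        raise ValueError("one value per tip required")
    return x


# ----------------------------------------------------------------------- ASR

@dataclass
class AsrResult:
    """Ancestral reconstruction: values (or state posteriors) per node."""
    node_ids: np.ndarray
    node_values: np.ndarray | None = None        # continuous point estimates
    node_var: np.ndarray | None = None           # prediction variances
    ci95: np.ndarray | None = None               # (m, 2) lower/upper
    state_posterior: np.ndarray | None = None    # (m, k) for discrete traits
    sigma2: float | None = None
    root_value: float | None = None
    rate: float | None = None
    extras: dict = field(default_factory=dict)

    def value_of(self, tree: TimeTree) -> np.ndarray:
        """Point values indexed by tree node id (tips included when present)."""
        out = np.full(int(self.node_ids.max()) + 1, np.nan)
        out[self.node_ids] = self.node_values
        return out


def asr_bm(tree: TimeTree, tip_values) -> AsrResult:
    """ML/GLS ancestral states under Brownian motion.

    Internal-node states are the best linear unbiased predictions given the
    tips; prediction variances include the uncertainty of the GLS root
    estimate, and 95% CIs are normal intervals at the ML rate.
    """
    x = _tip_values_array(tree, tip_values)
    tips = tree.tips
    internals = np.array([i for i in range(tree.n_nodes) if tree.children[i]],
                         dtype=np.int64)
    all_nodes = np.concatenate([tips, internals])
    Cfull = tree.mrca_depth_matrix(all_nodes)
    nt = tips.size
    Ctt = Cfull[:nt, :nt]
    Cit = Cfull[nt:, :nt]
    Cii = Cfull[nt:, nt:]
    # guard duplicate zero-length pendants producing singular Ctt
    try:
        L = cholesky(Ctt + 1e-12 * np.eye(nt))
    except LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("singular tip covariance (conflicting zero-length tips)") from exc
    ones = np.ones(nt)
    logL, beta, sigma2 = _gls_profile(Ctt + 1e-12 * np.eye(nt), ones[:, None], x)
    mu = float(beta[0])
    Li = np.linalg.solve(L, np.eye(nt))
    Cinv = Li.T @ Li
    w = Cit @ Cinv
    pred = mu + w @ (x - mu)
    var_mu = 1.0 / float(ones @ Cinv @ ones)
    cond = np.diag(Cii) - np.einsum("ij,ij->i", w, Cit)
    var = sigma2 * (np.clip(cond, 0.0, None) + var_mu * (1.0 - w @ ones) ** 2)
    sd = np.sqrt(var)
    ci = np.column_stack([pred - 1.959963984540054 * sd, pred + 1.959963984540054 * sd])
    return AsrResult(node_ids=internals, node_values=pred, node_var=var, ci95=ci,
                     sigma2=sigma2, root_value=mu, extras={"logL": logL})


def _mk_transition(k: int, q: float, t: float) -> np.ndarray:
    """Transition matrix of the symmetric k-state Mk chain (rate q per pair)."""
    e = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - e) / k)
    P[np.diag_indices(k)] = 1.0 / k + (k - 1.0) / k * e
    return P


def _mk_loglik(tree: TimeTree, states: np.ndarray, k: int, q: float):
    up = np.ones((tree.n_nodes, k))
    for i in tree.postorder:
        if tree.is_tip(i):
            up[i] = 0.0
            up[i, states[np.where(tree.tips == i)[0][0]]] = 1.0
        else:
            for c in tree.children[i]:
                P = _mk_transition(k, q, tree.blen[c])
                up[i] *= P @ up[c]
    lik = up[tree.root].sum() / k
    return np.log(lik) if lik > 0 else -np.inf, up


def asr_mk(tree: TimeTree, tip_states, k_states: int | None = None) -> AsrResult:
    """Marginal ancestral state posteriors under a one-rate symmetric Mk model.

    The rate is ML-fit; posteriors come from the standard up/down (rerooting)
    pass with a flat root prior, so they sum to one at every node.
    """
    if isinstance(tip_states, dict):
        states = np.array([tip_states[tree.labels[i]] for i in tree.tips], dtype=int)
    else:
        states = np.asarray(tip_states, dtype=int)
    k = int(k_states) if k_states else int(states.max()) + 1
    if states.min() < 0 or states.max() >= k:
        raise ValueError("states must lie in 0..k-1")

    def nll(logq):
        ll, _ = _mk_loglik(tree, states, k, np.exp(logq))
        return -ll

    if np.unique(states).size == 1:
        qhat = 1e-10  # boundary: a single observed state pins the rate at ~0
    else:
        res = optimize.minimize_scalar(nll, bounds=(np.log(1e-8), np.log(1e3)),
                                       method="bounded")
        qhat = float(np.exp(res.x))
    ll, up = _mk_loglik(tree, states, k, qhat)
    down = np.zeros((tree.n_nodes, k))
    down[tree.root] = 1.0 / k
    for i in tree.preorder:
        for c in tree.children[i]:
            sib_prod = down[i].copy()
            for s in tree.children[i]:
                if s != c:
                    Ps = _mk_transition(k, qhat, tree.blen[s])
                    sib_prod = sib_prod * (Ps @ up[s])
            Pc = _mk_transition(k, qhat, tree.blen[c])
            down[c] = sib_prod @ Pc
    post = up * down
    post /= post.sum(axis=1, keepdims=True)
    nodes = np.arange(tree.n_nodes)
    return AsrResult(node_ids=nodes, state_posterior=post, rate=qhat,
                     extras={"logL": ll, "k_states": k})


# ------------------------------------------------------------ phylogenetic signal

@dataclass
class SignalResult:
    lambda_hat: float | None = None
    p_lambda: float | None = None
    K: float | None = None
    p_K: float | None = None
    n_permutations: int = 0
    extras: dict = field(default_factory=dict)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _is_pd(M: np.ndarray) -> bool:
    try:
        cholesky(M)
        return True
    except LinAlgError:
        return False


def _lambda_max(C: np.ndarray) -> float:
    """Largest lambda keeping the lambda-transformed covariance PD (bisection)."""
    hi = 1.0
    while _is_pd(_lambda_cov(C, hi * 2)) and hi < 64:
        hi *= 2
    lo = hi if _is_pd(_lambda_cov(C, hi)) else 0.0
    hi2 = hi * 2
    for _ in range(60):
        mid = 0.5 * (lo + hi2)
        if _is_pd(_lambda_cov(C, mid)):
            lo = mid
        else:
            hi2 = mid
    return lo * 0.9999


def pagel_lambda(tree: TimeTree, tip_values, C: np.ndarray | None = None) -> SignalResult:
    """ML Pagel's lambda with a data-dependent upper bound (may exceed 1).

    Lambda scales the shared (internal) covariance while keeping tip variances,
    so lambda=1 reproduces plain Brownian motion and lambda=0 a star phylogeny.
    The p-value is a likelihood-ratio test against lambda=0 (chi2, 1 df).
    """
    x = _tip_values_array(tree, tip_values)
    if x.size < 4:
        raise ValueError("need at least 4 tips")
    C = tree.vcv() if C is None else C
    n = x.size
    X = np.ones((n, 1))
    lmax = _lambda_max(C)

    def nll(lam):
        Cl = _lambda_cov(C, lam)
        if not _is_pd(Cl):
            return 1e10  # rejected inside the search, never surfaced
        return -_gls_profile(Cl, X, x)[0]

    grid = np.linspace(0.0, lmax, 25)
    best = grid[int(np.argmin([nll(g) for g in grid]))]
    lo, hi = max(0.0, best - lmax / 24), min(lmax, best + lmax / 24)
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    lam_hat = float(res.x)
    ll1 = -nll(lam_hat)
    ll0 = -nll(0.0)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, 1))
    return SignalResult(lambda_hat=lam_hat, p_lambda=max(p, 1e-16),
                        extras={"logL_hat": ll1, "logL_lambda0": ll0,
                                "lambda_max": lmax})


def _blomberg_k_stat(x, Cinv, ones, expected_ratio, n):
    ahat = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)
    r = x - ahat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ Cinv @ r) / (n - 1)
    return (mse0 / mse) / expected_ratio


def blomberg_k(tree: TimeTree, tip_values, n_perm: int = 10_000,
               seed: int | None = None, C: np.ndarray | None = None) -> SignalResult:
    """Blomberg's K with a tip-shuffling permutation p-value.

    K is the observed MSE0/MSE ratio over its Brownian expectation
    (tr C - n / (1' C^-1 1)) / (n - 1); K = 1 is the BM expectation.  The
    smallest reportable p with the default 10,000 permutations is 1/10001.
    """
    x = _tip_values_array(tree, tip_values)
    if np.allclose(x, x[0]):
        raise ValueError("K is undefined for a constant trait")
    C = tree.vcv() if C is None else C
    n = x.size
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    expected = (np.trace(C) - n / float(ones @ Cinv @ ones)) / (n - 1)
    k_obs = _blomberg_k_stat(x, Cinv, ones, expected, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        if _blomberg_k_stat(xp, Cinv, ones, expected, n) >= k_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return SignalResult(K=float(k_obs), p_K=float(p), n_permutations=n_perm)


def phylo_signal(tree: TimeTree, tip_values, n_perm: int = 10_000,
                 seed: int | None = None) -> SignalResult:
    a = pagel_lambda(tree, tip_values)
    b = blomberg_k(tree, tip_values, n_perm=n_perm, seed=seed)
    return SignalResult(lambda_hat=a.lambda_hat, p_lambda=a.p_lambda,
                        K=b.K, p_K=b.p_K, n_permutations=n_perm,
                        extras=a.extras)


# --------------------------------------------------------- evolution model suite

def _depth_transform_cov(tree: TimeTree, tdepth: np.ndarray,
                         mrca: np.ndarray, tips: np.ndarray) -> np.ndarray:
    C = tdepth[mrca]
    return C


def fit_evo_models(tree: TimeTree, tip_values, models=None) -> pd.DataFrame:
    """ML fit of nine trait-evolution models, compared by AICc.

    WN white noise; BM Brownian motion; RT linear rate trend through time;
    MT directional mean trend (drift; identifiable thanks to fossil tips);
    DT delta (node-depth power); LB lambda; KP kappa (branch-length power);
    EB early burst (exponentially decaying rate); OU single-optimum
    Ornstein-Uhlenbeck with the root at the optimum.
    """
    x = _tip_values_array(tree, tip_values)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 tips")
    tips = tree.tips
    C = tree.vcv()
    mrca = tree.mrca_matrix(tips)
    depth = tree.depth
    T = float(depth[tips].max())
    D = depth[tips][:, None] + depth[tips][None, :] - 2 * C  # patristic distances
    ones = np.ones((n, 1))
    Xdrift = np.column_stack([np.ones(n), depth[tips]])

    def tdepth_cov(td):
        return td[mrca]

    specs = {}

    specs["WN"] = dict(k=2, theta=None,
                       R=lambda th: np.eye(n), X=ones)
    specs["BM"] = dict(k=2, theta=None, R=lambda th: C, X=ones)
    specs["MT"] = dict(k=3, theta=None, R=lambda th: C, X=Xdrift)

    def r_rt(th):
        b = th[0]
        td = depth + b * depth ** 2 / (2 * T)
        return tdepth_cov(td)
    specs["RT"] = dict(k=3, theta=([-0.99], [5.0]), R=r_rt, X=ones)

    def r_dt(th):
        d = th[0]
        td = T * (depth / T) ** d
        return tdepth_cov(td)
    specs["DT"] = dict(k=3, theta=([0.05], [3.0]), R=r_dt, X=ones)

    lmax = _lambda_max(C)
    specs["LB"] = dict(k=3, theta=([0.0], [lmax]),
                       R=lambda th: _lambda_cov(C, th[0]), X=ones)

    def r_kp(th):
        kap = th[0]
        td = np.zeros(tree.n_nodes)
        for i in tree.preorder:
            if i != tree.root:
                td[i] = td[tree.parent[i]] + tree.blen[i] ** kap
        return tdepth_cov(td)
    specs["KP"] = dict(k=3, theta=([1e-3], [3.0]), R=r_kp, X=ones)

    def r_eb(th):
        a = th[0]
        if abs(a) < 1e-9:
            return C
        return (np.exp(a * C) - 1.0) / a
    specs["EB"] = dict(k=3, theta=([-10.0 / T], [-1e-9]), R=r_eb, X=ones)

    def r_ou(th):
        al = th[0]
        if al < 1e-9:
            return C
        return np.exp(-al * D) * (1.0 - np.exp(-2.0 * al * C)) / (2.0 * al)
    specs["OU"] = dict(k=3, theta=([1e-9], [50.0 / T]), R=r_ou, X=ones)

    if models is not None:
        specs = {m: specs[m] for m in models}

    rows = []
    for name, sp in specs.items():
        try:
            if sp["theta"] is None:
                logL, beta, s2 = _gls_profile(sp["R"](None) + 1e-12 * np.eye(n),
                                              sp["X"], x)
                par = {}
            else:
                lo, hi = sp["theta"][0][0], sp["theta"][1][0]

                def nll(t):
                    R = sp["R"]([t])
                    try:
                        return -_gls_profile(R + 1e-12 * np.eye(n), sp["X"], x)[0]
                    except LinAlgError:
                        return 1e10

                grid = np.linspace(lo, hi, 20)
                t0 = grid[int(np.argmin([nll(g) for g in grid]))]
                res = optimize.minimize_scalar(
                    nll, bounds=(max(lo, t0 - (hi - lo) / 19),
                                 min(hi, t0 + (hi - lo) / 19)),
                    method="bounded", options={"xatol": 1e-9})
                that = float(res.x)
                logL, beta, s2 = _gls_profile(sp["R"]([that]) + 1e-12 * np.eye(n),
                                              sp["X"], x)
                pname = {"RT": "rate_slope", "DT": "delta", "LB": "lambda",
                         "KP": "kappa", "EB": "a", "OU": "alpha"}[name]
                par = {pname: that}
            k = sp["k"]
            aicc = -2 * logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            row = dict(model=name, logL=logL, k=k, AICc=aicc, sigma2=s2,
                       root=float(beta[0]), failed=False, **par)
            if name == "MT":
                row["drift"] = float(beta[1])
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - report, keep table
            warnings.warn(f"model {name} failed: {exc}")
            rows.append(dict(model=name, logL=np.nan, k=sp["k"], AICc=np.nan,
                             failed=True))
    tab = pd.DataFrame(rows).set_index("model")
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    return tab


# ---------------------------------------------------------------------- PGLS

def pgls(tree: TimeTree, response, predictors) -> dict:
    """Phylogenetic GLS under the Brownian correlation structure.

    On a star phylogeny this reduces to ordinary least squares.  Returns
    coefficients, standard errors, t statistics and two-sided p-values.
    """
    y = _tip_values_array(tree, response)
    P = np.asarray(predictors, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = y.size
    X = np.column_stack([np.ones(n), P])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear predictors")
    C = tree.vcv() + 1e-12 * np.eye(n)
    L = cholesky(C)
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
    resid = yi - Xi @ beta
    df = n - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(Xi.T @ Xi)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    return {"coef": beta, "se": se, "t": tstat, "p": pvals, "df": df,
            "sigma2": s2}


# ------------------------------------------------------- binning along branches

def _branch_segments(tree: TimeTree, values: np.ndarray):
    """Yield (age_old, age_young, v_old, v_young) per branch (parent->child)."""
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        p = tree.parent[i]
        yield float(tree.age[p]), float(tree.age[i]), float(values[p]), float(values[i])


def _values_over_nodes(tree: TimeTree, asr: AsrResult, tip_values) -> np.ndarray:
    vals = np.full(tree.n_nodes, np.nan)
    tips_x = _tip_values_array(tree, tip_values)
    vals[tree.tips] = tips_x
    vals[asr.node_ids] = asr.node_values
    if np.isnan(vals).any():
        raise ValueError("missing node values for some nodes")
    return vals


def branch_bin_means(tree: TimeTree, asr: AsrResult, tip_values, scheme) -> pd.DataFrame:
    """Length-weighted mean trait value of the branch portions in each time bin.

    Branch values are linearly interpolated between endpoint (node) values;
    each bin's mean weights every branch segment inside the bin by its length.
    Bins containing no branch length are flagged empty (NaN), including bins
    older than the root.
    """
    vals = _values_over_nodes(tree, asr, tip_values)
    edges = scheme.edges
    out = []
    for b in range(len(edges) - 1):
        older, younger = edges[b], edges[b + 1]
        tot_len = 0.0
        tot_int = 0.0
        for a_old, a_new, v_old, v_new in _branch_segments(tree, vals):
            lo = max(a_new, younger)
            hi = min(a_old, older)
            if hi <= lo:
                continue
            span = a_old - a_new
            if span <= 0:
                continue
            # value at age a on the branch (linear in age)
            def v_at(a):
                return v_old + (v_new - v_old) * (a_old - a) / span
            seg = hi - lo
            tot_len += seg
            tot_int += seg * 0.5 * (v_at(lo) + v_at(hi))
        out.append(dict(bin_older=older, bin_younger=younger,
                        label=scheme.labels[b],
                        mean=tot_int / tot_len if tot_len > 0 else np.nan,
                        branch_length=tot_len, empty=tot_len == 0.0))
    return pd.DataFrame(out)


def niche_thresholds_by_bin(tree: TimeTree, asr: AsrResult, tip_values,
                            scheme) -> pd.DataFrame:
    """Per-bin min/max trait value over all branch segments and tips in the bin.

    Because branch values are linear between endpoints, extremes occur at
    segment endpoints, evaluated exactly.
    """
    vals = _values_over_nodes(tree, asr, tip_values)
    edges = scheme.edges
    out = []
    for b in range(len(edges) - 1):
        older, younger = edges[b], edges[b + 1]
        vmin, vmax = np.inf, -np.inf
        found = False
        for a_old, a_new, v_old, v_new in _branch_segments(tree, vals):
            lo = max(a_new, younger)
            hi = min(a_old, older)
            if hi <= lo:
                continue
            span = a_old - a_new
            if span <= 0:
                continue
            for a in (lo, hi):
                v = v_old + (v_new - v_old) * (a_old - a) / span
                vmin, vmax = min(vmin, v), max(vmax, v)
                found = True
        # tips sitting exactly inside the bin are branch endpoints already
        out.append(dict(bin_older=older, bin_younger=younger,
                        label=scheme.labels[b],
                        vmin=vmin if found else np.nan,
                        vmax=vmax if found else np.nan,
                        empty=not found))
    return pd.DataFrame(out)


# ----------------------------------------------------------------------- LTT

def ltt(tree: TimeTree, count_extinct: bool = True):
    """Lineage-through-time step function.

    Returns (ages, counts): event ages in Ma descending and the lineage count
    immediately after each event.  Counts start at 1 before the root split.
    When ``count_extinct`` is on, tips with age > 0 decrement the count at
    their (death/sampling) age.
    """
    events: list[tuple[float, int]] = []
    for i in range(tree.n_nodes):
        if tree.children[i]:
            events.append((float(tree.age[i]), len(tree.children[i]) - 1))
        elif count_extinct and tree.age[i] > 1e-9:
            events.append((float(tree.age[i]), -1))
    events.sort(key=lambda e: -e[0])
    ages, counts = [], []
    c = 1
    for a, d in events:
        c += d
        ages.append(a)
        counts.append(c)
    return np.array(ages), np.array(counts, dtype=int)


# ----------------------------------------------- rate-through-time (contrast proxy)

def independent_contrasts(tree: TimeTree, tip_values):
    """Felsenstein's standardized contrasts; returns (node_ids, contrasts).

    Works on non-ultrametric trees; contrasts are standardized by the summed
    (rate-1) branch-length variance, so under constant-rate BM their squares
    estimate sigma^2.
    """
    x = np.full(tree.n_nodes, np.nan)
    x[tree.tips] = _tip_values_array(tree, tip_values)
    extra = np.zeros(tree.n_nodes)
    contrasts, nodes = [], []
    for i in tree.postorder:
        kids = tree.children[i]
        if not kids:
            continue
        if len(kids) != 2:
            raise ValueError("contrasts require a binary tree")
        c1, c2 = kids
        t1 = tree.blen[c1] + extra[c1]
        t2 = tree.blen[c2] + extra[c2]
        contrasts.append((x[c1] - x[c2]) / np.sqrt(t1 + t2))
        nodes.append(i)
        x[i] = (x[c1] / t1 + x[c2] / t2) / (1.0 / t1 + 1.0 / t2)
        extra[i] = t1 * t2 / (t1 + t2)
    return np.array(nodes, dtype=np.int64), np.array(contrasts)


def rate_through_time_proxy(tree: TimeTree, tip_values, scheme,
                            n_boot: int = 200, seed: int | None = None) -> pd.DataFrame:
    """Contrast-based evolutionary-rate proxy through time with bootstrap CIs.

    Each internal node's squared standardized contrast (a local sigma^2
    estimate under BM) is assigned to the node's age; bins average the
    contrasts falling inside them, with percentile bootstrap CIs.  This is a
    documented proxy for rate-through-time curves, not an rjMCMC shift model.
    """
    if tree.n_tips < 10:
        raise ValueError("need at least 10 tips")
    nodes, con = independent_contrasts(tree, tip_values)
    sq = con ** 2
    ages = tree.age[nodes]
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(len(scheme.edges) - 1):
        older, younger = scheme.edges[b], scheme.edges[b + 1]
        m = (ages <= older) & (ages > younger) if b < len(scheme.edges) - 2 else \
            (ages <= older) & (ages >= younger)
        vals = sq[m]
        if vals.size == 0:
            rows.append(dict(label=scheme.labels[b], bin_older=older,
                             bin_younger=younger, rate=np.nan, lo=np.nan,
                             hi=np.nan, n=0))
            continue
        boots = np.array([rng.choice(vals, vals.size, replace=True).mean()
                          for _ in range(n_boot)])
        rows.append(dict(label=scheme.labels[b], bin_older=older,
                         bin_younger=younger, rate=float(vals.mean()),
                         lo=float(np.percentile(boots, 2.5)),
                         hi=float(np.percentile(boots, 97.5)), n=int(vals.size)))
    return pd.DataFrame(rows)
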