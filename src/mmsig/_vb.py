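"""Mean-field coordinate-ascent engines for truncated stick-breaking DP-GMMs.

Two engines share the same math (normal-Wishart base measure, Beta stick
posteriors): a batched univariate engine whose leading axis runs over
independent 1-D problems (genes), and a single-model multivariate engine.
Both evaluate the evidence lower bound after every full coordinate pass, so
ELBO traces are non-decreasing up to floating-point noise.

Parameterization: the Wishart factor on each component precision is stored
through its *inverse* scale matrix ``invW`` (prior value ``invW0``), so the
posterior-expected covariance is ``invW / (dof - d - 1)``.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import digamma, gammaln, logsumexp

LN2 = float(np.log(2.0))
LN2PI = float(np.log(2.0 * np.pi))
LNPI = float(np.log(np.pi))

_EPS_N = 1e-12          # occupancy below this counts as an empty component
_ACCEPT_SLACK = 1e-9    # relative slack when accepting merge/delete moves


# ---------------------------------------------------------------------------
# univariate (batched) engine: X has shape (G, n)
# ---------------------------------------------------------------------------

def _uni_sub(pr: dict, idx) -> dict:
    """Subset per-gene prior arrays to the active genes."""
    out = dict(pr)
    for key in ("m0", "invW0"):
        v = pr[key]
        if np.ndim(v) == 1:
            out[key] = v[idx]
    return out


def uni_mstep(X: np.ndarray, r: np.ndarray, pr: dict) -> dict:
    """Closed-form updates of q(nu) and q(mu, lambda) given responsibilities."""
    m0 = np.atleast_1d(np.asarray(pr["m0"], dtype=float))[:, None]  # (G,1)
    Nk = r.sum(axis=1)                                   # (G,K)
    Nk_safe = np.maximum(Nk, _EPS_N)
    xbar = (r * X[:, :, None]).sum(axis=1) / Nk_safe
    xbar = np.where(Nk > _EPS_N, xbar, np.broadcast_to(m0, xbar.shape))
    diff = X[:, :, None] - xbar[:, None, :]
    Sk = (r * diff * diff).sum(axis=1)                   # (G,K) scatter
    kappa = pr["kappa0"] + Nk
    m = (pr["kappa0"] * m0 + Nk * xbar) / kappa
    dof = pr["dof0"] + Nk
    dm = xbar - m0
    invW = np.asarray(pr["invW0"], dtype=float)
    if invW.ndim == 1:
        invW = invW[:, None]
    invW = invW + Sk + pr["kappa0"] * Nk / kappa * dm * dm
    K = r.shape[2]
    if K > 1:
        a = 1.0 + Nk[:, :-1]
        tail = Nk[:, ::-1].cumsum(axis=1)[:, ::-1]       # tail_k = sum_{j>=k} N_j
        b = pr["alpha"] + tail[:, 1:]
    else:
        a = np.empty((Nk.shape[0], 0))
        b = np.empty((Nk.shape[0], 0))
    return {"Nk": Nk, "kappa": kappa, "m": m, "dof": dof, "invW": invW,
            "a": a, "b": b}


def uni_elog_pi(post: dict) -> np.ndarray:
    """E[log pi_k] under the Beta stick posteriors (last break fixed at 1)."""
    a, b = post["a"], post["b"]
    G, Km1 = a.shape
    K = Km1 + 1
    out = np.zeros((G, K))
    if Km1 == 0:
        return out
    ElogV = digamma(a) - digamma(a + b)
    Elog1mV = digamma(b) - digamma(a + b)
    cum = np.cumsum(Elog1mV, axis=1)
    prefix = np.concatenate([np.zeros((G, 1)), cum[:, :-1]], axis=1)
    out[:, :Km1] = ElogV + prefix
    out[:, Km1] = cum[:, -1]
    return out


def uni_log_rho(X: np.ndarray, post: dict) -> np.ndarray:
    """Unnormalized log responsibilities, shape (G, n, K)."""
    Elogdet = digamma(post["dof"] / 2.0) + LN2 - np.log(post["invW"])   # (G,K)
    Elogpi = uni_elog_pi(post)
    dev = X[:, :, None] - post["m"][:, None, :]
    quad = (1.0 / post["kappa"])[:, None, :] + \
        (post["dof"] / post["invW"])[:, None, :] * dev * dev
    return (Elogpi + 0.5 * Elogdet - 0.5 * LN2PI)[:, None, :] - 0.5 * quad


def _uni_kl_terms(post: dict, pr: dict) -> np.ndarray:
    """Sum of E[log p] - E[log q] for sticks and normal-Wishart factors, (G,)."""
    alpha = pr["alpha"]
    kappa0 = pr["kappa0"]
    dof0 = pr["dof0"]
    m0 = np.atleast_1d(np.asarray(pr["m0"], dtype=float))[:, None]
    invW0 = np.asarray(pr["invW0"], dtype=float)
    if invW0.ndim == 1:
        invW0 = invW0[:, None]
    kappa, m, dof, invW = post["kappa"], post["m"], post["dof"], post["invW"]

    Elogdet = digamma(dof / 2.0) + LN2 - np.log(invW)
    W = 1.0 / invW

    ln_b0 = 0.5 * dof0 * np.log(invW0) - 0.5 * dof0 * LN2 - gammaln(dof0 / 2.0)
    ln_bk = 0.5 * dof * np.log(invW) - 0.5 * dof * LN2 - gammaln(dof / 2.0)
    e_ln_p_nw = (0.5 * (np.log(kappa0 / (2.0 * np.pi)) + Elogdet
                        - kappa0 / kappa
                        - kappa0 * dof * W * (m - m0) ** 2)
                 + ln_b0 + 0.5 * (dof0 - 2.0) * Elogdet
                 - 0.5 * dof * invW0 * W)
    h_wishart = -ln_bk - 0.5 * (dof - 2.0) * Elogdet + 0.5 * dof
    e_ln_q_nw = 0.5 * Elogdet + 0.5 * np.log(kappa / (2.0 * np.pi)) - 0.5 \
        - h_wishart
    total = (e_ln_p_nw - e_ln_q_nw).sum(axis=1)

    a, b = post["a"], post["b"]
    if a.shape[1]:
        ElogV = digamma(a) - digamma(a + b)
        Elog1mV = digamma(b) - digamma(a + b)
        e_ln_p_v = np.log(alpha) + (alpha - 1.0) * Elog1mV
        e_ln_q_v = (a - 1.0) * ElogV + (b - 1.0) * Elog1mV \
            - (gammaln(a) + gammaln(b) - gammaln(a + b))
        total = total + (e_ln_p_v - e_ln_q_v).sum(axis=1)
    return total


def _softmax_lse(log_rho: np.ndarray):
    """Row softmax over the last axis plus the log-sum-exp, in one sweep."""
    mx = log_rho.max(axis=-1, keepdims=True)
    e = np.exp(log_rho - mx)
    s = e.sum(axis=-1, keepdims=True)
    return e / s, (mx + np.log(s))[..., 0]


def uni_pass(X: np.ndarray, r: np.ndarray, pr: dict):
    """One full coordinate pass; returns (r_new, elbo (G,), posterior)."""
    post = uni_mstep(X, r, pr)
    log_rho = uni_log_rho(X, post)
    r_new, lse = _softmax_lse(log_rho)
    elbo = lse.sum(axis=1) + _uni_kl_terms(post, pr)
    return r_new, elbo, post


def _uni_merge_round(Xa, ra, La, pra, record, traces, idx):
    """One vectorized round of duplicate-component merges (ELBO-guarded).

    Components that have drifted onto the same mode drain into each other
    only geometrically slowly under plain coordinate ascent; proposing their
    merge outright and keeping it wherever the ELBO does not drop removes
    the redundancy in a single step.
    """
    K = ra.shape[2]
    if K < 2:
        return ra, La
    post = uni_mstep(Xa, ra, pra)
    Nk = post["Nk"]
    m = post["m"]
    var = post["invW"] / np.maximum(post["dof"], 1e-9)
    ii, jj = np.triu_indices(K, k=1)
    dist = np.abs(m[:, ii] - m[:, jj]) / np.sqrt(
        0.5 * (var[:, ii] + var[:, jj]) + 1e-12)
    valid = (Nk[:, ii] > 0.02) & (Nk[:, jj] > 0.02)
    dist = np.where(valid, dist, np.inf)
    has_cand = np.isfinite(dist).any(axis=1) & (dist.min(axis=1) < 1.5)
    rows = np.flatnonzero(has_cand)
    if rows.size == 0:
        return ra, La
    r_prop = ra.copy()
    for g in rows:
        # greedily merge all disjoint close pairs for this gene at once
        order = np.argsort(dist[g])
        used: set[int] = set()
        for p in order:
            if dist[g, p] >= 1.5:
                break
            i, j = int(ii[p]), int(jj[p])
            if i in used or j in used:
                continue
            r_prop[g, :, i] = r_prop[g, :, i] + r_prop[g, :, j]
            r_prop[g, :, j] = 0.0
            used.update((i, j))
    # let the merged configuration relax before judging it
    r2 = r_prop
    for _ in range(3):
        r2, L2, _ = uni_pass(Xa, r2, pra)
    accept = L2 >= La - _ACCEPT_SLACK * (1.0 + np.abs(La))
    ra = np.where(accept[:, None, None], r2, ra)
    La = np.where(accept, L2, La)
    if record:
        for g in np.flatnonzero(accept):
            traces[idx[g]].append(La[g])
    return ra, La


def uni_cavi(X: np.ndarray, r: np.ndarray, pr: dict, max_iter: int, tol: float,
             record_trace: bool = False, merge_every: int = 8):
    """Run batched univariate CAVI to convergence.

    Returns (r, elbo (G,), posterior-of-final-r, traces or None).
    Genes are compacted out of the working set once their relative ELBO
    change falls below ``tol``; every ``merge_every`` iterations duplicate
    components are merged where the ELBO allows it.
    """
    G = X.shape[0]
    out_r = r.copy()
    elbo = np.full(G, -np.inf)
    traces = [[] for _ in range(G)] if record_trace else None
    idx = np.arange(G)
    Xa, ra, pra = X, r, pr
    La = np.full(G, -np.inf)
    for it in range(max_iter):
        ra, L_new, _ = uni_pass(Xa, ra, pra)
        if record_trace:
            for j, g in enumerate(idx):
                traces[g].append(L_new[j])
        delta = np.abs(L_new - La)
        La = L_new
        done = delta < tol * (1.0 + np.abs(L_new))
        if done.any():
            out_r[idx[done]] = ra[done]
            elbo[idx[done]] = La[done]
            keep = ~done
            idx = idx[keep]
            if idx.size == 0:
                break
            Xa, ra, La = Xa[keep], ra[keep], La[keep]
            pra = _uni_sub(pr, idx)
        if (it + 1) % merge_every == 0:
            ra, La = _uni_merge_round(Xa, ra, La, pra, record_trace, traces,
                                      idx)
    if idx.size:
        out_r[idx] = ra
        elbo[idx] = La
    post = uni_mstep(X, out_r, pr)
    return out_r, elbo, post, traces


# ---------------------------------------------------------------------------
# multivariate engine: X has shape (n, d)
# ---------------------------------------------------------------------------

def _chol_with_jitter(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, adding diagonal jitter if needed."""
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-6 * float(np.mean(np.diag(A))) + 1e-12
        eye = np.eye(A.shape[0])
        for _ in range(8):
            try:
                return np.linalg.cholesky(A + jitter * eye)
            except np.linalg.LinAlgError:
                jitter *= 10.0
        raise


def _log_wishart_b(logdet_invW: float, dof: float, d: int) -> float:
    """log B(W, dof) of the Wishart normalizer, using log|W^-1|."""
    j = np.arange(1, d + 1)
    return (0.5 * dof * logdet_invW - 0.5 * dof * d * LN2
            - 0.25 * d * (d - 1) * LNPI
            - gammaln(0.5 * (dof + 1 - j)).sum())


def multi_mstep(X: np.ndarray, r: np.ndarray, pr: dict) -> dict:
    n, d = X.shape
    K = r.shape[1]
    m0 = np.asarray(pr["m0"], dtype=float)
    Nk = r.sum(axis=0)                                    # (K,)
    Nk_safe = np.maximum(Nk, _EPS_N)
    xbar = (r.T @ X) / Nk_safe[:, None]
    xbar = np.where(Nk[:, None] > _EPS_N, xbar, m0[None, :])
    M2 = np.einsum("nk,nd,ne->kde", r, X, X, optimize=True)
    Sk = M2 - Nk_safe[:, None, None] * np.einsum("kd,ke->kde", xbar, xbar)
    kappa = pr["kappa0"] + Nk
    m = (pr["kappa0"] * m0[None, :] + Nk[:, None] * xbar) / kappa[:, None]
    dof = pr["dof0"] + Nk
    dm = xbar - m0[None, :]
    invW = pr["invW0"][None, :, :] + Sk + \
        (pr["kappa0"] * Nk / kappa)[:, None, None] * \
        np.einsum("kd,ke->kde", dm, dm)
    invW = 0.5 * (invW + np.swapaxes(invW, 1, 2))
    if K > 1:
        a = 1.0 + Nk[:-1]
        tail = Nk[::-1].cumsum()[::-1]
        b = pr["alpha"] + tail[1:]
    else:
        a = np.empty(0)
        b = np.empty(0)
    return {"Nk": Nk, "kappa": kappa, "m": m, "dof": dof, "invW": invW,
            "a": a, "b": b}


def multi_elog_pi(post: dict) -> np.ndarray:
    a, b = post["a"], post["b"]
    K = a.shape[0] + 1
    out = np.zeros(K)
    if K == 1:
        return out
    ElogV = digamma(a) - digamma(a + b)
    Elog1mV = digamma(b) - digamma(a + b)
    cum = np.cumsum(Elog1mV)
    out[: K - 1] = ElogV + np.concatenate([[0.0], cum[:-1]])
    out[K - 1] = cum[-1]
    return out


def multi_log_rho(X: np.ndarray, post: dict):
    """Returns (log_rho (n,K), per-component cholesky factors, Elogdet)."""
    n, d = X.shape
    K = post["m"].shape[0]
    Elogpi = multi_elog_pi(post)
    log_rho = np.empty((n, K))
    chols = []
    Elogdet = np.empty(K)
    j = np.arange(1, d + 1)
    for k in range(K):
        L = _chol_with_jitter(post["invW"][k])
        chols.append(L)
        logdet_invW = 2.0 * np.log(np.diag(L)).sum()
        Elogdet[k] = digamma(0.5 * (post["dof"][k] + 1 - j)).sum() \
            + d * LN2 - logdet_invW
        dev = X - post["m"][k]
        y = solve_triangular(L, dev.T, lower=True)
        quad = d / post["kappa"][k] + post["dof"][k] * (y * y).sum(axis=0)
        log_rho[:, k] = Elogpi[k] + 0.5 * Elogdet[k] - 0.5 * d * LN2PI \
            - 0.5 * quad
    return log_rho, chols, Elogdet


def _multi_kl_terms(post: dict, pr: dict, chols, Elogdet) -> float:
    d = post["m"].shape[1]
    K = post["m"].shape[0]
    kappa0, dof0, m0 = pr["kappa0"], pr["dof0"], np.asarray(pr["m0"], float)
    invW0 = pr["invW0"]
    L0 = _chol_with_jitter(invW0)
    logdet_invW0 = 2.0 * np.log(np.diag(L0)).sum()
    ln_b0 = _log_wishart_b(logdet_invW0, dof0, d)
    total = 0.0
    for k in range(K):
        Lk = chols[k]
        logdet_invWk = 2.0 * np.log(np.diag(Lk)).sum()
        Wk = cho_solve((Lk, True), np.eye(d))
        dm = post["m"][k] - m0
        y = solve_triangular(Lk, dm, lower=True)
        quad = float(y @ y)                               # dm' Wk dm
        e_ln_p = (0.5 * (d * np.log(kappa0 / (2.0 * np.pi)) + Elogdet[k]
                         - d * kappa0 / post["kappa"][k]
                         - kappa0 * post["dof"][k] * quad)
                  + ln_b0 + 0.5 * (dof0 - d - 1.0) * Elogdet[k]
                  - 0.5 * post["dof"][k] * float((invW0 * Wk).sum()))
        ln_bk = _log_wishart_b(logdet_invWk, post["dof"][k], d)
        h_wish = -ln_bk - 0.5 * (post["dof"][k] - d - 1.0) * Elogdet[k] \
            + 0.5 * post["dof"][k] * d
        e_ln_q = 0.5 * Elogdet[k] + 0.5 * d * np.log(post["kappa"][k] / (2.0 * np.pi)) \
            - 0.5 * d - h_wish
        total += e_ln_p - e_ln_q
    a, b = post["a"], post["b"]
    if a.size:
        alpha = pr["alpha"]
        ElogV = digamma(a) - digamma(a + b)
        Elog1mV = digamma(b) - digamma(a + b)
        e_ln_p_v = np.log(alpha) + (alpha - 1.0) * Elog1mV
        e_ln_q_v = (a - 1.0) * ElogV + (b - 1.0) * Elog1mV \
            - (gammaln(a) + gammaln(b) - gammaln(a + b))
        total += float((e_ln_p_v - e_ln_q_v).sum())
    return float(total)


def multi_pass(X: np.ndarray, r: np.ndarray, pr: dict):
    post = multi_mstep(X, r, pr)
    log_rho, chols, Elogdet = multi_log_rho(X, post)
    lse = logsumexp(log_rho, axis=1)
    r_new = np.exp(log_rho - lse[:, None])
    elbo = float(lse.sum()) + _multi_kl_terms(post, pr, chols, Elogdet)
    return r_new, elbo, post


def multi_cavi(X: np.ndarray, r: np.ndarray, pr: dict, max_iter: int,
               tol: float, record_trace: bool = False, mode: str = "full"):
    pass_fn = multi_pass if mode == "full" else diag_pass
    mstep_fn = multi_mstep if mode == "full" else diag_mstep
    r = r.copy()
    elbo = -np.inf
    trace = [] if record_trace else None
    for _ in range(max_iter):
        r, L, _ = pass_fn(X, r, pr)
        if record_trace:
            trace.append(L)
        if abs(L - elbo) < tol * (1.0 + abs(L)):
            elbo = L
            break
        elbo = L
    post = mstep_fn(X, r, pr)
    return r, elbo, post, trace


# ---------------------------------------------------------------------------
# multivariate engine, diagonal covariance: product of per-dimension
# normal-gamma bases sharing the component's responsibilities and dof/kappa
# ---------------------------------------------------------------------------

def diag_mstep(X: np.ndarray, r: np.ndarray, pr: dict) -> dict:
    n, d = X.shape
    K = r.shape[1]
    m0 = np.asarray(pr["m0"], dtype=float)                # (d,)
    invW0 = np.broadcast_to(np.asarray(pr["invW0"], dtype=float), (d,))
    Nk = r.sum(axis=0)
    Nk_safe = np.maximum(Nk, _EPS_N)
    xbar = (r.T @ X) / Nk_safe[:, None]
    xbar = np.where(Nk[:, None] > _EPS_N, xbar, m0[None, :])
    Sk = r.T @ (X * X) - Nk_safe[:, None] * xbar * xbar
    Sk = np.maximum(Sk, 0.0)
    kappa = pr["kappa0"] + Nk
    m = (pr["kappa0"] * m0[None, :] + Nk[:, None] * xbar) / kappa[:, None]
    dof = pr["dof0"] + Nk
    dm = xbar - m0[None, :]
    invW = invW0[None, :] + Sk + \
        (pr["kappa0"] * Nk / kappa)[:, None] * dm * dm
    if K > 1:
        a = 1.0 + Nk[:-1]
        tail = Nk[::-1].cumsum()[::-1]
        b = pr["alpha"] + tail[1:]
    else:
        a = np.empty(0)
        b = np.empty(0)
    return {"Nk": Nk, "kappa": kappa, "m": m, "dof": dof, "invW": invW,
            "a": a, "b": b}


def diag_log_rho(X: np.ndarray, post: dict) -> np.ndarray:
    n, d = X.shape
    dof = post["dof"][:, None]                            # (K,1)
    invW = post["invW"]                                   # (K,d)
    Elogdet = (digamma(dof / 2.0) + LN2 - np.log(invW)).sum(axis=1)  # (K,)
    dev = X[:, None, :] - post["m"][None, :, :]           # (n,K,d)
    quad = d / post["kappa"][None, :] + \
        (dev * dev * (post["dof"][:, None] / invW)[None, :, :]).sum(axis=2)
    Elogpi = multi_elog_pi(post)
    return Elogpi[None, :] + 0.5 * Elogdet[None, :] - 0.5 * d * LN2PI \
        - 0.5 * quad


def _diag_kl_terms(post: dict, pr: dict) -> float:
    d = post["m"].shape[1]
    m0 = np.asarray(pr["m0"], dtype=float)[None, :]
    invW0 = np.broadcast_to(np.asarray(pr["invW0"], dtype=float),
                            (d,))[None, :]
    kappa0, dof0 = pr["kappa0"], pr["dof0"]
    kappa = post["kappa"][:, None]
    dof = post["dof"][:, None]
    m, invW = post["m"], post["invW"]

    Elogdet = digamma(dof / 2.0) + LN2 - np.log(invW)     # (K,d)
    W = 1.0 / invW
    ln_b0 = 0.5 * dof0 * np.log(invW0) - 0.5 * dof0 * LN2 - gammaln(dof0 / 2.0)
    ln_bk = 0.5 * dof * np.log(invW) - 0.5 * dof * LN2 - gammaln(dof / 2.0)
    e_ln_p = (0.5 * (np.log(kappa0 / (2.0 * np.pi)) + Elogdet
                     - kappa0 / kappa
                     - kappa0 * dof * W * (m - m0) ** 2)
              + ln_b0 + 0.5 * (dof0 - 2.0) * Elogdet
              - 0.5 * dof * invW0 * W)
    h_wish = -ln_bk - 0.5 * (dof - 2.0) * Elogdet + 0.5 * dof
    e_ln_q = 0.5 * Elogdet + 0.5 * np.log(kappa / (2.0 * np.pi)) - 0.5 \
        - h_wish
    total = float((e_ln_p - e_ln_q).sum())
    a, b = post["a"], post["b"]
    if a.size:
        alpha = pr["alpha"]
        ElogV = digamma(a) - digamma(a + b)
        Elog1mV = digamma(b) - digamma(a + b)
        e_ln_p_v = np.log(alpha) + (alpha - 1.0) * Elog1mV
        e_ln_q_v = (a - 1.0) * ElogV + (b - 1.0) * Elog1mV \
            - (gammaln(a) + gammaln(b) - gammaln(a + b))
        total += float((e_ln_p_v - e_ln_q_v).sum())
    return total


def diag_pass(X: np.ndarray, r: np.ndarray, pr: dict):
    post = diag_mstep(X, r, pr)
    log_rho = diag_log_rho(X, post)
    lse = logsumexp(log_rho, axis=1)
    r_new = np.exp(log_rho - lse[:, None])
    elbo = float(lse.sum()) + _diag_kl_terms(post, pr)
    return r_new, elbo, post


# ---------------------------------------------------------------------------
# shared: expected stick weights, initialization, cleanup moves
# ---------------------------------------------------------------------------

def expected_weights(a: np.ndarray, b: np.ndarray, K: int) -> np.ndarray:
    """E[pi] from Beta stick posteriors; telescopes to exactly 1."""
    if K == 1:
        return np.ones(1)
    Ev = np.concatenate([a / (a + b), [1.0]])
    rem = np.concatenate([[1.0], np.cumprod(1.0 - Ev[:-1])])
    return Ev * rem


def init_responsibilities(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Soft seeding from K randomly chosen anchor samples (n, K) or (G, n, K).

    X may be (n, d) for the multivariate engine or (G, n) for the batched
    univariate engine (pass a list of per-gene rngs as ``rng`` in that case).
    """
    if X.ndim == 2 and isinstance(rng, np.random.Generator):
        n, d = X.shape
        idx = rng.choice(n, size=K, replace=K > n)
        centers = X[idx]                                  # (K,d)
        scale = float(np.mean(X.var(axis=0))) + 1e-8
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        log_r = -0.5 * d2 / scale
        log_r += 0.01 * rng.standard_normal(log_r.shape)
        return np.exp(log_r - logsumexp(log_r, axis=1)[:, None])
    raise TypeError("use init_uni_responsibilities for batched input")


def pc_split_inits(X: np.ndarray, K: int, n_pc: int = 4,
                   fractions=(0.15, 0.3, 0.5)) -> list[np.ndarray]:
    """Hard two-way splits along leading principal components.

    Expression subtypes show up as heavy tails along high-variance
    directions, so splitting at both tails of each leading PC seeds the
    coordinate ascent close to candidate cluster structures that random
    anchors rarely find in high dimension. Deterministic.
    """
    n, d = X.shape
    if K < 2:
        return []
    Xc = X - X.mean(axis=0)
    n_pc = min(n_pc, d, n - 1)
    if n_pc < 1:
        return []
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    inits = []
    for p in range(n_pc):
        proj = Xc @ Vt[p]
        for f in fractions:
            for tail in (1, -1):
                cut = np.quantile(tail * proj, 1.0 - f)
                lab = (tail * proj > cut).astype(int)
                if lab.sum() < 2 or lab.sum() > n - 2:
                    continue
                r0 = np.full((n, K), 1e-3)
                r0[np.arange(n), lab] = 1.0
                inits.append(r0 / r0.sum(axis=1, keepdims=True))
    return inits


def init_uni_responsibilities(X: np.ndarray, K: int, rngs,
                              quantile: bool = False) -> np.ndarray:
    """Batched univariate seeding; one Generator per gene.

    With ``quantile=True`` the K initial centers sit at evenly spaced
    quantiles of each gene (covering the support deterministically, which
    consolidates fastest); otherwise they are random data points.
    """
    G, n = X.shape
    noise = np.empty((G, n, K))
    if quantile:
        qs = np.linspace(0.03, 0.97, K)
        centers = np.quantile(X, qs, axis=1).T
        for g, rng in enumerate(rngs):
            noise[g] = 0.01 * rng.standard_normal((n, K))
    else:
        centers = np.empty((G, K))
        for g, rng in enumerate(rngs):
            idx = rng.choice(n, size=K, replace=K > n)
            centers[g] = X[g, idx]
            noise[g] = 0.01 * rng.standard_normal((n, K))
    scale = X.var(axis=1) + 1e-8                          # (G,)
    d2 = (X[:, :, None] - centers[:, None, :]) ** 2
    log_r = -0.5 * d2 / scale[:, None, None] + noise
    r0, _ = _softmax_lse(log_r)
    return r0


def _renorm_rows(r: np.ndarray) -> np.ndarray:
    s = r.sum(axis=-1, keepdims=True)
    bad = s[..., 0] <= 0
    if np.any(bad):
        r = r.copy()
        r[bad] = 1.0
        s = r.sum(axis=-1, keepdims=True)
    return r / s


def cleanup_moves(X: np.ndarray, r: np.ndarray, pr: dict, *, mode: str,
                  max_iter: int, tol: float, eff_min: float = 0.01,
                  delete_weight: float = 1e-4, trace=None):
    """Greedy merge/delete cleanup accepted only when the ELBO does not drop.

    ``mode`` is "uni" (X is (n,)), "full" or "diag" (X is (n, d));
    ``r`` is (n, K). Returns (r, elbo, posterior).
    """
    univariate = mode == "uni"

    def converge(r_cur):
        if univariate:
            r2, L, post, _ = uni_cavi(X[None, :], r_cur[None, :, :], pr,
                                      max_iter, tol)
            return r2[0], float(L[0]), post
        r2, L, post, _ = multi_cavi(X, r_cur, pr, max_iter, tol, mode=mode)
        return r2, L, post

    def weights_of(post):
        a = post["a"][0] if univariate else post["a"]
        b = post["b"][0] if univariate else post["b"]
        return expected_weights(a, b, len(a) + 1)

    r, elbo, post = converge(r)
    while True:
        K = r.shape[1]
        if K == 1:
            break
        w = weights_of(post)
        accepted = False
        # delete: drop all components with negligible mixing weight at once
        tiny = np.flatnonzero(w < delete_weight)
        if tiny.size and tiny.size < K:
            keep = np.setdiff1d(np.arange(K), tiny)
            r_try = _renorm_rows(r[:, keep])
            r2, L2, post2 = converge(r_try)
            if L2 >= elbo - _ACCEPT_SLACK * (1.0 + abs(elbo)):
                r, elbo, post = r2, L2, post2
                if trace is not None:
                    trace.append(L2)
                continue
        # merge: try effective pairs closest in mean first
        eff = np.flatnonzero(w >= eff_min)
        if eff.size >= 2:
            means = post["m"][0] if univariate else post["m"]
            pairs = []
            for ii in range(eff.size):
                for jj in range(ii + 1, eff.size):
                    i, j = eff[ii], eff[jj]
                    dist = float(np.linalg.norm(np.atleast_1d(means[i])
                                                - np.atleast_1d(means[j])))
                    pairs.append((dist, i, j))
            pairs.sort()
            for _, i, j in pairs:
                K = r.shape[1]
                r_try = r.copy()
                r_try[:, i] += r_try[:, j]
                r_try = np.delete(r_try, j, axis=1)
                r2, L2, post2 = converge(r_try)
                if L2 >= elbo - _ACCEPT_SLACK * (1.0 + abs(elbo)):
                    r, elbo, post = r2, L2, post2
                    if trace is not None:
                        trace.append(L2)
                    accepted = True
                    break
        if not accepted:
            break
    return r, elbo, post
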