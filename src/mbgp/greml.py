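"""Restricted maximum likelihood for multi-breed variance-component models.

The two breeds' phenotypes are treated as two correlated traits.  Each
genetic component contributes ``K_c (x) GRM_c`` to the phenotypic covariance,
where ``K_c`` is a 2x2 matrix of within-breed variances and a between-breed
covariance expanded over the breed blocks of the component's GRM.  Residuals
are independent between breeds with per-breed variances, optionally weighted
per individual (the dEDC device for deregressed proofs: individual i's
residual variance is ``var_breed(i) / w_i``).

With a single breed in the model the same machinery reduces to univariate
GBLUP/GREML: each component has one variance and the GRM covers all included
individuals (so across-breed designs can still predict the other breed
through the cross-breed GRM block).

Fitting uses average-information (AI) REML with step-halving and
boundary projection: variance components are constrained nonnegative, a
component pinned at zero also has its between-breed covariance pinned (its
genetic correlation is then undefined), and the covariance parameter is
otherwise unconstrained, so genetic correlations slightly above 1 can be
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "REMLFit",
    "NotPositiveDefiniteError",
    "build_model",
    "restricted_loglik",
    "reml_fit",
    "genetic_correlation",
    "heritability_report",
]

LOG2PI = np.log(2.0 * np.pi)


class NotPositiveDefiniteError(ValueError):
    """The phenotypic covariance matrix V is not positive definite."""


@dataclass
class ModelSpec:
    """Phenotypes, breed structure and genetic components of one model.

    ``components`` maps component name to the GRM sub-matrix aligned to the
    included individuals.  ``weights`` are the per-individual residual
    weights (dEDC role); all ones in simulation mode.
    """

    y: np.ndarray
    breeds: np.ndarray
    individual_ids: list[str]
    components: dict[str, np.ndarray]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.breeds = np.asarray(self.breeds)
        n = self.y.shape[0]
        if len(self.individual_ids) != n or self.breeds.shape[0] != n:
            raise ValueError("phenotype, breed and ID lengths disagree")
        if not self.components:
            raise ValueError("at least one genetic component is required")
        for name, grm in self.components.items():
            if np.asarray(grm).shape != (n, n):
                raise ValueError(f"GRM for component {name!r} is not {n}x{n}")
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            raise ValueError("residual weights must be strictly positive")
        labels = list(dict.fromkeys(self.breeds.tolist()))
        if len(labels) not in (1, 2):
            raise ValueError("model supports one or two breeds")
        self.breed_labels: list[str] = labels
        self.group_rows = {b: np.flatnonzero(self.breeds == b) for b in labels}

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_groups(self) -> int:
        return len(self.breed_labels)

    def design(self) -> np.ndarray:
        """Fixed-effect design: one mean per breed."""
        x = np.zeros((self.n, self.n_groups))
        for k, b in enumerate(self.breed_labels):
            x[self.group_rows[b], k] = 1.0
        return x


def build_model(
    pheno: pd.DataFrame,
    grms: dict[str, "object"],
    component_names: list[str] | tuple[str, ...],
    include_ids: list[str] | None = None,
    phenotype_col: str = "phenotype",
    weight_col: str | None = None,
) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from a phenotype table and full GRMs.

    ``grms`` maps marker-set name to a :class:`~mbgp.grm.MultiBreedGRM`
    covering all genotyped individuals; the model subsets each to the
    included (phenotyped) rows.
    """
    pheno = pheno.set_index("individual_id", drop=False)
    if include_ids is None:
        include_ids = pheno["individual_id"].tolist()
    sub = pheno.loc[include_ids]
    first = grms[component_names[0]]
    pos = {iid: i for i, iid in enumerate(first.individual_ids)}
    missing = [i for i in include_ids if i not in pos]
    if missing:
        raise ValueError(f"individuals absent from GRM: {missing[:5]}")
    rows = np.array([pos[i] for i in include_ids])
    comps = {}
    for name in component_names:
        g = grms[name]
        if list(g.individual_ids) != list(first.individual_ids):
            raise ValueError("all component GRMs must share one individual order")
        comps[name] = g.values[np.ix_(rows, rows)]
    weights = (sub[weight_col].to_numpy(dtype=float)
               if weight_col else np.ones(len(include_ids)))
    return ModelSpec(
        y=sub[phenotype_col].to_numpy(dtype=float),
        breeds=sub["breed"].to_numpy(),
        individual_ids=list(include_ids),
        components=comps,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """Maps the flat parameter vector onto covariance-structure terms.

    Per component: (var_A, var_B, cov_AB) with two breeds, or a single
    variance with one; residual variances come last, one per breed.
    V(theta) is linear in theta, so each parameter owns a fixed derivative
    matrix dV_i realized implicitly through breed-block index arithmetic.
    """

    model: ModelSpec
    names: list[str] = field(default_factory=list)
    kinds: list[str] = field(default_factory=list)   # "var" | "cov" | "resid"
    comp_of: list[str | None] = field(default_factory=list)
    group_of: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.model
        two = m.n_groups == 2
        for cname in m.components:
            for b in m.breed_labels:
                self.names.append(f"{cname}:var_{b}")
                self.kinds.append("var")
                self.comp_of.append(cname)
                self.group_of.append((b, b))
            if two:
                a, b = m.breed_labels
                self.names.append(f"{cname}:cov")
                self.kinds.append("cov")
                self.comp_of.append(cname)
                self.group_of.append((a, b))
        for b in m.breed_labels:
            self.names.append(f"resid:var_{b}")
            self.kinds.append("resid")
            self.comp_of.append(None)
            self.group_of.append((b, b))

    @property
    def n_params(self) -> int:
        return len(self.names)

    def build_v(self, theta: np.ndarray) -> np.ndarray:
        m = self.model
        n = m.n
        v = np.zeros((n, n))
        for i, th in enumerate(theta):
            if th == 0.0:
                continue
            kind = self.kinds[i]
            ga, gb = self.group_of[i]
            ra, rb = m.group_rows[ga], m.group_rows[gb]
            if kind == "resid":
                idx = np.arange(n)[ra]
                v[idx, idx] += th / m.weights[ra]
            else:
                grm = m.components[self.comp_of[i]]
                block = th * grm[np.ix_(ra, rb)]
                v[np.ix_(ra, rb)] += block
                if kind == "cov":
                    v[np.ix_(rb, ra)] += block.T
        return v

    def trace_p_dv(self, p: np.ndarray, i: int) -> float:
        m = self.model
        kind = self.kinds[i]
        ga, gb = self.group_of[i]
        ra, rb = m.group_rows[ga], m.group_rows[gb]
        if kind == "resid":
            return float(np.sum(np.diag(p)[ra] / m.weights[ra]))
        grm = m.components[self.comp_of[i]]
        t = float(np.sum(p[np.ix_(ra, rb)] * grm[np.ix_(ra, rb)]))
        return 2.0 * t if kind == "cov" else t

    def dv_dot(self, i: int, x: np.ndarray) -> np.ndarray:
        m = self.model
        kind = self.kinds[i]
        ga, gb = self.group_of[i]
        ra, rb = m.group_rows[ga], m.group_rows[gb]
        out = np.zeros_like(x)
        if kind == "resid":
            out[ra] = x[ra] / m.weights[ra]
            return out
        grm = m.components[self.comp_of[i]]
        out[ra] = grm[np.ix_(ra, rb)] @ x[rb]
        if kind == "cov":
            out[rb] += grm[np.ix_(rb, ra)] @ x[ra]
        return out

    def pack(self, params: dict) -> np.ndarray:
        """Flatten a structured parameter dict into the layout's order.

        ``params`` holds ``{"components": {name: {"var_<breed>": v, ...,
        "cov": c}}, "residual": {"var_<breed>": v}}``; with one breed the
        component entries may be plain floats.
        """
        theta = np.empty(self.n_params)
        for i, name in enumerate(self.names):
            scope, key = name.split(":", 1)
            if scope == "resid":
                theta[i] = params["residual"][key]
            else:
                entry = params["components"][scope]
                theta[i] = entry if np.isscalar(entry) else entry[key]
        return theta

    def unpack(self, theta: np.ndarray) -> dict:
        comps: dict[str, dict] = {c: {} for c in self.model.components}
        resid: dict[str, float] = {}
        for i, name in enumerate(self.names):
            scope, key = name.split(":", 1)
            if scope == "resid":
                resid[key] = float(theta[i])
            else:
                comps[scope][key] = float(theta[i])
        return {"components": comps, "residual": resid}


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------

def _reml_pieces(m: ModelSpec, v: np.ndarray):
    """Cholesky-based REML quantities for a given V.

    Returns (loglik, P, Py, vinv, beta_hat).  Raises
    :class:`NotPositiveDefiniteError` when V (or X'V^-1 X) has no Cholesky
    factor — a condition distinct from optimizer non-convergence.
    """
    x = m.design()
    n, p = x.shape
    try:
        c, low = cho_factor(v, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("V is not positive definite") from exc
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    vinv = cho_solve((c, low), np.eye(n), check_finite=False)
    vinv_x = vinv @ x
    xtvx = x.T @ vinv_x
    try:
        cx = np.linalg.cholesky(xtvx)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError("X'V^-1X is singular") from exc
    logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(cx))))
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ (vinv_x.T @ m.y)
    py = vinv @ m.y - vinv_x @ beta
    proj = vinv - vinv_x @ xtvx_inv @ vinv_x.T
    ytpy = float(m.y @ py)
    ll = -0.5 * (logdet_v + logdet_xtvx + ytpy + (n - p) * LOG2PI)
    return ll, proj, py, vinv, beta


def restricted_loglik(m: ModelSpec, params: dict) -> float:
    """Restricted log-likelihood at the given variance parameters.

    Evaluates ``-1/2 [log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2*pi]`` with
    ``P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1`` over the included
    individuals.
    """
    layout = _Layout(m)
    theta = layout.pack(params)
    v = layout.build_v(theta)
    ll, *_ = _reml_pieces(m, v)
    return ll


# ---------------------------------------------------------------------------
# AI-REML fit
# ---------------------------------------------------------------------------

@dataclass
class REMLFit:
    """Variance-component estimates and their asymptotic precision.

    ``params``/``se`` are structured like :meth:`_Layout.unpack`;
    ``param_cov`` is the inverse average-information matrix over the free
    (non-boundary) parameters, indexed by ``param_names``.  ``boundary``
    flags parameters pinned at the zero boundary.
    """

    params: dict
    se: dict
    loglik: float
    n_iter: int
    converged: bool
    boundary: dict
    param_names: list[str]
    param_cov: np.ndarray
    free_mask: np.ndarray
    breed_labels: list[str]
    component_names: list[str]
    scale: float = 1.0
    loglik_path: list[float] = field(default_factory=list)

    def theta(self) -> np.ndarray:
        """Flat parameter vector in ``param_names`` order."""
        vals = []
        for name in self.param_names:
            scope, key = name.split(":", 1)
            src = (self.params["residual"] if scope == "resid"
                   else self.params["components"][scope])
            vals.append(src[key])
        return np.array(vals)


def _default_start(layout: _Layout) -> np.ndarray:
    """Equal-share start: every component and the residual get an equal
    slice of each breed's phenotypic variance; covariances start at a
    quarter of the geometric mean of the paired variances."""
    m = layout.model
    n_c = len(m.components)
    share = {}
    for b in m.breed_labels:
        var_y = float(np.var(m.y[m.group_rows[b]]))
        if var_y <= 0:
            var_y = 1.0
        share[b] = var_y / (n_c + 1)
    theta = np.empty(layout.n_params)
    for i, name in enumerate(layout.names):
        kind = layout.kinds[i]
        ga, gb = layout.group_of[i]
        if kind == "cov":
            theta[i] = 0.25 * np.sqrt(share[ga] * share[gb])
        else:
            theta[i] = share[ga]
    return theta


def _grad_ai(layout: _Layout, proj: np.ndarray, py: np.ndarray):
    k = layout.n_params
    grad = np.empty(k)
    t = np.empty((layout.model.n, k))
    for i in range(k):
        dv_py = layout.dv_dot(i, py)
        t[:, i] = dv_py
        grad[i] = -0.5 * (layout.trace_p_dv(proj, i) - float(py @ dv_py))
    ai = 0.5 * (t.T @ proj @ t)
    return grad, ai


def reml_fit(
    m: ModelSpec,
    max_iter: int = 200,
    tol_param: float = 1e-6,
    tol_loglik: float = 1e-8,
    start: dict | None = None,
) -> REMLFit:
    """Average-information REML with step-halving and boundary projection.

    The phenotype is standardized internally (all tolerances act on the
    unit-variance scale) and estimates are mapped back afterwards.  An AI
    step that leaves the positive-definite region or decreases the
    likelihood is halved, up to 30 times; variances driven negative are
    pinned at zero (with the component's covariance) and re-enter the
    active set only when their likelihood gradient turns positive.
    """
    s = float(np.std(m.y))
    if s <= 0:
        raise ValueError("phenotype has zero variance")
    m_std = ModelSpec(
        y=m.y / s,
        breeds=m.breeds,
        individual_ids=list(m.individual_ids),
        components=m.components,
        weights=m.weights,
    )
    layout = _Layout(m_std)
    k = layout.n_params
    var_kind = np.array([kd in ("var", "resid") for kd in layout.kinds])

    if start is not None:
        theta = layout.pack(start) / (s * s)
    else:
        theta = _default_start(layout)

    pinned = np.zeros(k, dtype=bool)
    floor = 1e-10
    # residual variances are floored at a tiny positive value rather than
    # pinned at zero: breed-centered GRMs are singular along the breed-mean
    # direction, so V would lose positive definiteness without any residual
    resid_kind = np.array([kd == "resid" for kd in layout.kinds])
    resid_floor = 1e-6
    theta[resid_kind] = np.maximum(theta[resid_kind], resid_floor)

    # Covariances are never pinned: the parameter space is variances >= 0
    # with an unconstrained covariance (K need not stay positive
    # semi-definite — only V must), matching the convention that lets
    # genetic correlations exceed 1.  A component with a variance on the
    # zero boundary reports its correlation as undefined regardless.

    v = layout.build_v(theta)
    ll, proj, py, vinv, _ = _reml_pieces(m_std, v)
    ll_path = [float(ll)]

    converged = False
    n_iter = 0
    grad = np.zeros(k)
    ai = np.eye(k)
    for n_iter in range(1, max_iter + 1):
        grad, ai = _grad_ai(layout, proj, py)

        # release pinned parameters whose gradient points inward
        for i in np.flatnonzero(pinned):
            if grad[i] > 1e-8:
                pinned[i] = False
        free = ~pinned

        ai_free = ai[np.ix_(free, free)]
        grad_free = grad[free]
        ridge = 1e-8 * max(1.0, float(np.trace(ai_free)) / max(1, ai_free.shape[0]))
        try:
            delta_free = np.linalg.solve(
                ai_free + ridge * np.eye(ai_free.shape[0]), grad_free)
        except np.linalg.LinAlgError:
            delta_free = grad_free / max(1.0, float(np.abs(grad_free).max()))
        delta = np.zeros(k)
        delta[free] = delta_free
        # trust-region clip: on the standardized scale the phenotypic
        # variance is 1, so updates beyond O(1) are always overshoot
        biggest = float(np.abs(delta).max(initial=0.0))
        if biggest > 1.0:
            delta *= 1.0 / biggest

        def try_step(direction):
            alpha = 1.0
            for _ in range(30):
                cand = theta + alpha * direction
                new_pin = pinned.copy()
                neg = var_kind & ~resid_kind & (cand < floor)
                cand[neg] = 0.0
                new_pin[neg] = True
                low = resid_kind & (cand < resid_floor)
                cand[low] = resid_floor
                try:
                    v_cand = layout.build_v(cand)
                    pieces = _reml_pieces(m_std, v_cand)
                except NotPositiveDefiniteError:
                    alpha *= 0.5
                    continue
                if pieces[0] >= ll - 1e-10:
                    return cand, new_pin, pieces
                alpha *= 0.5
            return None

        outcome = try_step(delta)
        if outcome is None:
            # gradient-direction fallback with a conservative scale
            gnorm = float(np.abs(grad[free]).max(initial=0.0))
            if gnorm > 0:
                fallback = np.zeros(k)
                fallback[free] = grad[free] / gnorm * 0.1
                outcome = try_step(fallback)
        if outcome is not None:
            cand, new_pin, (ll_cand, proj_c, py_c, vinv_c, _) = outcome
            step = cand - theta
            theta, pinned = cand, new_pin
            ll_prev = ll
            ll, proj, py, vinv = ll_cand, proj_c, py_c, vinv_c
            ll_path.append(float(ll))
            accepted = True
        else:
            accepted = False
        if not accepted:
            # no uphill step available: treat as converged if the free
            # gradient is flat, otherwise keep iterating from a shrunk step
            if np.abs(grad[free]).max(initial=0.0) < 1e-4:
                converged = True
            break
        if (np.abs(step).max() < tol_param
                and abs(ll - ll_prev) < tol_loglik):
            converged = True
            break

    # SEs from the AI matrix at the optimum, free parameters only
    grad, ai = _grad_ai(layout, proj, py)
    free = ~pinned
    se = np.zeros(k)
    cov_free = np.zeros((int(free.sum()), int(free.sum())))
    if free.any():
        ai_free = ai[np.ix_(free, free)]
        try:
            cov_free = np.linalg.inv(ai_free)
        except np.linalg.LinAlgError:
            cov_free = np.linalg.pinv(ai_free)
        d = np.diag(cov_free).copy()
        d[d < 0] = 0.0
        se[free] = np.sqrt(d)

    # map back to the original phenotype scale
    s2 = s * s
    theta_out = theta * s2
    se_out = se * s2
    cov_out = cov_free * s2 * s2
    ll_out = ll - 0.5 * (m.n - m_std.n_groups) * np.log(s2)

    return REMLFit(
        params=layout.unpack(theta_out),
        se=layout.unpack(se_out),
        loglik=float(ll_out),
        n_iter=n_iter,
        converged=converged,
        boundary=layout.unpack(pinned.astype(float)),
        param_names=list(layout.names),
        param_cov=cov_out,
        free_mask=free,
        breed_labels=list(m_std.breed_labels),
        component_names=list(m_std.components),
        scale=s,
        loglik_path=[p - 0.5 * (m.n - m_std.n_groups) * np.log(s2)
                     for p in ll_path],
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def _param_cov_full(fit: REMLFit) -> np.ndarray:
    """Parameter covariance expanded to all parameters (0 rows for pinned)."""
    k = len(fit.param_names)
    out = np.zeros((k, k))
    idx = np.flatnonzero(fit.free_mask)
    out[np.ix_(idx, idx)] = fit.param_cov
    return out


def genetic_correlation(fit: REMLFit, component: str) -> tuple[float, float]:
    """Between-breed genetic correlation of one component, with delta-method SE.

    ``rg = cov_AB / sqrt(var_A * var_B)``.  Returns ``(nan, nan)`` when
    either variance sits on the zero boundary — the correlation is then
    undefined (reported as NA).
    """
    if len(fit.breed_labels) != 2:
        raise ValueError("genetic correlation requires a two-breed fit")
    a, b = fit.breed_labels
    entry = fit.params["components"][component]
    bound = fit.boundary["components"][component]
    va, vb, cab = entry[f"var_{a}"], entry[f"var_{b}"], entry["cov"]
    if bound[f"var_{a}"] or bound[f"var_{b}"] or va <= 0 or vb <= 0:
        return float("nan"), float("nan")
    rg = cab / np.sqrt(va * vb)
    names = fit.param_names
    i_a = names.index(f"{component}:var_{a}")
    i_b = names.index(f"{component}:var_{b}")
    i_c = names.index(f"{component}:cov")
    grad = np.zeros(len(names))
    grad[i_a] = -rg / (2.0 * va)
    grad[i_b] = -rg / (2.0 * vb)
    grad[i_c] = 1.0 / np.sqrt(va * vb)
    var_rg = float(grad @ _param_cov_full(fit) @ grad)
    return float(rg), float(np.sqrt(max(var_rg, 0.0)))


def heritability_report(fit: REMLFit, m: ModelSpec | None = None) -> pd.DataFrame:
    """Per-breed, per-component variance shares (heritabilities).

    ``h2[c, k] = var_ck / (sum_c var_ck + resid_k)``; in weighted (DRP) mode
    this is the explained-variance ratio at unit weight.  Delta-method SEs
    accompany each share.
    """
    rows = []
    cov_full = _param_cov_full(fit)
    names = fit.param_names
    for breed in fit.breed_labels:
        vkey = f"var_{breed}"
        comp_vars = {c: fit.params["components"][c][vkey]
                     for c in fit.component_names}
        resid = fit.params["residual"][vkey]
        total = sum(comp_vars.values()) + resid
        if total <= 0:
            raise ValueError(f"total variance is zero for breed {breed!r}")
        idx_all = ([names.index(f"{c}:{vkey}") for c in fit.component_names]
                   + [names.index(f"resid:{vkey}")])
        for c in fit.component_names:
            h2 = comp_vars[c] / total
            grad = np.zeros(len(names))
            for j, c2 in enumerate(fit.component_names):
                i_p = idx_all[j]
                grad[i_p] = ((1.0 if c2 == c else 0.0) * total
                             - comp_vars[c]) / total**2
            grad[idx_all[-1]] = -comp_vars[c] / total**2
            se = float(np.sqrt(max(grad @ cov_full @ grad, 0.0)))
            rows.append({"breed": breed, "component": c,
                         "h2": float(h2), "se": se,
                         "variance": float(comp_vars[c]),
                         "residual": float(resid)})
    return pd.DataFrame(rows)
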