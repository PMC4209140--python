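"""Site-class dN/dS mixture models (M1a, M2a, M7, M8, M8a) and their fitting.

The model family is the standard nested set used to test for positive
selection:

* M1a  "nearly neutral": classes (p0, omega0 < 1), (1-p0, omega1 = 1)
* M2a  "positive selection": M1a plus a class (1-p0-p1, omega2 >= 1)
* M7   "beta": omega ~ Beta(p, q) on (0, 1), discretized into K equal-mass
  categories
* M8   "beta & omega": p0 * Beta(p, q) plus a class (1-p0, omega_s >= 1)
* M8a  M8 with omega_s fixed to 1 (the boundary null of the M8a-M8 test)

``CodonSiteModel`` binds an alignment, a tree and a model id;  ``fit()``
maximizes the likelihood over (omega-structure parameters, kappa, tree
scale) with the mixture proportions profiled out by an inner EM loop (the
mixture log-likelihood is concave in the weights, so the inner problem has a
unique optimum), and returns a ``CodonSiteModelResults`` carrying the MLEs
and the cached per-site per-class log-likelihood matrix that the NEB/BEB
posterior computations need.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import optimize, special, stats

from ._pruning import PruningEngine
from .alignment import CodonAlignment
from .genetics import estimate_codon_frequencies, standard_genetic_code, validate_frequencies
from .trees import tree_index

MODEL_IDS = ("M1a", "M2a", "M7", "M8", "M8a")
#: free mixture/omega parameters per model (excluding kappa and branch terms)
MODEL_FREE_PARAMS = {"M1a": 2, "M2a": 4, "M7": 2, "M8": 4, "M8a": 3}

OMEGA0_BOUNDS = (1e-4, 0.999)
OMEGA_POS_BOUNDS = (1.0, 50.0)
BETA_SHAPE_BOUNDS = (0.005, 99.0)
KAPPA_BOUNDS = (0.01, 100.0)
SCALE_BOUNDS = (1e-4, 100.0)


def discretize_beta(beta_p: float, beta_q: float, ncat: int) -> np.ndarray:
    """K equal-probability categories of Beta(p, q); values are the
    conditional means of the distribution on each quantile interval."""
    if ncat < 1:
        raise ValueError("number of categories must be >= 1")
    if beta_p <= 0 or beta_q <= 0:
        raise ValueError("beta shape parameters must be positive")
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, ncat + 1), beta_p, beta_q)
    # E[X | a < X <= b] = mean * (I_b(p+1,q) - I_a(p+1,q)) / (1/K)
    inc = special.betainc(beta_p + 1.0, beta_q, edges)
    values = (beta_p / (beta_p + beta_q)) * np.diff(inc) * ncat
    return np.clip(values, 1e-9, 1.0 - 1e-9)


@dataclass
class SiteClassModel:
    """A named omega-mixture with its parameter values."""

    model_id: str
    p0: float | None = None
    p1: float | None = None
    omega0: float | None = None
    omega2: float | None = None  # the positive-selection omega (omega_s in M8)
    beta_p: float | None = None
    beta_q: float | None = None
    ncat: int = 10

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model {self.model_id!r}")
        if self.model_id == "M8a":
            self.omega2 = 1.0

    @property
    def n_free_params(self) -> int:
        return MODEL_FREE_PARAMS[self.model_id]

    def site_classes(self) -> list[tuple[float, float]]:
        """Expand to a list of (proportion, omega) pairs."""
        mid = self.model_id
        if mid == "M1a":
            _check_simplex([self.p0, 1.0 - self.p0])
            return [(self.p0, self.omega0), (1.0 - self.p0, 1.0)]
        if mid == "M2a":
            p2 = 1.0 - self.p0 - self.p1
            _check_simplex([self.p0, self.p1, p2])
            return [(self.p0, self.omega0), (self.p1, 1.0), (p2, self.omega2)]
        beta_values = discretize_beta(self.beta_p, self.beta_q, self.ncat)
        if mid == "M7":
            return [(1.0 / self.ncat, w) for w in beta_values]
        # M8 / M8a
        _check_simplex([self.p0, 1.0 - self.p0])
        classes = [(self.p0 / self.ncat, w) for w in beta_values]
        classes.append((1.0 - self.p0, self.omega2))
        return classes


def _check_simplex(props) -> None:
    props = np.asarray([p if p is not None else np.nan for p in props], float)
    if np.any(np.isnan(props)):
        raise ValueError("missing class proportion")
    if np.any(props < -1e-9) or np.any(props > 1 + 1e-9):
        raise ValueError(f"class proportions outside [0, 1]: {props}")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError(f"class proportions must sum to 1: {props}")


def expand_site_classes(model: SiteClassModel) -> list[tuple[float, float]]:
    return model.site_classes()


def log_likelihood(aln, tree, classes, pi, kappa, scale=1.0):
    """Mixture log-likelihood of (proportion, omega) classes on a fixed tree.

    Returns ``(lnL, site_class_loglik)`` where the second element is the
    (n_sites, n_classes) matrix of per-site per-class log-likelihoods.
    """
    props = np.array([p for p, _ in classes], float)
    omegas = np.array([w for _, w in classes], float)
    _check_simplex(props)
    engine = PruningEngine(aln, tree, pi)
    pat_loglik = engine.class_site_loglik(omegas, kappa, scale)
    with np.errstate(divide="ignore"):
        lnl = engine.mixture_loglik(np.log(props), pat_loglik)
    return lnl, engine.expand_to_sites(pat_loglik)


# ----------------------------------------------------------------------
# weight profiling (inner EM)
# ----------------------------------------------------------------------


def _em_weights(pattern_loglik, counts, w0, structure, ncat, tol=1e-10, max_iter=500):
    """Maximize lnL over mixture weights for fixed class log-likelihoods.

    ``structure`` is 'free' (every class its own weight, e.g. M1a/M2a after
    expansion), 'p0_last' (K beta classes share p0/K, last class 1-p0), or
    'none' (fixed equal weights, M7).  Returns (weights, lnL).
    """
    n_total = counts.sum()
    if structure == "none":
        w = np.full(pattern_loglik.shape[1], 1.0 / pattern_loglik.shape[1])
        return w, _weighted_mix_loglik(pattern_loglik, counts, w)

    w = np.asarray(w0, float).copy()
    prev = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logw = np.log(np.maximum(w, 1e-300))
        z = pattern_loglik + logw[None, :]
        m = z.max(axis=1, keepdims=True)
        ez = np.exp(z - m)
        denom = ez.sum(axis=1, keepdims=True)
        lnl = float(np.dot(counts, (np.log(denom[:, 0]) + m[:, 0])))
        resp = ez / denom  # responsibilities per pattern per class
        class_mass = counts @ resp
        if structure == "free":
            w = class_mass / n_total
        else:  # p0_last
            p0 = min(max(1.0 - class_mass[-1] / n_total, 1e-9), 1.0 - 1e-9)
            w = np.full(len(w), p0 / ncat)
            w[-1] = 1.0 - p0
        if lnl - prev < tol and np.isfinite(prev):
            break
        prev = lnl
    return w, _weighted_mix_loglik(pattern_loglik, counts, w)


def _weighted_mix_loglik(pattern_loglik, counts, w):
    with np.errstate(divide="ignore"):
        logw = np.log(np.maximum(w, 1e-300))
    z = pattern_loglik + logw[None, :]
    m = z.max(axis=1)
    return float(np.dot(counts, np.log(np.exp(z - m[:, None]).sum(axis=1)) + m))


# ----------------------------------------------------------------------
# the Model / Results pair
# ----------------------------------------------------------------------


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(x):
    return special.expit(x)


class CodonSiteModel:
    """A site-class codon substitution model bound to data.

    Parameters
    ----------
    alignment : CodonAlignment
    tree : dendropy.Tree or TreeIndex
        Branch lengths in expected substitutions per codon.
    model : str
        One of M1a, M2a, M7, M8, M8a.
    frequencies : str or array
        Codon-frequency model ('equal', 'F1x4', 'F3x4', 'empirical') or an
        explicit 61-vector.  F3x4 is the default.
    ncat : int
        Number of discretized beta categories for M7/M8/M8a.
    fix_kappa : float, optional
        Fix the transition/transversion ratio instead of estimating it.
    branch_mode : str
        'scale' (default): optimize a single multiplier of the input branch
        lengths; 'fixed': use them as given; 'full': optimize every branch
        length.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree,
        model: str = "M8",
        *,
        frequencies="F3x4",
        ncat: int = 10,
        fix_kappa: float | None = None,
        branch_mode: str = "scale",
        code=None,
    ):
        if model not in MODEL_IDS:
            raise ValueError(f"unknown model {model!r}")
        if branch_mode not in ("scale", "fixed", "full"):
            raise ValueError("branch_mode must be 'scale', 'fixed' or 'full'")
        self.model_id = model
        self.alignment = alignment
        self.tree = tree_index(tree)
        self.code = code or standard_genetic_code()
        if isinstance(frequencies, str):
            self.frequency_method = frequencies
            self.pi = estimate_codon_frequencies(alignment, frequencies, self.code)
        else:
            self.frequency_method = "given"
            self.pi = validate_frequencies(np.asarray(frequencies), self.code.n_states)
        self.ncat = int(ncat)
        self.fix_kappa = fix_kappa
        self.branch_mode = branch_mode
        self.engine = PruningEngine(alignment, self.tree, self.pi, self.code)

    # -- parameter vector <-> model ----------------------------------

    @property
    def _weight_structure(self):
        return {"M1a": "free", "M2a": "free", "M7": "none", "M8": "p0_last", "M8a": "p0_last"}[
            self.model_id
        ]

    def _n_classes(self):
        return {"M1a": 2, "M2a": 3, "M7": self.ncat, "M8": self.ncat + 1, "M8a": self.ncat + 1}[
            self.model_id
        ]

    def _theta_spec(self):
        """List of (name, transform, bounds) for the outer parameter vector."""
        spec = []
        mid = self.model_id
        if mid in ("M1a", "M2a"):
            spec.append(("omega0", "logit", OMEGA0_BOUNDS))
        if mid in ("M7", "M8", "M8a"):
            spec.append(("beta_p", "log", BETA_SHAPE_BOUNDS))
            spec.append(("beta_q", "log", BETA_SHAPE_BOUNDS))
        if mid in ("M2a", "M8"):
            spec.append(("omega2", "identity", OMEGA_POS_BOUNDS))
        if self.fix_kappa is None:
            spec.append(("kappa", "log", KAPPA_BOUNDS))
        if self.branch_mode == "scale":
            spec.append(("scale", "log", SCALE_BOUNDS))
        elif self.branch_mode == "full":
            for b in range(self.tree.n_branches):
                spec.append((f"t{b}", "log", (1e-6, 50.0)))
        return spec

    def _encode(self, values: dict) -> np.ndarray:
        x = []
        for name, tf, bounds in self._theta_spec():
            v = float(np.clip(values[name], bounds[0], bounds[1]))
            x.append(_logit(v) if tf == "logit" else np.log(v) if tf == "log" else v)
        return np.array(x)

    def _decode(self, x: np.ndarray) -> dict:
        out = {}
        for (name, tf, _), xi in zip(self._theta_spec(), x):
            out[name] = float(_expit(xi) if tf == "logit" else np.exp(xi) if tf == "log" else xi)
        return out

    def _transformed_bounds(self):
        bounds = []
        for _, tf, (lo, hi) in self._theta_spec():
            if tf == "logit":
                bounds.append((_logit(lo), _logit(hi)))
            elif tf == "log":
                bounds.append((np.log(lo), np.log(hi)))
            else:
                bounds.append((lo, hi))
        return bounds

    def _class_omegas(self, params: dict) -> np.ndarray:
        mid = self.model_id
        if mid == "M1a":
            return np.array([params["omega0"], 1.0])
        if mid == "M2a":
            return np.array([params["omega0"], 1.0, params["omega2"]])
        beta = discretize_beta(params["beta_p"], params["beta_q"], self.ncat)
        if mid == "M7":
            return beta
        tail = params["omega2"] if mid == "M8" else 1.0
        return np.append(beta, tail)

    def _pattern_loglik(self, params: dict) -> np.ndarray:
        omegas = self._class_omegas(params)
        kappa = self.fix_kappa if self.fix_kappa is not None else params["kappa"]
        if self.branch_mode == "scale":
            return self.engine.class_site_loglik(omegas, kappa, params["scale"])
        if self.branch_mode == "full":
            lengths = np.zeros(self.tree.n_nodes)
            for b in range(self.tree.n_branches):
                lengths[b] = params[f"t{b}"]
            return self.engine.class_site_loglik(omegas, kappa, 1.0, lengths)
        return self.engine.class_site_loglik(omegas, kappa, 1.0)

    # -- likelihood at explicit parameter values ----------------------

    def loglike(self, params: SiteClassModel | dict, kappa=None, scale=1.0):
        """lnL at explicit parameter values (no optimization).

        ``params`` may be a SiteClassModel (weights read from it) or a dict
        from an optimizer decode.
        """
        if isinstance(params, SiteClassModel):
            classes = params.site_classes()
            props = np.array([p for p, _ in classes])
            omegas = np.array([w for _, w in classes])
            kappa = kappa if kappa is not None else 2.0
            pat = self.engine.class_site_loglik(omegas, kappa, scale)
            with np.errstate(divide="ignore"):
                return self.engine.mixture_loglik(np.log(np.maximum(props, 1e-300)), pat)
        raise TypeError("params must be a SiteClassModel")

    # -- fitting -------------------------------------------------------

    def _default_starts(self, profile: str):
        mid = self.model_id
        base = {"kappa": 2.0, "scale": 1.0}
        if self.branch_mode == "full":
            base.update(
                {f"t{b}": max(self.tree.edge_length[b], 1e-4) for b in range(self.tree.n_branches)}
            )
        starts = []
        if mid == "M1a":
            omega0s = [0.1, 0.5] if profile == "default" else [0.1]
            starts = [dict(base, omega0=w) for w in omega0s]
        elif mid == "M2a":
            omega0s = [0.1, 0.5] if profile == "default" else [0.1]
            omega2s = [1.5, 3.0, 5.0] if profile == "default" else [3.0]
            starts = [dict(base, omega0=w0, omega2=w2) for w0 in omega0s for w2 in omega2s]
        elif mid == "M7":
            shapes = [(0.5, 2.0), (1.5, 1.5)] if profile == "default" else [(0.5, 2.0)]
            starts = [dict(base, beta_p=p, beta_q=q) for p, q in shapes]
        elif mid == "M8a":
            shapes = [(0.5, 2.0), (1.5, 1.5)] if profile == "default" else [(0.5, 2.0)]
            starts = [dict(base, beta_p=p, beta_q=q) for p, q in shapes]
        else:  # M8
            omega2s = [1.5, 3.0, 5.0] if profile == "default" else [2.5]
            starts = [dict(base, beta_p=0.5, beta_q=2.0, omega2=w) for w in omega2s]
        return starts

    def _initial_weights(self, start: dict) -> np.ndarray:
        mid = self.model_id
        nc = self._n_classes()
        if mid == "M1a":
            p0 = start.get("p0", 0.7)
            return np.array([p0, 1.0 - p0])
        if mid == "M2a":
            p0 = min(start.get("p0", 0.65), 0.98)
            p1 = min(start.get("p1", 0.7 * (1.0 - p0)), 0.99 * (1.0 - p0))
            return np.array([p0, p1, 1.0 - p0 - p1])
        if mid == "M7":
            return np.full(nc, 1.0 / nc)
        p0 = start.get("p0", 0.9)
        w = np.full(nc, p0 / self.ncat)
        w[-1] = 1.0 - p0
        return w

    def fit(
        self,
        *,
        starts: str | list[dict] = "default",
        init_from: "CodonSiteModelResults | None" = None,
        maxiter: int = 200,
        ftol: float = 1e-9,
        em_tol: float = 1e-10,
        fd_step: float = 1e-5,
        eval_points: list[dict] | None = None,
    ) -> "CodonSiteModelResults":
        """Maximum-likelihood fit.

        ``starts`` is 'default' (the documented multi-start grid), 'fast'
        (single start, for bulk simulation experiments), or an explicit list
        of start dicts.  ``init_from`` prepends a start decoded from another
        fitted results object (used to warm-start an alternative model from
        its null, which also guarantees the nested-model lnL ordering).
        ``eval_points`` are parameter dicts evaluated once, without an
        optimizer run, but competing for the reported optimum — e.g. the
        null's MLEs with the extra parameter at its boundary.
        """
        if isinstance(starts, str):
            start_list = self._default_starts(starts)
        else:
            start_list = [dict(s) for s in starts]
        if init_from is not None:
            start_list.insert(0, self.start_from(init_from))

        best = {"lnl": -np.inf, "x": None, "weights": None, "pat": None}
        weights_state = {"w": None}

        def objective(x):
            params = self._decode(x)
            try:
                pat = self._pattern_loglik(params)
            except (ValueError, FloatingPointError):
                return 1e10
            w0 = weights_state["w"]
            if w0 is None or len(w0) != pat.shape[1]:
                w0 = self._initial_weights({})
            w, lnl = _em_weights(
                pat, self.engine.pattern_weight, w0, self._weight_structure, self.ncat, em_tol
            )
            weights_state["w"] = w
            if not np.isfinite(lnl):
                return 1e10
            if lnl > best["lnl"]:
                best.update(lnl=lnl, x=x.copy(), weights=w.copy(), pat=pat)
            return -lnl

        bounds = self._transformed_bounds()
        for point in eval_points or []:
            weights_state["w"] = self._initial_weights(point)
            objective(self._encode({**{"kappa": 2.0, "scale": 1.0}, **point}))
        n_success = 0
        n_used = 0
        for start in start_list:
            n_used += 1
            weights_state["w"] = self._initial_weights(start)
            x0 = self._encode({**{"kappa": 2.0, "scale": 1.0}, **start})
            res = optimize.minimize(
                objective,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": ftol, "eps": fd_step},
            )
            if res.success:
                n_success += 1
        if n_success == 0:
            # quasi-Newton failed everywhere: polish the best point found so
            # far with Nelder-Mead before reporting a non-converged fit
            if best["x"] is not None:
                res = optimize.minimize(
                    objective,
                    best["x"],
                    method="Nelder-Mead",
                    options={"maxiter": 2000, "fatol": 1e-6},
                )
                n_success += int(res.success)
        if best["x"] is None:
            raise RuntimeError("likelihood could not be evaluated at any start point")

        params = self._decode(best["x"])
        return self._build_results(
            params, best["weights"], best["pat"], best["lnl"],
            converged=n_success > 0, n_restarts=n_used,
        )

    def start_from(self, results: "CodonSiteModelResults") -> dict:
        """Start dict decoded from another fitted results object (typically
        the nested null of this model)."""
        return self._start_from_results(results)

    def _start_from_results(self, results: "CodonSiteModelResults") -> dict:
        src = results.params
        start = {"kappa": results.kappa, "scale": results.tree_scale or 1.0}
        if self.branch_mode == "full" and results.branch_lengths is not None:
            start.update({f"t{b}": max(results.branch_lengths[b], 1e-6) for b in range(self.tree.n_branches)})
        for name in ("omega0", "beta_p", "beta_q", "p0", "p1"):
            v = getattr(src, name, None)
            if v is not None:
                start[name] = v
        if self.model_id in ("M2a", "M8"):
            # at omega2 = 1 the alternative reproduces its boundary null exactly
            start.setdefault("omega2", src.omega2 if src.omega2 is not None else 1.0)
        return start

    def results_at(self, params: dict, weights: np.ndarray, *, optimize_weights=False) -> "CodonSiteModelResults":
        """Results object evaluated at explicit parameters (no fitting)."""
        pat = self._pattern_loglik(params)
        w = np.asarray(weights, float)
        if optimize_weights:
            w, lnl = _em_weights(
                pat, self.engine.pattern_weight, w, self._weight_structure, self.ncat
            )
        else:
            lnl = _weighted_mix_loglik(pat, self.engine.pattern_weight, w)
        return self._build_results(params, w, pat, lnl, converged=True, n_restarts=0)

    def _build_results(self, params, weights, pat_loglik, lnl, *, converged, n_restarts):
        mid = self.model_id
        kw = {"ncat": self.ncat}
        if mid in ("M1a", "M2a"):
            kw["omega0"] = params["omega0"]
            kw["p0"] = float(weights[0])
        if mid == "M2a":
            kw["p1"] = float(weights[1])
            kw["omega2"] = params["omega2"]
        if mid in ("M7", "M8", "M8a"):
            kw["beta_p"] = params["beta_p"]
            kw["beta_q"] = params["beta_q"]
        if mid in ("M8", "M8a"):
            kw["p0"] = float(1.0 - weights[-1])
        if mid == "M8":
            kw["omega2"] = params["omega2"]
        site_model = SiteClassModel(mid, **kw)

        kappa = self.fix_kappa if self.fix_kappa is not None else params["kappa"]
        n_branch_params = {
            "scale": 1,
            "fixed": 0,
            "full": self.tree.n_branches,
        }[self.branch_mode]
        nparams = (
            site_model.n_free_params
            + (0 if self.fix_kappa is not None else 1)
            + n_branch_params
        )
        branch_lengths = None
        tree_scale = None
        if self.branch_mode == "scale":
            tree_scale = params["scale"]
        elif self.branch_mode == "full":
            branch_lengths = np.array(
                [params[f"t{b}"] for b in range(self.tree.n_branches)]
            )
        return CodonSiteModelResults(
            model=self,
            model_id=mid,
            params=site_model,
            kappa=float(kappa),
            tree_scale=tree_scale,
            branch_lengths=branch_lengths,
            lnL=float(lnl),
            nparams=int(nparams),
            class_weights=np.asarray(weights, float),
            class_omegas=self._class_omegas(params),
            site_class_loglik=self.engine.expand_to_sites(pat_loglik),
            converged=bool(converged),
            n_restarts_used=int(n_restarts),
        )


def fit_model(aln, tree, model_id: str, **options) -> "CodonSiteModelResults":
    """Functional wrapper: construct a CodonSiteModel and fit it."""
    fit_kw = {
        k: options.pop(k)
        for k in ("starts", "init_from", "maxiter", "ftol", "em_tol")
        if k in options
    }
    return CodonSiteModel(aln, tree, model_id, **options).fit(**fit_kw)


@dataclass
class CodonSiteModelResults:
    """MLEs, likelihood and cached site-class likelihoods of a fitted model."""

    model: CodonSiteModel | None
    model_id: str
    params: SiteClassModel
    kappa: float
    tree_scale: float | None
    branch_lengths: np.ndarray | None
    lnL: float
    nparams: int
    class_weights: np.ndarray
    class_omegas: np.ndarray
    site_class_loglik: np.ndarray
    converged: bool
    n_restarts_used: int

    @property
    def n_sites(self) -> int:
        return self.site_class_loglik.shape[0]

    # posterior shortcuts -------------------------------------------------
    def neb(self):
        from .posteriors import neb_posteriors

        return neb_posteriors(self)

    def beb(self, **kw):
        from .posteriors import beb_posteriors

        return beb_posteriors(self, **kw)

    def compare(self, null: "CodonSiteModelResults"):
        from .lrt import compute_lrt

        return compute_lrt(null, self)

    def summary(self) -> str:
        lines = [
            f"Codon site model {self.model_id}",
            "=" * 38,
            f"{'log-likelihood':<22}{self.lnL: .4f}",
            f"{'free parameters (np)':<22}{self.nparams}",
            f"{'codon sites':<22}{self.n_sites}",
            f"{'kappa (ts/tv)':<22}{self.kappa:.4f}",
            f"{'converged':<22}{self.converged}",
            f"{'restarts used':<22}{self.n_restarts_used}",
        ]
        if self.tree_scale is not None:
            lines.append(f"{'tree scale':<22}{self.tree_scale:.4f}")
        p = self.params
        for name in ("p0", "p1", "omega0", "omega2", "beta_p", "beta_q"):
            v = getattr(p, name)
            if v is not None:
                lines.append(f"{name:<22}{v:.4f}")
        lines.append("-" * 38)
        lines.append(f"{'class':<8}{'proportion':>12}{'omega':>12}")
        for w, om in zip(self.class_weights, self.class_omegas):
            lines.append(f"{'':<8}{w:>12.4f}{om:>12.4f}")
        return "\n".join(lines)

    # persistence ---------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "model_id": self.model_id,
            "params": {k: v for k, v in asdict(self.params).items() if v is not None},
            "kappa": self.kappa,
            "tree_scale": self.tree_scale,
            "branch_lengths": None
            if self.branch_lengths is None
            else list(self.branch_lengths),
            "lnL": self.lnL,
            "np": self.nparams,
            "class_weights": list(self.class_weights),
            "class_omegas": list(self.class_omegas),
            "site_class_loglik": self.site_class_loglik.tolist(),
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CodonSiteModelResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        params = SiteClassModel(payload["model_id"], **{
            k: v for k, v in payload["params"].items() if k != "model_id"
        })
        return cls(
            model=None,
            model_id=payload["model_id"],
            params=params,
            kappa=payload["kappa"],
            tree_scale=payload["tree_scale"],
            branch_lengths=None
            if payload["branch_lengths"] is None
            else np.array(payload["branch_lengths"]),
            lnL=payload["lnL"],
            nparams=payload["np"],
            class_weights=np.array(payload["class_weights"]),
            class_omegas=np.array(payload["class_omegas"]),
            site_class_loglik=np.array(payload["site_class_loglik"]),
            converged=payload["converged"],
            n_restarts_used=payload["n_restarts_used"],
        )
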