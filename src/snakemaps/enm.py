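"""Maxent-style presence-background niche model.

The model is the penalized Gibbs (maximum-entropy) density over the
landscape cells: p_w(x) proportional to exp(w . f(x)), fitted by
maximizing the L1-penalized log-likelihood of the presence sample with
the normalizer taken over the background-union-presence cells.  Feature
classes follow the classic Maxent repertoire — linear, quadratic,
pairwise product, and forward/reverse hinge — and prediction clamps
every variable to its training range so projections never extrapolate.

Output is the Maxent logistic transform (default prevalence 0.5):
``c * p / (1 + c * p)`` with ``c = exp(H)``, H the entropy of the
fitted density over the training cells.

The L1 penalty per feature is ``beta * sd(f) / sqrt(n_presences)``
(features are standardized internally, so the per-feature penalty is
``beta / sqrt(n)`` on the standardized scale), shrinking weights of
uninformative features exactly to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid import Grid, check_aligned

N_HINGE_KNOTS = 10


class ConvergenceError(RuntimeError):
    def __init__(self, n_iter: int, message: str = ""):
        self.n_iter = n_iter
        super().__init__(f"optimizer failed to converge after {n_iter} iterations {message}")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def hinge_value(x: np.ndarray, knot: float, lo: float, hi: float, forward: bool) -> np.ndarray:
    """Hinge feature normalized to [0, 1] over the training range.

    Forward: ramps 0 -> 1 from the knot to the training max; reverse
    ramps from the knot down to the training min.  A forward hinge with
    its knot at the training max (or reverse at the min) is identically
    zero.
    """
    x = np.asarray(x, dtype=float)
    if forward:
        denom = hi - knot
        if denom <= 0:
            return np.zeros_like(x)
        return np.clip((x - knot) / denom, 0.0, 1.0)
    denom = knot - lo
    if denom <= 0:
        return np.zeros_like(x)
    return np.clip((knot - x) / denom, 0.0, 1.0)


@dataclass
class FeatureSet:
    """Feature expansion with the training ranges needed for clamping."""

    variables: list[str]
    classes: tuple[str, ...]
    mins: dict[str, float]
    maxs: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float]
    terms: list[tuple] = field(default_factory=list)  # (kind, *params)
    n_knots: int = N_HINGE_KNOTS

    @property
    def names(self) -> list[str]:
        out = []
        for t in self.terms:
            kind = t[0]
            if kind in ("linear", "quadratic"):
                out.append(f"{kind}:{t[1]}")
            elif kind == "product":
                out.append(f"product:{t[1]}*{t[2]}")
            else:
                out.append(f"{kind}:{t[1]}@{t[2]:.6g}")
        return out

    def clamp(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict every variable to its training [min, max]."""
        X = X.copy()
        for v in self.variables:
            X[v] = X[v].clip(self.mins[v], self.maxs[v])
        return X

    def _z(self, X: pd.DataFrame, v: str) -> np.ndarray:
        sd = self.sds[v] if self.sds[v] > 0 else 1.0
        return (X[v].to_numpy(dtype=float) - self.means[v]) / sd

    def transform(self, X: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        missing = [v for v in self.variables if v not in X.columns]
        if missing:
            raise KeyError(f"missing variable(s): {', '.join(missing)}")
        if clamp:
            X = self.clamp(X)
        cols = []
        for t in self.terms:
            kind = t[0]
            if kind == "linear":
                cols.append(self._z(X, t[1]))
            elif kind == "quadratic":
                cols.append(self._z(X, t[1]) ** 2)
            elif kind == "product":
                cols.append(self._z(X, t[1]) * self._z(X, t[2]))
            else:  # hinge
                v, knot = t[1], t[2]
                cols.append(
                    hinge_value(
                        X[v].to_numpy(dtype=float),
                        knot,
                        self.mins[v],
                        self.maxs[v],
                        forward=(kind == "hinge_fwd"),
                    )
                )
        return np.column_stack(cols)


def build_features(
    values: pd.DataFrame,
    classes: tuple[str, ...] = ("linear", "quadratic", "product", "hinge"),
    allow_product: bool = True,
    n_knots: int = N_HINGE_KNOTS,
) -> FeatureSet:
    """Define the feature expansion from training-sample values.

    Linear and quadratic terms are always present; pairwise products only
    when ``allow_product`` (they are suppressed for data-sparse,
    range-restricted units to curb overfitting); hinges at ``n_knots``
    evenly spaced knots per variable per direction.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 samples to define features")
    variables = list(values.columns)
    fs = FeatureSet(
        variables=variables,
        classes=tuple(classes),
        mins={v: float(values[v].min()) for v in variables},
        maxs={v: float(values[v].max()) for v in variables},
        means={v: float(values[v].mean()) for v in variables},
        sds={v: float(values[v].std(ddof=0)) for v in variables},
        n_knots=n_knots,
    )
    for v in variables:
        fs.terms.append(("linear", v))
        if "quadratic" in classes:
            fs.terms.append(("quadratic", v))
    if "product" in classes and allow_product:
        for a in range(len(variables)):
            for b in range(a + 1, len(variables)):
                fs.terms.append(("product", variables[a], variables[b]))
    if "hinge" in classes:
        for v in variables:
            lo, hi = fs.mins[v], fs.maxs[v]
            if hi <= lo:
                continue
            knots = np.linspace(lo, hi, n_knots + 1)
            for k in knots[:-1]:  # forward hinge at max would be identically 0
                fs.terms.append(("hinge_fwd", v, float(k)))
            for k in knots[1:]:
                fs.terms.append(("hinge_rev", v, float(k)))
    return fs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    features: FeatureSet
    weights: np.ndarray          # on the standardized-feature scale
    f_mean: np.ndarray
    f_sd: np.ndarray
    log_z: float                 # log normalizer over training cells
    entropy: float               # entropy of fitted density over training cells
    beta: float
    n_presence: int
    threshold: float | None = None          # balance threshold t*
    cv_auc: list[float] | None = None
    importances: dict[str, float] | None = None
    train_presence_scores: np.ndarray | None = None
    train_scores: np.ndarray | None = None  # logistic over bg u presence cells
    train_raw: np.ndarray | None = None     # fitted density q over training cells

    def _eta(self, F: np.ndarray) -> np.ndarray:
        Fz = (F - self.f_mean) / self.f_sd
        return Fz @ self.weights

    def score_rows(self, X: pd.DataFrame, clamp: bool = True) -> np.ndarray:
        """Logistic suitability for rows of environmental values."""
        F = self.features.transform(X, clamp=clamp)
        return self._logistic(self._eta(F))

    def _logistic(self, eta: np.ndarray) -> np.ndarray:
        # Maxent logistic output with prevalence tau = 0.5
        log_cp = self.entropy + eta - self.log_z
        return 1.0 / (1.0 + np.exp(-log_cp))

    @property
    def nonzero_weights(self) -> int:
        return int(np.sum(np.abs(self.weights) > 1e-10))


def fit_model(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    features: FeatureSet | None = None,
    beta: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    allow_product: bool = True,
) -> FittedModel:
    """Fit the penalized Gibbs model to presence and background samples.

    The likelihood is evaluated over the union of background and
    presence rows (the training cells); the L1 penalty uses
    ``beta / sqrt(n_presence)`` per standardized feature.
    """
    if len(presence) < 2:
        raise ValueError("need at least 2 presence rows")
    if len(background) < 10:
        raise ValueError("need at least 10 background rows")
    if features is None:
        features = build_features(
            pd.concat([background, presence], ignore_index=True),
            allow_product=allow_product,
        )
    X_all = pd.concat([background, presence], ignore_index=True)
    F_all = features.transform(X_all)
    F_pres = features.transform(presence)
    f_mean = F_all.mean(axis=0)
    f_sd = F_all.std(axis=0)
    f_sd[f_sd == 0] = 1.0
    Fz_all = (F_all - f_mean) / f_sd
    Fz_pres = (F_pres - f_mean) / f_sd
    n_pres = len(presence)
    n_feat = F_all.shape[1]
    lam = beta / np.sqrt(n_pres)
    mean_pres = Fz_pres.mean(axis=0)

    def objective(wpm: np.ndarray):
        w = wpm[:n_feat] - wpm[n_feat:]
        eta = Fz_all @ w
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        nll = -mean_pres @ w + lz - np.log(len(eta))
        grad_w = -mean_pres + q @ Fz_all
        grad = np.concatenate([grad_w + lam, -grad_w + lam])
        return nll + lam * wpm.sum(), grad

    x0 = np.zeros(2 * n_feat)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * n_feat),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not res.success and "ITERATIONS" in (res.message or "").upper():
        raise ConvergenceError(res.nit)
    w = res.x[:n_feat] - res.x[n_feat:]
    eta_all = Fz_all @ w
    log_z = float(logsumexp(eta_all))
    q = np.exp(eta_all - log_z)
    entropy = float(-np.sum(q * np.log(np.clip(q, 1e-300, None))))
    model = FittedModel(
        features=features,
        weights=w,
        f_mean=f_mean,
        f_sd=f_sd,
        log_z=log_z,
        entropy=entropy,
        beta=beta,
        n_presence=n_pres,
        train_raw=q,
    )
    model.train_scores = model._logistic(eta_all)
    model.train_presence_scores = model._logistic(Fz_pres @ w)
    model.threshold = balance_threshold(model)
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: FittedModel, stack: dict[str, Grid]) -> Grid:
    """Project the model to a raster stack (clamped; nodata propagates)."""
    missing = [v for v in model.features.variables if v not in stack]
    if missing:
        raise KeyError(f"stack is missing model variable(s): {', '.join(missing)}")
    spec = check_aligned(*[stack[v] for v in model.features.variables])
    flat = pd.DataFrame(
        {v: stack[v].values.ravel() for v in model.features.variables}
    )
    valid = ~flat.isna().any(axis=1)
    out = np.full(spec.shape[0] * spec.shape[1], np.nan)
    if valid.any():
        out[valid.to_numpy()] = model.score_rows(flat.loc[valid], clamp=True)
    return Grid(spec, out.reshape(spec.shape))


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------

def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    from .validation import auc

    return auc(pos, neg)


def cross_validate(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    beta: float = 1.0,
    allow_product: bool = True,
) -> list[float]:
    """k repeated random train/test presence splits; returns the test AUCs.

    Each replicate trains on ``train_frac`` of the presences (background
    shared across replicates) and scores the held-out presences against
    the background sample.
    """
    n = len(presence)
    if n < 10:
        raise ValueError("need at least 10 presences to cross-validate")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("train fraction leaves too few presences for train or test")
    aucs = []
    for _ in range(k):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_model(
            presence.iloc[tr], background, beta=beta, allow_product=allow_product
        )
        test_scores = model.score_rows(presence.iloc[te])
        bg_scores = model.score_rows(background)
        aucs.append(_auc(test_scores, bg_scores))
    return aucs


def permutation_importance(
    model: FittedModel,
    presence: pd.DataFrame,
    background: pd.DataFrame,
    n_perm: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Per-variable importance as normalized drop in training AUC.

    Each variable's column is permuted jointly across presence and
    background rows; the mean AUC drop over ``n_perm`` permutations is
    clipped at zero and normalized so importances sum to 100%.
    """
    rng = np.random.default_rng(seed)
    X = pd.concat([presence, background], ignore_index=True)
    n_pres = len(presence)
    base_pres = model.score_rows(presence)
    base_bg = model.score_rows(background)
    base_auc = _auc(base_pres, base_bg)
    drops = {}
    for v in model.features.variables:
        d = 0.0
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[v] = rng.permutation(Xp[v].to_numpy())
            scores = model.score_rows(Xp)
            d += base_auc - _auc(scores[:n_pres], scores[n_pres:])
        drops[v] = max(d / n_perm, 0.0)
    total = sum(drops.values())
    if total == 0:
        return {v: 100.0 / len(drops) for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def cv_with_importance(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    n_perm: int = 2,
    beta: float = 1.0,
    allow_product: bool = True,
) -> tuple[list[float], dict[str, float]]:
    """One CV pass returning both test AUCs and CV-averaged importances.

    Shares the fitted replicate models between evaluation and
    permutation importance, halving the cost of the 'starting' stage.
    """
    n = len(presence)
    if n < 10:
        raise ValueError("need at least 10 presences to cross-validate")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("train fraction leaves too few presences for train or test")
    aucs: list[float] = []
    acc: dict[str, float] = {}
    for rep in range(k):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_model(
            presence.iloc[tr], background, beta=beta, allow_product=allow_product
        )
        bg_scores = model.score_rows(background)
        aucs.append(_auc(model.score_rows(presence.iloc[te]), bg_scores))
        imp = permutation_importance(
            model, presence.iloc[tr], background, n_perm=n_perm,
            seed=seed + 1000 + rep,
        )
        for v, x in imp.items():
            acc[v] = acc.get(v, 0.0) + x
    total = sum(acc.values())
    return aucs, {v: 100.0 * x / total for v, x in acc.items()}


def cv_permutation_importance(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    k: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    n_perm: int = 3,
    beta: float = 1.0,
    allow_product: bool = True,
) -> dict[str, float]:
    """Permutation importance averaged over k cross-validation replicates."""
    n = len(presence)
    rng = np.random.default_rng(seed)
    n_train = max(int(round(train_frac * n)), 2)
    acc: dict[str, float] = {}
    for rep in range(k):
        perm = rng.permutation(n)
        model = fit_model(
            presence.iloc[perm[:n_train]], background, beta=beta,
            allow_product=allow_product,
        )
        imp = permutation_importance(
            model, presence.iloc[perm[:n_train]], background,
            n_perm=n_perm, seed=seed + 1000 + rep,
        )
        for v, x in imp.items():
            acc[v] = acc.get(v, 0.0) + x
    total = sum(acc.values())
    return {v: 100.0 * x / total for v, x in acc.items()}


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def balance_threshold(model: FittedModel) -> float:
    """The 'balance training omission, predicted area and threshold' cut-off.

    Minimizes ``6*omission(t) + 0.04*cumulative(t) + 1.6*area(t)`` over
    candidate thresholds (the observed training scores), where omission
    is the fraction of training presences scoring below t, area the
    fraction of training cells at or above t, and cumulative the
    percentage of fitted raw density below t.
    """
    scores = model.train_scores
    pres = np.sort(model.train_presence_scores)
    order = np.argsort(scores)
    s_sorted = scores[order]
    q_cum = np.concatenate([[0.0], np.cumsum(model.train_raw[order])])
    cands = np.unique(np.concatenate([scores, pres]))
    # counts strictly below each candidate, via searchsorted on sorted arrays
    n_below = np.searchsorted(s_sorted, cands, side="left")
    omission = np.searchsorted(pres, cands, side="left") / len(pres)
    area = 1.0 - n_below / len(scores)
    cumulative = 100.0 * q_cum[n_below]
    obj = 6.0 * omission + 0.04 * cumulative + 1.6 * area
    return float(cands[int(np.argmin(obj))])


def threshold_and_rescale(suit: Grid, threshold: float) -> Grid:
    """Zero cells below the balance threshold, then rescale to [0, 1].

    The surviving values are min-max rescaled over the thresholded grid
    (whose minimum is 0 whenever any cell was cut), so the maximum
    becomes exactly 1 and outputs of models with different thresholds
    are comparable.
    """
    v = suit.values.copy()
    cut = v < threshold
    v[cut & ~np.isnan(v)] = 0.0
    finite = v[~np.isnan(v)]
    if finite.size == 0 or finite.max() == 0:
        warnings.warn("all cells fall below the balance threshold; grid is all zero")
        return Grid(suit.spec, v)
    vmin, vmax = finite.min(), finite.max()
    if vmax > vmin:
        v = np.where(np.isnan(v), np.nan, (v - vmin) / (vmax - vmin))
    else:
        v = np.where(np.isnan(v), np.nan, 1.0)
    return Grid(suit.spec, v)


def model_to_json(model: FittedModel) -> str:
    import json

    fs = model.features
    payload = {
        "variables": fs.variables,
        "classes": list(fs.classes),
        "mins": fs.mins,
        "maxs": fs.maxs,
        "means": fs.means,
        "sds": fs.sds,
        "terms": [list(t) for t in fs.terms],
        "n_knots": fs.n_knots,
        "weights": model.weights.tolist(),
        "f_mean": model.f_mean.tolist(),
        "f_sd": model.f_sd.tolist(),
        "log_z": model.log_z,
        "entropy": model.entropy,
        "beta": model.beta,
        "n_presence": model.n_presence,
        "threshold": model.threshold,
        "cv_auc": model.cv_auc,
        "importances": model.importances,
    }
    return json.dumps(payload)


def model_from_json(text: str) -> FittedModel:
    import json

    d = json.loads(text)
    fs = FeatureSet(
        variables=d["variables"],
        classes=tuple(d["classes"]),
        mins=d["mins"],
        maxs=d["maxs"],
        means=d["means"],
        sds=d["sds"],
        terms=[tuple(t) for t in d["terms"]],
        n_knots=d["n_knots"],
    )
    return FittedModel(
        features=fs,
        weights=np.asarray(d["weights"]),
        f_mean=np.asarray(d["f_mean"]),
        f_sd=np.asarray(d["f_sd"]),
        log_z=d["log_z"],
        entropy=d["entropy"],
        beta=d["beta"],
        n_presence=d["n_presence"],
        threshold=d["threshold"],
        cv_auc=d["cv_auc"],
        importances=d["importances"],
    )


def extract_values(stack: dict[str, Grid], cells: np.ndarray) -> pd.DataFrame:
    """Environmental values at (row, col) cells, as a samples x variables table."""
    return pd.DataFrame(
        {v: g.values[cells[:, 0], cells[:, 1]] for v, g in stack.items()}
    )
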